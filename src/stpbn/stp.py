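"""Semi-tensor product algebra on canonical basis vectors and logical matrices.

A Boolean value and, more generally, the joint ("integrated") state of an
n-node Boolean network are represented as canonical basis vectors
``e_d^j`` — column *j* of the *d*×*d* identity matrix — stored compactly as
the pair ``(dim, index)``.  The convention is

* logical 1 (true)  ↦ ``e_2^1`` = (1, 0)ᵀ,
* logical 0 (false) ↦ ``e_2^2`` = (0, 1)ᵀ,

and the integrated state of *n* nodes is the semi-tensor product of the
per-node vectors, which is again a basis vector of dimension 2ⁿ (the
all-ones state is ``e_{2^n}^1``, the all-zeros state ``e_{2^n}^{2^n}``).

Matrices whose every column is a canonical basis vector ("logical
matrices") are stored as a per-column row-index list.  Semi-tensor products
of logical matrices then reduce to integer index composition; dense arrays
are materialized only when a general (non-logical) operand is involved or
at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LogicalVector",
    "LogicalMatrix",
    "semi_tensor_product",
    "stp",
    "power_reducing_matrix",
    "dummy_matrix",
    "encode_state",
    "decode_state",
    "boolean_vector",
]


@dataclass(frozen=True)
class LogicalVector:
    """Canonical basis vector ``e_dim^index`` (1-based index)."""

    dim: int
    index: int

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dimension must be positive, got {self.dim}")
        if not 1 <= self.index <= self.dim:
            raise ValueError(
                f"index {self.index} out of range for dimension {self.dim}"
            )

    def dense(self) -> np.ndarray:
        """Column vector of shape ``(dim, 1)`` with a single 1."""
        v = np.zeros((self.dim, 1), dtype=np.int64)
        v[self.index - 1, 0] = 1
        return v

    def as_matrix(self) -> "LogicalMatrix":
        return LogicalMatrix(self.dim, 1, (self.index,))

    def __repr__(self) -> str:  # e_16^8 style, matching the field notation
        return f"e_{self.dim}^{self.index}"


@dataclass(frozen=True)
class LogicalMatrix:
    """0/1 matrix with exactly one 1 per column, stored by column indices.

    ``col_index[j-1]`` is the (1-based) row of the single 1 in column *j*.
    """

    rows: int
    cols: int
    col_index: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "col_index", tuple(self.col_index))
        if len(self.col_index) != self.cols:
            raise ValueError(
                f"expected {self.cols} column indices, got {len(self.col_index)}"
            )
        for r in self.col_index:
            if not 1 <= r <= self.rows:
                raise ValueError(f"row index {r} out of range [1, {self.rows}]")

    @classmethod
    def from_dense(cls, arr: np.ndarray) -> "LogicalMatrix":
        arr = np.asarray(arr)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D array")
        rows, cols = arr.shape
        col_index = []
        for j in range(cols):
            nz = np.flatnonzero(arr[:, j])
            if len(nz) != 1 or arr[nz[0], j] != 1:
                raise ValueError(f"column {j + 1} is not a canonical basis vector")
            col_index.append(int(nz[0]) + 1)
        return cls(rows, cols, tuple(col_index))

    @classmethod
    def identity(cls, n: int) -> "LogicalMatrix":
        return cls(n, n, tuple(range(1, n + 1)))

    def dense(self) -> np.ndarray:
        out = np.zeros((self.rows, self.cols), dtype=np.int64)
        for j, r in enumerate(self.col_index):
            out[r - 1, j] = 1
        return out

    def column(self, j: int) -> LogicalVector:
        """Column *j* (1-based) as a basis vector."""
        return LogicalVector(self.rows, self.col_index[j - 1])

    def kron(self, other: "LogicalMatrix") -> "LogicalMatrix":
        """Kronecker product of two logical matrices (again logical)."""
        br, bc = other.rows, other.cols
        col_index = tuple(
            (ra - 1) * br + rb
            for ra in self.col_index
            for rb in other.col_index
        )
        return LogicalMatrix(self.rows * br, self.cols * bc, col_index)


def _lcm(a: int, b: int) -> int:
    return math.lcm(a, b)


def _coerce_logical(x) -> LogicalMatrix | None:
    if isinstance(x, LogicalMatrix):
        return x
    if isinstance(x, LogicalVector):
        return x.as_matrix()
    return None


def _stp_logical(a: LogicalMatrix, b: LogicalMatrix) -> LogicalMatrix:
    # C = (A ⊗ I_s)(B ⊗ I_t) with s = α/n, t = α/p, evaluated purely on
    # column indices: both Kronecker lifts are logical, so composition is
    # an integer map.
    n, p = a.cols, b.rows
    alpha = _lcm(n, p)
    s, t = alpha // n, alpha // p
    col_index = []
    for u in range(b.cols * t):  # 0-based output column
        j, r = divmod(u, t)
        mid = (b.col_index[j] - 1) * t + r  # 0-based row in B ⊗ I_t
        ja, ra = divmod(mid, s)
        col_index.append((a.col_index[ja] - 1) * s + ra + 1)
    return LogicalMatrix(a.rows * s, b.cols * t, tuple(col_index))


def _as_dense_2d(x) -> np.ndarray:
    lg = _coerce_logical(x)
    if lg is not None:
        return lg.dense()
    arr = np.asarray(x)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if arr.ndim != 2:
        raise ValueError("semi-tensor product operands must be 2-D")
    return arr


def semi_tensor_product(a, b):
    """Semi-tensor product A ⋉ B = (A ⊗ I_{α/n})(B ⊗ I_{α/p}), α = lcm(n, p).

    *n* is the column count of *A* and *p* the row count of *B*; when
    ``n == p`` this reduces to the ordinary matrix product.  Accepts dense
    arrays (any dtype, including object arrays of symbolic entries),
    :class:`LogicalMatrix` and :class:`LogicalVector`; when both operands
    are logical the result is returned as a :class:`LogicalMatrix` computed
    by index composition, otherwise as a dense array.
    """
    la, lb = _coerce_logical(a), _coerce_logical(b)
    if la is not None and lb is not None:
        return _stp_logical(la, lb)
    da, db = _as_dense_2d(a), _as_dense_2d(b)
    n, p = da.shape[1], db.shape[0]
    alpha = _lcm(n, p)
    left = np.kron(da, np.eye(alpha // n, dtype=da.dtype))
    right = np.kron(db, np.eye(alpha // p, dtype=db.dtype))
    return left.dot(right)


def stp(*operands):
    """Left-to-right chained semi-tensor product (the product is associative)."""
    if not operands:
        raise ValueError("stp requires at least one operand")
    result = operands[0]
    for x in operands[1:]:
        result = semi_tensor_product(result, x)
    return result


def power_reducing_matrix(n: int) -> LogicalMatrix:
    """Power-reducing matrix Φₙ (2²ⁿ × 2ⁿ): x ⋉ x = Φₙ ⋉ x for basis states.

    Column *j* has its single 1 at row (j−1)·2ⁿ + j, which is exactly where
    ``e_{2^n}^j ⋉ e_{2^n}^j`` lands in dimension 2²ⁿ.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    d = 2**n
    return LogicalMatrix(d * d, d, tuple((j - 1) * d + j for j in range(1, d + 1)))


def dummy_matrix() -> LogicalMatrix:
    """The dummy operator E = (1 1 0 0 / 0 0 1 1).

    ``E ⋉ x ⋉ y = x`` for Boolean vectors x, y: pre-multiplying a structure
    matrix by E makes the function ignore one extra trailing variable.
    """
    return LogicalMatrix(2, 4, (1, 1, 2, 2))


def boolean_vector(value) -> LogicalVector:
    """Vector form of a Boolean scalar: 1 ↦ (1,0)ᵀ = e_2^1, 0 ↦ (0,1)ᵀ = e_2^2."""
    if value not in (0, 1, True, False):
        raise ValueError(f"Boolean value must be 0 or 1, got {value!r}")
    return LogicalVector(2, 1 if value else 2)


def encode_state(bits: Sequence[int] | Iterable[int]) -> LogicalVector:
    """Encode an ordered 0/1 tuple as the integrated-state basis vector.

    ``index = 2^n − Σ bits[i]·2^{n−i}`` (1-based i), so the all-ones tuple
    maps to index 1 and the all-zeros tuple to index 2ⁿ.  Equal to the
    chained semi-tensor product of the per-bit Boolean vectors.
    """
    bits = tuple(bits)
    if not bits:
        raise ValueError("state must have at least one bit")
    n = len(bits)
    acc = 0
    for b in bits:
        if b not in (0, 1, True, False):
            raise ValueError(f"state bits must be 0/1, got {b!r}")
        acc = (acc << 1) | int(b)
    return LogicalVector(2**n, 2**n - acc)


def decode_state(index: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state`: basis index (1-based) → 0/1 tuple."""
    d = 2**n
    if not 1 <= index <= d:
        raise ValueError(f"index {index} out of range [1, {d}]")
    acc = d - index
    return tuple((acc >> (n - 1 - i)) & 1 for i in range(n))
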