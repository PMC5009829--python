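"""Boolean network definitions and global transition-matrix construction.

A synchronous Boolean network is an ordered list of nodes, one update
expression per node, and optionally control-input symbols.  A closed
network (no unbound inputs) induces a deterministic successor map on its
2ⁿ integrated states; that map is the transition matrix L with
x(k+1) = L ⋉ x(k).

Two constructions of L are provided: direct state enumeration (the
normative, semantic definition — column j encodes the update of the state
decoded from j) and the algebraic product

    Lₙ = M₁ ⋉ ∏_{i=2..n} [(I_{2ⁿ} ⊗ Mᵢ) ⋉ Φₙ],

where Mᵢ is node i's structure matrix and Φₙ the power-reducing matrix.
The two must agree exactly; the algebraic route is evaluated entirely on
logical-matrix column indices, so it stays cheap for n well beyond the
sizes a dense 2ⁿ×2ⁿ product would allow.

Network file format (text)::

    # comment
    input u
    x1 = !x2
    x2 = x1 & u

one ``name = expression`` line per node and optional ``input`` declarations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ExpressionError, NetworkError
from .logic import (Expr, Var, evaluate, parse_expression, serialize,
                    structure_matrix)
from .stp import (LogicalMatrix, decode_state, encode_state,
                  power_reducing_matrix, semi_tensor_product)

__all__ = [
    "BooleanNetwork",
    "TransitionMatrix",
    "parse_network",
    "transition_matrix_direct",
    "transition_matrix_stp",
    "node_truth_tables",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """The 2ⁿ×2ⁿ logical matrix L of a closed n-node network.

    Stored as the successor index list: column j of L is
    ``e_{2^n}^{successor[j-1]}``, i.e. integrated state j steps to
    integrated state ``successor[j-1]``.
    """

    n: int
    successor: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "successor", tuple(self.successor))
        d = 2**self.n
        if len(self.successor) != d:
            raise ValueError(f"expected {d} columns, got {len(self.successor)}")
        for s in self.successor:
            if not 1 <= s <= d:
                raise ValueError(f"successor index {s} out of range [1, {d}]")

    @property
    def num_states(self) -> int:
        return 2**self.n

    def successor_of(self, j: int) -> int:
        if not 1 <= j <= self.num_states:
            raise ValueError(f"state index {j} out of range [1, {self.num_states}]")
        return self.successor[j - 1]

    def as_logical(self) -> LogicalMatrix:
        return LogicalMatrix(self.num_states, self.num_states, self.successor)

    @classmethod
    def from_logical(cls, m: LogicalMatrix) -> "TransitionMatrix":
        if m.rows != m.cols or m.rows & (m.rows - 1):
            raise ValueError(f"not a square power-of-2 logical matrix: {m.rows}x{m.cols}")
        return cls(m.rows.bit_length() - 1, m.col_index)

    def dense(self) -> np.ndarray:
        return self.as_logical().dense()

    def successor_list_str(self) -> str:
        """Compact column form, e.g. ``(e_16^14, e_16^10, ...)``."""
        d = self.num_states
        return "(" + ", ".join(f"e_{d}^{s}" for s in self.successor) + ")"


@dataclass(frozen=True)
class BooleanNetwork:
    """Ordered nodes with per-node update expressions and optional inputs."""

    nodes: tuple[str, ...]
    updates: tuple[Expr, ...]
    inputs: tuple[str, ...] = ()
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "updates", tuple(self.updates))
        object.__setattr__(self, "inputs", tuple(self.inputs))
        if not self.nodes:
            raise NetworkError("a network needs at least one node")
        if len(self.updates) != len(self.nodes):
            raise NetworkError("one update expression per node is required")
        symbols = set(self.nodes) | set(self.inputs)
        if len(symbols) != len(self.nodes) + len(self.inputs):
            raise NetworkError("node/input names must be unique")
        for name, expr in zip(self.nodes, self.updates):
            extra = expr.variables() - symbols
            if extra:
                raise NetworkError(
                    f"update of {name!r} references undeclared symbols {sorted(extra)}")

    @classmethod
    def from_strings(cls, updates: Mapping[str, str],
                     inputs: Sequence[str] = (), name: str = "") -> "BooleanNetwork":
        """Build from ``{node: expression text}`` (insertion order = node order)."""
        nodes = tuple(updates)
        symbols = list(nodes) + list(inputs)
        exprs = tuple(parse_expression(text, symbols) for text in updates.values())
        return cls(nodes, exprs, tuple(inputs), name=name)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def is_closed(self) -> bool:
        return not self.inputs

    def update_of(self, node: str) -> Expr:
        return self.updates[self.nodes.index(node)]

    def bind_input(self, input_name: str, law: Expr | str) -> "BooleanNetwork":
        """Close the loop: substitute a feedback expression for one input.

        The law may reference any node (state feedback) but no input.
        """
        if input_name not in self.inputs:
            raise NetworkError(f"{input_name!r} is not a declared input")
        if isinstance(law, str):
            law = parse_expression(law, self.nodes)
        if law.variables() - set(self.nodes):
            raise NetworkError("a feedback law may only reference state nodes")
        new_updates = tuple(_substitute(e, input_name, law) for e in self.updates)
        new_inputs = tuple(u for u in self.inputs if u != input_name)
        return replace(self, updates=new_updates, inputs=new_inputs)

    def step(self, bits: Sequence[int],
             input_values: Mapping[str, int] | None = None) -> tuple[int, ...]:
        """One synchronous update from an ordered 0/1 node-state tuple."""
        if len(bits) != self.n:
            raise NetworkError(f"expected {self.n} bits, got {len(bits)}")
        assignment = dict(zip(self.nodes, (int(b) for b in bits)))
        if self.inputs:
            if input_values is None:
                raise NetworkError(f"values required for inputs {list(self.inputs)}")
            for u in self.inputs:
                if u not in input_values:
                    raise NetworkError(f"no value for input {u!r}")
                assignment[u] = int(input_values[u])
        return tuple(evaluate(e, assignment) for e in self.updates)

    def to_text(self) -> str:
        """Serialize in the network file format."""
        lines = [f"# {self.name}"] if self.name else []
        lines += [f"input {u}" for u in self.inputs]
        lines += [f"{name} = {serialize(expr)}"
                  for name, expr in zip(self.nodes, self.updates)]
        return "\n".join(lines) + "\n"


def _substitute(e: Expr, name: str, replacement: Expr) -> Expr:
    from .logic import BinOp, Const, Not  # local import avoids cycles at module load
    if isinstance(e, Var):
        return replacement if e.name == name else e
    if isinstance(e, Const):
        return e
    if isinstance(e, Not):
        return Not(_substitute(e.child, name, replacement))
    assert isinstance(e, BinOp)
    return BinOp(e.op, _substitute(e.left, name, replacement),
                 _substitute(e.right, name, replacement))


def parse_network(text: str, name: str = "") -> BooleanNetwork:
    """Parse the network file format (see module docstring)."""
    input_names: list[str] = []
    node_lines: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("input "):
            for u in line[len("input "):].replace(",", " ").split():
                input_names.append(u)
            continue
        if "=" not in line:
            raise NetworkError(f"line {lineno}: expected 'name = expression': {raw!r}")
        node, expr_text = line.split("=", 1)
        node_lines.append((node.strip(), expr_text.strip(), lineno))
    nodes = [n for n, _, _ in node_lines]
    symbols = nodes + input_names
    updates = []
    for node, expr_text, lineno in node_lines:
        try:
            updates.append(parse_expression(expr_text, symbols))
        except ExpressionError as exc:
            raise NetworkError(f"line {lineno}, node {node!r}: {exc}") from exc
    return BooleanNetwork(tuple(nodes), tuple(updates), tuple(input_names), name=name)


def _require_closed(net: BooleanNetwork) -> None:
    if not net.is_closed:
        raise NetworkError(
            f"network has unbound inputs {list(net.inputs)}; bind them first "
            "(e.g. with bind_input) to obtain a square transition matrix")


def transition_matrix_direct(net: BooleanNetwork) -> TransitionMatrix:
    """L by direct state enumeration (normative definition).

    Column j encodes the synchronous update of the state decoded from j:
    ``successor[j] = encode(net.step(decode(j)))``.
    """
    _require_closed(net)
    n = net.n
    successor = tuple(
        encode_state(net.step(decode_state(j, n))).index
        for j in range(1, 2**n + 1)
    )
    return TransitionMatrix(n, successor)


def transition_matrix_stp(net: BooleanNetwork) -> TransitionMatrix:
    """L by the semi-tensor-product formula.

    Builds each node's structure matrix Mᵢ and evaluates
    ``L = M₁ ⋉ ∏_{i=2..n} [(I_{2ⁿ} ⊗ Mᵢ) ⋉ Φₙ]`` left to right on logical
    matrices.  Must equal :func:`transition_matrix_direct` exactly; a
    mismatch would indicate an internal inconsistency, not a user error.
    """
    _require_closed(net)
    n = net.n
    mats = [structure_matrix(expr, net.nodes) for expr in net.updates]
    result: LogicalMatrix = mats[0]
    if n > 1:
        phi = power_reducing_matrix(n)
        eye = LogicalMatrix.identity(2**n)
        for m_i in mats[1:]:
            factor = semi_tensor_product(eye.kron(m_i), phi)
            result = semi_tensor_product(result, factor)
    if (result.rows, result.cols) != (2**n, 2**n):
        raise AssertionError(
            f"semi-tensor product chain produced a {result.rows}x{result.cols} "
            f"matrix; expected {2**n}x{2**n}")
    return TransitionMatrix.from_logical(result)


def node_truth_tables(L: TransitionMatrix) -> list[np.ndarray]:
    """Per-node next-state truth tables read off a transition matrix.

    Entry j of table i is bit i of the decoded successor of state j — the
    truth table (in integrated-state order) of node i's update function.
    """
    n = L.n
    tables = [np.empty(L.num_states, dtype=np.int64) for _ in range(n)]
    for j in range(1, L.num_states + 1):
        bits = decode_state(L.successor_of(j), n)
        for i in range(n):
            tables[i][j - 1] = bits[i]
    return tables
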