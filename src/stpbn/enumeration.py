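"""Enumeration of reachable networks and recovery of simplest dynamics.

For two nodes, each node's update is one of the 2⁴ Boolean functions of
(x₁, x₂), so there are 2⁴·2⁴ = 256 structure-matrix combinations (M₁, M₂).
Building L column-wise — column j of L encodes the pair of truth-table
entries (M₁ⱼ, M₂ⱼ) — and keeping only reachable networks leaves exactly
six distinct transition matrices: the six single 4-cycle permutations.
They pair up under swapping x₁ with x₂ (conjugating L by the induced state
permutation maps each form onto its partner).

For general n, the reachable transition matrices are the single
2ⁿ-cycle permutations, of which there are (2ⁿ − 1)!.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from math import factorial
from typing import Iterator, Sequence

from .logic import Expr, minimize_to_sop
from .network import TransitionMatrix, node_truth_tables
from .reachability import is_reachable_network
from .stp import decode_state, encode_state

__all__ = [
    "CanonicalForm",
    "CANONICAL_TWO_NODE_SUCCESSORS",
    "enumerate_reachable_two_node",
    "enumerate_full_cycle_matrices",
    "count_full_cycle_matrices",
    "simplest_dynamics_from_L",
    "conjugate_by_state_permutation",
    "variable_swap_permutation",
]

#: Successor tuples of the six reachable 2-node forms, in canonical
#: (citable) order L1..L6.
CANONICAL_TWO_NODE_SUCCESSORS: tuple[tuple[int, ...], ...] = (
    (3, 1, 4, 2),
    (2, 4, 1, 3),
    (4, 1, 2, 3),
    (4, 3, 1, 2),
    (2, 3, 4, 1),
    (3, 4, 2, 1),
)


@dataclass(frozen=True)
class CanonicalForm:
    """One reachable 2-node form: its L, minimized dynamics, swap partner.

    ``partner`` is the 0-based position (in the enumerated list) of the
    form obtained by swapping x₁ with x₂.
    """

    L: TransitionMatrix
    dynamics: tuple[Expr, ...]
    partner: int


def variable_swap_permutation(n: int, i: int, j: int) -> tuple[int, ...]:
    """State permutation induced by swapping node variables i and j (1-based).

    Entry k (1-based) is the image of integrated state k.
    """
    out = []
    for k in range(1, 2**n + 1):
        bits = list(decode_state(k, n))
        bits[i - 1], bits[j - 1] = bits[j - 1], bits[i - 1]
        out.append(encode_state(bits).index)
    return tuple(out)


def conjugate_by_state_permutation(L: TransitionMatrix,
                                   sigma: Sequence[int]) -> TransitionMatrix:
    """Relabel states by σ: the new successor map is σ ∘ s ∘ σ⁻¹."""
    d = L.num_states
    sigma = tuple(sigma)
    if sorted(sigma) != list(range(1, d + 1)):
        raise ValueError("sigma must be a permutation of 1..2^n")
    inv = [0] * d
    for j, s in enumerate(sigma, start=1):
        inv[s - 1] = j
    new_successor = tuple(sigma[L.successor_of(inv[m - 1]) - 1]
                          for m in range(1, d + 1))
    return TransitionMatrix(L.n, new_successor)


def enumerate_reachable_two_node(
        node_names: Sequence[str] = ("x1", "x2")) -> list[CanonicalForm]:
    """All reachable 2-node networks, reduced to their six simplest forms.

    Sweeps the 256 structure-matrix combinations, filters with the
    single-cycle reachability test, deduplicates at the transition-matrix
    level and orders the survivors canonically (L1..L6).  Dynamics are the
    exact-minimized representatives; partners are matched by conjugating
    with the x₁↔x₂ state swap.
    """
    found: set[tuple[int, ...]] = set()
    for m1_table in product((0, 1), repeat=4):
        for m2_table in product((0, 1), repeat=4):
            successor = tuple(
                encode_state((m1_table[j], m2_table[j])).index for j in range(4))
            L = TransitionMatrix(2, successor)
            if is_reachable_network(L):
                found.add(successor)
    ordered = [s for s in CANONICAL_TWO_NODE_SUCCESSORS if s in found]
    ordered += sorted(found - set(CANONICAL_TWO_NODE_SUCCESSORS))
    swap = variable_swap_permutation(2, 1, 2)
    forms = []
    for successor in ordered:
        L = TransitionMatrix(2, successor)
        partner_succ = conjugate_by_state_permutation(L, swap).successor
        forms.append(CanonicalForm(
            L=L,
            dynamics=tuple(simplest_dynamics_from_L(L, node_names)),
            partner=ordered.index(partner_succ),
        ))
    return forms


def count_full_cycle_matrices(n: int) -> int:
    """Number of reachable n-node transition matrices: (2ⁿ − 1)!."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return factorial(2**n - 1)


def enumerate_full_cycle_matrices(n: int,
                                  count_only: bool = False
                                  ) -> Iterator[TransitionMatrix] | int:
    """All transition matrices whose successor map is a single 2ⁿ-cycle.

    Full enumeration is refused for n > 3 — (2ⁿ − 1)! explodes — in which
    case pass ``count_only=True`` to get the count.
    """
    if count_only:
        return count_full_cycle_matrices(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > 3:
        raise ValueError(
            f"full enumeration for n={n} would yield {count_full_cycle_matrices(n)} "
            "matrices; use count_only=True")
    return _full_cycle_iter(n)


def _full_cycle_iter(n: int) -> Iterator[TransitionMatrix]:
    d = 2**n
    # a single d-cycle is determined by the visiting order after state 1
    for rest in permutations(range(2, d + 1)):
        order = (1,) + rest
        successor = [0] * d
        for a, b in zip(order, order[1:] + (1,)):
            successor[a - 1] = b
        yield TransitionMatrix(n, tuple(successor))


def simplest_dynamics_from_L(L: TransitionMatrix,
                             node_names: Sequence[str]) -> list[Expr]:
    """Recover minimized per-node update expressions from a transition matrix.

    Node i's truth table is bit i of the decoded successor across all
    columns; each table is exact-minimized, and rebuilding L from the
    returned dynamics reproduces it exactly.
    """
    node_names = list(node_names)
    if len(node_names) != L.n:
        raise ValueError(f"expected {L.n} node names, got {len(node_names)}")
    return [minimize_to_sop(table, node_names)
            for table in node_truth_tables(L)]
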