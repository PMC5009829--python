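"""State-feedback control synthesis by transition-matrix block doubling.

A lower-triangle network is one whose first n nodes update independently
of node n+1, while node n+1 carries the control input u.  If the n-node
base network is reachable (its transition matrix Lₙ is a single 2ⁿ-cycle),
a feedback law u(x₁..x_{n+1}) making the whole (n+1)-node network
reachable always exists, and it can be read off an extension of Lₙ:

Partition the target L_{n+1} into 2×2 blocks.  Each nonzero cell ("1-block")
of Lₙ at (i, j) doubles into one 2×2 block at block position (i, j) that is
either the identity (extended state 2j−1 → 2i−1, 2j → 2i) or the
skew-identity (2j−1 → 2i, 2j → 2i−1).  Collapsing the blocks always
recovers Lₙ; the extension is itself a single 2^{n+1}-cycle iff the number
of skew blocks around the base cycle is odd, because the blocks compose
around the base cycle and swap the two sheets of the doubling exactly when
an odd number of swaps occurs.

Given an odd-skew extension, node n+1's truth table is read off L_{n+1}
and exact-minimized into the feedback law u; substituting u for the input
closes the loop with transition matrix exactly L_{n+1}.

Structure matrices of the base nodes lift to the extended state space by
pre-multiplying with the dummy operator E = (1 1 0 0 / 0 0 1 1):
M* = E ⋉ M computes the same function while ignoring the appended variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import NetworkError, SynthesisError
from .logic import Expr, minimize_to_sop, structure_matrix
from .network import (BooleanNetwork, TransitionMatrix,
                      node_truth_tables, transition_matrix_direct)
from .reachability import is_reachable_network
from .stp import LogicalMatrix, dummy_matrix, semi_tensor_product

__all__ = [
    "BlockAssignment",
    "FeedbackLaw",
    "lift_structure_matrix",
    "extend_transition_matrix",
    "collapse_blocks",
    "is_extension_reachable",
    "synthesize_feedback_control",
    "synthesize_from_template",
]

IDENTITY = "identity"
SKEW = "skew"


@dataclass(frozen=True)
class BlockAssignment:
    """Per-1-block choice (identity | skew) for one doubling step.

    The base transition matrix has one 1-block per column; entry j−1 of
    ``entries`` is the block type for the base cell in column j (its row is
    the base successor of j).
    """

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        for e in self.entries:
            if e not in (IDENTITY, SKEW):
                raise ValueError(f"block type must be {IDENTITY!r} or {SKEW!r}, got {e!r}")

    @classmethod
    def all_identity(cls, num_blocks: int) -> "BlockAssignment":
        return cls((IDENTITY,) * num_blocks)

    @classmethod
    def single_skew(cls, num_blocks: int, column: int | None = None) -> "BlockAssignment":
        """One skew block, by default on the base cell with the largest column."""
        if column is None:
            column = num_blocks
        entries = [IDENTITY] * num_blocks
        entries[column - 1] = SKEW
        return cls(tuple(entries))

    @classmethod
    def from_cells(cls, cells: Iterable[tuple[tuple[int, int], str]],
                   L_base: TransitionMatrix) -> "BlockAssignment":
        """Build from ((row, column), type) pairs keyed by base 1-block cells.

        Unlisted blocks default to identity; a cell that is not a 1-block
        of ``L_base`` is rejected.
        """
        entries = [IDENTITY] * L_base.num_states
        for (i, j), kind in cells:
            if not 1 <= j <= L_base.num_states or L_base.successor_of(j) != i:
                raise ValueError(f"({i}, {j}) is not a 1-block of the base matrix")
            entries[j - 1] = kind
        return cls(tuple(entries))

    @property
    def skew_count(self) -> int:
        return sum(1 for e in self.entries if e == SKEW)

    def __len__(self) -> int:
        return len(self.entries)


def lift_structure_matrix(m: LogicalMatrix) -> LogicalMatrix:
    """M* = E ⋉ M: the same Boolean function on a state space with one more node.

    Column (2j−1) and column 2j of M* — the extended states that agree with
    base state j on the original nodes — both equal column j of M.
    """
    if m.rows != 2:
        raise ValueError(f"structure matrices have 2 rows, got {m.rows}")
    return semi_tensor_product(dummy_matrix(), m)


def extend_transition_matrix(L_base: TransitionMatrix,
                             assignment: BlockAssignment) -> TransitionMatrix:
    """Double every 1-block of the base matrix into an identity or skew block."""
    d = L_base.num_states
    if len(assignment) != d:
        raise ValueError(
            f"assignment has {len(assignment)} entries; the base matrix has {d} 1-blocks")
    successor = [0] * (2 * d)
    for j in range(1, d + 1):
        i = L_base.successor_of(j)
        if assignment.entries[j - 1] == IDENTITY:
            successor[2 * j - 2] = 2 * i - 1
            successor[2 * j - 1] = 2 * i
        else:
            successor[2 * j - 2] = 2 * i
            successor[2 * j - 1] = 2 * i - 1
    return TransitionMatrix(L_base.n + 1, tuple(successor))


def collapse_blocks(L_ext: TransitionMatrix) -> TransitionMatrix:
    """Collapse 2×2 blocks of an extended matrix back to the base matrix."""
    if L_ext.n < 2:
        raise ValueError("need at least 2 nodes to collapse")
    d = L_ext.num_states // 2
    successor = []
    for j in range(1, d + 1):
        a = (L_ext.successor_of(2 * j - 1) + 1) // 2
        b = (L_ext.successor_of(2 * j) + 1) // 2
        if a != b:
            raise ValueError(
                f"columns {2*j-1} and {2*j} do not form a 2x2 block (rows {a} vs {b})")
        successor.append(a)
    return TransitionMatrix(L_ext.n - 1, tuple(successor))


def is_extension_reachable(assignment: BlockAssignment,
                           L_base: TransitionMatrix) -> bool:
    """Parity rule: an odd number of skew blocks makes the doubling a single cycle.

    Requires a reachable base — around its single 2ⁿ-cycle the 2×2 blocks
    compose, and the two sheets of the doubling are exchanged exactly when
    the number of skew (swap) blocks is odd.
    """
    if not is_reachable_network(L_base):
        raise SynthesisError(
            "the base transition matrix must itself be reachable "
            "(a single full-length cycle)")
    if len(assignment) != L_base.num_states:
        raise ValueError(
            f"assignment has {len(assignment)} entries; the base matrix has "
            f"{L_base.num_states} 1-blocks")
    return assignment.skew_count % 2 == 1


@dataclass(frozen=True)
class FeedbackLaw:
    """Synthesized state-feedback law and its closed loop."""

    u: Expr
    lifted_structure_matrix: LogicalMatrix
    closed_loop: BooleanNetwork
    transition_matrix: TransitionMatrix
    assignment: BlockAssignment


def synthesize_feedback_control(base: BooleanNetwork,
                                new_node: str = "x3",
                                assignment: BlockAssignment | str = "default"
                                ) -> FeedbackLaw:
    """Extend a reachable base network by one controlled node.

    Builds the target L_{n+1} from the base transition matrix and the
    block assignment (default: a single skew block on the base cell with
    the largest column index), reads the new node's truth table off it,
    exact-minimizes the table into the feedback law u, and returns the
    closed loop, whose transition matrix equals the target exactly.
    """
    if not base.is_closed:
        raise NetworkError("the base network must be closed (bind inputs first)")
    if new_node in base.nodes:
        raise NetworkError(f"node name {new_node!r} already in use")
    L_base = transition_matrix_direct(base)
    if not is_reachable_network(L_base):
        raise SynthesisError(
            "feedback synthesis requires a reachable base network "
            "(single full-length cycle)")
    if assignment == "default":
        assignment = BlockAssignment.single_skew(L_base.num_states)
    if not is_extension_reachable(assignment, L_base):
        raise SynthesisError(
            f"assignment with {assignment.skew_count} skew blocks violates the "
            "parity rule: the extension is a single cycle iff the skew count is odd")
    L_ext = extend_transition_matrix(L_base, assignment)
    nodes = base.nodes + (new_node,)
    u = minimize_to_sop(node_truth_tables(L_ext)[-1], nodes)
    closed = BooleanNetwork(nodes, base.updates + (u,), name=base.name or "")
    L_closed = transition_matrix_direct(closed)
    if L_closed.successor != L_ext.successor:
        raise AssertionError("closed-loop transition matrix deviates from the target")
    return FeedbackLaw(
        u=u,
        lifted_structure_matrix=structure_matrix(u, nodes),
        closed_loop=closed,
        transition_matrix=L_ext,
        assignment=assignment,
    )


def synthesize_from_template(net: BooleanNetwork,
                             assignment: BlockAssignment | str = "default"
                             ) -> FeedbackLaw:
    """Synthesis for a lower-triangle template with an explicit input.

    ``net`` must declare exactly one input u and have exactly one node
    whose update is the bare input symbol (the controlled node, expected
    last); the remaining nodes, which may not reference u or the
    controlled node, form the base network.
    """
    if len(net.inputs) != 1:
        raise NetworkError("expected exactly one declared input")
    u_name = net.inputs[0]
    from .logic import Var
    controlled = [name for name, expr in zip(net.nodes, net.updates)
                  if expr == Var(u_name)]
    if len(controlled) != 1:
        raise NetworkError(
            f"expected exactly one node updated by the bare input {u_name!r}")
    ctrl = controlled[0]
    base_nodes = tuple(n for n in net.nodes if n != ctrl)
    base_updates = []
    for name in base_nodes:
        expr = net.update_of(name)
        bad = expr.variables() & {u_name, ctrl}
        if bad:
            raise NetworkError(
                f"base node {name!r} references {sorted(bad)}; the template "
                "must be lower-triangle (base independent of the controlled node)")
        base_updates.append(expr)
    base = BooleanNetwork(base_nodes, tuple(base_updates), name=net.name)
    return synthesize_feedback_control(base, new_node=ctrl, assignment=assignment)
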