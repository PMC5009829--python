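"""Time-transition diagrams and reachability classification.

The transition diagram of a closed n-node network is the functional graph
on the 2ⁿ integrated states: every state has exactly one outgoing edge (to
its successor), so the graph decomposes into disjoint attractor cycles
with trees of transient states hanging off them.

A state is *reachable* when it is reached from every initial state in
finitely many (≥1) steps.  For a deterministic map this forces a unique
attractor cycle: the reachable states are exactly that cycle's states, and
with two or more attractors no state at all is reachable.  A *network* is
reachable when every integrated state is reachable, which holds iff the
successor map is a single 2ⁿ-cycle permutation — equivalently, iff the
signal flow passes through every node of the diagram in one direction,
each state having exactly one incoming and one outgoing arrow.

The transition matrix of a reachable network therefore satisfies three
checkable properties: it is a permutation matrix (one 1 per row and
column), its diagonal is zero (no self-transitions), and for n ≥ 2 it has
no 2-cycles (state pairs that swap).  The 2-cycle exclusion does not apply
to the single reachable 1-node network, whose two states necessarily swap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .network import TransitionMatrix

__all__ = [
    "TransitionDiagram",
    "MatrixProperties",
    "ReachabilityReport",
    "build_diagram",
    "is_reachable_network",
    "classify_states",
    "check_matrix_properties",
    "export_dot",
]


@dataclass(frozen=True)
class TransitionDiagram:
    """Deterministic successor map with its cycle decomposition.

    ``cycles`` are disjoint attractor cycles, each rotated to start at its
    smallest state index and listed in order of that index.  ``cycle_of``
    maps every state to the index (into ``cycles``) of the attractor its
    trajectory eventually enters.
    """

    n: int
    successor: tuple[int, ...]
    cycles: tuple[tuple[int, ...], ...]
    cycle_of: tuple[int, ...]

    @property
    def num_states(self) -> int:
        return 2**self.n

    @property
    def on_cycle(self) -> frozenset[int]:
        return frozenset(s for cyc in self.cycles for s in cyc)

    def edges(self) -> list[tuple[int, int]]:
        return [(j, s) for j, s in enumerate(self.successor, start=1)]


@dataclass(frozen=True)
class MatrixProperties:
    """Named structural checks on a transition matrix.

    ``no_two_cycles`` is ``None`` for n = 1, where the exclusion of
    2-cycles does not apply.
    """

    permutation: bool
    zero_diagonal: bool
    no_two_cycles: bool | None

    @property
    def violations(self) -> tuple[str, ...]:
        out = []
        if not self.permutation:
            out.append("permutation")
        if not self.zero_diagonal:
            out.append("zero_diagonal")
        if self.no_two_cycles is False:
            out.append("no_two_cycles")
        return tuple(out)

    @property
    def all_pass(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class ReachabilityReport:
    network_reachable: bool
    reachable_states: frozenset[int]
    non_reachable_states: frozenset[int]
    attractors: tuple[tuple[int, ...], ...]
    property_violations: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            "reachable network" if self.network_reachable else "not reachable",
            f"reachable states ({len(self.reachable_states)}): "
            + (", ".join(str(s) for s in sorted(self.reachable_states)) or "none"),
            f"non-reachable states ({len(self.non_reachable_states)}): "
            + (", ".join(str(s) for s in sorted(self.non_reachable_states)) or "none"),
            "attractors: " + "; ".join(
                "(" + " -> ".join(str(s) for s in cyc) + ")"
                for cyc in self.attractors),
        ]
        if self.property_violations:
            lines.append("failed matrix properties: "
                         + ", ".join(self.property_violations))
        return "\n".join(lines)


def build_diagram(L: TransitionMatrix) -> TransitionDiagram:
    """Cycle decomposition of the successor map by pointer traversal."""
    d = L.num_states
    succ = L.successor
    color = [0] * (d + 1)  # 0 unvisited, 1 on current path, 2 finished
    cycle_idx = [0] * (d + 1)
    cycles: list[tuple[int, ...]] = []
    for start in range(1, d + 1):
        if color[start]:
            continue
        path = []
        v = start
        while color[v] == 0:
            color[v] = 1
            path.append(v)
            v = succ[v - 1]
        if color[v] == 1:  # closed a new cycle within the current path
            i = path.index(v)
            cyc = path[i:]
            m = cyc.index(min(cyc))
            cycles.append(tuple(cyc[m:] + cyc[:m]))
            target = len(cycles) - 1
        else:
            target = cycle_idx[v]
        for u in path:
            color[u] = 2
            cycle_idx[u] = target
    order = sorted(range(len(cycles)), key=lambda i: cycles[i][0])
    rank = {old: new for new, old in enumerate(order)}
    return TransitionDiagram(
        n=L.n,
        successor=succ,
        cycles=tuple(cycles[i] for i in order),
        cycle_of=tuple(rank[cycle_idx[s]] for s in range(1, d + 1)),
    )


def is_reachable_network(L: TransitionMatrix) -> bool:
    """True iff the successor map is a single full-length cycle.

    Equivalently: the transition matrix is a permutation whose cycle
    decomposition is one cycle through all 2ⁿ states, so every state has
    one incoming and one outgoing arrow and the flow visits all of them.
    """
    if len(set(L.successor)) != L.num_states:
        return False
    diagram = build_diagram(L)
    return len(diagram.cycles) == 1 and len(diagram.cycles[0]) == L.num_states


def check_matrix_properties(L: TransitionMatrix) -> MatrixProperties:
    """The three structural properties of a reachable transition matrix."""
    d = L.num_states
    permutation = len(set(L.successor)) == d
    zero_diagonal = all(L.successor[j - 1] != j for j in range(1, d + 1))
    if L.n == 1:
        no_two_cycles: bool | None = None
    else:
        no_two_cycles = not any(
            k != j and L.successor[k - 1] == j
            for j in range(1, d + 1)
            for k in (L.successor[j - 1],)
        )
    return MatrixProperties(permutation, zero_diagonal, no_two_cycles)


def classify_states(L: TransitionMatrix) -> ReachabilityReport:
    """Partition the 2ⁿ integrated states into reachable / non-reachable.

    With a unique attractor every trajectory enters it and then visits all
    of its states forever, so the reachable states are exactly the cycle
    states; with two or more attractors no state is reached from every
    initial state, so the reachable set is empty.
    """
    diagram = build_diagram(L)
    all_states = frozenset(range(1, L.num_states + 1))
    if len(diagram.cycles) == 1:
        reachable = frozenset(diagram.cycles[0])
    else:
        reachable = frozenset()
    props = check_matrix_properties(L)
    return ReachabilityReport(
        network_reachable=is_reachable_network(L),
        reachable_states=reachable,
        non_reachable_states=all_states - reachable,
        attractors=diagram.cycles,
        property_violations=props.violations,
    )


def export_dot(diagram: TransitionDiagram,
               highlight: Iterable[int] | None = None) -> str:
    """Render the diagram as a Graphviz DOT digraph.

    ``highlight`` states (typically the reachable set) are filled red, the
    remainder blue, mirroring the usual red/blue state-diagram styling.
    """
    d = diagram.num_states
    hl = set(highlight) if highlight is not None else None
    lines = ["digraph transition_diagram {", "  rankdir=LR;"]
    for j in range(1, d + 1):
        label = f"e_{d}^{j}"
        attrs = [f'label="{label}"']
        if hl is not None:
            color = "red" if j in hl else "blue"
            attrs += ["style=filled", f'fillcolor="{color}"', 'fontcolor="white"']
        lines.append(f'  s{j} [{", ".join(attrs)}];')
    for j, k in diagram.edges():
        lines.append(f"  s{j} -> s{k};")
    lines.append("}")
    return "\n".join(lines) + "\n"
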