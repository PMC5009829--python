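"""Seeded random fixtures: Boolean networks and permutation matrices.

Used by the property-test suite and the ``fixtures`` CLI command.  All
generators take a :class:`numpy.random.Generator` (or an integer seed) so
runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from .logic import BINARY_OPS, BinOp, Const, Expr, Not, Var
from .network import BooleanNetwork, TransitionMatrix

__all__ = [
    "random_expression",
    "random_network",
    "random_transition_matrix",
    "random_full_cycle_matrix",
]

_GRAMMAR_OPS = tuple(op for op in BINARY_OPS if op not in ("nonimp", "conv_nonimp"))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_expression(variables: list[str], rng, max_depth: int = 3) -> Expr:
    """Random expression AST over the given variables (grammar operators only)."""
    rng = _rng(rng)
    if max_depth == 0 or rng.random() < 0.3:
        roll = rng.random()
        if roll < 0.05:
            return Const(bool(rng.integers(2)))
        leaf: Expr = Var(variables[int(rng.integers(len(variables)))])
        return Not(leaf) if roll < 0.35 else leaf
    op = _GRAMMAR_OPS[int(rng.integers(len(_GRAMMAR_OPS)))]
    left = random_expression(variables, rng, max_depth - 1)
    right = random_expression(variables, rng, max_depth - 1)
    e: Expr = BinOp(op, left, right)
    if rng.random() < 0.15:
        e = Not(e)
    return e


def random_network(n: int, rng, max_depth: int = 3) -> BooleanNetwork:
    """Random closed n-node network with nodes x1..xn."""
    rng = _rng(rng)
    names = [f"x{i}" for i in range(1, n + 1)]
    updates = tuple(random_expression(names, rng, max_depth) for _ in names)
    return BooleanNetwork(tuple(names), updates)


def random_transition_matrix(n: int, rng) -> TransitionMatrix:
    """Uniformly random deterministic successor map on 2ⁿ states."""
    rng = _rng(rng)
    d = 2**n
    return TransitionMatrix(n, tuple(int(s) for s in rng.integers(1, d + 1, size=d)))


def random_full_cycle_matrix(n: int, rng) -> TransitionMatrix:
    """Random single 2ⁿ-cycle permutation (a reachable transition matrix)."""
    rng = _rng(rng)
    d = 2**n
    order = [1] + [int(v) for v in rng.permutation(np.arange(2, d + 1))]
    successor = [0] * d
    for a, b in zip(order, order[1:] + [1]):
        successor[a - 1] = b
    return TransitionMatrix(n, tuple(successor))
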