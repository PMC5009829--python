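"""Boolean expressions over the sixteen two-variable logical connectives.

Provides an expression AST, a small ASCII/Unicode grammar, truth tables in
integrated-state order (the all-ones assignment first, matching the basis
encoding of :mod:`stpbn.stp`), structure matrices — the 2×2ᵏ logical matrix
M with f(x₁,…,x_k) = M ⋉ x₁ ⋉ … ⋉ x_k — and exact two-level minimization
to a simplest sum-of-products form (Quine–McCluskey prime implicants with a
Petrick-style minimum cover).

Grammar (ASCII, with Unicode synonyms in parentheses)::

    expr    := orexpr { lowop orexpr }          lowop: ^ (⊕), -> (→), <- (←),
                                                       <-> (↔, ⇔), nand (↑), nor (↓)
    orexpr  := andexpr { "|" andexpr }          (∨)
    andexpr := unary { "&" unary }              (∧)
    unary   := { "!" (¬) } atom
    atom    := "(" expr ")" | "True" | "False" | "1" | "0" | identifier

Precedence is ``!`` > ``&`` > ``|`` > the xor/implication family; operators
of equal precedence associate to the left.  The two nonimplication
connectives have no dedicated token; they exist as AST operators and
serialize to their conjunction/negation expansion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ExpressionError
from .stp import LogicalMatrix, decode_state

__all__ = [
    "Expr",
    "Var",
    "Const",
    "Not",
    "BinOp",
    "BINARY_OPS",
    "parse_expression",
    "serialize",
    "evaluate",
    "truth_table",
    "structure_matrix",
    "minimize_to_sop",
    "table1_operators",
    "expressions_equal",
]


# ---------------------------------------------------------------------------
# AST

class Expr:
    """Base class for Boolean expression nodes."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def __str__(self) -> str:
        return serialize(self)

    # convenience constructors mirroring the grammar
    def __and__(self, other: "Expr") -> "Expr":
        return BinOp("and", self, other)

    def __or__(self, other: "Expr") -> "Expr":
        return BinOp("or", self, other)

    def __xor__(self, other: "Expr") -> "Expr":
        return BinOp("xor", self, other)

    def __invert__(self) -> "Expr":
        return Not(self)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})


@dataclass(frozen=True)
class Const(Expr):
    value: bool

    def variables(self) -> frozenset[str]:
        return frozenset()


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def variables(self) -> frozenset[str]:
        return self.child.variables()


#: name → truth function for the ten binary connectives.
BINARY_OPS: Mapping[str, Callable[[int, int], int]] = {
    "and": lambda a, b: a & b,
    "or": lambda a, b: a | b,
    "xor": lambda a, b: a ^ b,
    "nand": lambda a, b: 1 - (a & b),
    "nor": lambda a, b: 1 - (a | b),
    "imp": lambda a, b: (1 - a) | b,          # a → b
    "conv_imp": lambda a, b: a | (1 - b),     # a ← b
    "iff": lambda a, b: 1 - (a ^ b),          # a ↔ b
    "nonimp": lambda a, b: a & (1 - b),       # a ↛ b
    "conv_nonimp": lambda a, b: (1 - a) & b,  # a ↚ b
}


@dataclass(frozen=True)
class BinOp(Expr):
    op: str
    left: Expr
    right: Expr

    def __post_init__(self) -> None:
        if self.op not in BINARY_OPS:
            raise ValueError(f"unknown binary operator {self.op!r}")

    def variables(self) -> frozenset[str]:
        return self.left.variables() | self.right.variables()


# ---------------------------------------------------------------------------
# Serialization

_PREC_LOW, _PREC_OR, _PREC_AND, _PREC_NOT = 0, 1, 2, 3

_OP_TOKEN = {
    "and": ("&", _PREC_AND),
    "or": ("|", _PREC_OR),
    "xor": ("^", _PREC_LOW),
    "imp": ("->", _PREC_LOW),
    "conv_imp": ("<-", _PREC_LOW),
    "iff": ("<->", _PREC_LOW),
    "nand": ("nand", _PREC_LOW),
    "nor": ("nor", _PREC_LOW),
}


def _desugar(e: Expr) -> Expr:
    """Rewrite AST-only connectives into grammar-expressible form."""
    if isinstance(e, BinOp):
        if e.op == "nonimp":
            return BinOp("and", e.left, Not(e.right))
        if e.op == "conv_nonimp":
            return BinOp("and", Not(e.left), e.right)
    return e


def _serialize(e: Expr) -> tuple[str, int]:
    e = _desugar(e)
    if isinstance(e, Var):
        return e.name, _PREC_NOT
    if isinstance(e, Const):
        return ("True" if e.value else "False"), _PREC_NOT
    if isinstance(e, Not):
        text, prec = _serialize(e.child)
        if prec < _PREC_NOT:
            text = f"({text})"
        return f"!{text}", _PREC_NOT
    assert isinstance(e, BinOp)
    token, prec = _OP_TOKEN[e.op]
    lt, lp = _serialize(e.left)
    rt, rp = _serialize(e.right)
    if lp < prec:
        lt = f"({lt})"
    # left-associative chains: the right operand needs parentheses at equal
    # precedence; for & and | (one associative operator per level) it does not
    needs_right = rp < prec or (rp == prec and prec == _PREC_LOW)
    if needs_right:
        rt = f"({rt})"
    return f"{lt} {token} {rt}", prec


def serialize(e: Expr) -> str:
    """Canonical ASCII form; re-parsing yields a semantically equal expression."""
    return _serialize(e)[0]


# ---------------------------------------------------------------------------
# Parsing

_TOKEN_RE = re.compile(
    r"\s+"
    r"|<->|<-|->"
    r"|[()!&|^]"
    r"|[A-Za-z_][A-Za-z0-9_]*"
    r"|[01]"
    r"|↔|⇔|→|←|¬|∧|∨|⊕|↑|↓"
)

_UNICODE_MAP = {
    "¬": "!", "∧": "&", "∨": "|", "⊕": "^",
    "→": "->", "←": "<-", "↔": "<->", "⇔": "<->",
    "↑": "nand", "↓": "nor",
}

_LOW_OPS = {"^": "xor", "->": "imp", "<-": "conv_imp", "<->": "iff",
            "nand": "nand", "nor": "nor"}

_CONSTS = {"True": True, "true": True, "1": True,
           "False": False, "false": False, "0": False}


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        tok = m.group()
        if not tok.isspace():
            tokens.append((_UNICODE_MAP.get(tok, tok), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]], variables: Sequence[str],
                 source_len: int):
        self.tokens = tokens
        self.i = 0
        self.variables = set(variables)
        self.source_len = source_len

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else self.source_len

    def _advance(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def parse(self) -> Expr:
        e = self.expr()
        if self._peek() is not None:
            raise ExpressionError(f"unexpected token {self._peek()!r}", self._pos())
        return e

    def expr(self) -> Expr:
        left = self.orexpr()
        while self._peek() in _LOW_OPS:
            op = _LOW_OPS[self._advance()]
            left = BinOp(op, left, self.orexpr())
        return left

    def orexpr(self) -> Expr:
        left = self.andexpr()
        while self._peek() == "|":
            self._advance()
            left = BinOp("or", left, self.andexpr())
        return left

    def andexpr(self) -> Expr:
        left = self.unary()
        while self._peek() == "&":
            self._advance()
            left = BinOp("and", left, self.unary())
        return left

    def unary(self) -> Expr:
        if self._peek() == "!":
            self._advance()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Expr:
        tok, pos = self._peek(), self._pos()
        if tok is None:
            raise ExpressionError("unexpected end of expression", pos)
        if tok == "(":
            self._advance()
            e = self.expr()
            if self._peek() != ")":
                raise ExpressionError("expected ')'", self._pos())
            self._advance()
            return e
        if tok in _CONSTS:
            self._advance()
            return Const(_CONSTS[tok])
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok) and tok not in _LOW_OPS:
            if tok not in self.variables:
                raise ExpressionError(f"undeclared symbol {tok!r}", pos)
            self._advance()
            return Var(tok)
        raise ExpressionError(f"unexpected token {tok!r}", pos)


def parse_expression(text: str, variables: Sequence[str]) -> Expr:
    """Parse expression text over the declared variable symbols.

    Raises :class:`~stpbn.errors.ExpressionError` (with a character
    position) on syntax errors or undeclared symbols.
    """
    return _Parser(_tokenize(text), variables, len(text)).parse()


# ---------------------------------------------------------------------------
# Evaluation, truth tables, structure matrices

def evaluate(e: Expr, assignment: Mapping[str, int]) -> int:
    if isinstance(e, Var):
        try:
            return int(assignment[e.name])
        except KeyError:
            raise ExpressionError(f"no value given for symbol {e.name!r}") from None
    if isinstance(e, Const):
        return int(e.value)
    if isinstance(e, Not):
        return 1 - evaluate(e.child, assignment)
    assert isinstance(e, BinOp)
    return BINARY_OPS[e.op](evaluate(e.left, assignment),
                            evaluate(e.right, assignment))


def truth_table(expr: Expr, variables: Sequence[str]) -> np.ndarray:
    """Truth table in integrated-state order (entry j ↦ assignment decode(j)).

    Entry 1 is the all-ones assignment and entry 2ᵏ the all-zeros
    assignment, matching the column order of structure matrices.
    """
    variables = list(variables)
    undeclared = expr.variables() - set(variables)
    if undeclared:
        raise ExpressionError(f"undeclared symbols {sorted(undeclared)}")
    k = len(variables)
    out = np.empty(2**k, dtype=np.int64)
    for j in range(1, 2**k + 1):
        bits = decode_state(j, k)
        out[j - 1] = evaluate(expr, dict(zip(variables, bits)))
    return out


def structure_matrix(expr: Expr, variables: Sequence[str]) -> LogicalMatrix:
    """The 2×2ᵏ logical matrix M with f(x₁..x_k) = M ⋉ x₁ ⋉ … ⋉ x_k.

    Column j encodes the truth-table entry j as a Boolean vector (row 1 for
    true, row 2 for false).
    """
    table = truth_table(expr, variables)
    return LogicalMatrix(2, len(table), tuple(1 if t else 2 for t in table))


# ---------------------------------------------------------------------------
# Exact two-level minimization (Quine–McCluskey + Petrick cover)

_DASH = 2  # implicant entries: 0, 1, or dash


def _prime_implicants(minterms: list[tuple[int, ...]], k: int) -> list[tuple[int, ...]]:
    current = {tuple(m) for m in minterms}
    primes: set[tuple[int, ...]] = set()
    while current:
        combined: set[tuple[int, ...]] = set()
        used: set[tuple[int, ...]] = set()
        items = sorted(current)
        for a, b in combinations(items, 2):
            diff = [i for i in range(k) if a[i] != b[i]]
            if len(diff) == 1 and _DASH not in (a[diff[0]], b[diff[0]]):
                merged = tuple(_DASH if i == diff[0] else a[i] for i in range(k))
                combined.add(merged)
                used.add(a)
                used.add(b)
        primes |= current - used
        current = combined
    return sorted(primes)


def _covers(imp: tuple[int, ...], minterm: tuple[int, ...]) -> bool:
    return all(i == _DASH or i == m for i, m in zip(imp, minterm))


def _term_expr(imp: tuple[int, ...], variables: Sequence[str]) -> Expr:
    literals: list[Expr] = []
    for v, bit in zip(variables, imp):
        if bit == 1:
            literals.append(Var(v))
        elif bit == 0:
            literals.append(Not(Var(v)))
    if not literals:
        return Const(True)
    term = literals[0]
    for lit in literals[1:]:
        term = BinOp("and", term, lit)
    return term


def _literal_count(imp: tuple[int, ...]) -> int:
    return sum(1 for b in imp if b != _DASH)


def _minimum_cover(primes: list[tuple[int, ...]],
                   minterms: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    # essential primes belong to every cover
    chosen: list[tuple[int, ...]] = []
    uncovered = list(minterms)
    changed = True
    while changed and uncovered:
        changed = False
        for m in uncovered:
            covering = [p for p in primes if _covers(p, m)]
            if len(covering) == 1 and covering[0] not in chosen:
                chosen.append(covering[0])
                changed = True
        if changed:
            uncovered = [m for m in uncovered
                         if not any(_covers(p, m) for p in chosen)]
    if not uncovered:
        return chosen
    # Petrick-style exact search over the remaining primes, smallest
    # cover first; ties broken by fewer literals, then lexicographically.
    rest = [p for p in primes if p not in chosen
            and any(_covers(p, m) for m in uncovered)]
    for size in range(1, len(rest) + 1):
        candidates = []
        for combo in combinations(rest, size):
            if all(any(_covers(p, m) for p in combo) for m in uncovered):
                full = chosen + list(combo)
                key = (sum(_literal_count(p) for p in full),
                       tuple(sorted(full)))
                candidates.append((key, full))
        if candidates:
            return min(candidates)[1]
    raise AssertionError("prime implicants failed to cover the minterms")


def minimize_to_sop(table: Sequence[int] | np.ndarray,
                    variables: Sequence[str]) -> Expr:
    """Exact minimal sum-of-products expression for a truth table.

    ``table`` is in integrated-state order (all-ones assignment first) and
    must have length 2ᵏ for k = len(variables).  The result is a
    disjunction of conjunctions of literals covering the table with a
    provably minimal number of prime implicants (ties: fewer literals, then
    lexicographically smallest serialized form), or a constant.
    """
    variables = list(variables)
    k = len(variables)
    table = [int(t) for t in table]
    if len(table) != 2**k:
        raise ValueError(f"table length {len(table)} != 2^{k}")
    if any(t not in (0, 1) for t in table):
        raise ValueError("truth table entries must be 0/1")
    minterms = [decode_state(j, k) for j in range(1, 2**k + 1) if table[j - 1]]
    if not minterms:
        return Const(False)
    if len(minterms) == 2**k:
        return Const(True)
    primes = _prime_implicants(minterms, k)
    cover = _minimum_cover(primes, minterms)
    terms = sorted((_term_expr(p, variables) for p in cover), key=serialize)
    expr = terms[0]
    for t in terms[1:]:
        expr = BinOp("or", expr, t)
    return expr


# ---------------------------------------------------------------------------
# The sixteen two-variable connectives

def table1_operators(x1: str = "x1", x2: str = "x2") -> dict[str, Expr]:
    """The sixteen Boolean connectives of two variables, as expressions.

    Ordered as: the two constants, the two propositions, their negations,
    conjunction, disjunction, the implications and nonimplications, the
    biconditional, the two denials and exclusive disjunction.
    """
    a, b = Var(x1), Var(x2)
    return {
        "true": Const(True),
        "false": Const(False),
        "x1": a,
        "x2": b,
        "not_x1": Not(a),
        "not_x2": Not(b),
        "and": BinOp("and", a, b),
        "or": BinOp("or", a, b),
        "converse_implication": BinOp("conv_imp", a, b),
        "implication": BinOp("imp", a, b),
        "converse_nonimplication": BinOp("conv_nonimp", a, b),
        "nonimplication": BinOp("nonimp", a, b),
        "biconditional": BinOp("iff", a, b),
        "nand": BinOp("nand", a, b),
        "nor": BinOp("nor", a, b),
        "xor": BinOp("xor", a, b),
    }


def expressions_equal(e1: Expr, e2: Expr, variables: Sequence[str]) -> bool:
    """Semantic (truth-table) equality over the given variable ordering."""
    return bool(np.array_equal(truth_table(e1, variables),
                               truth_table(e2, variables)))
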