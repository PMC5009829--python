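"""Expression parsing, truth tables, structure matrices, SOP minimization."""

from itertools import product

import numpy as np
import pytest

from stpbn.errors import ExpressionError
from stpbn.fixtures import random_expression
from stpbn.logic import (BinOp, Const, Not, Var, expressions_equal,
                         minimize_to_sop, parse_expression, serialize,
                         structure_matrix, table1_operators, truth_table)

PRINTED_CONTROL_LAW = "(!x1 & !x2 & !x3) | (x1 & x3) | (x2 & x3)"

# Table of the sixteen two-variable connectives: top row of each 2x4
# logical matrix in integrated-state column order (1,1), (1,0), (0,1), (0,0).
SIXTEEN_TOP_ROWS = {
    "true": (1, 1, 1, 1),
    "false": (0, 0, 0, 0),
    "x1": (1, 1, 0, 0),
    "x2": (1, 0, 1, 0),
    "not_x1": (0, 0, 1, 1),
    "not_x2": (0, 1, 0, 1),
    "and": (1, 0, 0, 0),
    "or": (1, 1, 1, 0),
    "converse_implication": (1, 1, 0, 1),
    "implication": (1, 0, 1, 1),
    "converse_nonimplication": (0, 0, 1, 0),
    "nonimplication": (0, 1, 0, 0),
    "biconditional": (1, 0, 0, 1),
    "nand": (0, 1, 1, 1),
    "nor": (0, 0, 0, 1),
    "xor": (0, 1, 1, 0),
}


class TestParsing:
    def test_simple_negation(self):
        assert parse_expression("!x2", ["x1", "x2"]) == Not(Var("x2"))

    def test_printed_control_law_shape(self):
        e = parse_expression(PRINTED_CONTROL_LAW, ["x1", "x2", "x3"])
        assert isinstance(e, BinOp) and e.op == "or"
        assert truth_table(e, ["x1", "x2", "x3"]).tolist() == [1, 0, 1, 0, 1, 0, 0, 1]

    def test_contradiction(self):
        e = parse_expression("x1 ^ x1", ["x1"])
        assert truth_table(e, ["x1"]).tolist() == [0, 0]

    def test_unicode_synonyms(self):
        ascii_e = parse_expression("(!x1 & x2) -> (x1 <-> x2)", ["x1", "x2"])
        uni_e = parse_expression("(¬x1 ∧ x2) → (x1 ⇔ x2)", ["x1", "x2"])
        assert expressions_equal(ascii_e, uni_e, ["x1", "x2"])

    @pytest.mark.parametrize("text", ["x1 &", "(x1 | x2", "x1 x2", "&x1", ""])
    def test_syntax_errors_carry_position(self, text):
        with pytest.raises(ExpressionError) as exc:
            parse_expression(text, ["x1", "x2"])
        assert exc.value.position is not None

    def test_undeclared_symbol(self):
        with pytest.raises(ExpressionError, match="undeclared"):
            parse_expression("x1 & y", ["x1", "x2"])

    def test_precedence_not_over_and_over_or(self):
        e = parse_expression("!x1 & x2 | x1", ["x1", "x2"])
        expected = BinOp("or", BinOp("and", Not(Var("x1")), Var("x2")), Var("x1"))
        assert e == expected

    def test_serialize_round_trip_random(self, rng):
        names = ["x1", "x2", "x3"]
        for _ in range(100):
            e = random_expression(names, rng, max_depth=4)
            back = parse_expression(serialize(e), names)
            assert expressions_equal(e, back, names)

    def test_nonimplication_serializes_to_equivalent_form(self):
        e = BinOp("nonimp", Var("x1"), Var("x2"))
        back = parse_expression(serialize(e), ["x1", "x2"])
        assert expressions_equal(e, back, ["x1", "x2"])


class TestTruthTable:
    def test_conjunction(self):
        e = BinOp("and", Var("x1"), Var("x2"))
        assert truth_table(e, ["x1", "x2"]).tolist() == [1, 0, 0, 0]

    def test_constant_true(self):
        assert truth_table(Const(True), ["x1", "x2"]).tolist() == [1, 1, 1, 1]

    def test_order_is_all_ones_first(self):
        assert truth_table(Var("x1"), ["x1"]).tolist() == [1, 0]


class TestStructureMatrix:
    def test_negation_x2(self):
        m = structure_matrix(Not(Var("x2")), ["x1", "x2"])
        assert np.array_equal(m.dense(), [[0, 1, 0, 1], [1, 0, 1, 0]])

    def test_proposition_x1(self):
        m = structure_matrix(Var("x1"), ["x1", "x2"])
        assert np.array_equal(m.dense(), [[1, 1, 0, 0], [0, 0, 1, 1]])

    def test_all_sixteen_connectives(self):
        ops = table1_operators()
        assert set(ops) == set(SIXTEEN_TOP_ROWS)
        for name, expr in ops.items():
            m = structure_matrix(expr, ["x1", "x2"])
            top = tuple(1 if c == 1 else 0 for c in m.col_index)
            assert top == SIXTEEN_TOP_ROWS[name], name

    def test_sixteen_matrices_enumerate_all_logical_2x4(self):
        tops = {tuple(1 if c == 1 else 0
                      for c in structure_matrix(e, ["x1", "x2"]).col_index)
                for e in table1_operators().values()}
        assert len(tops) == 16
        assert tops == set(product((0, 1), repeat=4))


class TestMinimization:
    def test_negation_recovered(self):
        e = minimize_to_sop([0, 1, 0, 1], ["x1", "x2"])
        assert serialize(e) == "!x2"

    def test_constants(self):
        assert minimize_to_sop([0, 0, 0, 0], ["x1", "x2"]) == Const(False)
        assert minimize_to_sop([1, 1, 1, 1], ["x1", "x2"]) == Const(True)

    def test_printed_control_law_table_minimizes_to_printed_form(self):
        e = minimize_to_sop([1, 0, 1, 0, 1, 0, 0, 1], ["x1", "x2", "x3"])
        printed = parse_expression(PRINTED_CONTROL_LAW, ["x1", "x2", "x3"])
        assert expressions_equal(e, printed, ["x1", "x2", "x3"])
        # exact minimal cover: the three printed products are all essential
        assert serialize(e) == "!x1 & !x2 & !x3 | x1 & x3 | x2 & x3"

    def test_random_tables_round_trip_and_literal_economy(self, rng):
        names = ["x1", "x2", "x3"]
        for _ in range(50):
            table = rng.integers(0, 2, size=8).tolist()
            e = minimize_to_sop(table, names)
            assert truth_table(e, names).tolist() == table
            minterm_literals = 3 * sum(table)
            assert _literal_count(e) <= max(minterm_literals, 1)

    def test_matches_sympy_exact_minimization(self, rng):
        """Independent oracle: never more product terms than sympy's SOPform."""
        sympy = pytest.importorskip("sympy")
        syms = sympy.symbols("x1 x2 x3")
        names = ["x1", "x2", "x3"]
        for _ in range(30):
            table = rng.integers(0, 2, size=8).tolist()
            if sum(table) in (0, 8):
                continue
            # sympy's minterms are little-endian over [x1, x2, x3] truth values
            minterms = [list(bits) for j, bits in
                        enumerate(product((1, 0), repeat=3)) if table[j]]
            ref = sympy.SOPform(syms, minterms)
            mine = minimize_to_sop(table, names)
            assert truth_table(mine, names).tolist() == table
            assert _term_count(mine) <= _sympy_term_count(ref)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_semantic_round_trip_exhaustive(self, k):
        """structure_matrix ∘ minimize ∘ truth_table is the identity."""
        names = [f"x{i}" for i in range(1, k + 1)]
        for bits in product((0, 1), repeat=2**k):
            e = minimize_to_sop(list(bits), names)
            assert truth_table(e, names).tolist() == list(bits)


def _literal_count(e) -> int:
    if isinstance(e, Var):
        return 1
    if isinstance(e, Const):
        return 0
    if isinstance(e, Not):
        return _literal_count(e.child)
    return _literal_count(e.left) + _literal_count(e.right)


def _term_count(e) -> int:
    if isinstance(e, BinOp) and e.op == "or":
        return _term_count(e.left) + _term_count(e.right)
    return 1


def _sympy_term_count(e) -> int:
    import sympy
    if isinstance(e, sympy.Or):
        return len(e.args)
    return 1
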