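"""Block-doubling extension and state-feedback control synthesis."""

from itertools import product

import numpy as np
import pytest

from stpbn.control import (IDENTITY, SKEW, BlockAssignment, collapse_blocks,
                           extend_transition_matrix, is_extension_reachable,
                           lift_structure_matrix, synthesize_feedback_control,
                           synthesize_from_template)
from stpbn.errors import SynthesisError
from stpbn.fixtures import random_full_cycle_matrix
from stpbn.logic import (Const, Not, Var, expressions_equal, parse_expression,
                         structure_matrix, truth_table)
from stpbn.network import TransitionMatrix, transition_matrix_direct
from stpbn.reachability import build_diagram, is_reachable_network
from stpbn.stp import dummy_matrix

L1 = TransitionMatrix(2, (3, 1, 4, 2))
PRINTED_U = "(!x1 & !x2 & !x3) | (x1 & x3) | (x2 & x3)"


class TestLift:
    def test_dummy_operator_matrix(self):
        assert np.array_equal(dummy_matrix().dense(),
                              [[1, 1, 0, 0], [0, 0, 1, 1]])

    def test_lift_negation_of_x2(self):
        m1 = structure_matrix(Not(Var("x2")), ["x1", "x2"])
        lifted = lift_structure_matrix(m1)
        assert (lifted.rows, lifted.cols) == (2, 8)
        top = tuple(1 if c == 1 else 0 for c in lifted.col_index)
        assert top == (0, 0, 1, 1, 0, 0, 1, 1)
        # agrees with evaluating the same function on three variables
        assert list(top) == truth_table(Not(Var("x2")),
                                        ["x1", "x2", "x3"]).tolist()

    def test_lift_constant_true(self):
        m = structure_matrix(Const(True), ["x1", "x2"])
        lifted = lift_structure_matrix(m)
        assert all(c == 1 for c in lifted.col_index)


class TestExtension:
    def test_single_skew_on_last_column_gives_eight_cycle(self):
        assignment = BlockAssignment.single_skew(4)
        ext = extend_transition_matrix(L1, assignment)
        assert ext.successor == (5, 6, 1, 2, 7, 8, 4, 3)
        diagram = build_diagram(ext)
        assert diagram.cycles == ((1, 5, 7, 4, 2, 6, 8, 3),)

    def test_all_identity_gives_two_disjoint_cycles(self):
        ext = extend_transition_matrix(L1, BlockAssignment.all_identity(4))
        diagram = build_diagram(ext)
        assert len(diagram.cycles) == 2
        assert not is_reachable_network(ext)

    def test_block_collapse_recovers_base(self, rng):
        for _ in range(20):
            base = random_full_cycle_matrix(2, rng)
            entries = tuple(SKEW if rng.random() < 0.5 else IDENTITY
                            for _ in range(4))
            ext = extend_transition_matrix(base, BlockAssignment(entries))
            assert collapse_blocks(ext).successor == base.successor

    def test_wrong_assignment_length_rejected(self):
        with pytest.raises(ValueError, match="1-block"):
            extend_transition_matrix(L1, BlockAssignment.all_identity(8))

    def test_from_cells_constructor(self):
        a = BlockAssignment.from_cells([((2, 4), SKEW)], L1)
        assert a.entries == (IDENTITY, IDENTITY, IDENTITY, SKEW)
        with pytest.raises(ValueError, match="not a 1-block"):
            BlockAssignment.from_cells([((1, 4), SKEW)], L1)


class TestParityRule:
    def test_single_skew_reachable(self):
        assert is_extension_reachable(BlockAssignment.single_skew(4), L1)

    def test_zero_skews_not_reachable(self):
        assert not is_extension_reachable(BlockAssignment.all_identity(4), L1)

    def test_exhaustive_on_l1(self):
        reachable_count = 0
        for entries in product((IDENTITY, SKEW), repeat=4):
            a = BlockAssignment(entries)
            predicted = is_extension_reachable(a, L1)
            actual = is_reachable_network(extend_transition_matrix(L1, a))
            assert predicted == actual
            reachable_count += predicted
        assert reachable_count == 8

    def test_sampled_on_three_node_bases(self, rng):
        for _ in range(10):
            base = random_full_cycle_matrix(3, rng)
            entries = tuple(SKEW if rng.random() < 0.5 else IDENTITY
                            for _ in range(8))
            a = BlockAssignment(entries)
            assert is_extension_reachable(a, base) \
                == is_reachable_network(extend_transition_matrix(base, a))

    def test_non_reachable_base_rejected(self):
        fixed_points = TransitionMatrix(2, (1, 2, 3, 4))
        with pytest.raises(SynthesisError, match="reachable"):
            is_extension_reachable(BlockAssignment.single_skew(4), fixed_points)


class TestSynthesis:
    def test_default_assignment_reproduces_printed_law(self, l1_network):
        law = synthesize_feedback_control(l1_network, new_node="x3")
        printed = parse_expression(PRINTED_U, ["x1", "x2", "x3"])
        assert expressions_equal(law.u, printed, ["x1", "x2", "x3"])
        assert law.transition_matrix.successor == (5, 6, 1, 2, 7, 8, 4, 3)
        assert is_reachable_network(law.transition_matrix)

    def test_closed_loop_matches_target_exactly(self, l1_network):
        law = synthesize_feedback_control(l1_network, new_node="x3")
        L = transition_matrix_direct(law.closed_loop)
        assert L.successor == law.transition_matrix.successor

    def test_every_odd_assignment_yields_reachable_loop(self, l1_network):
        for entries in product((IDENTITY, SKEW), repeat=4):
            a = BlockAssignment(entries)
            if a.skew_count % 2 == 1:
                law = synthesize_feedback_control(l1_network, "x3", a)
                assert is_reachable_network(
                    transition_matrix_direct(law.closed_loop))

    def test_even_assignment_fails_naming_parity(self, l1_network):
        with pytest.raises(SynthesisError, match="parity"):
            synthesize_feedback_control(l1_network, "x3",
                                        BlockAssignment.all_identity(4))

    def test_chained_extension_to_four_nodes(self, l1_network):
        law3 = synthesize_feedback_control(l1_network, "x3")
        law4 = synthesize_feedback_control(law3.closed_loop, "x4")
        L4 = transition_matrix_direct(law4.closed_loop)
        diagram = build_diagram(L4)
        assert len(diagram.cycles) == 1
        assert len(diagram.cycles[0]) == 16

    def test_lifted_structure_matrix_field(self, l1_network):
        law = synthesize_feedback_control(l1_network, "x3")
        assert (law.lifted_structure_matrix.rows,
                law.lifted_structure_matrix.cols) == (2, 8)
        top = [1 if c == 1 else 0 for c in law.lifted_structure_matrix.col_index]
        assert top == truth_table(law.u, ["x1", "x2", "x3"]).tolist()


class TestTemplateSynthesis:
    def test_bundled_template(self, control_template):
        law = synthesize_from_template(control_template)
        printed = parse_expression(PRINTED_U, ["x1", "x2", "x3"])
        assert expressions_equal(law.u, printed, ["x1", "x2", "x3"])
        assert law.closed_loop.nodes == ("x1", "x2", "x3")

    def test_non_lower_triangle_rejected(self):
        from stpbn.network import parse_network
        net = parse_network("input u\nx1 = !x2 & x3\nx2 = x1\nx3 = u\n")
        with pytest.raises(Exception, match="lower-triangle"):
            synthesize_from_template(net)
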