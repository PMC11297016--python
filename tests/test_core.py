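"""Unit and property tests for the grid model and the turning rule."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import turnfold as tf
from turnfold.core import Direction
from turnfold.errors import BlockedMove, RangeError, SelfIntersection

from conftest import enumerate_valid_configurations, reachable_configurations


class TestDirections:
    @pytest.mark.parametrize(
        "d, steps, expected",
        [
            (Direction.X, 2, Direction.W),
            (Direction.Y, 6, Direction.Y),
            (Direction.NEG_W, 1, Direction.X),
            (Direction.X, -2, Direction.NEG_Y),
        ],
    )
    def test_rotate(self, d, steps, expected):
        assert tf.rotate_direction(d, steps) == expected

    def test_rotate_identity_and_composition(self):
        for d in Direction:
            assert tf.rotate_direction(d, 0) == d
            for a, b in itertools.product(range(-6, 7), repeat=2):
                assert tf.rotate_direction(
                    tf.rotate_direction(d, a), b
                ) == tf.rotate_direction(d, a + b)

    def test_axis_identity(self):
        # x + w = y on the axial lattice
        x, y, w = Direction.X.vector, Direction.Y.vector, Direction.W.vector
        assert (x[0] + w[0], x[1] + w[1]) == y


class TestReconstruct:
    def test_line_rotated_by_one_sixth_turn(self):
        p, _ = tf.line_rotation_program(4, 1)
        c = tf.reconstruct_configuration(p, (1, 1, 1, 0))
        assert c.positions == ((0, 0), (0, 1), (0, 2), (0, 3))
        assert all(c.direction(i) == Direction.Y for i in range(3))

    def test_all_zero_is_initial(self):
        p = tf.Program([3, -2, 1, 0])
        c = tf.reconstruct_configuration(p, (0, 0, 0, 0))
        assert c.positions == tuple((i, 0) for i in range(4))
        assert c.states == (3, -2, 1, 0)

    def test_blocked_coil_geometry(self):
        # the permanently blocked coil of the state-6 line machine
        p, _ = tf.line_rotation_program(7, 6)
        c = tf.reconstruct_configuration(p, (0, 2, 3, 4, 5, 6, 0))
        assert c.positions == (
            (0, 0), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
        )
        assert c.states == (6, 4, 3, 2, 1, 0, 0)

    def test_range_error(self):
        p = tf.Program([2, 0])
        with pytest.raises(RangeError):
            tf.reconstruct_configuration(p, (3, 0))

    def test_self_intersection(self):
        p = tf.Program([3, 3, 0])
        with pytest.raises(SelfIntersection):
            tf.reconstruct_configuration(p, (0, 3, 0))


class TestRule:
    def test_blocked_at_coil(self):
        p, _ = tf.line_rotation_program(7, 6)
        c = tf.reconstruct_configuration(p, (0, 2, 3, 4, 5, 6, 0))
        assert not tf.rule_applicable(c, 0)

    def test_zero_state_never_applicable(self):
        p = tf.Program([0, 2, 0])
        c = tf.initial_configuration(p)
        assert not tf.rule_applicable(c, 0)
        assert not tf.rule_applicable(c, 2)

    def test_short_line_start_applicable(self):
        p, _ = tf.line_rotation_program(3, 1)
        assert tf.rule_applicable(tf.initial_configuration(p), 0)

    def test_apply_decrements_and_translates(self):
        # a state-3 monomer turning drags its whole head by +w
        p = tf.Program([3, 3, 0])
        c = tf.apply_rule(tf.initial_configuration(p), 0)
        assert c.states == (2, 3, 0)
        assert c.positions == ((0, 0), (0, 1), (1, 1))

    def test_last_monomer_state_change_only(self):
        p = tf.Program([0, 0, 1])
        c = tf.apply_rule(tf.initial_configuration(p), 2)
        assert c.states == (0, 0, 0)
        assert c.positions == tf.initial_configuration(p).positions

    def test_blocked_move_raises(self):
        p, _ = tf.line_rotation_program(7, 6)
        c = tf.reconstruct_configuration(p, (0, 2, 3, 4, 5, 6, 0))
        with pytest.raises(BlockedMove):
            tf.apply_rule(c, 0)

    def test_progress_measure(self):
        # every applied rule removes exactly one remaining move
        p = tf.Program([2, 2, 1, 0])
        c = tf.initial_configuration(p)
        total = sum(abs(s) for s in c.states)
        for _ in range(p.total_moves):
            moves = tf.applicable_moves(c)
            assert moves, "foldable program stalled"
            c = tf.apply_rule(c, moves[0])
            new_total = sum(abs(s) for s in c.states)
            assert new_total == total - 1
            total = new_total
        assert c.is_final


class TestObservables:
    def test_turn_angle_basics(self):
        p = tf.Program([1, 1, 0])
        straight = tf.initial_configuration(p)
        assert tf.turn_angle(straight, 1) == 0
        bent = tf.apply_rule(straight, 1)  # (0,0),(1,0),(1,1): left turn
        assert tf.turn_angle(bent, 1) == 1
        with pytest.raises(IndexError):
            tf.turn_angle(straight, 0)
        with pytest.raises(IndexError):
            tf.turn_angle(straight, 2)

    def test_right_turn_negative(self):
        p = tf.Program([0, -1, 0])
        c = tf.apply_rule(tf.initial_configuration(p), 1)
        assert tf.turn_angle(c, 1) == -1

    def test_permanently_blocked(self):
        p, _ = tf.line_rotation_program(7, 6)
        c = tf.reconstruct_configuration(p, (0, 2, 3, 4, 5, 6, 0))
        assert tf.is_permanently_blocked(c)
        assert not tf.is_permanently_blocked(tf.target_configuration(
            tf.line_rotation_program(4, 1)[0]
        ))
        for s in (1, 3, 6):
            prog, _ = tf.line_rotation_program(5, s)
            assert not tf.is_permanently_blocked(tf.initial_configuration(prog))

    def test_folding_error(self):
        p = tf.Program([0, 0, 0])
        c = tf.initial_configuration(p)
        assert tf.folding_error(c, tf.Shape([(0, 0), (1, 0), (2, 0)])) == 0
        assert tf.folding_error(c, tf.Shape([(0, 0), (1, 0), (1, 1)])) == 2


class TestInvariants:
    """Exhaustive checks of the reasoning tools on small machines."""

    @pytest.mark.parametrize("states", [
        (3, 3, 3, 3, 3, 3, 0),
        (2, 3, 1, 0, 3, 2, 0),
        (1, 1, 2, 3, 3, 0),
    ])
    def test_half_plane_invariant(self, states):
        # with all states in 0..3, heads stay on/above and tails
        # on/below the horizontal line through each monomer
        p = tf.Program(states)
        for c in reachable_configurations(p):
            pos = c.positions
            for i in range(p.n):
                yi = pos[i][1]
                assert all(q[1] >= yi for q in pos[i + 1:])
                assert all(q[1] <= yi for q in pos[: i + 1])

    @pytest.mark.parametrize("n,s", [(6, 5), (5, 4), (7, 3)])
    def test_adjacent_move_count_gap(self, n, s):
        # uniform initial direction bounds |Δs(m_i) - Δs(m_{i+1})| by 2
        # for pairs of turning monomers (the terminal monomer has state
        # 0 and no direction, so it is not constrained)
        p, _ = tf.line_rotation_program(n, s)
        for c in reachable_configurations(p):
            mc = c.move_counts
            assert max(abs(a - b) for a, b in zip(mc[:-1], mc[1:-1])) <= 2

    def test_turn_angle_sum_identity(self):
        # Δs(m_j) - Δs(m_i) equals the turn-angle sum between them
        p, _ = tf.line_rotation_program(5, 4)
        for c in reachable_configurations(p):
            mc = c.move_counts
            for i in range(p.n - 1):
                for j in range(i + 1, p.n - 1):
                    angles = sum(tf.turn_angle(c, k) for k in range(i + 1, j + 1))
                    assert mc[j] - mc[i] == angles

    def test_low_move_count_monomers_never_blocked(self):
        # with states at most 5, a monomer that has moved at most once
        # always has an applicable rule
        p, _ = tf.line_rotation_program(6, 5)
        for c in reachable_configurations(p):
            for i in range(p.n):
                if c.states[i] != 0 and c.move_counts[i] <= 1:
                    assert tf.rule_applicable(c, i)


SMALL_PROGRAMS = [
    (2, 4, 3, 0),
    (-3, -2, -4, 0),
    (3, -3, 2, -1, 0),
    (1, 2, 3, 4, 0, 1),
    (-2, 3, -3, 2, 0),
    (4, 4, 4, 0),
]


@pytest.mark.parametrize("states", SMALL_PROGRAMS)
def test_engine_matches_direct_geometry(states):
    """The vectorised applicability mask and the literal translate-and-
    intersect definition agree on every valid configuration, and so do
    the successor configurations."""
    p = tf.Program(states)
    checked = 0
    for c in enumerate_valid_configurations(p):
        fast = set(tf.applicable_moves(c))
        direct = {i for i in range(p.n) if tf.rule_applicable(c, i)}
        assert fast == direct
        for i in direct:
            succ = tf.apply_rule(c, i)
            # direct geometric successor: translate the head rigidly
            shift = (
                tf.rotate_direction(c.direction(i), 2 if c.states[i] > 0 else -2).vector
                if i < p.n - 1
                else (0, 0)
            )
            expected = tuple(
                (x + shift[0], y + shift[1]) if j > i else (x, y)
                for j, (x, y) in enumerate(c.positions)
            )
            assert succ.positions == expected
        checked += 1
    assert checked > 10


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=-3, max_value=3), min_size=2, max_size=6),
    st.randoms(use_true_random=False),
)
def test_random_walk_preserves_simplicity(states, rnd):
    """Any sequence of applicable rules keeps the chain self-avoiding
    and drains the remaining-move budget by one per step."""
    p = tf.Program(states)
    c = tf.initial_configuration(p)
    for _ in range(p.total_moves):
        moves = tf.applicable_moves(c)
        if not moves:
            assert tf.is_permanently_blocked(c) or c.is_final
            break
        c = tf.apply_rule(c, rnd.choice(moves))
        assert len(set(c.positions)) == p.n
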