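"""The iterative recursion: base case, first-crossing law, closed forms,
symmetry, and exact agreement with brute-force enumeration."""

import math
from fractions import Fraction

import pytest

from crossruns import (
    PROBABILITY,
    TIMES,
    BernoulliSpec,
    base_case,
    combine_unconditional,
    enumerate_joint,
    first_crossing_weight,
    joint_conditional,
    joint_unconditional,
    symmetric_joint,
)

P_GRID = [Fraction(3, 10), Fraction(1, 2), Fraction(4, 5)]


class TestBaseCase:
    @pytest.mark.parametrize("scale", [PROBABILITY, TIMES])
    def test_all_mass_on_single_run(self, scale):
        pair = base_case(scale)
        for member in (pair.given_success, pair.given_failure):
            assert member[0, 1] == 1
            assert member.total_mass() == 1  # m**0 == 1 on either scale


class TestFirstCrossing:
    def test_known_values(self):
        s = BernoulliSpec(Fraction(3, 5))
        assert first_crossing_weight(3, 1, s, side=1) == Fraction(9, 25)
        assert first_crossing_weight(3, 2, s, side=1) == Fraction(2, 5)
        # side 0 swaps the roles of p and q
        assert first_crossing_weight(3, 1, s, side=0) == Fraction(4, 25)

    @pytest.mark.parametrize("n", range(1, 21))
    @pytest.mark.parametrize("side", [0, 1])
    def test_distribution_normalizes(self, n, side):
        s = BernoulliSpec(Fraction(2, 7))
        assert sum(first_crossing_weight(n, f, s, side) for f in range(1, n + 1)) == 1

    def test_rejects_out_of_range_f(self):
        s = BernoulliSpec(Fraction(1, 2))
        with pytest.raises(ValueError):
            first_crossing_weight(4, 0, s)
        with pytest.raises(ValueError):
            first_crossing_weight(4, 5, s)


class TestRecursion:
    def test_n2_closed_form(self):
        p = Fraction(3, 5)
        pair = joint_conditional(2, p)
        assert pair.given_success[0, 2] == p
        assert pair.given_success[1, 1] == 1 - p
        assert pair.given_failure[0, 2] == 1 - p

    def test_rejects_invalid_n(self):
        with pytest.raises(ValueError):
            joint_conditional(0, Fraction(1, 2))

    @pytest.mark.parametrize("p", P_GRID)
    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_closed_form_corners(self, n, p):
        pmf = joint_unconditional(n, p)
        q = 1 - p
        assert pmf[0, n] == p**n + q**n
        hi, lo = -(-n // 2), n // 2
        assert pmf[n - 1, 1] == p**hi * q**lo + p**lo * q**hi

    @pytest.mark.parametrize("p", P_GRID)
    @pytest.mark.parametrize("n", range(1, 11))
    def test_swapping_p_and_q_exchanges_the_pair(self, n, p):
        a = joint_conditional(n, p)
        b = joint_conditional(n, 1 - p)
        assert (a.given_success.weights == b.given_failure.weights).all()

    @pytest.mark.parametrize("p", P_GRID)
    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_enumeration_exactly(self, n, p):
        pair = joint_conditional(n, p)
        assert (
            pair.given_success.weights
            == enumerate_joint(n, p, condition=1).weights
        ).all()
        assert (
            pair.given_failure.weights
            == enumerate_joint(n, p, condition=0).weights
        ).all()
        un = combine_unconditional(pair, p)
        assert (un.weights == enumerate_joint(n, p).weights).all()

    @pytest.mark.parametrize("p", P_GRID)
    @pytest.mark.parametrize("n", [1, 4, 8, 13])
    def test_normalization_and_support(self, n, p):
        for scale in (PROBABILITY, TIMES):
            joint_unconditional(n, p, scale=scale).validate()

    def test_symmetric_p_equals_conditionals(self):
        pair = joint_conditional(7, Fraction(1, 2))
        un = combine_unconditional(pair, Fraction(1, 2))
        assert un.weights.tolist() == pair.given_success.weights.tolist()


class TestSymmetricCase:
    def test_n1_is_degenerate(self):
        pmf = symmetric_joint(1)
        assert pmf[0, 1] == 1 and pmf.total_mass() == 1

    def test_matches_general_recursion_at_half(self, sym_cache):
        general = joint_unconditional(11, Fraction(1, 2), scale=TIMES)
        assert (sym_cache.matrix(11) == general.weights).all()

    def test_all_entries_are_integers(self, sym_cache):
        assert all(isinstance(v, int) for v in sym_cache.matrix(20).flat)

    @pytest.mark.parametrize("n", [2, 7, 30, 64, 100])
    def test_crossings_marginal_is_binomial(self, sym_cache, n):
        marg = sym_cache.joint(n).marginal_crossings()
        assert [int(v) for v in marg] == [math.comb(n - 1, c) for c in range(n)]

    def test_total_mass_is_power_of_two(self, sym_cache):
        for n in (1, 5, 17, 42):
            assert sym_cache.joint(n).total_mass() == 2 ** (n - 1)
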