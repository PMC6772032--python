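"""Container behaviour: indexing, scales, marginals, box masses."""

import math
from fractions import Fraction

import pytest

from crossruns import (
    PROBABILITY,
    TIMES,
    BernoulliSpec,
    JointPMF,
    as_fraction,
    joint_unconditional,
    round_half_away,
    symmetric_joint,
)


class TestRationals:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("0.6", Fraction(3, 5)),
            ("3/5", Fraction(3, 5)),
            (0.6, Fraction(3, 5)),  # decimal literal, not the binary double
            (1, Fraction(1)),
            (Fraction(7, 9), Fraction(7, 9)),
        ],
    )
    def test_as_fraction_is_exact(self, raw, expected):
        assert as_fraction(raw) == expected

    @pytest.mark.parametrize(
        "x, digits, expected",
        [
            (Fraction(9258, 1000), 1, Fraction(93, 10)),  # 9.258 -> 9.3
            (Fraction(25, 1000), 2, Fraction(3, 100)),  # half rounds away
            (Fraction(-25, 1000), 2, Fraction(-3, 100)),
            (Fraction(2716, 32768), 3, Fraction(83, 1000)),
        ],
    )
    def test_round_half_away(self, x, digits, expected):
        assert round_half_away(x, digits) == expected


class TestBernoulliSpec:
    def test_p_plus_q_is_exactly_one(self):
        s = BernoulliSpec(Fraction(3, 7))
        assert s.p + s.q == 1
        assert s.swapped().p == s.q

    @pytest.mark.parametrize("bad", [0, 1, Fraction(3, 2), Fraction(-1, 2)])
    def test_rejects_degenerate_probabilities(self, bad):
        with pytest.raises(ValueError):
            BernoulliSpec(bad)


class TestJointPMF:
    def test_indexing_follows_c_and_l_conventions(self):
        pmf = JointPMF(3, {(0, 3): Fraction(1, 2), (2, 1): Fraction(1, 2)})
        assert pmf[0, 3] == Fraction(1, 2)
        assert pmf[1, 2] == 0
        with pytest.raises(IndexError):
            pmf[3, 1]
        with pytest.raises(IndexError):
            pmf[0, 0]

    def test_rejects_floats_and_negative_weights(self):
        with pytest.raises(TypeError):
            JointPMF(2, {(0, 2): 0.5, (1, 1): 0.5})
        with pytest.raises(ValueError):
            JointPMF(2, {(0, 2): Fraction(3, 2), (1, 1): Fraction(-1, 2)})

    def test_rescale_round_trip_is_identity(self):
        pmf = joint_unconditional(8, Fraction(3, 5), scale=TIMES)
        back = pmf.rescale(PROBABILITY).rescale(TIMES)
        assert back == pmf
        assert pmf.rescale(PROBABILITY).total_mass() == 1

    def test_times_scale_factor(self):
        # the times matrix is m**(n-1) times the probability matrix
        pmf = joint_unconditional(6, Fraction(1, 3), scale=PROBABILITY)
        times = pmf.rescale(TIMES, m=2)
        assert times[1, 3] == 32 * pmf[1, 3]
        assert times.total_mass() == 32

    def test_marginals_share_total_mass(self):
        pmf = symmetric_joint(12)
        assert pmf.marginal_crossings().sum() == pmf.total_mass()
        assert pmf.marginal_longest_run().sum() == pmf.total_mass()

    def test_longest_run_marginal_small_case(self):
        # n=2: L=1 iff the two observations differ
        p = Fraction(7, 10)
        pmf = joint_unconditional(2, p)
        marg = pmf.marginal_longest_run()
        assert marg[0] == 2 * p * (1 - p)
        assert marg[1] == p**2 + (1 - p) ** 2

    def test_box_mass_bounds_and_totals(self):
        pmf = symmetric_joint(10)
        assert pmf.box_mass(0, 10) == pmf.total_mass()
        # strict alternation: the single cell (n-1, 1)
        assert pmf.box_mass(9, 1) == pmf[9, 1]
        with pytest.raises(IndexError):
            pmf.box_mass(10, 1)
        with pytest.raises(IndexError):
            pmf.box_mass(0, 11)

    @pytest.mark.parametrize("n", [1, 2, 5, 9])
    def test_validate_passes_on_real_distributions(self, n):
        joint_unconditional(n, Fraction(2, 7)).validate()

    def test_validate_flags_bad_mass_and_support(self):
        with_bad_mass = JointPMF(3, {(0, 3): Fraction(1, 2)})
        with pytest.raises(AssertionError):
            with_bad_mass.validate()
        # (c=2, l=2) impossible in n=3: 2 crossings force l=1
        bad_support = JointPMF(
            3, {(2, 2): Fraction(1, 2), (0, 3): Fraction(1, 2)}
        )
        with pytest.raises(AssertionError):
            bad_support.validate()

    def test_expectation_product_small_case(self):
        # n=2: C*L is 1*1 with prob 2pq, else 0*2
        p = Fraction(1, 4)
        pmf = joint_unconditional(2, p)
        assert pmf.expectation_product() == 2 * p * (1 - p)
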