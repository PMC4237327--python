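"""Unit and property tests for the per-cell transformation probability."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st
from scipy import stats

from nscglioma import (
    MutationParams,
    oncogenic_hit_probability,
    per_cell_transformation_prob,
    prob_x_hits_binomial,
    prob_x_hits_poisson,
    prob_x_transforming,
)


def exact_binomial_pmf(x: int, d: int, u_o: float) -> float:
    """Arbitrary-precision binomial pmf via sympy rationals (oracle)."""
    from decimal import Decimal
    from fractions import Fraction

    p = sympy.Rational(Fraction(Decimal(repr(u_o))))
    val = sympy.binomial(d, x) * p**x * (1 - p) ** (d - x)
    return float(val.evalf(50))


class TestHitProbability:
    @pytest.mark.parametrize(
        "u, n_onco, expected",
        [(1e-7, 29, 2.9e-6), (0.0, 29, 0.0), (0.0, 7, 0.0)],
    )
    def test_product(self, u, n_onco, expected):
        p = MutationParams(u=u, n_min=1, S=1.0, n_onco=n_onco)
        assert oncogenic_hit_probability(p) == pytest.approx(expected, rel=1e-12)

    def test_catalogue_constants_accepted(self):
        # 29 glioma oncogenes among 18,440 protein-coding genes
        p = MutationParams(u=1e-7, n_min=5, S=10.0, n_onco=29, G=18440)
        assert p.u_o == pytest.approx(2.9e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(u=float("nan"), n_min=1, S=1.0),
            dict(u=1e-2, n_min=1, S=1.0),
            dict(u=-1e-9, n_min=1, S=1.0),
            dict(u=1e-7, n_min=0, S=1.0),
            dict(u=1e-7, n_min=30, S=1.0),
            dict(u=1e-7, n_min=1, S=0.0),
            dict(u=1e-7, n_min=1, S=2.0),  # exceeds 1! ordering cap
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MutationParams(**kwargs)


class TestBinomialHits:
    def test_no_hit_case(self):
        assert prob_x_hits_binomial(0, 1000, 1e-6) == pytest.approx(
            (1 - 1e-6) ** 1000, rel=1e-12
        )

    def test_normalises(self):
        total = sum(prob_x_hits_binomial(x, 50, 0.01) for x in range(51))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_x_beyond_d_is_zero_not_error(self):
        assert prob_x_hits_binomial(51, 50, 0.01) == 0.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            prob_x_hits_binomial(1, 100, 1.5)
        with pytest.raises(ValueError):
            prob_x_hits_binomial(1, 100, -0.1)

    def test_matches_arbitrary_precision_oracle(self):
        # frozen oracle values from exact_binomial_pmf (sympy rationals)
        for x, d, u_o in [(0, 1000, 1e-6), (2, 20000, 2.9e-6), (5, 50000, 1e-5)]:
            exact = exact_binomial_pmf(x, d, u_o)
            assert prob_x_hits_binomial(x, d, u_o) == pytest.approx(exact, rel=1e-10)

    def test_two_hits_close_to_poisson(self):
        # x=2, d=20000, u_o=2.9e-6: binomial within 0.5% of Poisson(2; 0.058)
        b = prob_x_hits_binomial(2, 20000, 2.9e-6)
        p = prob_x_hits_poisson(2, 2.9e-6 * 20000)
        assert b == pytest.approx(p, rel=5e-3)


class TestPoissonHits:
    def test_empty_process(self):
        assert prob_x_hits_poisson(0, 0.0) == 1.0
        assert prob_x_hits_poisson(3, 0.0) == 0.0

    def test_closed_form(self):
        assert prob_x_hits_poisson(1, 0.01) == pytest.approx(
            0.01 * math.exp(-0.01), rel=1e-12
        )

    def test_vectorised_over_lambda(self):
        lam = np.array([0.0, 0.01, 0.5])
        out = prob_x_hits_poisson(1, lam)
        assert out.shape == lam.shape
        assert out[0] == 0.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            prob_x_hits_poisson(1, -0.1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(lam=st.floats(min_value=1e-6, max_value=5.0))
    def test_normalises_over_support(self, lam):
        total = sum(prob_x_hits_poisson(x, lam) for x in range(200))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "u_o, d", [(2.9e-6, 25_000), (1e-6, 1_000), (1e-4, 100_000), (5e-5, 10_000)]
    )
    def test_agrees_with_exact_binomial(self, u_o, d):
        """Rare-event regime: Poisson within 1% of the exact binomial for
        every x whose probability is at least 1e-12 (independent oracle:
        scipy's binomial pmf)."""
        lam = u_o * d
        for x in range(0, 30):
            exact = float(stats.binom.pmf(x, d, u_o))
            if exact < 1e-12:
                continue
            approx = prob_x_hits_poisson(x, lam)
            assert abs(approx - exact) / exact <= 0.01, (x, u_o, d)


class TestTransformingProbability:
    def test_full_multiplicity_recovers_poisson(self):
        for x, lam in [(3, 0.1), (5, 0.02)]:
            S = float(math.factorial(x))
            assert prob_x_transforming(x, lam, S) == pytest.approx(
                prob_x_hits_poisson(x, lam), rel=1e-12
            )

    def test_single_hit_single_ordering(self):
        assert prob_x_transforming(1, 0.05, 1.0) == pytest.approx(
            prob_x_hits_poisson(1, 0.05), rel=1e-12
        )

    def test_strictly_increasing_in_S(self):
        vals = [prob_x_transforming(4, 0.1, S) for S in (1.0, 5.0, 20.0, 24.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_multiplicity_cap_named_in_error(self):
        with pytest.raises(ValueError, match="24"):
            prob_x_transforming(4, 0.1, 25.0)  # 4! = 24

    def test_permutation_seam(self):
        # alternative ordering model: denominator perm(n_onco, x)
        x, lam, S = 3, 0.1, 100.0
        expected = prob_x_hits_poisson(x, lam) * S / math.perm(29, 3)
        got = prob_x_transforming(x, lam, S, ordering_model="permutation")
        assert got == pytest.approx(expected, rel=1e-12)


class TestPerCellProbability:
    def test_zero_intensity(self):
        p = MutationParams(u=1e-7, n_min=3, S=2.0)
        assert per_cell_transformation_prob(0.0, p) == 0.0

    def test_truncation_at_oncogene_count_is_negligible(self):
        # support {1..29} vs {1..200}: difference < 1e-12 for lam < 0.5
        p = MutationParams(u=1e-7, n_min=1, S=1.0)
        for lam in (0.01, 0.1, 0.49):
            truncated = per_cell_transformation_prob(lam, p)
            full = sum(
                prob_x_hits_poisson(x, lam) * math.exp(-math.lgamma(x + 1))
                for x in range(1, 201)
            )
            assert abs(truncated - full) < 1e-12

    def test_nondecreasing_in_intensity(self):
        p = MutationParams(u=1e-7, n_min=5, S=50.0)
        lam = np.linspace(0.0, 0.3, 1000)
        vals = per_cell_transformation_prob(lam, p)
        assert np.all(np.diff(vals) >= 0)

    def test_monotone_in_S_and_n_min(self):
        lam = 0.2
        lo = per_cell_transformation_prob(lam, MutationParams(u=1e-7, n_min=5, S=10.0))
        hi = per_cell_transformation_prob(lam, MutationParams(u=1e-7, n_min=5, S=100.0))
        assert lo < hi
        shallow = per_cell_transformation_prob(lam, MutationParams(u=1e-7, n_min=4, S=10.0))
        steep = per_cell_transformation_prob(lam, MutationParams(u=1e-7, n_min=6, S=10.0))
        assert steep < lo < shallow

    def test_small_lambda_leading_order(self):
        # P1 -> S lam^n_min e^{-lam} / (n_min!)^2 as lam -> 0
        p = MutationParams(u=1e-7, n_min=5, S=50.0)
        lam = 1e-4
        leading = p.S * lam**5 * math.exp(-lam) / math.factorial(5) ** 2
        assert per_cell_transformation_prob(lam, p) == pytest.approx(leading, rel=1e-4)

    def test_impossible_requirement_warns_and_returns_zero(self):
        p = MutationParams(u=1e-7, n_min=5, S=50.0)
        object.__setattr__(p, "n_min", 30)  # bypass ctor to hit runtime guard
        with pytest.warns(UserWarning):
            assert per_cell_transformation_prob(0.1, p) == 0.0
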