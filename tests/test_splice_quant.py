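import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from mblsplice import splice_quant as sq


class TestEstimatePsi:
    def test_junction_normalization(self):
        # 20 reads over 2 inclusion junctions vs 10 over 1 exclusion junction
        assert sq.estimate_psi(20, 10, 2, 1).psi == pytest.approx(0.5)

    def test_zero_inclusion(self):
        est = sq.estimate_psi(0, 7, 2, 1)
        assert est.psi == 0.0 and est.ci_low == 0.0

    def test_credible_interval_matches_beta_posterior(self):
        # normalized counts 15 and 10 -> Jeffreys posterior Beta(15.5, 10.5)
        est = sq.estimate_psi(30, 10, 2, 1)
        assert est.psi == pytest.approx(0.6)
        assert est.ci_low == pytest.approx(beta_dist.ppf(0.025, 15.5, 10.5))
        assert est.ci_high == pytest.approx(beta_dist.ppf(0.975, 15.5, 10.5))
        assert est.ci_low <= est.psi <= est.ci_high

    def test_no_coverage_flagged(self):
        est = sq.estimate_psi(0, 0)
        assert est.no_coverage and math.isnan(est.psi)

    @given(inc=st.integers(0, 500), exc=st.integers(0, 500),
           k=st.integers(1, 20))
    @settings(derandomize=True, max_examples=100)
    def test_psi_invariant_under_count_scaling(self, inc, exc, k):
        if inc + exc == 0:
            return
        a = sq.estimate_psi(inc, exc).psi
        b = sq.estimate_psi(k * inc, k * exc).psi
        assert a == pytest.approx(b)


class TestGelPsi:
    @pytest.mark.parametrize("inc,exc,bg,expected", [
        (110, 110, 10, 0.5),
        (210, 10, 10, 1.0),
        (77, 43, 10, 67 / 100),
    ])
    def test_background_corrected_inclusion(self, inc, exc, bg, expected):
        assert sq.gel_psi(inc, exc, bg) == pytest.approx(expected)

    def test_no_signal_is_undefined(self):
        assert math.isnan(sq.gel_psi(10, 10, 10))

    def test_below_background_rejected(self):
        with pytest.raises(ValueError):
            sq.gel_psi(5, 20, 10)


class TestRelativeActivity:
    def test_reported_reporter_values(self):
        # repression of an exon from 67% (mock) to 19% (HsMBNL1); the
        # weakest homolog leaves inclusion at 44%
        assert sq.relative_activity(0.44, 0.67, 0.19) == \
            pytest.approx((0.44 - 0.67) / (0.19 - 0.67))

    def test_self_and_mock_limits(self):
        assert sq.relative_activity(0.19, 0.67, 0.19) == 1.0
        assert sq.relative_activity(0.67, 0.67, 0.19) == 0.0

    def test_zero_denominator_undefined(self):
        assert math.isnan(sq.relative_activity(0.5, 0.3, 0.3))


class TestBayesFactor:
    def test_identical_counts_favor_shared_psi(self):
        assert sq.bayes_factor_two_sample(10, 10, 10, 10).value < 1

    def test_no_data_is_uninformative(self):
        res = sq.bayes_factor_two_sample(0, 0, 0, 0)
        assert res.value == 1.0 and res.no_information

    def test_matches_numerical_integration_oracle(self):
        # oracle: numerically integrate both marginal likelihoods
        def binom_lik(i, e):
            return quad(lambda p: p ** i * (1 - p) ** e, 0, 1)[0]

        m_h1 = binom_lik(18, 2) * binom_lik(2, 18)
        m_h0 = quad(lambda p: p ** 20 * (1 - p) ** 20, 0, 1)[0]
        bf = sq.bayes_factor_two_sample(18, 2, 2, 18).value
        assert bf == pytest.approx(m_h1 / m_h0, rel=1e-6)
        assert bf > 5

    def test_symmetry_in_sample_order(self):
        a = sq.bayes_factor_two_sample(18, 2, 2, 18).value
        b = sq.bayes_factor_two_sample(2, 18, 18, 2).value
        assert a == pytest.approx(b)


class TestMonotonicityZ:
    def test_identical_groups_are_zero(self):
        assert sq.monotonicity_z([0.5, 0.6, 0.7], [0.7, 0.5, 0.6]) == 0.0

    def test_variance_floor_on_constant_replicates(self):
        z = sq.monotonicity_z([0.7] * 3, [0.4] * 3)
        assert z == pytest.approx(0.3 / math.sqrt(1e-4 * 2 / 3))

    def test_undefined_below_two_replicates(self):
        assert math.isnan(sq.monotonicity_z([0.5], [0.4, 0.5]))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6),
           st.lists(st.floats(0, 1), min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetric_under_group_swap(self, a, b):
        assert sq.monotonicity_z(a, b) == pytest.approx(-sq.monotonicity_z(b, a))


class TestCallRegulation:
    @pytest.mark.parametrize("dpsi,bf,z,expected", [
        (0.3, 20, 4, "activated"),
        (0.3, 4.9, 4, "unaffected"),     # Bayes-factor gate
        (-0.15, 8, -2, "repressed"),
        (0.3, 20, 1.0, "unaffected"),    # Z gate
        (0.05, 20, 4, "unaffected"),     # dPSI gate
    ])
    def test_threshold_gates(self, dpsi, bf, z, expected):
        call = sq.call_regulation("e", "c", dpsi, bf, z)
        assert call.direction == expected
        assert call.significant == (expected != "unaffected")

    def test_single_sample_comparison_skips_z(self):
        call = sq.call_regulation("e", "c", 0.3, 20, z=None)
        assert call.direction == "activated"

    def test_undefined_statistics_flag_low_coverage(self):
        call = sq.call_regulation("e", "c", math.nan, 20, 2.0)
        assert call.direction == "unaffected" and call.low_coverage

    @given(dpsi=st.floats(-1, 1), bf=st.floats(0, 50), z=st.floats(-10, 10),
           bump=st.floats(0, 5))
    @settings(derandomize=True, max_examples=200)
    def test_raising_thresholds_never_creates_significance(self, dpsi, bf, z,
                                                           bump):
        lo = sq.call_regulation("e", "c", dpsi, bf, z)
        hi = sq.call_regulation("e", "c", dpsi, bf, z,
                                bf_min=5 + bump, dpsi_min=0.1 + bump / 10,
                                z_min=1.5 + bump)
        assert not (hi.significant and not lo.significant)


class TestAgreement:
    def _call(self, dpsi, significant, event="e"):
        direction = "unaffected"
        if significant:
            direction = "activated" if dpsi > 0 else "repressed"
        return sq.RegulationCall(event, "c", dpsi, None, 10, direction,
                                 significant)

    def test_all_five_homologs_consistent(self):
        ref = self._call(0.4, True)
        homs = {f"h{i}": self._call(0.2, True) for i in range(5)}
        s = sq.homolog_agreement(ref, homs)
        assert s.n_homologs_regulating == 5 and s.consistent_direction

    def test_no_significant_homologs(self):
        s = sq.homolog_agreement(self._call(0.4, True),
                                 {"h": self._call(0.2, False)})
        assert s.n_homologs_regulating == 0

    def test_mixed_directions_counted(self):
        homs = {"h1": self._call(0.3, True), "h2": self._call(0.2, True),
                "h3": self._call(-0.2, True), "h4": self._call(0.1, False)}
        s = sq.homolog_agreement(self._call(0.4, True), homs)
        assert s.n_homologs_regulating == 3
        assert s.consistent_fraction == pytest.approx(2 / 3)
        assert not s.consistent_direction

    def test_mismatched_events_rejected(self):
        with pytest.raises(ValueError):
            sq.homolog_agreement(self._call(0.4, True),
                                 {"h": self._call(0.2, True, event="other")})


class TestDirectionBias:
    def test_one_sided_extreme(self):
        assert sq.direction_bias_test(10, 0) == pytest.approx(2 * 0.5 ** 10)

    @pytest.mark.parametrize("a,r", [(5, 5), (0, 1)])
    def test_balanced_or_singleton_is_one(self, a, r):
        assert sq.direction_bias_test(a, r) == pytest.approx(1.0)


class TestRescueCorrelation:
    def test_perfect_linear_rescue(self):
        x = {f"e{i}": 0.1 * i - 0.5 for i in range(10)}
        y = {e: 0.5 * v for e, v in x.items()}
        assert sq.rescue_correlation(x, y).r_squared == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        x = {f"e{i}": v for i, v in enumerate([0.3, -0.2, 0.5, 0.1])}
        assert sq.rescue_correlation(x, x).r_squared == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        xs = [0.30, -0.20, 0.50, 0.10, -0.40, 0.25]
        ys = [0.20, -0.10, 0.35, 0.15, -0.20, 0.10]
        x = {f"e{i}": v for i, v in enumerate(xs)}
        y = {f"e{i}": v for i, v in enumerate(ys)}
        mx, my = sum(xs) / 6, sum(ys) / 6
        cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        vx = sum((a - mx) ** 2 for a in xs)
        vy = sum((b - my) ** 2 for b in ys)
        assert sq.rescue_correlation(x, y).r_squared == \
            pytest.approx(cov ** 2 / (vx * vy))

    def test_zero_variance_undefined(self):
        x = {f"e{i}": 0.2 for i in range(5)}
        y = {f"e{i}": 0.1 * i for i in range(5)}
        assert math.isnan(sq.rescue_correlation(x, y).r_squared)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sq.rescue_correlation({"a": 1.0}, {"a": 1.0})
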