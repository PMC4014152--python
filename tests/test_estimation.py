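"""Log-log regression, RCD-profile estimation and tail extension."""

import math

import numpy as np
import pytest

import clonobranch as cb
from clonobranch.branching import ColonySizeDistribution, RCDProfile, colony_size_pmf_array
from clonobranch.estimation import (
    InsufficientDataError,
    estimate_rcd_profile,
    excess_rcd,
    extend_profile,
    loglog_fit,
    smoothed_frequency,
)

from _oracles import normal_equations_fit


def _power_law_dist(a=0.3, slope=-1.5, n_max=15):
    return ColonySizeDistribution(
        {n: a * n**slope for n in range(1, n_max + 1)}, mode="all_colonies"
    )


class TestLogLogFit:
    def test_exact_power_law(self):
        fit = loglog_fit(_power_law_dist(), fit_range=(1, 15))
        assert fit.slope == pytest.approx(-1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log10(0.3), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-10)

    def test_two_points_fit_perfectly(self):
        d = ColonySizeDistribution({2: 0.31, 9: 0.007}, mode="all_colonies")
        assert loglog_fit(d, (1, 10)).r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        n = np.arange(1, 30)
        f = 0.4 * n**-1.8 * np.exp(rng.normal(0, 0.1, len(n)))
        d = ColonySizeDistribution(dict(zip(n, f)), mode="all_colonies")
        fit = loglog_fit(d, (1, 29))
        intercept, slope = normal_equations_fit(np.log10(n), np.log10(f))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_frequencies_are_dropped(self):
        d = ColonySizeDistribution(
            {1: 0.5, 2: 0.17, 3: 0.0, 4: 0.06}, mode="all_colonies"
        )
        assert loglog_fit(d, (1, 4)).n_points == 3

    def test_insufficient_data(self):
        d = ColonySizeDistribution({2: 1.0}, mode="ge2_observed")
        with pytest.raises(InsufficientDataError):
            loglog_fit(d, (1, 49))


class TestSmoothedFrequency:
    def test_reads_off_the_line(self):
        fit = cb.LogLogFit(
            slope=-1.5, intercept=math.log10(0.5), r_squared=1.0,
            residual_se=0.0, fit_range=(1, 15), n_points=15,
        )
        assert smoothed_frequency(fit, 1) == pytest.approx(0.5)
        assert smoothed_frequency(fit, 4) == pytest.approx(0.0625)

    def test_perfect_fit_has_zero_band(self):
        fit = loglog_fit(_power_law_dist(), (1, 15))
        v, lo, hi = smoothed_frequency(fit, 5, with_band=True)
        assert lo == pytest.approx(v) and hi == pytest.approx(v)

    def test_band_brackets_fitted_value(self):
        rng = np.random.default_rng(7)
        n = np.arange(1, 20)
        f = 0.4 * n**-1.6 * np.exp(rng.normal(0, 0.15, len(n)))
        fit = loglog_fit(
            ColonySizeDistribution(dict(zip(n, f)), mode="all_colonies"), (1, 19)
        )
        for m in (1, 5, 19):
            v, lo, hi = smoothed_frequency(fit, m, with_band=True)
            assert lo < v < hi

    def test_size_must_be_positive(self):
        fit = loglog_fit(_power_law_dist(), (1, 15))
        with pytest.raises(ValueError):
            smoothed_frequency(fit, 0)

    def test_spec_against_distribution_fit(self):
        fit = loglog_fit(_power_law_dist(a=0.3), (1, 15))
        assert smoothed_frequency(fit, 4) == pytest.approx(0.3 * 4**-1.5)


def _exact_observed(p=0.25, n_max=49):
    """Exact constant-p pmf presented the way the assay reports it."""
    f = colony_size_pmf_array(p, n_max)
    mass = 1.0 - f[1]
    values = {n: f[n] / mass for n in range(2, n_max + 1)}
    return ColonySizeDistribution(
        values=values,
        mode="ge2_observed",
        clonogenic=1.0 - sum(values.values()),
    )


class TestEstimateRCDProfile:
    def test_raw_mode_round_trip_is_exact(self):
        est = estimate_rcd_profile(_exact_observed(0.25), mode="raw")
        assert est.f1_estimate == pytest.approx(0.25, abs=1e-12)
        np.testing.assert_allclose(est.profile.p1, [0.25] * 6, atol=1e-8)

    def test_imputed_f1_equals_inverted_p10(self):
        est = estimate_rcd_profile(_exact_observed(0.4), mode="raw")
        assert est.profile.p1[0] == pytest.approx(est.f1_estimate, abs=1e-10)

    def test_degenerate_two_cell_mass(self):
        obs = ColonySizeDistribution({2: 1.0}, mode="ge2_observed")
        with pytest.raises(ValueError):
            estimate_rcd_profile(obs, mode="raw")

    def test_regression_invariant_to_count_rescaling(self):
        rng = np.random.default_rng(5)
        counts = {n: int(v) for n, v in zip(range(2, 12), rng.integers(50, 4000, 10))}
        a = ColonySizeDistribution(counts, mode="counts", clonogenic=500)
        b = ColonySizeDistribution(
            {n: 13 * v for n, v in counts.items()}, mode="counts", clonogenic=6500
        )
        ea = estimate_rcd_profile(a, mode="smoothed", fit_range=(1, 8))
        eb = estimate_rcd_profile(b, mode="smoothed", fit_range=(1, 8))
        np.testing.assert_allclose(ea.profile.p1, eb.profile.p1, atol=1e-10)

    def test_smoothed_bounds_cover_truth_in_most_repetitions(self, carbon_profiles):
        """95% bands, pushed through the inversion, should cover the true
        P1(g) in at least 90% of seeded repetitions at the study's scale."""
        truth_ext = carbon_profiles[2.0]
        truth = truth_ext.p1[:6]
        f = colony_size_pmf_array(truth_ext, 49)
        probs = np.append(f[1:50], 1.0 - f[1:].sum())
        rng = np.random.default_rng(2026)
        total, covered = 0, 0
        for _ in range(10):
            counts = rng.multinomial(50_000, probs)
            obs = ColonySizeDistribution(
                {n: int(c) for n, c in zip(range(1, 50), counts[:-1]) if c and n >= 2},
                mode="counts",
                clonogenic=int(counts[-1]),
            )
            est = estimate_rcd_profile(obs, mode="smoothed", fit_range=(1, 8))
            for lo, t, hi in zip(est.lower95, truth, est.upper95):
                total += 1
                covered += lo <= t <= hi
        assert covered / total >= 0.9


class TestExtendProfile:
    def test_linear_interpolation_values(self):
        prof = extend_profile([0.2] * 6, c=0.4)
        assert prof.p1[16] == pytest.approx(0.12, abs=1e-12)
        assert prof.p1[11] == pytest.approx(0.2 + (6 / 11) * (0.12 - 0.2), abs=1e-12)

    def test_tail_endpoint_identity(self):
        for c in (0.0, 0.25, 0.7, 1.0):
            prof = extend_profile([0.1, 0.2, 0.3, 0.3, 0.25, 0.2], c)
            assert abs(prof.p1[16] - (1 - c) * prof.p1[5]) <= 1e-12

    def test_zero_decline_keeps_plateau(self):
        prof = extend_profile([0.2] * 6, c=0.0)
        assert all(p == pytest.approx(0.2) for p in prof.p1[5:])

    def test_full_decline_reaches_zero(self):
        assert extend_profile([0.2] * 6, c=1.0).p1[16] == pytest.approx(0.0)

    def test_requires_six_generations(self):
        with pytest.raises(ValueError):
            extend_profile([0.2, 0.3], c=0.4)


class TestExcessRCD:
    def test_identical_profiles_give_zero(self):
        p = RCDProfile((0.2, 0.3, 0.4))
        np.testing.assert_allclose(excess_rcd(p, p), 0.0)

    def test_constant_offset(self):
        irr = RCDProfile.constant(0.3, 5)
        ctrl = RCDProfile.constant(0.1, 5)
        np.testing.assert_allclose(excess_rcd(irr, ctrl), 0.2)

    def test_antisymmetry(self):
        a = RCDProfile((0.2, 0.5, 0.4))
        b = RCDProfile((0.1, 0.6, 0.35))
        np.testing.assert_allclose(excess_rcd(a, b), -excess_rcd(b, a))

    def test_mismatched_support(self):
        with pytest.raises(ValueError):
            excess_rcd(RCDProfile((0.2,)), RCDProfile((0.2, 0.3)))
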