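"""Survival fits, RBE, AIC model selection and curve comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

import clonobranch as cb
from clonobranch.branching import ColonySizeDistribution, RCDProfile
from clonobranch.lattice import SimulationConfig
from clonobranch.survival import (
    SurvivalCurve,
    ZeroSlopeError,
    aic_select_c,
    chi2_curve_test,
    fit_exponential,
    rbe,
    secondary_colony_sf,
    threshold_scan,
)


def _curve(doses, sf, **kw):
    return SurvivalCurve(doses=np.array(doses), sf=np.array(sf), **kw)


class TestFitExponential:
    def test_exact_exponential(self):
        doses = [1.0, 2.0, 3.0]
        fit = fit_exponential(_curve(doses, np.exp(-0.5 * np.array(doses))))
        assert fit.a == pytest.approx(0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_d10_identity(self):
        fit = fit_exponential(_curve([1, 2, 4], np.exp(-1.0 * np.array([1, 2, 4]))))
        assert fit.a == pytest.approx(1.0)
        assert fit.d10 == pytest.approx(math.log(10), abs=1e-12)
        assert fit.d10 == pytest.approx(math.log(10) / fit.a, abs=1e-12)

    def test_zero_sf_points_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="SF = 0"):
            fit = fit_exponential(_curve([1, 2, 3], [np.exp(-0.5), np.exp(-1.0), 0.0]))
        assert fit.a == pytest.approx(0.5, abs=1e-9)

    def test_flat_curve_has_no_slope(self):
        with pytest.raises(ZeroSlopeError):
            fit_exponential(_curve([0, 1, 2], [1.0, 1.0, 1.0]))


class TestRBE:
    def test_identical_fits(self):
        f = fit_exponential(_curve([1, 2], np.exp(-0.4 * np.array([1, 2]))))
        assert rbe(f, f) == pytest.approx(1.0)

    def test_ratio_arithmetic_and_reciprocity(self):
        ref = fit_exponential(_curve([1, 2], np.exp(-0.2 * np.array([1, 2]))))
        test = fit_exponential(_curve([1, 2], np.exp(-0.7 * np.array([1, 2]))))
        assert rbe(ref, test) == pytest.approx(3.5, abs=1e-9)
        assert rbe(ref, test) * rbe(test, ref) == pytest.approx(1.0, abs=1e-12)
        assert rbe(ref, test) == pytest.approx(ref.d10 / test.d10, abs=1e-9)


class TestThresholdScan:
    def test_one_row_per_threshold(self, gamma_sims, carbon_sims):
        thresholds = list(range(10, 101, 10))
        scan = threshold_scan(gamma_sims, carbon_sims, thresholds)
        assert len(scan) == 10
        assert list(scan["threshold"]) == thresholds
        assert (scan["rbe"] > 0).all()

    def test_fit_degrades_at_small_thresholds(self, gamma_sims, carbon_sims):
        """The dose response is less exponential when tiny colonies count as
        survivors."""
        scan = threshold_scan(gamma_sims, carbon_sims, [10, 100])
        r2 = scan.set_index("threshold")
        assert r2.loc[10, "r2_test"] < r2.loc[100, "r2_test"]
        assert r2.loc[10, "r2_reference"] < r2.loc[100, "r2_reference"]

    def test_empty_thresholds(self, gamma_sims, carbon_sims):
        with pytest.raises(ValueError):
            threshold_scan(gamma_sims, carbon_sims, [])


class TestAICSelectC:
    def _dist(self, values, clono=0):
        return ColonySizeDistribution(values, mode="counts", clonogenic=clono)

    def test_perfect_fit_flagged(self):
        obs = self._dist({2: 100, 3: 50, 4: 25})
        sel = aic_select_c(obs, {0.4: obs, 0.1: self._dist({2: 90, 3: 60, 4: 25})})
        assert sel.best_c == 0.4
        assert sel.perfect_fit
        assert sel.aic[0.4] == -math.inf

    def test_equal_residuals_equal_aic(self):
        obs = ColonySizeDistribution({2: 0.3, 3: 0.2}, mode="all_colonies")
        # mirrored log residuals (+log 1.2, -log 1.2) in either order
        up = ColonySizeDistribution({2: 0.36, 3: 0.2 / 1.2}, mode="all_colonies")
        down = ColonySizeDistribution({2: 0.25, 3: 0.24}, mode="all_colonies")
        sel = aic_select_c(obs, {0.1: up, 0.2: down})
        assert sel.aic[0.1] == pytest.approx(sel.aic[0.2], abs=1e-9)

    def test_invariant_to_uniform_rescaling(self):
        obs = self._dist({2: 120, 3: 60, 4: 30, 5: 12}, clono=40)
        sim = self._dist({2: 100, 3: 70, 4: 25, 5: 15}, clono=30)
        sim_scaled = self._dist(
            {n: 7 * v for n, v in sim.values.items()}, clono=7 * 30
        )
        a = aic_select_c(obs, {0.1: sim})
        b = aic_select_c(obs, {0.1: sim_scaled})
        assert a.aic[0.1] == pytest.approx(b.aic[0.1], abs=1e-12)

    def test_empty_support_is_an_error(self):
        with pytest.raises(ValueError):
            aic_select_c(self._dist({2: 10}), {0.1: self._dist({40: 10})})


class TestChi2CurveTest:
    def _counts_curve(self, doses, clono, total):
        clono = np.array(clono, dtype=float)
        total = np.array(total, dtype=float)
        sf0 = clono[0] / total[0]
        return SurvivalCurve(
            doses=np.array(doses, dtype=float),
            sf=(clono / total) / sf0,
            n_clonogenic=clono,
            n_total=total,
        )

    def test_identical_curves_give_zero_statistic(self):
        c = self._counts_curve([0, 1, 2], [800, 400, 200], [1000] * 3)
        out = chi2_curve_test(c, c)
        assert np.allclose(out["chi2"], 0.0)
        assert np.allclose(out["p_bonferroni"], 1.0)

    def test_hand_computed_two_cell_table(self):
        obs = self._counts_curve([0, 1], [800, 300], [1000, 1000])
        sim = self._counts_curve([0, 1], [800, 400], [1000, 1000])
        out = chi2_curve_test(obs, sim).set_index("dose_Gy")
        # E = (400, 600); O = (300, 700): chi2 = 100^2/400 + 100^2/600
        assert out.loc[1.0, "chi2"] == pytest.approx(100**2 / 400 + 100**2 / 600)

    def test_corrected_p_clamped_to_one(self):
        obs = self._counts_curve([0, 1, 2], [800, 410, 195], [1000] * 3)
        sim = self._counts_curve([0, 1, 2], [800, 400, 200], [1000] * 3)
        out = chi2_curve_test(obs, sim, n_comparisons=50)
        assert (out["p_bonferroni"] <= 1.0).all()


class TestSecondaryColonies:
    def _config(self):
        return SimulationConfig(seed=3, n_colonies_per_run=2000, n_runs=1)

    def test_no_residual_death_gives_full_survival(self):
        prof = cb.extend_profile([0.3] * 6, c=1.0)  # p1(16) = 0
        ctrl = cb.extend_profile([0.1] * 6, c=1.0)
        res = secondary_colony_sf(prof, self._config(), ctrl)
        assert res.p1_secondary == 0.0
        assert res.sf == pytest.approx(1.0)

    def test_certain_residual_death_kills_all(self):
        prof = cb.extend_profile([1.0] * 6, c=0.0)  # p1(16) = 1
        ctrl = cb.extend_profile([0.1] * 6, c=1.0)
        res = secondary_colony_sf(prof, self._config(), ctrl)
        assert res.sf == 0.0

    def test_monotone_in_residual_death_probability(self):
        ctrl = cb.extend_profile([0.0] * 6, c=0.0)
        sfs = []
        for p16 in (0.05, 0.25, 0.45):
            prof = cb.extend_profile([p16 / 0.6] * 6, c=0.4)  # p1(16) = p16
            sfs.append(secondary_colony_sf(prof, self._config(), ctrl).sf)
        assert sfs[0] > sfs[1] > sfs[2]

    def test_requires_extended_profiles(self):
        with pytest.raises(ValueError):
            secondary_colony_sf(
                RCDProfile((0.2,) * 6), self._config(), RCDProfile((0.1,) * 17)
            )
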