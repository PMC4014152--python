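"""Downstream survival statistics: exponential fits, D10, RBE, AIC and chi-squared.

Surviving fractions from the simulated (or observed) clonogenic assay are
fitted to the single-hit exponential ``SF = exp(-a * dose)``; the 10% survival
dose is ``D10 = ln(10) / a`` and the relative biological effectiveness of a
test radiation against a reference is the ratio of their D10 doses.  The
tail-decline constant ``c`` of an RCD profile is selected by least-squares AIC
on log-transformed abortive size distributions, and observed and simulated
dose-response curves are compared per dose by a chi-squared test on
clonogenic/non-clonogenic counts with Bonferroni correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .branching import ColonySizeDistribution, RCDProfile
from .estimation import TAIL_GENERATION
from .lattice import ColonySimResult, SimulationConfig, simulate_experiment, surviving_fraction

__all__ = [
    "ExponentialSurvivalFit",
    "SurvivalCurve",
    "ZeroSlopeError",
    "AICSelection",
    "SecondaryColonyResult",
    "fit_exponential",
    "rbe",
    "threshold_scan",
    "aic_select_c",
    "chi2_curve_test",
    "secondary_colony_sf",
]


class ZeroSlopeError(ValueError):
    """The survival curve does not decrease; the exponential slope is zero."""


@dataclass(frozen=True)
class ExponentialSurvivalFit:
    """Least-squares fit of ``SF = exp(-a * dose)`` through the origin."""

    a: float
    r_squared: float

    @property
    def d10(self) -> float:
        """Dose reducing survival to 10%: ``ln(10) / a``."""
        return math.log(10.0) / self.a


@dataclass
class SurvivalCurve:
    """Dose-response curve of surviving fractions for one radiation quality.

    ``n_clonogenic`` / ``n_total`` (optional) carry the underlying colony
    counts per dose, needed for chi-squared curve comparisons.
    """

    doses: np.ndarray
    sf: np.ndarray
    sem: np.ndarray | None = None
    label: str = ""
    n_clonogenic: np.ndarray | None = None
    n_total: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.sf = np.asarray(self.sf, dtype=float)
        if self.doses.shape != self.sf.shape:
            raise ValueError("doses and sf must have the same length")
        if np.any(self.sf < 0) or np.any(self.sf > 1 + 1e-9):
            raise ValueError("surviving fractions must lie in [0, 1]")
        zero = np.isclose(self.doses, 0.0)
        if np.any(zero) and not np.allclose(self.sf[zero], 1.0):
            raise ValueError("SF at 0 Gy must be 1")
        for name in ("sem", "n_clonogenic", "n_total"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.doses.shape:
                    raise ValueError(f"{name} must match doses in length")
                setattr(self, name, v)


def fit_exponential(curve: SurvivalCurve) -> ExponentialSurvivalFit:
    """Fit ``ln SF = -a * dose`` through the origin by least squares.

    Points with ``SF = 0`` have no finite logarithm and are excluded with a
    warning.  R² is computed on the log scale about the mean of the retained
    points.
    """
    keep = curve.sf > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {int(np.sum(~keep))} dose point(s) with SF = 0 from the "
            "exponential fit (log undefined)",
            stacklevel=2,
        )
    d = curve.doses[keep]
    y = np.log(curve.sf[keep])
    if len(d) < 2:
        raise ValueError("need >= 2 dose points with SF > 0")
    denom = float(np.dot(d, d))
    if denom == 0:
        raise ValueError("all retained dose points are 0 Gy")
    a = -float(np.dot(d, y)) / denom
    if a <= 0:
        raise ZeroSlopeError(f"fitted slope a = {a} is not positive")
    resid = y + a * d
    rss = float(np.dot(resid, resid))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        r2 = 1.0 if rss < 1e-30 else 0.0
    else:
        r2 = 1.0 - rss / tss
    return ExponentialSurvivalFit(a=a, r_squared=r2)


def rbe(reference: ExponentialSurvivalFit, test: ExponentialSurvivalFit) -> float:
    """Relative biological effectiveness from 10% survival doses.

    ``RBE = D10(reference) / D10(test) = a_test / a_reference``; the test
    radiation is more effective when it needs less dose for the same kill.
    """
    if reference.a <= 0 or test.a <= 0:
        raise ValueError("both survival slopes must be positive")
    return test.a / reference.a


def _curve_from_results(
    results: dict[float, ColonySimResult],
    threshold: int,
    label: str,
) -> SurvivalCurve:
    if 0.0 not in results:
        raise ValueError(f"{label}: results must include the 0 Gy control")
    control_pe = results[0.0].plating_efficiency(threshold)
    doses = sorted(results)
    sf, n_clono, n_tot = [], [], []
    for d in doses:
        res = results[d]
        pe = res.plating_efficiency(threshold)
        sf.append(pe / control_pe if control_pe > 0 else np.nan)
        n_clono.append(int(np.sum(res.sizes >= threshold)))
        n_tot.append(len(res.sizes))
    return SurvivalCurve(
        doses=np.array(doses),
        sf=np.array(sf),
        label=label,
        n_clonogenic=np.array(n_clono),
        n_total=np.array(n_tot),
    )


def threshold_scan(
    sim_reference: dict[float, ColonySimResult],
    sim_test: dict[float, ColonySimResult],
    thresholds: list[int],
) -> pd.DataFrame:
    """Refit both survival curves at each clonogenic threshold.

    Returns one row per threshold with the exponential slopes, their R² and
    the RBE, exposing how the choice of the cells-per-colony criterion
    distorts the dose-response linearity and the RBE.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be nonempty")
    rows = []
    for thr in thresholds:
        ref_fit = fit_exponential(
            _curve_from_results(sim_reference, int(thr), "reference")
        )
        test_fit = fit_exponential(_curve_from_results(sim_test, int(thr), "test"))
        rows.append(
            {
                "threshold": int(thr),
                "a_reference": ref_fit.a,
                "a_test": test_fit.a,
                "r2_reference": ref_fit.r_squared,
                "r2_test": test_fit.r_squared,
                "rbe": rbe(ref_fit, test_fit),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AICSelection:
    """AIC per candidate tail constant and the minimizing value."""

    aic: dict[float, float]
    best_c: float
    perfect_fit: bool = False


def aic_select_c(
    obs: ColonySizeDistribution,
    sims: dict[float, ColonySizeDistribution],
    size_range: tuple[int, int] = (2, 49),
) -> AICSelection:
    """Select the tail-decline constant ``c`` by least-squares AIC.

    For each candidate, residuals are ``log10 f_obs - log10 f_sim`` over the
    abortive sizes where both distributions are positive, and
    ``AIC = N ln(RSS / N) + 2k`` with ``k = 1`` (the constant ``c``).  Both
    inputs are normalized to frequencies first, so the selection is invariant
    to uniform count rescaling.  A perfect fit (``RSS = 0``) is reported as
    ``-inf`` with the ``perfect_fit`` flag set.
    """
    if not sims:
        raise ValueError("sims must map at least one candidate c to a distribution")
    n_lo, n_hi = size_range
    obs_f = obs.to_frequencies() if obs.mode == "counts" else obs
    aic: dict[float, float] = {}
    perfect = False
    for c, sim in sims.items():
        sim_f = sim.to_frequencies() if sim.mode == "counts" else sim
        pairs = [
            (obs_f.freq(n), sim_f.freq(n))
            for n in range(n_lo, n_hi + 1)
            if obs_f.freq(n) > 0 and sim_f.freq(n) > 0
        ]
        if not pairs:
            raise ValueError(
                f"no common positive support in [{n_lo}, {n_hi}] for c = {c}"
            )
        resid = np.log10([o for o, _ in pairs]) - np.log10([s for _, s in pairs])
        rss = float(np.dot(resid, resid))
        n = len(pairs)
        if rss == 0.0:
            aic[c] = -math.inf
            perfect = True
        else:
            aic[c] = n * math.log(rss / n) + 2.0
    best = min(aic, key=lambda c: (aic[c], c))
    return AICSelection(aic=aic, best_c=best, perfect_fit=perfect)


def chi2_curve_test(
    observed: SurvivalCurve,
    simulated: SurvivalCurve,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Per-dose chi-squared comparison of observed vs simulated survival.

    At each paired dose the observed (clonogenic, non-clonogenic) counts are
    tested against expected counts obtained by scaling the simulated
    clonogenic proportion to the observed total (1 df).  P values are
    Bonferroni-corrected: ``p_corr = min(1, p * n_comparisons)``, with
    ``n_comparisons`` defaulting to the number of doses tested.
    """
    for curve, name in ((observed, "observed"), (simulated, "simulated")):
        if curve.n_clonogenic is None or curve.n_total is None:
            raise ValueError(f"{name} curve must carry clonogenic/total counts")
    if not np.array_equal(observed.doses, simulated.doses):
        raise ValueError("curves must be paired on identical doses")
    rows = []
    for i, dose in enumerate(observed.doses):
        o_clono = observed.n_clonogenic[i]
        o_total = observed.n_total[i]
        sim_prop = simulated.n_clonogenic[i] / simulated.n_total[i]
        e_clono = sim_prop * o_total
        e_non = (1.0 - sim_prop) * o_total
        if e_clono <= 0 or e_non <= 0:
            warnings.warn(
                f"dose {dose} Gy skipped: zero expected count", stacklevel=2
            )
            continue
        o = np.array([o_clono, o_total - o_clono])
        e = np.array([e_clono, e_non])
        stat = float(np.sum((o - e) ** 2 / e))
        p = float(stats.chi2.sf(stat, df=1))
        rows.append({"dose_Gy": float(dose), "chi2": stat, "p": p})
    df = pd.DataFrame(rows)
    m = len(df) if n_comparisons is None else int(n_comparisons)
    if len(df):
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    return df


@dataclass(frozen=True)
class SecondaryColonyResult:
    """Surviving fraction of re-plated (secondary) colonies."""

    sf: float
    plating_efficiency: float
    control_plating_efficiency: float
    p1_secondary: float
    result: ColonySimResult = field(repr=False)
    control_result: ColonySimResult = field(repr=False)


def secondary_colony_sf(
    primary_profile: RCDProfile,
    config: SimulationConfig,
    control: RCDProfile,
) -> SecondaryColonyResult:
    """Simulate secondary colony formation after re-plating.

    Cells harvested from a primary colony have been through 16 generations;
    their residual RCD probability is taken as the primary profile's value at
    generation 16 and assumed constant throughout secondary growth.  The SF
    is normalized to the secondary plating efficiency of the control.
    """
    for prof, name in ((primary_profile, "primary_profile"), (control, "control")):
        if prof.max_generation < TAIL_GENERATION:
            raise ValueError(f"{name} must be extended to generation {TAIL_GENERATION}")
    p16 = primary_profile.p1_at(TAIL_GENERATION)
    p16_ctrl = control.p1_at(TAIL_GENERATION)
    test_res = simulate_experiment(
        RCDProfile.constant(p16, config.n_generations), config
    )
    ctrl_res = simulate_experiment(
        RCDProfile.constant(p16_ctrl, config.n_generations), config
    )
    sf = surviving_fraction(test_res, ctrl_res)
    return SecondaryColonyResult(
        sf=sf,
        plating_efficiency=test_res.plating_efficiency(),
        control_plating_efficiency=ctrl_res.plating_efficiency(),
        p1_secondary=p16,
        result=test_res,
        control_result=ctrl_res,
    )
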