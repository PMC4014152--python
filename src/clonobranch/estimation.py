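"""Estimation of RCD probability profiles from observed colony-count data.

The estimation pipeline mirrors the analysis applied to clonogenic-assay
tables: impute the unobservable 1-cell colony frequency from the 2-cell
frequency, renormalize to the all-colony scale, fit the abortive size
distribution as a straight line on the log-log plot (with a 95% confidence
band for the regression mean), read smoothed frequencies for sizes 1..6 off
the fitted line, and invert them through the branching recursion to obtain
``P1(g)`` for generations 0..5.  Beyond generation 5 the profile is extended
linearly down to ``(1 - c) * P1(5)`` at generation 16, where ``c`` is the
tail-decline constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .branching import (
    ColonySizeDistribution,
    RCDProfile,
    colony_size_pmf_array,
    estimate_f1,
    invert_p1,
)

__all__ = [
    "LogLogFit",
    "RCDEstimate",
    "InsufficientDataError",
    "loglog_fit",
    "smoothed_frequency",
    "estimate_rcd_profile",
    "extend_profile",
    "excess_rcd",
]

#: generations recoverable from the abortive size distribution (0..5)
GMAX_ESTIMATED = 5

#: generation at which the linear tail extension ends
TAIL_GENERATION = 16


class InsufficientDataError(ValueError):
    """Fewer than two positive frequencies available for regression."""


@dataclass(frozen=True)
class LogLogFit:
    """Ordinary least-squares fit of ``log10 f_n`` against ``log10 n``.

    ``x_mean`` and ``sxx`` (the centered sum of squares of ``log10 n``) are
    retained so the confidence band of the regression mean can be evaluated
    at arbitrary sizes.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    fit_range: tuple[int, int]
    n_points: int
    x_mean: float = 0.0
    sxx: float = 0.0

    def __post_init__(self):
        if self.n_points < 2:
            raise InsufficientDataError("a log-log fit needs >= 2 points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError(f"R^2 = {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class RCDEstimate:
    """An estimated RCD profile with per-generation 95% bounds."""

    profile: RCDProfile
    lower95: tuple[float, ...]
    upper95: tuple[float, ...]
    fit: LogLogFit | None
    f1_estimate: float
    mode: str = "smoothed"

    def __post_init__(self):
        for g, (lo, p, hi) in enumerate(
            zip(self.lower95, self.profile.p1, self.upper95)
        ):
            if not (0.0 <= lo <= p <= hi <= 1.0):
                raise ValueError(
                    f"bounds at generation {g} do not bracket the estimate: "
                    f"{lo} <= {p} <= {hi} violated"
                )


def loglog_fit(
    dist: ColonySizeDistribution,
    fit_range: tuple[int, int] = (1, 49),
) -> LogLogFit:
    """OLS regression of log10 frequency on log10 colony size.

    Sizes with zero frequency carry no information on the log scale and are
    excluded.  Frequencies must be on the all-colony scale so that the
    imputed 1-cell point can participate in the fit.
    """
    n_lo, n_hi = int(fit_range[0]), int(fit_range[1])
    if n_lo < 1 or n_hi < n_lo:
        raise ValueError(f"invalid fit range {fit_range}")
    pts = [
        (n, v)
        for n, v in dist.values.items()
        if n_lo <= n <= n_hi and v > 0
    ]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 positive frequencies in [{n_lo}, {n_hi}], got {len(pts)}"
        )
    x = np.log10([n for n, _ in pts])
    y = np.log10([v for _, v in pts])
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rss = float(np.dot(resid, resid))
    df = len(pts) - 2
    s = math.sqrt(rss / df) if df > 0 else 0.0
    return LogLogFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(1.0, float(res.rvalue) ** 2),
        residual_se=s,
        fit_range=(n_lo, n_hi),
        n_points=len(pts),
        x_mean=float(x.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def smoothed_frequency(
    fit: LogLogFit,
    n: int,
    *,
    with_band: bool = False,
    confidence: float = 0.95,
):
    """Fitted frequency at size ``n``, optionally with the 95% band.

    The band is the confidence interval of the regression *mean* at
    ``log10 n`` (t distribution, ``n_points - 2`` degrees of freedom); it
    collapses to the fitted value for a perfect fit.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"colony size must be >= 1, got {n}")
    x0 = math.log10(n)
    yhat = fit.intercept + fit.slope * x0
    value = 10.0 ** yhat
    if not with_band:
        return value
    df = fit.n_points - 2
    if df <= 0 or fit.residual_se == 0.0 or fit.sxx == 0.0:
        return value, value, value
    t = stats.t.ppf(0.5 + confidence / 2.0, df)
    half = t * fit.residual_se * math.sqrt(
        1.0 / fit.n_points + (x0 - fit.x_mean) ** 2 / fit.sxx
    )
    return value, 10.0 ** (yhat - half), 10.0 ** (yhat + half)


def _invert_clamped(f_vals: Sequence[float], gmax: int) -> np.ndarray:
    prof = invert_p1(f_vals, gmax, clamp=True)
    return np.clip(np.asarray(prof.p1), 0.0, 1.0)


def estimate_rcd_profile(
    obs: ColonySizeDistribution,
    *,
    mode: str = "smoothed",
    fit_range: tuple[int, int] = (1, 49),
    gmax: int = GMAX_ESTIMATED,
    on_infeasible: str = "raise",
) -> RCDEstimate:
    """Estimate ``P1(0..gmax)`` from an observed (>= 2 cell) size distribution.

    Pipeline: (1) impute ``f1 = sqrt(F2)`` from the observed 2-cell
    frequency; (2) rescale observed frequencies to the all-colony scale,
    ``f_n = F_n (1 - f1)``; (3) in ``smoothed`` mode, fit the log-log
    regression over ``fit_range`` (the imputed 1-cell point included) and
    replace ``f_1..f_{gmax+1}`` with fitted values; (4) invert the branching
    recursion to obtain ``P1(0..gmax)``; (5) repeat the inversion at the
    lower and upper 95% confidence-band frequencies for per-generation
    probability bounds.  ``raw`` mode skips the regression and inverts the
    renormalized frequencies directly; when the input carries counts, its
    95% bounds come from re-inverting at +/- 1.96 multinomial standard
    errors of the observed frequencies (otherwise they collapse to the
    point estimate).

    ``on_infeasible`` controls what happens when a sampled frequency falls
    outside the range attainable by any probability — ``"raise"`` propagates
    the infeasibility error (with the generation index), ``"clamp"`` takes
    the boundary value 0 or 1, the constrained least-squares answer for a
    noisy target just past the feasible edge.
    """
    if mode not in ("smoothed", "raw"):
        raise ValueError(f"mode must be 'smoothed' or 'raw', got {mode!r}")
    if on_infeasible not in ("raise", "clamp"):
        raise ValueError("on_infeasible must be 'raise' or 'clamp'")
    clamp_point = on_infeasible == "clamp"
    n_observed = obs.total() if obs.mode == "counts" else None
    obs = obs.to_ge2_observed()
    F2 = obs.freq(2)
    if F2 <= 0:
        raise ValueError("observed distribution has no 2-cell colonies")
    f1 = estimate_f1(F2)
    if f1 >= 1.0:
        raise ValueError("imputed 1-cell frequency is 1: degenerate distribution")

    scale = 1.0 - f1
    all_vals = {1: f1}
    all_vals.update({n: v * scale for n, v in obs.values.items()})
    all_dist = ColonySizeDistribution(
        values=all_vals,
        mode="all_colonies",
        dose=obs.dose,
        clonogenic=obs.clonogenic * scale,
    )

    if mode == "raw":
        targets = [all_dist.freq(n) for n in range(1, gmax + 2)]
        profile = invert_p1(targets, gmax, clamp=clamp_point)
        p = np.asarray(profile.p1)
        lower = upper = p
        if n_observed and n_observed > 0:
            # Per-generation bounds from the multinomial SE of the one
            # observed frequency that fixes that generation (the system is
            # triangular: f_{g+1} -> P1(g) given the earlier generations).
            z = 1.96
            lower = p.copy()
            upper = p.copy()
            for g in range(gmax + 1):
                F = obs.freq(2) if g == 0 else obs.freq(g + 1)
                se = math.sqrt(max(F, 0.0) * (1.0 - min(F, 1.0)) / n_observed)
                if g == 0:
                    # f1 = sqrt(F2): transform the F2 interval directly
                    lower[0] = math.sqrt(max(0.0, F - z * se))
                    upper[0] = min(1.0, math.sqrt(min(1.0, F + z * se)))
                    continue
                for sign, store in ((-1.0, lower), (1.0, upper)):
                    t = targets.copy()
                    t[g] = (F + sign * z * se) * scale
                    store[g] = _invert_clamped(t, gmax)[g]
            lower = np.minimum(lower, p)
            upper = np.maximum(upper, p)
        return RCDEstimate(
            profile=profile,
            lower95=tuple(float(v) for v in lower),
            upper95=tuple(float(v) for v in upper),
            fit=None,
            f1_estimate=f1,
            mode="raw",
        )

    fit = loglog_fit(all_dist, fit_range)
    mid, lo, hi = [], [], []
    for n in range(1, gmax + 2):
        v, v_lo, v_hi = smoothed_frequency(fit, n, with_band=True)
        mid.append(v)
        lo.append(v_lo)
        hi.append(v_hi)
    profile = invert_p1(mid, gmax, clamp=clamp_point)
    p = np.asarray(profile.p1)
    p_lo = _invert_clamped(lo, gmax)
    p_hi = _invert_clamped(hi, gmax)
    lower = np.minimum(np.minimum(p_lo, p_hi), p)
    upper = np.maximum(np.maximum(p_lo, p_hi), p)
    return RCDEstimate(
        profile=profile,
        lower95=tuple(float(v) for v in lower),
        upper95=tuple(float(v) for v in upper),
        fit=fit,
        f1_estimate=f1,
        mode="smoothed",
    )


def extend_profile(estimate, c: float) -> RCDProfile:
    """Extend ``P1(0..5)`` to generation 16 by linear tail decline.

    ``P1(16) = (1 - c) * P1(5)`` and generations 6..15 are interpolated
    linearly between ``P1(5)`` and ``P1(16)``.  ``c = 0`` keeps the RCD
    probability constant in the tail; ``c = 1`` drives it to zero.
    """
    c = float(c)
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"c must lie in [0, 1], got {c}")
    if isinstance(estimate, RCDEstimate):
        head = estimate.profile.p1
    elif isinstance(estimate, RCDProfile):
        head = estimate.p1
    else:
        head = tuple(float(v) for v in estimate)
    if len(head) < GMAX_ESTIMATED + 1:
        raise ValueError("profile must define P1(0..5) before tail extension")
    head = head[: GMAX_ESTIMATED + 1]
    p5 = head[GMAX_ESTIMATED]
    p16 = (1.0 - c) * p5
    span = TAIL_GENERATION - GMAX_ESTIMATED
    tail = tuple(
        p5 + (g - GMAX_ESTIMATED) / span * (p16 - p5)
        for g in range(GMAX_ESTIMATED + 1, TAIL_GENERATION + 1)
    )
    return RCDProfile(head + tail, c=c)


def excess_rcd(irradiated: RCDProfile, control: RCDProfile) -> np.ndarray:
    """Irradiation-induced excess RCD probability per generation.

    Sign convention: ``excess(g) = P1_irradiated(g) - P1_control(g)``, so a
    dose that increases reproductive cell death yields positive excess.
    """
    if len(irradiated.p1) != len(control.p1):
        raise ValueError(
            f"generation support mismatch: {len(irradiated.p1)} vs {len(control.p1)}"
        )
    return np.asarray(irradiated.p1) - np.asarray(control.p1)
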