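"""Exact probability computations for the binary branching process.

A cell at each branch point either undergoes reproductive cell death (RCD,
probability ``P1``) or divides into two daughters (probability ``P2 = 1 - P1``).
The mother is replaced by its daughters, so the size of a fully abortive
colony is the number of terminal (dead) cells — the leaves of the binary
lineage tree.  ``P1`` may depend on the generation ``g`` (the depth of the
branch point), which is what lets the model express RCD that persists, and
slowly declines, over many generations after irradiation.

For a constant ``P1 = p`` the size distribution has the closed form

    f_n = C_{n-1} p^n (1-p)^{n-1}

with Catalan numbers ``C_k``; the recursion implemented here reduces to that
exactly and generalizes it to generation-dependent profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RCDProfile",
    "ColonySizeDistribution",
    "InversionInfeasibleError",
    "InversionConsistencyError",
    "colony_size_pmf",
    "extinction_mass",
    "estimate_f1",
    "invert_p1",
]

_PROB_TOL = 1e-12


class InversionInfeasibleError(ValueError):
    """No RCD probability in [0, 1] reproduces the target frequency."""

    def __init__(self, generation: int, message: str | None = None):
        self.generation = generation
        super().__init__(
            message
            or f"no P1({generation}) in [0, 1] reproduces the target frequency"
        )


class InversionConsistencyError(RuntimeError):
    """The inversion residual was not monotone in P1(g); internal error."""


def _check_prob(p: float, name: str = "probability") -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return p


@dataclass(frozen=True)
class RCDProfile:
    """Per-generation reproductive-cell-death probabilities ``P1(g)``.

    Parameters
    ----------
    p1
        Probabilities indexed by generation ``g = 0..G``.
    c
        Optional tail-decline constant used when the profile was produced by
        linear tail extension: ``p1[G] = (1 - c) * p1[5]``.

    Beyond the stored horizon the profile is continued at its last value,
    ``P1(g) = p1[G]`` for ``g > G``.
    """

    p1: tuple[float, ...]
    c: float | None = None

    def __post_init__(self):
        if len(self.p1) < 1:
            raise ValueError("profile must define at least generation 0")
        object.__setattr__(
            self, "p1", tuple(_check_prob(p, f"p1[{g}]") for g, p in enumerate(self.p1))
        )
        if self.c is not None:
            _check_prob(self.c, "c")

    @property
    def max_generation(self) -> int:
        return len(self.p1) - 1

    def p1_at(self, g: int) -> float:
        """``P1(g)``, continued at the last stored value beyond the horizon."""
        if g < 0:
            raise ValueError("generation must be nonnegative")
        return self.p1[min(g, self.max_generation)]

    def is_constant(self) -> bool:
        return all(p == self.p1[0] for p in self.p1)

    @classmethod
    def constant(cls, p: float, max_generation: int = 16) -> "RCDProfile":
        """Profile with the same death probability at every generation."""
        return cls(p1=(float(p),) * (max_generation + 1))


@dataclass
class ColonySizeDistribution:
    """Colony-size frequencies or counts.

    ``values`` maps the number of cells per colony (``n >= 1``) to a
    frequency or count.  ``clonogenic`` holds the mass or count of the
    clonogenic bucket (colonies at or above the scoring threshold) when the
    distribution does not resolve individual large sizes.

    Modes
    -----
    ``all_colonies``
        Frequencies over every inoculated cell's fate, including the
        (model-imputed) 1-cell colonies; total mass (plus ``clonogenic``)
        is at most 1.
    ``ge2_observed``
        The assay's view: frequencies over colonies with >= 2 cells
        (abortive sizes plus the clonogenic bucket), summing to 1.
    ``counts``
        Raw nonnegative counts.
    """

    values: dict[int, float]
    mode: str = "counts"
    dose: float | None = None
    clonogenic: float = 0.0

    _MODES = ("all_colonies", "ge2_observed", "counts")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        clean: dict[int, float] = {}
        for n, v in self.values.items():
            n = int(n)
            v = float(v)
            if n < 1:
                raise ValueError(f"colony size must be >= 1, got {n}")
            if v < 0:
                raise ValueError(f"negative value {v} for size {n}")
            clean[n] = v
        self.values = dict(sorted(clean.items()))
        if self.clonogenic < 0:
            raise ValueError("clonogenic mass must be nonnegative")
        total = sum(self.values.values()) + self.clonogenic
        if self.mode == "all_colonies" and total > 1 + 1e-9:
            raise ValueError(f"all_colonies mass {total} exceeds 1")
        if self.mode == "ge2_observed":
            if 1 in self.values:
                raise ValueError("ge2_observed support excludes 1-cell colonies")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"ge2_observed frequencies must sum to 1, got {total}")

    def freq(self, n: int) -> float:
        return self.values.get(int(n), 0.0)

    def total(self) -> float:
        return sum(self.values.values()) + self.clonogenic

    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.values), dtype=int)

    def to_frequencies(self) -> "ColonySizeDistribution":
        """Counts normalized by the grand total (clonogenic bucket included)."""
        if self.mode != "counts":
            return self
        tot = self.total()
        if tot == 0:
            raise ValueError("cannot normalize an empty count table")
        return ColonySizeDistribution(
            values={n: v / tot for n, v in self.values.items()},
            mode="all_colonies" if 1 in self.values else "ge2_observed",
            dose=self.dose,
            clonogenic=self.clonogenic / tot,
        )

    def to_ge2_observed(self) -> "ColonySizeDistribution":
        """Drop 1-cell colonies and renormalize over observable (>= 2 cell) colonies."""
        if self.mode == "ge2_observed":
            return self
        freqs = self.to_frequencies() if self.mode == "counts" else self
        mass = sum(v for n, v in freqs.values.items() if n >= 2) + freqs.clonogenic
        if mass <= 0:
            raise ValueError("no colonies with >= 2 cells")
        return ColonySizeDistribution(
            values={n: v / mass for n, v in freqs.values.items() if n >= 2},
            mode="ge2_observed",
            dose=self.dose,
            clonogenic=freqs.clonogenic / mass,
        )


def _as_profile(profile) -> RCDProfile:
    if isinstance(profile, RCDProfile):
        return profile
    return RCDProfile.constant(float(profile))


def _pmf_constant(p: float, n_max: int) -> np.ndarray:
    """Size pmf for constant P1 via the self-consistent convolution recursion."""
    f = np.zeros(n_max + 1)
    f[1] = p
    q = 1.0 - p
    for n in range(2, n_max + 1):
        # f_n = (1-p) * sum_{j=1}^{n-1} f_j f_{n-j}
        f[n] = q * float(np.dot(f[1:n], f[n - 1:0:-1]))
    return f


def _pmf_profile(profile: RCDProfile, n_max: int) -> np.ndarray:
    """Generation-0 size pmf for a generation-dependent profile.

    Works down from the deepest generation that can matter: a subtree rooted
    at depth g inside a colony of at most n_max cells has at most n_max - g
    leaves, so level n_max - 1 needs only its 1-cell term.
    """
    f_next = np.zeros(n_max + 1)
    f_g = np.zeros(n_max + 1)
    for g in range(n_max - 1, -1, -1):
        p = profile.p1_at(g)
        f_g = np.zeros(n_max + 1)
        f_g[1] = p
        if n_max >= 2:
            conv = np.convolve(f_next[1:], f_next[1:])
            f_g[2:] = (1.0 - p) * conv[: n_max - 1]
        f_next = f_g
    return f_g


def colony_size_pmf(profile, n_max: int) -> ColonySizeDistribution:
    """Probability of an abortive colony ending with exactly ``n`` cells.

    Parameters
    ----------
    profile
        An :class:`RCDProfile` or a single constant probability.
    n_max
        Largest colony size to evaluate.

    Returns
    -------
    ColonySizeDistribution
        ``all_colonies``-mode frequencies ``f_n`` for ``n = 1..n_max``.
        Mass not captured by any finite ``n`` is the clonogenic
        (non-extinct) component and is *not* included.

    Notes
    -----
    The generation-dependent recursion, with ``f^{(g)}_n`` the probability
    that a cell at generation ``g`` founds an ``n``-cell abortive subtree, is

        f^{(g)}_1 = P1(g)
        f^{(g)}_n = (1 - P1(g)) * sum_{j=0}^{n-2} f^{(g+1)}_{1+j} f^{(g+1)}_{n-1-j}

    and the colony distribution is ``f^{(0)}``.  For constant ``P1`` this is
    exactly the classical one-level recursion.
    """
    n_max = int(n_max)
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    prof = _as_profile(profile)
    if prof.is_constant():
        f = _pmf_constant(prof.p1[0], n_max)
    else:
        f = _pmf_profile(prof, n_max)
    return ColonySizeDistribution(
        values={n: float(f[n]) for n in range(1, n_max + 1)},
        mode="all_colonies",
    )


def colony_size_pmf_array(profile, n_max: int) -> np.ndarray:
    """Like :func:`colony_size_pmf` but returning ``f[0..n_max]`` (``f[0] = 0``)."""
    n_max = int(n_max)
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    prof = _as_profile(profile)
    if prof.is_constant():
        return _pmf_constant(prof.p1[0], n_max)
    return _pmf_profile(prof, n_max)


def extinction_mass(p: float) -> float:
    """Total probability that the colony of a single cell is finite (abortive).

    For constant death probability ``p`` the extinction probability of the
    binary process is the smaller root of ``q = p + (1 - p) q**2``, i.e.
    ``min(1, p / (1 - p))``.
    """
    p = _check_prob(p, "p")
    if p >= 1.0:
        return 1.0
    return min(1.0, p / (1.0 - p))


def estimate_f1(F2: float) -> float:
    """Impute the (unobservable) frequency of 1-cell colonies.

    One-cell colonies cannot be scored in the assay; their frequency is
    inferred from the observed frequency ``F2`` of 2-cell colonies among
    colonies with >= 2 cells, assuming the same RCD probability ``p`` at
    generations 0 and 1.  Then ``f1 = p``, ``f2 = (1 - p) p**2`` and
    ``F2 = f2 / (1 - f1) = p**2``, so ``f1 = sqrt(F2)``.
    """
    F2 = float(F2)
    if not (0.0 <= F2 <= 1.0) or math.isnan(F2):
        raise ValueError(f"F2 must lie in [0, 1], got {F2!r}")
    return math.sqrt(F2)


def invert_p1(
    f_target: Sequence[float],
    gmax: int,
    *,
    tol: float = 1e-15,
    max_iter: int = 200,
    clamp: bool = False,
) -> RCDProfile:
    """Recover ``P1(0..gmax)`` from all-colony frequencies ``f_1..f_{gmax+1}``.

    The system is triangular: ``f_1`` fixes ``P1(0)`` directly, and given
    ``P1(0..g-1)``, the frequency ``f_{g+1}`` is a polynomial in ``P1(g)``
    that is strictly increasing on [0, 1] (every depth-``g`` cell in a
    colony of ``g+1`` cells is necessarily a terminal cell), so each
    generation is solved by bisection.

    Parameters
    ----------
    f_target
        Frequencies ``f_1 .. f_{gmax+1}`` in ``all_colonies`` mode.
    gmax
        Last generation to recover.
    clamp
        When True, targets outside the attainable range yield 0 or 1
        instead of raising; used when inverting confidence-band frequencies
        that need not be jointly feasible.
    """
    gmax = int(gmax)
    if gmax < 0:
        raise ValueError("gmax must be >= 0")
    f_target = [float(v) for v in f_target]
    if len(f_target) < gmax + 1:
        raise ValueError(
            f"need f_1..f_{gmax + 1} ({gmax + 1} values), got {len(f_target)}"
        )

    p1: list[float] = []
    f1 = f_target[0]
    if not (0.0 <= f1 <= 1.0):
        if clamp:
            f1 = min(1.0, max(0.0, f1))
        else:
            raise InversionInfeasibleError(0, f"f_1 = {f1} is not a probability")
    p1.append(f1)

    for g in range(1, gmax + 1):
        target = f_target[g]

        def value(x: float) -> float:
            prof = RCDProfile(tuple(p1) + (x,))
            return colony_size_pmf_array(prof, g + 1)[g + 1]

        lo_val, hi_val = value(0.0), value(1.0)
        if hi_val < lo_val - _PROB_TOL:
            raise InversionConsistencyError(
                f"residual for generation {g} is not increasing in P1({g})"
            )
        # grace for round-off amplified through the earlier generations
        slack = 1e-9 * max(hi_val - lo_val, abs(target), 1e-12)
        if target < lo_val - slack or target > hi_val + slack:
            if clamp:
                p1.append(0.0 if target < lo_val else 1.0)
                continue
            raise InversionInfeasibleError(
                g,
                f"f_{g + 1} = {target} is outside the attainable range "
                f"[{lo_val}, {hi_val}] for generation {g}",
            )
        if target <= lo_val:
            p1.append(0.0)
            continue
        if target >= hi_val:
            p1.append(1.0)
            continue
        lo, hi = 0.0, 1.0
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if hi - lo <= tol or not (lo < mid < hi):
                break
            if value(mid) < target:
                lo = mid
            else:
                hi = mid
        p1.append(0.5 * (lo + hi))

    return RCDProfile(tuple(p1))
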