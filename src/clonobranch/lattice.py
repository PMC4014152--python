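"""Monte Carlo simulation of colony formation on a 2D lattice.

Each simulated colony starts from a single inoculated cell at the origin of
a square lattice (grid cell 31.6 µm, roughly one fibroblast footprint).
Generations are synchronous: at step ``g`` every live cell first faces
reproductive cell death with probability ``P1(g)``; a surviving cell then
divides, placing one daughter on a uniformly chosen free site among its
eight (Moore) neighbors.  A cell with no free neighbor is contact-inhibited
and simply persists.  Dead cells stay on the lattice by default — the assay
counts them — and keep blocking their site.  After 16 synchronous doublings
(about 13 days at a 20 h doubling time) the number of occupied sites is the
final colony size; colonies at or above the clonogenic threshold (50 cells)
score as survivors.

The per-colony update loop is compiled with numba; with contact inhibition
disabled the model reduces to the pure branching process and is simulated
directly from vectorized binomial draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .branching import ColonySizeDistribution, RCDProfile

__all__ = [
    "SimulationConfig",
    "ColonySimResult",
    "UndefinedSurvivalError",
    "simulate_colony",
    "simulate_experiment",
    "surviving_fraction",
]


class UndefinedSurvivalError(ZeroDivisionError):
    """The control plating efficiency is zero; SF is undefined."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the in silico colony assay.

    ``grid_cell_size`` (µm) and ``doubling_time`` (h) are bookkeeping only:
    they set the physical scale of a site and of one synchronous step but do
    not enter the stochastic dynamics.
    """

    grid_cell_size: float = 31.6
    doubling_time: float = 20.0
    n_generations: int = 16
    clonogenic_threshold: int = 50
    n_colonies_per_run: int = 10_000
    n_runs: int = 5
    contact_inhibition: bool = True
    retain_dead_cells: bool = True
    blocked_cells_die: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.clonogenic_threshold < 2:
            raise ValueError("clonogenic_threshold must be >= 2")
        if self.n_colonies_per_run < 1 or self.n_runs < 1:
            raise ValueError("colony and run counts must be >= 1")

    @property
    def total_colonies(self) -> int:
        return self.n_colonies_per_run * self.n_runs


@dataclass
class ColonySimResult:
    """Final sizes of all simulated colonies plus derived summaries."""

    sizes: np.ndarray
    config: SimulationConfig
    seed: int

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=np.int64)

    @property
    def distribution(self) -> ColonySizeDistribution:
        uniq, counts = np.unique(self.sizes[self.sizes >= 1], return_counts=True)
        return ColonySizeDistribution(
            values={int(n): int(c) for n, c in zip(uniq, counts)},
            mode="counts",
        )

    def plating_efficiency(self, threshold: int | None = None) -> float:
        """Fraction of inoculated cells whose colony reached the threshold."""
        thr = self.config.clonogenic_threshold if threshold is None else int(threshold)
        return float(np.mean(self.sizes >= thr))

    def abortive_frequencies(self, n_max: int = 49) -> ColonySizeDistribution:
        """All-colony frequencies of sizes ``1..n_max`` plus clonogenic mass."""
        total = len(self.sizes)
        uniq, counts = np.unique(self.sizes, return_counts=True)
        small = {int(n): int(c) / total for n, c in zip(uniq, counts) if 1 <= n <= n_max}
        clono = float(np.sum(self.sizes > n_max)) / total
        return ColonySizeDistribution(values=small, mode="all_colonies", clonogenic=clono)


# lattice codes: 0 free, 1 live, 2 dead (retained)
@njit(cache=True)
def _lattice_colonies(
    p1: np.ndarray,
    n_generations: int,
    retain_dead: bool,
    blocked_die: bool,
    seed: int,
    n_colonies: int,
) -> np.ndarray:  # pragma: no cover - exercised through simulate_* wrappers
    np.random.seed(seed)
    dim = 2 * n_generations + 5
    center = dim // 2
    grid = np.zeros((dim, dim), dtype=np.uint8)
    cap = dim * dim
    xs = np.empty(cap, dtype=np.int32)
    ys = np.empty(cap, dtype=np.int32)
    alive = np.empty(cap, dtype=np.bool_)
    nbr_x = np.empty(8, dtype=np.int32)
    nbr_y = np.empty(8, dtype=np.int32)
    sizes = np.empty(n_colonies, dtype=np.int64)

    for col in range(n_colonies):
        n_cells = 1
        xs[0] = center
        ys[0] = center
        alive[0] = True
        grid[center, center] = 1
        n_alive = 1

        for g in range(n_generations):
            if n_alive == 0:
                break
            p = p1[g] if g < p1.shape[0] else p1[p1.shape[0] - 1]
            n_now = n_cells  # daughters born this step act next step
            for i in range(n_now):
                if not alive[i]:
                    continue
                x = xs[i]
                y = ys[i]
                n_free = 0
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        if dx == 0 and dy == 0:
                            continue
                        if grid[x + dx, y + dy] == 0:
                            nbr_x[n_free] = x + dx
                            nbr_y[n_free] = y + dy
                            n_free += 1
                if n_free == 0 and not blocked_die:
                    continue  # contact-inhibited: no branch point, persists
                # at the branch point, death is evaluated before division
                if np.random.random() < p:
                    alive[i] = False
                    n_alive -= 1
                    grid[x, y] = 2 if retain_dead else 0
                    continue
                if n_free == 0:
                    continue  # survived the draw but contact-inhibited
                k = int(np.random.random() * n_free)
                if k == n_free:
                    k = n_free - 1
                nx = nbr_x[k]
                ny = nbr_y[k]
                grid[nx, ny] = 1
                xs[n_cells] = nx
                ys[n_cells] = ny
                alive[n_cells] = True
                n_cells += 1
                n_alive += 1

        if retain_dead:
            size = n_cells
        else:
            size = n_alive
        sizes[col] = size

        for i in range(n_cells):
            grid[xs[i], ys[i]] = 0

    return sizes


def _branching_colonies(
    p1: Sequence[float],
    n_generations: int,
    retain_dead: bool,
    rng: np.random.Generator,
    n_colonies: int,
) -> np.ndarray:
    """Contact inhibition off: the pure branching process, vectorized."""
    p1 = np.asarray(p1, dtype=float)
    live = np.ones(n_colonies, dtype=np.int64)
    dead = np.zeros(n_colonies, dtype=np.int64)
    for g in range(n_generations):
        p = p1[min(g, len(p1) - 1)]
        deaths = rng.binomial(live, p)
        dead += deaths
        live = 2 * (live - deaths)
    return live + dead if retain_dead else live


def _profile_array(profile: RCDProfile, n_generations: int) -> np.ndarray:
    if profile.max_generation < n_generations - 1:
        raise ValueError(
            f"profile defines generations 0..{profile.max_generation} but the "
            f"simulation needs 0..{n_generations - 1}"
        )
    return np.array(
        [profile.p1_at(g) for g in range(n_generations)], dtype=np.float64
    )


def _run_seed(master_seed: int, run_index: int) -> int:
    """Deterministic sub-seed for one run: SeedSequence(master, spawn_key=(run,))."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(run_index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_colony(
    profile: RCDProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """Final size of a single simulated colony (one inoculated cell)."""
    p1 = _profile_array(profile, config.n_generations)
    if config.contact_inhibition:
        seed = int(rng.integers(0, 2**31))
        sizes = _lattice_colonies(
            p1,
            config.n_generations,
            config.retain_dead_cells,
            config.blocked_cells_die,
            seed,
            1,
        )
        return int(sizes[0])
    sizes = _branching_colonies(
        p1, config.n_generations, config.retain_dead_cells, rng, 1
    )
    return int(sizes[0])


def simulate_experiment(
    profile: RCDProfile,
    config: SimulationConfig,
) -> ColonySimResult:
    """Simulate ``n_runs`` independent runs of ``n_colonies_per_run`` colonies.

    Each run draws its RNG stream from a sub-seed derived deterministically
    from the master seed and the run index, so results are reproducible
    draw-for-draw and runs are independent.
    """
    p1 = _profile_array(profile, config.n_generations)
    chunks = []
    for run in range(config.n_runs):
        seed = _run_seed(config.seed, run)
        if config.contact_inhibition:
            chunk = _lattice_colonies(
                p1,
                config.n_generations,
                config.retain_dead_cells,
                config.blocked_cells_die,
                seed,
                config.n_colonies_per_run,
            )
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(config.seed), spawn_key=(run,))
            )
            chunk = _branching_colonies(
                p1,
                config.n_generations,
                config.retain_dead_cells,
                rng,
                config.n_colonies_per_run,
            )
        chunks.append(chunk)
    return ColonySimResult(
        sizes=np.concatenate(chunks), config=config, seed=config.seed
    )


def surviving_fraction(
    result: ColonySimResult,
    control: ColonySimResult,
    threshold: int | None = None,
) -> float:
    """SF = plating efficiency of ``result`` over that of the 0 Gy control."""
    if len(result.sizes) == 0 or len(control.sizes) == 0:
        raise ValueError("both results must contain simulated colonies")
    thr = result.config.clonogenic_threshold if threshold is None else int(threshold)
    pe_control = control.plating_efficiency(thr)
    if pe_control == 0:
        raise UndefinedSurvivalError(
            f"control plating efficiency is 0 at threshold {thr}"
        )
    return result.plating_efficiency(thr) / pe_control
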