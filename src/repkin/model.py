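"""Stochastic forward model of S-phase replication along a linear chromosome.

The model is the standard bidirectional-fork picture of budding-yeast
replication: a chromosome carries point origins, each of which fires in a
given cell with probability ``efficiency`` at a time drawn from a normal
distribution truncated at zero.  Forks move outward at constant velocity, and
a locus is replicated by the first fork (or firing origin) to reach it.
Population curves arise from cell-to-cell variation in S-phase entry and
origin firing, plus a fraction of cells that never enter S-phase.

A phenomenological centromere effect advances the mean firing time of
origins near a *functional* centromere, decaying with distance.  Passive
replication is implicit: an origin that does not fire is replicated by an
incoming fork; there is no re-firing and no fork stalling.

Coordinates are 0-based integers in base pairs; times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CDEIII_WILDTYPE",
    "Origin",
    "Centromere",
    "ChromosomeModel",
    "CentromereEffect",
    "SimulationParams",
    "CellRealization",
    "CellPopulation",
    "apply_centromere_effect",
    "sample_cell",
    "sample_population",
    "locus_replication_time",
    "population_locus_times",
    "fraction_replicated",
    "true_profile",
]

#: Wild-type core of the centromere DNA element III (CDEIII); a centromere
#: is functional iff its CDEIII core equals this sequence.
CDEIII_WILDTYPE = "TCCGAA"


@dataclass(frozen=True)
class Origin:
    """A replication origin: position, mean firing time, variability, efficiency.

    ``mean_firing_time`` is measured from the start of S-phase in the
    individual cell (S-entry delay is modelled separately at the population
    level).  ``efficiency`` is the probability that the origin fires actively
    in a given cell cycle rather than being passively replicated.
    """

    id: str
    position: int
    mean_firing_time: float
    firing_sd: float = 4.0
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"origin {self.id}: position must be >= 0")
        if self.firing_sd < 0:
            raise ValueError(f"origin {self.id}: firing_sd must be >= 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"origin {self.id}: efficiency must be in [0, 1]")


@dataclass(frozen=True)
class Centromere:
    """A point centromere with its CDEIII core sequence.

    Functionality is derived from the sequence: only the wild-type CDEIII
    core assembles a kinetochore.  The 3-bp CDEIII point mutation used to
    kill centromere function (TCCGAA -> TCTAGA) therefore yields
    ``functional == False`` automatically.
    """

    position: int
    cdeiii_seq: str = CDEIII_WILDTYPE

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("centromere position must be >= 0")
        seq = self.cdeiii_seq.upper()
        if len(seq) != 6 or set(seq) - set("ACGT"):
            raise ValueError("cdeiii_seq must be a 6-letter ACGT string")
        object.__setattr__(self, "cdeiii_seq", seq)

    @property
    def functional(self) -> bool:
        return self.cdeiii_seq == CDEIII_WILDTYPE


@dataclass(frozen=True)
class ChromosomeModel:
    """A linear chromosome with origins and optional centromere annotations."""

    name: str
    length: int
    origins: tuple[Origin, ...]
    centromeres: tuple[Centromere, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be > 0")
        object.__setattr__(self, "origins", tuple(self.origins))
        object.__setattr__(self, "centromeres", tuple(self.centromeres))
        pos = [o.position for o in self.origins]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("origin positions must be strictly increasing")
        if any(p > self.length for p in pos):
            raise ValueError("origin positions must lie within the chromosome")
        if any(c.position > self.length for c in self.centromeres):
            raise ValueError("centromere position must lie within the chromosome")

    @property
    def centromere(self) -> Centromere | None:
        """The functional centromere if present, else the first annotation."""
        for cen in self.centromeres:
            if cen.functional:
                return cen
        return self.centromeres[0] if self.centromeres else None

    def origin_positions(self) -> np.ndarray:
        return np.array([o.position for o in self.origins], dtype=float)


@dataclass(frozen=True)
class CentromereEffect:
    """Distance-decaying advance of origin firing time near a functional centromere.

    ``max_advance`` is the advance (minutes) for an origin at the centromere
    itself; the advance decays to ~0 over ``range_bp``.  The decay shape is
    a modelling choice exposed as ``mode``:

    - ``linear``: max_advance * max(0, 1 - d/range_bp)  (default)
    - ``exponential``: max_advance * exp(-d/range_bp)
    - ``step``: max_advance for d < range_bp, else 0
    """

    max_advance: float = 30.0
    range_bp: int = 19_000
    mode: str = "linear"

    def __post_init__(self) -> None:
        if self.max_advance < 0:
            raise ValueError("max_advance must be >= 0")
        if self.range_bp <= 0:
            raise ValueError("range_bp must be > 0")
        if self.mode not in ("linear", "exponential", "step"):
            raise ValueError("mode must be linear, exponential or step")

    def advance_at(self, distance_bp: float) -> float:
        d = abs(float(distance_bp))
        if self.mode == "linear":
            return self.max_advance * max(0.0, 1.0 - d / self.range_bp)
        if self.mode == "exponential":
            return self.max_advance * float(np.exp(-d / self.range_bp))
        return self.max_advance if d < self.range_bp else 0.0


@dataclass(frozen=True)
class SimulationParams:
    """Population-level parameters of the S-phase simulation.

    fork_velocity : bp/min, constant bidirectional fork speed.
    s_entry_mean / s_entry_sd : minutes; per-cell delay between release and
        S-phase entry, normal truncated at 0 (cultures enter S around 40 min
        after release and reach 2C by ~140 min).
    fraction_cycling : probability that a cell enters (and completes)
        S-phase at all; kinetic curves plateau at this level, not at 1.
    n_cells : cells per simulated population.
    """

    fork_velocity: float = 800.0
    s_entry_mean: float = 40.0
    s_entry_sd: float = 10.0
    fraction_cycling: float = 0.8
    n_cells: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fork_velocity <= 0:
            raise ValueError("fork_velocity must be > 0")
        if not 0.0 <= self.fraction_cycling <= 1.0:
            raise ValueError("fraction_cycling must be in [0, 1]")
        if self.s_entry_sd < 0:
            raise ValueError("s_entry_sd must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be a positive integer")


@dataclass(frozen=True)
class CellRealization:
    """One cell's S-phase: entry delay plus per-origin firing outcomes."""

    s_entry_delay: float
    fired: np.ndarray
    firing_times: np.ndarray


@dataclass(frozen=True)
class CellPopulation:
    """Vectorized bundle of cell realizations sharing one chromosome.

    ``cycling`` marks cells that enter S-phase; non-cycling cells never
    replicate.  ``firing_times`` holds per-cell, per-origin firing times
    (only meaningful where ``fired``).
    """

    cycling: np.ndarray  # (n,) bool
    s_entry_delay: np.ndarray  # (n,) float
    fired: np.ndarray  # (n, k) bool
    firing_times: np.ndarray  # (n, k) float

    @property
    def n_cells(self) -> int:
        return self.cycling.shape[0]


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray | float,
    sd: np.ndarray | float,
    size: tuple[int, ...],
) -> np.ndarray:
    """Normal(mean, sd) truncated at 0; degenerate sd=0 collapses to max(mean, 0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size)
    out = np.array(mean, copy=True)
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], random_state=rng
        )
    np.clip(out, 0.0, None, out=out)
    return out


def apply_centromere_effect(
    chrom: ChromosomeModel, effect: CentromereEffect
) -> ChromosomeModel:
    """Advance origin firing times near every functional centromere.

    Each origin's mean firing time is reduced by the largest advance granted
    by any functional centromere, floored at 0 minutes.  Chromosomes without
    a functional centromere are returned unchanged (an equal copy): a
    CDEIII-dead centromere confers no advance.
    """
    functional = [c for c in chrom.centromeres if c.functional]
    if not functional:
        return replace(chrom)
    new_origins = []
    for o in chrom.origins:
        advance = max(
            effect.advance_at(o.position - c.position) for c in functional
        )
        new_origins.append(
            replace(o, mean_firing_time=max(0.0, o.mean_firing_time - advance))
        )
    return replace(chrom, origins=tuple(new_origins))


def _sample_fired(
    rng: np.random.Generator, efficiency: np.ndarray, n: int
) -> np.ndarray:
    """Per-cell, per-origin firing indicators; cells with no fired origin are resampled."""
    if not (efficiency > 0).any():
        raise ValueError("all origins have efficiency 0: chromosome can never replicate")
    fired = rng.random((n, efficiency.size)) < efficiency
    empty = ~fired.any(axis=1)
    while empty.any():
        fired[empty] = rng.random((int(empty.sum()), efficiency.size)) < efficiency
        empty = ~fired.any(axis=1)
    return fired


def sample_cell(
    chrom: ChromosomeModel, params: SimulationParams, rng: np.random.Generator
) -> CellRealization:
    """Draw one cell's origin firing pattern and S-entry delay.

    Each origin fires independently with its efficiency; firing times are
    truncated-normal.  Realizations in which no origin fired are rejected
    and resampled, since the chromosome must finish replication.
    """
    if not chrom.origins:
        raise ValueError("chromosome has no origins")
    eff = np.array([o.efficiency for o in chrom.origins])
    fired = _sample_fired(rng, eff, 1)[0]
    means = np.array([o.mean_firing_time for o in chrom.origins])
    sds = np.array([o.firing_sd for o in chrom.origins])
    times = _truncated_normal(rng, means, sds, (len(chrom.origins),))
    entry = float(
        _truncated_normal(rng, params.s_entry_mean, params.s_entry_sd, (1,))[0]
    )
    times = np.where(fired, times, np.inf)
    return CellRealization(s_entry_delay=entry, fired=fired, firing_times=times)


def sample_population(
    chrom: ChromosomeModel, params: SimulationParams, rng: np.random.Generator
) -> CellPopulation:
    """Draw a population of cells for one chromosome.

    Cells enter S-phase with probability ``fraction_cycling``; all cells
    (cycling or not) receive firing patterns so the population can be reused
    across timepoints and positions with coherent spatial structure.
    """
    if not chrom.origins:
        raise ValueError("chromosome has no origins")
    n = params.n_cells
    cycling = rng.random(n) < params.fraction_cycling
    entry = _truncated_normal(rng, params.s_entry_mean, params.s_entry_sd, (n,))
    eff = np.array([o.efficiency for o in chrom.origins])
    fired = _sample_fired(rng, eff, n)
    means = np.array([o.mean_firing_time for o in chrom.origins])
    sds = np.array([o.firing_sd for o in chrom.origins])
    times = _truncated_normal(rng, means, sds, (n, eff.size))
    times = np.where(fired, times, np.inf)
    return CellPopulation(
        cycling=cycling, s_entry_delay=entry, fired=fired, firing_times=times
    )


def locus_replication_time(
    cell: CellRealization,
    chrom: ChromosomeModel,
    x: float,
    params: SimulationParams,
) -> float:
    """Time (from S start) at which position ``x`` is replicated in one cell.

    min over fired origins i of firing_time_i + |x - position_i| / v.
    """
    if not 0 <= x <= chrom.length:
        raise ValueError("x must lie within the chromosome")
    if not cell.fired.any():
        raise ValueError("cell has no fired origin")
    travel = np.abs(x - chrom.origin_positions()) / params.fork_velocity
    return float(np.min(cell.firing_times + travel))


def population_locus_times(
    pop: CellPopulation,
    chrom: ChromosomeModel,
    positions: Sequence[float] | np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Per-cell replication times (from release) at each position; inf for non-cycling cells.

    Returns an (n_cells, n_positions) array of s_entry_delay + fork-arrival
    time.  Shares the population across positions, so spatial structure is
    coherent within each cell.
    """
    x = np.asarray(positions, dtype=float)
    if x.size and (x.min() < 0 or x.max() > chrom.length):
        raise ValueError("positions must lie within the chromosome")
    travel = (
        np.abs(x[None, :] - chrom.origin_positions()[:, None]) / params.fork_velocity
    )  # (k, m)
    # (n, k, m) -> min over origins
    t = np.min(pop.firing_times[:, :, None] + travel[None, :, :], axis=1)
    t = t + pop.s_entry_delay[:, None]
    t[~pop.cycling] = np.inf
    return t


def fraction_replicated(
    chrom: ChromosomeModel,
    x: float,
    t: float | np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    population: CellPopulation | None = None,
) -> float | np.ndarray:
    """Fraction of all cells in which position ``x`` is replicated by time ``t``.

    ``t`` is minutes from release.  Monte-Carlo over ``params.n_cells`` cells;
    with no explicit ``rng`` the population is drawn from ``params.seed`` so
    repeated calls at different ``t`` share one population (monotone in t).
    Bounded above by the cycling fraction.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t must be >= 0")
    if population is None:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        population = sample_population(chrom, params, rng)
    times = population_locus_times(population, chrom, [x], params)[:, 0]
    frac = (times[:, None] <= t_arr[None, :]).mean(axis=0)
    return float(frac[0]) if np.isscalar(t) or np.ndim(t) == 0 else frac


def true_profile(
    chrom: ChromosomeModel,
    t: float,
    grid_spacing: int,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    population: CellPopulation | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth replicated fraction on a regular grid at time ``t``.

    One cell population is shared across all grid positions.  Returns
    ``(positions, fractions)`` with fractions in [0, fraction_cycling].
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be > 0")
    positions = np.arange(0, chrom.length + 1, grid_spacing)
    if population is None:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        population = sample_population(chrom, params, rng)
    times = population_locus_times(population, chrom, positions, params)
    fractions = (times <= t).mean(axis=0)
    return positions, fractions
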