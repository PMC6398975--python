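"""Breeding-cycle orchestration, replicate batches and threshold experiments.

Each cycle runs five stages in order: (i) mate allocation, (ii) reproduction
and inheritance, (iii) zygotic shredding and germline homing (embedded in
offspring generation), (iv) density-dependent mortality applied to adults and
newborns alike, (v) aging.  Trajectories are recorded at the post-mortality,
post-aging census; cycle 0 is the initial inoculated census.

The reproduction stage is fully vectorized over conceptions; the scalar
operations in :mod:`shredsim.drive_genetics` and :mod:`shredsim.demography`
share the same sampling core.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import allocate_mates, survival_probability
from .drive_genetics import (
    DRIVE,
    WILDTYPE,
    XO,
    XX,
    XY,
    home_sites_vector,
    sample_functionality,
)
from .params import Placement, SimConfig, Strategy
from .population import AUTOSOME_PAIRS, Population

__all__ = [
    "SERIES",
    "SimResult",
    "ReplicateSummary",
    "initialize_population",
    "step_cycle",
    "run_simulation",
    "run_replicate_batch",
    "run_replicates",
    "summarize_replicates",
    "find_eradication_threshold",
    "coarse_to_fine_threshold",
]

SERIES = ("N", "XX", "XY", "XO") + AUTOSOME_PAIRS


@dataclass
class SimResult:
    """Per-cycle trajectories of one replicate.

    ``data`` has one row per recorded census (cycle 0 first) and one column
    per entry of :data:`SERIES`.  Eradicated runs stop recording at the first
    zero census; :meth:`padded` extends them with zeros (absorbing state).
    """

    data: np.ndarray
    eradicated: bool
    eradication_cycle: int | None
    horizon: int
    cycles_per_year: int

    def series(self, name: str) -> np.ndarray:
        return self.data[:, SERIES.index(name)]

    @property
    def final_n(self) -> int:
        return int(self.data[-1, 0])

    def padded(self) -> np.ndarray:
        """Trajectory array padded with zeros to the full horizon."""
        rows = self.horizon + 1
        if self.data.shape[0] == rows:
            return self.data
        out = np.zeros((rows, len(SERIES)), dtype=self.data.dtype)
        out[: self.data.shape[0]] = self.data
        return out

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        cycles = np.arange(self.data.shape[0])
        frame = pd.DataFrame(self.data, columns=list(SERIES))
        frame.insert(0, "cycle", cycles)
        frame.insert(0, "year", (cycles + self.cycles_per_year - 1) // self.cycles_per_year)
        frame.insert(0, "replicate", replicate)
        frame["eradicated"] = self.eradicated
        return frame


@dataclass
class ReplicateSummary:
    """Across-replicate summary: eradication probability plus per-cycle mean
    and percentile-based 95% intervals of every trajectory series."""

    eradication_probability: float
    n_replicates: int
    mean: np.ndarray  # (horizon+1, len(SERIES))
    lo: np.ndarray
    hi: np.ndarray
    final_n_mean: float
    final_n_lo: float
    final_n_hi: float
    eradication_cycles: list[int]
    cycles_per_year: int

    def series(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        j = SERIES.index(name)
        return self.mean[:, j], self.lo[:, j], self.hi[:, j]

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(self.mean.shape[0])
        cols = {"cycle": cycles}
        for j, name in enumerate(SERIES):
            cols[f"{name}_mean"] = self.mean[:, j]
            cols[f"{name}_lo"] = self.lo[:, j]
            cols[f"{name}_hi"] = self.hi[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """K wildtype residents (half XX, half XY) plus the drive inoculum:
    drive-heterozygous XX females for the Y-shredder strategy, or XY males
    carrying the Y-linked cassette for the X-shredder strategy."""
    k = config.demog.carrying_capacity
    if k % 2:
        raise ValueError("carrying_capacity must be even (equal initial sex ratio)")
    s0 = config.drive.n_guides
    pop = Population.zeros(k + config.inoculum_size)
    pop.allo[: k // 2] = XX
    pop.allo[k // 2 : k] = XY
    pop.kind_m[:] = WILDTYPE
    pop.kind_p[:] = WILDTYPE
    pop.sites_m[:] = s0
    pop.sites_p[:] = s0
    if config.inoculum_size:
        ino = slice(k, k + config.inoculum_size)
        if config.strategy is Strategy.YSHREDDER:
            pop.allo[ino] = XX
            pop.kind_m[ino] = DRIVE
            pop.sites_m[ino] = 0
        else:
            pop.allo[ino] = XY
            pop.y_drive[ino] = True
    return pop


# ---------------------------------------------------------------------------
# Vectorized reproduction
# ---------------------------------------------------------------------------


# geno column blocks: [allo | kind,sites,func,del (maternal) | ... (paternal) | y_drive, germline]
_M_SLOT = slice(1, 5)
_P_SLOT = slice(5, 9)


def _transmitted_autosomes(pop: Population, idx: np.ndarray, drive, rng) -> np.ndarray:
    """Per-conception transmitted autosomal allele from the parents at ``idx``
    (with repetition), applying germline homing in eligible heterozygotes.

    Returns an (n, 4) int8 block with columns kind, sites, func, del.
    """
    g = pop.geno[idx]  # fresh copy; slot views below are mutable
    slot_m = g[:, _M_SLOT]
    slot_p = g[:, _P_SLOT]
    for target, other in ((slot_m, slot_p), (slot_p, slot_m)):
        elig = (target[:, 0] == WILDTYPE) & (other[:, 0] == DRIVE)
        if elig.any():
            sub = target[elig]  # (k, 4) copy, written back as one block
            nk, ns, nd, nmut = home_sites_vector(sub[:, 1], drive, rng)
            sub[:, 0] = nk
            sub[:, 2] = sample_functionality(nd, nmut, drive, rng) & (sub[:, 2] != 0)
            sub[:, 3] = nd | (sub[:, 3] != 0)
            sub[:, 1] = ns
            target[elig] = sub
    coin = rng.random(idx.size) < 0.5
    return np.where(coin[:, None], slot_m, slot_p)


def _newborns(pop, mothers, fathers, config, rng) -> Population:
    drive = config.drive
    if mothers.size == 0:
        return Population.empty()
    mean = config.demog.litter_mean * np.where(
        pop.allo[mothers] == XO, drive.xo_fertility, 1.0
    )
    litters = rng.poisson(mean)
    mo = np.repeat(mothers, litters)
    fa = np.repeat(fathers, litters)
    n = mo.size
    if n == 0:
        return Population.empty()
    if config.strategy is Strategy.XSHREDDER:
        return _newborns_xshredder(pop, mo, fa, config, rng)

    tm = _transmitted_autosomes(pop, mo, drive, rng)
    tp = _transmitted_autosomes(pop, fa, drive, rng)
    mat_x = np.where(pop.allo[mo] == XO, rng.random(n) < drive.x_bias_xo, True)
    pat_y = rng.random(n) < 0.5
    dead = ~mat_x & pat_y  # YO
    allo = np.where(pat_y, XY, np.where(mat_x, XX, XO)).astype(np.int8)
    carrier = (tm[:, 0] == DRIVE) | (tp[:, 0] == DRIVE)
    shred = (allo == XY) & carrier & (rng.random(n) < drive.shred_prob)
    allo = np.where(shred, XO, allo).astype(np.int8)
    if drive.placement is Placement.CODING:
        dead |= (tm[:, 2] & tp[:, 2]) == 0  # inherited a non-functional allele
    keep = ~dead
    kids = Population.zeros(int(keep.sum()))
    kids.geno[:, 0] = allo[keep]
    kids.geno[:, _M_SLOT] = tm[keep]
    kids.geno[:, _P_SLOT] = tp[keep]
    return kids


def _newborns_xshredder(pop, mo, fa, config, rng) -> Population:
    drive = config.drive
    xp = config.xshredder
    n = mo.size
    carrier_f = pop.y_drive[fa] != 0
    if xp.per_gamete:
        yo = carrier_f & (rng.random(n) < xp.shred_prob_x)
    else:
        yo = pop.germline[fa] == 1
    u = rng.random(n)
    # paternal allosome: 0=X, 1=Y, 2=O
    pat = np.where(yo, np.where(u < xp.y_transmission_yo, 1, 2), np.where(u < 0.5, 1, 0))
    mat_x = np.where(pop.allo[mo] == XO, rng.random(n) < drive.x_bias_xo, True)
    dead = ~mat_x & (pat >= 1)  # YO and OO conceptions
    allo = np.where(pat == 1, XY, np.where(mat_x & (pat == 0), XX, XO)).astype(np.int8)
    # plain Mendelian autosomes (no autosomal drive in this strategy)
    g_mo = pop.geno[mo]
    g_fa = pop.geno[fa]
    cm = rng.random(n) < 0.5
    cp = rng.random(n) < 0.5
    from_mother = np.where(cm[:, None], g_mo[:, _M_SLOT], g_mo[:, _P_SLOT])
    from_father = np.where(cp[:, None], g_fa[:, _M_SLOT], g_fa[:, _P_SLOT])
    keep = ~dead
    kids = Population.zeros(int(keep.sum()))
    kids.geno[:, 0] = allo[keep]
    kids.geno[:, _M_SLOT] = from_mother[keep]
    kids.geno[:, _P_SLOT] = from_father[keep]
    kids.y_drive = ((pat == 1) & carrier_f)[keep]
    return kids


def _check_pairing(pairing, n_females: int, n_males: int, max_mates: int) -> None:
    expected = min(n_females, n_males * max_mates)
    if len(pairing) != expected:
        raise RuntimeError(
            f"mate allocation produced {len(pairing)} pairs, expected {expected}"
        )
    if len(pairing) and np.bincount(pairing.fathers).max() > max_mates:
        raise RuntimeError("a male exceeded max_mates")


# ---------------------------------------------------------------------------
# Cycle and run drivers
# ---------------------------------------------------------------------------


def step_cycle(
    population: Population,
    config: SimConfig,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one breeding cycle (the five stages)."""
    if population.size == 0:
        return population
    n_pre = population.size
    females = np.flatnonzero(population.female_mask())
    males = np.flatnonzero(population.allo == XY)
    pairing = allocate_mates(females, males, config.demog.max_mates, rng)
    _check_pairing(pairing, females.size, males.size, config.demog.max_mates)
    if config.strategy is Strategy.XSHREDDER and not config.xshredder.per_gamete:
        # lifetime germline state, decided at first breeding
        breeders = np.unique(pairing.fathers)
        fresh = breeders[
            (population.y_drive[breeders] != 0) & (population.germline[breeders] == -1)
        ]
        if fresh.size:
            population.germline[fresh] = (
                rng.random(fresh.size) < config.xshredder.shred_prob_x
            ).astype(np.int8)
    kids = _newborns(pop=population, mothers=pairing.mothers, fathers=pairing.fathers,
                     config=config, rng=rng)
    total = Population.concat([population, kids])
    p = float(survival_probability(n_pre, config.demog))
    keep = rng.random(total.size) < p
    survivors = total.subset(keep)
    survivors.age = survivors.age + 1
    return survivors


def _census_row(pop: Population) -> np.ndarray:
    row = np.empty(len(SERIES), dtype=np.int64)
    row[0] = pop.size
    row[1:4] = pop.allosome_counts()
    row[4:] = pop.autosome_counts()
    return row


def run_simulation(config: SimConfig, seed=None) -> SimResult:
    """Run one replicate for up to ``years * cycles_per_year`` cycles or until
    the population hits zero.  Fully reproducible given ``seed`` (an int or a
    :class:`numpy.random.SeedSequence`; defaults to ``config.seed``)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pop = initialize_population(config, rng)
    horizon = config.horizon
    rows = [_census_row(pop)]
    erad_cycle = None
    for cycle in range(1, horizon + 1):
        pop = step_cycle(pop, config, rng)
        rows.append(_census_row(pop))
        if pop.size == 0:
            erad_cycle = cycle
            break
    return SimResult(
        data=np.vstack(rows),
        eradicated=erad_cycle is not None,
        eradication_cycle=erad_cycle,
        horizon=horizon,
        cycles_per_year=config.demog.cycles_per_year,
    )


def run_replicate_batch(config: SimConfig, replicates: int | None = None) -> list[SimResult]:
    """Independent replicates seeded from spawned child streams of config.seed."""
    n = config.replicates if replicates is None else replicates
    seeds = np.random.SeedSequence(config.seed).spawn(n)
    return [run_simulation(config, seed) for seed in seeds]


def summarize_replicates(results: Sequence[SimResult]) -> ReplicateSummary:
    stack = np.stack([r.padded() for r in results])  # (reps, horizon+1, series)
    mean = stack.mean(axis=0)
    lo = np.percentile(stack, 2.5, axis=0)
    hi = np.percentile(stack, 97.5, axis=0)
    finals = stack[:, -1, 0]
    return ReplicateSummary(
        eradication_probability=float(np.mean([r.eradicated for r in results])),
        n_replicates=len(results),
        mean=mean,
        lo=lo,
        hi=hi,
        final_n_mean=float(finals.mean()),
        final_n_lo=float(np.percentile(finals, 2.5)),
        final_n_hi=float(np.percentile(finals, 97.5)),
        eradication_cycles=[
            r.eradication_cycle for r in results if r.eradication_cycle is not None
        ],
        cycles_per_year=results[0].cycles_per_year,
    )


def run_replicates(config: SimConfig, replicates: int | None = None) -> ReplicateSummary:
    return summarize_replicates(run_replicate_batch(config, replicates))


def coarse_to_fine_threshold(
    config: SimConfig,
    lo: float = 0.5,
    hi: float = 1.0,
    coarse_step: float = 0.05,
    fine_step: float = 0.01,
    required_fraction: float = 1.0,
    replicates: int | None = None,
) -> float | None:
    """Two-stage grid search for the minimum Y-shredding efficiency: a coarse
    ascending scan followed by a fine scan of the last coarse interval."""
    coarse = np.round(np.arange(lo, hi + 1e-9, coarse_step), 10).tolist()
    t_c = find_eradication_threshold(config, coarse, required_fraction, replicates)
    if t_c is None:
        return None
    fine_lo = max(lo, t_c - coarse_step + fine_step)
    fine = np.round(np.arange(fine_lo, t_c + 1e-9, fine_step), 10).tolist()
    t_f = find_eradication_threshold(config, fine, required_fraction, replicates)
    return t_f if t_f is not None else t_c


def find_eradication_threshold(
    config: SimConfig,
    py_grid: Sequence[float],
    required_fraction: float = 1.0,
    replicates: int | None = None,
) -> float | None:
    """Smallest Y-shredding efficiency on ``py_grid`` (ascending) whose
    replicate eradication fraction reaches ``required_fraction``; None when no
    grid point qualifies.

    A grid point is abandoned as soon as it has accumulated more failures than
    the required fraction allows (pure speed optimisation).
    """
    grid = list(py_grid)
    if not grid:
        raise ValueError("py_grid must not be empty")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("py_grid must be sorted ascending")
    if not (0.0 < required_fraction <= 1.0):
        raise ValueError("required_fraction must be in (0, 1]")
    reps = config.replicates if replicates is None else replicates
    allowed_failures = int(np.floor((1.0 - required_fraction) * reps))
    for gi, py in enumerate(grid):
        cfg = config.with_(drive=replace(config.drive, shred_prob=py))
        seeds = np.random.SeedSequence([int(config.seed), gi]).spawn(reps)
        failures = 0
        for seed in seeds:
            if not run_simulation(cfg, seed).eradicated:
                failures += 1
                if failures > allowed_failures:
                    break
        if failures <= allowed_failures:
            return float(py)
    return None
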