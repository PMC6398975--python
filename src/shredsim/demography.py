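"""Mating system, litter generation, density-dependent survival and aging.

Survival is a two-parameter logistic in population size, calibrated so that a
drive-free population with an equal sex ratio and full female mating is
stationary at carrying capacity and grows at exp(r_max / cycles_per_year) per
cycle as density approaches zero.  The expected per-cycle growth factor under
those conditions is (1 + litter_mean/2) * s(n), which pins down both logistic
coefficients in closed form.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit

from .drive_genetics import (
    DRIVE,
    EMBRYONIC_DEATH,
    XO,
    XY,
    Allele,
    shred_y,
    transmit_gametes,
)
from .params import DemogParams, DriveParams
from .population import Population

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Individual",
    "MatePairing",
    "allocate_mates",
    "expected_litter",
    "make_litter",
    "survival_probability",
    "logistic_coefficients",
    "max_feasible_r_max",
    "apply_mortality_and_age",
]


@dataclass
class Individual:
    """Scalar view of one mouse (the engine itself works on arrays)."""

    allosomes: int
    allele_m: Allele
    allele_p: Allele
    age: int = 0

    @property
    def sex(self) -> str:
        return "male" if self.allosomes == XY else "female"


@dataclass(frozen=True)
class MatePairing:
    """Mated pairs for one breeding cycle, as aligned index arrays."""

    mothers: np.ndarray
    fathers: np.ndarray

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.mothers.tolist(), self.fathers.tolist()))

    def __len__(self) -> int:
        return self.mothers.size


def _assign_py(n_females: int, n_males: int, max_mates: int, u: np.ndarray) -> np.ndarray:
    pool = np.arange(n_males, dtype=np.int64)
    counts = np.zeros(n_males, dtype=np.int64)
    out = np.full(n_females, -1, dtype=np.int64)
    p = n_males
    for i in range(n_females):
        if p == 0:
            break
        j = int(u[i] * p)
        if j >= p:
            j = p - 1
        m = pool[j]
        out[i] = m
        counts[m] += 1
        if counts[m] >= max_mates:
            pool[j] = pool[p - 1]
            p -= 1
    return out


if _HAVE_NUMBA:
    _assign_fast = njit(cache=False)(_assign_py)
else:  # pragma: no cover
    _assign_fast = _assign_py


def allocate_mates(females, males, max_mates: int, rng: np.random.Generator) -> MatePairing:
    """Sequentially pair each female with a male drawn uniformly from the pool
    of males that still have mating capacity.

    Females are processed in random order; a male leaves the pool once he has
    ``max_mates`` mates; females facing an empty pool stay unmated.  The
    number of pairs is min(#females, #males * max_mates).
    """
    females = np.asarray(females, dtype=np.int64)
    males = np.asarray(males, dtype=np.int64)
    if females.size == 0 or males.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return MatePairing(empty, empty)
    order = rng.permutation(females.size)
    u = rng.random(females.size)
    local = _assign_fast(females.size, males.size, max_mates, u)
    mated = local >= 0
    return MatePairing(females[order][mated], males[local[mated]])


def expected_litter(mother: Individual, drive: DriveParams, demog: DemogParams) -> float:
    """Mean litter size: litter_mean, scaled by the XO fertility multiplier."""
    if mother.allosomes == XY:
        raise ValueError("expected_litter requires a female")
    if mother.allosomes == XO:
        return demog.litter_mean * drive.xo_fertility
    return demog.litter_mean


def make_litter(
    mother: Individual,
    father: Individual,
    drive: DriveParams,
    demog: DemogParams,
    rng: np.random.Generator,
) -> list[Individual]:
    """Realize one litter: Poisson litter size, then per-conception gamete
    transmission (with germline homing), zygotic Y-shredding, and discarding
    of embryonic deaths."""
    n = rng.poisson(expected_litter(mother, drive, demog))
    out: list[Individual] = []
    for _ in range(int(n)):
        z = transmit_gametes(mother, father, drive, rng)
        if z is EMBRYONIC_DEATH:
            continue
        carries = z.allele_m.kind == DRIVE or z.allele_p.kind == DRIVE
        allo = shred_y(z.allosomes, carries, drive, rng)
        out.append(Individual(allo, z.allele_m, z.allele_p, age=0))
    return out


def max_feasible_r_max(litter_mean: float, cycles_per_year: int) -> float:
    """Largest r_max the logistic calibration can accommodate (survival < 1)."""
    return cycles_per_year * math.log1p(litter_mean / 2.0)


@lru_cache(maxsize=1024)
def logistic_coefficients(params: DemogParams) -> tuple[float, float]:
    """Coefficients (a, b) of s(n) = 1 / (1 + exp(a + b n)).

    Solved from s(0) = exp(r_max / cycles_per_year) / (1 + m/2) and
    s(K) = 1 / (1 + m/2).  Raises ValueError when the low-density constraint
    would require survival outside (0, 1).
    """
    ceiling = 1.0 + params.litter_mean / 2.0
    lam = math.exp(params.r_max / params.cycles_per_year)
    s0 = lam / ceiling
    s_k = 1.0 / ceiling
    if not (0.0 < s0 < 1.0):
        raise ValueError(
            f"infeasible calibration: required low-density survival {s0:.4f} "
            f"outside (0, 1); r_max must be < {max_feasible_r_max(params.litter_mean, params.cycles_per_year):.4f}"
        )
    a = math.log(1.0 / s0 - 1.0)
    a_k = math.log(1.0 / s_k - 1.0)
    b = (a_k - a) / params.carrying_capacity
    return a, b


def survival_probability(n: int | float | np.ndarray, params: DemogParams):
    """Per-cycle, per-individual survival probability at population size ``n``."""
    if np.any(np.asarray(n) < 0):
        raise ValueError("population size must be >= 0")
    a, b = logistic_coefficients(params)
    return expit(-(a + b * np.asarray(n, dtype=float)))


def apply_mortality_and_age(
    population: Population,
    params: DemogParams,
    rng: np.random.Generator,
    n_density: int | None = None,
) -> Population:
    """Bernoulli survival for every individual (newborns included) followed by
    aging of the survivors by one cycle.

    ``n_density`` is the population size at which the logistic is evaluated;
    the engine passes the pre-breeding census size so that the stationarity
    calibration at carrying capacity holds (see module docstring).  By default
    the current (post-reproduction) size is used.
    """
    if population.size == 0:
        return population
    n = population.size if n_density is None else n_density
    p = float(survival_probability(n, params))
    keep = rng.random(population.size) < p
    out = population.subset(keep)
    out.age = out.age + 1
    return out
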