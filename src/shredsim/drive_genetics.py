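"""Allele state machine, exact homing-transition tables and inheritance sampling.

The homing model assumes simultaneous cutting: each susceptible site on a
wildtype allele is cut independently with probability ``cut_prob``.  If at
least one site is cut the break is repaired either by homing (probability
``1 - nhej_prob``), converting the allele to a drive copy, or by NHEJ.  Under
NHEJ every cut site acquires an indel; if two or more sites were cut the
sequence between the outermost cuts is deleted, removing any uncut sites that
lie between them.  The susceptible sites remaining afterwards are the uncut
sites outside that span.  Alleles with at least one susceptible site left are
still wildtype-class (cuttable); alleles with none are resistant and can
never acquire the drive.

Transition tables are computed exactly by enumerating all 2**s cut subsets,
and gamete-level sampling draws from those tables, so Monte-Carlo frequencies
converge to the tabulated probabilities by construction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np

from .params import DriveParams, Placement

__all__ = [
    "WILDTYPE",
    "RESISTANT",
    "DRIVE",
    "XX",
    "XY",
    "XO",
    "KIND_LETTERS",
    "ALLOSOME_NAMES",
    "EMBRYONIC_DEATH",
    "Allele",
    "HomingTable",
    "Zygote",
    "build_homing_table",
    "homing_model",
    "germline_homing",
    "transmit_gametes",
    "shred_y",
]

# Autosomal allele kinds; serialized with the single letters W, R, G.
WILDTYPE, RESISTANT, DRIVE = 0, 1, 2
KIND_LETTERS = {WILDTYPE: "W", RESISTANT: "R", DRIVE: "G"}

# Allosome genotypes.  YO is embryonic-lethal and never constructed.
XX, XY, XO = 0, 1, 2
ALLOSOME_NAMES = {XX: "XX", XY: "XY", XO: "XO"}


class _EmbryonicDeath:
    """Sentinel for conceptions that never develop (YO, haploinsufficient lethals)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "EMBRYONIC_DEATH"


EMBRYONIC_DEATH = _EmbryonicDeath()


@dataclass(frozen=True)
class Allele:
    """State of one autosomal allele.

    ``susceptible_sites`` counts intact gRNA target sites (0 for resistant and
    drive alleles).  ``deletion_occurred`` records whether an NHEJ event ever
    deleted the sequence between two cut sites.  ``functional`` tracks the
    host gene's integrity and is only consulted under coding placement.
    """

    kind: int
    susceptible_sites: int = 0
    deletion_occurred: bool = False
    functional: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KIND_LETTERS:
            raise ValueError(f"unknown allele kind {self.kind!r}")
        if self.kind == WILDTYPE and self.susceptible_sites < 1:
            raise ValueError("wildtype alleles must retain >= 1 susceptible site")
        if self.kind == RESISTANT and self.susceptible_sites != 0:
            raise ValueError("resistant alleles have no susceptible sites")
        if self.kind == DRIVE and (
            self.susceptible_sites != 0 or self.deletion_occurred or not self.functional
        ):
            raise ValueError("drive alleles carry no sites, no deletion, and are functional")

    @classmethod
    def wildtype(cls, sites: int) -> "Allele":
        return cls(WILDTYPE, sites)

    @classmethod
    def resistant(cls, deletion: bool = False, functional: bool = True) -> "Allele":
        return cls(RESISTANT, 0, deletion, functional)

    @classmethod
    def drive(cls) -> "Allele":
        return cls(DRIVE, 0)

    @property
    def letter(self) -> str:
        return KIND_LETTERS[self.kind]


@dataclass(frozen=True)
class Zygote:
    """A viable conception before demographic bookkeeping."""

    allosomes: int
    allele_m: Allele
    allele_p: Allele


@dataclass(frozen=True)
class HomingTable:
    """Exact per-gamete transition distribution for one germline homing event.

    ``transition`` maps (remaining susceptible sites j, deletion flag, number
    of new site mutations) -> probability, covering every non-homing outcome
    (including "no cut": (s, False, 0)).  ``homing_prob`` is the probability
    mass converted to a drive allele.
    """

    n_sites_from: int
    homing_prob: float
    transition: Mapping[tuple[int, bool, int], float]

    def total(self) -> float:
        return self.homing_prob + float(sum(self.transition.values()))


def build_homing_table(s: int, params: DriveParams) -> HomingTable:
    """Enumerate all 2**s cut subsets of an allele with ``s`` susceptible sites.

    Raises ValueError when ``s`` is outside [1, params.n_guides].
    """
    if not (1 <= s <= params.n_guides):
        raise ValueError(f"s must be in [1, {params.n_guides}], got {s}")
    pc, pn = params.cut_prob, params.nhej_prob
    homing = 0.0
    transition: dict[tuple[int, bool, int], float] = {}
    for cuts in itertools.product((False, True), repeat=s):
        k = sum(cuts)
        p_subset = pc**k * (1.0 - pc) ** (s - k)
        if p_subset == 0.0:
            continue
        if k == 0:
            key = (s, False, 0)
            transition[key] = transition.get(key, 0.0) + p_subset
            continue
        homing += p_subset * (1.0 - pn)
        if pn == 0.0:
            continue
        if k == 1:
            key = (s - 1, False, 1)
        else:
            positions = [i for i, c in enumerate(cuts) if c]
            span = positions[-1] - positions[0] + 1
            key = (s - span, True, k)
        transition[key] = transition.get(key, 0.0) + p_subset * pn
    return HomingTable(s, homing, transition)


@lru_cache(maxsize=4096)
def homing_model(params: DriveParams) -> Mapping[int, HomingTable]:
    """Homing tables for every site count 1..n_guides under ``params``."""
    return {s: build_homing_table(s, params) for s in range(1, params.n_guides + 1)}


# ---------------------------------------------------------------------------
# Vectorized sampling core (the scalar operations wrap these with size-1 arrays)
# ---------------------------------------------------------------------------


class _OutcomeSampler:
    """Flattened homing table prepared for inverse-CDF sampling."""

    __slots__ = ("cum", "kind", "sites", "dele", "nmut")

    def __init__(self, table: HomingTable):
        keys = sorted(table.transition)
        probs = [table.homing_prob] + [table.transition[k] for k in keys]
        self.cum = np.cumsum(probs)
        self.cum[-1] = 1.0  # guard against fp drift; table.total() is checked in tests
        kind = [DRIVE] + [WILDTYPE if j >= 1 else RESISTANT for j, _, _ in keys]
        self.kind = np.array(kind, dtype=np.int8)
        self.sites = np.array([0] + [j for j, _, _ in keys], dtype=np.int8)
        self.dele = np.array([False] + [d for _, d, _ in keys], dtype=bool)
        self.nmut = np.array([0] + [m for _, _, m in keys], dtype=np.int8)


@lru_cache(maxsize=8192)
def _sampler(params: DriveParams, s: int) -> _OutcomeSampler:
    return _OutcomeSampler(homing_model(params)[s])


def home_sites_vector(sites: np.ndarray, params: DriveParams, rng: np.random.Generator):
    """Sample homing outcomes for an array of susceptible-site counts (all >= 1).

    Returns (kind, sites, deletion_event, n_new_mutations) arrays.
    """
    n = sites.size
    kind = np.empty(n, dtype=np.int8)
    out_sites = np.empty(n, dtype=np.int8)
    dele = np.empty(n, dtype=bool)
    nmut = np.empty(n, dtype=np.int8)
    for s in np.unique(sites):
        mask = sites == s
        smp = _sampler(params, int(s))
        idx = np.searchsorted(smp.cum, rng.random(int(mask.sum())), side="right")
        kind[mask] = smp.kind[idx]
        out_sites[mask] = smp.sites[idx]
        dele[mask] = smp.dele[idx]
        nmut[mask] = smp.nmut[idx]
    return kind, out_sites, dele, nmut


def sample_functionality(
    dele: np.ndarray, nmut: np.ndarray, params: DriveParams, rng: np.random.Generator
) -> np.ndarray:
    """Whether the host gene survives a homing outcome (coding placement only).

    Each new site mutation destroys function independently with probability
    ``nonfunctional_prob``; a span deletion always does.  Under non-coding
    placement every allele is functional.
    """
    if params.placement is not Placement.CODING:
        return np.ones(dele.size, dtype=bool)
    p_bad = np.where(dele, 1.0, 1.0 - (1.0 - params.nonfunctional_prob) ** nmut)
    return rng.random(dele.size) >= p_bad


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------


def _homing_eligible(a: Allele, b: Allele) -> int:
    """Return the index (0 or 1) of the cut-susceptible wildtype allele in a
    drive-heterozygous pair, or -1 when the pair is not eligible for homing."""
    if a.kind == DRIVE and b.kind == WILDTYPE:
        return 1
    if b.kind == DRIVE and a.kind == WILDTYPE:
        return 0
    return -1


def germline_homing(
    allele_pair: tuple[Allele, Allele],
    tables: Mapping[int, HomingTable] | None,
    params: DriveParams,
    rng: np.random.Generator,
) -> tuple[Allele, Allele]:
    """Resolve one germline homing event in a parent, per offspring.

    Only a parent carrying exactly one drive allele and one wildtype allele
    with >= 1 susceptible site is modified; all other pairs pass through
    unchanged.  The ``tables`` argument is accepted for explicitness but may
    be None, in which case the cached tables for ``params`` are used.
    """
    a, b = allele_pair
    target = _homing_eligible(a, b)
    if target < 0:
        return allele_pair
    old = a if target == 0 else b
    kind, sites, dele, nmut = home_sites_vector(
        np.array([old.susceptible_sites], dtype=np.int8), params, rng
    )
    func = sample_functionality(dele, nmut, params, rng)
    if kind[0] == DRIVE:
        new = Allele.drive()
    else:
        new = Allele(
            int(kind[0]),
            int(sites[0]),
            bool(dele[0]) or old.deletion_occurred,
            bool(func[0]) and old.functional,
        )
    return (new, b) if target == 0 else (a, new)


def _gamete(parent, params: DriveParams, rng: np.random.Generator) -> Allele:
    pair = germline_homing((parent.allele_m, parent.allele_p), None, params, rng)
    return pair[0] if rng.random() < 0.5 else pair[1]


def transmit_gametes(mother, father, params: DriveParams, rng: np.random.Generator):
    """Form one conception from a mated pair.

    Germline homing is resampled independently for this offspring in each
    eligible parent; one autosomal allele is then transmitted from each parent
    with probability 0.5.  The maternal allosome is X for XX mothers and X
    with probability ``x_bias_xo`` (else no allosome) for XO mothers; the
    paternal allosome is X or Y with equal probability.  YO conceptions, and
    under coding placement any conception inheriting a non-functional allele,
    return :data:`EMBRYONIC_DEATH`.
    """
    if mother.allosomes == XY or father.allosomes != XY:
        raise ValueError("transmit_gametes requires a female mother and an XY father")
    allele_m = _gamete(mother, params, rng)
    allele_p = _gamete(father, params, rng)
    if mother.allosomes == XX:
        mat_x = True
    else:
        mat_x = rng.random() < params.x_bias_xo
    pat_y = rng.random() < 0.5
    if not mat_x and pat_y:
        return EMBRYONIC_DEATH  # YO
    if params.placement is Placement.CODING and not (allele_m.functional and allele_p.functional):
        return EMBRYONIC_DEATH
    if pat_y:
        allosomes = XY
    elif mat_x:
        allosomes = XX
    else:
        allosomes = XO
    return Zygote(allosomes, allele_m, allele_p)


def shred_y(
    genotype: int, carries_drive: bool, params: DriveParams, rng: np.random.Generator
) -> int:
    """Zygotic Y-shredding: an XY drive carrier becomes XO with probability
    ``shred_prob``; every other input is returned unchanged."""
    if genotype == XY and carries_drive and rng.random() < params.shred_prob:
        return XO
    return genotype
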