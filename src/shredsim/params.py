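"""Parameter containers for the gene-drive simulator.

Every model symbol lives in exactly one dataclass here.  Defaults correspond
to the baseline parameterization (coding placement of the drive inside a
haploinsufficient gene, NHEJ allowed, maximum annual growth rate 7.76).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "Placement",
    "Strategy",
    "DriveParams",
    "DemogParams",
    "XShredderParams",
    "SimConfig",
]


class Placement(str, Enum):
    """Genomic placement of the drive cassette."""

    NONCODING = "noncoding"
    CODING = "coding"


class Strategy(str, Enum):
    """Which shredding strategy is simulated.

    ``yshredder``: autosomal homing drive whose cargo shreds the Y chromosome
    in the zygote (XY males become XO females).
    ``xshredder``: Y-linked cassette that shreds the paternal X during
    meiosis (comparator strategy).
    """

    YSHREDDER = "yshredder"
    XSHREDDER = "xshredder"


def _check_prob(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} must be in [{lo}, {hi}], got {value!r}")


@dataclass(frozen=True)
class DriveParams:
    """Gene-drive machinery parameters.

    cut_prob
        Per-site probability of endonuclease cutting during germline homing (P_C).
    nhej_prob
        Probability that a cut is repaired by NHEJ rather than homing (P_N).
    n_guides
        Number of multiplexed homing gRNAs, i.e. susceptible target sites (S).
    nonfunctional_prob
        Per-mutation probability that an NHEJ indel destroys the function of
        the host gene (P_nf); relevant only for coding placement.
    placement
        Whether the cassette sits in a non-coding region or inside a
        haploinsufficient coding gene.
    shred_prob
        Efficiency of zygotic Y-shredding (P_Y).
    xo_fertility
        Litter-size multiplier for sub-fertile XO females.
    x_bias_xo
        Probability that an XO mother transmits her X rather than no allosome
        (P_X|XO).
    """

    cut_prob: float = 0.95
    nhej_prob: float = 0.1
    n_guides: int = 3
    nonfunctional_prob: float = 1.0
    placement: Placement = Placement.CODING
    shred_prob: float = 1.0
    xo_fertility: float = 0.6
    x_bias_xo: float = 0.66

    def __post_init__(self) -> None:
        _check_prob("cut_prob", self.cut_prob)
        _check_prob("nhej_prob", self.nhej_prob)
        _check_prob("nonfunctional_prob", self.nonfunctional_prob)
        _check_prob("shred_prob", self.shred_prob)
        _check_prob("xo_fertility", self.xo_fertility)
        _check_prob("x_bias_xo", self.x_bias_xo, lo=0.5)
        if not isinstance(self.n_guides, int) or self.n_guides < 1:
            raise ValueError(f"n_guides must be an integer >= 1, got {self.n_guides!r}")
        object.__setattr__(self, "placement", Placement(self.placement))


@dataclass(frozen=True)
class DemogParams:
    """Demographic parameters of the target population."""

    carrying_capacity: int = 10_000
    litter_mean: float = 6.0
    r_max: float = 7.76
    max_mates: int = 1
    cycles_per_year: int = 10

    def __post_init__(self) -> None:
        if self.carrying_capacity < 2:
            raise ValueError("carrying_capacity must be >= 2")
        if self.litter_mean <= 0:
            raise ValueError("litter_mean must be > 0")
        if self.r_max <= 0:
            raise ValueError("r_max must be > 0")
        if not isinstance(self.max_mates, int) or self.max_mates < 1:
            raise ValueError(f"max_mates must be an integer >= 1, got {self.max_mates!r}")
        if self.cycles_per_year < 1:
            raise ValueError("cycles_per_year must be >= 1")

    @property
    def growth_ceiling(self) -> float:
        """Largest feasible r_max: cycles_per_year * ln(1 + litter_mean / 2)."""
        return self.cycles_per_year * math.log1p(self.litter_mean / 2.0)


@dataclass(frozen=True)
class XShredderParams:
    """Parameters specific to the Y-linked X-shredding comparator.

    shred_prob_x
        Probability that a carrier male's germline X is destroyed (P_X).
    y_transmission_yo
        Probability that a germline-YO male transmits Y-bearing rather than
        O-bearing sperm (P_Y|YO).
    per_gamete
        If true, X-shredding is resampled per gamete instead of being fixed
        once per male at first breeding (default: lifetime state).
    """

    shred_prob_x: float = 1.0
    y_transmission_yo: float = 1.0
    per_gamete: bool = False

    def __post_init__(self) -> None:
        _check_prob("shred_prob_x", self.shred_prob_x)
        _check_prob("y_transmission_yo", self.y_transmission_yo)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration for one simulation experiment."""

    drive: DriveParams = field(default_factory=DriveParams)
    demog: DemogParams = field(default_factory=DemogParams)
    strategy: Strategy = Strategy.YSHREDDER
    xshredder: XShredderParams = field(default_factory=XShredderParams)
    inoculum_size: int = 100
    years: int = 10
    replicates: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.inoculum_size < 0:
            raise ValueError("inoculum_size must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "strategy", Strategy(self.strategy))

    @property
    def horizon(self) -> int:
        """Total number of breeding cycles simulated."""
        return self.years * self.demog.cycles_per_year

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with top-level fields replaced."""
        return replace(self, **kwargs)
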