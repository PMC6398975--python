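"""Structure-of-arrays population container used by the simulation engine.

All per-individual genotype state is packed into one int8 matrix (one row per
individual) so that subsetting, concatenation and parent gathers are single
numpy operations; named column views keep call sites readable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drive_genetics import DRIVE, RESISTANT, WILDTYPE, XO, XX, XY, Allele

__all__ = ["Population", "AUTOSOME_PAIRS", "GENO_COLS"]

# Unordered autosomal genotype classes in output order.
AUTOSOME_PAIRS = ("WW", "WG", "GG", "WR", "GR", "RR")

# Column layout of Population.geno.  func/del/y_drive are 0/1 flags; germline
# is -1 undecided, 0 intact, 1 shredded (X-shredder strategy only).
GENO_COLS = (
    "allo",
    "kind_m",
    "sites_m",
    "func_m",
    "del_m",
    "kind_p",
    "sites_p",
    "func_p",
    "del_p",
    "y_drive",
    "germline",
)
_COL = {name: j for j, name in enumerate(GENO_COLS)}

# kind_m * 3 + kind_p -> column of AUTOSOME_PAIRS
_PAIR_INDEX = np.empty(9, dtype=np.int64)
_letters = {WILDTYPE: "W", RESISTANT: "R", DRIVE: "G"}
for _km in (WILDTYPE, RESISTANT, DRIVE):
    for _kp in (WILDTYPE, RESISTANT, DRIVE):
        _name = "".join(sorted(_letters[_km] + _letters[_kp], key="WGR".index))
        _PAIR_INDEX[_km * 3 + _kp] = AUTOSOME_PAIRS.index(_name)


def _column(name: str):
    j = _COL[name]

    def get(self) -> np.ndarray:
        return self.geno[:, j]

    def set_(self, value) -> None:
        self.geno[:, j] = value

    return property(get, set_)


@dataclass
class Population:
    """All individuals alive at a census."""

    geno: np.ndarray  # (n, len(GENO_COLS)) int8
    age: np.ndarray  # (n,) int16, in cycles

    allo = _column("allo")
    kind_m = _column("kind_m")
    sites_m = _column("sites_m")
    func_m = _column("func_m")
    del_m = _column("del_m")
    kind_p = _column("kind_p")
    sites_p = _column("sites_p")
    func_p = _column("func_p")
    del_p = _column("del_p")
    y_drive = _column("y_drive")
    germline = _column("germline")

    @property
    def size(self) -> int:
        return self.geno.shape[0]

    @classmethod
    def empty(cls) -> "Population":
        return cls.zeros(0)

    @classmethod
    def zeros(cls, n: int) -> "Population":
        geno = np.zeros((n, len(GENO_COLS)), dtype=np.int8)
        geno[:, _COL["func_m"]] = 1
        geno[:, _COL["func_p"]] = 1
        geno[:, _COL["germline"]] = -1
        return cls(geno=geno, age=np.zeros(n, dtype=np.int16))

    def subset(self, mask: np.ndarray) -> "Population":
        return Population(geno=self.geno[mask], age=self.age[mask])

    @staticmethod
    def concat(pops: list["Population"]) -> "Population":
        pops = [p for p in pops if p.size > 0]
        if not pops:
            return Population.empty()
        if len(pops) == 1:
            return pops[0]
        return Population(
            geno=np.concatenate([p.geno for p in pops]),
            age=np.concatenate([p.age for p in pops]),
        )

    # -- census bookkeeping -------------------------------------------------

    def allosome_counts(self) -> np.ndarray:
        """Counts of XX, XY, XO individuals."""
        return np.bincount(self.allo, minlength=3)[[XX, XY, XO]]

    def autosome_counts(self) -> np.ndarray:
        """Counts of unordered genotype pairs in AUTOSOME_PAIRS order."""
        codes = self.kind_m.astype(np.int64) * 3 + self.kind_p
        raw = np.bincount(codes, minlength=9)
        out = np.zeros(len(AUTOSOME_PAIRS), dtype=np.int64)
        np.add.at(out, _PAIR_INDEX, raw)
        return out

    def drive_carrier_mask(self) -> np.ndarray:
        return (self.kind_m == DRIVE) | (self.kind_p == DRIVE)

    def female_mask(self) -> np.ndarray:
        return self.allo != XY

    # -- scalar bridge ------------------------------------------------------

    def allele_at(self, i: int, slot: str) -> Allele:
        return Allele(
            int(getattr(self, f"kind_{slot}")[i]),
            int(getattr(self, f"sites_{slot}")[i]),
            bool(getattr(self, f"del_{slot}")[i]),
            bool(getattr(self, f"func_{slot}")[i]),
        )
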