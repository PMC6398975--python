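"""Comparator strategy: a Y-linked cassette that shreds the paternal X during
meiosis, producing male-biased (or O-bearing) sperm in germline-YO carriers.

Selected in the engine with ``strategy="xshredder"``; these scalar operations
define the per-male germline state and the paternal allosome distribution the
vectorized engine implements.
"""
from __future__ import annotations

import numpy as np

from .params import XShredderParams

__all__ = ["XShredderParams", "assign_germline_state", "xshredder_paternal_gamete", "X", "Y", "O"]

X, Y, O = "X", "Y", "O"


def assign_germline_state(
    male_carrier: bool, params: XShredderParams, rng: np.random.Generator
) -> bool:
    """Whether a carrier male's germline X is destroyed (decided once per male
    at first breeding, fixed for life)."""
    if not male_carrier:
        raise ValueError("germline state is only defined for carrier males")
    return bool(rng.random() < params.shred_prob_x)


def xshredder_paternal_gamete(
    father_is_carrier: bool,
    germline_yo: bool,
    params: XShredderParams,
    rng: np.random.Generator,
) -> str:
    """Paternal allosome for one conception.

    Non-carriers and non-shredded carriers transmit X or Y Mendelian;
    germline-YO carriers transmit Y with probability ``y_transmission_yo``
    and O otherwise.  Every Y transmitted by a carrier carries the cassette
    (Y-linkage) — the caller tracks carrier status on the Y itself.
    """
    if germline_yo and not father_is_carrier:
        raise ValueError("only carrier males can be germline YO")
    if germline_yo:
        return Y if rng.random() < params.y_transmission_yo else O
    return Y if rng.random() < 0.5 else X
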