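"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values with a different implementation
style from the package (explicit subset enumeration over site index sets),
so the tests are a genuine dual route.
"""
from itertools import combinations


def enumerate_homing_outcomes(s: int, cut_prob: float, nhej_prob: float):
    """Exhaustive distribution over homing outcomes for an allele with ``s``
    susceptible sites under simultaneous cutting.

    Returns (homing_prob, transitions) where transitions maps
    (remaining_sites, deletion_flag, n_new_mutations) -> probability.
    """
    homing = 0.0
    transitions: dict[tuple[int, bool, int], float] = {}
    sites = range(s)
    for k in range(s + 1):
        for cut_set in combinations(sites, k):
            prob = 1.0
            for site in sites:
                prob *= cut_prob if site in cut_set else (1.0 - cut_prob)
            if k == 0:
                key = (s, False, 0)
                transitions[key] = transitions.get(key, 0.0) + prob
                continue
            homing += prob * (1.0 - nhej_prob)
            if k == 1:
                key = (s - 1, False, 1)
            else:
                span = set(range(min(cut_set), max(cut_set) + 1))
                survivors = [x for x in sites if x not in span and x not in cut_set]
                key = (len(survivors), True, k)
            transitions[key] = transitions.get(key, 0.0) + prob * nhej_prob
    return homing, transitions


def logistic_survival(n: float, k: float, m: float, r_max: float, cpy: int) -> float:
    """Closed-form survival oracle from the two calibration constraints."""
    import math

    ceiling = 1.0 + m / 2.0
    s0 = math.exp(r_max / cpy) / ceiling
    sk = 1.0 / ceiling
    a = math.log(1.0 / s0 - 1.0)
    b = (math.log(1.0 / sk - 1.0) - a) / k
    return 1.0 / (1.0 + math.exp(a + b * n))
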