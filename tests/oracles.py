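"""Independent brute-force oracles, written separately from the package
implementations so agreement between the two routes is meaningful."""

from __future__ import annotations

import math

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


def k2p_bruteforce(a: str, b: str) -> float:
    """K2P distance by direct per-character mismatch counting."""
    n = ts = tv = 0
    for x, y in zip(a, b, strict=True):
        if x in BASES and y in BASES:
            n += 1
            if x != y:
                same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
                if same_class:
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return math.nan
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def classify_column(column: list[str]) -> tuple[bool, bool]:
    """(variable, parsimony-informative) for one alignment column."""
    states = [c for c in column if c in BASES]
    distinct = set(states)
    variable = len(distinct) >= 2
    informative = sum(1 for s in distinct if states.count(s) >= 2) >= 2
    return variable, informative


def site_counts_bruteforce(rows: list[str]) -> tuple[int, int]:
    """(variable sites, parsimony-informative sites) by per-column scan."""
    var = pi = 0
    for col in zip(*rows):
        v, p = classify_column(list(col))
        var += v
        pi += p
    return var, pi


def best_match_bruteforce(query: str, dists: dict[tuple[str, str], float],
                          species: dict[str, str], tol: float = 1e-12) -> str:
    """Verdict for one query by full enumeration of its pairs."""
    mine = {}
    for (a, b), d in dists.items():
        if query in (a, b) and not math.isnan(d):
            other = b if a == query else a
            mine[other] = d
    if not mine:
        return "excluded"
    dmin = min(mine.values())
    tied = [o for o, d in mine.items() if d <= dmin + tol]
    kinds = {species[o] == species[query] for o in tied}
    if kinds == {True}:
        return "correct"
    if kinds == {False}:
        return "incorrect"
    return "ambiguous"
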