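"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles with the
standard library only (plain loops, ``statistics``), without importing
the code paths under test.
"""

from __future__ import annotations

import math
import statistics

PETAL_MEMBERS = ("dorsal_petal", "lateral_petal", "ventral_petal")
DOMAINS = {
    "A": ("sepal", "petal"),
    "B": ("petal", "stamen"),
    "C": ("stamen", "carpel"),
}
MERGED_CATEGORIES = ("sepal", "petal", "stamen", "carpel", "leaf", "root")


def category_value(row: dict[str, float], category: str) -> float:
    """Per-gene category expression recomputed from a plain organ->value dict."""
    if category in row:
        return row[category]
    if category == "petal":
        return sum(row[o] for o in PETAL_MEMBERS) / 3.0
    if category in DOMAINS:
        members = DOMAINS[category]
        return sum(category_value(row, m) for m in members) / len(members)
    raise KeyError(category)


def category_organs(category: str) -> set[str]:
    if category == "petal":
        return set(PETAL_MEMBERS)
    if category in DOMAINS:
        out: set[str] = set()
        for m in DOMAINS[category]:
            out |= category_organs(m)
        return out
    return {category}


def brute_force_call(
    row: dict[str, float],
    category: str,
    ratio_up: float = 2.0,
    z_up: float = 3.75,
    ratio_down: float = 0.5,
    z_down: float = -1.5,
    pseudocount: float = 0.01,
) -> tuple[float, float, str]:
    """(ratio, zscore, status) for one gene and one category, merged petals."""
    xi = category_value(row, category)
    target_organs = category_organs(category)
    others = [
        category_value(row, c)
        for c in MERGED_CATEGORIES
        if not (category_organs(c) & target_organs)
    ]
    mu = statistics.mean(others)
    sd = statistics.stdev(others)  # n-1 denominator
    if sd == 0:
        z = math.inf if xi > mu else (-math.inf if xi < mu else 0.0)
    else:
        z = (xi - mu) / sd
    ratio = (xi + pseudocount) / (mu + pseudocount)
    if ratio > ratio_up and z > z_up:
        status = "enriched"
    elif ratio < ratio_down and z < z_down:
        status = "downregulated"
    else:
        status = "neutral"
    return ratio, z, status


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_scan(seq: str, pattern: str, both: bool) -> set[tuple[int, str]]:
    """Exhaustive sliding-window match of an IUPAC pattern.

    Tests every window at every position; a reverse-strand hit is a
    window whose reverse complement matches the pattern read forward.
    Genome bases outside ACGT never match.
    """
    k = len(pattern)
    hits: set[tuple[int, str]] = set()

    def window_matches(window: str) -> bool:
        return all(
            b in "ACGT" and b in IUPAC[p] for b, p in zip(window, pattern)
        )

    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window_matches(window):
            hits.add((i, "+"))
        if both and all(b in "ACGT" for b in window) and window_matches(
            oracle_revcomp(window)
        ):
            hits.add((i, "-"))
    return hits
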