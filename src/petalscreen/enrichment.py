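"""Organ-enrichment and downregulation screening by Ratio and Z-score.

The screen asks, per gene and per target category (a single organ, the
merged petal category, or an ABC-domain organ combination), whether its
expression stands out against the remaining categories.  Two statistics
are computed:

* ``Z = (Xi - mu) / SD`` where *Xi* is the target-category expression
  and *mu*, *SD* the mean and (sample, n-1) standard deviation of the
  other categories.  When SD is zero the Z-score is reported as a
  signed-infinity sentinel (+inf if Xi > mu, -inf if Xi < mu, 0 at
  equality): a gene expressed only in the target category should pass.
* ``Ratio = (X + c) / (mean(O) + c)`` where *O* are the other
  categories' values and *c* a small pseudocount (default 0.01 RPKM)
  added to keep the ratio finite; the pseudocount never enters Z.

A gene is called *enriched* when Ratio > 2.0 and Z > 3.75, and
*downregulated* when Ratio < 0.5 and Z < -1.5 (strict inequalities).
Both statistics are invariant to rescaling the whole matrix (at zero
pseudocount), so the screen is unit-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "OrganScheme",
    "ScreenThresholds",
    "EnrichmentCall",
    "ScreenSummary",
    "category_expression",
    "z_score",
    "expression_ratio",
    "screen",
    "rpkm",
    "summarize_screen",
    "calls_to_frame",
    "calls_from_frame",
]

DEFAULT_ORGANS = (
    "sepal",
    "dorsal_petal",
    "lateral_petal",
    "ventral_petal",
    "stamen",
    "carpel",
    "leaf",
    "root",
)
PETAL = "petal"


@dataclass(frozen=True)
class OrganScheme:
    """Organ vocabulary: floral/control split, petal members, ABC domains.

    Domains are defined over category names; ``petal`` stands for the
    mean of its member organ columns and counts once inside a domain.
    """

    organs: tuple[str, ...] = DEFAULT_ORGANS
    floral: tuple[str, ...] = ("sepal", PETAL, "stamen", "carpel")
    petal_members: tuple[str, ...] = ("dorsal_petal", "lateral_petal", "ventral_petal")
    domains: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "A": ("sepal", PETAL),
            "B": (PETAL, "stamen"),
            "C": ("stamen", "carpel"),
        }
    )
    adjacency: tuple[tuple[str, str], ...] = (
        ("sepal", PETAL),
        (PETAL, "stamen"),
        ("stamen", "carpel"),
    )

    def __post_init__(self) -> None:
        known = set(self.organs) | {PETAL}
        for name, members in list(self.domains.items()):
            bad = set(members) - known
            if bad:
                raise ValueError(f"domain {name!r} names unknown category {bad}")
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"degenerate adjacency pair ({a}, {b})")
            if {a, b} - known:
                raise ValueError(f"adjacency pair ({a}, {b}) names unknown category")
        if set(self.petal_members) - set(self.organs):
            raise ValueError("petal members must be declared organs")

    def base_categories(self, merge_petals: bool = True) -> list[str]:
        """The category universe of a screen run.

        With ``merge_petals`` the three petal columns collapse into one
        ``petal`` category (default 6 categories); without it the raw
        organ columns are used.
        """
        if not merge_petals:
            return list(self.organs)
        out: list[str] = []
        for organ in self.organs:
            if organ in self.petal_members:
                if PETAL not in out:
                    out.append(PETAL)
            else:
                out.append(organ)
        return out

    def member_organs(self, category: str) -> tuple[str, ...]:
        """The organ columns underlying a category name."""
        if category in self.organs:
            return (category,)
        if category == PETAL:
            return self.petal_members
        if category in self.domains:
            organs: list[str] = []
            for member in self.domains[category]:
                for organ in self.member_organs(member):
                    if organ not in organs:
                        organs.append(organ)
            return tuple(organs)
        raise KeyError(f"unknown category {category!r}")

    def screen_categories(self) -> list[str]:
        """The seven standard screen targets: four floral + three domains."""
        return [*self.floral, *self.domains]


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs for the enrichment/downregulation calls."""

    ratio_up: float = 2.0
    z_up: float = 3.75
    ratio_down: float = 0.5
    z_down: float = -1.5
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not (self.ratio_up > 1 > self.ratio_down > 0):
            raise ValueError("require ratio_up > 1 > ratio_down > 0")
        if not (self.z_up > 0 > self.z_down):
            raise ValueError("require z_up > 0 > z_down")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class EnrichmentCall:
    """Per gene x category screen outcome."""

    gene_id: str
    category: str
    ratio: float
    zscore: float
    status: str  # enriched | downregulated | neutral | undefined


def category_expression(
    matrix: ExpressionMatrix, scheme: OrganScheme, category: str
) -> np.ndarray:
    """Per-gene expression of a category.

    Single organs return their column; ``petal`` and domains return the
    arithmetic mean over member categories, with the petal mean counting
    once inside a domain.
    """
    if category in matrix.organ_labels:
        return matrix.column(category).astype(float)
    if category == PETAL:
        cols = [matrix.column(o) for o in scheme.petal_members]
        return np.mean(cols, axis=0)
    if category in scheme.domains:
        member_values = [
            category_expression(matrix, scheme, m) for m in scheme.domains[category]
        ]
        return np.mean(member_values, axis=0)
    raise KeyError(f"unknown category {category!r}")


def z_score(
    target_value: float, other_values: Sequence[float], ddof: int = 1
) -> float:
    """Z-score of a target value against the other categories.

    Uses the sample (n-1) standard deviation by default.  A zero SD
    yields the signed-infinity sentinel (0 when the target equals the
    mean).
    """
    others = np.asarray(other_values, dtype=float)
    if others.size < 2:
        raise ValueError("z_score requires at least 2 other values")
    mu = float(others.mean())
    sd = float(others.std(ddof=ddof))
    if sd == 0.0:
        if target_value > mu:
            return math.inf
        if target_value < mu:
            return -math.inf
        return 0.0
    return (target_value - mu) / sd


def expression_ratio(
    target_value: float, other_values: Sequence[float], pseudocount: float = 0.01
) -> float:
    """Ratio of target expression to the mean of the other categories."""
    others = np.asarray(other_values, dtype=float)
    num = target_value + pseudocount
    den = float(others.mean()) + pseudocount
    if den == 0.0:
        return math.inf if num > 0 else 1.0
    return num / den


def _other_categories(
    scheme: OrganScheme, category: str, merge_petals: bool
) -> list[str]:
    """Base categories sharing no member organ with the target."""
    target_organs = set(scheme.member_organs(category))
    return [
        c
        for c in scheme.base_categories(merge_petals)
        if not target_organs & set(scheme.member_organs(c))
    ]


def screen(
    matrix: ExpressionMatrix,
    scheme: OrganScheme,
    category: str,
    thresholds: ScreenThresholds | None = None,
    merge_petals: bool = True,
    ddof: int = 1,
) -> list[EnrichmentCall]:
    """Screen every gene for enrichment/downregulation in one category.

    The "other" set is the base-category universe (6 categories when
    petals are merged, 8 otherwise) minus every category sharing a
    member organ with the target.  Strict inequalities against the
    thresholds decide the status; infinity sentinels compare as
    greater/less than any finite cutoff.
    """
    th = thresholds or ScreenThresholds()
    xi = category_expression(matrix, scheme, category)
    other_names = _other_categories(scheme, category, merge_petals)
    if len(other_names) < 2:
        raise ValueError(
            f"category {category!r} leaves fewer than 2 comparison categories"
        )
    others = np.column_stack(
        [category_expression(matrix, scheme, c) for c in other_names]
    )
    mu = others.mean(axis=1)
    sd = others.std(axis=1, ddof=ddof)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (xi - mu) / sd
    zero_sd = sd == 0.0
    z[zero_sd & (xi > mu)] = math.inf
    z[zero_sd & (xi < mu)] = -math.inf
    z[zero_sd & (xi == mu)] = 0.0

    ratio = (xi + th.pseudocount) / (mu + th.pseudocount)

    calls: list[EnrichmentCall] = []
    for gid, r, zv in zip(matrix.gene_ids, ratio, z):
        if math.isnan(r) or math.isnan(zv):
            status = "undefined"
        elif r > th.ratio_up and zv > th.z_up:
            status = "enriched"
        elif r < th.ratio_down and zv < th.z_down:
            status = "downregulated"
        else:
            status = "neutral"
        calls.append(EnrichmentCall(gid, category, float(r), float(zv), status))
    return calls


def rpkm(
    read_counts: np.ndarray,
    gene_lengths: Sequence[float],
    mapped_totals: Sequence[float],
    gene_ids: Sequence[str] | None = None,
    organ_labels: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of exon per million mapped reads.

    ``value = 1e9 * C / (N * L)`` with C the gene x organ read count,
    L the gene length in bp and N the organ's mapped-read total.
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    totals = np.asarray(mapped_totals, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(totals <= 0):
        raise ValueError("mapped-read totals must be positive")
    values = 1e9 * counts / (totals[None, :] * lengths[:, None])
    genes = list(gene_ids) if gene_ids is not None else [
        f"g{i}" for i in range(counts.shape[0])
    ]
    organs = list(organ_labels) if organ_labels is not None else [
        f"organ{j}" for j in range(counts.shape[1])
    ]
    return ExpressionMatrix(genes, organs, values)


@dataclass
class ScreenSummary:
    """Per-category enriched/downregulated counts plus deduplicated unions."""

    counts: pd.DataFrame  # index: category; columns: enriched, downregulated
    organ_enriched_union: set[str]
    domain_enriched_union: set[str]

    @property
    def total_enriched_union(self) -> set[str]:
        return self.organ_enriched_union | self.domain_enriched_union


def summarize_screen(
    calls_by_category: Mapping[str, Iterable[EnrichmentCall]],
    domain_names: Iterable[str] = ("A", "B", "C"),
) -> ScreenSummary:
    """Count enriched/downregulated genes per category and union them.

    Unions deduplicate by gene id; the organ union covers non-domain
    categories, the domain union the named combinations.
    """
    domains = set(domain_names)
    rows = {}
    organ_union: set[str] = set()
    domain_union: set[str] = set()
    for cat, calls in calls_by_category.items():
        calls = list(calls)
        enriched = {c.gene_id for c in calls if c.status == "enriched"}
        down = {c.gene_id for c in calls if c.status == "downregulated"}
        rows[cat] = {"enriched": len(enriched), "downregulated": len(down)}
        if cat in domains:
            domain_union |= enriched
        else:
            organ_union |= enriched
    counts = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    return ScreenSummary(counts, organ_union, domain_union)


def calls_to_frame(calls: Iterable[EnrichmentCall]) -> pd.DataFrame:
    """Tabulate calls; +/-inf serialize as ``inf`` / ``-inf`` via to_csv."""
    return pd.DataFrame(
        [(c.gene_id, c.category, c.ratio, c.zscore, c.status) for c in calls],
        columns=["gene_id", "category", "ratio", "zscore", "status"],
    )


def calls_from_frame(frame: pd.DataFrame) -> list[EnrichmentCall]:
    return [
        EnrichmentCall(
            str(r.gene_id), str(r.category), float(r.ratio), float(r.zscore), str(r.status)
        )
        for r in frame.itertuples(index=False)
    ]
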