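"""Organ-similarity analyses and qPCR/sequencing concordance arithmetic.

Covers organ-pairwise Spearman correlations, Pearson correlations
between adjacent floral organs (optionally on log2(x+1) values), the
log2 floral-organ / non-adjacent-organ profile used to visualize
expression-domain boundaries, average-linkage hierarchical clustering of
organs on 1 - Pearson distances, the 2^-ddCt qPCR fold change, and the
per-gene cross-platform correlation pass rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import OrganScheme, category_expression
from .io_formats import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "QpcrRecord",
    "ConcordanceResult",
    "pairwise_spearman",
    "adjacent_pearson",
    "log2_nonadjacent_profile",
    "hierarchical_cluster",
    "ddct_fold_change",
    "platform_concordance",
    "pass_percentage",
]


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with unit diagonal.

    Undefined entries (a constant column) are carried as NaN, never as a
    silent zero.
    """

    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.labels)
        if self.r.shape != (n, n):
            raise ValueError("correlation grid does not match labels")

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def _flat_scheme(matrix: ExpressionMatrix) -> OrganScheme:
    """A scheme over the matrix's raw columns, with no derived categories."""
    return OrganScheme(
        organs=tuple(matrix.organ_labels),
        floral=(),
        petal_members=(),
        domains={},
        adjacency=(),
    )


def _category_columns(
    matrix: ExpressionMatrix,
    categories: Sequence[str] | None,
    merge_petals: bool,
    scheme: OrganScheme | None = None,
) -> tuple[list[str], np.ndarray]:
    if scheme is None:
        scheme = OrganScheme() if merge_petals else _flat_scheme(matrix)
    if categories is None:
        categories = scheme.base_categories(merge_petals)
    cols = np.column_stack(
        [category_expression(matrix, scheme, c) for c in categories]
    )
    return list(categories), cols


def pairwise_spearman(
    matrix: ExpressionMatrix,
    categories: Sequence[str] | None = None,
    merge_petals: bool = False,
    scheme: OrganScheme | None = None,
) -> CorrelationMatrix:
    """Spearman rank correlation over all genes for each category pair.

    Ties receive average ranks; a constant category yields NaN against
    every other category.
    """
    if matrix.n_genes < 3:
        raise ValueError("pairwise_spearman requires at least 3 genes")
    labels, cols = _category_columns(matrix, categories, merge_petals, scheme)
    n = len(labels)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(cols[:, i]) == 0 or np.ptp(cols[:, j]) == 0:
                rho = math.nan
            else:
                rho = stats.spearmanr(cols[:, i], cols[:, j]).statistic
            r[i, j] = r[j, i] = rho
    return CorrelationMatrix(labels, r)


def adjacent_pearson(
    matrix: ExpressionMatrix,
    scheme: OrganScheme | None = None,
    transform: str = "log2p1",
) -> dict[tuple[str, str], float]:
    """Pearson r between adjacent floral-organ categories.

    ``transform='log2p1'`` applies log2(x+1) first (scatter plots of
    expression are conventionally drawn on that scale); ``'raw'`` uses
    the RPKM values directly.  Zero-variance columns give NaN.
    """
    if transform not in ("raw", "log2p1"):
        raise ValueError(f"unknown transform {transform!r}")
    scheme = scheme or OrganScheme()
    out: dict[tuple[str, str], float] = {}
    for a, b in scheme.adjacency:
        x = category_expression(matrix, scheme, a)
        y = category_expression(matrix, scheme, b)
        if transform == "log2p1":
            x, y = np.log2(x + 1), np.log2(y + 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[(a, b)] = math.nan
        else:
            out[(a, b)] = float(stats.pearsonr(x, y).statistic)
    return out


def log2_nonadjacent_profile(
    matrix: ExpressionMatrix,
    scheme: OrganScheme | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Log2 ratio of each floral category to its non-adjacent floral organs.

    Non-adjacency is the complement of the adjacency list within the
    floral categories: under the default scheme sepal is compared with
    {stamen, carpel}, petal with {carpel}, stamen with {sepal}, and
    carpel with {sepal, petal}.  A gene constant across the floral
    categories maps to an all-zero row.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    scheme = scheme or OrganScheme()
    floral = list(scheme.floral)
    adjacent = {c: set() for c in floral}
    for a, b in scheme.adjacency:
        adjacent.setdefault(a, set()).add(b)
        adjacent.setdefault(b, set()).add(a)
    values = {c: category_expression(matrix, scheme, c) for c in floral}
    out = {}
    for cat in floral:
        nonadj = [c for c in floral if c != cat and c not in adjacent[cat]]
        if not nonadj:
            raise ValueError(f"category {cat!r} has no non-adjacent floral organ")
        baseline = np.mean([values[c] for c in nonadj], axis=0)
        out[cat] = np.log2((values[cat] + pseudocount) / (baseline + pseudocount))
    return pd.DataFrame(out, index=matrix.gene_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge history over category labels.

    ``merges`` lists (left cluster, right cluster, height) with clusters
    as sorted label tuples; heights are non-decreasing (average linkage
    is monotonic).
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Newick serialization; branch length = parent height - child height."""
        node: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaves
        }
        for left, right, height in self.merges:
            ltext, lheight = node.pop(left)
            rtext, rheight = node.pop(right)
            text = f"({ltext}:{height - lheight:g},{rtext}:{height - rheight:g})"
            node[tuple(sorted(left + right))] = (text, height)
        (text, _), = node.values()
        return text + ";"


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    categories: Sequence[str] | None = None,
    merge_petals: bool = False,
    scheme: OrganScheme | None = None,
) -> Dendrogram:
    """Average-linkage clustering of categories on 1 - Pearson distance.

    The agglomeration is written out explicitly (the category count is
    tiny) so that distance ties break deterministically on the
    lexicographically smallest pair of cluster labels.  A constant
    column has no defined correlation and is an error naming the
    category.
    """
    labels, cols = _category_columns(matrix, categories, merge_petals, scheme)
    if len(labels) < 2:
        raise ValueError("clustering requires at least 2 categories")
    for lbl, col in zip(labels, cols.T):
        if np.ptp(col) == 0:
            raise ValueError(f"category {lbl!r} is constant; correlation undefined")
    corr = np.corrcoef(cols.T)
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    clusters: list[tuple[str, ...]] = [(lbl,) for lbl in labels]
    sizes = {(lbl,): 1 for lbl in labels}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[frozenset(((labels[i],), (labels[j],)))] = 1.0 - corr[i, j]

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                d = dist[frozenset((a, b))]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merged = tuple(sorted(a + b))
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)]
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged, other))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        dist.pop(frozenset((a, b)))
        sizes[merged] = sizes.pop(a) + sizes.pop(b)
        clusters.append(merged)
    return Dendrogram(sorted(labels), merges)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene Ct in one sample."""

    gene_id: str
    organ: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError(f"non-finite Ct for {self.gene_id}/{self.organ}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(sample: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_sample - (same)_calibrator; the
    fold change is 2 to the minus ddCt.
    """
    if sample.gene_id != calibrator.gene_id:
        raise ValueError(
            f"gene mismatch: {sample.gene_id!r} vs {calibrator.gene_id!r}"
        )
    return 2.0 ** (-(sample.dct - calibrator.dct))


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pass_percentage(n_pass: int, n_total: int) -> float:
    """Percentage of passing genes, half-up rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return _round_half_up(100.0 * n_pass / n_total, 1)


@dataclass
class ConcordanceResult:
    """Per-gene cross-platform correlation and the aggregate pass rate."""

    per_gene_r: pd.Series
    passes: pd.Series
    pass_pct: float


def platform_concordance(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    r_threshold: float = 0.707,
) -> ConcordanceResult:
    """Per-gene Pearson r between two platforms across organs.

    A gene passes iff r > r_threshold (strict).  A constant profile on
    either platform has no defined correlation: the gene is reported as
    NaN and counted as a non-pass.
    """
    if list(expr_a.index) != list(expr_b.index) or list(expr_a.columns) != list(
        expr_b.columns
    ):
        raise ValueError("platforms must cover the same genes and organs")
    if expr_a.shape[1] < 3:
        raise ValueError("need at least 3 organs per gene")
    rs = {}
    for gid in expr_a.index:
        x = expr_a.loc[gid].to_numpy(dtype=float)
        y = expr_b.loc[gid].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs[gid] = math.nan
        else:
            rs[gid] = float(stats.pearsonr(x, y).statistic)
    per_gene_r = pd.Series(rs, name="r")
    passes = per_gene_r > r_threshold  # NaN compares False
    return ConcordanceResult(
        per_gene_r, passes, pass_percentage(int(passes.sum()), len(passes))
    )
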