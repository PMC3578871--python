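"""Homolog mapping and cross-species expression-concordance accounting.

From BLAST tabular hits, build best-hit or reciprocal-best-hit homolog
maps (strict E-value cutoff, default 1e-5).  Each gene enriched in the
source species is then classified against the partner species:

* ``NH`` - no homolog under the map;
* ``EE`` - the homolog is enriched in at least one of the partner's
  screened categories (or, in strict counterpart mode, in the same
  category);
* ``DE`` - the homolog's expression exceeds the detection threshold in
  at least one screened partner category;
* ``UE`` - the homolog is undetectable throughout.

Precedence is EE > DE > UE, and the accounting identities
``HH = DE + EE + UE`` and ``NH + HH = enriched`` hold on every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentCall
from .io_formats import ExpressionMatrix, HomologHit

__all__ = [
    "HomologMap",
    "CrossClass",
    "AccountingTable",
    "best_hits",
    "reciprocal_best_pairs",
    "classify_cross_expression",
    "accounting",
    "enrichment_percentage",
]

CLASS_ROWS = ("NH", "DE", "EE", "UE")


@dataclass
class HomologMap:
    """query -> subject homolog assignment."""

    pairs: dict[str, str]
    mode: str = "best_hit"  # best_hit | reciprocal_best

    def __post_init__(self) -> None:
        if self.mode not in ("best_hit", "reciprocal_best"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "reciprocal_best" and len(set(self.pairs.values())) != len(
            self.pairs
        ):
            raise ValueError("reciprocal-best map must be one-to-one")

    def __contains__(self, query: str) -> bool:
        return query in self.pairs

    def __getitem__(self, query: str) -> str:
        return self.pairs[query]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CrossClass:
    """Cross-species expression class of one source-enriched gene."""

    gene_id: str
    category: str
    klass: str  # NH | DE | EE | UE
    homolog_id: str | None = None

    def __post_init__(self) -> None:
        if self.klass not in CLASS_ROWS:
            raise ValueError(f"unknown class {self.klass!r}")
        if (self.klass == "NH") != (self.homolog_id is None):
            raise ValueError("NH iff the gene has no homolog")


def best_hits(hits: Iterable[HomologHit], evalue_cutoff: float = 1e-5) -> HomologMap:
    """Best hit per query among hits with evalue strictly below the cutoff.

    Ties on evalue break by larger bitscore, then by lexicographically
    smallest subject id.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue cutoff must be positive")
    best: dict[str, HomologHit] = {}
    for hit in hits:
        if hit.evalue >= evalue_cutoff:
            continue
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        cand = (hit.evalue, -hit.bitscore, hit.subject_id)
        incumbent = (cur.evalue, -cur.bitscore, cur.subject_id)
        if cand < incumbent:
            best[hit.query_id] = hit
    return HomologMap({q: h.subject_id for q, h in best.items()}, "best_hit")


def reciprocal_best_pairs(map_ab: HomologMap, map_ba: HomologMap) -> HomologMap:
    """Keep (a, b) iff a's best hit is b and b's best hit is a."""
    pairs = {
        a: b
        for a, b in map_ab.pairs.items()
        if map_ba.pairs.get(b) == a
    }
    return HomologMap(pairs, "reciprocal_best")


def classify_cross_expression(
    source_enriched: Iterable[str],
    partner_calls: Iterable[EnrichmentCall],
    partner_expr: ExpressionMatrix,
    homolog_map: HomologMap,
    detect_threshold: float = 0.0,
    category: str = "",
    counterpart_only: bool = False,
    screened_organs: Sequence[str] | None = None,
) -> list[CrossClass]:
    """Classify source-enriched genes as NH / EE / DE / UE in the partner.

    ``partner_calls`` are the partner species' screen results over its
    categories; EE means enriched in any of them (``counterpart_only``
    restricts to calls whose category equals ``category``).  DE means
    expression above ``detect_threshold`` in at least one screened organ
    column (default: all columns of ``partner_expr``).
    """
    if detect_threshold < 0:
        raise ValueError("detect threshold must be >= 0")
    enriched_in: dict[str, set[str]] = {}
    for call in partner_calls:
        if call.status == "enriched":
            enriched_in.setdefault(call.gene_id, set()).add(call.category)
    organs = list(screened_organs) if screened_organs else list(
        partner_expr.organ_labels
    )
    gene_index = {g: i for i, g in enumerate(partner_expr.gene_ids)}
    organ_idx = [partner_expr.organ_labels.index(o) for o in organs]

    out: list[CrossClass] = []
    for gid in source_enriched:
        if gid not in homolog_map:
            out.append(CrossClass(gid, category, "NH"))
            continue
        hom = homolog_map[gid]
        if hom not in gene_index:
            raise KeyError(f"homolog {hom!r} absent from partner expression matrix")
        partner_cats = enriched_in.get(hom, set())
        if partner_cats and (not counterpart_only or category in partner_cats):
            klass = "EE"
        elif np.any(
            partner_expr.values[gene_index[hom], organ_idx] > detect_threshold
        ):
            klass = "DE"
        else:
            klass = "UE"
        out.append(CrossClass(gid, category, klass, hom))
    return out


@dataclass
class AccountingTable:
    """Cross-species class counts per category, with the HH and total rows.

    Rows: ``enriched`` (source-enriched genes), ``NH``, ``DE``, ``EE``,
    ``UE``, ``HH`` (= DE + EE + UE); one column per category plus a
    ``Total`` column.
    """

    table: pd.DataFrame = field(repr=False)

    ROW_ORDER = ("enriched", "NH", "DE", "EE", "UE", "HH")

    def __post_init__(self) -> None:
        self.table = self.table.loc[list(self.ROW_ORDER)].astype(int)
        hh = self.table.loc[["DE", "EE", "UE"]].sum(axis=0)
        if not (self.table.loc["HH"] == hh).all():
            raise ValueError("accounting identity HH = DE + EE + UE violated")
        if not (
            self.table.loc["enriched"] == self.table.loc["NH"] + self.table.loc["HH"]
        ).all():
            raise ValueError("accounting identity NH + HH = enriched violated")

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]]
    ) -> "AccountingTable":
        """Build from per-category {NH, DE, EE, UE} counts; derives HH,
        the enriched row and the Total column."""
        cols = {}
        for cat, c in counts.items():
            nh, de, ee, ue = (int(c[k]) for k in CLASS_ROWS)
            hh = de + ee + ue
            cols[cat] = {
                "enriched": nh + hh,
                "NH": nh,
                "DE": de,
                "EE": ee,
                "UE": ue,
                "HH": hh,
            }
        table = pd.DataFrame(cols)
        table["Total"] = table.sum(axis=1)
        return cls(table)

    def value(self, row: str, category: str) -> int:
        return int(self.table.loc[row, category])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def accounting(
    classes_by_category: Mapping[str, Iterable[CrossClass]],
) -> AccountingTable:
    """Tally per-category class counts into the standard accounting layout."""
    counts = {}
    for cat, classes in classes_by_category.items():
        tally = {k: 0 for k in CLASS_ROWS}
        for c in classes:
            tally[c.klass] += 1
        counts[cat] = tally
    if not counts:
        counts = {"all": {k: 0 for k in CLASS_ROWS}}
    return AccountingTable.from_counts(counts)


def enrichment_percentage(enriched_count: int, total_genes: int) -> float:
    """100 * enriched / total, half-up rounded to two decimals."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if not (0 <= enriched_count <= total_genes):
        raise ValueError("enriched count outside [0, total]")
    pct = Decimal(100) * Decimal(enriched_count) / Decimal(total_genes)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
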