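"""Synthetic data with planted truth for every pipeline input.

The generator emulates the structure of an 8-organ floral RPKM atlas
(sepal, three petal types, stamen, carpel, plus leaf and root controls):
a right-skewed log-normal baseline per gene, multiplicative log-normal
noise at a controllable coefficient of variation, and planted
organ-enriched / downregulated genes whose target-category columns are
multiplied / divided by a fold factor.  Companion generators produce a
partner species with a controllable fraction of conserved enrichment
(plus reciprocal-best-hit BLAST tables with decoy hits), promoters with
planted motif instances, and qPCR Ct tables consistent with a planted
expression matrix.  Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .enrichment import PETAL, OrganScheme
from .io_formats import ExpressionMatrix, HomologHit
from .motifs import IUPAC_CLASSES, Promoter
from .similarity import QpcrRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_homology",
    "simulate_promoters",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror a small version of the study conditions: 8 organs,
    a 5 RPKM median baseline, 10-fold planted effects, 20% multiplicative
    noise, 2,000 bp promoters.
    """

    n_genes: int = 1000
    scheme: OrganScheme = field(default_factory=OrganScheme)
    planted_enriched: Mapping[str, int] = field(
        default_factory=lambda: {"sepal": 30, PETAL: 30, "stamen": 30, "carpel": 30}
    )
    planted_down: Mapping[str, int] = field(
        default_factory=lambda: {"sepal": 10, PETAL: 10, "stamen": 10, "carpel": 10}
    )
    effect_fold: float = 10.0
    baseline_mean: float = 5.0
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.2
    ortholog_fraction: float = 0.8
    conserved_enrichment_fraction: float = 0.5
    undetectable_fraction: float = 0.05
    promoter_length: int = 2000
    planted_sites_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in (
            "ortholog_fraction",
            "conserved_enrichment_fraction",
            "undetectable_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.planted_enriched.values()) + sum(self.planted_down.values())
        if total > self.n_genes:
            raise ValueError(
                f"planted gene counts ({total}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    enriched: dict[str, set[str]] = field(default_factory=dict)  # category -> genes
    downregulated: dict[str, set[str]] = field(default_factory=dict)
    ortholog_pairs: dict[str, str] = field(default_factory=dict)  # A gene -> B gene
    conserved: set[str] = field(default_factory=set)  # A genes with conserved enrichment
    undetectable_partners: set[str] = field(default_factory=set)  # B genes set to 0
    planted_sites: dict[str, list[int]] = field(default_factory=dict)  # gene -> starts

    def enriched_category_of(self, gene_id: str) -> str | None:
        for cat, genes in self.enriched.items():
            if gene_id in genes:
                return cat
        return None


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=shape))


def simulate_expression(
    config: SimulationConfig, gene_prefix: str = "g"
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an RPKM matrix with planted enriched/downregulated genes.

    Baselines are log-normal around ``baseline_mean`` (median); planted
    enriched genes have their target category's member-organ columns
    multiplied by ``effect_fold``, downregulated genes divided by it;
    multiplicative log-normal noise at ``noise_cv`` is applied last.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    organs = list(scheme.organs)
    n = config.n_genes
    gene_ids = [f"{gene_prefix}{i:05d}" for i in range(n)]

    baseline = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=n)
    )
    values = np.tile(baseline[:, None], (1, len(organs)))

    truth = SyntheticTruth()
    cursor = 0
    for direction, planted in (
        ("enriched", config.planted_enriched),
        ("downregulated", config.planted_down),
    ):
        store = truth.enriched if direction == "enriched" else truth.downregulated
        for category, count in planted.items():
            members = scheme.member_organs(category)
            idx = [organs.index(o) for o in members]
            genes = set(gene_ids[cursor : cursor + count])
            if len(genes) < count:
                raise ValueError("planted counts exceed available genes")
            for row in range(cursor, cursor + count):
                if direction == "enriched":
                    values[row, idx] *= config.effect_fold
                else:
                    values[row, idx] /= config.effect_fold
            store[category] = genes
            cursor += count

    values = values * _lognormal_noise(rng, config.noise_cv, values.shape)
    return ExpressionMatrix(gene_ids, organs, values), truth


def simulate_homology(
    matrix_a: ExpressionMatrix,
    truth_a: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[list[HomologHit], list[HomologHit], ExpressionMatrix, SyntheticTruth]:
    """Simulate a partner species with controllable enrichment conservation.

    A fraction ``ortholog_fraction`` of A genes get a unique B partner
    (mutual best hits at E = 1e-30).  A planted-enriched A gene keeps its
    enrichment in B with probability ``conserved_enrichment_fraction``;
    a fraction ``undetectable_fraction`` of the remaining partners is
    zeroed out (UE).  Decoy hits with E-values above the 1e-5 cutoff are
    interleaved to exercise the filtering.
    """
    rng = np.random.default_rng(config.seed + 1)
    scheme = config.scheme
    organs = list(scheme.organs)

    a_genes = list(matrix_a.gene_ids)
    is_ortholog = rng.random(len(a_genes)) < config.ortholog_fraction
    pairs = {
        a: f"B_{a}" for a, keep in zip(a_genes, is_ortholog) if keep
    }

    b_genes = [pairs[a] for a in a_genes if a in pairs]
    nb = len(b_genes)
    baseline = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=nb)
    )
    values = np.tile(baseline[:, None], (1, len(organs)))

    truth_b = SyntheticTruth(ortholog_pairs=dict(pairs))
    b_index = {b: i for i, b in enumerate(b_genes)}
    for a_gene, b_gene in pairs.items():
        cat = truth_a.enriched_category_of(a_gene)
        row = b_index[b_gene]
        if cat is not None:
            if rng.random() < config.conserved_enrichment_fraction:
                idx = [organs.index(o) for o in scheme.member_organs(cat)]
                values[row, idx] *= config.effect_fold
                truth_b.enriched.setdefault(cat, set()).add(b_gene)
                truth_b.conserved.add(a_gene)
            elif rng.random() < config.undetectable_fraction:
                values[row, :] = 0.0
                truth_b.undetectable_partners.add(b_gene)
    noisy = values * _lognormal_noise(rng, config.noise_cv, values.shape)
    noisy[values == 0.0] = 0.0
    matrix_b = ExpressionMatrix(b_genes, organs, noisy)

    hits_ab: list[HomologHit] = []
    hits_ba: list[HomologHit] = []
    for a_gene, b_gene in pairs.items():
        bits = float(200 + rng.integers(0, 100))
        hits_ab.append(HomologHit(a_gene, b_gene, 1e-30, bits))
        hits_ba.append(HomologHit(b_gene, a_gene, 1e-30, bits))
    # Decoys: above-cutoff self-inconsistent hits that best_hits must drop.
    for a_gene in a_genes[:: max(1, len(a_genes) // 20)]:
        decoy = b_genes[int(rng.integers(0, nb))] if nb else "B_none"
        hits_ab.append(HomologHit(a_gene, decoy, 1e-3, 40.0))
    return hits_ab, hits_ba, matrix_b, truth_b


def simulate_promoters(
    config: SimulationConfig,
    pattern: str,
    n_genes: int | None = None,
    gene_prefix: str = "p",
) -> tuple[dict[str, Promoter], SyntheticTruth]:
    """Uniform-ACGT promoters with planted, non-overlapping pattern sites.

    Planted sites are concrete instantiations of the IUPAC pattern at
    recorded positions; background occurrences may also arise and are
    not suppressed (truth records planted positions only).
    """
    sets = [IUPAC_CLASSES[ch] for ch in pattern.upper()]
    k = len(pattern)
    if k > config.promoter_length:
        raise ValueError(
            f"pattern length {k} exceeds promoter length {config.promoter_length}"
        )
    n_sites = config.planted_sites_per_gene
    if n_sites * 2 * k > config.promoter_length:
        raise ValueError("infeasible planting density")
    rng = np.random.default_rng(config.seed + 2)
    n = n_genes if n_genes is not None else max(1, config.n_genes // 10)
    bases = "ACGT"
    truth = SyntheticTruth()
    promoters: dict[str, Promoter] = {}
    for i in range(n):
        gid = f"{gene_prefix}{i:04d}"
        seq = list(
            "".join(bases[j] for j in rng.integers(0, 4, size=config.promoter_length))
        )
        # non-overlapping slots: partition the sequence into n_sites blocks
        starts = []
        block = config.promoter_length // max(1, n_sites)
        for s in range(n_sites):
            lo = s * block
            hi = min((s + 1) * block, config.promoter_length) - k
            start = int(rng.integers(lo, hi + 1))
            site = "".join(
                sorted(cls)[int(rng.integers(0, len(cls)))] for cls in sets
            )
            seq[start : start + k] = site
            starts.append(start)
        promoters[gid] = Promoter(gid, "".join(seq), config.promoter_length, False)
        truth.planted_sites[gid] = starts
    return promoters, truth


def simulate_qpcr(
    matrix: ExpressionMatrix,
    config: SimulationConfig,
    genes: list[str] | None = None,
    ct_noise_sd: float = 0.0,
    c0: float = 30.0,
    reference_ct: float = 20.0,
    pseudocount: float = 0.01,
) -> list[QpcrRecord]:
    """Ct tables consistent with an expression matrix.

    ``ct_target = c0 - log2(expression + pseudocount) + N(0, sd)`` with a
    constant reference-gene Ct, so noiseless Ct profiles are a strictly
    decreasing transform of expression and correlate perfectly with it.
    """
    rng = np.random.default_rng(config.seed + 3)
    gene_set = genes if genes is not None else list(matrix.gene_ids)
    records: list[QpcrRecord] = []
    for gid in gene_set:
        row = matrix.values[matrix.gene_ids.index(gid)]
        for organ, value in zip(matrix.organ_labels, row):
            ct = c0 - math.log2(value + pseudocount)
            if ct_noise_sd > 0:
                ct += float(rng.normal(0.0, ct_noise_sd))
            records.append(QpcrRecord(gid, organ, ct, reference_ct))
    return records
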