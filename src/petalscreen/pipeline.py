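"""End-to-end orchestration: screens -> similarity -> cross-species -> motifs.

``run_pipeline`` executes the enabled stages in dependency order from a
flat configuration, writes tab-separated outputs plus one structured
JSON report per run, and logs the thresholds and the exact "other
categories" set used by every screen (the under-specified knobs).  The
run is deterministic: identical config and inputs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import cross_species, enrichment, io_formats, motifs, similarity
from .enrichment import OrganScheme, ScreenThresholds

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; keys mirror the CLI flags."""

    expr: str = ""
    hits_ab: str = ""
    hits_ba: str = ""
    expr_b: str = ""
    genome: str = ""
    gff: str = ""
    outdir: str = "petalscreen_out"
    # stage toggles
    run_screen: bool = True
    run_similarity: bool = True
    run_cross: bool = False
    run_motifs: bool = False
    # screen parameters
    ratio_up: float = 2.0
    z_up: float = 3.75
    ratio_down: float = 0.5
    z_down: float = -1.5
    pseudocount: float = 0.01
    merge_petals: bool = True
    # cross-species parameters
    homolog_mode: str = "best"  # best | rbh
    evalue_cutoff: float = 1e-5
    detect_threshold: float = 0.0
    # motif parameters
    pattern: str = "GGNCCC"
    promoter_length: int = 2000
    strands: str = "both"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(
            self.ratio_up, self.z_up, self.ratio_down, self.z_down, self.pseudocount
        )


def _screen_stage(
    config: PipelineConfig,
    matrix: io_formats.ExpressionMatrix,
    scheme: OrganScheme,
    outdir: Path,
    tag: str = "",
) -> tuple[dict[str, list[enrichment.EnrichmentCall]], dict[str, Any]]:
    thresholds = config.thresholds()
    calls_by_cat: dict[str, list[enrichment.EnrichmentCall]] = {}
    log: dict[str, Any] = {"thresholds": asdict(thresholds), "categories": {}}
    for category in scheme.screen_categories():
        calls = enrichment.screen(
            matrix, scheme, category, thresholds, merge_petals=config.merge_petals
        )
        calls_by_cat[category] = calls
        log["categories"][category] = {
            "other_categories": enrichment._other_categories(
                scheme, category, config.merge_petals
            )
        }
    frame = enrichment.calls_to_frame(
        [c for calls in calls_by_cat.values() for c in calls]
    )
    path = outdir / f"screen_calls{tag}.tsv"
    frame.to_csv(path, sep="\t", index=False)
    summary = enrichment.summarize_screen(calls_by_cat, scheme.domains.keys())
    summary.counts.to_csv(outdir / f"screen_counts{tag}.tsv", sep="\t")
    log["outputs"] = [path.name]
    log["counts"] = {
        cat: row.to_dict() for cat, row in summary.counts.iterrows()
    }
    log["organ_enriched_union"] = len(summary.organ_enriched_union)
    log["domain_enriched_union"] = len(summary.domain_enriched_union)
    log["total_enriched_union"] = len(summary.total_enriched_union)
    return calls_by_cat, log


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": asdict(config), "stages": {}}

    matrix = None
    scheme = OrganScheme()
    if config.run_screen or config.run_similarity or config.run_cross:
        if not config.expr:
            raise PipelineError("screen: no expression table configured")
        try:
            matrix = io_formats.read_expression_table(Path(config.expr).read_text())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"screen: failed to read {config.expr}: {exc}") from exc
        scheme = OrganScheme(organs=tuple(matrix.organ_labels))

    calls_a: dict[str, list[enrichment.EnrichmentCall]] = {}
    if config.run_screen:
        try:
            calls_a, log = _screen_stage(config, matrix, scheme, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"screen: {exc}") from exc
        report["stages"]["screen"] = log
    else:
        report["stages"]["screen"] = "skipped"

    if config.run_similarity:
        try:
            corr = similarity.pairwise_spearman(matrix, merge_petals=True, scheme=scheme)
            corr.to_frame().to_csv(outdir / "spearman.tsv", sep="\t")
            adj = similarity.adjacent_pearson(matrix, scheme)
            dend = similarity.hierarchical_cluster(
                matrix, merge_petals=False, scheme=scheme
            )
            (outdir / "organ_dendrogram.nwk").write_text(dend.to_newick() + "\n")
            profile = similarity.log2_nonadjacent_profile(matrix, scheme)
            profile.to_csv(outdir / "log2_nonadjacent_profile.tsv", sep="\t")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"similarity: {exc}") from exc
        report["stages"]["similarity"] = {
            "adjacent_pearson": {f"{a}-{b}": r for (a, b), r in adj.items()},
            "outputs": [
                "spearman.tsv",
                "organ_dendrogram.nwk",
                "log2_nonadjacent_profile.tsv",
            ],
        }
    else:
        report["stages"]["similarity"] = "skipped"

    if config.run_cross:
        try:
            hits_ab = io_formats.read_blast_tabular(Path(config.hits_ab).read_text())
            hits_ba = io_formats.read_blast_tabular(Path(config.hits_ba).read_text())
            matrix_b = io_formats.read_expression_table(Path(config.expr_b).read_text())
            scheme_b = OrganScheme(organs=tuple(matrix_b.organ_labels))
            map_ab = cross_species.best_hits(hits_ab, config.evalue_cutoff)
            if config.homolog_mode == "rbh":
                map_ba = cross_species.best_hits(hits_ba, config.evalue_cutoff)
                homolog_map = cross_species.reciprocal_best_pairs(map_ab, map_ba)
            else:
                homolog_map = map_ab
            thresholds = config.thresholds()
            calls_b = [
                c
                for cat in scheme_b.screen_categories()
                for c in enrichment.screen(
                    matrix_b, scheme_b, cat, thresholds, config.merge_petals
                )
            ]
            classes = {
                cat: cross_species.classify_cross_expression(
                    sorted({c.gene_id for c in calls if c.status == "enriched"}),
                    calls_b,
                    matrix_b,
                    homolog_map,
                    config.detect_threshold,
                    category=cat,
                )
                for cat, calls in calls_a.items()
            }
            table = cross_species.accounting(classes)
            table.to_frame().to_csv(outdir / "accounting.tsv", sep="\t")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"cross: {exc}") from exc
        report["stages"]["cross"] = {
            "homolog_mode": config.homolog_mode,
            "n_homolog_pairs": len(homolog_map),
            "accounting": {
                cat: table.to_frame()[cat].to_dict() for cat in table.to_frame()
            },
            "outputs": ["accounting.tsv"],
        }
    else:
        report["stages"]["cross"] = "skipped"

    if config.run_motifs:
        try:
            genome = io_formats.read_fasta(Path(config.genome).read_text())
            loci = io_formats.read_gene_loci(Path(config.gff).read_text())
            promoters = motifs.extract_promoters(
                genome, loci, config.promoter_length
            )
            hits, counts = motifs.scan(promoters, config.pattern, config.strands)
            with open(outdir / "motif_hits.tsv", "w") as fh:
                fh.write("gene_id\tstart\tstrand\tmatched\n")
                for h in hits:
                    fh.write(f"{h.gene_id}\t{h.start}\t{h.strand}\t{h.matched}\n")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"motifs: {exc}") from exc
        report["stages"]["motifs"] = {
            "pattern": config.pattern,
            "total_sites": sum(counts.values()),
            "genes_with_site": sum(1 for c in counts.values() if c > 0),
            "outputs": ["motif_hits.tsv"],
        }
    else:
        report["stages"]["motifs"] = "skipped"

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
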