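"""End-to-end orchestration and reporting.

Two entry points matter:

* :func:`run_simulation_study` — generate a synthetic scenario, run every
  analysis stage on it (catalog -> synteny -> duplication modes), and
  score the inferences against the planted truth. This is the package's
  recovery harness.
* :func:`run_pipeline` — file-driven orchestration from a
  :class:`PipelineConfig` (YAML-loadable), producing TSV outputs plus a
  Markdown report whose every number is recomputed from the emitted TSVs
  by a self-consistency audit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import catalog, dupmodes, expression, fixtures, kaks, simulate, synteny
from ._util import make_percentage, round_half_up

logger = logging.getLogger(__name__)


def make_percentages(numerator: float, denominator: float, decimals: int = 2):
    """Half-up percentage; 'NA' when the denominator is zero."""
    if denominator == 0:
        return "NA"
    return make_percentage(numerator, denominator, decimals)


# ---------------------------------------------------------------------------
# simulation recovery study
# ---------------------------------------------------------------------------


@dataclass
class DescendantAnalysis:
    species: str
    records: pd.DataFrame
    copy_summary: pd.DataFrame
    arrays: list
    partition: dupmodes.DuplicationPartition
    age_recovery: dupmodes.AgeRecovery
    copy_class_accuracy: float
    n_blocks: int


def analyze_descendant(
    ancestor: simulate.AncestorGenome,
    genome: simulate.Genome,
    subgenome_map: pd.DataFrame,
    anchors: pd.DataFrame,
    truth: simulate.DuplicationTruth | None = None,
    family_genes=None,
    min_anchors: int = 5,
    max_rank_gap: int = 25,
    max_intervening: int = 1,
) -> DescendantAnalysis:
    """Run synteny + duplication-mode stages for one descendant genome."""
    filtered = synteny.filter_anchors(anchors, target_genes=genome.genes)
    blocks = synteny.chain_synteny_blocks(
        filtered, ancestor.genes, genome.genes, min_anchors, max_rank_gap
    )
    blocks = synteny.assign_subgenomes(blocks, subgenome_map, genome.genes)
    blocks = [b for b in blocks if b.subgenome is not None]
    if family_genes is None:
        family_genes = set(ancestor.genes["gene_id"])
    records, copy_summary = synteny.build_ortholog_records(
        blocks, family_genes, species=genome.species
    )

    ref_arrays = dupmodes.detect_tandem_arrays(
        ancestor.genes, ancestor.families, max_intervening
    )
    arrays = dupmodes.detect_tandem_arrays(
        genome.genes, genome.families, max_intervening
    )
    arrays = dupmodes.classify_array_age(arrays, records, ref_arrays)
    wgt = synteny.wgt_gene_set(records)
    td = dupmodes.tandem_gene_set(arrays)
    partition = dupmodes.partition_wgt_td(wgt, td)

    age_recovery = None
    copy_acc = float("nan")
    if truth is not None:
        excluded = _degraded_members(truth, genome.species)
        age_recovery = dupmodes.score_age_recovery(
            arrays, records, truth.origin, excluded_genes=excluded
        )
        copy_acc = _copy_class_accuracy(records, truth, genome.species)
    return DescendantAnalysis(
        species=genome.species,
        records=records,
        copy_summary=copy_summary,
        arrays=arrays,
        partition=partition,
        age_recovery=age_recovery,
        copy_class_accuracy=copy_acc,
        n_blocks=len(blocks),
    )


def _degraded_members(truth: simulate.DuplicationTruth, species: str) -> set:
    """Descendant copies of planted arrays degraded below two members.

    A planted array reduced to 0 or 1 members in a subgenome cannot be
    recognized as an array there; the surviving member (if any) is
    excluded from member-level scoring, not guessed at.
    """
    att = truth.array_attrition
    att = att[(att["species"] == species) & (att["members_retained"] == 1)]
    degraded_sources = {
        (row.subgenome, g)
        for row in att.itertuples(index=False)
        for g in row.array.split(",")
    }
    out = set()
    for row in truth.ortholog_map.itertuples(index=False):
        if row.species == species and (row.subgenome, row.ref_gene) in degraded_sources:
            out.add(row.descendant_gene)
    return out


def _copy_class_accuracy(
    records: pd.DataFrame, truth: simulate.DuplicationTruth, species: str
) -> float:
    """Fraction of reference genes whose recovered subgenome slots match truth."""
    tm = truth.ortholog_map
    tm = tm[tm["species"] == species]
    true_slots: dict[str, dict[str, str]] = {}
    for row in tm.itertuples(index=False):
        true_slots.setdefault(row.ref_gene, {})[row.subgenome] = row.descendant_gene
    n_ok = 0
    for row in records.itertuples(index=False):
        expected = true_slots.get(row.ref_gene, {})
        got = {
            sg: getattr(row, sg)
            for sg in simulate.SUBGENOMES
            if getattr(row, sg) is not None and pd.notna(getattr(row, sg))
        }
        if got == expected:
            n_ok += 1
    return n_ok / len(records) if len(records) else 1.0


def run_simulation_study(
    config: simulate.SimulationConfig, n_descendants: int = 2
) -> dict:
    """Simulate a scenario and score every recoverable inference.

    Returns a dict with the scenario objects and per-descendant analyses
    plus aggregate recovery metrics (member-level tandem-age precision and
    recall, copy-class accuracy, counts of degraded planted arrays).
    """
    ancestor = simulate.simulate_ancestor(config)
    descendants, sg_map, anchors, truth = simulate.simulate_triplication_descendants(
        ancestor, config, n_descendants
    )
    analyses = [
        analyze_descendant(ancestor, g, sg_map, anchors, truth) for g in descendants
    ]
    recs = [a.age_recovery for a in analyses]
    metrics = {
        "precision_ancient": min(r.precision_ancient for r in recs),
        "recall_ancient": min(r.recall_ancient for r in recs),
        "precision_lineage": min(r.precision_lineage for r in recs),
        "recall_lineage": min(r.recall_lineage for r in recs),
        "copy_class_accuracy": min(a.copy_class_accuracy for a in analyses),
        "n_members_scored": sum(r.n_members for r in recs),
        "n_members_excluded": sum(r.n_excluded for r in recs),
        "n_degraded_arrays": int(len(truth.array_attrition)),
    }
    return {
        "ancestor": ancestor,
        "descendants": descendants,
        "subgenome_map": sg_map,
        "anchors": anchors,
        "truth": truth,
        "analyses": analyses,
        "metrics": metrics,
    }


# ---------------------------------------------------------------------------
# file-driven pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Stage toggles, parameters, and input paths for a file-driven run."""

    out_dir: str = "famexpand_out"
    seed: int | None = None
    decimals: int = 2
    # stage toggles
    run_catalog: bool = False
    run_synteny: bool = False
    run_dupmodes: bool = False
    run_kaks: bool = False
    run_express: bool = False
    fixture_mode: bool = False
    # inputs
    gff: str | None = None
    families: str | None = None
    ref_gff: str | None = None
    ref_families: str | None = None
    anchors: str | None = None
    subgenome_map: str | None = None
    pairs_fasta: str | None = None
    expression_matrix: str | None = None
    # parameters
    max_gap: int = 8
    max_intervening: int = 1
    min_anchors: int = 5
    max_rank_gap: int = 25
    max_significance: float = 1e-20
    k: int = 9
    neutral_band: float = 0.05
    placed_chromosomes: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageDependencyError(RuntimeError):
    """A stage was enabled without the stage output it depends on."""


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages, write TSVs and a Markdown report.

    Returns a dict of the in-memory results keyed by stage. Every number
    in the report comes from the written TSVs (re-read and audited).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    report: list[str] = ["# famexpand report", ""]

    for name, path in (
        ("gff", config.gff),
        ("families", config.families),
        ("anchors", config.anchors),
    ):
        if path:
            logger.info("input %s: %s sha256=%s", name, path, _checksum(path))

    genes = families = None
    if config.run_catalog:
        if not (config.gff and config.families):
            raise StageDependencyError("catalog stage needs --gff and --families")
        genes = catalog.load_annotation(config.gff)
        genes = catalog.assign_ranks(
            genes, config.placed_chromosomes or None
        )
        families = catalog.load_family_assignments(config.families)
        clusters, singletons = catalog.detect_gene_clusters(
            genes, families, max_gap=config.max_gap
        )
        cframe = catalog.clusters_to_frame(clusters)
        cframe.to_csv(out / "clusters.tsv", sep="\t", index=False)
        placed = config.placed_chromosomes or sorted(genes["chromosome"].unique())
        dist = catalog.chromosome_distribution(genes, placed, decimals=1)
        pd.DataFrame([dist | {"per_chromosome": ""}]).to_csv(
            out / "chromosome_distribution.tsv", sep="\t", index=False
        )
        results["catalog"] = {
            "clusters": clusters,
            "singletons": singletons,
            "distribution": dist,
        }
        audited = pd.read_csv(out / "clusters.tsv", sep="\t")
        n_genes_in_clusters = int(audited["n_members"].sum()) if len(audited) else 0
        report += [
            "## Gene clusters",
            f"- clusters: {len(audited)}",
            f"- genes in clusters: {n_genes_in_clusters}"
            f" ({make_percentages(n_genes_in_clusters, dist['placed'], config.decimals)}%"
            " of placed genes)",
            f"- placed on chromosomes: {dist['placed']}/{dist['total']}"
            f" ({dist['placed_pct']}%)",
            "",
        ]

    records = None
    if config.run_synteny:
        needed = (config.ref_gff, config.gff, config.anchors, config.subgenome_map)
        if not all(needed):
            raise StageDependencyError(
                "synteny stage needs --ref-gff, --gff, --anchors and --subgenome-map"
            )
        ref_genes = catalog.assign_ranks(catalog.load_annotation(config.ref_gff))
        if genes is None:
            genes = catalog.assign_ranks(catalog.load_annotation(config.gff))
        anchors = synteny.load_anchors(config.anchors)
        sg_map = synteny.load_subgenome_map(config.subgenome_map)
        filtered = synteny.filter_anchors(
            anchors, target_genes=genes, max_significance=config.max_significance
        )
        blocks = synteny.chain_synteny_blocks(
            filtered, ref_genes, genes, config.min_anchors, config.max_rank_gap
        )
        blocks = synteny.assign_subgenomes(blocks, sg_map, genes)
        labeled = [b for b in blocks if b.subgenome is not None]
        if config.ref_families:
            fam_genes = set(
                catalog.load_family_assignments(config.ref_families)["gene_id"]
            )
        else:
            fam_genes = set(ref_genes["gene_id"])
        records, copy_summary = synteny.build_ortholog_records(labeled, fam_genes)
        records.to_csv(out / "ortholog_records.tsv", sep="\t", index=False)
        copy_summary.to_csv(out / "copy_class_summary.tsv", sep="\t", index=False)
        results["synteny"] = {"blocks": blocks, "records": records}
        audited = pd.read_csv(out / "copy_class_summary.tsv", sep="\t")
        report += ["## Ortholog retention (copy classes)"]
        for row in audited.itertuples(index=False):
            report.append(
                f"- {row.copy_class}-copy: {row.n_ref_genes} reference genes"
                f" ({row.descendant_copies} descendant copies)"
            )
        report.append("")

    if config.run_dupmodes:
        if genes is None or families is None:
            raise StageDependencyError("dupmodes stage needs the catalog stage")
        arrays = dupmodes.detect_tandem_arrays(
            genes, families, config.max_intervening
        )
        if records is not None and config.ref_gff:
            ref_genes = catalog.assign_ranks(catalog.load_annotation(config.ref_gff))
            if config.ref_families:
                ref_fams = catalog.load_family_assignments(config.ref_families)
                ref_arrays = dupmodes.detect_tandem_arrays(
                    ref_genes, ref_fams, config.max_intervening
                )
                arrays = dupmodes.classify_array_age(arrays, records, ref_arrays)
        elif records is None:
            logger.warning(
                "dupmodes: no ortholog records (synteny stage disabled); "
                "arrays left undated"
            )
        dupmodes.arrays_to_frame(arrays).to_csv(
            out / "tandem_arrays.tsv", sep="\t", index=False
        )
        td = dupmodes.tandem_gene_set(arrays)
        if records is not None:
            wgt = synteny.wgt_gene_set(records)
            part = dupmodes.partition_wgt_td(wgt, td, config.decimals)
            pd.DataFrame(
                [
                    {
                        "wgt_only": len(part.wgt_only),
                        "td_only": len(part.td_only),
                        "both": len(part.both),
                        "ancient_td_pct": part.ancient_td_pct,
                    }
                ]
            ).to_csv(out / "wgt_td_partition.tsv", sep="\t", index=False)
            summary = dupmodes.family_mode_summary(families, wgt, td, config.decimals)
            summary.to_csv(out / "family_mode_summary.tsv", sep="\t", index=False)
            audited = pd.read_csv(out / "wgt_td_partition.tsv", sep="\t").iloc[0]
            report += [
                "## Duplication modes",
                f"- WGT only: {audited['wgt_only']}, TD only: {audited['td_only']},"
                f" both: {audited['both']}",
                f"- ancient TD fraction: {audited['ancient_td_pct']}%",
                "",
            ]
            results["dupmodes"] = {"arrays": arrays, "partition": part}
        else:
            results["dupmodes"] = {"arrays": arrays}

    if config.run_kaks:
        if not config.pairs_fasta:
            raise StageDependencyError("kaks stage needs --pairs-fasta")
        pairs = simulate.read_pairs_fasta(config.pairs_fasta)
        table = kaks.kaks_table(pairs, neutral_band=config.neutral_band)
        table.to_csv(out / "kaks.tsv", sep="\t", index=False)
        audited = pd.read_csv(out / "kaks.tsv", sep="\t")
        defined = audited[audited["mode"] != "undefined"]
        report += [
            "## Selection pressure (NG86)",
            f"- pairs: {len(audited)} ({len(defined)} with defined Ka/Ks)",
            f"- mean Ka/Ks: {round_half_up(float(defined['ratio'].mean()), 4)}"
            if len(defined)
            else "- mean Ka/Ks: NA",
            f"- negative selection: {int((defined['mode'] == 'negative').sum())}"
            f" of {len(defined)}",
            "",
        ]
        results["kaks"] = table

    if config.run_express:
        if not config.expression_matrix:
            raise StageDependencyError("express stage needs --expression-matrix")
        matrix = expression.load_matrix(config.expression_matrix)
        matrix = expression.filter_expressed(matrix)
        dist = expression.spearman_distance(matrix)
        clust = expression.complete_linkage(dist, config.k)
        clust.labels.rename("cluster").to_frame().to_csv(
            out / "expression_clusters.tsv", sep="\t"
        )
        patterns = expression.call_patterns(matrix, clust.labels)
        patterns.to_csv(out / "expression_patterns.tsv", sep="\t")
        audited = pd.read_csv(out / "expression_clusters.tsv", sep="\t", index_col=0)
        sizes = audited["cluster"].value_counts().sort_index()
        report += [
            "## Expression clusters",
            f"- genes clustered: {len(audited)} into k={config.k} clusters",
            f"- cluster sizes: {', '.join(str(int(s)) for s in sizes)}",
            "",
        ]
        results["express"] = clust

    if config.fixture_mode:
        recount = fixtures.ancient_tandem_recount()
        totals = fixtures.duplication_mode_totals(config.decimals)
        totals.to_csv(out / "fixture_duplication_totals.tsv", sep="\t", index=False)
        report += ["## Fixture tables"]
        for sp, r in recount.items():
            report.append(
                f"- {sp}: {r['ancient_genes']} ancient tandem genes,"
                f" {r['complete_arrays']} complete arrays"
                f" ({r['genes_in_complete_arrays']} genes)"
            )
        report.append("")
        results["fixtures"] = {"recount": recount, "totals": totals}

    (out / "report.md").write_text("\n".join(report))
    results["report_path"] = out / "report.md"
    return results
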