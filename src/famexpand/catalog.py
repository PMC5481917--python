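"""Gene catalog: annotations, chromosome placement, and adjacency clusters.

Genes are carried as a pandas DataFrame with columns
``gene_id, chromosome, start, end, strand`` (GFF3 dialect: 1-based,
inclusive) plus a ``rank`` column once :func:`assign_ranks` has run.
The rank is the 0-based ordinal of a gene among *all* annotated genes on
its chromosome sorted by start — every adjacency rule downstream
(gene clusters, tandem arrays, synteny gaps) is expressed in ranks, so
it counts intervening ORFs rather than base pairs.

The cluster rule implemented by :func:`detect_gene_clusters` is the
classic R-gene convention: two or more family genes form a cluster when
each consecutive pair lies within ``max_gap`` (default 8) open reading
frames on the same chromosome, boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand"]

#: sentinel rank for genes on unanchored scaffolds
UNRANKED = np.nan


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene; ``rank`` is None for genes on unplaced scaffolds."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int | None = None


@dataclass
class GeneCluster:
    """A chromosomal run of family genes under the rank-gap rule."""

    chromosome: str
    members: list[str]
    family_scope: str = "any-family"
    families: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def load_annotation(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a gene table.

    Only ``gene`` features are consumed. Raises :class:`AnnotationError`
    with the offending line number on unparseable lines or duplicate
    gene ids. An empty file yields an empty table.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
                raise AnnotationError(f"{path}: unparseable GFF3 line {lineno}")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(f"{path}: unparseable GFF3 line {lineno}: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            ids = feat.attributes.get("ID")
            if not ids:
                raise AnnotationError(f"{path}: gene feature without ID at line {lineno}")
            if feat.start > feat.end:
                raise AnnotationError(f"{path}: start > end at line {lineno}")
            rows.append((ids[0], feat.seqid, feat.start, feat.end, feat.strand))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise AnnotationError(f"{path}: duplicate gene_id {dup!r}")
    return genes


def write_gff3(genes: pd.DataFrame, path, source: str = "famexpand") -> None:
    """Write a gene table as a gene-only GFF3 file (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{source}\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def assign_ranks(genes: pd.DataFrame, placed_chromosomes=None) -> pd.DataFrame:
    """Attach the per-chromosome ordinal rank to each gene.

    Ranks run 0..n-1 along each chromosome by ascending start (ties broken
    by end, then gene_id). Genes on chromosomes outside
    ``placed_chromosomes`` (when given) keep a missing rank: they are
    retained in the table but take no part in adjacency rules.
    """
    genes = genes.copy()
    order = genes.sort_values(["chromosome", "start", "end", "gene_id"], kind="mergesort")
    genes["rank"] = order.groupby("chromosome").cumcount().reindex(genes.index)
    if placed_chromosomes is not None:
        placed = set(placed_chromosomes)
        genes.loc[~genes["chromosome"].isin(placed), "rank"] = UNRANKED
    return genes


def load_family_assignments(path) -> pd.DataFrame:
    """Read a family-assignment TSV with columns gene_id, family[, species, ...]."""
    fam = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "family"} - set(fam.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    if fam["gene_id"].duplicated().any():
        raise AnnotationError(f"{path}: a gene may carry only one family")
    return fam


def _chain_by_rank_gap(sub: pd.DataFrame, max_gap: int) -> list[list[int]]:
    """Split rank-sorted rows of one chromosome into maximal chains."""
    chains: list[list[int]] = []
    current: list[int] = []
    prev_rank = None
    for idx, rank in zip(sub.index, sub["rank"]):
        if prev_rank is not None and rank - prev_rank <= max_gap:
            current.append(idx)
        else:
            if current:
                chains.append(current)
            current = [idx]
        prev_rank = rank
    if current:
        chains.append(current)
    return chains


def detect_gene_clusters(
    genes: pd.DataFrame,
    family_assignments: pd.DataFrame | None = None,
    max_gap: int = 8,
    pool_families: bool = True,
) -> tuple[list[GeneCluster], list[str]]:
    """Find gene clusters among family genes under the 8-ORF rule.

    ``genes`` must carry ranks computed against the *full* gene complement
    (intervening non-family ORFs count toward the gap). When
    ``family_assignments`` is given, only assigned genes are clustered;
    with ``pool_families=True`` (default, matching the superfamily-wide
    convention) genes of different families may share a cluster, otherwise
    chains are built per family.

    Returns ``(clusters, singleton_gene_ids)``; every ranked family gene
    lands in exactly one of the two.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    fam_map = None
    work = genes
    if family_assignments is not None:
        fam_map = dict(zip(family_assignments["gene_id"], family_assignments["family"]))
        work = genes[genes["gene_id"].isin(fam_map)]
    work = work.dropna(subset=["rank"]).sort_values(["chromosome", "rank"])

    clusters: list[GeneCluster] = []
    singletons: list[str] = []
    scope = "any-family" if pool_families else "same-family"
    if pool_families:
        groups = work.groupby("chromosome", sort=True)
    else:
        work = work.assign(_family=work["gene_id"].map(fam_map))
        groups = work.groupby(["chromosome", "_family"], sort=True)
    for key, sub in groups:
        chrom = key if isinstance(key, str) else key[0]
        for chain in _chain_by_rank_gap(sub, max_gap):
            ids = list(work.loc[chain, "gene_id"])
            if len(ids) >= 2:
                fams = sorted({fam_map[g] for g in ids}) if fam_map else []
                clusters.append(GeneCluster(chrom, ids, scope, fams))
            else:
                singletons.extend(ids)
    return clusters, singletons


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [f"cluster{i + 1:03d}" for i in range(len(clusters))],
            "chromosome": [c.chromosome for c in clusters],
            "n_members": [len(c) for c in clusters],
            "member_ids": [",".join(c.members) for c in clusters],
        }
    )


def chromosome_distribution(
    genes: pd.DataFrame, placed_chromosomes, decimals: int = 1
) -> dict:
    """Per-chromosome counts and the placed-on-chromosome percentage.

    The percentage is 100*placed/total, rounded half-up. A fully empty
    input is reported as 0% with a warning flag rather than an error.
    """
    from ._util import make_percentage

    placed_set = set(placed_chromosomes)
    total = len(genes)
    on_chrom = genes[genes["chromosome"].isin(placed_set)]
    counts = on_chrom.groupby("chromosome").size().to_dict()
    pct = make_percentage(len(on_chrom), total, decimals) if total else 0.0
    return {
        "total": total,
        "placed": len(on_chrom),
        "placed_pct": pct,
        "per_chromosome": counts,
        "warning": "empty input" if total == 0 else None,
    }


def family_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Count genes per (species, family); requires a ``species`` column."""
    if "species" not in assignments.columns:
        raise AnnotationError("family assignments need a 'species' column")
    return (
        assignments.groupby(["species", "family"]).size().rename("count").reset_index()
    )


def expansion_ratios(
    counts: pd.DataFrame, reference_species: str, species: str | None = None
) -> pd.DataFrame:
    """Per-family descendant/reference count ratios with trend labels.

    ``counts`` is a long table (species, family, count) as produced by
    :func:`family_counts`. Families absent from the reference get an
    undefined (NaN) ratio and the label ``undefined``. Ratios > 1 are
    ``increased``, == 1 ``identical``, < 1 ``decreased``.
    """
    known = set(counts["species"])
    if reference_species not in known:
        raise ValueError(f"unknown reference species {reference_species!r}")
    if species is not None and species not in known:
        raise ValueError(f"unknown species {species!r}")
    wide = counts.pivot_table(
        index="family", columns="species", values="count", fill_value=0, aggfunc="sum"
    )
    out = []
    targets = [species] if species else [s for s in known if s != reference_species]
    for sp in targets:
        for fam, row in wide.iterrows():
            ref_n = int(row[reference_species])
            n = int(row[sp])
            if ref_n == 0:
                ratio, label = np.nan, "undefined"
            else:
                ratio = n / ref_n
                label = "increased" if ratio > 1 else ("decreased" if ratio < 1 else "identical")
            out.append((sp, fam, n, ref_n, ratio, label))
    return pd.DataFrame(
        out, columns=["species", "family", "count", "reference_count", "ratio", "trend"]
    )
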