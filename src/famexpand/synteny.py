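"""Collinear anchor chaining, subgenome assignment, ortholog retention.

Homology anchors (reference gene, target gene, similarity score,
e-value-like significance) are filtered, then chained per chromosome pair
into synteny blocks: maximal chains of anchors whose reference ranks are
strictly increasing and whose target ranks are strictly monotone
(increasing = same orientation, decreasing = inverted), with the rank gap
between consecutive anchors bounded on both genomes. Chains are extracted
greedily by dynamic programming (largest chain first, anchors removed
between rounds); chains shorter than ``min_anchors`` are discarded.

Blocks are labeled with the subgenome (LF / MF1 / MF2) whose map interval
contains the majority of their anchors, and family genes inside labeled
blocks populate per-reference-gene ortholog records whose copy class
(0-3) counts the subgenomes that retained a syntenic copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SUBGENOMES

logger = logging.getLogger(__name__)


@dataclass
class SyntenyBlock:
    ref_chromosome: str
    target_chromosome: str
    anchors: pd.DataFrame  # rows ordered by ref rank
    orientation: str  # "same" | "inverted"
    subgenome: str | None = None
    ambiguous_subgenome: bool = False

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class OrthologRecord:
    ref_gene: str
    copies: dict = field(default_factory=dict)  # subgenome -> gene_id

    @property
    def copy_class(self) -> int:
        return len(self.copies)


def load_anchors(path) -> pd.DataFrame:
    anchors = pd.read_csv(path, sep="\t")
    needed = {"ref_gene", "target_gene", "score", "significance"}
    missing = needed - set(anchors.columns)
    if missing:
        raise ValueError(f"{path}: anchor table missing columns {sorted(missing)}")
    return anchors


def load_subgenome_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    missing = {"chromosome", "start", "end", "subgenome"} - set(m.columns)
    if missing:
        raise ValueError(f"{path}: subgenome map missing columns {sorted(missing)}")
    return m


def filter_anchors(
    anchors: pd.DataFrame,
    target_genes: pd.DataFrame | None = None,
    max_significance: float = 1e-20,
    unique_per_chromosome: bool = True,
) -> pd.DataFrame:
    """Significance filter plus optional per-(ref, target chromosome) uniqueness.

    With ``unique_per_chromosome`` (the u=1 convention) only the
    best-scoring anchor of each reference gene per target chromosome is
    kept (ties broken by gene id for determinism). Passing
    ``target_genes`` attaches target chromosomes; without it the
    uniqueness rule needs a ``target_chromosome`` column already present.
    """
    out = anchors[anchors["significance"] <= max_significance].copy()
    if target_genes is not None:
        chrom = dict(zip(target_genes["gene_id"], target_genes["chromosome"]))
        out["target_chromosome"] = out["target_gene"].map(chrom)
        out = out.dropna(subset=["target_chromosome"])
    if unique_per_chromosome and len(out):
        if "target_chromosome" not in out.columns:
            raise ValueError("uniqueness filter needs target chromosomes")
        out = (
            out.sort_values(
                ["ref_gene", "target_chromosome", "score", "target_gene"],
                ascending=[True, True, False, True],
            )
            .groupby(["ref_gene", "target_chromosome"], as_index=False)
            .head(1)
        )
    return out.reset_index(drop=True)


def _best_chain(
    ref_ranks: np.ndarray, tgt_ranks: np.ndarray, direction: int, max_rank_gap: int
) -> list[int]:
    """Longest chain (anchor indices) monotone in both genomes with bounded gaps.

    Anchors must be pre-sorted by (ref rank, target rank). ``direction``
    is +1 for same-orientation chains, -1 for inverted. O(n^2) dynamic
    program; ties prefer the earliest predecessor, so extraction is
    deterministic.
    """
    n = len(ref_ranks)
    if n == 0:
        return []
    best = np.ones(n, dtype=int)
    prev = np.full(n, -1, dtype=int)
    for j in range(1, n):
        dr = ref_ranks[j] - ref_ranks[:j]
        dt = direction * (tgt_ranks[j] - tgt_ranks[:j])
        ok = (dr > 0) & (dr <= max_rank_gap) & (dt > 0) & (dt <= max_rank_gap)
        if ok.any():
            cand = np.where(ok, best[:j], 0)
            i = int(np.argmax(cand))  # first maximum -> earliest predecessor
            if cand[i] + 1 > best[j]:
                best[j] = cand[i] + 1
                prev[j] = i
    end = int(np.argmax(best))  # first maximum -> deterministic
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_synteny_blocks(
    anchors: pd.DataFrame,
    ref_genes: pd.DataFrame,
    target_genes: pd.DataFrame,
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain filtered anchors into synteny blocks per chromosome pair.

    ``ref_genes`` / ``target_genes`` must carry ranks (see
    :func:`famexpand.catalog.assign_ranks`). For each chromosome pair,
    the largest valid chain (same or inverted orientation, whichever is
    longer; same wins ties) is extracted, its anchors removed, and the
    search repeated until no chain reaches ``min_anchors``.
    """
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    ref_rank = dict(zip(ref_genes["gene_id"], ref_genes["rank"]))
    ref_chrom = dict(zip(ref_genes["gene_id"], ref_genes["chromosome"]))
    tgt_rank = dict(zip(target_genes["gene_id"], target_genes["rank"]))
    tgt_chrom = dict(zip(target_genes["gene_id"], target_genes["chromosome"]))

    work = anchors.copy()
    work["ref_rank"] = work["ref_gene"].map(ref_rank)
    work["ref_chromosome"] = work["ref_gene"].map(ref_chrom)
    work["target_rank"] = work["target_gene"].map(tgt_rank)
    work["target_chromosome"] = work["target_gene"].map(tgt_chrom)
    dropped = work[["ref_rank", "target_rank"]].isna().any(axis=1)
    if dropped.any():
        logger.warning("dropping %d anchors without ranks", int(dropped.sum()))
        work = work[~dropped]

    blocks: list[SyntenyBlock] = []
    for (rchrom, tchrom), sub in work.groupby(
        ["ref_chromosome", "target_chromosome"], sort=True
    ):
        sub = sub.sort_values(
            ["ref_rank", "target_rank", "ref_gene", "target_gene"]
        ).reset_index(drop=True)
        while len(sub) >= min_anchors:
            rr = sub["ref_rank"].to_numpy()
            tr = sub["target_rank"].to_numpy()
            fwd = _best_chain(rr, tr, +1, max_rank_gap)
            rev = _best_chain(rr, tr, -1, max_rank_gap)
            chain, orientation = (
                (fwd, "same") if len(fwd) >= len(rev) else (rev, "inverted")
            )
            if len(chain) < min_anchors:
                break
            rows = sub.iloc[chain].reset_index(drop=True)
            blocks.append(SyntenyBlock(rchrom, tchrom, rows, orientation))
            sub = sub.drop(sub.index[chain]).reset_index(drop=True)
    return blocks


def assign_subgenomes(
    blocks: list[SyntenyBlock],
    subgenome_map: pd.DataFrame,
    target_genes: pd.DataFrame,
) -> list[SyntenyBlock]:
    """Label each block with the subgenome holding the majority of its anchors.

    A tie flags the block ambiguous; blocks entirely outside the map stay
    unlabeled with a warning.
    """
    starts = dict(zip(target_genes["gene_id"], target_genes["start"]))
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for row in subgenome_map.itertuples(index=False):
        intervals.setdefault(row.chromosome, []).append(
            (row.start, row.end, row.subgenome)
        )
    for block in blocks:
        votes: dict[str, int] = {}
        chrom_intervals = intervals.get(block.target_chromosome, [])
        for g in block.anchors["target_gene"]:
            pos = starts.get(g)
            if pos is None:
                continue
            for lo, hi, sg in chrom_intervals:
                if lo <= pos <= hi:
                    votes[sg] = votes.get(sg, 0) + 1
        if not votes:
            logger.warning(
                "block %s~%s lies outside the subgenome map",
                block.ref_chromosome, block.target_chromosome,
            )
            block.subgenome = None
            continue
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        block.subgenome = ranked[0][0]
        block.ambiguous_subgenome = (
            len(ranked) > 1 and ranked[0][1] == ranked[1][1]
        )
    return blocks


def build_ortholog_records(
    blocks: list[SyntenyBlock],
    family_genes,
    species: str = "descendant",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Populate per-reference-gene subgenome slots from labeled blocks.

    ``family_genes`` is the set of reference gene ids under study (the
    gene family); only anchors whose reference gene belongs to it
    contribute. Best score wins a slot; a descendant gene claimed by two
    reference genes goes to the higher-scoring one (then lexicographic
    gene id), with the conflict logged.

    Returns ``(records, summary)``: records have columns
    ``ref_gene, LF, MF1, MF2, copy_class``; the summary counts records per
    copy class and totals retained descendant copies (sum of classes).
    """
    if any(b.subgenome is None for b in blocks):
        raise ValueError(
            "all blocks must carry subgenome labels; run assign_subgenomes "
            "with a covering map first"
        )
    family = set(family_genes)
    candidates = []
    for block in blocks:
        sub = block.anchors[block.anchors["ref_gene"].isin(family)]
        for row in sub.itertuples(index=False):
            candidates.append(
                (row.ref_gene, block.subgenome, row.target_gene, row.score)
            )
    cand = pd.DataFrame(
        candidates, columns=["ref_gene", "subgenome", "target_gene", "score"]
    )
    # one descendant gene may serve only one reference gene: best score wins
    if len(cand):
        cand = (
            cand.sort_values(
                ["target_gene", "score", "ref_gene"], ascending=[True, False, True]
            )
            .groupby("target_gene", as_index=False)
            .head(1)
        )
        n_conflicts = len(candidates) - len(cand)
        if n_conflicts:
            logger.info("resolved %d descendant-gene conflicts by score", n_conflicts)
        # best score per (ref gene, subgenome) slot
        cand = (
            cand.sort_values(
                ["ref_gene", "subgenome", "score", "target_gene"],
                ascending=[True, True, False, True],
            )
            .groupby(["ref_gene", "subgenome"], as_index=False)
            .head(1)
        )

    slot_of: dict[tuple[str, str], str] = {}
    if len(cand):
        for row in cand.itertuples(index=False):
            slot_of[(row.ref_gene, row.subgenome)] = row.target_gene
    records = []
    for ref_gene in sorted(family):
        slots = {sg: slot_of.get((ref_gene, sg)) for sg in SUBGENOMES}
        copy_class = sum(v is not None for v in slots.values())
        records.append((ref_gene, slots["LF"], slots["MF1"], slots["MF2"], copy_class))
    records_df = pd.DataFrame(
        records, columns=["ref_gene", "LF", "MF1", "MF2", "copy_class"]
    )
    records_df.insert(0, "species", species)

    counts = records_df["copy_class"].value_counts().to_dict()
    summary = pd.DataFrame(
        {
            "copy_class": [0, 1, 2, 3],
            "n_ref_genes": [counts.get(k, 0) for k in (0, 1, 2, 3)],
        }
    )
    summary["descendant_copies"] = summary["copy_class"] * summary["n_ref_genes"]
    return records_df, summary


def wgt_gene_set(records: pd.DataFrame) -> set:
    """All descendant genes occupying a subgenome slot (WGT-derived genes)."""
    out: set = set()
    for sg in SUBGENOMES:
        out.update(records[sg].dropna())
    return out
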