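"""Tandem arrays, duplication-mode partition, and tandem-array dating.

A tandem array is a maximal run of same-family genes on one chromosome
with at most ``max_intervening`` non-family genes between consecutive
members (ranks computed over the full annotation). Crossing the tandem
gene set with the set of whole-genome-triplication (WGT) derived genes
from the ortholog records partitions duplicated genes into WGT-only,
TD-only, and both; the intersection is the *ancient* tandem fraction —
genes that sit in syntenic (co-retained) regions *and* in a tandem array,
hence duplicated before the reference/descendant split.

An array is *ancient-complete* when at least two of its members are
WGT-derived and their reference partners themselves form a tandem array
in the reference genome; ancient members without such reference-side
support belong to incomplete arrays. Arrays with no WGT-derived member
are lineage-specific; arrays mixing ancient and lineage-specific members
are ``mixed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import make_percentage
from .catalog import detect_gene_clusters


@dataclass
class TandemArray:
    chromosome: str
    members: list[str]  # ordered by rank
    family: str
    max_intervening: int = 1
    completeness: str | None = None  # complete | incomplete
    age: str | None = None  # ancient | lineage_specific | mixed

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DuplicationPartition:
    wgt_only: set
    td_only: set
    both: set
    ancient_td_pct: float

    def __post_init__(self):
        assert not (self.wgt_only & self.td_only)
        assert not (self.wgt_only & self.both)
        assert not (self.td_only & self.both)

    @property
    def wgt_total(self) -> int:
        return len(self.wgt_only) + len(self.both)

    @property
    def td_total(self) -> int:
        return len(self.td_only) + len(self.both)


def detect_tandem_arrays(
    genes: pd.DataFrame,
    family_assignments: pd.DataFrame,
    max_intervening: int = 1,
) -> list[TandemArray]:
    """Maximal same-family runs with <= max_intervening intervening genes.

    Equivalent to per-family rank chaining with gap ``max_intervening + 1``
    over ranks assigned against the full annotation. Genes without a rank
    (unplaced scaffolds) never join arrays.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    clusters, _ = detect_gene_clusters(
        genes,
        family_assignments,
        max_gap=max_intervening + 1,
        pool_families=False,
    )
    fam_map = dict(zip(family_assignments["gene_id"], family_assignments["family"]))
    return [
        TandemArray(c.chromosome, c.members, fam_map[c.members[0]], max_intervening)
        for c in clusters
    ]


def load_tandem_arrays(path) -> list[TandemArray]:
    """Load a precomputed tandem-array TSV (chromosome, family, member_ids)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chromosome", "family", "member_ids"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: tandem table missing columns {sorted(missing)}")
    return [
        TandemArray(r.chromosome, r.member_ids.split(","), r.family)
        for r in df.itertuples(index=False)
    ]


def arrays_to_frame(arrays: list[TandemArray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "array_id": [f"array{i + 1:03d}" for i in range(len(arrays))],
            "chromosome": [a.chromosome for a in arrays],
            "family": [a.family for a in arrays],
            "n_members": [len(a) for a in arrays],
            "member_ids": [",".join(a.members) for a in arrays],
            "completeness": [a.completeness for a in arrays],
            "age": [a.age for a in arrays],
        }
    )


def tandem_gene_set(arrays: list[TandemArray]) -> set:
    out: set = set()
    for a in arrays:
        out.update(a.members)
    return out


def partition_wgt_td(wgt_genes, td_genes, decimals: int = 2) -> DuplicationPartition:
    """Disjoint WGT-only / TD-only / both sets plus the ancient-TD percentage.

    The percentage reported is |both| / |TD| * 100: the fraction of
    tandem-duplicated genes that are also syntenically retained, i.e.
    ancient.
    """
    wgt = set(wgt_genes)
    td = set(td_genes)
    both = wgt & td
    pct = make_percentage(len(both), len(td), decimals) if td else 0.0
    return DuplicationPartition(wgt - td, td - wgt, both, pct)


def classify_array_age(
    arrays: list[TandemArray],
    ortholog_records: pd.DataFrame,
    reference_arrays: list[TandemArray],
) -> list[TandemArray]:
    """Date descendant tandem arrays against the ortholog records.

    A member is *ancient* iff it occupies a subgenome slot in the ortholog
    records (it is WGT-derived, so it predates the split). Array age is
    ``ancient`` when all members are ancient, ``lineage_specific`` when
    none is, ``mixed`` otherwise. Completeness is ``complete`` when at
    least two ancient members have reference partners lying in one
    reference tandem array.
    """
    ref_of: dict[str, str] = {}
    for row in ortholog_records.itertuples(index=False):
        for sg in ("LF", "MF1", "MF2"):
            g = getattr(row, sg)
            if pd.notna(g) and g is not None:
                if g in ref_of and ref_of[g] != row.ref_gene:
                    raise ValueError(
                        f"descendant gene {g} claimed by two ortholog records"
                    )
                ref_of[g] = row.ref_gene

    ref_array_of: dict[str, int] = {}
    for i, arr in enumerate(reference_arrays):
        for g in arr.members:
            ref_array_of[g] = i

    for arr in arrays:
        ancient = [m for m in arr.members if m in ref_of]
        if not ancient:
            arr.age = "lineage_specific"
            arr.completeness = None
            continue
        arr.age = "ancient" if len(ancient) == len(arr.members) else "mixed"
        counts: dict[int, int] = {}
        for m in ancient:
            ra = ref_array_of.get(ref_of[m])
            if ra is not None:
                counts[ra] = counts.get(ra, 0) + 1
        arr.completeness = (
            "complete" if counts and max(counts.values()) >= 2 else "incomplete"
        )
    return arrays


@dataclass
class AgeRecovery:
    """Member-level scoring of ancient vs lineage-specific calls vs truth."""

    precision_ancient: float
    recall_ancient: float
    precision_lineage: float
    recall_lineage: float
    n_members: int
    n_excluded: int  # members of degraded planted arrays (age undecidable)


def score_age_recovery(
    arrays: list[TandemArray],
    ortholog_records: pd.DataFrame,
    truth_origin: dict,
    excluded_genes=frozenset(),
) -> AgeRecovery:
    """Compare per-member age calls with the simulator's planted origins.

    Each detected array member is called ancient when it holds an ortholog
    slot, lineage-specific otherwise; the truth label is ancient for
    retained WGT copies (`origin == "wgt"`) and lineage-specific for
    post-split tandem copies. ``excluded_genes`` (e.g. members of planted
    arrays degraded by whole-array loss) are counted but not scored.
    """
    from .synteny import wgt_gene_set

    wgt = wgt_gene_set(ortholog_records)
    tp_a = fp_a = fn_a = tp_l = fp_l = fn_l = 0
    n = excluded = 0
    for arr in arrays:
        for m in arr.members:
            if m in excluded_genes:
                excluded += 1
                continue
            n += 1
            called_ancient = m in wgt
            truly_ancient = truth_origin[m] == "wgt"
            if called_ancient and truly_ancient:
                tp_a += 1
            elif called_ancient:
                fp_a += 1
            elif truly_ancient:
                fn_a += 1
            if (not called_ancient) and (not truly_ancient):
                tp_l += 1
            elif not called_ancient:
                fp_l += 1
            elif not truly_ancient:
                fn_l += 1

    def _safe(num, den):
        return num / den if den else 1.0

    return AgeRecovery(
        precision_ancient=_safe(tp_a, tp_a + fp_a),
        recall_ancient=_safe(tp_a, tp_a + fn_a),
        precision_lineage=_safe(tp_l, tp_l + fp_l),
        recall_lineage=_safe(tp_l, tp_l + fn_l),
        n_members=n,
        n_excluded=excluded,
    )


def family_mode_summary(
    family_assignments: pd.DataFrame,
    wgt_genes,
    td_genes,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-family totals with WGT-derived and TD-derived counts.

    The two mode columns are *not* disjoint (a gene can descend from both
    events); the totals row carries percentages of the species total.
    """
    wgt = set(wgt_genes)
    td = set(td_genes)
    rows = []
    for fam, sub in family_assignments.groupby("family", sort=True):
        ids = set(sub["gene_id"])
        rows.append((fam, len(ids), len(ids & wgt), len(ids & td)))
    out = pd.DataFrame(rows, columns=["family", "total", "wgt", "td"])
    total, wtot, ttot = out["total"].sum(), out["wgt"].sum(), out["td"].sum()
    summary = pd.concat(
        [out, pd.DataFrame([("Total", total, wtot, ttot)], columns=out.columns)],
        ignore_index=True,
    )
    summary["wgt_pct"] = [
        make_percentage(w, total, decimals) if total else 0.0 for w in summary["wgt"]
    ]
    summary["td_pct"] = [
        make_percentage(t, total, decimals) if total else 0.0 for t in summary["td"]
    ]
    return summary
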