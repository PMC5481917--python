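"""Packaged worked-example tables and their recounting logic.

Three small TSVs ship with the package, transcribed from the printed
summary tables of the motivating UGT superfamily study:

* ``ugt_family_counts.tsv`` — per-family gene counts in A. thaliana,
  B. rapa and B. oleracea (with the two species-specific singleton
  clusters),
* ``ugt_ancient_tandem_arrays.tsv`` — ancient tandem arrays: reference
  (A. thaliana) genes against their retained copies in the six
  descendant subgenome slots (BraLF..BolMF2, NA = not retained),
* ``ugt_duplication_modes.tsv`` — per-family totals with WGT-derived and
  TD-derived counts per species.

`fixture mode` recomputes the headline counts from these tables alone:
distinct ancient tandem genes per species, complete ancient arrays,
expansion trends, and the duplication-mode percentages.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from ._util import make_percentage

BRA_SLOTS = ["BraLF", "BraMF1", "BraMF2"]
BOL_SLOTS = ["BolLF", "BolMF1", "BolMF2"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("famexpand.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_family_counts() -> pd.DataFrame:
    """Per-family gene counts (columns family, subgroup, one per species)."""
    return _load("ugt_family_counts.tsv")


def load_ancient_tandem_arrays() -> pd.DataFrame:
    """Ancient tandem arrays: reference genes x six subgenome slots (NA kept)."""
    return _load("ugt_ancient_tandem_arrays.tsv")


def load_duplication_modes() -> pd.DataFrame:
    """Per-family WGT/TD-derived counts for the three species."""
    return _load("ugt_duplication_modes.tsv")


def _gene_number(gene_id: str) -> int:
    m = re.search(r"(\d+)$", gene_id)
    if not m:
        raise ValueError(f"gene id {gene_id!r} carries no numeric suffix")
    return int(m.group(1))


def _complete_arrays(table: pd.DataFrame, slots: list[str], max_id_gap: int) -> list[list[str]]:
    """Group one species' ancient genes into complete arrays.

    Within each (family, subgenome slot), non-NA descendant genes are
    sorted by their numeric id (descendant database ids run sequentially
    along chromosomes) and chained while consecutive ids differ by at most
    ``max_id_gap`` — the id-space analogue of allowing one intervening
    gene. Chains of >= 2 genes are complete arrays.
    """
    arrays: list[list[str]] = []
    for (_, _), genes in _iter_slot_genes(table, slots):
        genes = sorted(genes, key=_gene_number)
        run = [genes[0]]
        for g in genes[1:]:
            if _gene_number(g) - _gene_number(run[-1]) <= max_id_gap:
                run.append(g)
            else:
                if len(run) >= 2:
                    arrays.append(run)
                run = [g]
        if len(run) >= 2:
            arrays.append(run)
    return arrays


def _iter_slot_genes(table: pd.DataFrame, slots: list[str]):
    for fam, sub in table.groupby("family", sort=True):
        for slot in slots:
            genes = [g for g in sub[slot] if pd.notna(g) and g != "NA"]
            if genes:
                yield (fam, slot), genes


def ancient_tandem_recount(max_id_gap: int = 2) -> dict:
    """Recount the ancient-tandem-array table.

    Returns distinct ancient tandem gene counts and complete-array counts
    per species, plus the arrays themselves.
    """
    table = load_ancient_tandem_arrays()
    out = {}
    for species, slots in (("B_rapa", BRA_SLOTS), ("B_oleracea", BOL_SLOTS)):
        genes = {
            g
            for slot in slots
            for g in table[slot]
            if pd.notna(g) and g != "NA"
        }
        arrays = _complete_arrays(table, slots, max_id_gap)
        out[species] = {
            "ancient_genes": len(genes),
            "complete_arrays": len(arrays),
            "genes_in_complete_arrays": sum(len(a) for a in arrays),
            "arrays": arrays,
        }
    return out


def expansion_trend_summary(reference: str = "A_thaliana") -> pd.DataFrame:
    """Expansion trends (increased/identical/decreased) from the count table.

    Species-specific singleton clusters (zero reference count) yield
    undefined ratios and are excluded from the trend tally, mirroring the
    family-level comparison.
    """
    from .catalog import expansion_ratios

    counts = load_family_counts()
    long = counts.melt(
        id_vars=["family", "subgroup"],
        var_name="species",
        value_name="count",
    )
    ratios = expansion_ratios(long.rename(columns={"count": "count"}), reference)
    tally = (
        ratios[ratios["trend"] != "undefined"]
        .groupby(["species", "trend"])
        .size()
        .rename("n_families")
        .reset_index()
    )
    return tally


def duplication_mode_totals(decimals: int = 2) -> pd.DataFrame:
    """Species totals (gene count, WGT and TD counts and percentages)."""
    modes = load_duplication_modes()
    rows = []
    for sp in ("At", "Bra", "Bol"):
        total = int(modes[f"{sp}_total"].sum())
        wgt = int(modes[f"{sp}_wgt"].sum())
        td = int(modes[f"{sp}_td"].sum())
        rows.append(
            (
                sp,
                total,
                wgt,
                make_percentage(wgt, total, decimals),
                td,
                make_percentage(td, total, decimals),
            )
        )
    return pd.DataFrame(
        rows, columns=["species", "total", "wgt", "wgt_pct", "td", "td_pct"]
    )
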