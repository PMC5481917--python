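"""Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

The NG86 counting method estimates the number of synonymous (S) and
nonsynonymous (N) *sites* per sequence by asking, for every codon
position, what fraction of the three possible point mutations preserves
the encoded amino acid; *differences* between two codons that disagree at
k positions are averaged over all k! mutational pathways. Proportions
ps = Sd/S and pn = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3), giving Ks and Ka. The
ratio omega = Ka/Ks measures selection: < 1 purifying (negative), > 1
positive, ~ 1 neutral.

Stop codons follow the standard NG86 convention: mutations that create a
stop codon are excluded from the site denominators, and mutational
pathways passing through a stop are dropped (the remaining pathways are
re-weighted). Internal stop codons in the input are an error.

Lineage-level statistics (Mann-Whitney U, 2x2 chi-square) are thin,
explicitly-contracted wrappers over scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

BASES = "ACGT"
STOP_CODONS = set(standard_dna_table.stop_codons)
_TABLE = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Amino acid for a codon, or '*' for a stop."""
    return "*" if codon in STOP_CODONS else _TABLE[codon]


class CodonSequenceError(ValueError):
    """Invalid codon sequence (length, alphabet, or internal stop)."""


def _codons(seq: str, name: str = "sequence") -> list[str]:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise CodonSequenceError(f"{name}: length {len(seq)} is not a multiple of 3")
    if set(seq) - set(BASES):
        raise CodonSequenceError(f"{name}: alphabet must be A/C/G/T")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise CodonSequenceError(f"{name}: internal stop codon {c} at codon {i}")
    return codons


def _site_fractions() -> dict[str, tuple[float, float]]:
    """Per-codon (syn_sites, nonsyn_sites) with stop mutations excluded.

    Each of the 3 positions carries weight 1 split over its 3 possible
    mutations; mutations to stop codons contribute to neither class, so a
    codon's S + N can be less than 3.
    """
    out = {}
    for codon, aa in _TABLE.items():
        s = n = 0.0
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                if translate_codon(mutant) == aa:
                    s += 1 / 3
                else:
                    n += 1 / 3
        out[codon] = (s, n)
    return out


_SITES = _site_fractions()


@dataclass(frozen=True)
class CodonAlignmentPair:
    """A gap-stripped, codon-aligned sequence pair."""

    pair_id: str
    seq_a: str
    seq_b: str
    lineage_tag: str = ""

    def __post_init__(self):
        a = _codons(self.seq_a, f"{self.pair_id}/a")
        b = _codons(self.seq_b, f"{self.pair_id}/b")
        if len(a) != len(b):
            raise CodonSequenceError(f"{self.pair_id}: unequal lengths")
        if not a:
            raise CodonSequenceError(f"{self.pair_id}: empty alignment")


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float
    mode: str
    reason: str = ""
    skipped_codons: int = 0
    lineage_tag: str = ""


def ng86_sites(seq: str) -> tuple[float, float]:
    """(S, N) fractional site counts for one sequence.

    An empty sequence returns (0, 0).
    """
    if seq == "":
        return 0.0, 0.0
    codons = _codons(seq)
    s = sum(_SITES[c][0] for c in codons)
    n = sum(_SITES[c][1] for c in codons)
    return s, n


def _codon_pathways(ca: str, cb: str) -> tuple[float, float, bool]:
    """Pathway-averaged (syn, nonsyn) differences for one codon pair.

    Averages over all orderings of the differing positions, dropping
    pathways that pass through a stop codon and renormalizing over the
    survivors. Returns ``(sd, nd, skipped)`` where ``skipped`` is True
    when every pathway hits a stop (the codon is then excluded).
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0, False
    syn_total = nonsyn_total = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        cur = ca
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        return 0.0, 0.0, True
    return syn_total / n_valid, nonsyn_total / n_valid, False


def ng86_differences(pair: CodonAlignmentPair) -> tuple[float, float, int]:
    """Pathway-averaged (Sd, Nd, skipped_codons) for an aligned pair.

    Sd + Nd equals the raw count of differing nucleotide positions, up to
    codons skipped because every pathway runs through a stop.
    """
    a = _codons(pair.seq_a, f"{pair.pair_id}/a")
    b = _codons(pair.seq_b, f"{pair.pair_id}/b")
    if len(a) != len(b):
        raise CodonSequenceError(f"{pair.pair_id}: unequal lengths")
    sd = nd = 0.0
    skipped = 0
    for ca, cb in zip(a, b):
        s, n, skip = _codon_pathways(ca, cb)
        if skip:
            skipped += 1
        sd += s
        nd += n
    return sd, nd, skipped


def jukes_cantor(p: float) -> float:
    """JC69 distance -(3/4) ln(1 - 4p/3); NaN at or beyond saturation p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks(
    pair: CodonAlignmentPair, neutral_band: float = 0.05
) -> KaKsResult:
    """Full NG86 Ka/Ks for one pair, with selection-mode classification.

    Sites are averaged over the two sequences. ``mode`` is ``negative``
    when ratio < 1 - neutral_band, ``positive`` when > 1 + neutral_band,
    ``neutral`` within the band, and ``undefined`` (with a reason code)
    when Ks = 0 or either proportion is saturated (p >= 3/4).
    """
    sa, na = ng86_sites(pair.seq_a)
    sb, nb = ng86_sites(pair.seq_b)
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    sd, nd, skipped = ng86_differences(pair)
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)

    ratio = float("nan")
    mode, reason = "undefined", ""
    if math.isnan(ks) or math.isnan(ka):
        reason = "saturated"
    elif ks == 0.0:
        reason = "Ks=0 (identical synonymous sites)" if ka > 0 else "Ks=0 and Ka=0"
    else:
        ratio = ka / ks
        if ratio > 1.0 + neutral_band:
            mode = "positive"
        elif ratio < 1.0 - neutral_band:
            mode = "negative"
        else:
            mode = "neutral"
    return KaKsResult(
        pair_id=pair.pair_id,
        S=s_sites,
        N=n_sites,
        Sd=sd,
        Nd=nd,
        ps=ps,
        pn=pn,
        Ks=ks,
        Ka=ka,
        ratio=ratio,
        mode=mode,
        reason=reason,
        skipped_codons=skipped,
        lineage_tag=pair.lineage_tag,
    )


def kaks_table(pairs, neutral_band: float = 0.05):
    """Run :func:`kaks` over an iterable of pairs; returns a DataFrame."""
    import pandas as pd

    rows = [kaks(p, neutral_band) for p in pairs]
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class LineageComparison:
    mean_x: float
    mean_y: float
    U: float
    p_value: float
    method: str


def mann_whitney(x, y) -> LineageComparison:
    """Two-sided Mann-Whitney U comparison of two ratio samples.

    Uses exact enumeration when the combined sample size is <= 12 and
    there are no ties; otherwise the normal approximation with tie and
    continuity correction. Two identical samples are reported as p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= 12 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        method = "normal-approximation"
        if np.ptp(pooled) == 0:  # zero variance: no evidence of any difference
            return LineageComparison(float(x.mean()), float(y.mean()),
                                     x.size * y.size / 2.0, 1.0, method)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(min(res.pvalue, 1.0))
    return LineageComparison(float(x.mean()), float(y.mean()), float(res.statistic), p, method)


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False):
    """Pearson chi-square (df=1) for the 2x2 table [[a, b], [c, d]].

    No continuity correction by default; set ``yates=True`` for Yates.
    Zero margins are an error.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)
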