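"""NG86 site/difference counting, JC correction, and lineage statistics."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famexpand import kaks, simulate
from famexpand.kaks import (
    CodonAlignmentPair,
    CodonSequenceError,
    chi_square_2x2,
    jukes_cantor,
    mann_whitney,
    ng86_differences,
    ng86_sites,
    translate_codon,
)


class TestSites:
    def test_phenylalanine_codon_hand_count(self):
        # TTT: only TTT->TTC is synonymous; no mutation reaches a stop
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_empty_sequence(self):
        assert ng86_sites("") == (0.0, 0.0)

    def test_concatenation_is_additive(self):
        s1, n1 = ng86_sites("TTT")
        s2, n2 = ng86_sites("TTTTTT")
        assert s2 == pytest.approx(2 * s1)
        assert n2 == pytest.approx(2 * n1)

    def test_stop_mutations_excluded_from_both_classes(self):
        # TGG (Trp): TGA and TAG (stops) reachable -> total sites < 3
        s, n = ng86_sites("TGG")
        assert s == 0.0
        assert s + n < 3.0

    def test_internal_stop_rejected(self):
        with pytest.raises(CodonSequenceError, match="codon 1"):
            CodonAlignmentPair("p", "AAATAAAAA", "AAATAAAAA")


def _brute_force_pathways(ca, cb):
    """Independent pathway enumeration for one codon pair."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    totals, n_valid = [0.0, 0.0], 0
    for order in permutations(diff):
        cur, syn, nonsyn, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in kaks.STOP_CODONS:
                ok = False
                break
            syn += translate_codon(cur) == translate_codon(nxt)
            nonsyn += translate_codon(cur) != translate_codon(nxt)
            cur = nxt
        if ok:
            totals[0] += syn
            totals[1] += nonsyn
            n_valid += 1
    return (totals[0] / n_valid, totals[1] / n_valid) if n_valid else (0.0, 0.0)


class TestDifferences:
    def test_identical_pair_is_zero(self):
        p = CodonAlignmentPair("p", "AAACCC", "AAACCC")
        assert ng86_differences(p) == (0.0, 0.0, 0)

    def test_single_synonymous_change(self):
        p = CodonAlignmentPair("p", "AAA", "AAG")  # Lys -> Lys
        assert ng86_differences(p) == (1.0, 0.0, 0)

    def test_two_difference_codon_matches_enumeration(self):
        # TTT -> GTA: pathways via GTT (Phe->Val->Val: 1 syn) and TTA
        # (Phe->Leu->Val: 0 syn), average (0.5, 1.5)
        p = CodonAlignmentPair("p", "TTT", "GTA")
        sd, nd, skipped = ng86_differences(p)
        assert (sd, nd) == _brute_force_pathways("TTT", "GTA")
        assert (sd, nd) == (0.5, 1.5) and skipped == 0

    def test_random_codon_pairs_match_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        sense = simulate._SENSE_CODONS
        for _ in range(300):
            ca, cb = (sense[i] for i in rng.integers(0, len(sense), 2))
            p = CodonAlignmentPair("p", ca, cb)
            sd, nd, skipped = ng86_differences(p)
            exp = _brute_force_pathways(ca, cb)
            assert (sd, nd) == pytest.approx(exp)
            if not skipped:
                n_diff = sum(a != b for a, b in zip(ca, cb))
                assert sd + nd == pytest.approx(n_diff)


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        r = kaks.kaks(CodonAlignmentPair("p", "AAACCC", "AAACCC"))
        assert r.Ks == 0.0 and r.Ka == 0.0
        assert math.isnan(r.ratio) and r.mode == "undefined"

    def test_jc_closed_form(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6))
        assert math.isnan(jukes_cantor(0.75))

    def test_symmetry_in_every_field(self):
        cfg = simulate.SimulationConfig(seed=31, codon_length=60, ks_target=0.4,
                                        omega_values=(0.7,))
        pairs, _ = simulate.evolve_codon_pairs(10, cfg)
        for p in pairs:
            fwd = kaks.kaks(p)
            rev = kaks.kaks(CodonAlignmentPair(p.pair_id, p.seq_b, p.seq_a))
            for f in ("S", "N", "Sd", "Nd", "Ks", "Ka"):
                assert getattr(fwd, f) == pytest.approx(getattr(rev, f)), f
            assert fwd.mode == rev.mode

    def test_mean_ratio_monotone_in_omega(self):
        means = []
        for om in (0.1, 0.5, 1.0):
            cfg = simulate.SimulationConfig(
                seed=32, codon_length=300, ks_target=0.3, omega_values=(om,)
            )
            pairs, _ = simulate.evolve_codon_pairs(30, cfg)
            t = kaks.kaks_table(pairs)
            means.append(t[t["mode"] != "undefined"]["ratio"].mean())
        assert means[0] < means[1] < means[2]

    def test_agreement_with_independent_ng86_implementation(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        cfg = simulate.SimulationConfig(seed=33, codon_length=150, ks_target=0.25,
                                        omega_values=(0.4,))
        pairs, _ = simulate.evolve_codon_pairs(8, cfg)
        for p in pairs:
            ours = kaks.kaks(p)
            dn, ds = cal_dn_ds(CodonSeq(p.seq_a), CodonSeq(p.seq_b), method="NG86")
            # conventions differ only in stop-codon handling (site
            # denominators and pathway exclusion), so agreement is close
            # but not exact
            assert ours.Ks == pytest.approx(ds, rel=0.05)
            assert ours.Ka == pytest.approx(dn, rel=0.12)


_sense = simulate._SENSE_CODONS


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.sampled_from(_sense), st.sampled_from(_sense)),
        min_size=1,
        max_size=15,
    )
)
def test_pathway_averaging_conserves_totals_and_is_symmetric(codon_pairs):
    """Sd + Nd equals the raw differing-position count (up to skipped codons),
    and every NG86 quantity is direction-independent."""
    seq_a = "".join(a for a, _ in codon_pairs)
    seq_b = "".join(b for _, b in codon_pairs)
    fwd = kaks.kaks(CodonAlignmentPair("h", seq_a, seq_b))
    rev = kaks.kaks(CodonAlignmentPair("h", seq_b, seq_a))
    for f in ("S", "N", "Sd", "Nd"):
        assert getattr(fwd, f) == pytest.approx(getattr(rev, f))
    if fwd.skipped_codons == 0:
        n_diff = sum(x != y for x, y in zip(seq_a, seq_b))
        assert fwd.Sd + fwd.Nd == pytest.approx(n_diff)


def _enumeration_p_value(x, y):
    """Exact two-sided Mann-Whitney p by full labeling enumeration."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)

    def u_stat(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b)

    u_obs = u_stat(x, y)
    center = n1 * (len(pooled) - n1) / 2
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= abs(u_obs - center):
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_small_sample_exact_value(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_path_matches_enumeration_for_all_splits(self):
        values = [1, 2, 3, 4, 5, 6]
        for n1 in range(1, 6):
            for idx in combinations(range(6), n1):
                x = [values[i] for i in idx]
                y = [values[i] for i in range(6) if i not in idx]
                res = mann_whitney(x, y)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(_enumeration_p_value(x, y))

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0

    def test_equal_multisets_take_approximation_path(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "normal-approximation"
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(10, 1, 30)
        assert mann_whitney(x, y).p_value < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_symmetric_table_is_null(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_pearson_closed_form(self):
        stat, _ = chi_square_2x2(94, 53, 90, 57)
        # closed form: n(ad-bc)^2 / (row1 row2 col1 col2)
        n = 94 + 53 + 90 + 57
        expected = n * (94 * 57 - 53 * 90) ** 2 / (147 * 147 * 184 * 110)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(0.2324, abs=1e-4)

    def test_brute_force_expected_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, 4)
            stat, _ = chi_square_2x2(a, b, c, d)
            table = np.array([[a, b], [c, d]], float)
            rows, cols, n = table.sum(1), table.sum(0), table.sum()
            exp = np.outer(rows, cols) / n
            assert stat == pytest.approx((((table - exp) ** 2) / exp).sum())

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)
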