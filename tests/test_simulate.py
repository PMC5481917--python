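"""Synthetic-genome generator: determinism, planted-event bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from famexpand import simulate
from famexpand.simulate import ConfigurationError, SimulationConfig


class TestAncestor:
    def test_gene_counts_and_gapfree_ranks(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=5, genes_per_chromosome=200,
                               tandem_rate_pre_split=0.0)
        anc = simulate.simulate_ancestor(cfg)
        assert len(anc.genes) == 1000
        for _, sub in anc.genes.groupby("chromosome"):
            assert sorted(sub["rank"]) == list(range(200))

    def test_zero_tandem_rate_means_no_adjacent_family_pairs(self):
        cfg = SimulationConfig(seed=2, tandem_rate_pre_split=0.0)
        anc = simulate.simulate_ancestor(cfg)
        fam = dict(zip(anc.families["gene_id"], anc.families["family"]))
        for _, sub in anc.genes.sort_values(["chromosome", "rank"]).groupby("chromosome"):
            ids = list(sub["gene_id"])
            assert all(fam[a] != fam[b] for a, b in zip(ids, ids[1:]))
        assert anc.pre_split_arrays == []

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=3)
        a, b = simulate.simulate_ancestor(cfg), simulate.simulate_ancestor(cfg)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.families, b.families)
        assert a.pre_split_arrays == b.pre_split_arrays

    def test_planted_arrays_are_adjacent_same_family(self):
        cfg = SimulationConfig(seed=4, tandem_rate_pre_split=0.2)
        anc = simulate.simulate_ancestor(cfg)
        rank = dict(zip(anc.genes["gene_id"], anc.genes["rank"]))
        fam = dict(zip(anc.families["gene_id"], anc.families["family"]))
        assert anc.pre_split_arrays
        for arr in anc.pre_split_arrays:
            assert len({fam[g] for g in arr}) == 1
            rs = [rank[g] for g in arr]
            assert rs == list(range(rs[0], rs[0] + len(arr)))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"retention_probs": {"LF": 1.2, "MF1": 0.4, "MF2": 0.3}},
            {"codon_length": 12},
            {"max_array_size": 1},
            {"n_families": 10_000},
            {"omega_values": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            simulate.simulate_ancestor(SimulationConfig(seed=0, **kwargs))


class TestTriplication:
    def test_full_retention_no_tandem_gives_three_copies_everywhere(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=2, genes_per_chromosome=50, n_families=10,
            retention_probs={"LF": 1.0, "MF1": 1.0, "MF2": 1.0},
            tandem_rate_pre_split=0.0, tandem_rate_post_split=0.0,
        )
        anc = simulate.simulate_ancestor(cfg)
        descendants, _, _, truth = simulate.simulate_triplication_descendants(anc, cfg)
        per = truth.ortholog_map.groupby(["species", "ref_gene"]).size()
        assert (per == 3).all()
        assert set(truth.ortholog_map["ref_gene"]) == set(anc.genes["gene_id"])
        for g in descendants:
            assert len(g.genes) == 3 * len(anc.genes)

    def test_zero_retention_gives_empty_descendants(self):
        cfg = SimulationConfig(
            seed=6, n_chromosomes=2, genes_per_chromosome=50, n_families=10,
            retention_probs={"LF": 0.0, "MF1": 0.0, "MF2": 0.0},
            tandem_rate_post_split=0.0,
        )
        anc = simulate.simulate_ancestor(cfg)
        descendants, _, _, truth = simulate.simulate_triplication_descendants(anc, cfg)
        assert all(g.genes.empty for g in descendants)
        assert truth.ortholog_map.empty

    def test_realized_retention_within_three_binomial_se(self):
        cfg = SimulationConfig(seed=7, n_chromosomes=10, genes_per_chromosome=500,
                               tandem_rate_pre_split=0.0)
        anc = simulate.simulate_ancestor(cfg)
        _, _, _, truth = simulate.simulate_triplication_descendants(anc, cfg)
        n = len(anc.genes)
        assert n >= 5000
        per_sg = truth.ortholog_map.groupby(["species", "subgenome"]).size()
        for (sp, sg), kept in per_sg.items():
            p = cfg.retention_probs[sg]
            se = np.sqrt(n * p * (1 - p))
            assert abs(kept - n * p) <= 3 * se, (sp, sg, kept)

    def test_conservation_identity(self, small_study):
        """Descendant gene count = retained WGT copies + planted tandem copies."""
        truth = small_study["truth"]
        for genome in small_study["descendants"]:
            n_wgt = (truth.ortholog_map["species"] == genome.species).sum()
            n_td = sum(
                1
                for g in genome.genes["gene_id"]
                if truth.origin[g] == "td_copy"
            )
            assert len(genome.genes) == n_wgt + n_td

    def test_truth_tandem_sets_disjoint(self, small_study):
        truth = small_study["truth"]
        assert not (truth.ancient_tandem_genes & truth.lineage_specific_tandem_genes)

    def test_anchor_table_covers_every_descendant_gene(self, small_study):
        anchors = small_study["anchors"]
        for genome in small_study["descendants"]:
            assert set(genome.genes["gene_id"]) <= set(anchors["target_gene"])


class TestCodonPairs:
    def test_omega_zero_preserves_protein(self):
        cfg = SimulationConfig(seed=8, codon_length=60, omega_values=(0.0,),
                               ks_target=0.5)
        pairs, _ = simulate.evolve_codon_pairs(5, cfg)
        from famexpand.kaks import translate_codon

        for p in pairs:
            aa_a = [translate_codon(p.seq_a[i:i + 3]) for i in range(0, len(p.seq_a), 3)]
            aa_b = [translate_codon(p.seq_b[i:i + 3]) for i in range(0, len(p.seq_b), 3)]
            assert aa_a == aa_b
            assert p.seq_a != p.seq_b  # synonymous changes did happen

    def test_ks_zero_gives_identical_pairs(self):
        cfg = SimulationConfig(seed=9, codon_length=40, ks_target=0.0)
        pairs, _ = simulate.evolve_codon_pairs(3, cfg)
        assert all(p.seq_a == p.seq_b for p in pairs)

    def test_saturating_ks_flagged(self):
        cfg = SimulationConfig(seed=10, codon_length=40, ks_target=5.0)
        _, table = simulate.evolve_codon_pairs(2, cfg)
        assert table["saturation_warning"].all()

    def test_deterministic(self):
        cfg = SimulationConfig(seed=11, codon_length=40)
        p1, _ = simulate.evolve_codon_pairs(4, cfg)
        p2, _ = simulate.evolve_codon_pairs(4, cfg)
        assert [(p.seq_a, p.seq_b) for p in p1] == [(p.seq_a, p.seq_b) for p in p2]

    def test_no_stop_codons_ever(self):
        cfg = SimulationConfig(seed=12, codon_length=50, ks_target=1.0,
                               omega_values=(1.0,))
        pairs, _ = simulate.evolve_codon_pairs(10, cfg)
        from famexpand.kaks import STOP_CODONS

        for p in pairs:
            for seq in (p.seq_a, p.seq_b):
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & STOP_CODONS)


class TestExpression:
    def test_zero_noise_identical_rows_per_cluster(self):
        cfg = SimulationConfig(seed=13, noise_sd=0.0, n_expression_clusters=3)
        mat, labels = simulate.simulate_expression([f"g{i}" for i in range(30)], cfg)
        for _, idx in labels.groupby(labels).groups.items():
            rows = mat.loc[idx].to_numpy()
            assert np.allclose(rows, rows[0])

    def test_deterministic_and_nonnegative(self):
        cfg = SimulationConfig(seed=14)
        genes = [f"g{i}" for i in range(20)]
        m1, l1 = simulate.simulate_expression(genes, cfg)
        m2, l2 = simulate.simulate_expression(genes, cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_series_equal(l1, l2)
        assert (m1.to_numpy() >= 0).all()

    def test_more_clusters_than_genes_rejected(self):
        cfg = SimulationConfig(seed=15, n_expression_clusters=10)
        with pytest.raises(ConfigurationError):
            simulate.simulate_expression(["a", "b"], cfg)


def test_export_scenario_roundtrip(tmp_path, small_study, small_config):
    from famexpand import catalog

    simulate.export_scenario(
        tmp_path, small_study["ancestor"], small_study["descendants"],
        small_study["subgenome_map"], small_study["anchors"],
        small_study["truth"], small_config,
    )
    reloaded = catalog.load_annotation(tmp_path / "desc1.gff3")
    genes = small_study["descendants"][0].genes
    assert len(reloaded) == len(genes)
    assert set(reloaded["gene_id"]) == set(genes["gene_id"])
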