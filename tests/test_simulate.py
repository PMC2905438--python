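import math

import numpy as np
import pytest

from wgdtiming.alignment_qc import frame_qc
from wgdtiming.io import read_fasta, read_hit_table, read_newick
from wgdtiming.pipeline import run_pipeline
from wgdtiming.simulate import (
    SimulationConfig,
    apply_losses,
    build_locus_tree,
    emit_dataset,
    evolve_codons,
    simulate_families,
)
from wgdtiming.tree_scoring import MODELS, canonicalize, extract_legume_clades, root_on_vitis


class TestConfigValidation:
    def test_defaults_validate_for_every_hypothesis(self):
        for h in MODELS:
            SimulationConfig(hypothesis=h).validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_cf_split": 120.0},                      # above the Vitis split
            {"hypothesis": "H1a", "t_early_wgd": 60.0},  # H1 WGD before the C split
            {"hypothesis": "H2a", "t_early_wgd": 50.0},  # H2 WGD after the C split
            {"hypothesis": "H1b", "t_cf_wgd": 70.0},     # Cf WGD older than the split
            {"loss_prob": 1.0},
            {"loss_mode": "sometimes"},
        ],
    )
    def test_inconsistent_times_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()


class TestBuildLocusTree:
    @pytest.mark.parametrize("name", list(MODELS))
    def test_lossfree_legume_clade_matches_hypothesis_pattern(self, name):
        tree = build_locus_tree(SimulationConfig(hypothesis=name))
        rooted = root_on_vitis(tree)
        (clade,) = extract_legume_clades(rooted)
        assert canonicalize(clade) == MODELS[name].canonical_pattern

    def test_h2a_has_two_single_c_subclades(self):
        tree = build_locus_tree(SimulationConfig(hypothesis="H2a"))
        rooted = root_on_vitis(tree)
        (clade,) = extract_legume_clades(rooted)
        halves = clade.child_nodes()
        assert len(halves) == 2
        for half in halves:
            labels = [lf.taxon.label for lf in half.leaf_iter()]
            assert sum(l.startswith("Cf") for l in labels) == 1

    def test_b_variant_produces_cf_cherries(self):
        tree = build_locus_tree(SimulationConfig(hypothesis="H1b"))
        assert "(C,C)" in canonicalize(tree)

    def test_mt_branch_runs_faster(self):
        cfg = SimulationConfig(hypothesis="H1a", mt_rate_multiplier=1.5)
        tree = build_locus_tree(cfg)
        mt = [lf for lf in tree.leaf_node_iter() if lf.taxon.label.startswith("Mt")]
        assert all(
            lf.edge.length == pytest.approx(cfg.t_gm_mt_split * 1.5) for lf in mt
        )


class TestApplyLosses:
    def test_zero_loss_probability_changes_nothing(self, rng):
        tree = build_locus_tree(SimulationConfig(hypothesis="H1a"))
        n = len(tree.leaf_nodes())
        outcome = apply_losses(tree, 0.0, rng)
        assert outcome.deleted_leaf_count == 0
        assert len(tree.leaf_nodes()) == n

    def test_certain_loss_collapses_to_species_tree(self, rng):
        tree = build_locus_tree(SimulationConfig(hypothesis="H2b"))
        outcome = apply_losses(tree, 1.0 - 1e-12, rng)
        assert canonicalize(outcome.tree) == "(((G,M),C),V)"

    def test_deletion_frequency_within_binomial_ci(self):
        """Per-lineage deletion frequency over many families stays inside
        the 99% binomial interval around the configured probability."""
        rng = np.random.default_rng(12)
        p = 0.1
        decisions = deletions = 0
        for _ in range(1000):
            tree = build_locus_tree(SimulationConfig(hypothesis="H1a"))
            out = apply_losses(tree, p, rng)
            decisions += out.decisions
            deletions += out.deletions
        freq = deletions / decisions
        half_width = 2.576 * math.sqrt(p * (1 - p) / decisions)
        assert abs(freq - p) < half_width

    def test_deleted_leaf_count_matches_leaf_deficit(self, rng):
        tree = build_locus_tree(SimulationConfig(hypothesis="H1a"))
        n_before = len(tree.leaf_nodes())
        out = apply_losses(tree, 0.5, rng)
        assert out.deleted_leaf_count == n_before - len(out.tree.leaf_nodes())


class TestEvolveCodons:
    def test_zero_branch_length_copies_parent(self, rng):
        cfg = SimulationConfig(hypothesis="H1a", syn_rate=0.0005)
        tree = build_locus_tree(cfg)
        for nd in tree.preorder_node_iter():
            nd.edge.length = 0.0
        aln = evolve_codons(tree, 60, cfg.syn_rate, rng)
        seqs = {r.residues for r in aln.rows}
        assert len(seqs) == 1

    def test_alignment_is_in_frame_and_stop_free(self, rng):
        tree = build_locus_tree(SimulationConfig(hypothesis="H1a"))
        aln = evolve_codons(tree, 100, 0.005, rng)
        assert aln.length_nt == 300
        report = frame_qc(aln)
        assert report.n_internal_stops == 0

    def test_small_codon_count_warns(self, rng):
        tree = build_locus_tree(SimulationConfig(hypothesis="H1a"))
        with pytest.warns(UserWarning, match="noisy"):
            evolve_codons(tree, 30, 0.005, rng)


class TestEmitDataset:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(hypothesis="H1a", n_families=5, seed=9, n_codons=60)
        emit_dataset(cfg, tmp_path / "a")
        emit_dataset(cfg, tmp_path / "b")
        for rel in ("truth.tsv", "hits.tsv", "alignments/fam0001.fasta",
                    "trees/fam0001.nwk"):
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_refuses_nonempty_output_dir(self, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "stale.txt").write_text("x")
        cfg = SimulationConfig(n_families=1, n_codons=60)
        with pytest.raises(FileExistsError):
            emit_dataset(cfg, out)
        emit_dataset(cfg, out, force=True)  # explicit override works

    def test_truth_rows_match_family_count(self, tmp_path):
        cfg = SimulationConfig(hypothesis="H2a", n_families=7, seed=1, n_codons=60)
        emit_dataset(cfg, tmp_path / "d")
        rows = (tmp_path / "d" / "truth.tsv").read_text().splitlines()
        assert len(rows) == 8  # header + 7 families

    def test_hit_identities_reconstruct_true_families(self, tmp_path):
        """Full round trip: emitted hits -> clustering -> QC -> scoring
        recovers the generating hypothesis for every loss-free family."""
        cfg = SimulationConfig(hypothesis="H2a", n_families=20, loss_prob=0.0,
                               seed=13, n_codons=80)
        emit_dataset(cfg, tmp_path / "d")
        result = run_pipeline(tmp_path / "d")
        assert result.cascade["clusters_initial"] == 20
        assert result.cascade["alignments_final"] == 20
        assert result.summary.model_loss_counts["H2a"][0] == 20

    def test_emitted_files_parse_with_standard_readers(self, tmp_path):
        cfg = SimulationConfig(hypothesis="H1b", n_families=2, seed=3, n_codons=60)
        emit_dataset(cfg, tmp_path / "d")
        records = read_fasta(tmp_path / "d" / "alignments" / "fam0001.fasta")
        assert {r.species for r in records} <= set("CGMV")
        (tree,) = read_newick(tmp_path / "d" / "trees" / "fam0001.nwk")
        assert len(tree.leaf_nodes()) == len(records)
        hits = read_hit_table(tmp_path / "d" / "hits.tsv")
        assert all(h.pct_identity >= 50.0 for h in hits)


class TestSimulateFamilies:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(hypothesis="H1a", n_families=3, seed=21, n_codons=60)
        a = simulate_families(cfg)
        b = simulate_families(cfg)
        for fa, fb in zip(a, b):
            assert [r.residues for r in fa.alignment.rows] == [
                r.residues for r in fb.alignment.rows
            ]

    def test_gm_mt_divergence_younger_than_cf_gm(self):
        """Simulated GmMt gene pairs are younger (lower Ks) than CfGm pairs,
        as the species phylogeny dictates."""
        from wgdtiming.ks import family_ks

        fams = simulate_families(
            SimulationConfig(hypothesis="H1a", n_families=60, loss_prob=0.0,
                             seed=17, n_codons=150)
        )
        gm_mt, cf_gm = [], []
        for f in fams:
            for rec in family_ks(f.alignment):
                if rec.category == "GmMt" and not math.isnan(rec.ks):
                    gm_mt.append(rec.ks)
                elif rec.category == "CfGm" and not math.isnan(rec.ks):
                    cf_gm.append(rec.ks)
        assert np.median(gm_mt) < np.median(cf_gm)
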