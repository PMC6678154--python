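import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteoannot.orf_finder import find_orfs
from proteoannot.synthetic_data import (
    SAMPLES,
    SimConfig,
    file_sha256,
    simulate,
    simulate_genome_and_models,
    write_bundle,
)


class TestConfig:
    def test_proportions_validated(self):
        with pytest.raises(ValueError):
            SimConfig(frac_lncrna_coding=1.4)
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)

    def test_defaults_anchor_observed_proportions(self):
        cfg = SimConfig()
        assert cfg.frac_lncrna_coding == 0.5
        assert cfg.frac_isoform_nmd == 0.22


class TestGenomeAndModels:
    def test_nmd_zero_config(self):
        cfg = SimConfig(seed=3, n_genes=25, n_lncrnas=5, frac_isoform_nmd=0.0)
        bundle = simulate_genome_and_models(cfg)
        iso = bundle.transcript_truth.query("kind == 'isoform'")
        assert len(iso) > 0
        assert iso["nmd_true"].sum() == 0

    def test_all_lncrnas_coding_config(self):
        cfg = SimConfig(seed=3, n_genes=5, n_lncrnas=20, frac_lncrna_coding=1.0)
        bundle = simulate_genome_and_models(cfg)
        lnc = bundle.transcript_truth.query("kind == 'lncrna'")
        assert (lnc["coding"] == 1).all()
        # every planted lncRNA ORF clears the >100 aa filter
        assert (lnc["protein_length_aa"] > 100).all()

    def test_realized_nmd_fraction_within_binomial_bounds(self):
        cfg = SimConfig(seed=1, n_genes=300)
        bundle = simulate_genome_and_models(cfg)
        iso = bundle.transcript_truth.query("kind == 'isoform'")
        n = len(iso)
        k = int(iso["nmd_true"].sum())
        lo = stats.binom.ppf(0.005, n, 0.22)
        hi = stats.binom.ppf(0.995, n, 0.22)
        assert lo <= k <= hi

    def test_truth_table_complete(self, small_bundle):
        truth = small_bundle.transcript_truth
        emitted = (
            {m.transcript_id for m in small_bundle.models}
            | set(small_bundle.lncrna_seqs)
        )
        assert set(truth["transcript_id"]) == emitted
        assert truth["transcript_id"].is_unique

    def test_exactly_one_atg_per_coding_transcript(self, small_bundle):
        truth = small_bundle.transcript_truth
        seqs = {m.transcript_id: m.spliced_seq for m in small_bundle.models}
        seqs.update(small_bundle.lncrna_seqs)
        for row in truth.itertuples(index=False):
            n_atg = seqs[row.transcript_id].count("ATG")
            assert n_atg == (1 if row.coding else 0)

    def test_planted_orf_is_what_finder_reports(self, small_bundle):
        truth = small_bundle.transcript_truth
        coding = truth[truth["coding"] == 1].head(40)
        seqs = {m.transcript_id: m.spliced_seq for m in small_bundle.models}
        seqs.update(small_bundle.lncrna_seqs)
        for row in coding.itertuples(index=False):
            (orf,) = find_orfs(seqs[row.transcript_id], min_aa=1)
            assert orf.start_nt == row.orf_start_nt
            assert orf.stop_nt == row.stop_end_nt
            assert orf.protein_seq == row.protein_seq


class TestPsms:
    def test_single_peptide_proteins_emit_one_peptide(self, small_bundle):
        pt = small_bundle.protein_truth
        forced = pt[pt["forced_single_peptide"] == 1]
        assert (forced["n_observed_peptides"] <= 1).all()

    def test_undetected_proteins_emit_nothing(self, small_bundle):
        pt = small_bundle.protein_truth
        undetected = pt[pt["detected"] == 0]
        assert (undetected["n_observed_peptides"] == 0).all()

    def test_decoy_rows_present_and_flagged(self, small_bundle):
        psms = [p for s in SAMPLES for p in small_bundle.psms[s]]
        n_decoy = sum(1 for p in psms if p.is_decoy)
        assert n_decoy > 0
        assert all(p.spectral_count >= 1 for p in psms)

    def test_observed_peptides_are_tryptic_products(self, small_bundle):
        from proteoannot.peptide_engine import digest

        pt = small_bundle.protein_truth
        row = pt[pt["n_observed_peptides"] >= 2].iloc[0]
        truth = small_bundle.transcript_truth.set_index("protein_id")
        seq = truth.loc[row["protein_id"], "protein_seq"]
        peps = set(row["observed_peptides"].split(";"))
        assert peps <= digest(seq, missed_cleavages=0)

    def test_log2fc_parameter_recovery(self, tmp_path):
        """Realized pipeline log2FC tracks truth at moderate error.

        NSAF normalizes within sample, so all realized log2FCs share one
        global offset (the log ratio of the per-sample totals); recovery is
        assessed after removing that offset.
        """
        from proteoannot.pipeline import PipelineConfig, run_all

        out = tmp_path / "recovery"
        run_all(
            PipelineConfig(
                seed=5, out_dir=str(out), n_genes=300, n_lncrnas=40,
                sim={"spc_scale": 50.0, "spc_dispersion": 0.1},
            )
        )
        quant = pd.read_csv(out / "quant" / "quant.tsv", sep="\t")
        truth = pd.read_csv(out / "sim" / "truth_proteins.tsv", sep="\t")
        merged = quant.merge(truth, on="protein_id")
        both = merged[
            (merged[f"spc_{SAMPLES[0]}"] > 0) & (merged[f"spc_{SAMPLES[1]}"] > 0)
        ]
        err = both["log2fc"].astype(float) - both["log2fc_true"]
        centered = (err - err.median()).abs()
        assert len(both) > 100
        assert centered.median() < 0.35  # preregistered bound

    def test_infinite_shift_limit_keeps_all_true_targets(self):
        # decoy_score_shift -> infinity: every genuine target survives FDR
        # (planted false targets share the decoy score distribution and sink)
        from proteoannot.peptide_engine import fdr_filter

        cfg = SimConfig(seed=9, n_genes=20, n_lncrnas=5, decoy_score_shift=1000.0)
        bundle = simulate(cfg)
        psms = [p for s in SAMPLES for p in bundle.psms[s]]
        accepted, _ = fdr_filter(psms, 0.01)
        true_targets = [
            p for p in psms if not p.is_decoy and p.peptide not in bundle.false_peptides
        ]
        accepted_ids = {id(p) for p in accepted}
        assert all(id(p) in accepted_ids for p in true_targets)
        assert not any(p.is_decoy for p in accepted)


class TestDeterminism:
    def test_identical_config_identical_files(self, tmp_path):
        cfg = SimConfig(seed=4, n_genes=15, n_lncrnas=8)
        h1 = {
            name: file_sha256(p)
            for name, p in write_bundle(simulate(cfg), tmp_path / "a").items()
        }
        h2 = {
            name: file_sha256(p)
            for name, p in write_bundle(simulate(cfg), tmp_path / "b").items()
        }
        assert h1 == h2

    def test_different_seed_different_files(self, tmp_path):
        b1 = simulate(SimConfig(seed=4, n_genes=10, n_lncrnas=5))
        b2 = simulate(SimConfig(seed=5, n_genes=10, n_lncrnas=5))
        assert b1.genome != b2.genome
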