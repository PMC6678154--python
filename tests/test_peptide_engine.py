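import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_digest
from proteoannot.io_formats import PsmRecord
from proteoannot.peptide_engine import (
    FdrError,
    UNIQ_GENE,
    UNIQ_ISOFORM,
    UNIQ_SHARED,
    UNIQ_UNMAPPED,
    PeptideEvidence,
    aggregate_evidence,
    collapse_il,
    digest,
    fdr_filter,
    infer_proteins,
    match_peptides,
    reverse_decoy,
    td_score_cutoff,
)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(list(PROTEIN_ALPHABET), size=n))


class TestDigest:
    def test_hand_checkable(self):
        assert digest("AAAKGGGRCCC", 0, 3, 50) == {"AAAK", "GGGR", "CCC"}

    def test_no_cleavage_before_proline(self):
        assert digest("AAAKPGGG", 0, 3, 50) == {"AAAKPGGG"}

    def test_missed_cleavages(self):
        assert digest("AAAKGGGRCCC", 1, 3, 50) == {
            "AAAK", "GGGR", "CCC", "AAAKGGGR", "GGGRCCC",
        }

    def test_empty_protein(self):
        assert digest("", 2, 3, 50) == set()

    def test_length_filter(self):
        assert digest("AKCCCCCCCK", 0, 3, 50) == {"CCCCCCCK"}

    @pytest.mark.parametrize("mc", [0, 1, 2])
    def test_bruteforce_oracle(self, mc):
        rng = np.random.default_rng(mc)
        for _ in range(100):
            seq = _random_protein(rng, int(rng.integers(5, 120)))
            assert digest(seq, mc, 4, 30) == brute_force_digest(seq, mc, 4, 30)

    @given(st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_case_invariance(self, seq):
        assert digest(seq.lower(), 1, 3, 40) == digest(seq, 1, 3, 40)


class TestReverseDecoy:
    def test_simple_reverse(self):
        db = reverse_decoy({"p1": "MKR"})
        assert db == {"p1": "MKR", "DECOY_p1": "RKM"}

    def test_palindrome_distinct_id(self):
        db = reverse_decoy({"p1": "MKM"})
        assert db["DECOY_p1"] == "MKM"
        assert len(db) == 2

    def test_double_decoy_rejected(self):
        with pytest.raises(ValueError):
            reverse_decoy({"DECOY_p1": "MKR"})

    def test_size_exactly_doubles(self):
        rng = np.random.default_rng(5)
        db = {f"p{i}": _random_protein(rng, 50) for i in range(20)}
        assert len(reverse_decoy(db)) == 40

    def test_decoy_peptide_length_distribution_close(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(6)
        db = {f"p{i}": _random_protein(rng, 300) for i in range(60)}
        full = reverse_decoy(db)
        t_lens = [len(p) for pid, s in full.items() if not pid.startswith("DECOY_")
                  for p in digest(s, 0, 4, 40)]
        d_lens = [len(p) for pid, s in full.items() if pid.startswith("DECOY_")
                  for p in digest(s, 0, 4, 40)]
        bins = np.arange(4, 42, 4)
        t_hist, _ = np.histogram(t_lens, bins=bins)
        d_hist, _ = np.histogram(d_lens, bins=bins)
        keep = (t_hist + d_hist) > 5
        _, p, _, _ = chi2_contingency(np.vstack([t_hist[keep] + 1, d_hist[keep] + 1]))
        assert p > 0.01  # same cleavage-site structure reversed


def _psm(score, decoy, peptide="AAAAK", sample="s", spc=1):
    return PsmRecord(peptide, (), score, decoy, sample, spc)


class TestFdrFilter:
    def test_separable_case(self):
        psms = [_psm(10.0, False) for _ in range(100)] + [_psm(5.0, True)]
        accepted, cutoff = fdr_filter(psms, 0.01)
        assert len(accepted) == 100
        assert 5.0 < cutoff <= 10.0

    def test_all_decoys_above_targets_errors(self):
        psms = [_psm(10.0, True), _psm(11.0, True), _psm(1.0, False)]
        with pytest.raises(FdrError):
            fdr_filter(psms, 0.01)

    def test_decoys_removed_from_accepted(self):
        psms = [_psm(10.0, False)] * 50 + [_psm(10.0, True)] * 0 + [_psm(2.0, True)]
        accepted, _ = fdr_filter(psms, 0.05)
        assert all(not p.is_decoy for p in accepted)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        psms = [_psm(float(rng.normal(10, 3)), False) for _ in range(300)] + [
            _psm(float(rng.normal(6, 3)), True) for _ in range(30)
        ]
        prev: set | None = None
        for thr in (0.005, 0.01, 0.05, 0.2):
            accepted, _ = fdr_filter(psms, thr)
            ids = {id(p) for p in accepted}
            if prev is not None:
                assert prev <= ids
            prev = ids

    def test_ties_accepted_at_cutoff(self):
        psms = [_psm(10.0, False)] * 200 + [_psm(10.0, True)]
        accepted, cutoff = fdr_filter(psms, 0.01)
        assert cutoff == 10.0
        assert len(accepted) == 200

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            td_score_cutoff([1.0], [False], 1.5)

    def test_realized_fdp_calibrated_across_seeds(self):
        from proteoannot.synthetic_data import SAMPLES, SimConfig, simulate

        fdps = []
        for seed in range(1, 21):
            cfg = SimConfig(seed=seed, n_genes=40, n_lncrnas=15, decoy_score_shift=5.0)
            bundle = simulate(cfg)
            psms = [p for s in SAMPLES for p in bundle.psms[s]]
            accepted, _ = fdr_filter(psms, 0.01)
            n_false = sum(1 for p in accepted if p.peptide in bundle.false_peptides)
            fdps.append(n_false / len(accepted))
        assert float(np.mean(fdps)) <= 0.02

    def test_infinite_separation_keeps_all_targets(self, small_bundle):
        # decoy_score_shift -> infinity limit: all targets retained
        from proteoannot.synthetic_data import SAMPLES

        psms = [p for s in SAMPLES for p in small_bundle.psms[s]]
        shifted = [
            PsmRecord(p.peptide, (), p.score - (1e6 if p.is_decoy else 0.0),
                      p.is_decoy, p.sample, p.spectral_count)
            for p in psms
        ]
        accepted, _ = fdr_filter(shifted, 0.01)
        assert len(accepted) == sum(1 for p in psms if not p.is_decoy)


DBS = {
    "annotated": {"GENE1": "MAAAKNIEKGGGR", "GENE2": "MCCCKDDDR"},
    "lncrna_orf": {"LNC1.p1": "MWWWKEEER", "LNC2.p1": "MAAAKYYYK"},
    "isoform_orf": {"GENE1.i1.p1": "MAAAKNIEKPPLV", "GENE1.i2.p1": "MAAAKHHHK"},
}
P2G = {
    "GENE1": "GENE1", "GENE2": "GENE2",
    "LNC1.p1": "LNC1", "LNC2.p1": "LNC2",
    "GENE1.i1.p1": "GENE1", "GENE1.i2.p1": "GENE1",
}


def _evidence(peptide, spc=2, sample="s", score=20.0):
    return PeptideEvidence(collapse_il(peptide), peptide, {sample: spc}, score)


class TestMatchPeptides:
    def test_unique_to_one_lncrna_orf(self):
        (ev,) = match_peptides([_evidence("MWWWK")], DBS, P2G)
        assert ev.mapped_proteins == frozenset({"LNC1.p1"})
        assert ev.uniqueness == UNIQ_ISOFORM

    def test_il_collapse_matches(self):
        # NIEK is in GENE1; NLEK differs only by I/L
        (ev,) = match_peptides([_evidence("NLEK")], DBS, P2G)
        assert "GENE1" in ev.mapped_proteins
        assert "GENE1.i1.p1" in ev.mapped_proteins

    def test_gene_unique_across_isoforms(self):
        (ev,) = match_peptides([_evidence("MAAAKH")], DBS, P2G)
        assert ev.mapped_proteins == frozenset({"GENE1.i2.p1"})
        assert ev.uniqueness == UNIQ_ISOFORM
        (ev2,) = match_peptides([_evidence("MAAAKN")], DBS, P2G)
        assert ev2.mapped_proteins == frozenset({"GENE1", "GENE1.i1.p1"})
        assert ev2.uniqueness == UNIQ_GENE

    def test_annotated_plus_lncrna_is_shared(self):
        (ev,) = match_peptides([_evidence("MAAAK")], DBS, P2G)
        assert {"GENE1", "LNC2.p1"} <= set(ev.mapped_proteins)
        assert ev.uniqueness == UNIQ_SHARED

    def test_unmapped_retained_and_flagged(self):
        (ev,) = match_peptides([_evidence("QQQQQQQ")], DBS, P2G)
        assert ev.mapped_proteins == frozenset()
        assert ev.uniqueness == UNIQ_UNMAPPED


class TestInferProteins:
    def test_one_peptide_high_spc_not_validated(self):
        evidence = match_peptides([_evidence("MWWWK", spc=500)], DBS, P2G)
        groups = {g.protein_id: g for g in infer_proteins(evidence, DBS, P2G)}
        assert not groups["LNC1.p1"].validated

    def test_two_isoforms_sharing_all_peptides_not_validated(self):
        dbs = {
            "annotated": {},
            "lncrna_orf": {},
            "isoform_orf": {"G.i1.p1": "MAAAKCCCKDDDR", "G.i2.p1": "MAAAKCCCKEEEK"},
        }
        p2g = {"G.i1.p1": "G", "G.i2.p1": "G"}
        evidence = match_peptides(
            [_evidence("MAAAK"), _evidence("CCCK")], dbs, p2g
        )
        groups = {g.protein_id: g for g in infer_proteins(evidence, dbs, p2g)}
        assert groups["G.i1.p1"].n_distinct_peptides == 2
        assert not groups["G.i1.p1"].validated
        assert not groups["G.i2.p1"].validated

    def test_two_unique_peptides_validate(self):
        evidence = match_peptides([_evidence("MWWWK"), _evidence("EEER")], DBS, P2G)
        groups = {g.protein_id: g for g in infer_proteins(evidence, DBS, P2G)}
        assert groups["LNC1.p1"].validated

    def test_spc_conservation(self, small_bundle):
        from proteoannot.synthetic_data import SAMPLES

        psms = [p for s in SAMPLES for p in small_bundle.psms[s]]
        accepted, _ = fdr_filter(psms, 0.01)
        evidence = aggregate_evidence(accepted)
        total_ev = sum(spc for ev in evidence for spc in ev.samples.values())
        total_psm = sum(p.spectral_count for p in accepted)
        assert total_ev == total_psm

    def test_shared_spc_not_counted_at_isoform_level(self):
        evidence = match_peptides([_evidence("MAAAK", spc=7)], DBS, P2G)
        groups = {g.protein_id: g for g in infer_proteins(evidence, DBS, P2G)}
        assert groups["GENE1"].spc_per_sample.get("s", 0) == 7  # gene level keeps it
        assert groups["LNC2.p1"].spc_per_sample.get("s", 0) == 0
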