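import math

import numpy as np
import pytest

from proteoannot.quantification import (
    CALL_DOWN,
    CALL_NOT_QUANT,
    CALL_UP,
    QuantError,
    QuantRow,
    differential,
    nsaf,
    sample_correlation,
)


def _row(pid, spc_a, spc_b, length=100, npep=2):
    return QuantRow(
        protein_id=pid, gene_id=pid, source="annotated", length_aa=length,
        spc={"a": spc_a, "b": spc_b},
        n_peptides={"a": npep, "b": npep},
    )


class TestNsaf:
    def test_single_protein_is_one(self):
        rows = [_row("p1", 17, 0)]
        nsaf(rows, "a")
        assert rows[0].nsaf["a"] == 1.0

    def test_equal_saf_splits_evenly(self):
        rows = [_row("p1", 10, 0, length=100), _row("p2", 5, 0, length=50)]
        nsaf(rows, "a")
        assert rows[0].nsaf["a"] == pytest.approx(0.5)
        assert rows[1].nsaf["a"] == pytest.approx(0.5)

    def test_zero_spc_gets_zero(self):
        rows = [_row("p1", 10, 0), _row("p2", 0, 3)]
        nsaf(rows, "a")
        assert rows[1].nsaf["a"] == 0.0

    def test_all_zero_sample_errors(self):
        with pytest.raises(QuantError):
            nsaf([_row("p1", 0, 0)], "a")

    def test_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            spcs = rng.integers(0, 200, size=n)
            if spcs.sum() == 0:
                spcs[0] = 1
            lens = rng.integers(50, 900, size=n)
            rows = [_row(f"p{i}", int(s), 0, length=int(l))
                    for i, (s, l) in enumerate(zip(spcs, lens))]
            nsaf(rows, "a")
            assert math.isclose(sum(r.nsaf["a"] for r in rows), 1.0, abs_tol=1e-9)
            scaled = [_row(f"p{i}", int(s) * 7, 0, length=int(l))
                      for i, (s, l) in enumerate(zip(spcs, lens))]
            nsaf(scaled, "a")
            for r1, r2 in zip(rows, scaled):
                assert r2.nsaf["a"] == pytest.approx(r1.nsaf["a"])

    def test_monotonicity(self):
        rows = [_row("p1", 10, 0), _row("p2", 20, 0), _row("p3", 5, 0)]
        nsaf(rows, "a")
        before = [r.nsaf["a"] for r in rows]
        bumped = [_row("p1", 11, 0), _row("p2", 20, 0), _row("p3", 5, 0)]
        nsaf(bumped, "a")
        after = [r.nsaf["a"] for r in bumped]
        assert after[0] >= before[0]
        assert after[1] <= before[1] and after[2] <= before[2]


class TestDifferential:
    def test_boundary_fold_change_4_is_up(self):
        # one protein 4x the other way to hold totals equal: use symmetric design
        rows = [_row("p1", 8, 2), _row("p2", 2, 8)]
        summary = differential(rows, "a", "b", pseudocount=0.0)
        assert rows[1].fold_change == pytest.approx(4.0)
        assert rows[1].call == CALL_UP
        assert rows[0].call == CALL_DOWN
        assert summary["n_total_de"] == 2

    def test_absent_protein_finite_fold_change(self):
        rows = [_row("p1", 0, 40), _row("p2", 40, 40)]
        differential(rows, "a", "b")
        assert math.isfinite(rows[0].fold_change)
        assert rows[0].call == CALL_UP

    def test_min_peptides_rule(self):
        rows = [_row("p1", 50, 2, npep=1), _row("p2", 10, 10)]
        summary = differential(rows, "a", "b")
        assert rows[0].call == CALL_NOT_QUANT
        assert summary["n_not_quantifiable"] == 1

    def test_threshold_duality(self):
        rng = np.random.default_rng(9)
        rows = [_row(f"p{i}", int(rng.integers(0, 100)), int(rng.integers(0, 100)))
                for i in range(50)]
        differential(rows, "a", "b")
        forward = {r.protein_id: r.call for r in rows}
        differential(rows, "b", "a")
        backward = {r.protein_id: r.call for r in rows}
        for pid in forward:
            if forward[pid] == CALL_UP:
                assert backward[pid] == CALL_DOWN
            elif forward[pid] == CALL_DOWN:
                assert backward[pid] == CALL_UP

    def test_recovers_planted_effects(self, pipeline_run):
        import json

        summary = json.load(open(pipeline_run["out"] / "quant" / "quant_summary.json"))
        assert summary["n_total_de"] == summary["n_up"] + summary["n_down"]
        assert summary["n_total_de"] > 0


class TestCorrelation:
    def test_identical_samples(self):
        rows = [_row(f"p{i}", s, s) for i, s in enumerate((3, 10, 40, 7))]
        nsaf(rows, "a")
        nsaf(rows, "b")
        assert sample_correlation(rows, "a", "b") == pytest.approx(1.0)

    def test_scale_invariance(self):
        rows = [_row(f"p{i}", s, 5 * s) for i, s in enumerate((3, 10, 40, 7))]
        nsaf(rows, "a")
        nsaf(rows, "b")
        assert sample_correlation(rows, "a", "b") == pytest.approx(1.0)

    def test_anti_ordered_matches_direct_formula(self):
        spc_a = [2, 4, 8, 16, 32]
        spc_b = [32, 16, 8, 4, 2]
        rows = [_row(f"p{i}", a, b) for i, (a, b) in enumerate(zip(spc_a, spc_b))]
        nsaf(rows, "a")
        nsaf(rows, "b")
        r = sample_correlation(rows, "a", "b")
        x = np.log10([row.nsaf["a"] for row in rows])
        y = np.log10([row.nsaf["b"] for row in rows])
        direct = float(np.corrcoef(x, y)[0, 1])
        assert r == pytest.approx(direct)
        assert r < 0

    def test_too_few_shared_proteins(self):
        rows = [_row("p1", 3, 3), _row("p2", 4, 0), _row("p3", 0, 4)]
        nsaf(rows, "a")
        nsaf(rows, "b")
        with pytest.raises(QuantError):
            sample_correlation(rows, "a", "b")

    def test_spearman_available(self):
        rows = [_row(f"p{i}", s, s * s) for i, s in enumerate((2, 5, 11, 23))]
        nsaf(rows, "a")
        nsaf(rows, "b")
        assert sample_correlation(rows, "a", "b", method="spearman") == pytest.approx(1.0)
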