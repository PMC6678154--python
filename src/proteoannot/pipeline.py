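"""End-to-end orchestration of the re-annotation analysis.

``run_all`` drives: simulate -> ORF calling -> decoy database -> FDR
filtering -> peptide matching -> protein inference -> NSAF quantification
-> NMD classification -> domain comparison -> summary report. Every stage
writes plain-text artifacts into its own subdirectory and a manifest with
content hashes makes determinism checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io_formats, nmd_classifier, orf_finder, peptide_engine, quantification, report
from .io_formats import PsmRecord, write_fasta, write_tsv
from .orf_finder import OrfRecord
from .peptide_engine import DECOY_PREFIX, PeptideEvidence, ProteinGroup
from .rounding import percent
from .synthetic_data import SAMPLES, SimConfig, file_sha256, simulate, write_bundle


@dataclass
class PipelineConfig:
    """Thresholds default to the study's stated values."""

    seed: int = 1
    out_dir: str = "pipeline_out"
    n_genes: int = 300
    n_lncrnas: int = 80
    fdr: float = 0.01
    min_peptides: int = 2
    up_fc: float = 4.0
    down_fc: float = 0.25
    nmd_nt: int = 50
    min_orf_aa: int = 100
    missed_cleavages: int = 2
    peptide_len: tuple[int, int] = (7, 50)
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides

    def header(self) -> dict:
        d = asdict(self)
        d.pop("sim")
        d.pop("out_dir")  # location must not affect content hashes
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stage helpers (also used by the CLI subcommands)
# ---------------------------------------------------------------------------

def build_databases(
    annotated: Mapping[str, str],
    lncrna_orfs: Mapping[str, str],
    isoform_orfs: Mapping[str, str],
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Assemble the three search databases and the protein->gene map.

    Annotated protein IDs are gene IDs (one protein per locus); ORF IDs are
    ``<transcript_id>.p<k>`` with the gene recovered from the transcript.
    """
    databases = {
        "annotated": dict(annotated),
        "lncrna_orf": dict(lncrna_orfs),
        "isoform_orf": dict(isoform_orfs),
    }
    protein_to_gene: dict[str, str] = {pid: pid for pid in annotated}
    for pid in lncrna_orfs:
        protein_to_gene[pid] = pid.rsplit(".", 1)[0]  # lncRNA id is its own locus
    for pid in isoform_orfs:
        tid = pid.rsplit(".", 1)[0]
        gene = tid.rsplit(".", 1)[0]
        protein_to_gene[pid] = gene
    return databases, protein_to_gene


def validate_proteins(
    psms: Sequence[PsmRecord],
    databases: Mapping[str, Mapping[str, str]],
    protein_to_gene: Mapping[str, str],
    fdr: float = 0.01,
    min_peptides: int = 2,
) -> tuple[list[PeptideEvidence], list[ProteinGroup], dict]:
    """Peptide FDR -> matching -> protein FDR -> two-peptide inference."""
    accepted, pep_cutoff = peptide_engine.fdr_filter(list(psms), fdr)
    evidence = peptide_engine.aggregate_evidence(accepted)
    matched = peptide_engine.match_peptides(evidence, databases, protein_to_gene)
    groups = peptide_engine.infer_proteins(
        matched, databases, protein_to_gene, min_peptides=min_peptides
    )

    # protein-level pass: best-peptide scores, decoys rebuilt from the same
    # reversed database so both levels see the same decoy space
    decoy_dbs = {
        src: {
            DECOY_PREFIX + pid: seq[::-1] for pid, seq in databases[src].items()
        }
        for src in databases
    }
    decoy_gene = {
        pid: DECOY_PREFIX + protein_to_gene[pid.removeprefix(DECOY_PREFIX)]
        for src in decoy_dbs
        for pid in decoy_dbs[src]
    }
    decoy_psms = [p for p in psms if p.is_decoy and p.score >= pep_cutoff]
    decoy_evidence = peptide_engine.aggregate_evidence(decoy_psms)
    decoy_matched = peptide_engine.match_peptides(decoy_evidence, decoy_dbs, decoy_gene)
    best: dict[str, float] = {g.protein_id: g.best_score for g in groups}
    for ev in decoy_matched:
        for pid in ev.mapped_proteins:
            best[pid] = max(best.get(pid, float("-inf")), ev.best_score)
    if best:
        accepted_ids, prot_cutoff = peptide_engine.protein_fdr_filter(best, fdr)
        for g in groups:
            if g.protein_id not in accepted_ids:
                g.validated = False
    else:
        prot_cutoff = float("nan")
    stats = {
        "n_psms": len(psms),
        "n_accepted_psms": len(accepted),
        "peptide_score_cutoff": pep_cutoff,
        "protein_score_cutoff": prot_cutoff,
        "n_peptides": len(evidence),
        "n_unmapped_peptides": sum(
            1 for ev in matched if ev.uniqueness == peptide_engine.UNIQ_UNMAPPED
        ),
        "n_proteins_with_evidence": len(groups),
        "n_validated": sum(1 for g in groups if g.validated),
    }
    return matched, groups, stats


def evidence_frame(evidence: Sequence[PeptideEvidence]) -> pd.DataFrame:
    rows = [
        {
            "peptide_key": ev.peptide_key,
            "raw_peptide": ev.raw_peptide,
            "best_score": round(ev.best_score, 4),
            "uniqueness": ev.uniqueness,
            "mapped_proteins": ";".join(sorted(ev.mapped_proteins)),
            **{f"spc_{s}": ev.samples.get(s, 0) for s in SAMPLES},
        }
        for ev in evidence
    ]
    return pd.DataFrame(rows)


def groups_frame(groups: Sequence[ProteinGroup]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": g.protein_id,
            "gene_id": g.gene_id,
            "source": g.source,
            "length_aa": g.length_aa,
            "n_distinct_peptides": g.n_distinct_peptides,
            "n_isoform_unique": g.n_isoform_unique,
            "validated": int(g.validated),
            **{f"spc_{s}": g.spc_per_sample.get(s, 0) for s in SAMPLES},
            **{f"n_peptides_{s}": g.n_peptides_per_sample.get(s, 0) for s in SAMPLES},
        }
        for g in groups
    ]
    return pd.DataFrame(rows)


def quant_frame(rows: Sequence[quantification.QuantRow]) -> pd.DataFrame:
    out = [
        {
            "protein_id": r.protein_id,
            "gene_id": r.gene_id,
            "source": r.source,
            "length_aa": r.length_aa,
            **{f"spc_{s}": r.spc.get(s, 0) for s in SAMPLES},
            **{f"nsaf_{s}": format(r.nsaf.get(s, 0.0), ".10g") for s in SAMPLES},
            "fold_change": format(r.fold_change, ".6g") if r.fold_change else "",
            "log2fc": format(r.log2fc, ".6g") if r.log2fc is not None else "",
            "call": r.call,
        }
        for r in rows
    ]
    return pd.DataFrame(out)


def orfs_from_table(table: pd.DataFrame) -> dict[str, OrfRecord]:
    """Longest ORF per transcript, rebuilt from an ORF table."""
    best: dict[str, OrfRecord] = {}
    for row in table.itertuples(index=False):
        rec = OrfRecord(
            orf_id=row.orf_id,
            transcript_id=row.transcript_id,
            frame=int(getattr(row, "frame", 0)),
            start_nt=int(row.start_nt),
            stop_nt=int(row.stop_nt),
            protein_seq=getattr(row, "protein_seq", ""),
            has_stop=bool(row.has_stop),
            length_aa=int(row.length_aa),
        )
        prev = best.get(rec.transcript_id)
        if prev is None or rec.length_aa > prev.length_aa:
            best[rec.transcript_id] = rec
    return best


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> dict:
    """Run the whole analysis on a simulated study; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- simulate -----------------------------------------------------------
    sim_cfg = SimConfig(
        seed=config.seed,
        n_genes=config.n_genes,
        n_lncrnas=config.n_lncrnas,
        **config.sim,
    )
    bundle = simulate(sim_cfg)
    sim_paths = write_bundle(bundle, out / "sim")
    artifacts.update({f"sim/{k}": v for k, v in sim_paths.items()})

    # --- ORF calling --------------------------------------------------------
    stage_dir = out / "orfs"
    stage_dir.mkdir(exist_ok=True)
    genome = bundle.genome
    isoform_seqs = {
        m.transcript_id: io_formats.spliced_sequence(m, genome)
        for m in bundle.models
        if m.biotype == "isoform"
    }
    iso_proteins, iso_table = orf_finder.translate_database(isoform_seqs, "isoform")
    lnc_proteins, lnc_table = orf_finder.translate_database(bundle.lncrna_seqs, "lncrna")
    write_fasta(iso_proteins, stage_dir / "isoform_orfs.fa")
    write_fasta(lnc_proteins, stage_dir / "lncrna_orfs.fa")
    write_tsv(iso_table, stage_dir / "isoform_orfs.tsv")
    write_tsv(lnc_table, stage_dir / "lncrna_orfs.tsv")
    for name in ("isoform_orfs.fa", "lncrna_orfs.fa", "isoform_orfs.tsv", "lncrna_orfs.tsv"):
        artifacts[f"orfs/{name}"] = str(stage_dir / name)

    # --- decoy database -----------------------------------------------------
    stage_dir = out / "decoy"
    stage_dir.mkdir(exist_ok=True)
    databases, protein_to_gene = build_databases(
        bundle.annotated_proteins, lnc_proteins, iso_proteins
    )
    target_db = {pid: seq for db in databases.values() for pid, seq in db.items()}
    td_db = peptide_engine.reverse_decoy(dict(sorted(target_db.items())))
    write_fasta(td_db, stage_dir / "target_decoy.fa")
    artifacts["decoy/target_decoy.fa"] = str(stage_dir / "target_decoy.fa")

    # --- FDR + matching + inference ----------------------------------------
    stage_dir = out / "match"
    stage_dir.mkdir(exist_ok=True)
    all_psms = [p for s in SAMPLES for p in bundle.psms[s]]
    if not all_psms:
        raise StageError("match", "no PSMs simulated")
    matched, groups, match_stats = validate_proteins(
        all_psms, databases, protein_to_gene,
        fdr=config.fdr, min_peptides=config.min_peptides,
    )
    write_tsv(evidence_frame(matched), stage_dir / "peptides.tsv")
    write_tsv(groups_frame(groups), stage_dir / "proteins.tsv")
    _write_json(match_stats, stage_dir / "match_summary.json")
    for name in ("peptides.tsv", "proteins.tsv", "match_summary.json"):
        artifacts[f"match/{name}"] = str(stage_dir / name)

    # --- quantification -----------------------------------------------------
    stage_dir = out / "quant"
    stage_dir.mkdir(exist_ok=True)
    rows = quantification.make_rows(groups, validated_only=True)
    if not rows:
        raise StageError("quant", "no validated proteins to quantify")
    for sample in SAMPLES:
        quantification.nsaf(rows, sample)
    de_summary = quantification.differential(
        rows, SAMPLES[0], SAMPLES[1],
        min_peptides=config.min_peptides, up_fc=config.up_fc, down_fc=config.down_fc,
    )
    try:
        de_summary["nsaf_correlation"] = round(
            quantification.sample_correlation(rows, SAMPLES[0], SAMPLES[1]), 4
        )
    except quantification.QuantError:
        de_summary["nsaf_correlation"] = None
    write_tsv(quant_frame(rows), stage_dir / "quant.tsv")
    _write_json(de_summary, stage_dir / "quant_summary.json")
    artifacts["quant/quant.tsv"] = str(stage_dir / "quant.tsv")
    artifacts["quant/quant_summary.json"] = str(stage_dir / "quant_summary.json")

    # --- NMD classification -------------------------------------------------
    stage_dir = out / "nmd"
    stage_dir.mkdir(exist_ok=True)
    iso_models = {m.transcript_id: m for m in bundle.models if m.biotype == "isoform"}
    best_orfs = orfs_from_table(iso_table)
    calls = [
        nmd_classifier.classify_nmd(iso_models[tid], orf, config.nmd_nt)
        for tid, orf in sorted(best_orfs.items())
        if tid in iso_models
    ]
    call_df = pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "orf_id": c.orf_id,
                "n_exons": c.n_exons,
                "last_junction_pos": c.last_junction_pos,
                "stop_end": c.stop_end,
                "d": c.d,
                "is_nmd": int(c.is_nmd),
            }
            for c in calls
        ]
    )
    write_tsv(call_df, stage_dir / "nmd_calls.tsv")
    nmd_summary: dict = {"threshold_nt": config.nmd_nt}
    if calls:
        n_nmd, n_total, pct = nmd_classifier.nmd_composition(calls)
        nmd_summary["all_isoforms"] = {"n_nmd": n_nmd, "n_total": n_total, "percent": pct}
        validated_iso_tids = {
            g.protein_id.rsplit(".", 1)[0]
            for g in groups
            if g.validated and g.source == "isoform_orf"
        }
        if validated_iso_tids & {c.transcript_id for c in calls}:
            n_nmd_v, n_total_v, pct_v = nmd_classifier.nmd_composition(
                calls, subset=validated_iso_tids
            )
            nmd_summary["validated_isoforms"] = {
                "n_nmd": n_nmd_v, "n_total": n_total_v, "percent": pct_v,
            }
    _write_json(nmd_summary, stage_dir / "nmd_summary.json")
    artifacts["nmd/nmd_calls.tsv"] = str(stage_dir / "nmd_calls.tsv")
    artifacts["nmd/nmd_summary.json"] = str(stage_dir / "nmd_summary.json")

    # --- domain comparison --------------------------------------------------
    from .domain_compare import classify_genes

    stage_dir = out / "domains"
    stage_dir.mkdir(exist_ok=True)
    validated_ids = {g.protein_id for g in groups if g.validated}
    categories, counts, skipped = classify_genes(
        bundle.domain_assignments, validated_ids=validated_ids
    )
    cat_df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "category": c.category,
                "isoform_ids": ";".join(c.isoform_ids),
            }
            for c in categories
        ],
        columns=["gene_id", "category", "isoform_ids"],
    )
    write_tsv(cat_df, stage_dir / "categories.tsv")
    _write_json(
        {"counts": counts, "n_genes_categorized": len(categories), "n_skipped": len(skipped)},
        stage_dir / "domain_summary.json",
    )
    artifacts["domains/categories.tsv"] = str(stage_dir / "categories.tsv")
    artifacts["domains/domain_summary.json"] = str(stage_dir / "domain_summary.json")

    # --- report -------------------------------------------------------------
    stage_dir = out / "report"
    stage_dir.mkdir(exist_ok=True)
    per_sample_sets = {
        s: {g.protein_id for g in groups if g.validated and g.spc_per_sample.get(s, 0) > 0}
        for s in SAMPLES
    }
    overlap = report.overlap_summary(per_sample_sets[SAMPLES[0]], per_sample_sets[SAMPLES[1]])
    n_lnc_validated = sum(
        1 for g in groups if g.validated and g.source == "lncrna_orf"
    )
    n_iso_validated = sum(
        1 for g in groups if g.validated and g.source == "isoform_orf"
    )
    n_iso_genes = len(
        {g.gene_id for g in groups if g.validated and g.source == "isoform_orf"}
    )
    n_isoforms_total = len(iso_models)
    validated_seqs = [
        target_db[g.protein_id] for g in groups if g.validated and g.protein_id in target_db
    ]
    hist = report.mw_histogram(validated_seqs) if validated_seqs else pd.DataFrame()
    write_tsv(hist, stage_dir / "mw_histogram.tsv")
    summary = {
        "thresholds": config.header(),
        "tissue_overlap": overlap.asdict(),
        "lncrna": {
            "n_validated": n_lnc_validated,
            "n_total": len(bundle.lncrna_seqs),
            "percent": percent(n_lnc_validated, len(bundle.lncrna_seqs), 2),
        },
        "isoforms": {
            "n_validated": n_iso_validated,
            "n_genes": n_iso_genes,
            "n_total": n_isoforms_total,
            "percent": percent(n_iso_validated, n_isoforms_total, 2)
            if n_isoforms_total
            else None,
        },
        "differential_expression": de_summary,
        "nmd": nmd_summary,
        "domain_counts": counts,
    }
    _write_json(summary, stage_dir / "summary.json")
    artifacts["report/summary.json"] = str(stage_dir / "summary.json")
    artifacts["report/mw_histogram.tsv"] = str(stage_dir / "mw_histogram.tsv")

    # --- manifest -----------------------------------------------------------
    manifest = {
        name: file_sha256(path) for name, path in sorted(artifacts.items())
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
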