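"""Self-contained toy study generator.

Builds a multi-exon toy genome with annotated genes, alternative isoforms,
lncRNAs, a known true proteome, and two-tissue PSM tables with reversed
decoys — everything the downstream stages consume, with a truth table that
makes every metric checkable.

Construction guarantees used by the truth tables:

* every coding transcript contains exactly one ATG, so its planted ORF is
  the only ORF the finder can report;
* noncoding lncRNAs contain no ATG at all;
* NMD status is realized geometrically (a junction placed >= 50 nt
  downstream of the planted stop, or not) and the truth label is computed
  from the realized junction arithmetic, independent of the classifier
  module;
* spectral counts are negative-binomial around abundance x length, decoy
  and planted-false-target scores share one shifted score distribution.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_compare import CAT_DISJOINT, CAT_IDENTICAL, CAT_PARTIAL, CAT_SUPERSET
from .io_formats import (
    DomainAssignment,
    PsmRecord,
    TranscriptModel,
    write_domain_table,
    write_fasta,
    write_gff3,
    write_psm_table,
    write_tsv,
)
from .peptide_engine import digest, reverse_decoy

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SAMPLES = ("seedling", "leaf")


@dataclass
class SimConfig:
    """All knobs of the toy study; one seed governs every draw."""

    seed: int = 1
    n_genes: int = 300
    n_lncrnas: int = 80
    mean_isoforms_per_gene: float = 1.5
    max_isoforms_per_gene: int = 4
    frac_genes_detected: float = 0.6
    frac_lncrna_coding: float = 0.5
    frac_isoform_nmd: float = 0.22
    frac_isoform_detected: float = 0.25
    frac_single_peptide: float = 0.06
    frac_forced_de: float = 0.12
    frac_false_targets: float = 0.08
    peptide_detect_prob: float = 0.6
    target_score_mean: float = 20.0
    score_sd: float = 2.0
    decoy_score_shift: float = 10.0
    spc_dispersion: float = 0.5
    spc_scale: float = 4.0
    tissue_effect_sd: float = 0.8

    def __post_init__(self) -> None:
        fracs = {
            "frac_genes_detected": self.frac_genes_detected,
            "frac_lncrna_coding": self.frac_lncrna_coding,
            "frac_isoform_nmd": self.frac_isoform_nmd,
            "frac_isoform_detected": self.frac_isoform_detected,
            "frac_single_peptide": self.frac_single_peptide,
            "frac_forced_de": self.frac_forced_de,
            "frac_false_targets": self.frac_false_targets,
            "peptide_detect_prob": self.peptide_detect_prob,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.spc_dispersion <= 0:
            raise ValueError("spc_dispersion must be > 0")


@dataclass
class SimBundle:
    """Everything the simulator produced, in memory."""

    config: SimConfig
    genome: dict[str, str]
    models: list[TranscriptModel]
    lncrna_seqs: dict[str, str]
    annotated_proteins: dict[str, str]
    transcript_truth: pd.DataFrame
    protein_truth: pd.DataFrame
    psms: dict[str, list[PsmRecord]] = field(default_factory=dict)
    false_peptides: set[str] = field(default_factory=set)
    domain_assignments: list[DomainAssignment] = field(default_factory=list)
    domain_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# sequence construction primitives
# ---------------------------------------------------------------------------

def _masked_random_seq(rng: np.random.Generator, n: int) -> str:
    """Random ACGT sequence guaranteed to contain no ATG."""
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return seq.replace("ATG", "ACG")  # C breaks the window, cannot create a new one


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) sense codons with no internal ATG, even across
    codon boundaries, and no in-frame stop. Ends without the stop codon."""
    parts = ["ATG"]
    tail = "TG"
    for _ in range(n_aa - 1):
        while True:
            codon = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
            if "ATG" not in tail + codon:
                break
        parts.append(codon)
        tail = codon[-2:]
    return "".join(parts)


def _build_mrna(
    rng: np.random.Generator, n_aa: int, utr5_len: int, utr3_len: int
) -> tuple[str, int, int]:
    """mRNA = 5'UTR + CDS + TAA + 3'UTR with exactly one ATG.

    Returns (mrna, orf_start, stop_end) in 0-based mRNA coordinates
    (stop_end exclusive).
    """
    utr5 = _masked_random_seq(rng, utr5_len)
    cds = _random_cds(rng, n_aa)
    utr3 = _masked_random_seq(rng, utr3_len)
    if utr3.startswith("TG"):  # TAA|TG.. would create a spanning ATG
        utr3 = "C" + utr3[1:]
    mrna = utr5 + cds + "TAA" + utr3
    return mrna, utr5_len, utr5_len + len(cds) + 3


_AA64 = "ACDEFGHLNPQSTVWY"  # no M (extra ATG), no K/R (tryptic sites), no I


def _random_false_peptide(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 15))
    body = "".join(_AA64[rng.integers(0, len(_AA64))] for _ in range(n))
    return body + ("K" if rng.integers(0, 2) == 0 else "R")


def translate_planted(cds_mrna: str, start: int, stop_end: int) -> str:
    """Translate the planted ORF (used only for the truth table)."""
    from .orf_finder import translate

    prot = translate(cds_mrna[start : stop_end - 3])
    return prot


# ---------------------------------------------------------------------------
# stage 1: genome, models, lncRNAs, true proteome
# ---------------------------------------------------------------------------

def _choose_junctions_non_nmd(
    rng: np.random.Generator, stop_end: int, mrna_len: int
) -> list[int]:
    """1-3 junctions, the last one < 50 nt past the stop -> not NMD."""
    hi = min(stop_end + 45, mrna_len - 10)
    candidates = np.arange(10, hi, 5)
    n = int(rng.integers(1, 4))
    n = min(n, len(candidates))
    return sorted(int(x) for x in rng.choice(candidates, size=n, replace=False))


def _choose_junctions_nmd(
    rng: np.random.Generator, stop_end: int, mrna_len: int, utr3_len: int
) -> list[int]:
    """Junctions with the last one >= 50 nt past the stop -> NMD."""
    body = np.arange(10, stop_end - 10, 5)
    n = int(rng.integers(0, 3))
    n = min(n, len(body))
    junctions = sorted(int(x) for x in rng.choice(body, size=n, replace=False)) if n else []
    delta = int(rng.integers(50, max(51, utr3_len - 30)))
    last = stop_end + delta
    assert last < mrna_len - 1
    junctions.append(last)
    return junctions


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class _ChromBuilder:
    """Lays transcript exon blocks onto a growing chromosome string."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.length = 0

    def _pad(self, n: int) -> None:
        self.parts.append(_masked_random_seq(self.rng, n))
        self.length += n

    def add_transcript(
        self, mrna: str, junctions: list[int], strand: str
    ) -> tuple[tuple[int, int], ...]:
        """Place one transcript; returns exons (1-based closed) in
        transcript 5'->3' orientation."""
        bounds = [0] + list(junctions) + [len(mrna)]
        segments = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
        if strand == "+":
            genomic_blocks = segments
        else:
            genomic_blocks = [_revcomp(s) for s in reversed(segments)]
        self._pad(int(self.rng.integers(30, 60)))
        exons_ascending: list[tuple[int, int]] = []
        for i, block in enumerate(genomic_blocks):
            if i:
                self._pad(int(self.rng.integers(20, 50)))
            start = self.length + 1  # 1-based
            self.parts.append(block)
            self.length += len(block)
            exons_ascending.append((start, self.length))
        if strand == "+":
            return tuple(exons_ascending)
        return tuple(reversed(exons_ascending))

    def sequence(self) -> str:
        return "".join(self.parts)


def simulate_genome_and_models(config: SimConfig) -> SimBundle:
    """Stage 1: genome FASTA, GFF3 gene models + isoforms, lncRNA FASTA,
    annotated proteome, and the transcript truth table."""
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    models: list[TranscriptModel] = []
    annotated: dict[str, str] = {}
    rows: list[dict] = []

    for gi in range(config.n_genes):
        gene_id = f"G{gi:04d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        builder = _ChromBuilder(rng)

        # primary transcript: always coding, never NMD
        n_aa = int(rng.integers(150, 400))
        utr5, utr3 = int(rng.integers(30, 80)), int(rng.integers(130, 250))
        mrna, orf_start, stop_end = _build_mrna(rng, n_aa, utr5, utr3)
        junctions = _choose_junctions_non_nmd(rng, stop_end, len(mrna))
        tid = f"{gene_id}.t1"
        exons = builder.add_transcript(mrna, junctions, strand)
        models.append(
            TranscriptModel(tid, gene_id, chrom, strand, exons, mrna, "annotated_mrna")
        )
        protein = translate_planted(mrna, orf_start, stop_end)
        annotated[gene_id] = protein
        rows.append(
            {
                "transcript_id": tid, "kind": "annotated_mrna", "gene_id": gene_id,
                "coding": 1, "protein_id": gene_id, "protein_length_aa": n_aa,
                "orf_start_nt": orf_start, "stop_end_nt": stop_end,
                "last_junction_nt": junctions[-1], "n_exons": len(junctions) + 1,
                "nmd_true": 0, "protein_seq": protein,
            }
        )

        # alternative isoforms with controlled NMD geometry
        n_iso = min(int(rng.poisson(config.mean_isoforms_per_gene)),
                    config.max_isoforms_per_gene)
        for k in range(n_iso):
            iso_id = f"{gene_id}.i{k + 1}"
            n_aa_i = int(rng.integers(110, 350))
            utr5_i, utr3_i = int(rng.integers(30, 80)), int(rng.integers(130, 250))
            mrna_i, orf_start_i, stop_end_i = _build_mrna(rng, n_aa_i, utr5_i, utr3_i)
            is_nmd = bool(rng.random() < config.frac_isoform_nmd)
            if is_nmd:
                j = _choose_junctions_nmd(rng, stop_end_i, len(mrna_i), utr3_i)
            else:
                j = _choose_junctions_non_nmd(rng, stop_end_i, len(mrna_i))
            exons_i = builder.add_transcript(mrna_i, j, strand)
            models.append(
                TranscriptModel(iso_id, gene_id, chrom, strand, exons_i, mrna_i, "isoform")
            )
            # truth label from realized geometry, not from intent
            d = j[-1] - stop_end_i
            nmd_true = int(len(j) >= 1 and d >= 50)
            assert nmd_true == int(is_nmd)
            protein_i = translate_planted(mrna_i, orf_start_i, stop_end_i)
            rows.append(
                {
                    "transcript_id": iso_id, "kind": "isoform", "gene_id": gene_id,
                    "coding": 1, "protein_id": f"{iso_id}.p1",
                    "protein_length_aa": n_aa_i,
                    "orf_start_nt": orf_start_i, "stop_end_nt": stop_end_i,
                    "last_junction_nt": j[-1], "n_exons": len(j) + 1,
                    "nmd_true": nmd_true, "protein_seq": protein_i,
                }
            )
        builder._pad(int(rng.integers(30, 60)))
        genome[chrom] = builder.sequence()

    lncrna_seqs: dict[str, str] = {}
    for li in range(config.n_lncrnas):
        lnc_id = f"LNC{li:04d}"
        coding = bool(rng.random() < config.frac_lncrna_coding)
        if coding:
            n_aa = int(rng.integers(105, 300))
            utr5, utr3 = int(rng.integers(20, 60)), int(rng.integers(40, 120))
            seq, orf_start, stop_end = _build_mrna(rng, n_aa, utr5, utr3)
            protein = translate_planted(seq, orf_start, stop_end)
            rows.append(
                {
                    "transcript_id": lnc_id, "kind": "lncrna", "gene_id": lnc_id,
                    "coding": 1, "protein_id": f"{lnc_id}.p1",
                    "protein_length_aa": n_aa,
                    "orf_start_nt": orf_start, "stop_end_nt": stop_end,
                    "last_junction_nt": -1, "n_exons": 1, "nmd_true": 0,
                    "protein_seq": protein,
                }
            )
        else:
            seq = _masked_random_seq(rng, int(rng.integers(400, 1200)))
            rows.append(
                {
                    "transcript_id": lnc_id, "kind": "lncrna", "gene_id": lnc_id,
                    "coding": 0, "protein_id": "", "protein_length_aa": 0,
                    "orf_start_nt": -1, "stop_end_nt": -1,
                    "last_junction_nt": -1, "n_exons": 1, "nmd_true": 0,
                    "protein_seq": "",
                }
            )
        lncrna_seqs[lnc_id] = seq

    truth = pd.DataFrame(rows)
    return SimBundle(
        config=config,
        genome=genome,
        models=models,
        lncrna_seqs=lncrna_seqs,
        annotated_proteins=annotated,
        transcript_truth=truth,
        protein_truth=pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# stage 2: PSM tables
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def simulate_psms(bundle: SimBundle) -> None:
    """Stage 2: per-tissue PSM tables plus the protein truth table.

    Fills ``bundle.psms``, ``bundle.protein_truth`` and
    ``bundle.false_peptides`` in place.
    """
    config = bundle.config
    rng = np.random.default_rng(config.seed + 1)
    truth = bundle.transcript_truth

    candidates = truth[truth["coding"] == 1].copy()
    detect_p = {
        "annotated_mrna": config.frac_genes_detected,
        "isoform": config.frac_isoform_detected,
        "lncrna": 1.0,  # every truth-coding lncRNA is detectable
    }
    protein_rows: list[dict] = []
    psms: dict[str, list[PsmRecord]] = {s: [] for s in SAMPLES}

    for row in candidates.itertuples(index=False):
        detected = bool(rng.random() < detect_p[row.kind])
        peptides = sorted(digest(row.protein_seq, missed_cleavages=0))
        if not peptides:
            detected = False
        forced_single = bool(detected and rng.random() < config.frac_single_peptide)
        base = float(np.exp(rng.normal(0.0, 1.0)))
        forced_de = bool(rng.random() < config.frac_forced_de)
        if forced_de:
            sign = 1.0 if rng.integers(0, 2) == 0 else -1.0
            lfc = sign * (2.0 + abs(rng.normal(0.0, 0.5)))
        else:
            lfc = float(rng.normal(0.0, config.tissue_effect_sd))
        abundance = {"seedling": base, "leaf": base * 2.0**lfc}

        observed: list[str] = []
        if detected:
            if forced_single:
                observed = [peptides[int(rng.integers(0, len(peptides)))]]
            else:
                mask = rng.random(len(peptides)) < config.peptide_detect_prob
                observed = [p for p, m in zip(peptides, mask) if m]
                if len(observed) < 2 and len(peptides) >= 2:
                    observed = [
                        peptides[i]
                        for i in sorted(rng.choice(len(peptides), size=2, replace=False))
                    ]
        emitted: set[str] = set()
        for sample in SAMPLES:
            for pep in observed:
                mean_spc = (
                    config.spc_scale
                    * abundance[sample]
                    * (row.protein_length_aa / 200.0)
                    / max(len(observed), 1)
                )
                spc = _nb_draw(rng, mean_spc, config.spc_dispersion)
                if spc < 1:
                    continue
                emitted.add(pep)
                psms[sample].append(
                    PsmRecord(
                        peptide=pep,
                        protein_candidates=(),
                        score=float(rng.normal(config.target_score_mean, config.score_sd)),
                        is_decoy=False,
                        sample=sample,
                        spectral_count=spc,
                    )
                )
        protein_rows.append(
            {
                "protein_id": row.protein_id,
                "gene_id": row.gene_id,
                "kind": row.kind,
                "transcript_id": row.transcript_id,
                "length_aa": row.protein_length_aa,
                "detected": int(detected),
                "forced_single_peptide": int(forced_single),
                "abundance_seedling": abundance["seedling"],
                "abundance_leaf": abundance["leaf"],
                "log2fc_true": lfc,
                "forced_de": int(forced_de),
                "n_digestible_peptides": len(peptides),
                "n_observed_peptides": len(emitted),
                "observed_peptides": ";".join(sorted(emitted)),
            }
        )

    n_true_rows = sum(len(v) for v in psms.values())
    n_null = max(1, int(round(config.frac_false_targets * n_true_rows)))
    null_score = config.target_score_mean - config.decoy_score_shift

    false_peptides: set[str] = set()
    for _ in range(n_null):
        pep = _random_false_peptide(rng)
        false_peptides.add(pep)
        sample = SAMPLES[int(rng.integers(0, 2))]
        psms[sample].append(
            PsmRecord(
                peptide=pep,
                protein_candidates=(),
                score=float(rng.normal(null_score, config.score_sd)),
                is_decoy=False,
                sample=sample,
                spectral_count=1,
            )
        )

    # decoy PSMs drawn from the pipeline's own reversed database
    seq_of = dict(zip(candidates["protein_id"], candidates["protein_seq"]))
    target_db = {r["protein_id"]: seq_of[r["protein_id"]] for r in protein_rows}
    decoy_db = {
        pid: seq for pid, seq in reverse_decoy(target_db).items()
        if pid.startswith("DECOY_")
    }
    decoy_pool = sorted(
        {pep for seq in decoy_db.values() for pep in digest(seq, missed_cleavages=0)}
    )
    for _ in range(n_null):
        pep = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
        sample = SAMPLES[int(rng.integers(0, 2))]
        psms[sample].append(
            PsmRecord(
                peptide=pep,
                protein_candidates=(),
                score=float(rng.normal(null_score, config.score_sd)),
                is_decoy=True,
                sample=sample,
                spectral_count=1,
            )
        )

    for sample in SAMPLES:
        psms[sample].sort(key=lambda p: (p.peptide, p.score))
    bundle.psms = psms
    bundle.false_peptides = false_peptides
    bundle.protein_truth = pd.DataFrame(protein_rows)


# ---------------------------------------------------------------------------
# stage 3: domain assignments with planted categories
# ---------------------------------------------------------------------------

_CATEGORY_PROPORTIONS = {
    CAT_SUPERSET: 0.35,
    CAT_PARTIAL: 0.22,
    CAT_DISJOINT: 0.16,
    CAT_IDENTICAL: 0.27,
}


def simulate_domains(bundle: SimBundle) -> None:
    """Stage 3: domain sets per isoform protein, planted so the
    most-divergent-pair rule recovers a known per-gene category."""
    config = bundle.config
    rng = np.random.default_rng(config.seed + 2)
    truth = bundle.transcript_truth
    iso = truth[truth["kind"] == "isoform"]
    cats = list(_CATEGORY_PROPORTIONS)
    probs = np.array([_CATEGORY_PROPORTIONS[c] for c in cats])
    assignments: list[DomainAssignment] = []
    truth_rows: list[dict] = []
    domain_counter = 0

    def fresh(n: int) -> list[str]:
        nonlocal domain_counter
        out = [f"PF{domain_counter + i:05d}" for i in range(n)]
        domain_counter += n
        return out

    for gene_id, group in iso.groupby("gene_id", sort=True):
        pids = sorted(f"{t}.p1" for t in group["transcript_id"])
        if len(pids) < 2:
            # single-isoform genes still get a domain row (uncategorizable)
            for pid in pids:
                assignments.append(
                    DomainAssignment(pid, str(gene_id), frozenset(fresh(2)))
                )
            continue
        category = cats[int(rng.choice(len(cats), p=probs))]
        if category == CAT_IDENTICAL:
            shared = frozenset(fresh(int(rng.integers(1, 4))))
            sets = [shared for _ in pids]
        elif category == CAT_SUPERSET:
            core = fresh(int(rng.integers(1, 3)))
            extra = fresh(int(rng.integers(1, 3)))
            sets = [frozenset(core + extra)] + [frozenset(core) for _ in pids[1:]]
        elif category == CAT_PARTIAL:
            a, b, c = fresh(1), fresh(1), fresh(1)
            sets = [frozenset(a + b)] + [frozenset(b + c) for _ in pids[1:]]
        else:  # disjoint
            a, b = fresh(1), fresh(1)
            sets = [frozenset(a)] + [frozenset(b) for _ in pids[1:]]
        for pid, s in zip(pids, sets):
            assignments.append(DomainAssignment(pid, str(gene_id), s))
        truth_rows.append({"gene_id": gene_id, "category": category})

    bundle.domain_assignments = assignments
    bundle.domain_truth = pd.DataFrame(truth_rows, columns=["gene_id", "category"])


# ---------------------------------------------------------------------------
# front door + files
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimBundle:
    """Run all three stages for one config."""
    bundle = simulate_genome_and_models(config)
    simulate_psms(bundle)
    simulate_domains(bundle)
    return bundle


def write_bundle(bundle: SimBundle, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write every artifact as plain text; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def register(name: str, path: Path) -> None:
        paths[name] = str(path)

    p = out / "genome.fa"
    write_fasta(dict(sorted(bundle.genome.items())), p)
    register("genome", p)

    p = out / "models.gff3"
    write_gff3(bundle.models, p)
    register("models", p)

    p = out / "lncrna.fa"
    write_fasta(dict(sorted(bundle.lncrna_seqs.items())), p)
    register("lncrna", p)

    p = out / "proteins_annotated.fa"
    write_fasta(dict(sorted(bundle.annotated_proteins.items())), p)
    register("annotated_proteins", p)

    p = out / "truth_transcripts.tsv"
    write_tsv(bundle.transcript_truth, p)
    register("truth_transcripts", p)

    p = out / "truth_proteins.tsv"
    write_tsv(bundle.protein_truth, p)
    register("truth_proteins", p)

    for sample in SAMPLES:
        p = out / f"psms_{sample}.tsv"
        write_psm_table(bundle.psms[sample], p)
        register(f"psms_{sample}", p)

    p = out / "truth_false_peptides.tsv"
    write_tsv(pd.DataFrame({"peptide": sorted(bundle.false_peptides)}), p)
    register("truth_false_peptides", p)

    p = out / "domains.tsv"
    write_domain_table(bundle.domain_assignments, p)
    register("domains", p)

    p = out / "truth_domains.tsv"
    write_tsv(bundle.domain_truth, p)
    register("truth_domains", p)

    p = out / "sim_config.json"
    with open(p, "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    register("sim_config", p)
    return paths


def file_sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
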