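"""Readers and writers for FASTA, GFF3 and the pipeline's TSV tables.

Genomic coordinates are 1-based closed (GFF3); transcript-internal
coordinates are 0-based half-open. All conversions go through
:mod:`proteoannot.coords`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import gff_to_internal, interval_length

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

PSM_COLUMNS = ("peptide", "protein_candidates", "score", "is_decoy", "sample", "spectral_count")
DOMAIN_COLUMNS = ("protein_id", "gene_id", "domains")

_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript.

    ``exons`` are genomic intervals (1-based, closed) ordered 5'→3' in
    transcript orientation: ascending genomic start on the plus strand,
    descending on the minus strand. ``spliced_seq`` is the mature mRNA,
    5'→3', or ``None`` when the genome has not been consulted yet.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    spliced_seq: str | None = None
    biotype: str = "annotated_mrna"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in ("annotated_mrna", "lncrna", "isoform"):
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.transcript_id}: zero-length exon [{s}, {e}]")
        starts = [s for s, _ in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not ordered 5'→3' for strand {self.strand}"
            )
        ivals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons [{s1},{e1}] and [{s2},{e2}]")
        if self.spliced_seq is not None and len(self.spliced_seq) != self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: spliced_seq length {len(self.spliced_seq)} "
                f"!= sum of exon lengths {self.spliced_length}"
            )

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(interval_length(s, e) for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def without_sequence(self) -> "TranscriptModel":
        return replace(self, spliced_seq=None)


@dataclass(frozen=True)
class DomainAssignment:
    """Domain identifiers assigned to one protein. May be empty."""

    protein_id: str
    gene_id: str
    domains: frozenset[str]


@dataclass
class PsmRecord:
    """One row of a peptide-spectrum-match table."""

    peptide: str
    protein_candidates: tuple[str, ...]
    score: float
    is_decoy: bool
    sample: str
    spectral_count: int
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: str | None = None) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercased).

    ``alphabet='nucleotide'`` rejects characters outside ACGTN;
    ``alphabet='protein'`` rejects characters outside the 20 residues + X*.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence ID {rec.id!r}")
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            bad = set(seq) - NUCLEOTIDE_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: sequence {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
                )
        elif alphabet == "protein":
            bad = set(seq) - STANDARD_RESIDUES - {"X", "*"}
            if bad:
                raise FormatError(
                    f"{path}: sequence {rec.id!r} contains non-residue characters {sorted(bad)}"
                )
        out[rec.id] = seq
    return out


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write sequences wrapped at 60 columns, in mapping order."""
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _prevalidate_gff3(path: str | os.PathLike) -> None:
    """Line-level checks that gffutils does not report with line numbers."""
    transcript_ids: set[str] = set()
    exon_lines: list[tuple[int, str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            ftype = fields[2]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if kv and "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                if "ID" not in attrs:
                    raise FormatError(f"{path}:{lineno}: mRNA feature without ID")
                transcript_ids.add(attrs["ID"])
            elif ftype == "exon":
                if end < start:
                    raise FormatError(f"{path}:{lineno}: zero-length exon [{start}, {end}]")
                parents = attrs.get("Parent", "")
                exon_lines.append((lineno, line, parents.split(",") if parents else []))
    for lineno, line, parents in exon_lines:
        if not parents:
            raise FormatError(f"{path}:{lineno}: exon with no Parent attribute: {line!r}")
        missing = [p for p in parents if p not in transcript_ids]
        if missing:
            raise FormatError(
                f"{path}:{lineno}: exon parent(s) {missing} not defined as mRNA/transcript"
            )


def read_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read gene models: one :class:`TranscriptModel` per mRNA/transcript feature.

    Exons are returned in transcript orientation (genomic-descending for the
    minus strand). ``spliced_seq`` is left unset.
    """
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    for ftype in ("mRNA", "transcript"):
        for mrna in db.features_of_type(ftype, order_by="start"):
            exons = sorted(
                ((ex.start, ex.end) for ex in db.children(mrna, featuretype="exon")),
                reverse=mrna.strand == "-",
            )
            if not exons:
                raise FormatError(f"{path}: transcript {mrna.id!r} has no exons")
            gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
            biotype = mrna.attributes.get("biotype", ["annotated_mrna"])[0]
            models.append(
                TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene_id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=tuple(exons),
                    biotype=biotype,
                )
            )
    models.sort(key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id))
    return models


def write_gff3(models: Sequence[TranscriptModel], path: str | os.PathLike) -> None:
    """Write gene, mRNA and exon features; round-trips through :func:`read_gff3`."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    def span(ms: Iterable[TranscriptModel]) -> tuple[int, int]:
        coords = [c for m in ms for iv in m.exons for c in iv]
        return min(coords), max(coords)
    for gene_id in sorted(by_gene):
        gms = by_gene[gene_id]
        gs, ge = span(gms)
        chrom, strand = gms[0].chrom, gms[0].strand
        buf.write(f"{chrom}\t.\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}\n")
        for m in sorted(gms, key=lambda m: m.transcript_id):
            ts, te = span([m])
            buf.write(
                f"{m.chrom}\t.\tmRNA\t{ts}\t{te}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id};biotype={m.biotype}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), start=1):
                buf.write(
                    f"{m.chrom}\t.\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def spliced_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Extract the mature mRNA (5'→3', uppercase) of ``model`` from ``genome``."""
    if model.chrom not in genome:
        raise FormatError(f"{model.transcript_id}: chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom].upper()
    parts: list[str] = []
    for s, e in sorted(model.exons):
        if s < 1 or e > len(chrom_seq):
            raise FormatError(
                f"{model.transcript_id}: exon [{s},{e}] outside {model.chrom} "
                f"(length {len(chrom_seq)})"
            )
        i, j = gff_to_internal(s, e)
        parts.append(chrom_seq[i:j])
    seq = "".join(parts)
    if model.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )


def read_psm_table(path: str | os.PathLike) -> list[PsmRecord]:
    """Read a PSM TSV into typed records; unknown columns go into ``extras``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PSM_COLUMNS, path)
    extra_cols = [c for c in df.columns if c not in PSM_COLUMNS]
    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        raw_decoy = d["is_decoy"]
        if raw_decoy in _TRUTHY:
            is_decoy = True
        elif raw_decoy in _FALSY:
            is_decoy = False
        else:
            raise FormatError(
                f"{path}: is_decoy value {raw_decoy!r} not in {{0,1,true,false}}"
            )
        cands = tuple(p for p in d["protein_candidates"].split(";") if p)
        records.append(
            PsmRecord(
                peptide=d["peptide"],
                protein_candidates=cands,
                score=float(d["score"]),
                is_decoy=is_decoy,
                sample=d["sample"],
                spectral_count=int(d["spectral_count"]),
                extras={c: d[c] for c in extra_cols},
            )
        )
    return records


def write_psm_table(records: Sequence[PsmRecord], path: str | os.PathLike) -> None:
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in records:
        row = {
            "peptide": rec.peptide,
            "protein_candidates": ";".join(rec.protein_candidates),
            "score": format(rec.score, ".6g"),
            "is_decoy": int(rec.is_decoy),
            "sample": rec.sample,
            "spectral_count": rec.spectral_count,
        }
        for c in extra_cols:
            row[c] = rec.extras.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(PSM_COLUMNS) + extra_cols)
    df.to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | os.PathLike) -> list[DomainAssignment]:
    """Read domain assignments (protein_id, gene_id, semicolon-joined domains)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DOMAIN_COLUMNS, path)
    seen: set[str] = set()
    out: list[DomainAssignment] = []
    for row in df.itertuples(index=False):
        if row.protein_id in seen:
            raise FormatError(f"{path}: duplicate protein_id {row.protein_id!r}")
        seen.add(row.protein_id)
        domains = frozenset(d for d in row.domains.split(";") if d)
        out.append(DomainAssignment(row.protein_id, row.gene_id, domains))
    return out


def write_domain_table(assignments: Sequence[DomainAssignment], path: str | os.PathLike) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "gene_id": a.gene_id,
            "domains": ";".join(sorted(a.domains)),
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as a TSV with header, no index."""
    df.to_csv(path, sep="\t", index=False)
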