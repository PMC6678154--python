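"""Candidate ORF extraction and translation of transcript databases.

Forward strand only, three frames; ORFs are ATG-initiated by default and
run to the first in-frame stop (or the transcript end, flagged
``has_stop=False``). Codons containing N translate to X, and X never
terminates an ORF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import NUCLEOTIDE_ALPHABET, FormatError

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TABLE = dict(standard_dna_table.forward_table)

#: default minimum ORF length (aa) for mRNA / isoform databases
MIN_AA_DEFAULT = 100
#: lncRNA filter is "> 100 aa", i.e. at least 101 residues
MIN_AA_LNCRNA = 101


@dataclass(frozen=True)
class OrfRecord:
    """A candidate coding region in transcript (0-based half-open) coordinates.

    ``stop_nt`` is exclusive: the end of the stop codon when ``has_stop``,
    otherwise the end of the last complete codon.
    """

    orf_id: str
    transcript_id: str
    frame: int
    start_nt: int
    stop_nt: int
    protein_seq: str
    has_stop: bool
    length_aa: int


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing N gives X."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    try:
        return _CODON_TABLE[codon]
    except KeyError as exc:
        raise ValueError(f"untranslatable codon {codon!r}") from exc


def translate(seq: str) -> str:
    """Translate complete codons of ``seq``; stops become '*'."""
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3))


def find_orfs(
    seq: str,
    min_aa: int = 1,
    transcript_id: str = "",
    require_atg: bool = True,
) -> list[OrfRecord]:
    """Find ATG-initiated ORFs in all three forward frames.

    Nested ORFs sharing a stop are reduced to the one with the most 5' ATG.
    Results are sorted by ``length_aa`` descending, ties by ``start_nt``
    ascending. With ``require_atg=False`` each frame additionally yields a
    5'-partial ORF starting at the frame's first codon.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = seq.upper()
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters {sorted(bad)}")
    found: list[tuple[int, int, int, str, bool]] = []  # (frame, start, stop, protein, has_stop)

    for frame in range(3):
        start: int | None = frame if not require_atg else None
        residues: list[str] = []
        pos = frame
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            aa = translate_codon(codon)
            if aa == "*":
                if start is not None:
                    found.append((frame, start, pos + 3, "".join(residues), True))
                start = None
                residues = []
            else:
                if start is None and codon == "ATG":
                    start = pos
                if start is not None:
                    residues.append(aa)
            pos += 3
        if start is not None and residues:
            found.append((frame, start, pos, "".join(residues), False))

    records = [
        OrfRecord(
            orf_id="",
            transcript_id=transcript_id,
            frame=frame,
            start_nt=start,
            stop_nt=stop,
            protein_seq=protein,
            has_stop=has_stop,
            length_aa=len(protein),
        )
        for frame, start, stop, protein, has_stop in found
        if len(protein) >= min_aa
    ]
    records.sort(key=lambda r: (-r.length_aa, r.start_nt))
    return [
        OrfRecord(
            orf_id=f"{transcript_id}.p{i}" if transcript_id else f"p{i}",
            transcript_id=r.transcript_id,
            frame=r.frame,
            start_nt=r.start_nt,
            stop_nt=r.stop_nt,
            protein_seq=r.protein_seq,
            has_stop=r.has_stop,
            length_aa=r.length_aa,
        )
        for i, r in enumerate(records, start=1)
    ]


def min_aa_for_biotype(biotype: str) -> int:
    return MIN_AA_LNCRNA if biotype == "lncrna" else MIN_AA_DEFAULT


def translate_database(
    transcripts: Mapping[str, str],
    biotype: str,
    min_aa: int | None = None,
    require_atg: bool = True,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Translate a transcript database into candidate proteins.

    Returns ``(proteins, orf_table)`` where ``proteins`` maps protein IDs
    (``<transcript_id>.p<k>``) to amino-acid sequences and ``orf_table``
    has one row per retained ORF. For lncRNAs the length filter is strictly
    greater than 100 aa; mRNA/isoform databases keep all ORFs of >= 100 aa,
    multiple per transcript.
    """
    if biotype not in ("annotated_mrna", "lncrna", "isoform"):
        raise ValueError(f"unknown biotype {biotype!r}")
    if min_aa is None:
        min_aa = min_aa_for_biotype(biotype)
    seen: set[str] = set()
    proteins: dict[str, str] = {}
    rows: list[dict] = []
    for tid, seq in transcripts.items():
        if tid in seen:
            raise FormatError(f"duplicate transcript ID {tid!r}")
        seen.add(tid)
        for orf in find_orfs(seq, min_aa=min_aa, transcript_id=tid, require_atg=require_atg):
            proteins[orf.orf_id] = orf.protein_seq
            rows.append(
                {
                    "orf_id": orf.orf_id,
                    "transcript_id": tid,
                    "biotype": biotype,
                    "frame": orf.frame,
                    "start_nt": orf.start_nt,
                    "stop_nt": orf.stop_nt,
                    "has_stop": int(orf.has_stop),
                    "length_aa": orf.length_aa,
                    "protein_seq": orf.protein_seq,
                }
            )
    columns = [
        "orf_id", "transcript_id", "biotype", "frame", "start_nt",
        "stop_nt", "has_stop", "length_aa", "protein_seq",
    ]
    return proteins, pd.DataFrame(rows, columns=columns)


def read_orf_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "orf_id": str})
    required = {"orf_id", "transcript_id", "start_nt", "stop_nt", "has_stop", "length_aa"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing ORF table column(s) {sorted(missing)}")
    return df
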