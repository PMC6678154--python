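"""NMD classification by the 50-nt last-junction rule.

A transcript is classified NMD-targeted when its stop codon ends at least
``threshold_nt`` (default 50) nucleotides upstream of the last exon-exon
junction, measured in mature-mRNA coordinates. Single-exon transcripts
have no junction and are never NMD; so are ORFs without a stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import TranscriptModel
from .orf_finder import OrfRecord
from .rounding import percent

NMD_THRESHOLD_NT = 50


@dataclass(frozen=True)
class NmdCall:
    transcript_id: str
    orf_id: str
    n_exons: int
    last_junction_pos: int  # mature-mRNA coordinate of the last junction
    stop_end: int  # exclusive end of the stop codon in mature mRNA
    d: int  # last_junction_pos - stop_end; negative when stop is downstream
    is_nmd: bool


def last_junction_position(model: TranscriptModel) -> int | None:
    """Spliced-coordinate position of the last exon-exon junction, i.e. the
    cumulative length of all exons except the last; None for single-exon."""
    if model.n_exons < 2:
        return None
    return sum(model.exon_lengths[:-1])


def classify_nmd(
    model: TranscriptModel,
    orf: OrfRecord,
    threshold_nt: int = NMD_THRESHOLD_NT,
) -> NmdCall:
    if orf.transcript_id and orf.transcript_id != model.transcript_id:
        raise ValueError(
            f"ORF {orf.orf_id!r} belongs to {orf.transcript_id!r}, "
            f"not {model.transcript_id!r}"
        )
    if orf.stop_nt > model.spliced_length:
        raise ValueError(
            f"{orf.orf_id!r}: stop_nt {orf.stop_nt} exceeds spliced length "
            f"{model.spliced_length} of {model.transcript_id!r}"
        )
    junction = last_junction_position(model)
    stop_end = orf.stop_nt
    if junction is None:
        d = 0 - stop_end  # no junction; d only reported for audit
        is_nmd = False
    else:
        d = junction - stop_end
        is_nmd = bool(orf.has_stop and d >= threshold_nt)
    return NmdCall(
        transcript_id=model.transcript_id,
        orf_id=orf.orf_id,
        n_exons=model.n_exons,
        last_junction_pos=junction if junction is not None else -1,
        stop_end=stop_end,
        d=d,
        is_nmd=is_nmd,
    )


def nmd_composition(
    calls: Sequence[NmdCall] | Sequence[bool],
    subset: Iterable[str] | None = None,
) -> tuple[int, int, float]:
    """(n_nmd, n_total, percent to one decimal) of a set of calls.

    ``subset`` restricts to the given transcript IDs. Accepts either
    NmdCall objects or plain booleans (printed-count arithmetic).
    """
    items = list(calls)
    if items and isinstance(items[0], NmdCall):
        if subset is not None:
            wanted = set(subset)
            items = [c for c in items if c.transcript_id in wanted]
        flags = [c.is_nmd for c in items]
    else:
        flags = [bool(c) for c in items]
    if not flags:
        raise ValueError("empty call set")
    n_nmd = sum(flags)
    n_total = len(flags)
    return n_nmd, n_total, percent(n_nmd, n_total, decimals=1)
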