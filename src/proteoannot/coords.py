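"""Coordinate conventions and conversions.

Two dialects are used package-wide:

* **Genomic** coordinates are 1-based, fully closed — the GFF3 convention.
  An exon annotated ``start=101 end=200`` spans 100 bases.
* **Transcript-internal** (mature mRNA) coordinates are 0-based, half-open —
  the Python slicing convention. ORF starts/stops and NMD distances live
  in this space.

Every conversion between the two goes through the two helpers below so an
off-by-one can only exist in one place.
"""

from __future__ import annotations

Interval = tuple[int, int]


def gff_to_internal(start: int, end: int) -> Interval:
    """Convert a 1-based closed interval to 0-based half-open.

    >>> gff_to_internal(101, 200)
    (100, 200)
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based closed interval [{start}, {end}]")
    return start - 1, end


def internal_to_gff(start: int, end: int) -> Interval:
    """Convert a 0-based half-open interval to 1-based closed.

    >>> internal_to_gff(100, 200)
    (101, 200)
    """
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based half-open interval [{start}, {end})")
    return start + 1, end


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based closed genomic interval."""
    if end < start:
        raise ValueError(f"invalid interval [{start}, {end}]")
    return end - start + 1
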