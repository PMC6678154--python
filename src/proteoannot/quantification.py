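"""NSAF label-free quantification and two-sample differential expression.

NSAF for protein *i* in a sample is (SpC_i / L_i) / sum_j (SpC_j / L_j),
so values sum to one per sample. Fold changes are computed on a
pseudocounted variant (SpC + 0.5) so tissue-specific proteins get finite
calls; the pseudocount never touches the reported NSAF values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .peptide_engine import ProteinGroup

#: fold-change thresholds for the up / down calls
UP_FC = 4.0
DOWN_FC = 0.25
PSEUDOCOUNT = 0.5

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_NOT_QUANT = "not_quantifiable"


class QuantError(RuntimeError):
    pass


@dataclass
class QuantRow:
    protein_id: str
    gene_id: str
    source: str
    length_aa: int
    spc: dict[str, int]
    n_peptides: dict[str, int]
    saf: dict[str, float] = field(default_factory=dict)
    nsaf: dict[str, float] = field(default_factory=dict)
    fold_change: float | None = None
    log2fc: float | None = None
    call: str = CALL_NOT_QUANT


def make_rows(groups: Sequence[ProteinGroup], validated_only: bool = True) -> list[QuantRow]:
    rows = []
    for g in groups:
        if validated_only and not g.validated:
            continue
        rows.append(
            QuantRow(
                protein_id=g.protein_id,
                gene_id=g.gene_id,
                source=g.source,
                length_aa=g.length_aa,
                spc=dict(g.spc_per_sample),
                n_peptides=dict(g.n_peptides_per_sample),
            )
        )
    return rows


def nsaf(rows: Sequence[QuantRow], sample: str) -> None:
    """Fill ``saf`` and ``nsaf`` for ``sample`` in place.

    Proteins with zero SpC in the sample get nsaf 0 (they contribute
    nothing to the denominator).
    """
    if not rows:
        raise QuantError(f"nothing quantified in sample {sample!r}")
    for row in rows:
        if row.length_aa <= 0:
            raise QuantError(f"{row.protein_id}: non-positive length")
        row.saf[sample] = row.spc.get(sample, 0) / row.length_aa
    total = sum(row.saf[sample] for row in rows)
    if total == 0:
        raise QuantError(f"nothing quantified in sample {sample!r}")
    for row in rows:
        row.nsaf[sample] = row.saf[sample] / total


def differential(
    rows: Sequence[QuantRow],
    sample_a: str,
    sample_b: str,
    min_peptides: int = 2,
    up_fc: float = UP_FC,
    down_fc: float = DOWN_FC,
    pseudocount: float = PSEUDOCOUNT,
) -> dict:
    """Call differential expression of ``sample_b`` relative to ``sample_a``.

    Fold change is the ratio of pseudocounted NSAF values; proteins with
    fewer than ``min_peptides`` distinct peptides in both samples are
    ``not_quantifiable``. Boundary inclusive: fc >= up_fc is up,
    fc <= down_fc is down. Returns a summary dict with the call counts.
    """
    if not rows:
        raise QuantError("no rows to test")
    totals = {}
    for sample in (sample_a, sample_b):
        totals[sample] = sum(
            (row.spc.get(sample, 0) + pseudocount) / row.length_aa for row in rows
        )
    n_up = n_down = n_unchanged = n_not_quant = 0
    for row in rows:
        pn_a = ((row.spc.get(sample_a, 0) + pseudocount) / row.length_aa) / totals[sample_a]
        pn_b = ((row.spc.get(sample_b, 0) + pseudocount) / row.length_aa) / totals[sample_b]
        row.fold_change = pn_b / pn_a
        row.log2fc = math.log2(row.fold_change)
        quantifiable = (
            row.n_peptides.get(sample_a, 0) >= min_peptides
            or row.n_peptides.get(sample_b, 0) >= min_peptides
        )
        if not quantifiable:
            row.call = CALL_NOT_QUANT
            n_not_quant += 1
        elif row.fold_change >= up_fc:
            row.call = CALL_UP
            n_up += 1
        elif row.fold_change <= down_fc:
            row.call = CALL_DOWN
            n_down += 1
        else:
            row.call = CALL_UNCHANGED
            n_unchanged += 1
    return {
        "sample_a": sample_a,
        "sample_b": sample_b,
        "n_up": n_up,
        "n_down": n_down,
        "n_total_de": n_up + n_down,
        "n_unchanged": n_unchanged,
        "n_not_quantifiable": n_not_quant,
        "n_tested": len(rows),
    }


def sample_correlation(
    rows: Sequence[QuantRow],
    sample_a: str,
    sample_b: str,
    method: str = "pearson",
) -> float:
    """Correlation of log10 NSAF over proteins nonzero in both samples."""
    pairs = [
        (row.nsaf[sample_a], row.nsaf[sample_b])
        for row in rows
        if row.nsaf.get(sample_a, 0) > 0 and row.nsaf.get(sample_b, 0) > 0
    ]
    if len(pairs) < 3:
        raise QuantError(
            f"need >= 3 proteins quantified in both samples, got {len(pairs)}"
        )
    x = np.log10([a for a, _ in pairs])
    y = np.log10([b for _, b in pairs])
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)
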