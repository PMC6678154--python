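"""Summary surfaces: set overlaps, molecular weights, enrichment.

Every number here is recomputed from upstream tables; nothing is cached.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rounding import integer_percent

# Average residue masses (Da); intact-protein MW = sum + one water.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    n_a_specific: int
    n_b_specific: int
    share_intersection_of_a: int  # integer percent
    share_intersection_of_b: int

    def asdict(self) -> dict:
        return asdict(self)


def overlap_summary(set_a: Iterable, set_b: Iterable) -> OverlapSummary:
    """Exact set arithmetic for a two-sample Venn, shares as integer percents."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    summary = OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_union=len(a | b),
        n_a_specific=len(a - inter),
        n_b_specific=len(b - inter),
        share_intersection_of_a=integer_percent(len(inter), len(a)) if a else 0,
        share_intersection_of_b=integer_percent(len(inter), len(b)) if b else 0,
    )
    # Venn identities, asserted on every run
    assert summary.n_union == summary.n_a + summary.n_b - summary.n_intersection
    assert summary.n_a_specific == summary.n_a - summary.n_intersection
    assert summary.n_b_specific == summary.n_b - summary.n_intersection
    return summary


def molecular_weight(protein_seq: str, kda: bool = True) -> float:
    """Average (not monoisotopic) molecular weight of an intact protein."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    seq = protein_seq.upper()
    mass = WATER_MASS
    for aa in seq:
        try:
            mass += AVERAGE_RESIDUE_MASS[aa]
        except KeyError as exc:
            raise ValueError(f"nonstandard residue {aa!r}") from exc
    return mass / 1000.0 if kda else mass


def mw_histogram(
    protein_seqs: Iterable[str], bin_width_kda: float = 5.0
) -> pd.DataFrame:
    """Histogram of protein molecular weights in fixed-width kDa bins."""
    weights = [molecular_weight(s) for s in protein_seqs]
    if not weights:
        raise ValueError("no proteins")
    top = max(weights)
    edges = np.arange(0.0, top + bin_width_kda, bin_width_kda)
    counts, edges = np.histogram(weights, bins=edges)
    return pd.DataFrame(
        {"bin_low_kda": edges[:-1], "bin_high_kda": edges[1:], "count": counts}
    )


def hypergeom_enrich(
    term_sets: Mapping[str, Iterable],
    selected: Iterable,
    universe: Iterable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in ``selected``.

    p = P[X >= k] with population N = |universe|, K = |term|, draws
    n = |selected|. Terms with raw p < ``alpha`` are flagged enriched;
    Benjamini-Hochberg adjusted values are emitted alongside as an
    auxiliary column (the raw cutoff is the headline filter).
    """
    uni = set(universe)
    sel = set(selected)
    if not uni or not sel:
        raise ValueError("empty universe or selection")
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for term in sorted(term_sets):
        genes = set(term_sets[term]) & uni
        k = len(genes & sel)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(genes), len(sel)))
        rows.append({"term": term, "k": k, "K": len(genes), "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "p_value"])
    if len(df):
        df["p_bh"] = stats.false_discovery_control(df["p_value"].to_numpy())
        df["enriched"] = df["p_value"] < alpha
    else:
        df["p_bh"] = []
        df["enriched"] = []
    return df


def de_summary_counts(calls: Sequence[str]) -> dict:
    """Tally of differential-expression calls with the total-DE identity."""
    n_up = sum(1 for c in calls if c == "up")
    n_down = sum(1 for c in calls if c == "down")
    return {"n_up": n_up, "n_down": n_down, "n_total_de": n_up + n_down}
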