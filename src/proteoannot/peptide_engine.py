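"""In-silico tryptic digestion, peptide matching and target-decoy validation.

The stages here turn a PSM table plus candidate protein databases into a
validated protein list: score-based FDR filtering against reversed decoys,
substring peptide-to-protein matching with I/L equivalence, and the
two-peptide inference rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import PsmRecord

#: default peptide length window (aa) for digestion products
PEPTIDE_LEN_RANGE = (7, 50)

DECOY_PREFIX = "DECOY_"

_IL_COLLAPSE = str.maketrans("I", "L")


class FdrError(RuntimeError):
    """Raised when no identifications survive at the requested FDR."""


def collapse_il(peptide: str) -> str:
    """Collapse isobaric I/L to L — MS cannot distinguish them."""
    return peptide.upper().translate(_IL_COLLAPSE)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def cleavage_sites(protein_seq: str, suppress_proline: bool = True) -> list[int]:
    """0-based positions after which trypsin cleaves (after K/R, not before P)."""
    seq = protein_seq.upper()
    sites = []
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and not (suppress_proline and seq[i + 1] == "P"):
            sites.append(i)
    return sites


def digest(
    protein_seq: str,
    missed_cleavages: int = 2,
    min_len: int = PEPTIDE_LEN_RANGE[0],
    max_len: int = PEPTIDE_LEN_RANGE[1],
    suppress_proline: bool = True,
) -> set[str]:
    """Tryptic digestion: all products with 0..``missed_cleavages`` internal
    missed sites, length-filtered to [min_len, max_len]. Terminal peptides
    are included; the empty protein digests to the empty set.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = protein_seq.upper()
    if not seq:
        return set()
    cuts = [0] + [i + 1 for i in cleavage_sites(seq, suppress_proline)] + [len(seq)]
    fragments = [seq[a:b] for a, b in zip(cuts, cuts[1:])]
    peptides: set[str] = set()
    for i in range(len(fragments)):
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            pep = "".join(fragments[i : j + 1])
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return peptides


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def reverse_decoy(db: Mapping[str, str]) -> dict[str, str]:
    """Concatenated target+decoy database: each entry appended reversed
    under a ``DECOY_`` ID. Output has exactly twice the input entries."""
    for pid in db:
        if pid.startswith(DECOY_PREFIX):
            raise ValueError(f"database already contains decoy ID {pid!r}")
    out = dict(db)
    for pid, seq in db.items():
        out[DECOY_PREFIX + pid] = seq[::-1]
    return out


# ---------------------------------------------------------------------------
# target-decoy FDR
# ---------------------------------------------------------------------------

def td_score_cutoff(
    scores: Sequence[float], is_decoy: Sequence[bool], fdr_threshold: float
) -> float:
    """Smallest score cutoff ``s`` with ``#decoy(>=s) / #target(>=s) < fdr``.

    Estimator is D/T; ties are accepted at the cutoff score.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    if len(scores) != len(is_decoy) or not scores:
        raise ValueError("scores and is_decoy must be equal-length and nonempty")
    order = sorted(range(len(scores)), key=lambda i: scores[i], reverse=True)
    best: float | None = None
    n_target = n_decoy = 0
    k = 0
    n = len(order)
    while k < n:
        s = scores[order[k]]
        # absorb the whole tie group at score s
        while k < n and scores[order[k]] == s:
            if is_decoy[order[k]]:
                n_decoy += 1
            else:
                n_target += 1
            k += 1
        if n_target > 0 and n_decoy / n_target < fdr_threshold:
            best = s  # keep lowering the cutoff while FDR stays under threshold
    if best is None:
        raise FdrError("no identifications at requested FDR")
    return best


def fdr_filter(
    psms: Sequence[PsmRecord], fdr_threshold: float = 0.01
) -> tuple[list[PsmRecord], float]:
    """Filter PSMs at the given target-decoy FDR.

    Returns the accepted target PSMs (decoys removed) and the score cutoff.
    """
    cutoff = td_score_cutoff(
        [p.score for p in psms], [p.is_decoy for p in psms], fdr_threshold
    )
    accepted = [p for p in psms if not p.is_decoy and p.score >= cutoff]
    return accepted, cutoff


def protein_fdr_filter(
    best_scores: Mapping[str, float], fdr_threshold: float = 0.01
) -> tuple[set[str], float]:
    """Protein-level pass: proteins scored by their best peptide, decoy
    status taken from the ``DECOY_`` ID prefix."""
    ids = sorted(best_scores)
    cutoff = td_score_cutoff(
        [best_scores[i] for i in ids],
        [i.startswith(DECOY_PREFIX) for i in ids],
        fdr_threshold,
    )
    accepted = {
        i for i in ids if not i.startswith(DECOY_PREFIX) and best_scores[i] >= cutoff
    }
    return accepted, cutoff


# ---------------------------------------------------------------------------
# peptide-to-database matching
# ---------------------------------------------------------------------------

UNIQ_ISOFORM = "isoform_unique"
UNIQ_GENE = "gene_unique"
UNIQ_SHARED = "shared"
UNIQ_UNMAPPED = "unmapped"


@dataclass
class PeptideEvidence:
    """Aggregated evidence for one peptide (I/L-collapsed key)."""

    peptide_key: str
    raw_peptide: str
    samples: dict[str, int]  # sample -> spectral count
    best_score: float
    is_decoy: bool = False
    mapped_proteins: frozenset[str] = frozenset()
    uniqueness: str = UNIQ_UNMAPPED


@dataclass
class ProteinGroup:
    """A candidate protein with its supporting peptide evidence."""

    protein_id: str
    gene_id: str
    source: str  # annotated | lncrna_orf | isoform_orf
    length_aa: int
    peptides: set[str] = field(default_factory=set)
    spc_per_sample: dict[str, int] = field(default_factory=dict)
    n_peptides_per_sample: dict[str, int] = field(default_factory=dict)
    n_isoform_unique: int = 0
    best_score: float = float("-inf")
    validated: bool = False

    @property
    def n_distinct_peptides(self) -> int:
        return len(self.peptides)


def aggregate_evidence(psms: Iterable[PsmRecord]) -> list[PeptideEvidence]:
    """Collapse accepted PSM rows to per-peptide evidence, summing spectral
    counts per sample and keeping the best score."""
    by_key: dict[str, PeptideEvidence] = {}
    for psm in psms:
        key = collapse_il(psm.peptide)
        ev = by_key.get(key)
        if ev is None:
            ev = PeptideEvidence(
                peptide_key=key,
                raw_peptide=psm.peptide,
                samples={},
                best_score=psm.score,
                is_decoy=psm.is_decoy,
            )
            by_key[key] = ev
        ev.samples[psm.sample] = ev.samples.get(psm.sample, 0) + psm.spectral_count
        ev.best_score = max(ev.best_score, psm.score)
    return [by_key[k] for k in sorted(by_key)]


def match_peptides(
    evidence: Sequence[PeptideEvidence],
    databases: Mapping[str, Mapping[str, str]],
    protein_to_gene: Mapping[str, str],
) -> list[PeptideEvidence]:
    """Map peptides to proteins by I/L-collapsed substring search.

    ``databases`` maps source name (``annotated``, ``lncrna_orf``,
    ``isoform_orf``) to ``{protein_id: sequence}``. Uniqueness:
    ``isoform_unique`` — exactly one protein; ``gene_unique`` — several
    proteins, all of one gene; ``shared`` — proteins of more than one gene
    (a hit in both an annotated protein and a lncRNA ORF is shared and does
    not validate the lncRNA). Unmatched peptides are retained, flagged
    ``unmapped``.
    """
    collapsed: list[tuple[str, str, str]] = []  # (protein_id, source, collapsed seq)
    for source in sorted(databases):
        for pid, seq in databases[source].items():
            if pid not in protein_to_gene:
                raise KeyError(f"protein {pid!r} has no gene mapping")
            collapsed.append((pid, source, collapse_il(seq)))
    out: list[PeptideEvidence] = []
    for ev in evidence:
        hits = frozenset(pid for pid, _, seq in collapsed if ev.peptide_key in seq)
        genes = {protein_to_gene[pid] for pid in hits}
        if not hits:
            uniqueness = UNIQ_UNMAPPED
        elif len(genes) > 1:
            uniqueness = UNIQ_SHARED
        elif len(hits) == 1:
            uniqueness = UNIQ_ISOFORM
        else:
            uniqueness = UNIQ_GENE
        out.append(
            PeptideEvidence(
                peptide_key=ev.peptide_key,
                raw_peptide=ev.raw_peptide,
                samples=dict(ev.samples),
                best_score=ev.best_score,
                is_decoy=ev.is_decoy,
                mapped_proteins=hits,
                uniqueness=uniqueness,
            )
        )
    return out


def infer_proteins(
    evidence: Sequence[PeptideEvidence],
    databases: Mapping[str, Mapping[str, str]],
    protein_to_gene: Mapping[str, str],
    min_peptides: int = 2,
) -> list[ProteinGroup]:
    """Two-peptide protein inference.

    A protein is validated with >= ``min_peptides`` distinct peptide keys;
    lncRNA/isoform ORFs additionally need >= 1 isoform-unique peptide
    (shared peptides cannot distinguish isoforms). Spectral counts of
    shared peptides count toward annotated (gene-level) groups but only
    isoform-unique peptides count toward isoform-level spectral counts,
    so isoform NSAF is never double-counted.
    """
    groups: dict[str, ProteinGroup] = {}
    source_of: dict[str, str] = {}
    for source in sorted(databases):
        for pid, seq in databases[source].items():
            source_of[pid] = source
            groups[pid] = ProteinGroup(
                protein_id=pid,
                gene_id=protein_to_gene[pid],
                source=source,
                length_aa=len(seq),
            )
    pep_sets_per_sample: dict[str, dict[str, set[str]]] = {pid: {} for pid in groups}
    for ev in evidence:
        for pid in sorted(ev.mapped_proteins):
            g = groups[pid]
            isoform_level = g.source != "annotated"
            quantifiable = (not isoform_level) or ev.uniqueness == UNIQ_ISOFORM
            g.peptides.add(ev.peptide_key)
            g.best_score = max(g.best_score, ev.best_score)
            if ev.uniqueness == UNIQ_ISOFORM:
                g.n_isoform_unique += 1
            if quantifiable:
                for sample, spc in ev.samples.items():
                    g.spc_per_sample[sample] = g.spc_per_sample.get(sample, 0) + spc
                    pep_sets_per_sample[pid].setdefault(sample, set()).add(ev.peptide_key)
    result: list[ProteinGroup] = []
    for pid in sorted(groups):
        g = groups[pid]
        if not g.peptides:
            continue
        g.n_peptides_per_sample = {
            s: len(peps) for s, peps in sorted(pep_sets_per_sample[pid].items())
        }
        g.validated = g.n_distinct_peptides >= min_peptides and (
            g.source == "annotated" or g.n_isoform_unique >= 1
        )
        result.append(g)
    return result
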