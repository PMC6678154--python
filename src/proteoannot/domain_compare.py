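"""Domain-composition comparison of a gene's validated protein isoforms.

Four categories of pairwise set relation between isoform domain sets:
superset (one isoform carries all of the other's domains plus more),
partial overlap, disjoint, identical. Genes with more than two isoforms
take the label of their most divergent pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainAssignment

CAT_SUPERSET = "1_superset"
CAT_PARTIAL = "2_partial_overlap"
CAT_DISJOINT = "3_disjoint"
CAT_IDENTICAL = "4_identical"

CATEGORIES = (CAT_SUPERSET, CAT_PARTIAL, CAT_DISJOINT, CAT_IDENTICAL)

#: similarity order: identical > superset > partial overlap > disjoint.
#: The gene-level label is the minimum over pairs under this order.
_DIVERGENCE = {CAT_IDENTICAL: 0, CAT_SUPERSET: 1, CAT_PARTIAL: 2, CAT_DISJOINT: 3}


@dataclass(frozen=True)
class DomainCategory:
    gene_id: str
    isoform_ids: tuple[str, ...]
    category: str
    domain_sets: tuple[frozenset[str], ...]
    pair_relations: tuple[tuple[str, str, str], ...]  # (id_a, id_b, category)


def classify_domain_relation(a: Iterable[str], b: Iterable[str]) -> str:
    """Relation of two nonempty domain sets; copy number is ignored."""
    sa, sb = frozenset(a), frozenset(b)
    if not sa or not sb:
        raise ValueError("no domains assigned")
    if sa == sb:
        return CAT_IDENTICAL
    if sa < sb or sb < sa:
        return CAT_SUPERSET
    if sa.isdisjoint(sb):
        return CAT_DISJOINT
    return CAT_PARTIAL


def classify_gene(assignments: Sequence[DomainAssignment]) -> DomainCategory:
    """Categorize one gene from >= 2 isoforms that each have >= 1 domain."""
    usable = [a for a in assignments if a.domains]
    if len(usable) < 2:
        raise ValueError(
            f"gene needs >= 2 isoforms with domains, got {len(usable)}"
        )
    genes = {a.gene_id for a in usable}
    if len(genes) != 1:
        raise ValueError(f"assignments span multiple genes: {sorted(genes)}")
    usable = sorted(usable, key=lambda a: a.protein_id)
    pairs: list[tuple[str, str, str]] = []
    worst = CAT_IDENTICAL
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            rel = classify_domain_relation(a.domains, b.domains)
            pairs.append((a.protein_id, b.protein_id, rel))
            if _DIVERGENCE[rel] > _DIVERGENCE[worst]:
                worst = rel
    return DomainCategory(
        gene_id=usable[0].gene_id,
        isoform_ids=tuple(a.protein_id for a in usable),
        category=worst,
        domain_sets=tuple(a.domains for a in usable),
        pair_relations=tuple(pairs),
    )


def classify_genes(
    assignments: Sequence[DomainAssignment],
    validated_ids: Iterable[str] | None = None,
) -> tuple[list[DomainCategory], Mapping[str, int], list[str]]:
    """Categorize every gene with >= 2 validated, domain-bearing isoforms.

    Returns (categories, per-category counts, skipped gene IDs).
    """
    keep = set(validated_ids) if validated_ids is not None else None
    by_gene: dict[str, list[DomainAssignment]] = {}
    for a in assignments:
        if keep is not None and a.protein_id not in keep:
            continue
        by_gene.setdefault(a.gene_id, []).append(a)
    categories: list[DomainCategory] = []
    skipped: list[str] = []
    for gene_id in sorted(by_gene):
        usable = [a for a in by_gene[gene_id] if a.domains]
        if len(usable) < 2:
            skipped.append(gene_id)
            continue
        categories.append(classify_gene(usable))
    counts = {cat: 0 for cat in CATEGORIES}
    for c in categories:
        counts[c.category] += 1
    return categories, counts, skipped
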