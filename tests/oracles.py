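"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's scanning/accumulation code paths:
ORFs are enumerated position by position, digestion products by substring
enumeration over all cleavage-site subsets.
"""

from __future__ import annotations

from Bio.Seq import Seq


def brute_force_orfs(seq: str, min_aa: int) -> list[tuple[int, int, int, str, bool]]:
    """All ATG-initiated ORFs as (frame, start, stop_exclusive, protein,
    has_stop), nested-same-stop reduced to the most 5' start, sorted by
    protein length descending then start ascending. ACGT sequences only."""
    seq = seq.upper()
    raw = []
    for p in range(len(seq) - 2):
        if seq[p : p + 3] != "ATG":
            continue
        q = p
        protein = []
        has_stop = False
        while q + 3 <= len(seq):
            aa = str(Seq(seq[q : q + 3]).translate())
            if aa == "*":
                has_stop = True
                q += 3
                break
            protein.append(aa)
            q += 3
        raw.append((p % 3, p, q, "".join(protein), has_stop))
    # reduce nested ORFs sharing a stop to the most 5' ATG
    best: dict[tuple[int, int], tuple] = {}
    for frame, start, stop, protein, has_stop in raw:
        key = (frame, stop)
        if key not in best or start < best[key][1]:
            best[key] = (frame, start, stop, protein, has_stop)
    out = [v for v in best.values() if len(v[3]) >= min_aa]
    out.sort(key=lambda v: (-len(v[3]), v[1]))
    return out


def brute_force_digest(
    seq: str, missed_cleavages: int, min_len: int, max_len: int
) -> set[str]:
    """Tryptic peptides by enumerating every (i, j) substring whose both
    boundaries are termini or cleavage sites and whose internal missed-site
    count is within budget."""
    seq = seq.upper()
    n = len(seq)

    def is_site(k: int) -> bool:  # cleavage between k and k+1
        return seq[k] in "KR" and (k + 1 >= n or seq[k + 1] != "P")

    peptides = set()
    for i in range(n):
        if not (i == 0 or is_site(i - 1)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or is_site(j - 1)):
                continue
            missed = sum(1 for k in range(i, j - 1) if is_site(k))
            if missed <= missed_cleavages and min_len <= j - i <= max_len:
                peptides.add(seq[i:j])
    return peptides
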