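"""Independent brute-force oracles for cross-checking the fast paths.

These deliberately avoid the incremental logic of the implementation: best
hits are found by a full scan over every row, and collinear runs by directly
validating whole candidate slices against the three block criteria.
"""

from __future__ import annotations

from locustrans.orthologs import AlignmentHit
from locustrans.synteny import AnchorPair


def brute_force_best_hits(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Exhaustive per-query minimum scan with the documented tie rules."""
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        incumbent = best.get(hit.query_locus)
        if incumbent is None:
            best[hit.query_locus] = hit
            continue
        a = (hit.evalue, -hit.bit_score, -hit.alignment_length, hit.subject_locus)
        b = (
            incumbent.evalue,
            -incumbent.bit_score,
            -incumbent.alignment_length,
            incumbent.subject_locus,
        )
        if a < b:
            best[hit.query_locus] = hit
    return best


def _slice_is_valid(chain: list[AnchorPair], max_gap: int) -> bool:
    """Check a candidate run against all three criteria, from scratch."""
    if len(chain) < 2:
        return True
    ra = [a.gene_a.rank for a in chain]
    if sorted(ra) != ra or len(set(ra)) != len(ra):
        return False
    rb = [a.gene_b.rank for a in chain]
    inc = all(x < y for x, y in zip(rb, rb[1:]))
    dec = all(x > y for x, y in zip(rb, rb[1:]))
    if not (inc or dec):
        return False
    for prev, nxt in zip(chain, chain[1:]):
        if abs(nxt.gene_a.start - prev.gene_a.start) >= max_gap:
            return False
        if abs(nxt.gene_b.start - prev.gene_b.start) >= max_gap:
            return False
    return True


def brute_force_blocks(
    anchors: list[AnchorPair], min_anchors: int = 4, max_gap: int = 2_000_000
) -> list[tuple[tuple[str, str], ...]]:
    """Maximal monotone gap-respecting runs, greedy left-to-right, no reuse.

    Same tie rules as the detector (emit a maximal run of sufficient length
    and jump past it, otherwise advance one anchor), but every candidate
    slice is validated wholesale rather than extended incrementally.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.gene_a.chromosome, a.gene_b.chromosome), []).append(a)
    out: list[tuple[tuple[str, str], ...]] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda a: (a.gene_a.rank, a.gene_b.rank))
        i = 0
        while i < len(group):
            j = i
            while j + 1 < len(group) and _slice_is_valid(group[i : j + 2], max_gap):
                j += 1
            if j - i + 1 >= min_anchors:
                out.append(
                    tuple(
                        (a.gene_a.locus_id, a.gene_b.locus_id) for a in group[i : j + 1]
                    )
                )
                i = j + 1
            else:
                i += 1
    return out
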