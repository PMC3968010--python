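"""Synteny-block and tandem-duplication detection on ortholog anchors.

Orthologous gene pairs ("anchors") are ordered along both genomes by their
within-chromosome rank and chained into collinear blocks under three rules:

1. a block holds at least ``min_anchors`` consecutive collinear anchors
   (default 4);
2. counterpart ranks run consistently increasing or consistently decreasing
   (an inverted block);
3. consecutive anchors sit less than ``max_gap`` apart (start-to-start,
   default 2 Mb) on *both* genomes.

Chaining is greedy left-to-right in genome-A order within each chromosome
pair, with restart on violation, and no anchor is reused. Tandem duplications
are runs of near-adjacent same-chromosome genes sharing one best counterpart
in the other genome; duplication *sites* are classified by whether the array
exists in genome A only, genome B only, or both.

Coordinates are 0-based half-open internally and converted at GFF3 I/O
boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthologs import AlignmentHit, OrthologCall

__all__ = [
    "GeneModel",
    "AnchorPair",
    "Orientation",
    "SyntenyBlock",
    "TandemArray",
    "TandemSite",
    "rank_genes",
    "build_anchors",
    "detect_synteny_blocks",
    "validate_block",
    "best_counterpart_maps",
    "detect_tandem_arrays",
    "classify_tandem_sites",
    "export_comparative_map",
]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: location plus within-chromosome rank.

    ``start``/``end`` are 0-based half-open; GFF3 I/O converts from/to
    1-based inclusive.
    """

    locus_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.locus_id}: start must be < end (0-based half-open), "
                f"got [{self.start}, {self.end})"
            )


class Orientation(enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"


@dataclass(frozen=True)
class AnchorPair:
    """An ortholog pair placed on both genomes; the atom of block detection."""

    gene_a: GeneModel
    gene_b: GeneModel
    call: OrthologCall | None = None

    def __post_init__(self) -> None:
        if self.gene_a.species == self.gene_b.species:
            raise ValueError("anchor genes must come from different species")


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: int
    chromosome_a: str
    chromosome_b: str
    anchors: tuple[AnchorPair, ...]
    orientation: Orientation
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class TandemArray:
    """Near-adjacent same-chromosome genes sharing one counterpart."""

    species: str
    chromosome: str
    member_loci: tuple[str, ...]
    counterpart_locus: str

    def __post_init__(self) -> None:
        if len(self.member_loci) < 2:
            raise ValueError("a tandem array needs at least 2 members")


@dataclass(frozen=True)
class TandemSite:
    """A tandem-duplication site: its arrays and which genome(s) carry them."""

    site_id: int
    category: str  # "A-only" | "B-only" | "both"
    arrays: tuple[TandemArray, ...]


def rank_genes(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Assign 0-based per-(species, chromosome) ranks by start coordinate.

    Ties break by end coordinate then locus ID. The result is independent of
    input order. Duplicate locus IDs raise ``ValueError``.
    """
    models = list(models)
    seen: set[tuple[str, str]] = set()
    for m in models:
        key = (m.species, m.locus_id)
        if key in seen:
            raise ValueError(f"duplicate locus ID {m.locus_id!r} in {m.species}")
        seen.add(key)
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault((m.species, m.chromosome), []).append(m)
    ranked: list[GeneModel] = []
    for key in sorted(by_chrom):
        genes = sorted(by_chrom[key], key=lambda g: (g.start, g.end, g.locus_id))
        ranked.extend(replace(g, rank=i) for i, g in enumerate(genes))
    return ranked


def _index_models(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    return {m.locus_id: m for m in models}


def build_anchors(
    calls: Iterable[OrthologCall],
    models_a: Iterable[GeneModel],
    models_b: Iterable[GeneModel],
) -> tuple[list[AnchorPair], int]:
    """Place ortholog calls on both genomes, sorted by (chromosome_a, rank_a).

    Calls whose loci cannot be resolved in the gene models (including NA
    calls) are skipped; the second return value counts the skips.
    """
    idx_a = _index_models(models_a)
    idx_b = _index_models(models_b)
    anchors: list[AnchorPair] = []
    skipped = 0
    for call in calls:
        gene_a = idx_a.get(call.query_locus)
        gene_b = idx_b.get(call.subject_locus) if call.subject_locus else None
        if gene_a is None or gene_b is None:
            skipped += 1
            continue
        if gene_a.rank is None or gene_b.rank is None:
            raise ValueError("gene models must be ranked (rank_genes) before anchoring")
        anchors.append(AnchorPair(gene_a=gene_a, gene_b=gene_b, call=call))
    anchors.sort(key=lambda a: (a.gene_a.chromosome, a.gene_a.rank))
    return anchors, skipped


def _pair_ok(prev: AnchorPair, nxt: AnchorPair, direction: int, max_gap: int) -> bool:
    """Can *nxt* follow *prev* in a chain running in *direction* (0 = free)?"""
    step = nxt.gene_b.rank - prev.gene_b.rank
    if step == 0:
        return False
    if direction and (step > 0) != (direction > 0):
        return False
    if abs(nxt.gene_a.start - prev.gene_a.start) >= max_gap:
        return False
    if abs(nxt.gene_b.start - prev.gene_b.start) >= max_gap:
        return False
    return True


def _extend_chain(anchors: Sequence[AnchorPair], i: int, max_gap: int) -> int:
    """Index one past the end of the maximal valid chain starting at *i*."""
    j = i
    direction = 0
    while j + 1 < len(anchors):
        if not _pair_ok(anchors[j], anchors[j + 1], direction, max_gap):
            break
        if direction == 0:
            direction = 1 if anchors[j + 1].gene_b.rank > anchors[j].gene_b.rank else -1
        j += 1
    return j + 1


def detect_synteny_blocks(
    anchors: Sequence[AnchorPair],
    min_anchors: int = 4,
    max_gap: int = 2_000_000,
) -> list[SyntenyBlock]:
    """Chain anchors into maximal collinear blocks under the three rules.

    Within each (chromosome_a, chromosome_b) pairing, anchors are scanned in
    genome-A order; a chain extends while counterpart ranks stay strictly
    monotone in a fixed direction and both start-to-start gaps stay below
    ``max_gap``. Maximal chains of at least ``min_anchors`` anchors become
    blocks; shorter chains advance the scan by a single anchor so a block
    starting mid-chain is still found. No anchor joins two blocks.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.gene_a.chromosome, a.gene_b.chromosome), []).append(a)
    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda a: (a.gene_a.rank, a.gene_b.rank))
        i = 0
        while i < len(group):
            end = _extend_chain(group, i, max_gap)
            if end - i >= min_anchors:
                chain = tuple(group[i:end])
                orientation = (
                    Orientation.INCREASING
                    if chain[1].gene_b.rank > chain[0].gene_b.rank
                    else Orientation.DECREASING
                )
                blocks.append(
                    SyntenyBlock(
                        block_id=len(blocks),
                        chromosome_a=key[0],
                        chromosome_b=key[1],
                        anchors=chain,
                        orientation=orientation,
                        span_a=(
                            min(a.gene_a.start for a in chain),
                            max(a.gene_a.end for a in chain),
                        ),
                        span_b=(
                            min(a.gene_b.start for a in chain),
                            max(a.gene_b.end for a in chain),
                        ),
                    )
                )
                i = end
            else:
                i += 1
    return blocks


def validate_block(
    block: SyntenyBlock, min_anchors: int = 4, max_gap: int = 2_000_000
) -> bool:
    """Re-check the three block criteria from scratch (independent of chaining)."""
    chain = block.anchors
    if len(chain) < min_anchors:
        return False
    ranks_b = [a.gene_b.rank for a in chain]
    increasing = all(x < y for x, y in zip(ranks_b, ranks_b[1:]))
    decreasing = all(x > y for x, y in zip(ranks_b, ranks_b[1:]))
    if not (increasing or decreasing):
        return False
    ranks_a = [a.gene_a.rank for a in chain]
    if not all(x < y for x, y in zip(ranks_a, ranks_a[1:])):
        return False
    for prev, nxt in zip(chain, chain[1:]):
        if abs(nxt.gene_a.start - prev.gene_a.start) >= max_gap:
            return False
        if abs(nxt.gene_b.start - prev.gene_b.start) >= max_gap:
            return False
    return True


def best_counterpart_maps(
    hits: Iterable[AlignmentHit],
) -> tuple[dict[str, str], dict[str, str]]:
    """Best counterpart per query gene and per subject gene.

    The winner minimises E-value with ties broken by larger bit score, longer
    alignment, then lexicographic counterpart ID — the same rules as best-hit
    calling, applied symmetrically so tandem families on either genome share
    a label.
    """

    best_q: dict[str, tuple] = {}
    best_s: dict[str, tuple] = {}
    for h in hits:
        key_q = (h.evalue, -h.bit_score, -h.alignment_length, h.subject_locus)
        if h.query_locus not in best_q or key_q < best_q[h.query_locus]:
            best_q[h.query_locus] = key_q
        key_s = (h.evalue, -h.bit_score, -h.alignment_length, h.query_locus)
        if h.subject_locus not in best_s or key_s < best_s[h.subject_locus]:
            best_s[h.subject_locus] = key_s
    return (
        {q: key[3] for q, key in best_q.items()},
        {s: key[3] for s, key in best_s.items()},
    )


def detect_tandem_arrays(
    models: Iterable[GeneModel],
    hits: Iterable[AlignmentHit],
    max_intervening: int = 1,
    min_members: int = 2,
) -> list[TandemArray]:
    """Find runs of near-adjacent genes sharing one best counterpart.

    *models* may cover one or both genomes; each gene's family label is its
    best counterpart in the hit table (query-side for genes appearing as
    queries, subject-side otherwise). Genes on the same chromosome with the
    same label whose ranks differ by at most ``max_intervening + 1`` between
    consecutive members chain into an array; arrays shorter than
    ``min_members`` are dropped.
    """
    models = list(models)
    if any(m.rank is None for m in models):
        raise ValueError("gene models must be ranked (rank_genes) first")
    by_query, by_subject = best_counterpart_maps(hits)
    groups: dict[tuple[str, str, str], list[GeneModel]] = {}
    for m in models:
        label = by_query.get(m.locus_id) or by_subject.get(m.locus_id)
        if label is None:
            continue
        groups.setdefault((m.species, m.chromosome, label), []).append(m)
    arrays: list[TandemArray] = []
    for (species, chrom, label), genes in sorted(groups.items()):
        genes.sort(key=lambda g: g.rank)
        run: list[GeneModel] = [genes[0]]
        for gene in genes[1:]:
            if gene.rank - run[-1].rank <= max_intervening + 1:
                run.append(gene)
            else:
                if len(run) >= min_members:
                    arrays.append(
                        TandemArray(species, chrom, tuple(g.locus_id for g in run), label)
                    )
                run = [gene]
        if len(run) >= min_members:
            arrays.append(
                TandemArray(species, chrom, tuple(g.locus_id for g in run), label)
            )
    return arrays


def classify_tandem_sites(
    arrays: Sequence[TandemArray], species_a: str, species_b: str
) -> list[TandemSite]:
    """Group arrays into duplication sites: A-only, B-only, or both genomes.

    An A-genome array and a B-genome array belong to one site when either
    array's counterpart is a member of the other — i.e. the same gene family
    expanded in both genomes.
    """
    a_arrays = [arr for arr in arrays if arr.species == species_a]
    b_arrays = [arr for arr in arrays if arr.species == species_b]
    sites: list[TandemSite] = []
    used_b: set[int] = set()
    for arr_a in a_arrays:
        partner = None
        for j, arr_b in enumerate(b_arrays):
            if j in used_b:
                continue
            if arr_b.counterpart_locus in arr_a.member_loci or (
                arr_a.counterpart_locus in arr_b.member_loci
            ):
                partner = j
                break
        if partner is not None:
            used_b.add(partner)
            sites.append(
                TandemSite(len(sites), "both", (arr_a, b_arrays[partner]))
            )
        else:
            sites.append(TandemSite(len(sites), "A-only", (arr_a,)))
    for j, arr_b in enumerate(b_arrays):
        if j not in used_b:
            sites.append(TandemSite(len(sites), "B-only", (arr_b,)))
    return sites


def export_comparative_map(
    blocks: Sequence[SyntenyBlock],
    anchors: Sequence[AnchorPair],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write anchor-link and block tables plus a chromosome-pair summary.

    Produces ``links.tsv`` (one row per anchor with its block assignment or
    empty), ``blocks.tsv`` (one row per block) and ``pair_summary.tsv``
    (anchor/block counts per chromosome pair). Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    anchor_block: dict[tuple[str, str], int] = {}
    for block in blocks:
        for a in block.anchors:
            anchor_block[(a.gene_a.locus_id, a.gene_b.locus_id)] = block.block_id
    link_rows = [
        {
            "locus_a": a.gene_a.locus_id,
            "chromosome_a": a.gene_a.chromosome,
            "start_a": a.gene_a.start + 1,
            "locus_b": a.gene_b.locus_id,
            "chromosome_b": a.gene_b.chromosome,
            "start_b": a.gene_b.start + 1,
            "block_id": anchor_block.get((a.gene_a.locus_id, a.gene_b.locus_id)),
        }
        for a in anchors
    ]
    links = pd.DataFrame(
        link_rows,
        columns=[
            "locus_a", "chromosome_a", "start_a",
            "locus_b", "chromosome_b", "start_b", "block_id",
        ],
    )
    block_rows = [
        {
            "block_id": b.block_id,
            "chromosome_a": b.chromosome_a,
            "chromosome_b": b.chromosome_b,
            "n_anchors": b.n_anchors,
            "orientation": b.orientation.value,
            "span_a_start": b.span_a[0] + 1,
            "span_a_end": b.span_a[1],
            "span_b_start": b.span_b[0] + 1,
            "span_b_end": b.span_b[1],
        }
        for b in blocks
    ]
    block_frame = pd.DataFrame(
        block_rows,
        columns=[
            "block_id", "chromosome_a", "chromosome_b", "n_anchors", "orientation",
            "span_a_start", "span_a_end", "span_b_start", "span_b_end",
        ],
    )
    if link_rows:
        summary = (
            links.groupby(["chromosome_a", "chromosome_b"])
            .agg(
                n_anchors=("locus_a", "size"),
                n_blocks=("block_id", "nunique"),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            columns=["chromosome_a", "chromosome_b", "n_anchors", "n_blocks"]
        )
    paths = {
        "links": outdir / "links.tsv",
        "blocks": outdir / "blocks.tsv",
        "pair_summary": outdir / "pair_summary.tsv",
    }
    links.to_csv(paths["links"], sep="\t", index=False)
    block_frame.to_csv(paths["blocks"], sep="\t", index=False)
    summary.to_csv(paths["pair_summary"], sep="\t", index=False)
    return paths
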