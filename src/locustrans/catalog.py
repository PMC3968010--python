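"""Stress-responsive gene catalog: loading, validation and summaries.

The catalog lists genes reported responsive to abiotic stress, each with one
of 18 flat biological-process GO classes, a non-empty set of stress cues
(drought / salt / cold, plus a miscellaneous class for ambiguous cues such as
ABA- or ROS-induction) and the evidence sources (databases / studies) that
reported it. Summaries reproduce the standard views: per-GO-class counts, the
three-set stress Venn with the miscellaneous category alongside, multi-
evidence gene subsets, and a chromosome-by-GO-class count matrix.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthologs import round_percent
from .synteny import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "STRESS_CUES",
    "MISC_CUE",
    "N_GO_CLASSES",
    "StressGene",
    "VennSummary",
    "load_catalog",
    "write_catalog",
    "go_summary",
    "stress_venn",
    "multi_evidence_genes",
    "chromosome_go_matrix",
]

#: The three stress cues of the three-set Venn.
STRESS_CUES = ("drought", "salt", "cold")
#: Ambiguous-cue class, reported alongside the Venn but outside it.
MISC_CUE = "misc"
N_GO_CLASSES = 18

_VALID_CUES = frozenset(STRESS_CUES) | {MISC_CUE}


@dataclass(frozen=True)
class StressGene:
    """One catalog entry."""

    locus_id: str
    go_class: int
    cues: frozenset[str]
    sources: frozenset[str]

    def __post_init__(self) -> None:
        if not 1 <= self.go_class <= N_GO_CLASSES:
            raise ValueError(
                f"{self.locus_id}: go_class must be 1..{N_GO_CLASSES}, got {self.go_class}"
            )
        if not self.cues:
            raise ValueError(f"{self.locus_id}: cues must be non-empty")
        unknown = self.cues - _VALID_CUES
        if unknown:
            raise ValueError(f"{self.locus_id}: unknown cues {sorted(unknown)}")
        if not self.sources:
            raise ValueError(f"{self.locus_id}: sources must be non-empty")


def load_catalog(path: str | Path) -> list[StressGene]:
    """Read a catalog TSV (locus_id, go_class, cues, sources; ';'-separated sets).

    Duplicate locus rows are merged by union of cues and sources (keeping the
    first row's GO class; the merge is logged). Invalid GO classes or empty
    cue sets raise ``ValueError`` naming the offending line.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "go_class", "cues", "sources"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes: dict[str, StressGene] = {}
    for lineno, row in zip(frame.index + 2, frame.itertuples(index=False)):
        try:
            cues = frozenset(c for c in str(row.cues).split(";") if c)
            sources = frozenset(s for s in str(row.sources).split(";") if s)
            gene = StressGene(
                locus_id=row.locus_id,
                go_class=int(row.go_class),
                cues=cues,
                sources=sources,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid catalog row at line {lineno}: {exc}") from exc
        if gene.locus_id in genes:
            old = genes[gene.locus_id]
            logger.info("merging duplicate catalog rows for %s", gene.locus_id)
            gene = StressGene(
                locus_id=old.locus_id,
                go_class=old.go_class,
                cues=old.cues | gene.cues,
                sources=old.sources | gene.sources,
            )
        genes[gene.locus_id] = gene
    return list(genes.values())


def write_catalog(genes: Iterable[StressGene], path: str | Path) -> None:
    rows = [
        {
            "locus_id": g.locus_id,
            "go_class": g.go_class,
            "cues": ";".join(sorted(g.cues)),
            "sources": ";".join(sorted(g.sources)),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=["locus_id", "go_class", "cues", "sources"]).to_csv(
        path, sep="\t", index=False
    )


def go_summary(catalog: Sequence[StressGene]) -> pd.DataFrame:
    """Counts and percentage shares per GO class 1..18 (all classes present)."""
    counts = Counter(g.go_class for g in catalog)
    total = len(catalog)
    rows = [
        {
            "go_class": k,
            "count": counts.get(k, 0),
            "percent": round_percent(counts.get(k, 0), total) if total else None,
        }
        for k in range(1, N_GO_CLASSES + 1)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VennSummary:
    """Three-set stress Venn plus the miscellaneous class.

    ``region_counts`` holds the seven exclusive Venn regions keyed by sorted
    cue tuples; ``misc_only`` counts genes whose only cue is miscellaneous.
    ``multi_stress_count`` counts genes carrying at least two of the three
    stress cues (whatever else they carry).
    """

    totals: Mapping[str, int]
    pairwise: Mapping[tuple[str, str], int]
    triple: int
    region_counts: Mapping[tuple[str, ...], int]
    misc_only: int
    misc_total: int
    multi_stress_count: int
    n_genes: int

    def to_dict(self) -> dict:
        return {
            "totals": dict(self.totals),
            "pairwise": {"+".join(k): v for k, v in self.pairwise.items()},
            "triple": self.triple,
            "regions": {"+".join(k) if k else "misc_only": v
                        for k, v in self.region_counts.items()},
            "misc_only": self.misc_only,
            "misc_total": self.misc_total,
            "multi_stress_count": self.multi_stress_count,
            "n_genes": self.n_genes,
        }


def stress_venn(catalog: Sequence[StressGene]) -> VennSummary:
    """Compute the drought/salt/cold Venn; misc is tallied separately."""
    region: Counter = Counter()
    totals = Counter()
    pairwise = Counter()
    triple = 0
    misc_only = 0
    misc_total = 0
    multi = 0
    for g in catalog:
        stress = tuple(c for c in STRESS_CUES if c in g.cues)
        if MISC_CUE in g.cues:
            misc_total += 1
        if not stress:
            misc_only += 1
        region[stress] += 1
        for c in stress:
            totals[c] += 1
        for pair in combinations(STRESS_CUES, 2):
            if pair[0] in g.cues and pair[1] in g.cues:
                pairwise[pair] += 1
        if len(stress) == 3:
            triple += 1
        if len(stress) >= 2:
            multi += 1
    region.pop((), None)
    return VennSummary(
        totals={c: totals.get(c, 0) for c in STRESS_CUES},
        pairwise={p: pairwise.get(p, 0) for p in combinations(STRESS_CUES, 2)},
        triple=triple,
        region_counts=dict(region),
        misc_only=misc_only,
        misc_total=misc_total,
        multi_stress_count=multi,
        n_genes=len(catalog),
    )


def multi_evidence_genes(
    catalog: Sequence[StressGene],
    min_sources: int = 2,
    combined_classes: tuple[int, ...] = (3, 4, 6),
) -> tuple[list[StressGene], pd.DataFrame, tuple[int, int]]:
    """Genes supported by at least ``min_sources`` evidence sources.

    Returns the subset, its per-GO-class breakdown, and the count pair
    (genes of the combined GO classes, subset size) — by default classes
    3/4/6: transcriptional and signalling regulators plus stress/defense
    response.
    """
    subset = [g for g in catalog if len(g.sources) >= min_sources]
    breakdown = go_summary(subset)
    combined = sum(1 for g in subset if g.go_class in combined_classes)
    return subset, breakdown, (combined, len(subset))


def chromosome_go_matrix(
    catalog: Sequence[StressGene], models: Iterable[GeneModel]
) -> tuple[pd.DataFrame, int]:
    """Chromosome x GO-class count matrix over catalog genes with known loci.

    Catalog entries with no gene model are skipped; the skip count is
    returned alongside the matrix.
    """
    by_locus = {m.locus_id: m for m in models}
    counts: Counter = Counter()
    skipped = 0
    chroms: set[str] = set()
    for g in catalog:
        model = by_locus.get(g.locus_id)
        if model is None:
            skipped += 1
            continue
        counts[(model.chromosome, g.go_class)] += 1
        chroms.add(model.chromosome)
    matrix = pd.DataFrame(
        0,
        index=sorted(chroms),
        columns=list(range(1, N_GO_CLASSES + 1)),
        dtype=int,
    )
    for (chrom, go), n in counts.items():
        matrix.loc[chrom, go] = n
    matrix.index.name = "chromosome"
    return matrix, skipped
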