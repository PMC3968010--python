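"""Ortholog calling from pairwise homology-search tables.

Given a BLAST tabular (outfmt-6 style) hit table between two genomes, this
module assigns each query gene its best cross-species counterpart, bins the
call by E-value magnitude, grades alignment specificity with a remark
(UQ > VS > S > FS > LS > SM > M, plus UC/NA outside the order), filters the
call set by significance, and summarises translation rates — the fraction of
source-genome genes for which a confident counterpart exists in the target
genome.

The remark grading is a deterministic surrogate for expert visual inspection
of alignments: it ranks the separation (bit-score ratio) between a query's
best hit and its runner-up homologs. All thresholds are configurable via
:class:`RemarkParams`.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OUTFMT6_COLUMNS",
    "AlignmentHit",
    "EvalueBin",
    "Remark",
    "RemarkParams",
    "OrthologCall",
    "TranslationReport",
    "parse_alignment_table",
    "hits_to_frame",
    "best_hits_per_query",
    "assign_evalue_bin",
    "assign_remark",
    "filter_translated_set",
    "translation_report",
    "round_percent",
]

#: Standard 12 columns of BLAST tabular output (-outfmt 6).
OUTFMT6_COLUMNS = (
    "query_locus",
    "subject_locus",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bit_score",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a pairwise homology search table."""

    query_locus: str
    subject_locus: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue!r} for {self.query_locus}")
        if self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1, got {self.alignment_length}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")


class EvalueBin(enum.Enum):
    """Magnitude bins partitioning the E-value axis.

    ``ZERO`` holds exact E = 0 (reported below the floating-point floor of the
    search tool); the remaining bins are half-open with every boundary value
    assigned to the *weaker* (larger-E) bin.
    """

    ZERO = "E=0"
    LT_100 = "0<E<1e-100"
    E100_80 = "1e-100<=E<1e-80"
    E80_60 = "1e-80<=E<1e-60"
    E60_40 = "1e-60<=E<1e-40"
    E40_30 = "1e-40<=E<1e-30"
    E30_10 = "1e-30<=E<1e-10"
    GE_10 = "E>=1e-10"


#: Upper (exclusive) bound of each non-zero bin, in bin order.
_BIN_EDGES: tuple[tuple[float, EvalueBin], ...] = (
    (1e-100, EvalueBin.LT_100),
    (1e-80, EvalueBin.E100_80),
    (1e-60, EvalueBin.E80_60),
    (1e-40, EvalueBin.E60_40),
    (1e-30, EvalueBin.E40_30),
    (1e-10, EvalueBin.E30_10),
    (math.inf, EvalueBin.GE_10),
)


def assign_evalue_bin(evalue: float) -> EvalueBin:
    """Map a non-negative E-value to its unique magnitude bin.

    Boundary values (e.g. exactly 1e-100) fall into the weaker bin, so
    ``assign_evalue_bin(1e-100) is EvalueBin.E100_80``.
    """
    if evalue < 0 or math.isnan(evalue):
        raise ValueError(f"E-value must be non-negative, got {evalue!r}")
    if evalue == 0:
        return EvalueBin.ZERO
    for edge, bin_ in _BIN_EDGES:
        if evalue < edge:
            return bin_
    return EvalueBin.GE_10  # pragma: no cover - inf edge is exhaustive


class Remark(enum.Enum):
    """Alignment-specificity remark.

    The graded remarks are totally ordered UQ > VS > S > FS > LS > SM > M.
    UC (uncertain) and NA (no hit at all) sit outside the order and are
    excluded from "above level" counting.
    """

    UQ = "unique"
    VS = "very specific"
    S = "specific"
    FS = "fairly specific"
    LS = "less specific"
    SM = "specific but multiple homologs"
    M = "multiple homologs"
    UC = "uncertain"
    NA = "not available"

    @property
    def level(self) -> int | None:
        """Rank in the specificity order (higher = more specific); None for UC/NA."""
        return _REMARK_LEVEL.get(self)

    def at_or_above(self, level: "Remark", inclusive: bool = True) -> bool:
        """Whether this remark is at least as specific as *level*.

        UC/NA are never above any level. With ``inclusive=False`` the
        comparison is strict.
        """
        mine, ref = self.level, level.level
        if mine is None:
            return False
        if ref is None:
            raise ValueError(f"{level} is not an ordered remark level")
        return mine >= ref if inclusive else mine > ref


_REMARK_LEVEL: dict[Remark, int] = {
    Remark.M: 1,
    Remark.SM: 2,
    Remark.LS: 3,
    Remark.FS: 4,
    Remark.S: 5,
    Remark.VS: 6,
    Remark.UQ: 7,
}


@dataclass(frozen=True)
class RemarkParams:
    """Thresholds of the deterministic remark grading.

    uncertainty_evalue
        Best hits weaker than this are UC (uncertain).
    significance_evalue
        Hits at or below this E-value count as significant homologs.
    gap_vs / gap_s / gap_fs
        Bit-score ratio (best / second best) cut-offs for VS, S, FS.
    ls_max_hits
        With a weak gap, at most this many significant homologs still grades
        LS rather than SM/M.
    sm_third_gap
        Bit-score ratio (best / third best) required for SM in crowded
        families.
    """

    uncertainty_evalue: float = 1e-5
    significance_evalue: float = 1e-10
    gap_vs: float = 4.0
    gap_s: float = 2.0
    gap_fs: float = 1.3
    ls_max_hits: int = 3
    sm_third_gap: float = 1.3


@dataclass(frozen=True)
class OrthologCall:
    """Best cross-species assignment for one query gene.

    ``subject_locus`` is None exactly when the query had no hits at all
    (remark NA); ``score_gap`` is the ratio of best to second-best bit score
    among significant hits (inf when the best hit is unrivalled).
    """

    query_locus: str
    subject_locus: str | None
    evalue: float | None
    bin: EvalueBin | None
    remark: Remark
    n_significant_hits: int
    score_gap: float

    def __post_init__(self) -> None:
        if (self.subject_locus is None) != (self.remark is Remark.NA):
            raise ValueError("subject_locus is None iff remark is NA")
        if self.remark is Remark.UQ and self.n_significant_hits != 1:
            raise ValueError("UQ requires exactly one significant hit")


def _hit_sort_key(hit: AlignmentHit) -> tuple:
    # Smallest E first; ties by larger bit score, longer alignment,
    # lexicographically smallest subject ID.
    return (hit.evalue, -hit.bit_score, -hit.alignment_length, hit.subject_locus)


def assign_remark(
    hits: Sequence[AlignmentHit], params: RemarkParams = RemarkParams()
) -> Remark:
    """Grade the specificity of one query's hit list.

    No hits -> NA. Best E above the uncertainty threshold (or no hit passing
    the significance threshold) -> UC. Otherwise the grade is decided by the
    number of significant homologs and the bit-score separation of the best
    hit from its runners-up.
    """
    if not hits:
        return Remark.NA
    ordered = sorted(hits, key=_hit_sort_key)
    if ordered[0].evalue > params.uncertainty_evalue:
        return Remark.UC
    sig = [h for h in ordered if h.evalue <= params.significance_evalue]
    if not sig:
        # Best hit is credible but nothing clears the significance bar:
        # the gap grading is undefined, so the call stays uncertain.
        return Remark.UC
    if len(sig) == 1:
        return Remark.UQ
    best, second = sig[0].bit_score, sig[1].bit_score
    gap = math.inf if second <= 0 else best / second
    if gap >= params.gap_vs:
        return Remark.VS
    if gap >= params.gap_s:
        return Remark.S
    if gap >= params.gap_fs:
        return Remark.FS
    if len(sig) <= params.ls_max_hits:
        return Remark.LS
    third = sig[2].bit_score
    third_gap = math.inf if third <= 0 else best / third
    if third_gap >= params.sm_third_gap:
        return Remark.SM
    return Remark.M


def best_hits_per_query(
    hits: Iterable[AlignmentHit], params: RemarkParams = RemarkParams()
) -> list[OrthologCall]:
    """Call one best counterpart per distinct query gene.

    The winner per query has the smallest E-value; ties break by larger bit
    score, then longer alignment, then lexicographic subject ID. Queries with
    no rows are not fabricated. Output order follows first appearance of each
    query in the input.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_locus, []).append(hit)
    calls: list[OrthologCall] = []
    for query, qhits in by_query.items():
        ordered = sorted(qhits, key=_hit_sort_key)
        best = ordered[0]
        sig = [h for h in ordered if h.evalue <= params.significance_evalue]
        if len(sig) >= 2 and sig[1].bit_score > 0:
            gap = sig[0].bit_score / sig[1].bit_score
        else:
            gap = math.inf
        calls.append(
            OrthologCall(
                query_locus=query,
                subject_locus=best.subject_locus,
                evalue=best.evalue,
                bin=assign_evalue_bin(best.evalue),
                remark=assign_remark(qhits, params),
                n_significant_hits=len(sig),
                score_gap=gap,
            )
        )
    return calls


def parse_alignment_table(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST outfmt-6 TSV into hits, preserving row order.

    An E-value written ``0.0`` is preserved as exact zero. An empty file
    yields an empty list; a malformed row raises ``ValueError`` naming the
    1-based line number.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            engine="python",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if frame.shape[1] != len(OUTFMT6_COLUMNS):
        raise ValueError(
            f"{path}: expected 12 tab-separated columns, found {frame.shape[1]}"
        )
    frame.columns = list(OUTFMT6_COLUMNS)
    hits: list[AlignmentHit] = []
    for lineno, row in zip(frame.index + 1, frame.itertuples(index=False)):
        try:
            if any(pd.isna(v) for v in row):
                raise ValueError("missing field")
            hits.append(
                AlignmentHit(
                    query_locus=row.query_locus,
                    subject_locus=row.subject_locus,
                    percent_identity=float(row.percent_identity),
                    alignment_length=int(row.alignment_length),
                    mismatches=int(row.mismatches),
                    gap_opens=int(row.gap_opens),
                    query_start=int(row.query_start),
                    query_end=int(row.query_end),
                    subject_start=int(row.subject_start),
                    subject_end=int(row.subject_end),
                    evalue=float(row.evalue),
                    bit_score=float(row.bit_score),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return hits


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    """Hits as a 12-column DataFrame in outfmt-6 column order."""
    return pd.DataFrame([asdict(h) for h in hits], columns=list(OUTFMT6_COLUMNS))


def filter_translated_set(
    calls: Iterable[OrthologCall],
    e_threshold: float = 1e-30,
    excluded_remarks: frozenset[Remark] = frozenset({Remark.UC, Remark.NA}),
) -> list[OrthologCall]:
    """Keep calls with E strictly below *e_threshold* and an allowed remark."""
    return [
        c
        for c in calls
        if c.evalue is not None
        and c.evalue < e_threshold
        and c.remark not in excluded_remarks
    ]


def round_percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator/denominator, rounded half-up to *ndigits* decimals."""
    if denominator == 0:
        raise ZeroDivisionError("cannot compute a percentage of an empty set")
    quotient = Decimal(100 * numerator) / Decimal(denominator)
    exponent = Decimal(1).scaleb(-ndigits)
    return float(quotient.quantize(exponent, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TranslationReport:
    """Counts and rates summarising a cross-species translation run.

    ``above_level_count`` counts graded remarks at or above the chosen level
    over the *whole* call set; ``above_level_filtered`` restricts to calls
    surviving the E/remark filter. ``rates`` carries the derived percentages
    (half-up, one decimal) on both bases; it is None for an empty call set
    (rates undefined, not zero).
    """

    total_genes: int
    bin_counts: Mapping[EvalueBin, int]
    remark_counts: Mapping[Remark, int]
    filtered_total: int
    above_level_count: int
    above_level_filtered: int
    level: Remark
    e_threshold: float
    rates: Mapping[str, float] | None

    def to_dict(self) -> dict:
        return {
            "total_genes": self.total_genes,
            "bin_counts": {b.name: self.bin_counts[b] for b in EvalueBin},
            "remark_counts": {r.name: self.remark_counts[r] for r in Remark},
            "filtered_total": self.filtered_total,
            "above_level_count": self.above_level_count,
            "above_level_filtered": self.above_level_filtered,
            "level": self.level.name,
            "e_threshold": self.e_threshold,
            "rates": dict(self.rates) if self.rates is not None else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def bin_table(self) -> pd.DataFrame:
        """Per-bin counts and shares as a plot-ready table."""
        rows = []
        for b in EvalueBin:
            count = self.bin_counts[b]
            pct = (
                round_percent(count, self.total_genes) if self.total_genes else None
            )
            rows.append({"bin": b.value, "count": count, "percent": pct})
        return pd.DataFrame(rows)


def translation_report(
    calls: Sequence[OrthologCall],
    level: Remark = Remark.FS,
    e_threshold: float = 1e-30,
    excluded_remarks: frozenset[Remark] = frozenset({Remark.UC, Remark.NA}),
    inclusive: bool = True,
) -> TranslationReport:
    """Summarise calls: E-bin spectrum, remark spectrum, translation rates.

    Calls with no counterpart (remark NA) are counted in the weakest E bin so
    that bin counts always sum to the call count.
    """
    bins: Counter = Counter()
    remarks: Counter = Counter()
    for call in calls:
        bins[call.bin if call.bin is not None else EvalueBin.GE_10] += 1
        remarks[call.remark] += 1
    filtered = filter_translated_set(calls, e_threshold, excluded_remarks)
    above = sum(1 for c in calls if c.remark.at_or_above(level, inclusive))
    above_filtered = sum(1 for c in filtered if c.remark.at_or_above(level, inclusive))
    total = len(calls)
    rates: dict[str, float] | None
    if total == 0:
        rates = None
    else:
        rates = {
            "above_level_pct": round_percent(above, total),
            "filtered_pct": round_percent(len(filtered), total),
            "above_level_total_base_pct": round_percent(above_filtered, total),
        }
        if filtered:
            rates["above_level_filtered_base_pct"] = round_percent(
                above_filtered, len(filtered)
            )
    return TranslationReport(
        total_genes=total,
        bin_counts={b: bins.get(b, 0) for b in EvalueBin},
        remark_counts={r: remarks.get(r, 0) for r in Remark},
        filtered_total=len(filtered),
        above_level_count=above,
        above_level_filtered=above_filtered,
        level=level,
        e_threshold=e_threshold,
        rates=rates,
    )
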