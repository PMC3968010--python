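"""Synthetic genome pairs with planted comparative-genomics ground truth.

The generator lays out two annotated genomes (Arabidopsis-style ``AtNgNNNNN``
and Medicago-style ``MtNgNNNNNN`` locus IDs whose numeric part encodes gene
order, as in AGI identifiers), plants:

* collinear synteny blocks — runs of consecutive ortholog anchors that
  satisfy the three detection criteria by construction (at least the minimum
  anchor count, strictly monotone counterpart ranks in a fixed direction,
  inter-anchor start-to-start gaps below 2 Mb on both genomes), a configured
  fraction of them in decreasing (inverted) orientation;
* tandem arrays — adjacent genes on one chromosome sharing a single
  counterpart in the other genome, at sites present in genome A only, B only,
  or both;
* background ortholog pairs up to a configured ortholog fraction, and
  spurious noise hits;

and emits a BLAST-outfmt-6-style alignment table in which true relations
receive the most significant E-values under a configurable log-normal
E-value model (with a point mass at the literal E = 0). Companion generators
produce a stress-gene catalog with overlapping drought/salt/cold cue sets
plus a miscellaneous class, and a pair of partially overlapping PPI edge
lists.

No nucleotide or peptide sequence is simulated — only alignment statistics.
All randomness flows from explicit seeds; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MISC_CUE, N_GO_CLASSES, STRESS_CUES, StressGene
from .orthologs import OUTFMT6_COLUMNS
from .synteny import GeneModel, rank_genes

__all__ = [
    "InfeasibleConfigError",
    "EvalueModel",
    "SimConfig",
    "PlantedBlock",
    "PlantedArray",
    "PlantedTruth",
    "simulate_genome_pair",
    "emit_alignment_table",
    "write_alignment_table",
    "simulate_stress_catalog",
    "simulate_ppi",
    "write_truth",
    "load_truth",
]


class InfeasibleConfigError(ValueError):
    """The requested structures cannot be placed under the configuration."""


@dataclass(frozen=True)
class EvalueModel:
    """Log10 E-value distributions per relation class, clamped to E <= 1.

    True ortholog relations draw log10(E) from a normal; a configured
    fraction of them is emitted as the literal ``0`` (below the reporting
    floor of search tools). Paralogous relations (secondary tandem-family
    rows) sit a fixed log10 offset per extra copy above their family's
    primary pair, keeping the primary the best hit. Noise hits are weak.
    """

    true_log10_mean: float = -150.0
    true_log10_sd: float = 25.0
    zero_fraction: float = 0.256
    paralog_offset: float = 5.0
    noise_log10_mean: float = -4.0
    noise_log10_sd: float = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Stated world of one synthetic genome pair."""

    seed: int
    n_genes_a: int = 2000
    n_genes_b: int = 2000
    n_chromosomes_a: int = 5
    n_chromosomes_b: int = 8
    chromosome_length: int = 30_000_000
    n_blocks: int = 8
    block_size_range: tuple[int, int] = (4, 12)
    inversion_fraction: float = 0.3
    n_tandem_arrays: int = 5
    tandem_copy_range: tuple[int, int] = (2, 4)
    tandem_site_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # A-only, B-only, both
    ortholog_fraction: float = 0.6
    noise_hit_rate: float = 1.0
    evalue_model: EvalueModel = field(default_factory=EvalueModel)
    species_a: str = "At"
    species_b: str = "Mt"

    def __post_init__(self) -> None:
        for name in ("n_genes_a", "n_genes_b", "n_chromosomes_a", "n_chromosomes_b",
                     "chromosome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_blocks", "n_tandem_arrays"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("inversion_fraction", "ortholog_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.noise_hit_rate < 0:
            raise ValueError("noise_hit_rate must be non-negative")
        if self.block_size_range[0] < 4:
            raise ValueError("block_size_range minimum must be >= 4")
        if self.block_size_range[0] > self.block_size_range[1]:
            raise ValueError("block_size_range must be (min, max) with min <= max")
        if self.tandem_copy_range[0] < 2:
            raise ValueError("tandem_copy_range minimum must be >= 2")
        if not math.isclose(sum(self.tandem_site_probs), 1.0, abs_tol=1e-9):
            raise ValueError("tandem_site_probs must sum to 1")


@dataclass(frozen=True)
class PlantedBlock:
    chromosome_a: str
    chromosome_b: str
    anchor_pairs: tuple[tuple[str, str], ...]
    orientation: str  # "increasing" | "decreasing"


@dataclass(frozen=True)
class PlantedArray:
    species: str
    chromosome: str
    member_loci: tuple[str, ...]
    counterpart_locus: str
    site_id: int
    category: str  # "A-only" | "B-only" | "both"


@dataclass(frozen=True)
class PlantedTruth:
    """Everything the generator planted, for downstream recovery checks.

    ``ortholog_pairs`` lists, for every genome-A gene with a true relation,
    the counterpart expected to win best-hit calling.
    """

    ortholog_pairs: tuple[tuple[str, str], ...]
    blocks: tuple[PlantedBlock, ...]
    tandem_arrays: tuple[PlantedArray, ...]
    noise_hits: tuple[tuple[str, str], ...]
    loci_a: tuple[str, ...]
    loci_b: tuple[str, ...]


# --------------------------------------------------------------------------
# genome layout


def _layout_genome(
    rng: np.random.Generator,
    n_genes: int,
    n_chromosomes: int,
    chrom_length: int,
    species: str,
    pad: int,
) -> list[GeneModel]:
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1
    models: list[GeneModel] = []
    for c, n_chr in enumerate(per_chrom, start=1):
        if n_chr == 0:
            continue
        spacing = chrom_length // (n_chr + 1)
        if spacing < 3000:
            raise InfeasibleConfigError(
                f"{species} chromosome {c}: {n_chr} genes do not fit in "
                f"{chrom_length} bp with workable spacing"
            )
        gene_len = min(2500, max(500, spacing // 3))
        jitter = rng.integers(0, max(1, spacing // 5), size=n_chr)
        for i in range(n_chr):
            start = (i + 1) * spacing + int(jitter[i])
            models.append(
                GeneModel(
                    locus_id=f"{species}{c}g{(i + 1) * 10:0{pad}d}",
                    species=species,
                    chromosome=f"{species}Chr{c}",
                    start=start,
                    end=start + gene_len,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return models


def _consecutive_free_run(
    rng: np.random.Generator,
    by_chrom: Mapping[str, list[GeneModel]],
    used: set[str],
    k: int,
) -> list[GeneModel] | None:
    """Pick a random run of *k* consecutive unused genes on one chromosome."""
    chroms = sorted(by_chrom)
    for _ in range(200):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        genes = by_chrom[chrom]
        if len(genes) < k + 2:
            continue
        start = int(rng.integers(1, len(genes) - k))  # keep one flank gene free
        run = genes[start : start + k]
        flanks = [genes[start - 1], genes[start + k]] if start + k < len(genes) else [genes[start - 1]]
        if any(g.locus_id in used for g in run) or any(g.locus_id in used for g in flanks):
            continue
        return run
    return None


def _free_gene(
    rng: np.random.Generator, models: Sequence[GeneModel], used: set[str]
) -> GeneModel:
    for _ in range(1000):
        g = models[int(rng.integers(0, len(models)))]
        if g.locus_id not in used:
            return g
    raise InfeasibleConfigError("no free gene left to place a planted structure")


# --------------------------------------------------------------------------
# internal well-formedness validation (independent of the detector module)


def _is_valid_run(rows: Sequence[tuple], max_gap: int) -> bool:
    """rows: (rank_a, start_a, rank_b, start_b), sorted by rank_a."""
    if len(rows) < 2:
        return True
    steps = [b[2] - a[2] for a, b in zip(rows, rows[1:])]
    if any(s == 0 for s in steps):
        return False
    if not (all(s > 0 for s in steps) or all(s < 0 for s in steps)):
        return False
    return all(
        abs(b[1] - a[1]) < max_gap and abs(b[3] - a[3]) < max_gap
        for a, b in zip(rows, rows[1:])
    )


def _maximal_runs(
    anchor_rows: Sequence[tuple], min_anchors: int = 4, max_gap: int = 2_000_000
) -> list[tuple[tuple[str, str], ...]]:
    """Brute-force maximal monotone gap-respecting runs, greedy left-to-right.

    anchor_rows: (chrom_a, rank_a, start_a, chrom_b, rank_b, start_b,
    locus_a, locus_b). Used to certify that planted blocks are exactly what
    a criteria-faithful detector must find.
    """
    groups: dict[tuple[str, str], list[tuple]] = {}
    for row in anchor_rows:
        groups.setdefault((row[0], row[3]), []).append(row)
    found: list[tuple[tuple[str, str], ...]] = []
    for key in sorted(groups):
        rows = sorted(groups[key], key=lambda r: r[1])
        quads = [(r[1], r[2], r[4], r[5]) for r in rows]
        i = 0
        while i < len(rows):
            best_j = i
            for j in range(i + 1, len(rows)):
                if _is_valid_run(quads[i : j + 1], max_gap):
                    best_j = j
                else:
                    break
            if best_j - i + 1 >= min_anchors:
                found.append(tuple((r[6], r[7]) for r in rows[i : best_j + 1]))
                i = best_j + 1
            else:
                i += 1
    return found


# --------------------------------------------------------------------------
# main generator


def simulate_genome_pair(
    config: SimConfig,
) -> tuple[list[GeneModel], list[GeneModel], PlantedTruth]:
    """Generate two ranked genomes and the planted comparative truth.

    Planted blocks are guaranteed (by construction plus an internal
    re-validation) to be exactly the maximal collinear runs of the anchor
    set at the default detection thresholds; background ortholog pairs are
    re-drawn, from the same seeded stream, in the rare event they would
    create or extend a collinear run.
    """
    rng = np.random.default_rng(config.seed)
    models_a = rank_genes(
        _layout_genome(rng, config.n_genes_a, config.n_chromosomes_a,
                       config.chromosome_length, config.species_a, pad=5)
    )
    models_b = rank_genes(
        _layout_genome(rng, config.n_genes_b, config.n_chromosomes_b,
                       config.chromosome_length, config.species_b, pad=6)
    )
    if config.n_blocks > 0:
        for models, n_chrom in ((models_a, config.n_chromosomes_a),
                                (models_b, config.n_chromosomes_b)):
            n_chr = max(1, len(models) // n_chrom)
            spacing = config.chromosome_length // (n_chr + 1)
            if spacing + spacing // 5 >= 2_000_000:
                raise InfeasibleConfigError(
                    "gene spacing exceeds the 2 Mb gap rule; planted blocks "
                    "would be undetectable"
                )

    by_chrom_a: dict[str, list[GeneModel]] = {}
    for m in models_a:
        by_chrom_a.setdefault(m.chromosome, []).append(m)
    by_chrom_b: dict[str, list[GeneModel]] = {}
    for m in models_b:
        by_chrom_b.setdefault(m.chromosome, []).append(m)
    for genes in by_chrom_a.values():
        genes.sort(key=lambda g: g.rank)
    for genes in by_chrom_b.values():
        genes.sort(key=lambda g: g.rank)

    used_a: set[str] = set()
    used_b: set[str] = set()

    # --- synteny blocks
    n_decreasing = round(config.inversion_fraction * config.n_blocks)
    orientations = ["decreasing"] * n_decreasing + ["increasing"] * (
        config.n_blocks - n_decreasing
    )
    rng.shuffle(orientations)
    blocks: list[PlantedBlock] = []
    for orientation in orientations:
        k = int(rng.integers(config.block_size_range[0], config.block_size_range[1] + 1))
        run_a = _consecutive_free_run(rng, by_chrom_a, used_a, k)
        run_b = _consecutive_free_run(rng, by_chrom_b, used_b, k)
        if run_a is None or run_b is None:
            raise InfeasibleConfigError(
                "could not place all requested synteny blocks; genome too small "
                "or too crowded"
            )
        partners = list(run_b) if orientation == "increasing" else list(reversed(run_b))
        pairs = tuple((a.locus_id, b.locus_id) for a, b in zip(run_a, partners))
        used_a.update(a.locus_id for a in run_a)
        used_b.update(b.locus_id for b in run_b)
        # Reserve the genome-A flank genes of the block: an anchor planted on
        # a flank could otherwise extend the block into a longer run.
        for run, by_chrom, used in ((run_a, by_chrom_a, used_a),
                                    (run_b, by_chrom_b, used_b)):
            genes = by_chrom[run[0].chromosome]
            for flank_rank in (run[0].rank - 1, run[-1].rank + 1):
                if 0 <= flank_rank < len(genes):
                    used.add(genes[flank_rank].locus_id)
        blocks.append(
            PlantedBlock(
                chromosome_a=run_a[0].chromosome,
                chromosome_b=run_b[0].chromosome,
                anchor_pairs=pairs,
                orientation=orientation,
            )
        )

    # --- tandem arrays
    arrays: list[PlantedArray] = []
    categories = [
        str(c)
        for c in rng.choice(
            ["A-only", "B-only", "both"], size=config.n_tandem_arrays,
            p=list(config.tandem_site_probs),
        )
    ]
    for site_id, category in enumerate(categories):
        lo, hi = config.tandem_copy_range
        if category in ("A-only", "both"):
            k = int(rng.integers(lo, hi + 1))
            run_a = _consecutive_free_run(rng, by_chrom_a, used_a, k)
            if run_a is None:
                raise InfeasibleConfigError("could not place a tandem array in genome A")
            used_a.update(g.locus_id for g in run_a)
        if category in ("B-only", "both"):
            k = int(rng.integers(lo, hi + 1))
            run_b = _consecutive_free_run(rng, by_chrom_b, used_b, k)
            if run_b is None:
                raise InfeasibleConfigError("could not place a tandem array in genome B")
            used_b.update(g.locus_id for g in run_b)
        if category == "A-only":
            counterpart = _free_gene(rng, models_b, used_b)
            used_b.add(counterpart.locus_id)
            arrays.append(PlantedArray(config.species_a, run_a[0].chromosome,
                                       tuple(g.locus_id for g in run_a),
                                       counterpart.locus_id, site_id, category))
        elif category == "B-only":
            counterpart = _free_gene(rng, models_a, used_a)
            used_a.add(counterpart.locus_id)
            arrays.append(PlantedArray(config.species_b, run_b[0].chromosome,
                                       tuple(g.locus_id for g in run_b),
                                       counterpart.locus_id, site_id, category))
        else:  # both: the two arrays are counterparts of each other
            arrays.append(PlantedArray(config.species_a, run_a[0].chromosome,
                                       tuple(g.locus_id for g in run_a),
                                       run_b[0].locus_id, site_id, category))
            arrays.append(PlantedArray(config.species_b, run_b[0].chromosome,
                                       tuple(g.locus_id for g in run_b),
                                       run_a[0].locus_id, site_id, category))

    # --- query-side expected best pairs from blocks and arrays
    fixed_pairs: list[tuple[str, str]] = []
    for block in blocks:
        fixed_pairs.extend(block.anchor_pairs)
    arrays_by_site: dict[int, list[PlantedArray]] = {}
    for arr in arrays:
        arrays_by_site.setdefault(arr.site_id, []).append(arr)
    for site_arrays in arrays_by_site.values():
        a_arr = next((a for a in site_arrays if a.species == config.species_a), None)
        b_arr = next((a for a in site_arrays if a.species == config.species_b), None)
        if a_arr and b_arr:  # both-genome site
            for member in a_arr.member_loci:
                fixed_pairs.append((member, b_arr.member_loci[0]))
        elif a_arr:
            for member in a_arr.member_loci:
                fixed_pairs.append((member, a_arr.counterpart_locus))
        elif b_arr:
            fixed_pairs.append((b_arr.counterpart_locus, b_arr.member_loci[0]))

    # --- background ortholog pairs, rejection-validated against the planted map
    n_with_counterpart = len({a for a, _ in fixed_pairs})
    n_background = max(0, round(config.ortholog_fraction * config.n_genes_a)
                       - n_with_counterpart)
    free_a = [m for m in models_a if m.locus_id not in used_a]
    free_b = [m for m in models_b if m.locus_id not in used_b]
    n_background = min(n_background, len(free_a), len(free_b))
    rank_a = {m.locus_id: m for m in models_a}
    rank_b = {m.locus_id: m for m in models_b}
    planted_keys = {tuple(b.anchor_pairs) for b in blocks}

    def anchor_row(pair: tuple[str, str]) -> tuple:
        ga, gb = rank_a[pair[0]], rank_b[pair[1]]
        return (ga.chromosome, ga.rank, ga.start, gb.chromosome, gb.rank, gb.start,
                ga.locus_id, gb.locus_id)

    idx_a = rng.permutation(len(free_a))[:n_background]
    idx_b = rng.permutation(len(free_b))[:n_background]
    background = [
        (free_a[i].locus_id, free_b[j].locus_id) for i, j in zip(idx_a, idx_b)
    ]
    bg_index = {a: k for k, (a, _) in enumerate(background)}
    for attempt in range(500):
        rows = [anchor_row(p) for p in fixed_pairs + background]
        runs = {tuple(r) for r in _maximal_runs(rows)}
        if runs == planted_keys:
            break
        # Targeted repair: every background anchor participating in a run
        # that is not exactly a planted block swaps counterparts with a
        # random background peer. Injectivity is preserved; the configured
        # regime (pair count, gene layout) is untouched.
        offenders = sorted(
            {
                bg_index[a]
                for run in runs - planted_keys
                for a, _ in run
                if a in bg_index
            }
        )
        if not offenders or len(background) < 2:
            raise InfeasibleConfigError(
                "planted blocks are not recoverable as maximal collinear runs"
            )
        for o in offenders:
            r = int(rng.integers(0, len(background)))
            (qa, sa), (qb, sb) = background[o], background[r]
            background[o], background[r] = (qa, sb), (qb, sa)
    else:
        raise InfeasibleConfigError(
            "background ortholog pairing kept colliding with planted blocks"
        )

    ortholog_pairs = tuple(fixed_pairs + background)

    # --- noise hits
    noise: list[tuple[str, str]] = []
    if config.noise_hit_rate > 0:
        loci_b = [m.locus_id for m in models_b]
        true_subject = dict(ortholog_pairs)
        for m in models_a:
            for _ in range(int(rng.poisson(config.noise_hit_rate))):
                s = loci_b[int(rng.integers(0, len(loci_b)))]
                if true_subject.get(m.locus_id) != s:
                    noise.append((m.locus_id, s))

    truth = PlantedTruth(
        ortholog_pairs=ortholog_pairs,
        blocks=tuple(blocks),
        tandem_arrays=tuple(arrays),
        noise_hits=tuple(noise),
        loci_a=tuple(m.locus_id for m in models_a),
        loci_b=tuple(m.locus_id for m in models_b),
    )
    return models_a, models_b, truth


# --------------------------------------------------------------------------
# alignment-table emission


def _round_sig(x: float) -> float:
    # limit precision so text round-trips are lossless
    return float(f"{x:.2e}") if x != 0 else 0.0


def _row(
    rng: np.random.Generator, query: str, subject: str, log10_e: float | None
) -> dict:
    """One outfmt-6 row; log10_e None means the literal E = 0."""
    evalue = 0.0 if log10_e is None else _round_sig(10.0 ** min(0.0, log10_e))
    l10 = -220.0 if log10_e is None else min(0.0, log10_e)
    length = int(rng.integers(80, 900))
    pident = round(float(rng.uniform(35.0, 98.0)), 1)
    mismatches = int(length * (100.0 - pident) / 100.0 * 0.8)
    bit = round(max(25.0, -2.2 * l10 + float(rng.normal(40.0, 5.0))), 1)
    qstart = int(rng.integers(1, 200))
    sstart = int(rng.integers(1, 200))
    return {
        "query_locus": query,
        "subject_locus": subject,
        "percent_identity": pident,
        "alignment_length": length,
        "mismatches": mismatches,
        "gap_opens": int(rng.integers(0, 6)),
        "query_start": qstart,
        "query_end": qstart + length - 1,
        "subject_start": sstart,
        "subject_end": sstart + length - 1,
        "evalue": evalue,
        "bit_score": bit,
    }


def emit_alignment_table(truth: PlantedTruth, config: SimConfig) -> pd.DataFrame:
    """Materialise the hit table implied by the planted truth.

    True pairs draw from the strong E-value class (with a point mass at
    E = 0); secondary rows within a tandem family sit ``paralog_offset``
    log10 units per extra copy above the family's primary pair so the primary
    stays the best hit on both the query and subject side; noise pairs draw
    from the weak class. One row per (query, subject) relation, deterministic
    under the configured seed.
    """
    rng = np.random.default_rng([config.seed, 7])
    em = config.evalue_model
    rows: list[dict] = []
    seen: set[tuple[str, str]] = set()

    # Per family site, ONE base draw is shared by every cross pair, with a
    # fixed log10 offset per extra copy index on either side; this pins the
    # (primary, primary) pair as the best hit for every family member on
    # both the query and the subject side.
    array_pairs: dict[tuple[str, str], tuple[int, float]] = {}
    site_base: dict[int, float | None] = {}
    arrays_by_site: dict[int, list[PlantedArray]] = {}
    for arr in truth.tandem_arrays:
        arrays_by_site.setdefault(arr.site_id, []).append(arr)
    for site_id, site_arrays in arrays_by_site.items():
        a_arr = next((a for a in site_arrays if a.species == config.species_a), None)
        b_arr = next((a for a in site_arrays if a.species == config.species_b), None)
        if a_arr and b_arr:
            for i, qa in enumerate(a_arr.member_loci):
                for j, sb in enumerate(b_arr.member_loci):
                    array_pairs[(qa, sb)] = (site_id, em.paralog_offset * (i + j))
        elif b_arr:
            for j, sb in enumerate(b_arr.member_loci):
                array_pairs[(b_arr.counterpart_locus, sb)] = (
                    site_id, em.paralog_offset * j,
                )
        # A-only arrays: every member-counterpart row is an ordinary true pair
        if (a_arr and b_arr) or b_arr:
            if rng.random() < em.zero_fraction:
                site_base[site_id] = None  # primary pair reports E = 0
            else:
                site_base[site_id] = float(
                    rng.normal(em.true_log10_mean, em.true_log10_sd)
                )

    def family_log10(site_id: int, offset: float) -> float | None:
        base = site_base[site_id]
        if offset == 0.0:
            return base
        return (-220.0 if base is None else base) + offset

    def true_log10() -> float | None:
        if rng.random() < em.zero_fraction:
            return None  # literal E = 0
        return float(rng.normal(em.true_log10_mean, em.true_log10_sd))

    for query, subject in truth.ortholog_pairs:
        if (query, subject) in array_pairs:
            site_id, offset = array_pairs.pop((query, subject))
            log10_e = family_log10(site_id, offset)
        else:
            log10_e = true_log10()
        rows.append(_row(rng, query, subject, log10_e))
        seen.add((query, subject))
    for (query, subject), (site_id, offset) in sorted(array_pairs.items()):
        if (query, subject) in seen:
            continue
        rows.append(_row(rng, query, subject, family_log10(site_id, offset)))
        seen.add((query, subject))
    for query, subject in truth.noise_hits:
        if (query, subject) in seen:
            continue
        rows.append(
            _row(rng, query, subject,
                 float(rng.normal(em.noise_log10_mean, em.noise_log10_sd)))
        )
        seen.add((query, subject))
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def write_alignment_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write hits as headerless 12-column TSV; exact zero prints as ``0.0``."""
    table.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# stress catalog


def _default_go_weights() -> np.ndarray:
    # shares echoing the classic catalog: transcription factors (class 3),
    # signalling (4) and stress/defense response (6) dominate
    weights = np.full(N_GO_CLASSES, np.nan)
    weights[2] = 196 / 1377
    weights[3] = 110 / 1377
    weights[5] = 0.134
    rest = (1.0 - np.nansum(weights)) / (N_GO_CLASSES - 3)
    weights[np.isnan(weights)] = rest
    return weights


#: Per-cue weights: ``misc`` is the probability of a miscellaneous-only gene;
#: the stress entries weight which cues a stress gene receives.
DEFAULT_CUE_PROBS: Mapping[str, float] = {
    MISC_CUE: 128 / 1377,
    "drought": 811 / 1545,
    "salt": 434 / 1545,
    "cold": 300 / 1545,
}

#: P(exactly 1, 2, 3 stress cues) for a stress-responsive gene. Real stress
#: catalogs show far *less* cue overlap than independent assignment would
#: give: most genes respond to a single cue, a small minority to all three.
DEFAULT_N_CUE_PROBS: tuple[float, float, float] = (0.852, 0.058, 0.090)


def simulate_stress_catalog(
    n_genes: int,
    go_weights: Sequence[float] | None = None,
    cue_probs: Mapping[str, float] | None = None,
    source_pool: int = 20,
    seed: int = 0,
    multi_source_prob: float = 188 / 1377,
    n_cue_probs: tuple[float, float, float] = DEFAULT_N_CUE_PROBS,
    locus_ids: Sequence[str] | None = None,
) -> list[StressGene]:
    """Generate a stress-gene catalog with overlapping cue structure.

    Each gene gets exactly one GO class (multinomial on *go_weights*) and a
    non-empty cue set: miscellaneous-only with probability
    ``cue_probs["misc"]``, otherwise the *number* of stress cues is drawn
    from ``n_cue_probs`` and the cue identities by weight (without
    replacement) from the stress entries of ``cue_probs``; a stress cue with
    weight exactly 1.0 is always included. Evidence sources come from a pool
    of ``source_pool`` labels, two or more with ``multi_source_prob``.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if source_pool < 1:
        raise ValueError("source_pool must be at least 1")
    weights = np.asarray(
        _default_go_weights() if go_weights is None else go_weights, dtype=float
    )
    if weights.size != N_GO_CLASSES:
        raise ValueError(f"go_weights must have {N_GO_CLASSES} entries")
    if not math.isclose(float(weights.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("go_weights must sum to 1")
    probs = dict(DEFAULT_CUE_PROBS if cue_probs is None else cue_probs)
    if locus_ids is not None and len(locus_ids) != n_genes:
        raise ValueError("locus_ids length must equal n_genes")
    if not math.isclose(sum(n_cue_probs), 1.0, abs_tol=1e-9) or min(n_cue_probs) < 0:
        raise ValueError("n_cue_probs must be a probability vector over 1..3 cues")
    stress_weights = np.array([probs.get(c, 0.0) for c in STRESS_CUES], dtype=float)
    forced = [c for c, w in zip(STRESS_CUES, stress_weights) if w == 1.0]
    if stress_weights.sum() <= 0:
        raise ValueError("at least one stress cue needs positive weight")
    rng = np.random.default_rng(seed)
    genes: list[StressGene] = []
    for i in range(n_genes):
        locus = locus_ids[i] if locus_ids is not None else f"SG{i + 1:05d}"
        go = int(rng.choice(N_GO_CLASSES, p=weights)) + 1
        if rng.random() < probs.get(MISC_CUE, 0.0):
            cues = frozenset({MISC_CUE})
        else:
            n_cues = max(1 + int(rng.choice(3, p=list(n_cue_probs))), len(forced))
            chosen = list(forced)
            open_cues = [c for c in STRESS_CUES if c not in forced]
            while len(chosen) < n_cues and open_cues:
                w = np.array([probs.get(c, 0.0) for c in open_cues], dtype=float)
                if w.sum() <= 0:
                    break
                pick = open_cues[int(rng.choice(len(open_cues), p=w / w.sum()))]
                chosen.append(pick)
                open_cues.remove(pick)
            cues = frozenset(chosen)
        if rng.random() < multi_source_prob:
            k = 2 + int(rng.poisson(0.8))
        else:
            k = 1
        k = min(k, source_pool)
        picks = rng.choice(source_pool, size=k, replace=False)
        sources = frozenset(f"src{int(p) + 1:02d}" for p in picks)
        genes.append(StressGene(locus_id=locus, go_class=go, cues=cues, sources=sources))
    return genes


# --------------------------------------------------------------------------
# PPI


def simulate_ppi(
    node_pool: Sequence[str],
    n_edges_per_source: tuple[int, int] = (100, 80),
    overlap_fraction: float = 0.25,
    seed: int = 0,
    source_labels: tuple[str, str] = ("source1", "source2"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two undirected edge lists sharing s = round(overlap * min(n1,n2)) edges.

    No self-loops; no duplicate edges within a source; shared edges are
    identical (up to endpoint order) across the two sources.
    """
    if not node_pool:
        raise ValueError("node_pool must be non-empty")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0,1]")
    n1, n2 = n_edges_per_source
    shared = round(overlap_fraction * min(n1, n2))
    needed = n1 + n2 - shared
    n = len(node_pool)
    possible = n * (n - 1) // 2
    if needed > possible:
        raise InfeasibleConfigError(
            f"{needed} distinct edges requested but only {possible} node pairs exist"
        )
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[int, int]] = set()
    while len(pairs) < needed:
        i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((node_pool[key[0]], node_pool[key[1]]))
    shared_pairs = pairs[:shared]
    only1 = pairs[shared : shared + (n1 - shared)]
    only2 = pairs[shared + (n1 - shared) :]

    def frame(edges: Sequence[tuple[str, str]], label: str) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node_a": a, "node_b": b, "source": label} for a, b in edges],
            columns=["node_a", "node_b", "source"],
        )

    return (
        frame(shared_pairs + only1, source_labels[0]),
        frame(shared_pairs + only2, source_labels[1]),
    )


# --------------------------------------------------------------------------
# truth serialisation


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2) + "\n")


def load_truth(path: str | Path) -> PlantedTruth:
    raw = json.loads(Path(path).read_text())
    return PlantedTruth(
        ortholog_pairs=tuple(tuple(p) for p in raw["ortholog_pairs"]),
        blocks=tuple(
            PlantedBlock(
                chromosome_a=b["chromosome_a"],
                chromosome_b=b["chromosome_b"],
                anchor_pairs=tuple(tuple(p) for p in b["anchor_pairs"]),
                orientation=b["orientation"],
            )
            for b in raw["blocks"]
        ),
        tandem_arrays=tuple(
            PlantedArray(
                species=a["species"],
                chromosome=a["chromosome"],
                member_loci=tuple(a["member_loci"]),
                counterpart_locus=a["counterpart_locus"],
                site_id=a["site_id"],
                category=a["category"],
            )
            for a in raw["tandem_arrays"]
        ),
        noise_hits=tuple(tuple(p) for p in raw["noise_hits"]),
        loci_a=tuple(raw["loci_a"]),
        loci_b=tuple(raw["loci_b"]),
    )
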