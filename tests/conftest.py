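from __future__ import annotations

import numpy as np
import pytest

from locustrans.orthologs import AlignmentHit
from locustrans.simulate import SimConfig, emit_alignment_table, simulate_genome_pair
from locustrans.synteny import AnchorPair, GeneModel


def make_hit(query: str, subject: str, evalue: float, bit: float = 100.0,
             length: int = 200, pident: float = 80.0) -> AlignmentHit:
    return AlignmentHit(
        query_locus=query,
        subject_locus=subject,
        percent_identity=pident,
        alignment_length=length,
        mismatches=int(length * 0.2),
        gap_opens=1,
        query_start=1,
        query_end=length,
        subject_start=1,
        subject_end=length,
        evalue=evalue,
        bit_score=bit,
    )


def make_anchor(
    rank_a: int,
    rank_b: int,
    start_a: int | None = None,
    start_b: int | None = None,
    chrom_a: str = "AChr1",
    chrom_b: str = "BChr1",
) -> AnchorPair:
    """Anchor with default ~100 kb gene spacing (well under the 2 Mb rule)."""
    sa = rank_a * 100_000 if start_a is None else start_a
    sb = rank_b * 100_000 if start_b is None else start_b
    return AnchorPair(
        gene_a=GeneModel(f"A{chrom_a}_{rank_a}", "A", chrom_a, sa, sa + 1000,
                         rank=rank_a),
        gene_b=GeneModel(f"B{chrom_b}_{rank_b}", "B", chrom_b, sb, sb + 1000,
                         rank=rank_b),
    )


def anchors_from_b_ranks(b_ranks: list[int], **kwargs) -> list[AnchorPair]:
    return [make_anchor(i, rb, **kwargs) for i, rb in enumerate(b_ranks)]


@pytest.fixture(scope="session")
def noisefree_world():
    """One deterministic noise-free genome pair with its alignment table."""
    config = SimConfig(seed=202, n_blocks=6, n_tandem_arrays=5,
                       noise_hit_rate=0.0)
    models_a, models_b, truth = simulate_genome_pair(config)
    table = emit_alignment_table(truth, config)
    hits = [AlignmentHit(**row) for row in table.to_dict("records")]
    return config, models_a, models_b, truth, table, hits


def random_anchor_set(rng: np.random.Generator, max_anchors: int = 500) -> list[AnchorPair]:
    """A random anchor configuration exercising all three block criteria.

    Counterpart ranks repeat and jump; coordinates follow the ranks with
    occasional gaps beyond 2 Mb on either genome.
    """
    n = int(rng.integers(2, max_anchors + 1))
    n_b_genes = max(4, int(rng.integers(n // 2 + 1, n * 2 + 1)))
    gaps_a = rng.choice([80_000, 400_000, 2_500_000], size=n, p=[0.6, 0.3, 0.1])
    starts_a = np.cumsum(gaps_a)
    gaps_b = rng.choice([80_000, 400_000, 2_500_000], size=n_b_genes,
                        p=[0.6, 0.3, 0.1])
    starts_b = np.cumsum(gaps_b)
    chrom_bs = ["BChr1", "BChr2"]
    anchors = []
    for i in range(n):
        # mixture of locally collinear stretches and random jumps
        if i and rng.random() < 0.5:
            prev = anchors[-1].gene_b.rank
            rb = int(np.clip(prev + rng.integers(-2, 3), 0, n_b_genes - 1))
        else:
            rb = int(rng.integers(0, n_b_genes))
        anchors.append(
            make_anchor(
                i,
                rb,
                start_a=int(starts_a[i]),
                start_b=int(starts_b[rb]),
                chrom_b=chrom_bs[int(rng.integers(0, 2))],
            )
        )
    return anchors
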