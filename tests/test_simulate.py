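import numpy as np
import pytest

from locustrans.gff import read_gene_models, write_gene_models
from locustrans.orthologs import AlignmentHit, best_hits_per_query
from locustrans.simulate import (
    InfeasibleConfigError,
    SimConfig,
    emit_alignment_table,
    load_truth,
    simulate_genome_pair,
    simulate_ppi,
    simulate_stress_catalog,
    write_alignment_table,
    write_truth,
)
from locustrans.synteny import detect_synteny_blocks, build_anchors
from locustrans.catalog import stress_venn


def small(**overrides):
    base = dict(n_genes_a=400, n_genes_b=400, n_chromosomes_a=3,
                n_chromosomes_b=3, chromosome_length=30_000_000,
                n_blocks=3, n_tandem_arrays=2)
    base.update(overrides)
    return base


class TestConfigValidation:
    def test_block_minimum_enforced(self):
        with pytest.raises(ValueError, match="block_size_range"):
            SimConfig(seed=1, block_size_range=(3, 6))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, inversion_fraction=1.5)

    def test_genes_must_fit_on_chromosomes(self):
        with pytest.raises(InfeasibleConfigError):
            simulate_genome_pair(
                SimConfig(seed=1, n_genes_a=50_000, n_chromosomes_a=1,
                          chromosome_length=1_000_000)
            )

    def test_sparse_genome_breaks_gap_rule(self):
        # 4 genes on a 100 Mb chromosome: spacing alone exceeds 2 Mb
        with pytest.raises(InfeasibleConfigError):
            simulate_genome_pair(
                SimConfig(seed=1, n_genes_a=4, n_genes_b=4, n_chromosomes_a=1,
                          n_chromosomes_b=1, chromosome_length=100_000_000,
                          n_blocks=1, n_tandem_arrays=0)
            )


class TestGenomePair:
    def test_empty_truth_when_nothing_planted(self):
        config = SimConfig(seed=5, **small(n_blocks=0, n_tandem_arrays=0,
                                    ortholog_fraction=0.0, noise_hit_rate=0.0))
        _, _, truth = simulate_genome_pair(config)
        assert truth.blocks == () and truth.ortholog_pairs == ()
        assert emit_alignment_table(truth, config).empty

    def test_determinism_byte_identical(self, tmp_path):
        config = SimConfig(seed=77, **small())
        outputs = []
        for tag in ("x", "y"):
            models_a, models_b, truth = simulate_genome_pair(config)
            d = tmp_path / tag
            d.mkdir()
            write_gene_models(models_a, d / "a.gff3")
            write_gene_models(models_b, d / "b.gff3")
            write_alignment_table(emit_alignment_table(truth, config), d / "aln.tsv")
            write_truth(truth, d / "truth.json")
            outputs.append(
                tuple((d / f).read_bytes()
                      for f in ("a.gff3", "b.gff3", "aln.tsv", "truth.json"))
            )
        assert outputs[0] == outputs[1]

    def test_gene_layout_is_well_formed(self):
        config = SimConfig(seed=3, **small())
        models_a, _, _ = simulate_genome_pair(config)
        by_chrom = {}
        for m in models_a:
            by_chrom.setdefault(m.chromosome, []).append(m)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            assert [g.rank for g in genes] == list(range(len(genes)))
            for prev, nxt in zip(genes, genes[1:]):
                assert prev.end <= nxt.start  # non-overlapping
            assert genes[-1].end <= config.chromosome_length

    def test_locus_ids_encode_rank_order(self):
        config = SimConfig(seed=3, **small())
        models_a, _, _ = simulate_genome_pair(config)
        for m in models_a:
            assert int(m.locus_id.split("g")[1]) == (m.rank + 1) * 10

    def test_planted_blocks_detected_exactly(self):
        config = SimConfig(seed=11, block_size_range=(4, 6),
                           **small(inversion_fraction=0.0, noise_hit_rate=0.0))
        models_a, models_b, truth = simulate_genome_pair(config)
        hits = [AlignmentHit(**r)
                for r in emit_alignment_table(truth, config).to_dict("records")]
        anchors, _ = build_anchors(best_hits_per_query(hits), models_a, models_b)
        blocks = detect_synteny_blocks(anchors)
        assert len(blocks) == 3
        detected = {
            tuple((a.gene_a.locus_id, a.gene_b.locus_id) for a in b.anchors)
            for b in blocks
        }
        assert detected == {b.anchor_pairs for b in truth.blocks}
        assert all(b.orientation.value == "increasing" for b in blocks)

    def test_decreasing_blocks_have_decreasing_counterpart_ranks(self):
        config = SimConfig(seed=19,
                           **small(n_blocks=4, inversion_fraction=1.0,
                                   noise_hit_rate=0.0))
        _, models_b, truth = simulate_genome_pair(config)
        rank = {m.locus_id: m.rank for m in models_b}
        for block in truth.blocks:
            assert block.orientation == "decreasing"
            ranks_b = [rank[b] for _, b in block.anchor_pairs]
            assert all(x > y for x, y in zip(ranks_b, ranks_b[1:]))

    def test_truth_json_round_trip(self, tmp_path):
        config = SimConfig(seed=23, **small(n_blocks=2, n_tandem_arrays=3))
        _, _, truth = simulate_genome_pair(config)
        write_truth(truth, tmp_path / "t.json")
        assert load_truth(tmp_path / "t.json") == truth


class TestAlignmentTable:
    def test_single_pair_no_noise_single_row(self):
        config = SimConfig(seed=2,
                           **small(n_blocks=0, n_tandem_arrays=0,
                                   ortholog_fraction=1 / 400,
                                   noise_hit_rate=0.0))
        _, _, truth = simulate_genome_pair(config)
        assert len(truth.ortholog_pairs) == 1
        table = emit_alignment_table(truth, config)
        assert len(table) == 1

    def test_tandem_array_rows_share_subject(self):
        config = SimConfig(seed=8, tandem_site_probs=(1.0, 0.0, 0.0),
                           tandem_copy_range=(3, 3),
                           **small(n_blocks=0, n_tandem_arrays=1,
                                   ortholog_fraction=0.0, noise_hit_rate=0.0))
        _, _, truth = simulate_genome_pair(config)
        (array,) = truth.tandem_arrays
        table = emit_alignment_table(truth, config)
        assert len(table) == 3
        assert set(table.subject_locus) == {array.counterpart_locus}

    def test_strong_evalues_recover_all_planted_pairs(self):
        config = SimConfig(seed=13, **small(noise_hit_rate=2.0))
        _, _, truth = simulate_genome_pair(config)
        hits = [AlignmentHit(**r)
                for r in emit_alignment_table(truth, config).to_dict("records")]
        calls = best_hits_per_query(hits)
        recovered = {(c.query_locus, c.subject_locus) for c in calls}
        assert set(truth.ortholog_pairs) <= recovered

    def test_every_planted_query_has_a_row(self, noisefree_world):
        _, _, _, truth, table, _ = noisefree_world
        assert {q for q, _ in truth.ortholog_pairs} <= set(table.query_locus)


class TestStressCatalogSim:
    def test_empty(self):
        assert simulate_stress_catalog(0, seed=1) == []

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_stress_catalog(10, go_weights=[1.0] * 18, seed=1)
        with pytest.raises(ValueError):
            simulate_stress_catalog(10, source_pool=0, seed=1)

    def test_forced_triple_overlap(self):
        catalog = simulate_stress_catalog(
            40, cue_probs={"misc": 0.0, "drought": 1.0, "salt": 1.0, "cold": 1.0},
            seed=2,
        )
        assert stress_venn(catalog).triple == 40

    def test_go_proportions_within_binomial_bounds(self):
        n = 1000
        weights = np.full(18, 1 / 18)
        catalog = simulate_stress_catalog(n, go_weights=weights, seed=14)
        from collections import Counter

        counts = Counter(g.go_class for g in catalog)
        p = 1 / 18
        sigma = np.sqrt(n * p * (1 - p))
        for k in range(1, 19):
            assert abs(counts.get(k, 0) - n * p) <= 3 * sigma

    def test_every_gene_well_formed(self):
        for g in simulate_stress_catalog(300, seed=21):
            assert g.cues and g.sources and 1 <= g.go_class <= 18


class TestPPISim:
    def test_full_overlap(self):
        pool = [f"N{i}" for i in range(80)]
        df1, df2 = simulate_ppi(pool, (50, 50), overlap_fraction=1.0, seed=4)
        from locustrans.ppi import merge_ppi

        assert merge_ppi([df1, df2]).number_of_edges() == 50

    def test_no_overlap(self):
        pool = [f"N{i}" for i in range(80)]
        df1, df2 = simulate_ppi(pool, (50, 40), overlap_fraction=0.0, seed=4)
        from locustrans.ppi import merge_ppi

        assert merge_ppi([df1, df2]).number_of_edges() == 90

    def test_no_self_loops_or_duplicates_within_source(self):
        pool = [f"N{i}" for i in range(30)]
        df1, _ = simulate_ppi(pool, (60, 10), 0.5, seed=9)
        assert (df1.node_a != df1.node_b).all()
        canon = df1.apply(lambda r: tuple(sorted((r.node_a, r.node_b))), axis=1)
        assert canon.is_unique

    def test_infeasible_edge_count(self):
        with pytest.raises(InfeasibleConfigError):
            simulate_ppi(["a", "b", "c"], (10, 10), 0.0, seed=1)


class TestGFF:
    def test_round_trip(self, tmp_path):
        config = SimConfig(seed=6, **small())
        models_a, _, _ = simulate_genome_pair(config)
        path = tmp_path / "a.gff3"
        write_gene_models(models_a, path)
        back = read_gene_models(path, "At")
        key = lambda ms: {(m.locus_id, m.chromosome, m.start, m.end, m.strand)
                          for m in ms}
        assert key(back) == key(models_a)
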