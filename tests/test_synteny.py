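import numpy as np
import pytest

from locustrans.orthologs import OrthologCall, Remark, best_hits_per_query
from locustrans.synteny import (
    GeneModel,
    Orientation,
    build_anchors,
    classify_tandem_sites,
    detect_synteny_blocks,
    detect_tandem_arrays,
    export_comparative_map,
    rank_genes,
    validate_block,
)

from .conftest import anchors_from_b_ranks, make_anchor, make_hit, random_anchor_set
from ._oracles import brute_force_blocks


def _call(query, subject, evalue=1e-80):
    from locustrans.orthologs import assign_evalue_bin

    return OrthologCall(
        query_locus=query,
        subject_locus=subject,
        evalue=evalue,
        bin=assign_evalue_bin(evalue),
        remark=Remark.UQ,
        n_significant_hits=1,
        score_gap=float("inf"),
    )


class TestRanking:
    def test_ranks_follow_start_coordinates(self):
        genes = [
            GeneModel("g1", "A", "c1", 100, 200),
            GeneModel("g2", "A", "c1", 50, 80),
            GeneModel("g3", "A", "c1", 200, 300),
        ]
        ranked = {g.locus_id: g.rank for g in rank_genes(genes)}
        assert ranked == {"g2": 0, "g1": 1, "g3": 2}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        genes = [
            GeneModel(f"g{i}", "A", f"c{i % 3}", int(s), int(s) + 10)
            for i, s in enumerate(rng.choice(10_000, size=50, replace=False))
        ]
        ref = {g.locus_id: g.rank for g in rank_genes(genes)}
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert {g.locus_id: g.rank for g in rank_genes(shuffled)} == ref

    def test_duplicate_locus_ids_rejected(self):
        genes = [
            GeneModel("g1", "A", "c1", 0, 10),
            GeneModel("g1", "A", "c2", 0, 10),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            rank_genes(genes)


class TestAnchors:
    def test_unknown_locus_skipped_and_counted(self):
        models_a = rank_genes([GeneModel("a1", "A", "c1", 0, 10)])
        models_b = rank_genes([GeneModel("b1", "B", "c1", 0, 10)])
        calls = [_call("a1", "b1"), _call("aX", "b1"), _call("a1X", "bX")]
        anchors, skipped = build_anchors(calls, models_a, models_b)
        assert len(anchors) == 1 and skipped == 2

    def test_zero_calls(self):
        anchors, skipped = build_anchors([], [], [])
        assert anchors == [] and skipped == 0


class TestBlockDetection:
    def test_minimal_increasing_block(self):
        blocks = detect_synteny_blocks(anchors_from_b_ranks([1, 2, 3, 4]))
        assert len(blocks) == 1
        assert blocks[0].orientation is Orientation.INCREASING
        assert blocks[0].n_anchors == 4

    def test_inversion_block(self):
        blocks = detect_synteny_blocks(anchors_from_b_ranks([9, 7, 5, 3, 1]))
        assert len(blocks) == 1
        assert blocks[0].orientation is Orientation.DECREASING
        assert blocks[0].n_anchors == 5

    def test_three_anchors_are_not_a_block(self):
        assert detect_synteny_blocks(anchors_from_b_ranks([1, 2, 3])) == []

    def test_direction_switch_restarts_chain(self):
        # 1,2,3,4 up then 3,2,1,0 down: two blocks, no anchor reuse
        blocks = detect_synteny_blocks(anchors_from_b_ranks([1, 2, 3, 4, 3, 2, 1, 0]))
        assert [b.orientation for b in blocks] == [
            Orientation.INCREASING,
            Orientation.DECREASING,
        ]
        all_anchors = [a for b in blocks for a in b.anchors]
        assert len(all_anchors) == len(set(id(a) for a in all_anchors)) == 8

    def test_block_found_after_noise_prefix(self):
        # a stray high-rank anchor precedes a clean run
        blocks = detect_synteny_blocks(anchors_from_b_ranks([50, 1, 2, 3, 4]))
        assert len(blocks) == 1 and blocks[0].n_anchors == 4

    def test_gap_rule_on_genome_a(self):
        anchors = anchors_from_b_ranks([1, 2, 3, 4])
        far = make_anchor(4, 5, start_a=anchors[-1].gene_a.start + 2_500_000)
        blocks = detect_synteny_blocks(anchors + [far])
        assert blocks[0].n_anchors == 4
        blocks = detect_synteny_blocks(anchors + [far], max_gap=3_000_000)
        assert blocks[0].n_anchors == 5

    def test_gap_rule_on_genome_b(self):
        anchors = anchors_from_b_ranks([1, 2, 3, 4])
        far = make_anchor(4, 30, start_b=3_000_000 + anchors[-1].gene_b.start)
        assert detect_synteny_blocks(anchors + [far])[0].n_anchors == 4

    def test_equal_counterpart_rank_breaks_chain(self):
        # two queries hitting the same counterpart cannot be collinear
        anchors = anchors_from_b_ranks([1, 2, 2, 3, 4])
        assert detect_synteny_blocks(anchors) == []

    def test_detected_blocks_validate_independently(self, noisefree_world):
        _, models_a, models_b, _, _, hits = noisefree_world
        calls = best_hits_per_query(hits)
        anchors, _ = build_anchors(calls, models_a, models_b)
        blocks = detect_synteny_blocks(anchors)
        assert blocks
        assert all(validate_block(b) for b in blocks)
        seen = set()
        for b in blocks:
            for a in b.anchors:
                key = (a.gene_a.locus_id, a.gene_b.locus_id)
                assert key not in seen
                seen.add(key)

    def test_monotone_parameter_response(self, noisefree_world):
        _, models_a, models_b, _, _, hits = noisefree_world
        anchors, _ = build_anchors(best_hits_per_query(hits), models_a, models_b)
        n_blocks = [
            len(detect_synteny_blocks(anchors, min_anchors=k)) for k in (4, 5, 6, 8)
        ]
        assert n_blocks == sorted(n_blocks, reverse=True)
        in_blocks = [
            sum(b.n_anchors for b in detect_synteny_blocks(anchors, max_gap=g))
            for g in (500_000, 2_000_000, 5_000_000)
        ]
        assert in_blocks == sorted(in_blocks)

    def test_agrees_with_brute_force_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            anchors = random_anchor_set(rng, max_anchors=120)
            fast = [
                tuple((a.gene_a.locus_id, a.gene_b.locus_id) for a in b.anchors)
                for b in detect_synteny_blocks(anchors)
            ]
            assert sorted(fast) == sorted(brute_force_blocks(anchors))


class TestTandem:
    def _models(self, n=8, species="A", chrom="c1"):
        return rank_genes(
            [
                GeneModel(f"{species}{i}", species, chrom, i * 1000, i * 1000 + 500)
                for i in range(n)
            ]
        )

    def test_adjacent_pair_sharing_counterpart(self):
        models = self._models()
        hits = [make_hit("A1", "bX", 1e-80), make_hit("A2", "bX", 1e-75)]
        arrays = detect_tandem_arrays(models, hits)
        assert len(arrays) == 1
        assert arrays[0].member_loci == ("A1", "A2")
        assert arrays[0].counterpart_locus == "bX"

    def test_distant_genes_do_not_form_array(self):
        models = self._models()
        hits = [make_hit("A1", "bX", 1e-80), make_hit("A5", "bX", 1e-75)]
        assert detect_tandem_arrays(models, hits, max_intervening=1) == []

    def test_one_intervening_gene_allowed(self):
        models = self._models()
        hits = [make_hit("A1", "bX", 1e-80), make_hit("A3", "bX", 1e-75)]
        assert len(detect_tandem_arrays(models, hits, max_intervening=1)) == 1
        assert detect_tandem_arrays(models, hits, max_intervening=0) == []

    def test_subject_side_array_detected(self):
        # duplicates on genome B are found via the subject side of the hits
        models_b = self._models(species="B")
        hits = [make_hit("aX", "B3", 1e-90), make_hit("aX", "B4", 1e-82)]
        arrays = detect_tandem_arrays(models_b, hits)
        assert len(arrays) == 1
        assert arrays[0].member_loci == ("B3", "B4")
        assert arrays[0].counterpart_locus == "aX"

    def test_planted_arrays_and_site_classes_recovered(self, noisefree_world):
        config, models_a, models_b, truth, _, hits = noisefree_world
        arrays = detect_tandem_arrays(models_a + models_b, hits)
        detected = {(a.species, a.member_loci, a.counterpart_locus) for a in arrays}
        planted = {
            (a.species, a.member_loci, a.counterpart_locus)
            for a in truth.tandem_arrays
        }
        assert detected == planted
        sites = classify_tandem_sites(arrays, config.species_a, config.species_b)
        from collections import Counter

        truth_sites = Counter(
            {a.site_id: a.category for a in truth.tandem_arrays}.values()
        )
        assert Counter(s.category for s in sites) == truth_sites


class TestExport:
    def test_round_trip_preserves_block_membership(self, tmp_path, noisefree_world):
        import pandas as pd

        _, models_a, models_b, _, _, hits = noisefree_world
        anchors, _ = build_anchors(best_hits_per_query(hits), models_a, models_b)
        blocks = detect_synteny_blocks(anchors)
        paths = export_comparative_map(blocks, anchors, tmp_path)
        links = pd.read_csv(paths["links"], sep="\t")
        assert len(links) == len(anchors)
        by_block = (
            links.dropna(subset=["block_id"])
            .groupby("block_id")["locus_a"]
            .apply(tuple)
            .to_dict()
        )
        expected = {
            float(b.block_id): tuple(a.gene_a.locus_id for a in b.anchors)
            for b in blocks
        }
        assert by_block == expected

    def test_zero_blocks_leaves_block_column_empty(self, tmp_path):
        import pandas as pd

        anchors = anchors_from_b_ranks([5, 1, 4, 2])
        paths = export_comparative_map([], anchors, tmp_path)
        links = pd.read_csv(paths["links"], sep="\t")
        assert links["block_id"].isna().all()
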