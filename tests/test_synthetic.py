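"""The ground-truth generator, the binner noise models and truth evaluation."""

import pytest

import magrefine as mg


class TestGenerateTruth:
    def test_same_seed_reproduces(self, small_marker_sets):
        a = mg.generate_truth(4, contigs_per_genome=6, seed=11, marker_sets=small_marker_sets)
        b = mg.generate_truth(4, contigs_per_genome=6, seed=11, marker_sets=small_marker_sets)
        assert a == b

    def test_different_seed_differs(self, small_marker_sets):
        a = mg.generate_truth(4, contigs_per_genome=6, seed=11, marker_sets=small_marker_sets)
        b = mg.generate_truth(4, contigs_per_genome=6, seed=12, marker_sets=small_marker_sets)
        assert a != b

    def test_contigs_unique_across_genomes(self, small_marker_sets):
        truth = mg.generate_truth(5, contigs_per_genome=6, seed=0, marker_sets=small_marker_sets)
        all_contigs = [c for cs in truth.genomes.values() for c in cs]
        assert len(all_contigs) == len(set(all_contigs))

    def test_markers_within_domain_set(self, small_marker_sets):
        truth = mg.generate_truth(4, contigs_per_genome=6, seed=2,
                                  archaeal_fraction=0.5, marker_sets=small_marker_sets)
        for gid, contigs in truth.genomes.items():
            mset = small_marker_sets[truth.genome_domain[gid]]
            for c in contigs:
                assert set(truth.contig_markers[c]) <= mset.marker_ids

    def test_too_many_markers_rejected(self, small_marker_sets):
        with pytest.raises(ValueError):
            mg.generate_truth(2, markers_per_genome=9999, marker_sets=small_marker_sets)

    def test_perfect_genome_scores_one(self, marker_sets):
        truth = mg.generate_truth(1, contigs_per_genome=10, duplicate_marker_rate=0.0,
                                  archaeal_fraction=0.0, seed=4, marker_sets=marker_sets)
        hits = mg.truth_annotation_hits(truth)
        anns = mg.select_best_hits(hits)
        (gid, contigs), = truth.genomes.items()
        prof = mg.build_profiles(
            [mg.Bin(gid, "truth", frozenset(contigs))], anns, marker_sets["bacteria"])[gid]
        assert mg.score_profile(prof, marker_sets["bacteria"]).score == 1.0

    def test_zero_duplicate_rate_no_duplicates(self, marker_sets):
        truth = mg.generate_truth(4, contigs_per_genome=8, duplicate_marker_rate=0.0,
                                  seed=6, marker_sets=marker_sets)
        anns = mg.select_best_hits(mg.truth_annotation_hits(truth))
        for gid, contigs in truth.genomes.items():
            mset = marker_sets[truth.genome_domain[gid]]
            prof = mg.build_profiles(
                [mg.Bin(gid, "truth", frozenset(contigs))], anns, mset)[gid]
            assert mg.score_profile(prof, mset).duplicate_fraction == 0.0


class TestSimulateBinners:
    def test_zero_noise_reproduces_truth(self, small_marker_sets):
        truth = mg.generate_truth(4, contigs_per_genome=6, seed=1, marker_sets=small_marker_sets)
        binsets, _hits = mg.simulate_binners(truth, [mg.NoiseModel(label="clean")])
        bins = {}
        for rec in binsets[0]:
            bins.setdefault(rec.bin_id, set()).add(rec.contig_id)
        assert sorted(map(frozenset, bins.values())) == sorted(
            map(frozenset, truth.genomes.values()))

    def test_every_binset_is_a_partition(self, small_marker_sets):
        truth = mg.generate_truth(6, contigs_per_genome=8, seed=2, marker_sets=small_marker_sets)
        binsets, _ = mg.simulate_binners(truth, mg.default_noise_models(seed=2))
        for records in binsets:
            assert mg.is_partition(records)

    def test_split_prob_one_splits_every_genome(self, small_marker_sets):
        truth = mg.generate_truth(4, contigs_per_genome=6, seed=3, marker_sets=small_marker_sets)
        binsets, _ = mg.simulate_binners(
            truth, [mg.NoiseModel(label="split", split_prob=1.0, seed=3)])
        assert len({r.bin_id for r in binsets[0]}) == 2 * len(truth.genomes)

    def test_merge_prob_one_fuses_same_domain_genomes(self, marker_sets):
        truth = mg.generate_truth(2, contigs_per_genome=6, duplicate_marker_rate=0.0,
                                  archaeal_fraction=0.0, seed=4, marker_sets=marker_sets)
        binsets, hits = mg.simulate_binners(
            truth, [mg.NoiseModel(label="fuse", merge_prob=1.0, seed=4)])
        bin_ids = {r.bin_id for r in binsets[0]}
        assert len(bin_ids) == 1
        anns = mg.select_best_hits(hits)
        contigs = frozenset(r.contig_id for r in binsets[0])
        prof = mg.build_profiles(
            [mg.Bin("fused", "fuse", contigs)], anns, marker_sets["bacteria"])["fused"]
        assert mg.score_profile(prof, marker_sets["bacteria"]).duplicate_fraction > 0

    def test_protein_ids_round_trip_to_contigs(self, small_marker_sets):
        truth = mg.generate_truth(3, contigs_per_genome=5, seed=5, marker_sets=small_marker_sets)
        hits = mg.truth_annotation_hits(truth)
        assert hits  # non-degenerate
        for h in hits:
            assert mg.protein_to_contig(h.protein_id) in truth.contigs

    def test_no_models_rejected(self, small_marker_sets):
        truth = mg.generate_truth(2, contigs_per_genome=4, seed=6, marker_sets=small_marker_sets)
        with pytest.raises(ValueError):
            mg.simulate_binners(truth, [])


class TestEvaluateAgainstTruth:
    def test_perfect_refinement_of_noiseless_input(self, marker_sets, pipeline):
        truth = mg.generate_truth(3, contigs_per_genome=8, archaeal_fraction=0.0,
                                  seed=7, marker_sets=marker_sets)
        binsets, hits = mg.simulate_binners(truth, [mg.NoiseModel(label="clean")])
        res = pipeline(binsets, hits, marker_sets)
        table = mg.evaluate_against_truth(res, truth)
        assert (table["true_completeness"] == 1.0).all()
        assert (table["purity"] == 1.0).all()

    def test_purity_arithmetic(self, small_marker_sets):
        truth = mg.generate_truth(2, contigs_per_genome=8, seed=8,
                                  archaeal_fraction=0.0, marker_sets=small_marker_sets)
        g1, g2 = sorted(truth.genomes)
        mixed = sorted(truth.genomes[g1])[:6] + sorted(truth.genomes[g2])[:2]
        table = mg.evaluate_against_truth({"b1": mixed}, truth)
        assert table.loc[g1, "purity"] == pytest.approx(0.75)
        assert table.loc[g1, "true_completeness"] == pytest.approx(6 / 8)

    def test_empty_result_all_zero(self, small_marker_sets):
        truth = mg.generate_truth(2, contigs_per_genome=4, seed=9, marker_sets=small_marker_sets)
        table = mg.evaluate_against_truth({}, truth)
        assert (table["true_completeness"] == 0.0).all()
        assert (table["purity"] == 0.0).all()
        assert len(table) == 2

    def test_count_high_quality(self, small_marker_sets):
        truth = mg.generate_truth(2, contigs_per_genome=4, seed=10, marker_sets=small_marker_sets)
        g1, g2 = sorted(truth.genomes)
        bins = {"b1": set(truth.genomes[g1]),
                "b2": set(list(truth.genomes[g2])[:1])}
        table = mg.evaluate_against_truth(bins, truth)
        assert mg.count_high_quality(table) == 1
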