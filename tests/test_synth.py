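"""Synthetic family generator: contracts, determinism, planted recovery."""

import numpy as np
import pytest

import fuzzyfam as ff


class TestGenerateFamilySet:
    def test_cardinality_contract(self):
        spec = ff.FamilySpec(n_families=2, seqs_per_family=20, seed=0)
        records, hits, truth = ff.generate_family_set(spec)
        assert len(records) == 40 and len(truth.labels) == 40
        architectures = {
            frozenset(h.domain_model for h in hits if h.sequence_id == r.id)
            for r in records}
        assert len(architectures) == 2  # two distinct domain architectures

    def test_same_seed_identical_output(self):
        spec = ff.FamilySpec(seed=9)
        a = ff.generate_family_set(spec)
        b = ff.generate_family_set(spec)
        assert [r.sequence for r in a[0]] == [r.sequence for r in b[0]]
        assert [(h.sequence_id, h.domain_model, h.e_value) for h in a[1]] == \
               [(h.sequence_id, h.domain_model, h.e_value) for h in b[1]]

    def test_zero_noise_identical_members(self):
        spec = ff.FamilySpec(within_noise=0.0, seqs_per_family=3, seed=2)
        records, _, truth = ff.generate_family_set(spec)
        by_family = {}
        for r in records:
            by_family.setdefault(truth.labels[r.id], set()).add(r.sequence)
        assert all(len(s) == 1 for s in by_family.values())

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ff.FamilySpec(length_range=(2, 10))
        with pytest.raises(ValueError):
            ff.FamilySpec(n_families=1)
        with pytest.raises(ValueError):
            ff.FamilySpec(within_noise=1.5)

    def test_domain_evalues_below_one(self):
        _, hits, _ = ff.generate_family_set(ff.FamilySpec(seed=1))
        assert all(0 < h.e_value < 1 for h in hits)


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        truth = ff.PlantedTruth({"a": 0, "b": 0, "c": 1})
        assert ff.adjusted_rand_index(truth, ["a", "b", "c"], [5, 5, 9]) == 1.0

    def test_single_cluster_vs_split_is_zero(self):
        truth = ff.PlantedTruth({f"s{i}": i % 2 for i in range(10)})
        ids = sorted(truth.labels)
        assert ff.adjusted_rand_index(truth, ids, [0] * 10) == pytest.approx(0.0)

    def test_random_labels_near_zero(self):
        truth = ff.PlantedTruth({f"s{i}": i % 2 for i in range(40)})
        ids = sorted(truth.labels)
        rng = np.random.default_rng(0)
        aris = [ff.adjusted_rand_index(truth, ids, rng.integers(0, 2, 40))
                for _ in range(100)]
        assert np.max(np.abs(aris)) < 0.2

    def test_id_mismatch_rejected(self):
        truth = ff.PlantedTruth({"a": 0, "b": 1})
        with pytest.raises(ValueError):
            ff.adjusted_rand_index(truth, ["a", "x"], [0, 1])


class TestGenerateEstTable:
    def test_zero_redundancy_all_unique(self):
        truth = ff.PlantedTruth({f"s{i}": i % 2 for i in range(10)})
        hits, counts = ff.generate_est_table(
            truth, ests_per_group=20, redundancy_rate=0.0, seed=0)
        assert all(v == 0 for v in counts.redundant.values())
        assert all(v > 0 for v in counts.unique.values())

    def test_zero_sharing_no_common(self):
        truth = ff.PlantedTruth({f"s{i}": i % 2 for i in range(10)})
        _, counts = ff.generate_est_table(truth, sharing_rate=0.0, seed=0)
        assert counts.common_redundant == 0 and counts.common_unique == 0

    def test_profile_recovers_planted_counts(self):
        """classify_ests + group_overlap_stats reproduce the generator's
        own ground-truth counts exactly."""
        truth = ff.PlantedTruth({f"s{i}": i % 2 for i in range(12)})
        hits, counts = ff.generate_est_table(
            truth, ests_per_group=60, redundancy_rate=0.5,
            sharing_rate=0.2, seed=3)
        p0 = ff.classify_ests(hits, "0")
        p1 = ff.classify_ests(hits, "1")
        assert p0.n_redundant == counts.redundant["0"]
        assert p1.n_redundant == counts.redundant["1"]
        assert p0.n_unique == counts.unique["0"]
        assert p1.n_unique == counts.unique["1"]
        stats = ff.group_overlap_stats(p0, p1, "0")
        assert stats.common_redundant == counts.common_redundant
        assert stats.common_unique == counts.common_unique


class TestPipelineRecovery:
    def test_default_spec_recovered_perfectly(self):
        """encode -> fanny(k=2, r=2) -> harden recovers the planted split."""
        for seed in (0, 1):
            records, hits, truth = ff.generate_family_set(ff.FamilySpec(seed=seed))
            space, vectors = ff.build_feature_matrix(records, hits)
            D = ff.dissimilarity_matrix(space, vectors)
            res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=seed))
            labels, _ = ff.harden(res.membership)
            assert ff.adjusted_rand_index(truth, D.ids, labels) == 1.0

    def test_difficulty_increases_with_noise(self):
        """Mean ARI does not improve as within-family noise rises."""
        means = []
        for noise in (0.05, 0.4):
            aris = []
            for seed in range(3):
                spec = ff.FamilySpec(within_noise=noise, seqs_per_family=8,
                                     length_range=(80, 120), seed=seed)
                records, hits, truth = ff.generate_family_set(spec)
                space, vectors = ff.build_feature_matrix(records, hits)
                D = ff.dissimilarity_matrix(space, vectors)
                res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=seed))
                labels, _ = ff.harden(res.membership)
                aris.append(ff.adjusted_rand_index(truth, D.ids, labels))
            means.append(np.mean(aris))
        assert means[1] <= means[0] + 1e-9
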