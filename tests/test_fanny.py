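"""Fuzzy clustering: objective evaluation, fit-vs-oracle, hardening."""

import numpy as np
import pytest

import fuzzyfam as ff
from conftest import random_dissim


def make_D(matrix):
    m = np.asarray(matrix, float)
    return ff.DissimilarityMatrix([f"o{i}" for i in range(len(m))], m)


class TestFannyObjective:
    def test_hand_evaluated_single_cluster(self):
        """Two points, one cluster, d=1: (1+1)/(1+1) = 1 (paper convention)."""
        U = ff.MembershipMatrix(["o0", "o1"], np.array([[1.0], [1.0]]))
        D = make_D([[0, 1], [1, 0]])
        assert ff.fanny_objective(U, D, r=2) == pytest.approx(1.0)

    def test_zero_geometry_zero_objective(self):
        U = ff.MembershipMatrix(["o0", "o1"], np.array([[0.3, 0.7], [0.6, 0.4]]))
        D = make_D(np.zeros((2, 2)))
        assert ff.fanny_objective(U, D, r=2) == 0.0

    def test_planted_indicator_on_separated_pairs(self):
        pts = np.array([0.0, 0.0, 10.0, 10.0])
        D = make_D(np.abs(pts[:, None] - pts[None, :]))
        U = ff.MembershipMatrix(D.ids, np.array(
            [[1, 0], [1, 0], [0, 1], [0, 1]], float))
        assert ff.fanny_objective(U, D, r=2) == pytest.approx(0.0)

    def test_row_sum_violation_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ff.MembershipMatrix(["o0"], np.array([[0.4, 0.4]]))


class TestFannyFit:
    def test_recovers_separated_pairs(self, line_dissim):
        res = ff.fanny_fit(line_dissim, ff.FannyConfig(k=2, r=2, seed=0))
        labels, _ = ff.harden(res.membership)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        assert res.membership.values.max(axis=1).min() > 0.95
        assert res.converged

    def test_larger_r_is_fuzzier(self, line_dissim):
        res2 = ff.fanny_fit(line_dissim, ff.FannyConfig(k=2, r=2, seed=0))
        res10 = ff.fanny_fit(line_dissim, ff.FannyConfig(k=2, r=10, seed=0))
        dev = lambda res: np.abs(res.membership.values - 0.5).max()
        assert dev(res10) < dev(res2)

    def test_zero_dissimilarity_converges_at_zero(self):
        D = make_D(np.zeros((4, 4)))
        res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=0))
        assert res.objective == 0.0 and res.converged
        assert np.allclose(res.membership.values.sum(axis=1), 1.0)

    def test_k_not_below_n_rejected(self, line_dissim):
        with pytest.raises(ValueError, match="k=4"):
            ff.fanny_fit(line_dissim, ff.FannyConfig(k=4, r=2))

    def test_seeded_determinism_bit_identical(self, line_dissim):
        a = ff.fanny_fit(line_dissim, ff.FannyConfig(k=2, r=2, seed=42))
        b = ff.fanny_fit(line_dissim, ff.FannyConfig(k=2, r=2, seed=42))
        assert np.array_equal(a.membership.values, b.membership.values)
        assert a.objective == b.objective
        assert a.restart_objectives == b.restart_objectives

    def test_label_equivariance_under_permutation(self):
        rng = np.random.default_rng(5)
        D = random_dissim(rng, 6)
        perm = rng.permutation(6)
        Dp = ff.DissimilarityMatrix(
            [D.ids[i] for i in perm], D.values[np.ix_(perm, perm)])
        la, _ = ff.harden(ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=1)).membership)
        lp, _ = ff.harden(ff.fanny_fit(Dp, ff.FannyConfig(k=2, r=2, seed=1)).membership)
        # same partition of ids, up to cluster relabeling
        part = lambda ids, lab: {frozenset(i for i, l in zip(ids, lab) if l == c)
                                 for c in set(lab)}
        assert part(D.ids, la) == part(Dp.ids, lp)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            D = random_dissim(rng, 6)
            res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=2, seed=trial))
            tr = np.array(res.objective_trace)
            assert np.all(np.diff(tr) <= 1e-12 * np.maximum(1, np.abs(tr[:-1])))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            ff.FannyConfig(k=2, r=1.0)
        with pytest.raises(ValueError):
            ff.FannyConfig(k=1, r=2.0)


class TestBruteForceOracle:
    def test_two_points_split_perfectly(self):
        obj, U = ff.brute_force_min(make_D([[0, 1], [1, 0]]), k=2, r=2)
        assert obj == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(np.sort(U, axis=1)[:, -1], 1.0, atol=1e-3)
        assert U[0].argmax() != U[1].argmax()

    def test_large_r_drives_memberships_toward_uniform(self, line_dissim):
        # fuzzification grows with r: near-crisp at r=2, strongly interior
        # at r=50 (not exactly uniform — each cluster still tilts its mass
        # onto one object, whose self-dissimilarity of zero keeps the
        # objective near zero)
        _, U2 = ff.brute_force_min(line_dissim, k=2, r=2)
        _, U50 = ff.brute_force_min(line_dissim, k=2, r=50)
        assert np.abs(U50 - 0.5).max() < np.abs(U2 - 0.5).max()
        assert np.abs(U50 - 0.5).max() < 0.35

    def test_size_guard(self):
        with pytest.raises(ValueError):
            ff.brute_force_min(np.zeros((7, 7)), k=2, r=2)

    @pytest.mark.parametrize("r", [1.5, 2.0, 8.2])
    def test_fit_matches_oracle(self, r):
        """fanny_fit reaches the global optimum found by exhaustive search."""
        rng = np.random.default_rng(int(r * 10))
        for trial in range(4):
            D = random_dissim(rng, int(rng.integers(4, 7)))
            obj_bf, _ = ff.brute_force_min(D, k=2, r=r)
            res = ff.fanny_fit(D, ff.FannyConfig(k=2, r=r, seed=trial))
            assert res.objective <= obj_bf + 1e-4 * max(abs(obj_bf), 1e-12)


class TestHarden:
    def test_argmax_label(self):
        U = ff.MembershipMatrix(["a"], np.array([[0.8, 0.2]]))
        labels, straddlers = ff.harden(U)
        assert labels[0] == 0 and not straddlers[0]

    def test_tie_to_lowest_index_and_straddler_flag(self):
        U = ff.MembershipMatrix(["a"], np.array([[0.5, 0.5]]))
        labels, straddlers = ff.harden(U)
        assert labels[0] == 0 and straddlers[0]

    def test_column_permutation_permutes_labels(self):
        vals = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        la, _ = ff.harden(ff.MembershipMatrix(list("abc"), vals))
        lb, _ = ff.harden(ff.MembershipMatrix(list("abc"), vals[:, ::-1]))
        assert np.array_equal(la, 1 - lb)
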