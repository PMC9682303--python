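"""Convergence metrics, ellipse crossings, disparity through time."""

import numpy as np
import pytest

import phylomorph as pm
from phylomorph.macro import DisparityProfile, _c_stats, min_enclosing_ellipse
from phylomorph.tree import Phylogeny

BALANCED = "((A:1,B:1):1,(C:1,D:1):1);"


class TestCMetrics:
    def test_identical_focal_tips_give_c1_one(self):
        t = Phylogeny.from_newick(BALANCED)
        # A and C identical at the tips, B and D far apart (distinct ancestors)
        scores = {"A": [0.0, 0.0], "B": [4.0, 0.0], "C": [0.0, 0.0],
                  "D": [-4.0, 0.0]}
        Y = np.array([scores[l] for l in t.tip_labels])
        c1, c2, *_ = _c_stats(t, Y, [t.index_of("A"), t.index_of("C")])
        assert c1 == pytest.approx(1.0)
        assert c2 > 0

    def test_pure_divergence_gives_zero(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        Y = np.array([[0.0], [2.0]])[[t.index_of(l) for l in ("A", "B")]]
        Y = np.array([[0.0 if l == "A" else 2.0] for l in t.tip_labels])
        c1, c2, c3, c4, dtip, dmax, _ = _c_stats(
            t, Y, [t.index_of("A"), t.index_of("B")])
        assert dtip == pytest.approx(dmax)
        assert c1 == pytest.approx(0.0)
        assert c2 == pytest.approx(0.0)

    def test_rigid_motion_invariance(self):
        t = pm.simulate_pure_birth_tree(10, seed=3)
        rng = np.random.default_rng(0)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((10, 2))
        focal = [t.tip_indices[0], t.tip_indices[5]]
        base = _c_stats(t, Y, focal)[:4]
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = Y @ R.T + np.array([3.0, -1.0])
        assert np.allclose(_c_stats(t, moved, focal)[:4], base, atol=1e-10)

    def test_result_bounds_and_pvalues(self):
        t = pm.simulate_pure_birth_tree(12, seed=1)
        rng = np.random.default_rng(2)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((12, 3))
        res = pm.convergence_c_metrics(Y, t, t.tip_labels[:2] , n_sim=50, rng=0)
        assert 0.0 <= res.c1 <= 1.0
        assert res.c2 >= 0.0
        for v in res.p.values():
            assert 0.0 < v <= 1.0

    def test_single_lineage_rejected(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        # A and its direct ancestor-side partner... use identical lineage:
        with pytest.raises(ValueError):
            pm.convergence_c_metrics(np.zeros((3, 2)), t, ["A"])


class TestEllipse:
    def test_minimal_ellipse_contains_points(self, rng):
        P = rng.normal(size=(6, 2))
        c, A = min_enclosing_ellipse(P)
        for p in P:
            assert (p - c) @ A @ (p - c) <= 1.0 + 1e-6

    def test_crossing_counts(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        scores = {"A": [0.0, 0.1], "B": [0.1, 0.0], "C": [0.08, 0.09],
                  "D": [9.0, 9.0]}
        Y = np.array([scores[l] for l in t.tip_labels])
        out = pm.convnum_ellipse(Y, t, ["A", "B", "C"])
        # the focal tips sit inside their own ellipse
        assert set(["A", "B", "C"]).issubset(out.crossing_taxa)
        assert out.count >= 3
        assert out.count_nonfocal == out.count - 3

    def test_far_lineage_not_counted(self):
        t = Phylogeny.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
        scores = {"A": [0.0, 0.1], "B": [0.1, 0.0], "C": [0.05, 0.08],
                  "D": [50.0, 50.0]}
        Y = np.array([scores[l] for l in t.tip_labels])
        out = pm.convnum_ellipse(Y, t, ["A", "B", "C"])
        assert "D" not in out.crossing_taxa

    def test_rigid_motion_leaves_count_and_area(self):
        t = pm.simulate_pure_birth_tree(12, seed=5)
        rng = np.random.default_rng(1)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((12, 2))
        focal = t.tip_labels[:4]
        out1 = pm.convnum_ellipse(Y, t, focal)
        theta = 1.2
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        out2 = pm.convnum_ellipse(Y @ R.T + np.array([5.0, 2.0]), t, focal)
        assert out1.count == out2.count
        assert out1.area == pytest.approx(out2.area, rel=1e-5)

    def test_degenerate_focal_set_suggests_buffer(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        Y = np.array([[float(i), 0.0] for i in range(4)])  # collinear
        with pytest.raises(ValueError, match="buffer"):
            pm.convnum_ellipse(Y, t, ["A", "B", "C"])


class TestDisparity:
    def test_identical_tips_zero_everywhere(self):
        t = pm.simulate_pure_birth_tree(8, seed=7)
        profs = pm.disparity_through_time(np.zeros((8, 2)), t)
        assert np.allclose(profs["all"].disparity, 0.0)

    def test_root_slice_zero_and_times_increasing(self):
        t = pm.simulate_pure_birth_tree(10, seed=8)
        rng = np.random.default_rng(0)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((10, 2))
        prof = pm.disparity_through_time(Y, t)["all"]
        assert prof.disparity[0] == pytest.approx(0.0)
        assert np.all(np.diff(prof.times) > 0)
        assert prof.times.size == 31

    def test_two_tip_closed_form(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        s = 3.0
        Y = np.array([[0.0 if l == "A" else s] for l in t.tip_labels])
        prof = pm.disparity_through_time(Y, t, n_slices=5)["all"]
        # final slice: two points distance s apart -> mean squared pairwise = s^2
        assert prof.disparity[-1] == pytest.approx(s ** 2)

    def test_final_slice_equals_direct_tip_disparity(self):
        t = pm.simulate_pure_birth_tree(12, seed=12)
        rng = np.random.default_rng(1)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((12, 3))
        prof = pm.disparity_through_time(Y, t)["all"]
        sq = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        iu = np.triu_indices(12, 1)
        assert prof.disparity[-1] == pytest.approx(sq[iu].mean(), rel=1e-9)

    def test_subclade_profile(self):
        t = pm.simulate_pure_birth_tree(12, seed=13)
        rng = np.random.default_rng(2)
        Y = np.linalg.cholesky(t.vcv()) @ rng.standard_normal((12, 2))
        clade = t.tip_labels[:5]
        profs = pm.disparity_through_time(Y, t, clades={"sub": clade})
        assert "sub" in profs
        assert profs["sub"].disparity[0] == pytest.approx(0.0)

    def test_non_ultrametric_rejected(self):
        t = Phylogeny.from_newick("(A:1,B:2);")
        with pytest.raises(ValueError, match="ultrametric"):
            pm.disparity_through_time(np.zeros((2, 1)), t)

    def test_mean_disparity_increases_under_bm(self):
        """Property: under single-rate BM the mean disparity profile rises
        with time (Spearman over the averaged profile > 0.95)."""
        from scipy.stats import spearmanr
        t = pm.simulate_pure_birth_tree(15, seed=30)
        L = np.linalg.cholesky(t.vcv())
        rng = np.random.default_rng(3)
        profiles = []
        for _ in range(100):
            Y = L @ rng.standard_normal((15, 2))
            profiles.append(pm.disparity_through_time(Y, t)["all"].disparity)
        mean_prof = np.mean(profiles, axis=0)
        rho = spearmanr(np.arange(31), mean_prof).statistic
        assert rho > 0.95


class TestBursts:
    def test_worked_example(self):
        prof = DisparityProfile(times=np.arange(4.0),
                                disparity=np.array([0.0, 3.0, 15.0, 16.0]),
                                clade="x")
        bursts = pm.detect_bursts(prof, threshold=10)
        assert bursts == [(1, 2, 12.0)]

    def test_steps_at_threshold_not_bursts(self):
        prof = DisparityProfile(times=np.arange(5.0),
                                disparity=np.array([0.0, 10.0, 20.0, 30.0, 40.0]),
                                clade="x")
        assert pm.detect_bursts(prof, threshold=10) == []

    def test_adjacent_bursts_reported_separately(self):
        prof = DisparityProfile(times=np.arange(4.0),
                                disparity=np.array([0.0, 11.0, 23.0, 24.0]),
                                clade="x")
        assert len(pm.detect_bursts(prof, threshold=10)) == 2
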