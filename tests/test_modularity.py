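"""Covariance ratio, PLS integration, EMMLi model selection."""

import numpy as np
import pytest

import phylomorph as pm
from phylomorph.io import ModuleMap
from phylomorph.modularity import (_pair_rpls, congruence_matrix,
                                   default_battery, seven_region_map)


def _two_module_map(k_each=4):
    return ModuleMap(["a"] * k_each + ["b"] * k_each)


class TestCovarianceRatio:
    def test_zero_between_covariance_gives_zero(self):
        # block-diagonal covariance: between-block sample covariance exactly 0
        S = np.zeros((8, 8))
        S[:4, :4] = 0.5
        S[4:, 4:] = 0.5
        np.fill_diagonal(S, 1.0)
        mm = ModuleMap(list("aabb"))  # 4 landmarks x 2 dims
        assert pm.covariance_ratio(None, mm, d=2, S=S) == pytest.approx(0.0)

    def test_duplicated_module_exceeds_one(self, rng):
        # module 2 an exact copy of module 1: the numerator keeps the
        # (large) matched-coordinate covariances that the denominator's
        # zeroed diagonal drops
        X = rng.normal(size=(40, 8))
        X2 = np.hstack([X, X])
        mm = _two_module_map(4)
        cr = pm.covariance_ratio(X2, mm, d=2)
        assert cr >= 1.0

    def test_matches_formula_oracle(self, rng):
        """Oracle: the two-module formula written out verbatim."""
        X = rng.normal(size=(30, 8))
        mm = _two_module_map(2)
        S = np.cov(X, rowvar=False, ddof=1)
        S11, S22, S12 = S[:4, :4].copy(), S[4:, 4:].copy(), S[:4, 4:]
        np.fill_diagonal(S11, 0)
        np.fill_diagonal(S22, 0)
        expect = np.sqrt(np.trace(S12 @ S12.T) /
                         np.sqrt(np.trace(S11 @ S11) * np.trace(S22 @ S22)))
        assert pm.covariance_ratio(X, mm, d=2) == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_landmark_order_and_labels(self, rng):
        X = rng.normal(size=(25, 12))
        mm = ModuleMap(list("aaabbc"))
        cr0 = pm.covariance_ratio(X, mm, d=2)
        # relabel modules
        mm2 = ModuleMap(list("xxxyyz"))
        assert pm.covariance_ratio(X, mm2, d=2) == pytest.approx(cr0, abs=1e-12)
        # permute landmarks within modules (swap landmarks 0 and 2, both 'a')
        perm = [2, 1, 0, 3, 4, 5]
        cols = np.array([[2 * i, 2 * i + 1] for i in perm]).ravel()
        assert pm.covariance_ratio(X[:, cols], mm, d=2) == pytest.approx(cr0, abs=1e-12)

    def test_single_coordinate_module_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        mm = ModuleMap(list("aab"))  # with scalar traits, module b has 1 column
        with pytest.raises(ValueError, match="single coordinate"):
            pm.covariance_ratio(X, mm, d=1)


class TestModularityTest:
    def test_two_module_cr_matches_compare_models(self, small_sim):
        X = small_sim.mean_matrix()
        taxa = small_sim.tree.tip_labels
        mm = small_sim.spec.module_map.merged(
            {"front": ["head"], "rest": ["body", "tail"]})
        res = pm.modularity_test(X, mm, small_sim.tree, n_perm=100, d=2,
                                 rng=0, taxa=taxa)
        battery = [pm.ModelHypothesis("h2", mm),
                   pm.ModelHypothesis("h3", small_sim.spec.module_map)]
        table = pm.compare_cr_models(X, battery, small_sim.tree, n_perm=100,
                                     d=2, rng=1, taxa=taxa)
        cr_in_table = float(table.loc[table.model == "h2", "cr"].iloc[0])
        assert cr_in_table == pytest.approx(res.cr, abs=1e-12)

    def test_low_permutations_warn(self, small_sim):
        X = small_sim.mean_matrix()
        mm = small_sim.spec.module_map
        with pytest.warns(UserWarning, match="low"):
            pm.modularity_test(X, mm, None, n_perm=20, d=2, rng=0)

    def test_modular_data_detected(self, small_sim):
        res = pm.modularity_test(small_sim.mean_matrix(),
                                 small_sim.spec.module_map, small_sim.tree,
                                 n_perm=200, d=2, rng=0,
                                 taxa=small_sim.tree.tip_labels)
        assert res.cr < 1.0
        assert res.p <= 0.05
        assert res.effect_size_z < 0
        assert np.allclose(res.pairwise.values, res.pairwise.values.T,
                           equal_nan=True)


class TestIntegration:
    def test_similarity_image_gives_rpls_one(self, rng):
        # block B a rotated, scaled, shifted copy of block A: the first
        # singular variates align and correlate perfectly
        A = rng.normal(size=(30, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        B = 2.5 * A @ Q + 1.0
        mm = _two_module_map(2)
        res = pm.integration_test(np.hstack([A, B]), mm, None, n_perm=50,
                                  d=2, rng=0)
        assert res.rpls == pytest.approx(1.0, abs=1e-10)

    def test_rpls_invariant_to_block_rotation(self, rng):
        X = rng.normal(size=(40, 8))
        A, B = X[:, :4], X[:, 4:]
        r0 = _pair_rpls(A - A.mean(0), B - B.mean(0))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        r1 = _pair_rpls((A @ Q) - (A @ Q).mean(0), B - B.mean(0))
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_independent_blocks_not_significant(self):
        # null calibration at modest replication: independent blocks should
        # rarely reach significance and rpls stays moderate
        hits, rs = 0, []
        runs = 25
        for i in range(runs):
            rng = np.random.default_rng(100 + i)
            X = rng.normal(size=(60, 8))
            res = pm.integration_test(X, _two_module_map(2), None,
                                      n_perm=99, d=2, rng=i)
            rs.append(res.rpls)
            hits += res.p <= 0.05
        assert hits <= runs * 0.2
        assert np.mean(rs) < 0.5


class TestEmmli:
    def test_aicc_arithmetic(self):
        # logL=-100, K=5, n=60 -> 2*5 + 200 + (2*5*6)/(60-5-1) = 211.111...
        aicc = 2 * 5 - 2 * (-100) + (2 * 5 * (5 + 1)) / (60 - 5 - 1)
        assert aicc == pytest.approx(211.1111, abs=1e-3)
        # the same arithmetic as implemented:
        from phylomorph.modularity import emmli_fit  # noqa: F401 (surface check)

    def test_uniform_correlation_prefers_one_module(self, rng):
        # uniform correlation over all coordinates: every landmark pair has
        # about the same congruence, so pooling to one rho loses nothing
        n, k, d = 120, 12, 2
        p = k * d
        R = np.full((p, p), 0.5)
        np.fill_diagonal(R, 1.0)
        dev = rng.multivariate_normal(np.zeros(p), R, size=n).reshape(n, k, d)
        dev -= dev.mean(0, keepdims=True)
        battery = [
            pm.ModelHypothesis("one", ModuleMap(["w"] * k)),
            pm.ModelHypothesis("six", ModuleMap(list("aabbccddeeff"))),
        ]
        res = pm.emmli_fit(dev, battery, sample_size=n)
        assert res.best_model == "one"

    def test_parameter_recovery_on_modular_data(self):
        """Known within/between correlations are recovered within 0.1."""
        rho_w, rho_b = 0.7, 0.1
        errs_w, errs_b = [], []
        for i in range(12):
            spec = pm.SimSpec(n_species=100, d=2,
                              module_sizes={"a": 6, "b": 6, "c": 6},
                              within_module_corr=rho_w,
                              between_module_corr=rho_b, seed=600 + i)
            sim = pm.simulate_modular_shapes(spec)
            dev = np.array([sim.node_values[t].reshape(spec.k, spec.d)
                            for t in sim.tree.tip_indices])
            dev -= dev.mean(0, keepdims=True)
            battery = [pm.ModelHypothesis("true", spec.module_map),
                       pm.ModelHypothesis("one", ModuleMap(["w"] * spec.k))]
            res = pm.emmli_fit(dev, battery, sample_size=100)
            w = np.mean(list(res.rho_within.values()))
            b = np.mean(list(res.rho_between.values()))
            errs_w.append(abs(w - rho_w))
            errs_b.append(abs(b - rho_b))
        assert np.median(errs_w) < 0.1
        assert np.median(errs_b) < 0.1

    def test_small_sample_flags_unfit(self, rng):
        dev = rng.normal(size=(10, 33, 2))
        battery = default_battery(seven_region_map())
        res = pm.emmli_fit(dev, battery, sample_size=10)
        tab = res.table.set_index("model")
        assert bool(tab.loc["7_regions", "unfit"])
        assert tab.loc["7_regions", "weight"] == 0.0

    def test_congruence_matrix_properties(self, rng):
        dev = rng.normal(size=(20, 6, 3))
        R = congruence_matrix(dev)
        assert np.allclose(np.diag(R), 1.0)
        assert np.allclose(R, R.T)
        assert np.abs(R).max() <= 1.0 + 1e-12


class TestBattery:
    def test_ten_models_from_fully_integrated_to_seven(self):
        battery = default_battery()
        assert len(battery) == 10
        counts = sorted(h.n_modules for h in battery)
        assert counts[0] == 1 and counts[-1] == 7
        for h in battery:
            assert h.partition.k == 33
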