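import math

import numpy as np
import pandas as pd
import pytest

from minorsplice import coexpression as coex
from minorsplice.simulate import ExprSimConfig, simulate_expression


def brute_force_tom(adj):
    """Independent double-loop implementation of the TOM formula."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(adj[i, u] * adj[u, j] for u in range(n))
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


class TestTOM:
    def test_matches_brute_force_random_instances(self, rng):
        for _ in range(10):
            expr = pd.DataFrame(
                rng.standard_normal((20, 15)),
                index=[f"g{i}" for i in range(20)],
            )
            adj = coex.compute_adjacency(expr, 6, signed=True)
            np.testing.assert_allclose(
                coex.compute_tom(expr, 6).to_numpy(), brute_force_tom(adj), atol=1e-10
            )

    def test_hand_computed_three_node_instance(self):
        # a12 = 0.5, everything else 0:
        # TOM_01 = (0 + 0.5) / (min(0.5, 0.5) + 1 - 0.5) = 0.5
        adj = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.0]])
        tom = coex.tom_from_adjacency(adj)
        assert math.isclose(tom[0, 1], 0.5)
        assert tom[0, 2] == 0.0 and tom[2, 2] == 1.0

    def test_perfect_pair_identical_neighborhoods(self):
        """Duplicated gene profiles give TOM = 1 for the pair."""
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        # third gene anti-correlated: signed adjacency exactly 0, so the
        # identical pair's overlap is complete and the formula limit is 1
        expr = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
        tom = coex.compute_tom(expr, 6)
        assert tom.loc["a", "b"] == pytest.approx(1.0, abs=1e-9)

    def test_invariants_random(self, rng):
        expr = pd.DataFrame(rng.standard_normal((15, 10)))
        t = coex.compute_tom(expr, 3).to_numpy()
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)
        assert (t >= 0).all() and (t <= 1).all()

    def test_constant_gene_errors(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            coex.compute_tom(expr, 6)


class TestSoftThreshold:
    def test_single_candidate_power(self, rng):
        expr = pd.DataFrame(rng.standard_normal((30, 10)))
        res = coex.pick_soft_threshold(expr, coex.NetworkConfig(powers=[6]))
        assert res.power == 6

    def test_planted_modular_data_meets_target(self):
        """Frozen config where the scale-free fit reaches the 0.8 target."""
        cfg = ExprSimConfig(seed=1, n_trait_modules=0, module_sizes=(100, 50, 25, 12, 6),
                            n_background_genes=400, within_module_correlation=0.8)
        expr, _ = simulate_expression(cfg)
        res = coex.pick_soft_threshold(expr, coex.NetworkConfig())
        assert not res.warning
        assert res.r2_by_power[res.power] >= 0.8
        # independent recomputation of the fit from the adjacency
        adj = coex.compute_adjacency(expr, res.power, signed=True)
        assert math.isclose(
            coex._scale_free_r2(adj.sum(axis=1)), res.r2_by_power[res.power], rel_tol=1e-12
        )

    def test_pure_noise_sets_warning(self, rng):
        expr = pd.DataFrame(rng.standard_normal((40, 20)))
        res = coex.pick_soft_threshold(
            expr, coex.NetworkConfig(powers=list(range(1, 7)))
        )
        assert res.warning

    def test_too_small_input_errors(self, rng):
        with pytest.raises(ValueError):
            coex.pick_soft_threshold(
                pd.DataFrame(rng.standard_normal((5, 10))), coex.NetworkConfig()
            )


class TestDetectModules:
    def test_two_planted_blocks_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = ExprSimConfig(seed=2, module_sizes=(40, 40), n_background_genes=0,
                            n_trait_modules=0, within_module_correlation=0.9)
        expr, truth = simulate_expression(cfg)
        tom = coex.compute_tom(expr, 6)
        labels = coex.detect_modules(tom, coex.NetworkConfig(cut_height=0.9, min_module_size=10))
        assert len(set(labels) - {coex.UNASSIGNED}) == 2
        ari = adjusted_rand_score(truth.module_of_gene[labels.index], labels)
        assert ari >= 0.9

    def test_min_size_above_n_all_unassigned(self, rng):
        expr = pd.DataFrame(rng.standard_normal((12, 8)))
        tom = coex.compute_tom(expr, 2)
        labels = coex.detect_modules(tom, coex.NetworkConfig(min_module_size=50))
        assert (labels == coex.UNASSIGNED).all()

    def test_gene_order_permutation_stable_partition(self):
        cfg = ExprSimConfig(seed=3, module_sizes=(30, 30, 30), n_background_genes=20,
                            n_trait_modules=0)
        expr, _ = simulate_expression(cfg)
        perm = expr.sample(frac=1.0, random_state=1)
        a = coex.detect_modules(coex.compute_tom(expr, 6),
                                coex.NetworkConfig(cut_height=0.9, min_module_size=10))
        b = coex.detect_modules(coex.compute_tom(perm, 6),
                                coex.NetworkConfig(cut_height=0.9, min_module_size=10))
        # same partition up to label names
        joined = pd.crosstab(a, b.loc[a.index])
        assert ((joined > 0).sum(axis=1) == 1).all()


class TestEigengenes:
    def test_identical_genes_recover_shared_profile(self):
        rng = np.random.default_rng(1)
        profile = rng.standard_normal(20)
        expr = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        labels = pd.Series("turquoise", index=expr.index)
        eig = coex.module_eigengenes(expr, labels)["turquoise"]
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig, profile)[0, 1] > 0  # sign convention

    def test_negation_invariance_after_alignment(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.standard_normal((6, 15)), index=[f"g{i}" for i in range(6)])
        labels = pd.Series("blue", index=expr.index)
        e1 = coex.module_eigengenes(expr, labels)["blue"]
        e2 = coex.module_eigengenes(-expr, labels)["blue"]
        assert np.corrcoef(e1, -e2)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_single_gene_module(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.standard_normal((1, 10)), index=["solo"])
        eig = coex.module_eigengenes(expr, pd.Series("red", index=["solo"]))["red"]
        z = (expr.iloc[0] - expr.iloc[0].mean()) / expr.iloc[0].std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), z.to_numpy(), atol=1e-12)

    def test_planted_factor_recovery(self):
        """One-factor module, noise 0.3, 50 genes, n=40: |cor| >= 0.95."""
        rng = np.random.default_rng(4)
        f = rng.standard_normal(40)
        expr = pd.DataFrame(
            f[None, :] + 0.3 * rng.standard_normal((50, 40)),
            index=[f"g{i}" for i in range(50)],
        )
        eig = coex.module_eigengenes(expr, pd.Series("m", index=expr.index))["m"]
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.95


class TestModuleTrait:
    def test_perfect_correlation(self):
        eig = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        res = coex.module_trait_correlation(eig, traits)
        assert res["r"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_formula(self):
        rng = np.random.default_rng(5)
        eig = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("ABCDE"))
        traits = pd.DataFrame(rng.standard_normal((30, 2)), columns=["t1", "t2"],
                              index=eig.index)
        res = coex.module_trait_correlation(eig, traits)
        np.testing.assert_allclose(
            res["bonferroni_p"], np.minimum(1.0, res["p_value"] * 10), atol=1e-12
        )

    def test_constant_trait_flagged_undefined(self):
        eig = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=list("abc"))
        traits = pd.DataFrame({"t": [1.0, 1.0, 1.0]}, index=list("abc"))
        res = coex.module_trait_correlation(eig, traits)
        assert res["undefined"].iloc[0] and not res["significant"].iloc[0]

    def test_planted_trait_modules_recovered(self):
        """2 of 8 planted trait modules exactly significant in >= 80% of seeds."""
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            expr, truth = simulate_expression(ExprSimConfig(seed=seed))
            tom = coex.compute_tom(expr, 6)
            labels = coex.detect_modules(
                tom, coex.NetworkConfig(cut_height=0.9, min_module_size=20)
            )
            eig = coex.module_eigengenes(expr, labels)
            res = coex.module_trait_correlation(eig, truth.status.to_frame().astype(float))
            sig = res.loc[res["significant"], "module"]
            sig_truth = {
                truth.module_of_gene[labels.index[labels == m]].mode()[0] for m in sig
            }
            if sig_truth == set(truth.trait_modules) and len(sig) == len(sig_truth):
                ok += 1
        assert ok >= 0.8 * n_seeds

    def test_null_no_significant_pairs(self):
        """No planted trait modules: zero Bonferroni hits in >= 95% of seeds."""
        clean = 0
        for seed in range(20):
            expr, truth = simulate_expression(
                ExprSimConfig(seed=seed, n_trait_modules=0, module_sizes=(30,) * 4,
                              n_background_genes=20)
            )
            tom = coex.compute_tom(expr, 6)
            labels = coex.detect_modules(
                tom, coex.NetworkConfig(cut_height=0.9, min_module_size=20)
            )
            eig = coex.module_eigengenes(expr, labels)
            res = coex.module_trait_correlation(eig, truth.status.to_frame().astype(float))
            if not res["significant"].any():
                clean += 1
        assert clean >= 19


class TestEnrichment:
    def test_closed_form_tail(self):
        """Module == gene set of size 5 in background 20: p = 1 / C(20,5)."""
        genes = [f"g{i}" for i in range(20)]
        labels = pd.Series(
            ["m1"] * 5 + [coex.UNASSIGNED] * 15, index=genes, name="module"
        )
        res = coex.enrich_modules(labels, {"setA": genes[:5]})
        assert res["p_value"].iloc[0] == pytest.approx(1.0 / math.comb(20, 5))

    def test_disjoint_overlap_zero_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        labels = pd.Series(["m1"] * 4 + [coex.UNASSIGNED] * 6, index=genes)
        res = coex.enrich_modules(labels, {"setA": genes[4:]})
        assert res["overlap"].iloc[0] == 0
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, rng):
        """Oracle: sum the hypergeometric pmf directly on random small instances."""

        def brute_tail(n_bg, set_size, module_size, overlap):
            total = 0.0
            for k in range(overlap, min(set_size, module_size) + 1):
                total += (
                    math.comb(set_size, k)
                    * math.comb(n_bg - set_size, module_size - k)
                    / math.comb(n_bg, module_size)
                )
            return total

        for _ in range(20):
            n_bg = int(rng.integers(10, 30))
            genes = [f"g{i}" for i in range(n_bg)]
            module_size = int(rng.integers(2, n_bg // 2))
            set_size = int(rng.integers(2, n_bg // 2))
            labels = pd.Series(coex.UNASSIGNED, index=genes)
            labels.iloc[:module_size] = "m1"
            members = rng.choice(genes, size=set_size, replace=False).tolist()
            res = coex.enrich_modules(labels, {"s": members})
            overlap = int(res["overlap"].iloc[0])
            assert res["p_value"].iloc[0] == pytest.approx(
                brute_tail(n_bg, set_size, module_size, overlap), rel=1e-9
            )

    def test_empty_set_skipped(self):
        genes = ["g1", "g2", "g3"]
        labels = pd.Series(["m1", "m1", coex.UNASSIGNED], index=genes)
        res = coex.enrich_modules(labels, {"empty": ["zz"], "ok": ["g1"]})
        assert list(res["gene_set"]) == ["ok"]


class TestSimulatorProperties:
    def test_high_correlation_low_noise(self):
        cfg = ExprSimConfig(seed=6, module_sizes=(20,), n_background_genes=0,
                            within_module_correlation=0.99, noise_sd=0.05,
                            n_trait_modules=0)
        expr, _ = simulate_expression(cfg)
        cor = np.corrcoef(expr.to_numpy())
        off = np.abs(cor[np.triu_indices_from(cor, k=1)])
        assert off.mean() >= 0.9

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError, match="size 0"):
            ExprSimConfig(n_cases=0, n_controls=0)

    def test_oversized_modules_rejected(self):
        # module sizes are independent of gene count here, but invalid sizes fail
        with pytest.raises(ValueError):
            ExprSimConfig(module_sizes=(0, 10))

    def test_null_eigengene_correlation_bounded(self):
        """n_trait_modules=0: no module-trait |r| > 0.5 at n=40 in >=95% of seeds."""
        ok = 0
        for seed in range(20):
            expr, truth = simulate_expression(
                ExprSimConfig(seed=seed, n_trait_modules=0)
            )
            eig = coex.module_eigengenes(expr, truth.module_of_gene.replace("background",
                                                                            coex.UNASSIGNED))
            rs = eig.apply(lambda e: np.corrcoef(e, truth.status)[0, 1])
            if (rs.abs() <= 0.5).all():
                ok += 1
        assert ok >= 19

    def test_determinism(self):
        a, _ = simulate_expression(ExprSimConfig(seed=10))
        b, _ = simulate_expression(ExprSimConfig(seed=10))
        pd.testing.assert_frame_equal(a, b)
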