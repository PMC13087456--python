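import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minorsplice import intron_retention as ir
from minorsplice.simulate import IRSimConfig, round_half_up, simulate_intron_counts


class TestComputePsi:
    def test_trivial_values(self, small_counts):
        retained, spliced = small_counts
        psi = ir.compute_psi(retained, spliced, min_coverage=10)
        assert psi.psi.loc["i1", "s1"] == 0.0
        assert psi.psi.loc["i2", "s1"] == 0.5
        assert np.isnan(psi.psi.loc["i3", "s1"])  # coverage 5 < 10

    def test_splicing_orientation(self, small_counts):
        retained, spliced = small_counts
        psi = ir.compute_psi(retained, spliced, orientation="splicing")
        assert psi.psi.loc["i1", "s1"] == 1.0

    def test_negative_counts_error(self, small_counts):
        retained, spliced = small_counts
        with pytest.raises(ValueError):
            ir.compute_psi(retained - 10, spliced)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_psi_bounded(self, r, s):
        retained = pd.DataFrame({"x": [r]}, index=["i"])
        spliced = pd.DataFrame({"x": [s]}, index=["i"])
        psi = ir.compute_psi(retained, spliced, min_coverage=1).psi.iloc[0, 0]
        if r + s >= 1:
            assert 0.0 <= psi <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 100), st.integers(1, 100), st.integers(1, 50))
    def test_psi_monotone_in_retained(self, r, s, bump):
        def one(rr):
            return ir.compute_psi(
                pd.DataFrame({"x": [rr]}, index=["i"]),
                pd.DataFrame({"x": [s]}, index=["i"]),
                min_coverage=1,
            ).psi.iloc[0, 0]

        assert one(r + bump) >= one(r)


class TestBH:
    def test_matches_brute_force_step_up(self, rng):
        """Oracle: literal BH step-up definition on 200 random p-vectors."""

        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.full(m, np.nan)
            prev = 1.0
            for rank_idx in range(m - 1, -1, -1):
                i = order[rank_idx]
                val = min(prev, p[i] * m / (rank_idx + 1))
                adj[i] = val
                prev = val
            return np.minimum(adj, 1.0)

        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(ir.bh_adjust(p), brute(p), atol=1e-12)

    def test_adjusted_geq_raw(self, rng):
        p = rng.uniform(size=50)
        assert (ir.bh_adjust(p) >= p - 1e-15).all()


def _psi_from(retained, spliced, **kw):
    return ir.compute_psi(retained, spliced, **kw)


class TestDifferentialIR:
    def test_identical_groups_null(self):
        idx = [f"i{k}" for k in range(5)]
        vals = np.tile([[20, 30, 10, 5, 40]], (4, 1)).T
        retained = pd.DataFrame(vals, index=idx, columns=["c1", "c2", "k1", "k2"])
        spliced = pd.DataFrame(100 - vals, index=idx, columns=["c1", "c2", "k1", "k2"])
        res = ir.test_differential_ir(_psi_from(retained, spliced), ["c1", "c2"], ["k1", "k2"])
        assert (res["p_value"] == 1.0).all()
        assert not res["significant"].any()

    def test_empty_group_errors(self, small_counts):
        retained, spliced = small_counts
        with pytest.raises(ValueError):
            ir.test_differential_ir(_psi_from(retained, spliced), [], ["s1"])

    def test_low_coverage_reported_untested(self):
        retained = pd.DataFrame([[1, 1, 1, 1]], index=["i"], columns=list("abcd"))
        spliced = pd.DataFrame([[1, 1, 1, 1]], index=["i"], columns=list("abcd"))
        res = ir.test_differential_ir(
            _psi_from(retained, spliced, min_coverage=10), ["a", "b"], ["c", "d"]
        )
        assert not res["tested"].iloc[0] and np.isnan(res["p_value"].iloc[0])

    def test_within_group_label_permutation_invariant(self):
        cfg = IRSimConfig(seed=4, n_cases=4, n_controls=6, n_genes=20)
        retained, spliced, _, truth = simulate_intron_counts(cfg)
        psi = _psi_from(retained, spliced)
        a = ir.test_differential_ir(psi, truth.case_samples, truth.control_samples)
        b = ir.test_differential_ir(
            psi, truth.case_samples[::-1], truth.control_samples[::-1]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_sensitivity_and_fdr_on_planted_simulation(self):
        """Planted dPSI=0.3 at depth 200, 3v9: sens >= 0.8, FDP <= 0.1 (5 seeds)."""
        sens, fdp = [], []
        for seed in range(5):
            cfg = IRSimConfig(seed=seed, n_cases=3, n_controls=9, n_genes=100,
                              introns_per_gene=5, frac_u12_genes=0.10, delta_psi=0.3)
            retained, spliced, _, truth = simulate_intron_counts(cfg)
            res = ir.test_differential_ir(
                _psi_from(retained, spliced), truth.case_samples, truth.control_samples
            )
            planted = set(truth.planted_introns)
            sig = set(res.index[res["significant"]])
            sens.append(len(sig & planted) / len(planted))
            fdp.append(len(sig - planted) / max(len(sig), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdp) <= 0.1


class TestGeneLevel:
    @pytest.fixture()
    def setup(self):
        cfg = IRSimConfig(seed=6, n_genes=30, frac_u12_genes=0.2, delta_psi=0.4)
        retained, spliced, annotation, truth = simulate_intron_counts(cfg)
        res = ir.test_differential_ir(
            _psi_from(retained, spliced), truth.case_samples, truth.control_samples
        )
        return res, annotation, truth

    def test_any_rule_matches_intron_truth(self, setup):
        res, annotation, _ = setup
        genes = ir.call_gene_level(res, annotation, rule="any")
        expected = set(annotation.loc[res.index[res["significant"]], "gene"])
        assert genes == expected

    def test_no_significant_introns_empty_set(self, setup):
        res, annotation, _ = setup
        res = res.copy()
        res["significant"] = False
        assert ir.call_gene_level(res, annotation) == set()

    def test_unannotated_intron_errors(self, setup):
        res, annotation, _ = setup
        with pytest.raises(ValueError, match="annotation"):
            ir.call_gene_level(res, annotation.iloc[:-5])


class TestOverlap:
    def test_empty_sets_all_zero(self):
        ann = pd.DataFrame(
            {"gene": ["g1"], "spliceosome_class": ["U12"]}, index=["g1_i0"]
        )
        cats, counts = ir.classify_cohort_overlap([], [], ann)
        assert cats == [] and counts["novel_in_both"] == 0

    def test_disjoint_cohorts_no_both(self):
        ann = pd.DataFrame(
            {"gene": ["g1", "g2"], "spliceosome_class": ["U2", "U2"]},
            index=["g1_i0", "g2_i0"],
        )
        cats, counts = ir.classify_cohort_overlap(["g1"], ["g2"], ann)
        assert counts["A1_B1_U120"] == 0 and counts["novel_in_both"] == 0

    def test_hidden_planted_genes_counted_as_novel(self):
        """Two-cohort run: hidden U12 genes detected in both are novel-in-both."""
        cfg = IRSimConfig(seed=1, n_genes=50, frac_u12_genes=0.3, frac_hidden_u12=0.2,
                          delta_psi=0.4, n_cases=8, n_controls=8)
        ra, sa, ann, truth = simulate_intron_counts(cfg)
        psi = _psi_from(ra, sa)
        # two "cohorts": disjoint case/control halves of the same simulation
        res_a = ir.test_differential_ir(psi, truth.case_samples[:4], truth.control_samples[:4])
        genes_a = ir.call_gene_level(res_a, ann)
        res_b = ir.test_differential_ir(psi, truth.case_samples[4:], truth.control_samples[4:])
        genes_b = ir.call_gene_level(res_b, ann)
        _, counts = ir.classify_cohort_overlap(genes_a, genes_b, ann)
        expected = len(set(truth.hidden_genes) & genes_a & genes_b)
        assert counts["novel_in_both"] == expected


class TestSimulator:
    def test_hidden_count_rounding(self):
        cfg = IRSimConfig(seed=7, n_genes=100, frac_u12_genes=0.15, frac_hidden_u12=0.2)
        _, _, annotation, truth = simulate_intron_counts(cfg)
        assert len(truth.u12_genes) == round_half_up(0.15 * 100) == 15
        assert len(truth.hidden_genes) == round_half_up(0.2 * 15) == 3
        unknown_genes = set(annotation.loc[annotation["spliceosome_class"] == "unknown", "gene"])
        assert unknown_genes == set(truth.hidden_genes)

    def test_null_case_truth_identical(self):
        cfg = IRSimConfig(seed=3, delta_psi=0.0)
        _, _, _, truth = simulate_intron_counts(cfg)
        assert (truth.table["psi_case"] == truth.table["psi_control"]).all()

    def test_observed_delta_within_3_mcse(self):
        """Mean case-control PSI gap over planted introns ~ delta_psi (3 MC SEs)."""
        cfg = IRSimConfig(seed=5, n_cases=20, n_controls=20, depth_mean=200,
                          n_genes=100, frac_u12_genes=0.15, delta_psi=0.3)
        retained, spliced, _, truth = simulate_intron_counts(cfg)
        psi = (retained / (retained + spliced)).loc[truth.planted_introns]
        gaps = psi[truth.case_samples].mean(axis=1) - psi[truth.control_samples].mean(axis=1)
        mcse = gaps.std(ddof=1) / np.sqrt(len(gaps))
        assert abs(gaps.mean() - 0.3) <= 3 * mcse

    def test_invalid_delta_rejected_at_config_time(self):
        with pytest.raises(ValueError, match="delta_psi"):
            IRSimConfig(baseline_psi=(8.0, 2.0), delta_psi=0.5)

    def test_determinism(self):
        a = simulate_intron_counts(IRSimConfig(seed=8))
        b = simulate_intron_counts(IRSimConfig(seed=8))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_null_type_i_control(self):
        """delta=0: BH-significant fraction stays near nominal (<= alpha + 3 SE)."""
        fracs = []
        for seed in range(10):
            cfg = IRSimConfig(seed=seed, delta_psi=0.0, n_cases=3, n_controls=9, n_genes=40)
            retained, spliced, _, truth = simulate_intron_counts(cfg)
            res = ir.test_differential_ir(
                _psi_from(retained, spliced), truth.case_samples, truth.control_samples
            )
            fracs.append(res["significant"].mean())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 3 * max(se, 1e-3)


def test_plot_psi_heatmap_writes_file(tmp_path):
    cfg = IRSimConfig(seed=9, n_genes=10)
    retained, spliced, _, _ = simulate_intron_counts(cfg)
    psi = ir.compute_psi(retained, spliced)
    out = tmp_path / "heatmap.png"
    ir.plot_psi_heatmap(psi.psi, str(out))
    assert out.exists() and out.stat().st_size > 0
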