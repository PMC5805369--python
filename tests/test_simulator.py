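"""Synthetic-data generators and the two study designs."""

import numpy as np
import pytest
from scipy import stats

from smarttissue import (
    Design1Config,
    Design1Runner,
    Design2Config,
    Design2Runner,
    build_annotation_matrix,
    center_annotations,
    evaluate_power_at_fdr,
    marginal_scan,
    per_block_pve,
    simulate_causal_annotations,
    simulate_effects_phenotype,
    simulate_genotypes,
    simulate_tissue_annotations,
    standardize_genotypes,
)


class TestGenotypes:
    def test_independent_maf_within_binomial_ci(self, rng):
        n = 4000
        G = simulate_genotypes(n, 1, maf_range=(0.3, 0.3), rng=rng)
        freq = G.mean() / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert abs(freq - 0.3) < 4 * se

    def test_rho_zero_ar1_matches_independent_marginals(self):
        G1 = simulate_genotypes(3000, 4, (0.2, 0.2), ("ar1", 0.0, 4),
                                np.random.default_rng(0))
        G2 = simulate_genotypes(3000, 4, (0.2, 0.2), "independent",
                                np.random.default_rng(1))
        # same marginal distribution: compare genotype frequency tables
        for g in (0, 1, 2):
            assert abs((G1 == g).mean() - (G2 == g).mean()) < 0.03

    def test_ar1_induces_decaying_within_block_correlation(self, rng):
        G = simulate_genotypes(5000, 6, (0.4, 0.4), ("ar1", 0.8, 6), rng)
        X, _, _ = standardize_genotypes(G)
        corr = np.corrcoef(X.T)
        assert corr[0, 1] > corr[0, 3] > corr[0, 5] - 0.05
        assert corr[0, 1] > 0.3

    def test_fixed_seed_bit_identical(self):
        a = simulate_genotypes(50, 20, ld=("ar1", 0.5, 10),
                               rng=np.random.default_rng(7))
        b = simulate_genotypes(50, 20, ld=("ar1", 0.5, 10),
                               rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 10, maf_range=(0.0, 0.6))


class TestTissueAnnotations:
    def test_occupancy_matches_parameter(self, rng):
        annos = simulate_tissue_annotations(20_000, 3, (0.18,), 0.5, rng)
        for A in annos:
            assert A.annotations[:, 0].mean() == pytest.approx(0.18, abs=0.02)

    def test_zero_correlation_gives_independent_tissues(self, rng):
        annos = simulate_tissue_annotations(10_000, 2, (0.3,), 0.0, rng)
        r = np.corrcoef(annos[0].annotations[:, 0], annos[1].annotations[:, 0])[0, 1]
        assert abs(r) < 0.05

    def test_cross_tissue_correlation_monotone(self, rng):
        realized = []
        for target in (0.2, 0.5, 0.9):
            annos = simulate_tissue_annotations(20_000, 2, (0.25,), target, rng)
            realized.append(np.corrcoef(annos[0].annotations[:, 0],
                                        annos[1].annotations[:, 0])[0, 1])
        assert realized[0] < realized[1] < realized[2]
        np.testing.assert_allclose(realized, [0.2, 0.5, 0.9], atol=0.06)


class TestCausalAnnotations:
    def test_group_scheme_elevation(self, rng):
        causal = np.arange(0, 600)
        C1, C2, groups = simulate_causal_annotations(5000, causal, (0.0, 0.0, 1.0), rng)
        # all causal SNPs in group 3: both annotations elevated and correlated
        assert C1[causal].mean() == pytest.approx(10.0, abs=0.2)
        assert C2[causal].mean() == pytest.approx(10.0, abs=0.2)
        assert (groups == 3).all()

    def test_disjoint_halves_scheme(self, rng):
        causal = np.arange(400)
        C1, C2, groups = simulate_causal_annotations(4000, causal, (0.5, 0.5, 0.0), rng)
        g1, g2 = causal[groups == 1], causal[groups == 2]
        assert len(g1) == len(g2) == 200
        assert C2[g1].mean() == pytest.approx(10.0, abs=0.3)   # anno2 elevated in group 1
        assert C1[g1].mean() == pytest.approx(0.0, abs=0.3)
        assert C1[g2].mean() == pytest.approx(10.0, abs=0.3)   # anno1 elevated in group 2
        assert C2[g2].mean() == pytest.approx(0.0, abs=0.3)

    def test_noncausal_standard_normal(self, rng):
        causal = np.arange(100)
        C1, _, _ = simulate_causal_annotations(10_000, causal, (1 / 3, 1 / 3, 1 / 3), rng)
        noncausal = C1[100:]
        assert noncausal.mean() == pytest.approx(0.0, abs=0.05)
        assert noncausal.var() == pytest.approx(1.0, abs=0.05)


class TestEffectsAndScan:
    def test_heritability_bookkeeping(self, rng):
        # centered annotations: E[sum beta_j^2] = alpha0, h2 = alpha0/(alpha0+sige2)
        m, n = 400, 100
        X = rng.standard_normal((n, m))
        A = center_annotations(build_annotation_matrix(
            [(rng.random(m) < 0.2).astype(float)], ["a"]))
        tot = []
        for _ in range(200):
            beta, _ = simulate_effects_phenotype(X, A, (0.1, 0.05, 0.0)[:2], 0.9, rng)
            tot.append(np.sum(beta ** 2))
        se = np.std(tot) / np.sqrt(len(tot))
        assert np.mean(tot) == pytest.approx(0.1, abs=4 * se)

    def test_null_alpha_gives_pure_noise(self, rng):
        X = rng.standard_normal((50, 30))
        A = center_annotations(build_annotation_matrix([rng.random(30)], ["a"]))
        beta, y = simulate_effects_phenotype(X, A, (0.0, 0.0), 1.0, rng)
        assert np.all(beta == 0.0)
        assert y.var() == pytest.approx(1.0, rel=0.5)

    def test_scan_matches_single_regression_oracle(self, rng):
        n, m = 500, 5
        G = simulate_genotypes(n, m, rng=rng)
        X, _, _ = standardize_genotypes(G)
        y = 1.5 * X[:, 2] + rng.standard_normal(n)
        z, chisq = marginal_scan(X, y)
        j = 2
        slope, _, _, pval, _ = stats.linregress(X[:, j], y)
        np.testing.assert_allclose(chisq[j], z[j] ** 2)
        # z^2 equals the squared t statistic of the simple regression
        t2 = stats.t.ppf(pval / 2, n - 2) ** 2
        assert chisq[j] == pytest.approx(t2, rel=1e-6)

    def test_null_scan_mean_chisq_near_one(self, rng):
        X = rng.standard_normal((400, 300))
        X = (X - X.mean(0)) / X.std(0)
        _, chisq = marginal_scan(X, rng.standard_normal(400))
        assert chisq.mean() == pytest.approx(1.0, abs=0.15)

    def test_duplicated_columns_identical_statistics(self, rng):
        x = rng.standard_normal(200)
        X = np.column_stack([x, x])
        X = (X - X.mean(0)) / X.std(0)
        _, chisq = marginal_scan(X, rng.standard_normal(200))
        assert chisq[0] == pytest.approx(chisq[1])


class TestPerBlockPVE:
    def test_zero_effect_block_zero_pve(self, rng):
        X = rng.standard_normal((100, 20))
        beta = np.zeros(20)
        beta[15] = 0.5
        y = X @ beta + rng.standard_normal(100)
        pve = per_block_pve(beta, X, [slice(0, 10), slice(10, 20)], y)
        assert pve[0] == 0.0
        assert pve[1] > 0.0

    def test_variance_decomposition_for_independent_blocks(self, rng):
        n, m = 2000, 40
        X = rng.standard_normal((n, m))
        beta = rng.standard_normal(m) * 0.1
        y = X @ beta + rng.standard_normal(n)
        blocks = [slice(i, i + 10) for i in range(0, m, 10)]
        pve = per_block_pve(beta, X, blocks, y)
        total = np.var(X @ beta) / np.var(y)
        assert pve.sum() == pytest.approx(total, rel=0.05)


class TestPowerAtFDR:
    def test_perfect_separation_full_power(self):
        pp = np.zeros((8, 4))
        truth = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        pp[np.arange(8), truth] = 1.0
        power = evaluate_power_at_fdr(pp, truth)
        assert all(v == 1.0 for v in power.values())

    def test_matches_enumeration_oracle_on_random_table(self, rng):
        R, T = 20, 5
        pp = rng.random((R, T))
        truth = rng.integers(T, size=R)
        got = evaluate_power_at_fdr(pp, truth, fdr_levels=(0.1, 0.3))
        # brute-force enumeration over all prefixes of the sorted call list
        calls = sorted(
            ((pp[r, t], r, t) for r in range(R) for t in range(T)),
            key=lambda c: -c[0])
        for level in (0.1, 0.3):
            best = 0
            tp = fp = 0
            for _, r, t in calls:
                tp += truth[r] == t
                fp += truth[r] != t
                if fp / (fp + tp) <= level:
                    best = tp
            assert got[level] == pytest.approx(best / R)

    def test_multiple_columns_per_tissue_deduplicates_detections(self):
        # two annotation columns per tissue: a replicate counts as detected
        # once even when both columns of the true tissue rank on top
        pp = np.zeros((4, 4))  # 2 tissues x 2 annotations
        truth = np.array([0, 0, 1, 1])
        col_tissue = np.array([0, 0, 1, 1])
        pp[np.arange(4), 2 * truth] = 1.0
        pp[np.arange(4), 2 * truth + 1] = 0.9
        power = evaluate_power_at_fdr(pp, truth, fdr_levels=(0.1,),
                                      col_tissue=col_tissue)
        assert power[0.1] == 1.0

    def test_power_monotone_in_fdr_level(self, rng):
        pp = rng.random((30, 6))
        truth = rng.integers(6, size=30)
        power = evaluate_power_at_fdr(pp, truth, fdr_levels=(0.05, 0.1, 0.2, 0.5))
        vals = [power[k] for k in (0.05, 0.1, 0.2, 0.5)]
        assert vals == sorted(vals)


@pytest.fixture(scope="module")
def d1():
    cfg = Design1Config(n=400, m=400, n_ref=150, n_reps=5)
    return Design1Runner(cfg, seed=9)


@pytest.fixture(scope="module")
def d2():
    cfg = Design2Config(n=1500, m=1000, n_train=1000, n_ref=200,
                        n_causal_blocks=4)
    return Design2Runner(cfg, seed=4, with_training=True)


class TestDesignRunners:

    def test_design1_deterministic_given_seed(self, d1):
        a = d1.run_setting(0.25, 0.25, 3)
        b = d1.run_setting(0.25, 0.25, 3)
        np.testing.assert_array_equal(a["truth"], b["truth"])
        np.testing.assert_allclose(a["pp_smart"], b["pp_smart"])

    def test_design1_outputs_shapes_and_ranges(self, d1):
        res = d1.run_setting(0.1, 0.05, 4)
        assert res["pp_smart"].shape == (4, 10)
        assert np.all((res["pp_smart"] >= 0) & (res["pp_smart"] <= 1))
        assert set(res["power_smart"]) == {0.05, 0.1, 0.2}

    def test_design1_uni_mode_classifies_each_annotation(self, d1):
        res = d1.run_setting(0.25, 0.25, 3, include_uni=True)
        assert res["pp_uni"].shape == (3, 20)  # 10 tissues x 2 annotations
        assert set(res["power_uni"]) == {0.05, 0.1, 0.2}

    def test_design2_causal_blocks_nonadjacent_and_counts(self, d2, rng):
        blocks, causal = d2._draw_causal(rng)
        assert np.all(np.diff(blocks) > 1)
        assert len(causal) == 4 * 20
        assert len(np.unique(causal)) == len(causal)

    def test_design2_replicate_variance_accounting(self, d2, rng):
        rep = d2.simulate_replicate((0.4, 0.4), (1 / 3, 1 / 3, 1 / 3), rng)
        assert np.count_nonzero(rep["beta"]) <= 80
        assert rep["y"].shape == (1500,)
        # phenotype variance ~ genetic + residual
        gen = np.count_nonzero(rep["beta"]) and np.var(
            d2._standardized_cols(rep["causal"]) @ rep["beta"][rep["causal"]])
        assert rep["y"].var() == pytest.approx(gen + 0.5, rel=0.25)

    def test_design2_power_ordering_oracle_estimated_equal(self, d2):
        res = d2.run_setting((0.4, 0.4), (0.5, 0.5, 0.0), n_reps=8,
                             methods=("equal", "oracle", "smart"))
        assert res["power_oracle"] >= res["power_equal"] - 0.05
        assert res["power_oracle"] >= res["power_smart"] - 0.1

    def test_design2_deterministic_given_seed(self, d2):
        a = d2.run_setting((0.4, 0.0), (0.0, 0.0, 1.0), 3, methods=("equal",))
        b = d2.run_setting((0.4, 0.0), (0.0, 0.0, 1.0), 3, methods=("equal",))
        np.testing.assert_allclose(a["power_per_rep"]["equal"],
                                   b["power_per_rep"]["equal"])
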