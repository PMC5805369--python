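"""GEE engine: design construction, closed-form fit, Wald statistics."""

import numpy as np
import pytest

from smarttissue import (
    SummaryStats,
    build_annotation_matrix,
    build_design,
    center_annotations,
    chisq_from_z,
    estimate_ld_blocks,
    fit_all_tissues,
    gee_fit,
    identity_ld,
    wald_statistic,
)
from smarttissue.gee import GEEFit, GEESolver


def _centered(cols, labels=None, tissue=""):
    labels = labels or [f"a{i}" for i in range(len(cols))]
    return center_annotations(build_annotation_matrix(cols, labels, tissue))


class TestChisqFromZ:
    def test_squares_and_sign_invariance(self):
        ss = chisq_from_z(np.array([0.0, -2.0, 1.96]), n=100)
        np.testing.assert_allclose(ss.chisq, [0.0, 4.0, 3.8416])

    def test_missing_dropped(self):
        ss = chisq_from_z(np.array([1.0, np.nan, 2.0]), n=50)
        assert ss.m == 2
        np.testing.assert_allclose(ss.chisq, [1.0, 4.0])


class TestLDBlocks:
    def test_small_block_matches_brute_force_pearson(self):
        # small hand-checkable 4 x 3 genotype fixture
        G = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float)
        ld = estimate_ld_blocks(G, block_size=3, adjust_r2=False)
        expected = np.corrcoef(G.T)
        np.testing.assert_allclose(ld.corr[0], expected, atol=1e-12)

    def test_duplicated_column_perfect_ld(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        ld = estimate_ld_blocks(np.column_stack([g, g]), block_size=2,
                                adjust_r2=False)
        assert ld.corr[0][0, 1] == pytest.approx(1.0)

    def test_monomorphic_snp_treated_independent(self, rng):
        G = np.column_stack([np.full(30, 2.0), rng.binomial(2, 0.4, 30)])
        ld = estimate_ld_blocks(G, block_size=2, adjust_r2=False)
        np.testing.assert_allclose(ld.corr[0][0], [1.0, 0.0])


class TestBuildDesign:
    def test_identity_ld_reduces_to_scaled_annotations(self, rng):
        m, n = 40, 200
        A = _centered([rng.random(m)])
        ld = identity_ld(m, 10)
        D = build_design(ld, A, n)
        np.testing.assert_allclose(D.D, (n / m) * A.values)
        np.testing.assert_allclose(D.ld_scores, 1.0)

    def test_two_snp_block_hand_computation(self):
        from smarttissue.gee import LDBlocks

        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDBlocks(np.array([0, 2]), (r,), n_ref=0)
        A = _centered([np.array([2.0, -2.0])])
        n = 10
        D = build_design(ld, A, n)
        # d_1 = (n/m) * (A_1 + 0.25 A_2), element-wise over (intercept, anno)
        expected_row0 = (n / 2) * (A.values[0] + 0.25 * A.values[1])
        np.testing.assert_allclose(D.D[0], expected_row0)
        np.testing.assert_allclose(D.ld_scores, [1.25, 1.25])

    def test_intercept_only_design_is_ld_score(self):
        from smarttissue import AnnotationMatrix
        from smarttissue.gee import LDBlocks

        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        ld = LDBlocks(np.array([0, 2]), (r,), n_ref=0)
        A = AnnotationMatrix(np.ones((2, 1)), [], centered=True)
        D = build_design(ld, A, 4)
        np.testing.assert_allclose(D.D[:, 0], (4 / 2) * D.ld_scores)

    def test_dimension_mismatch_raises(self, rng):
        A = _centered([rng.random(5)])
        with pytest.raises(ValueError):
            build_design(identity_ld(6, 3), A, 10)


class TestGEEFit:
    def test_unit_chisq_gives_zero_coefficients(self, rng):
        m = 50
        A = _centered([rng.random(m)])
        ld = identity_ld(m, 10)
        ss = SummaryStats(np.arange(m).astype(object), np.ones(m), 100)
        fit = gee_fit(build_design(ld, A, 100), ss, ld)
        np.testing.assert_allclose(fit.alpha_star_hat, 0.0, atol=1e-12)
        assert fit.wald == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_oracle_under_independence(self, rng):
        m = 50
        A = _centered([rng.random(m), rng.random(m)])
        ld = identity_ld(m, 10)
        chisq = rng.chisquare(1, m)
        ss = SummaryStats(np.arange(m).astype(object), chisq, 100)
        D = build_design(ld, A, 100)
        fit = gee_fit(D, ss, ld, "independence")
        ols = np.linalg.solve(D.D.T @ D.D, D.D.T @ (chisq - 1.0))
        np.testing.assert_allclose(fit.alpha_star_hat, ols, rtol=1e-12)

    def test_wald_invariant_to_annotation_rescaling(self, rng):
        m = 80
        x = rng.random(m)
        ld = identity_ld(m, 20)
        chisq = rng.chisquare(1, m) + x
        ss = SummaryStats(np.arange(m).astype(object), chisq, 200)
        w1 = gee_fit(build_design(ld, _centered([x]), 200), ss, ld).wald
        w2 = gee_fit(build_design(ld, _centered([7.3 * x]), 200), ss, ld).wald
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_null_simulation_centered_at_zero(self, rng):
        m, n, reps = 300, 500, 60
        A = _centered([(rng.random(m) < 0.2).astype(float)])
        ld = identity_ld(m, 50)
        solver = GEESolver(build_design(ld, A, n), ld, "independence")
        est = []
        for _ in range(reps):
            chisq = rng.chisquare(1, m)
            est.append(solver.fit(
                SummaryStats(np.arange(m).astype(object), chisq, n)).alpha_star_hat)
        est = np.asarray(est)
        se = est.std(axis=0) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0)) < 4 * se + 1e-12)

    def test_free_intercept_absorbs_additive_inflation(self, rng):
        # chi-squares inflated by a constant (confounding): the free
        # intercept soaks it up and the coefficients stay unbiased.  Needs
        # varying LD scores, otherwise the model-intercept column is itself
        # constant and the guard is unidentifiable.
        m, n, reps = 400, 800, 40
        from smarttissue.simulate import simulate_genotypes

        G_ref = simulate_genotypes(300, m, ld=("ar1", 0.8, 50), rng=rng)
        ld = estimate_ld_blocks(G_ref, block_size=50)
        A = _centered([rng.random(m)])
        D = build_design(ld, A, n)
        assert np.ptp(D.ld_scores) > 0.5  # identifiability precondition
        free = GEESolver(D, ld, "independence", free_intercept=True)
        truth = np.array([0.1, 0.3])
        est, inflation = [], []
        for _ in range(reps):
            mean = 1.0 + 0.4 + D.D @ truth
            chisq = np.maximum(mean + rng.standard_normal(m) * 0.3, 0.0)
            ss = SummaryStats(np.arange(m).astype(object), chisq, n)
            fit = free.fit(ss)
            est.append(fit.alpha_star_hat)
            inflation.append(fit.free_intercept_hat)
        assert np.mean(inflation) == pytest.approx(0.4, abs=0.1)
        np.testing.assert_allclose(np.mean(est, axis=0), truth, atol=0.1)

    def test_winsorize_caps_only_when_requested(self):
        from smarttissue import winsorize_chisq

        ss = SummaryStats(np.array(["a", "b"], dtype=object),
                          np.array([3.0, 120.0]), 100)
        capped = winsorize_chisq(ss, 80.0)
        np.testing.assert_allclose(capped.chisq, [3.0, 80.0])
        np.testing.assert_allclose(ss.chisq, [3.0, 120.0])

    def test_collinear_columns_raise(self, rng):
        m = 30
        x = rng.random(m)
        A = _centered([x, 2.0 * x])
        ld = identity_ld(m, 10)
        ss = SummaryStats(np.arange(m).astype(object), np.ones(m), 10)
        with pytest.raises(np.linalg.LinAlgError):
            gee_fit(build_design(ld, A, 10), ss, ld)


class TestWaldStatistic:
    def test_univariate_identity(self):
        fit = GEEFit(np.array([0.0, 0.3]),
                     np.array([[1.0, 0.0], [0.0, 0.04]]), np.nan, 1, "independence")
        out = wald_statistic(fit)
        assert out.wald == pytest.approx((0.3 / 0.2) ** 2)
        assert out.df == 1

    def test_hand_computed_two_by_two_case(self):
        # alpha = (1, 0), V = diag(1, 4) -> W = 1
        cov = np.zeros((3, 3))
        cov[1, 1], cov[2, 2] = 1.0, 4.0
        cov[0, 0] = 1.0
        fit = GEEFit(np.array([0.0, 1.0, 0.0]), cov, np.nan, 2, "independence")
        assert wald_statistic(fit).wald == pytest.approx(1.0)


class TestFitAllTissues:
    def test_identical_annotations_identical_wald(self, rng):
        m = 60
        A = _centered([rng.random(m), rng.random(m)], tissue="t")
        ld = identity_ld(m, 20)
        ss = SummaryStats(np.arange(m).astype(object), rng.chisquare(1, m), 100)
        table = fit_all_tissues(ss, [A, A, A], ld)
        assert table["wald"].nunique() == 1
        assert (table["df"] == 2).all()

    def test_unimax_takes_larger_univariate(self, rng):
        m = 60
        x1, x2 = rng.random(m), rng.random(m)
        A = _centered([x1, x2], tissue="t")
        ld = identity_ld(m, 20)
        ss = SummaryStats(np.arange(m).astype(object), rng.chisquare(1, m), 100)
        table = fit_all_tissues(ss, [A], ld, mode="unimax")
        singles = [
            gee_fit(build_design(ld, _centered([c]), 100), ss, ld).wald
            for c in (x1, x2)
        ]
        assert table["wald"].iloc[0] == pytest.approx(max(singles))
        assert table["df"].iloc[0] == 1

    def test_tissue_order_equivariance(self, rng):
        m = 40
        tissues = [_centered([rng.random(m)], tissue=f"t{i}") for i in range(3)]
        ld = identity_ld(m, 10)
        ss = SummaryStats(np.arange(m).astype(object), rng.chisquare(1, m), 50)
        fwd = fit_all_tissues(ss, tissues, ld)
        rev = fit_all_tissues(ss, tissues[::-1], ld)
        np.testing.assert_allclose(fwd["wald"].to_numpy(), rev["wald"].to_numpy()[::-1])
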