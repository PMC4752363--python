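import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ovotrait.phylosignal import (
    PagelLambda,
    apply_lambda,
    bm_profile_loglik,
    estimate_lambda,
    repeatability_icc,
    spearman_rho,
)
from ovotrait.simulate import simulate_bm_traits
from ovotrait.trees import tree_covariance


class TestApplyLambda:
    def test_identity_at_one(self, three_taxon_tree):
        V, _ = tree_covariance(three_taxon_tree)
        assert np.allclose(apply_lambda(V, 1.0), V)

    def test_diagonal_at_zero(self, three_taxon_tree):
        V, _ = tree_covariance(three_taxon_tree)
        out = apply_lambda(V, 0.0)
        assert np.allclose(out, np.diag(np.diag(V)))

    def test_half_scales_off_diagonal(self, three_taxon_tree):
        V, labels = tree_covariance(three_taxon_tree)
        i = {lab: k for k, lab in enumerate(labels)}
        out = apply_lambda(V, 0.5)
        assert out[i["A"], i["B"]] == pytest.approx(0.5)
        assert out[i["A"], i["A"]] == pytest.approx(2.0)

    def test_out_of_range_rejected(self, three_taxon_tree):
        V, _ = tree_covariance(three_taxon_tree)
        with pytest.raises(ValueError):
            apply_lambda(V, -0.1)
        with pytest.raises(ValueError):
            apply_lambda(V, 1.1)


class TestProfileLoglik:
    def test_identity_covariance_reduces_to_iid_ml(self, rng):
        x = rng.normal(2.0, 1.5, size=25)
        mu, s2, ll = bm_profile_loglik(x, np.eye(25))
        assert mu == pytest.approx(x.mean())
        assert s2 == pytest.approx(np.mean((x - x.mean()) ** 2))

    def test_matches_dense_mvn_density(self, rng):
        # independent oracle: evaluate the multivariate normal density at
        # the profile maximisers for a small random SPD covariance
        n = 8
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        x = rng.normal(size=n)
        mu, s2, ll = bm_profile_loglik(x, V)
        oracle = stats.multivariate_normal(mean=np.full(n, mu), cov=s2 * V).logpdf(x)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_scale_equivariance(self, yule71):
        _, V, _ = yule71
        rng = np.random.default_rng(0)
        x = rng.normal(size=71)
        _, s2a, _ = bm_profile_loglik(x, V)
        _, s2b, _ = bm_profile_loglik(3.0 * x, V)
        assert s2b == pytest.approx(9.0 * s2a)

    def test_singular_covariance_diagnosed(self):
        V = np.ones((4, 4))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            bm_profile_loglik(np.arange(4.0), V)


class TestLambdaEstimation:
    def test_matches_grid_argmax(self, yule71):
        # the optimiser must land within one step of a 1001-point grid argmax
        _, V, labels = yule71
        vals, _ = simulate_bm_traits(V=V, labels=labels, sigma2=1.0, lam=0.7,
                                     n_traits=3, seed=5)
        grid = np.linspace(0, 1, 1001)
        for j in range(3):
            model = PagelLambda(vals[:, j], V=V)
            fit = model.fit()
            lls = np.array([model.loglik(g) for g in grid])
            assert abs(fit.lambda_ - grid[int(np.argmax(lls))]) <= 0.001 + 1e-12
            assert fit.llf >= lls.max() - 1e-9

    def test_scaling_leaves_argmax_unchanged(self, yule71):
        _, V, labels = yule71
        vals, _ = simulate_bm_traits(V=V, labels=labels, sigma2=1.0, lam=0.5,
                                     n_traits=1, seed=8)
        a = estimate_lambda(vals[:, 0], V=V)
        b = estimate_lambda(10.0 * vals[:, 0], V=V)
        assert b.lambda_ == pytest.approx(a.lambda_, abs=1e-4)
        assert b.sigma2 == pytest.approx(100.0 * a.sigma2, rel=1e-4)

    def test_bm_traits_hit_upper_boundary(self, yule71):
        _, V, labels = yule71
        vals, _ = simulate_bm_traits(V=V, labels=labels, sigma2=1.0, lam=1.0,
                                     n_traits=25, seed=6)
        lams = [estimate_lambda(vals[:, j], V=V).lambda_ for j in range(25)]
        assert np.median(lams) == pytest.approx(1.0, abs=0.02)

    def test_iid_traits_near_zero(self, yule71):
        _, V, _ = yule71
        rng = np.random.default_rng(7)
        lams = [
            estimate_lambda(rng.standard_normal(71), V=V).lambda_
            for _ in range(25)
        ]
        assert np.median(lams) <= 0.05

    def test_ci_contains_estimate_and_orders(self, yule71):
        _, V, labels = yule71
        vals, _ = simulate_bm_traits(V=V, labels=labels, sigma2=1.0, lam=0.8,
                                     n_traits=1, seed=9)
        fit = estimate_lambda(vals[:, 0], V=V)
        assert 0.0 <= fit.ci_low <= fit.lambda_ <= fit.ci_high <= 1.0
        model = PagelLambda(vals[:, 0], V=V)
        cutoff = fit.llf - stats.chi2.ppf(0.95, 1) / 2
        if fit.ci_low > 0:
            assert model.loglik(fit.ci_low) == pytest.approx(cutoff, abs=1e-3)

    def test_ci_coverage_under_bm(self, yule71):
        # 95% profile CI should contain lambda=1 in >= 90% of BM replicates
        _, V, labels = yule71
        vals, _ = simulate_bm_traits(V=V, labels=labels, sigma2=1.0, lam=1.0,
                                     n_traits=200, seed=10)
        hits = sum(
            estimate_lambda(vals[:, j], V=V).ci_high >= 1.0 - 1e-9
            for j in range(200)
        )
        assert hits / 200 >= 0.90

    def test_star_tree_unidentifiable(self):
        V = np.eye(10)
        fit = estimate_lambda(np.random.default_rng(0).normal(size=10), V=V)
        assert not fit.identifiable
        assert fit.lambda_ == 0.0

    def test_input_validation(self, yule71):
        _, V, _ = yule71
        with pytest.raises(ValueError):
            PagelLambda(np.ones(71), V=V)  # zero variance
        with pytest.raises(ValueError):
            PagelLambda(np.arange(3.0), V=V[:3, :3])  # too few species


class TestRepeatability:
    def test_zero_within_variance_gives_one(self):
        values = np.repeat([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        assert repeatability_icc(values, groups, n_boot=50, seed=0).icc == 1.0

    def test_identical_means_noisy_replicates_near_zero(self, rng):
        groups = np.repeat([f"s{i}" for i in range(40)], 3)
        values = rng.normal(0.0, 1.0, size=120)
        est = repeatability_icc(values, groups, n_boot=50, seed=0)
        assert est.icc <= 0.15

    def test_recovers_generating_variance_ratio(self):
        # between-species variance 3, within 1 -> ICC 0.75
        rng = np.random.default_rng(42)
        target = 3.0 / 4.0
        iccs = []
        for _ in range(200):
            mu = rng.normal(0, np.sqrt(3.0), size=71)
            vals = (mu[:, None] + rng.normal(0, 1.0, size=(71, 3))).ravel()
            groups = np.repeat(np.arange(71), 3)
            iccs.append(repeatability_icc(vals, groups, n_boot=0, seed=0).icc)
        assert np.mean(iccs) == pytest.approx(target, abs=0.05)

    def test_percentiles_ordered_and_bounded(self, small_dataset):
        ds = small_dataset
        est = repeatability_icc(
            ds.traits["log10_biliverdin"], ds.traits["species"], n_boot=300, seed=3
        )
        assert 0.0 <= est.p5 <= est.icc + 1e-9
        assert est.p5 <= est.p95 <= 1.0

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        mu = rng.normal(0, 1, size=12)
        vals = (mu[:, None] + rng.normal(0, 0.5, size=(12, 3))).ravel()
        groups = np.repeat(np.arange(12), 3)
        a = repeatability_icc(vals, groups, n_boot=0, seed=0).icc
        b = repeatability_icc(scale * vals + shift, groups, n_boot=0, seed=0).icc
        assert b == pytest.approx(a, abs=1e-9)

    def test_single_replicate_everywhere_rejected(self):
        with pytest.raises(ValueError):
            repeatability_icc([1.0, 2.0, 3.0], ["a", "b", "c"])


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_tied_example_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        rx = stats.rankdata(x)  # average ranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    @given(st.permutations(list(range(8))))
    @settings(max_examples=40, derandomize=True)
    def test_invariant_to_monotone_transform(self, perm):
        x = np.array(perm, dtype=float)
        y = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0, 6.0, 5.0])
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 3), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, y**3) == pytest.approx(base, abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = spearman_rho(np.ones(5), np.arange(5.0))
        assert np.isnan(out)
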