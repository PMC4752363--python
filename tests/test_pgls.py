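import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovotrait.pgls import (
    PGLS,
    akaike_weights,
    confidence_set,
    enumerate_models,
    fit_model_set,
    model_average,
)
from ovotrait.simulate import simulate_bm_traits


@pytest.fixture(scope="module")
def design(yule71):
    tree, V, labels = yule71
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=71),
            "x2": rng.binomial(1, 0.5, size=71).astype(float),
            "x3": rng.normal(2.0, 0.5, size=71),
        },
        index=labels,
    )
    return tree, V, df


class TestPGLSFit:
    def test_identity_covariance_equals_ols(self, design):
        _, V, df = design
        rng = np.random.default_rng(3)
        y = 1.0 + 0.5 * df["x1"] - 0.3 * df["x2"] + rng.normal(size=71)
        model = PGLS(
            y.to_numpy(),
            df[["x1", "x2"]].to_numpy(),
            V=np.eye(71),
            exog_names=["x1", "x2"],
        )
        res = model.fit(lambda_mode=1.0)
        X = np.column_stack([np.ones(71), df[["x1", "x2"]].to_numpy()])
        beta_ols = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
        assert np.allclose(res.params.to_numpy(), beta_ols, atol=1e-8)

    def test_loglik_matches_dense_mvn(self, design):
        # oracle: direct multivariate normal density at the GLS maximisers
        tree, V, df = design
        n = 10
        Vs = V[:n, :n]
        rng = np.random.default_rng(4)
        y = rng.normal(size=n)
        X = df["x1"].to_numpy()[:n]
        model = PGLS(y, X, V=Vs, exog_names=["x1"])
        res = model.fit(lambda_mode=1.0)
        mean = np.column_stack([np.ones(n), X]) @ res.params.to_numpy()
        oracle = stats.multivariate_normal(mean=mean, cov=res.sigma2 * Vs).logpdf(y)
        assert res.llf == pytest.approx(oracle, abs=1e-9)

    def test_aic_identity_and_k_counting(self, design):
        _, V, df = design
        y = np.random.default_rng(5).normal(size=71)
        model = PGLS(y, df[["x1"]].to_numpy(), V=V, exog_names=["x1"])
        fixed = model.fit(lambda_mode=1.0)
        ml = model.fit(lambda_mode="ml")
        assert fixed.k_params == 3  # intercept, slope, sigma2
        assert ml.k_params == 4  # + lambda
        assert fixed.aic == pytest.approx(-2 * fixed.llf + 2 * fixed.k_params)

    def test_joint_ml_lambda_beats_fixed(self, design):
        tree, V, df = design
        vals, _ = simulate_bm_traits(V=V, labels=list(df.index), sigma2=0.1,
                                     lam=1.0, n_traits=1, seed=11)
        y = 1.0 + 0.4 * df["x1"].to_numpy() + vals[:, 0]
        model = PGLS(y, df[["x1"]].to_numpy(), V=V, exog_names=["x1"])
        ml = model.fit(lambda_mode="ml")
        assert ml.llf >= model.fit(lambda_mode=0.0).llf - 1e-9
        assert ml.llf >= model.fit(lambda_mode=1.0).llf - 1e-9
        assert 0.0 <= ml.lam <= 1.0

    def test_predictor_rescaling_leaves_aic_invariant(self, design):
        _, V, df = design
        y = np.random.default_rng(6).normal(size=71)
        a = PGLS(y, df[["x1", "x3"]].to_numpy(), V=V).fit(lambda_mode=1.0)
        scaled = df[["x1", "x3"]].to_numpy().copy()
        scaled[:, 0] *= 100.0
        b = PGLS(y, scaled, V=V).fit(lambda_mode=1.0)
        assert b.aic == pytest.approx(a.aic, abs=1e-8)
        assert b.params.iloc[1] == pytest.approx(a.params.iloc[1] / 100.0)

    def test_rank_deficient_design_named(self, design):
        _, V, df = design
        X = np.column_stack([df["x1"], 2.0 * df["x1"]])
        with pytest.raises(ValueError, match="collinear"):
            PGLS(np.zeros(71), X, V=V, exog_names=["a", "b"])

    def test_species_mismatch_listed(self, design):
        tree, _, df = design
        bad = df.rename(index={df.index[0]: "nonesuch"})
        with pytest.raises(ValueError, match="nonesuch"):
            PGLS.from_dataframe(bad.assign(y=0.0), "y", ["x1"], tree=tree)

    def test_coverage_of_true_coefficients_under_bm(self, design):
        # lambda fixed at 1, correctly specified model: 95% CIs should
        # cover each true coefficient in >= 90% of replicates
        _, V, df = design
        beta = {"intercept": 1.0, "x1": 0.4, "x2": -0.3}
        X = df[["x1", "x2"]].to_numpy()
        reps, hits = 100, np.zeros(3)
        errs, _ = simulate_bm_traits(V=V, labels=list(df.index), sigma2=0.3,
                                     lam=1.0, n_traits=reps, seed=12)
        truth = np.array(list(beta.values()))
        for r in range(reps):
            y = truth[0] + X @ truth[1:] + errs[:, r]
            res = PGLS(y, X, V=V, exog_names=["x1", "x2"]).fit(lambda_mode=1.0)
            ci = res.conf_int()
            hits += (ci["lower"].to_numpy() <= truth) & (truth <= ci["upper"].to_numpy())
        assert (hits / reps >= 0.90).all()

    def test_summary_mentions_lambda_and_aic(self, design):
        _, V, df = design
        y = np.random.default_rng(7).normal(size=71)
        res = PGLS(y, df[["x1"]].to_numpy(), V=V, exog_names=["x1"]).fit()
        text = res.summary()
        assert "lambda" in text and "AIC" in text and "x1" in text


class TestEnumeration:
    def test_subset_counts(self):
        assert len(enumerate_models(["a", "b", "c"])) == 8
        assert enumerate_models([]) == [()]
        assert len(enumerate_models(list("abcdef"))) == 64

    def test_ordering_by_size_then_lexicographic(self):
        models = enumerate_models(["a", "b"])
        assert models == [(), ("a",), ("b",), ("a", "b")]

    def test_always_terms_in_every_model(self):
        models = enumerate_models(["a", "b"], always=("co",))
        assert all(m[0] == "co" for m in models)
        assert len(models) == 4

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="exceed"):
            enumerate_models([f"p{i}" for i in range(13)])


class TestWeightsAndConfidenceSet:
    def test_equal_aics_uniform_weights(self):
        w = akaike_weights([10.0, 10.0, 10.0, 10.0])
        assert np.allclose(w, 0.25)

    def test_delta_two_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_shift_invariance(self):
        a = akaike_weights([3.0, 4.5, 7.0])
        b = akaike_weights([103.0, 104.5, 107.0])
        assert np.allclose(a, b)

    def test_nonfinite_excluded(self):
        with pytest.warns(UserWarning, match="non-finite"):
            w = akaike_weights([1.0, np.inf, 2.0])
        assert w[1] == 0.0
        assert w.sum() == pytest.approx(1.0)

    def test_confidence_set_accumulation(self):
        idx = confidence_set([0.6, 0.3, 0.08, 0.02], threshold=0.95)
        assert idx == [0, 1, 2]

    def test_single_model_and_zero_threshold(self):
        assert confidence_set([1.0]) == [0]
        assert confidence_set([0.5, 0.3, 0.2], threshold=0.0) == [0]

    def test_tie_broken_by_fewer_parameters(self):
        idx = confidence_set([0.4, 0.4, 0.2], threshold=0.5, k_params=[3, 2, 1])
        assert idx[0] == 1


class TestModelAverage:
    @staticmethod
    def _fake_fit(params: dict, ses: dict, V=None):
        class Fake:
            pass

        f = Fake()
        f.params = pd.Series(params)
        f.bse = pd.Series(ses)
        return f

    def test_two_model_hand_oracle(self):
        f1 = self._fake_fit({"intercept": 0.0, "x": 1.0}, {"intercept": 1.0, "x": 0.2})
        f2 = self._fake_fit({"intercept": 0.0, "x": 2.0}, {"intercept": 1.0, "x": 0.3})
        out = model_average([f1, f2], [0.75, 0.25], terms=["intercept", "x"])
        assert out.loc["x", "estimate"] == pytest.approx(1.25)
        se_hand = 0.75 * np.sqrt(0.2**2 + (1.0 - 1.25) ** 2) + 0.25 * np.sqrt(
            0.3**2 + (2.0 - 1.25) ** 2
        )
        assert out.loc["x", "se"] == pytest.approx(se_hand, abs=1e-12)
        assert out.loc["x", "ci95_low"] == pytest.approx(1.25 - 1.96 * se_hand)
        assert out.loc["x", "ci90_high"] == pytest.approx(1.25 + 1.645 * se_hand)
        assert out.loc["x", "importance"] == pytest.approx(1.0)
        assert out.loc["x", "n_containing_models"] == 2

    def test_predictor_in_all_models_plain_weighted_mean(self):
        fits = [
            self._fake_fit({"x": b}, {"x": 0.1}) for b in (0.5, 1.0, 1.5)
        ]
        w = np.array([0.2, 0.5, 0.3])
        out = model_average(fits, w, terms=["x"])
        assert out.loc["x", "estimate"] == pytest.approx(float(w @ [0.5, 1.0, 1.5]))

    def test_degenerate_equal_estimates(self):
        fits = [self._fake_fit({"x": 0.7}, {"x": 0.25}) for _ in range(3)]
        out = model_average(fits, [0.5, 0.3, 0.2], terms=["x"])
        assert out.loc["x", "estimate"] == pytest.approx(0.7)
        assert out.loc["x", "se"] == pytest.approx(0.25)

    def test_absent_predictor_reported_with_zero_importance(self):
        f = self._fake_fit({"x": 1.0}, {"x": 0.1})
        out = model_average([f], [1.0], terms=["x", "ghost"])
        assert out.loc["ghost", "importance"] == 0.0
        assert np.isnan(out.loc["ghost", "estimate"])
        assert out.loc["ghost", "n_containing_models"] == 0


class TestModelSet:
    def test_full_candidate_set_and_weights(self, design):
        tree, V, df = design
        rng = np.random.default_rng(9)
        data = df.assign(y=rng.normal(size=71))
        res = fit_model_set(
            data, "y", ["x1", "x2", "x3"], V=V, lambda_mode=1.0
        )
        assert res.n_models == 8
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert 1 <= res.confidence_set_size <= 8
        assert set(res.averaged.index) == {"intercept", "x1", "x2", "x3"}
        assert "candidate models" in res.summary()

    def test_always_term_has_full_importance(self, design):
        tree, V, df = design
        rng = np.random.default_rng(10)
        data = df.assign(y=rng.normal(size=71))
        res = fit_model_set(
            data, "y", ["x2", "x3"], V=V, always=("x1",), lambda_mode=1.0
        )
        assert res.n_models == 4
        assert res.averaged.loc["x1", "importance"] == pytest.approx(1.0)
        assert (
            res.averaged.loc["x1", "n_containing_models"]
            == res.confidence_set_size
        )
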