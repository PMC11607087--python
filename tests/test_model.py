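import numpy as np
import pandas as pd
import pytest
from scipy import stats

import matriline as ml
from matriline.model import McmcSettings, MixedModel, ModelSpec, RandomTerm, build_design

from conftest import FAST


def fit_fast(df, spec, seed=0, **kw):
    settings = McmcSettings(**{**FAST.__dict__, "seed": seed, **kw})
    return MixedModel(df, spec).fit(settings)


class TestBuildDesign:
    def test_scaled_covariate_is_standardized(self):
        df = pd.DataFrame({"y": [0.0, 1, 2], "x": [1.0, 2, 3]})
        d = build_design(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),)))
        col = d.x[:, d.x_names.index("x")]
        assert col.mean() == pytest.approx(0)
        assert col.std(ddof=1) == pytest.approx(1)

    def test_zero_variance_covariate_rejected(self):
        df = pd.DataFrame({"y": [0.0, 1, 2], "x": [2.0, 2, 2]})
        with pytest.raises(ValueError, match="zero variance"):
            build_design(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),)))

    def test_interaction_is_product_of_scaled_parents(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(size=10), "a": rng.normal(size=10),
                           "b": rng.normal(size=10)})
        spec = ModelSpec("y", fixed=(
            ml.FixedTerm("a", ("a",), "linear"),
            ml.FixedTerm("b", ("b",), "linear"),
            ml.FixedTerm("a:b", ("a", "b"), "interaction"),
        ))
        d = build_design(df, spec)
        za = d.x[:, d.x_names.index("a")]
        zb = d.x[:, d.x_names.index("b")]
        np.testing.assert_allclose(d.x[:, d.x_names.index("a:b")], za * zb)

    def test_quadratic_is_square_of_scaled(self):
        df = pd.DataFrame({"y": np.zeros(5), "x": [1.0, 2, 3, 4, 5]})
        d = build_design(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "quadratic"),)))
        z = d.x[:, d.x_names.index("x")]
        np.testing.assert_allclose(d.x[:, d.x_names.index("x_sq")], z**2)

    def test_missing_covariate_rows_reported(self):
        df = pd.DataFrame({"y": [0.0, 1, 2], "x": [1.0, np.nan, 3]})
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            build_design(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),)))

    def test_grouping_levels_must_be_covered_by_covariance(self, trio_pedigree):
        a = ml.additive_relationship_matrix(trio_pedigree)
        df = pd.DataFrame({"y": [0.0, 1], "bear_id": ["kid1", "stranger"]})
        spec = ModelSpec("y", random=(RandomTerm("genetic", "bear_id", cov=a),))
        with pytest.raises(ValueError, match="stranger"):
            build_design(df, spec)


class TestFit:
    def test_residual_variance_recovered_intercept_only(self):
        y = np.random.default_rng(0).normal(5.0, 1.0, 500)
        res = fit_fast(pd.DataFrame({"y": y}), ModelSpec("y"))
        assert 0.85 < np.median(res.sigma2_flat("residual")) < 1.15
        assert res.converged

    def test_reproducible_per_seed(self):
        df = pd.DataFrame({"y": np.random.default_rng(1).normal(size=50)})
        a = fit_fast(df, ModelSpec("y"), seed=7)
        b = fit_fast(df, ModelSpec("y"), seed=7)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma2["residual"], b.sigma2["residual"])

    def test_unreplicated_random_intercepts_flagged_unidentified(self):
        """One level per observation: σ²_I and σ²_R are jointly unidentified
        and the convergence gate must refuse a summary."""
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(0, 1, 60),
                           "gid": [f"g{i}" for i in range(60)]})
        res = fit_fast(df, ModelSpec("y", random=(RandomTerm("individual", "gid"),)))
        d = res.diagnostics()
        assert (d["ess"] <= 400).any()
        assert not res.converged
        with pytest.raises(ml.ConvergenceError):
            res.summary()

    def test_repeatability_matches_anova_oracle(self):
        """Balanced grouped design with ICC 0.5: the posterior repeatability
        agrees with the closed-form ANOVA intraclass correlation."""
        rng = np.random.default_rng(3)
        n_id, k = 100, 4
        u = rng.normal(0, 1, n_id)
        y = (u[:, None] + rng.normal(0, 1, (n_id, k))).ravel()
        gid = np.repeat([f"g{i}" for i in range(n_id)], k)
        df = pd.DataFrame({"y": y, "gid": gid})
        res = fit_fast(df, ModelSpec("y", random=(RandomTerm("individual", "gid"),)))
        groups = df.groupby("gid")["y"].mean()
        msb = k * groups.var(ddof=1)
        msw = df.groupby("gid")["y"].var(ddof=1).mean()
        icc = (msb - msw) / (msb + (k - 1) * msw)
        rep = ml.repeatability(res, include_fixed=False)
        assert rep["median"] == pytest.approx(icc, abs=0.05)

    def test_non_psd_covariance_rejected(self):
        bad = ml.SimilarityMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]), "environment")
        df = pd.DataFrame({"y": [0.0, 1], "bear_id": ["a", "b"]})
        spec = ModelSpec("y", random=(RandomTerm("environment", "bear_id", cov=bad),))
        with pytest.raises(ValueError, match="positive definite"):
            build_design(df, spec)


class TestIndividualExtraction:
    def test_known_intercepts_recovered(self):
        rng = np.random.default_rng(5)
        n_id, k = 60, 5
        u = rng.normal(0, 1, n_id)
        ids = [f"m{i}" for i in range(n_id)]
        df = pd.DataFrame({
            "y": (3.0 + u[:, None] + rng.normal(0, 0.7, (n_id, k))).ravel(),
            "bear_id": np.repeat(ids, k),
        })
        res = fit_fast(df, ModelSpec("y", random=(RandomTerm("individual", "bear_id"),)))
        table = res.random_effect_table("individual").set_index("id")
        r = stats.pearsonr(table.loc[ids, "posterior_tp"], 3.0 + u)[0]
        assert r > 0.9

    def test_shrinkage_direction_and_unknown_id(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "y": np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 0.1, 6)]),
            "bear_id": ["lo"] * 40 + ["hi"] * 6,
        })
        res = fit_fast(df, ModelSpec("y", random=(RandomTerm("individual", "bear_id"),)))
        intercept = np.median(res.beta_flat()[:, 0])
        assert res.extract_individual_tp("hi", "individual") > intercept
        with pytest.raises(KeyError, match="ghost"):
            res.extract_individual_tp("ghost", "individual")

    def test_unobserved_level_returns_prior_centred_value(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({
            "y": rng.normal(2.0, 1.0, 60),
            "bear_id": np.repeat([f"g{i}" for i in range(20)], 3),
        })
        levels = tuple([f"g{i}" for i in range(20)] + ["never_seen"])
        res = fit_fast(
            df, ModelSpec("y", random=(RandomTerm("individual", "bear_id", levels=levels),))
        )
        intercept = np.median(res.beta_flat()[:, 0])
        extracted = res.extract_individual_tp("never_seen", "individual")
        assert extracted == pytest.approx(intercept, abs=0.15)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"y": rng.normal(1.0, 0.5, 40), "x": rng.normal(size=40)})
    return fit_fast(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),)))


class TestPointwiseLoglik:
    def test_matches_direct_normal_density_oracle(self, fitted):
        ll = fitted.pointwise_loglik()
        mu = fitted.mu.reshape(ll.shape)
        s = np.sqrt(fitted.sigma2_flat("residual"))
        y = fitted.design.y
        direct = stats.norm.logpdf(y[None, :], loc=mu, scale=s[:, None])
        np.testing.assert_allclose(ll, direct, atol=1e-10)
        # sums across observations reproduce the joint conditional loglik
        np.testing.assert_allclose(ll.sum(axis=1), direct.sum(axis=1), atol=1e-10)

    def test_closed_form_at_predicted_mean_and_monotonicity(self):
        """An observation sitting exactly at its predicted mean has density
        −½·log(2πσ²), which decreases when the residual SD doubles."""
        from conftest import fabricate_results
        df = pd.DataFrame({"y": [1.0, 2.0]})
        beta = np.zeros((1, 2, 1))
        res = fabricate_results(
            df, ModelSpec("y"),
            beta=beta,
            sigma2={"residual": np.array([[0.25, 1.0]])},
            mu=np.tile(df["y"].to_numpy(), (1, 2, 1)),
        )
        ll = res.pointwise_loglik()
        np.testing.assert_allclose(ll[0], -0.5 * np.log(2 * np.pi * 0.25))
        np.testing.assert_allclose(ll[1], -0.5 * np.log(2 * np.pi * 1.0))
        assert np.all(ll[1] < ll[0])


class TestLoo:
    def test_identical_models_have_zero_elpd_difference(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"y": rng.normal(size=30)})
        a = fit_fast(df, ModelSpec("y"), seed=1)
        b = fit_fast(df, ModelSpec("y"), seed=1)
        cmp = ml.compare_models({"a": a, "b": b})
        assert cmp["elpd_loo"].iloc[0] == pytest.approx(cmp["elpd_loo"].iloc[1])

    def test_psis_loo_within_two_se_of_exact_refits(self):
        """n = 8: PSIS-LOO agrees with brute-force leave-one-out refits."""
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"y": rng.normal(2.0, 1.0, 8)})
        res = fit_fast(df, ModelSpec("y"), seed=2)
        psis = res.loo()
        exact = 0.0
        for i in range(len(df)):
            held = df.drop(index=i).reset_index(drop=True)
            refit = fit_fast(held, ModelSpec("y"), seed=2)
            mu = refit.beta_flat()[:, 0]  # intercept-only predictive mean
            s = np.sqrt(refit.sigma2_flat("residual"))
            dens = stats.norm.pdf(df.loc[i, "y"], loc=mu, scale=s)
            exact += np.log(dens.mean())
        assert abs(float(psis.elpd_loo) - exact) < 2 * float(psis.se)

    def test_noise_predictor_gives_no_preference(self):
        rng = np.random.default_rng(11)
        n = 120
        x = rng.normal(size=n)
        df = pd.DataFrame({
            "y": 1.0 + 0.8 * x + rng.normal(0, 1, n),
            "x": x,
            "noise": rng.normal(size=n),
        })
        true = fit_fast(df, ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),)), seed=3)
        bigger = fit_fast(
            df,
            ModelSpec("y", fixed=(ml.FixedTerm("x", ("x",), "linear"),
                                  ml.FixedTerm("noise", ("noise",), "linear"))),
            seed=4,
        )
        cmp = ml.compare_models({"true": true, "with_noise": bigger})
        diff = abs(float(cmp["elpd_loo"].iloc[0] - cmp["elpd_loo"].iloc[1]))
        assert diff < 4

    def test_too_few_draws_rejected(self):
        df = pd.DataFrame({"y": np.random.default_rng(0).normal(size=10)})
        res = MixedModel(df, ModelSpec("y")).fit(
            McmcSettings(chains=1, iterations=60, warmup=30, thin=1, seed=0)
        )
        with pytest.raises(ValueError, match="100 draws"):
            res.loo()
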