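import numpy as np
import pandas as pd
import pytest

import matriline as ml
from matriline.model import FixedTerm, ModelSpec, RandomTerm
from matriline.partition import decompose, nakagawa_r2, partition_fixed, repeatability

from conftest import MEDIUM, fabricate_results


def _two_group_frame(n=24, seed=0, orthogonal=False):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    if orthogonal:
        b = rng.normal(size=n)
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal after centering below
        a = a - a.mean()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
    else:
        b = 0.7 * a + rng.normal(0, 0.7, n)
    return pd.DataFrame({"y": rng.normal(size=n), "a": a, "b": b})


def _spec_two_groups():
    return ModelSpec("y", fixed=(
        FixedTerm("a", ("a",), "linear", "G1"),
        FixedTerm("b", ("b",), "linear", "G2"),
    ))


class TestDecomposeTrivial:
    def test_pure_fixed_effect_has_proportion_one(self):
        df = _two_group_frame()
        beta = np.tile([0.0, 1.0, 0.5], (1, 5, 1))
        res = fabricate_results(
            df, _spec_two_groups(), beta=beta,
            sigma2={"residual": np.zeros((1, 5))},
        )
        dec = decompose(res)
        fixed_total = dec.proportions["G1"] + dec.proportions["G2"]
        np.testing.assert_allclose(fixed_total, 1.0, atol=1e-12)

    def test_symmetric_iid_components_split_evenly(self):
        df = pd.DataFrame({"y": np.zeros(6),
                           "g1": list("aabbcc"), "g2": list("abcabc")})
        spec = ModelSpec("y", random=(RandomTerm("r1", "g1"), RandomTerm("r2", "g2")))
        res = fabricate_results(
            df, spec, beta=np.zeros((1, 4, 1)),
            sigma2={"r1": np.full((1, 4), 2.0), "r2": np.full((1, 4), 2.0),
                    "residual": np.zeros((1, 4))},
        )
        dec = decompose(res)
        np.testing.assert_allclose(dec.proportions["r1"], 0.5)
        np.testing.assert_allclose(dec.proportions["r2"], 0.5)

    def test_relabeling_random_terms_keeps_proportions(self):
        df = pd.DataFrame({"y": np.zeros(4), "g": list("abab")})
        for name in ("alpha", "zeta"):
            spec = ModelSpec("y", random=(RandomTerm(name, "g"),))
            res = fabricate_results(
                df, spec, beta=np.zeros((1, 3, 1)),
                sigma2={name: np.full((1, 3), 1.0), "residual": np.full((1, 3), 3.0)},
            )
            np.testing.assert_allclose(decompose(res).proportions[name], 0.25)


class TestPartitionFixed:
    def test_zeroed_group_contributes_nothing(self):
        df = _two_group_frame()
        beta = np.tile([0.3, 0.0, 1.0], (1, 5, 1))  # group G1 coefficient zero
        res = fabricate_results(df, _spec_two_groups(), beta=beta,
                                sigma2={"residual": np.ones((1, 5))})
        parts = partition_fixed(res)
        np.testing.assert_allclose(parts["G1"], 0.0, atol=1e-12)

    def test_orthogonal_groups_get_their_own_variance(self):
        df = _two_group_frame(orthogonal=True)
        beta = np.tile([0.1, 0.8, -0.6], (1, 5, 1))
        res = fabricate_results(df, _spec_two_groups(), beta=beta,
                                sigma2={"residual": np.ones((1, 5))})
        parts = partition_fixed(res)
        d = res.design
        za = d.x[:, d.x_names.index("a")]
        zb = d.x[:, d.x_names.index("b")]
        np.testing.assert_allclose(parts["G1"], (0.8 * za).var(ddof=1), rtol=1e-9)
        np.testing.assert_allclose(parts["G2"], (-0.6 * zb).var(ddof=1), rtol=1e-9)

    def test_correlated_groups_rescale_to_full_variance(self):
        rng = np.random.default_rng(4)
        df = _two_group_frame(seed=4)
        beta = rng.normal(size=(2, 8, 3))
        res = fabricate_results(df, _spec_two_groups(), beta=beta,
                                sigma2={"residual": np.ones((2, 8))})
        parts = partition_fixed(res)
        full = res.fixed_linear_predictor().var(axis=1, ddof=1)
        np.testing.assert_allclose(parts["G1"] + parts["G2"], full, atol=1e-10)
        assert (parts["G1"] >= 0).all() and (parts["G2"] >= 0).all()

    def test_single_group_reduces_to_plain_fixed_variance(self):
        df = _two_group_frame()
        beta = np.tile([0.2, 0.5, 0.7], (1, 6, 1))
        res = fabricate_results(df, _spec_two_groups(), beta=beta,
                                sigma2={"residual": np.ones((1, 6))})
        parts = partition_fixed(res, groups={"all": ["a", "b"]})
        np.testing.assert_allclose(
            parts["all"], res.fixed_linear_predictor().var(axis=1, ddof=1), atol=1e-12
        )

    def test_empty_group_rejected(self):
        df = _two_group_frame()
        res = fabricate_results(df, _spec_two_groups(),
                                beta=np.zeros((1, 2, 3)),
                                sigma2={"residual": np.ones((1, 2))})
        with pytest.raises(ValueError, match="covers no design columns"):
            partition_fixed(res, groups={"empty": []})


class TestRepeatability:
    def test_equal_variances_give_half(self):
        df = pd.DataFrame({"y": np.zeros(4), "bear_id": list("abab")})
        spec = ModelSpec("y", random=(RandomTerm("individual", "bear_id"),))
        res = fabricate_results(
            df, spec, beta=np.zeros((1, 3, 1)),
            sigma2={"individual": np.full((1, 3), 1.3),
                    "residual": np.full((1, 3), 1.3)},
        )
        assert repeatability(res)["median"] == pytest.approx(0.5)

    def test_no_individual_variance_gives_zero(self):
        df = pd.DataFrame({"y": np.zeros(4), "bear_id": list("abab")})
        spec = ModelSpec("y", random=(RandomTerm("individual", "bear_id"),))
        res = fabricate_results(
            df, spec, beta=np.zeros((1, 3, 1)),
            sigma2={"individual": np.zeros((1, 3)), "residual": np.ones((1, 3))},
        )
        assert repeatability(res)["median"] == 0.0

    def test_missing_individual_term_rejected(self):
        df = pd.DataFrame({"y": np.zeros(4), "g": list("abab")})
        spec = ModelSpec("y", random=(RandomTerm("other", "g"),))
        res = fabricate_results(
            df, spec, beta=np.zeros((1, 2, 1)),
            sigma2={"other": np.ones((1, 2)), "residual": np.ones((1, 2))},
        )
        with pytest.raises(KeyError, match="individual"):
            repeatability(res)

    def test_posterior_matches_anova_on_balanced_design(self):
        rng = np.random.default_rng(12)
        n_id, k = 70, 2
        icc_sd = np.sqrt(0.48 / 0.52)  # between-SD giving true ICC 0.48
        u = rng.normal(0, icc_sd, n_id)
        df = pd.DataFrame({
            "trophic_position": (u[:, None] + rng.normal(0, 1, (n_id, k))).ravel(),
            "bear_id": np.repeat([f"i{j}" for j in range(n_id)], k),
        })
        spec = ModelSpec("trophic_position",
                         random=(RandomTerm("individual", "bear_id"),))
        res = ml.MixedModel(df, spec).fit(
            ml.McmcSettings(chains=4, iterations=800, warmup=400, thin=1, seed=5)
        )
        groups = df.groupby("bear_id")["trophic_position"]
        msb = k * groups.mean().var(ddof=1)
        msw = groups.var(ddof=1).mean()
        icc = (msb - msw) / (msb + (k - 1) * msw)
        assert repeatability(res, include_fixed=False)["median"] == pytest.approx(icc, abs=0.1)


class TestNakagawaR2:
    def test_no_random_effects_marginal_equals_conditional(self):
        df = _two_group_frame()
        beta = np.tile([0.0, 1.0, 0.2], (1, 4, 1))
        res = fabricate_results(df, _spec_two_groups(), beta=beta,
                                sigma2={"residual": np.ones((1, 4))})
        r2 = nakagawa_r2(res)
        np.testing.assert_allclose(r2["marginal_draws"], r2["conditional_draws"])

    def test_intercept_only_marginal_is_zero(self):
        df = pd.DataFrame({"y": np.zeros(4), "g": list("abab")})
        spec = ModelSpec("y", random=(RandomTerm("individual", "g"),))
        res = fabricate_results(
            df, spec, beta=np.full((1, 3, 1), 2.5),
            sigma2={"individual": np.ones((1, 3)), "residual": np.ones((1, 3))},
        )
        r2 = nakagawa_r2(res)
        np.testing.assert_allclose(r2["marginal_draws"], 0.0, atol=1e-12)
        np.testing.assert_allclose(r2["conditional_draws"], 0.5)


class TestKnownTruthRecovery:
    def test_animal_model_recovers_constructed_proportions(self):
        """Phenotypes drawn from the animal model itself — breeding values on
        the pedigree A, environmental effects on the habitat E, maternal,
        permanent and residual effects with variance shares (A .10, M .15,
        E .05, I .10, R .60) over ~400 observations of ~200 individuals:
        posterior medians of every proportion land within ±0.07 of the
        construction values, and per-draw proportions always sum to one."""
        from matriline.model import MixedModel, animal_model_spec
        from matriline.pedigree import additive_relationship_matrix
        from matriline.similarity import env_similarity_matrix

        total = 0.04
        props = {"genetic": 0.10, "maternal": 0.15, "environment": 0.05,
                 "individual": 0.10, "residual": 0.60}
        ds = ml.simulate_dataset(
            seed=21, n_mothers=100,
            obs_count_probs=(0.3, 0.4, 0.3, 0, 0, 0, 0, 0, 0, 0, 0),
        )
        focal = ds.samples[ds.samples.sex == "female"].reset_index(drop=True)
        assert len(focal) >= 400
        ids = focal["bear_id"].unique().tolist()
        a_mat = additive_relationship_matrix(ds.pedigree.prune(ids)).subset(ids)
        hr = (ds.home_ranges[ds.home_ranges.bear_id.isin(ids)]
              .set_index("bear_id").loc[ids].reset_index())
        e_mat = env_similarity_matrix(hr)

        rng = np.random.default_rng(1021)
        n_id = len(ids)
        a = np.linalg.cholesky(a_mat.values + 1e-10 * np.eye(n_id)) \
            @ rng.standard_normal(n_id) * np.sqrt(props["genetic"] * total)
        u = np.linalg.cholesky(e_mat.values + 1e-9 * np.eye(n_id)) \
            @ rng.standard_normal(n_id) * np.sqrt(props["environment"] * total)
        p = rng.standard_normal(n_id) * np.sqrt(props["individual"] * total)
        mothers = focal["mother_id"].unique().tolist()
        m_eff = rng.standard_normal(len(mothers)) * np.sqrt(props["maternal"] * total)
        row = focal["bear_id"].map({i: k for k, i in enumerate(ids)}).to_numpy()
        mrow = focal["mother_id"].map({m: k for k, m in enumerate(mothers)}).to_numpy()
        focal["trophic_position"] = (
            2.9 + a[row] + u[row] + p[row] + m_eff[mrow]
            + rng.standard_normal(len(focal)) * np.sqrt(props["residual"] * total)
        )

        spec = animal_model_spec(a_mat, e_mat, social_learning=False)
        res = MixedModel(focal, spec).fit(MEDIUM)
        dec = res.variance_decomposition()
        total_draws = np.sum(list(dec.components.values()), axis=0)
        np.testing.assert_allclose(total_draws / dec.total, 1.0, atol=1e-10)
        summary = dec.summary().set_index("component")
        for comp, truth in props.items():
            assert summary.loc[comp, "median"] == pytest.approx(truth, abs=0.07)

    def test_r2_recovers_constructed_share(self):
        rng = np.random.default_rng(30)
        n_id, k = 80, 4
        u = rng.normal(0, np.sqrt(0.3), n_id)
        x = rng.normal(size=(n_id, k))
        y = 0.5 + np.sqrt(0.3) * x + u[:, None] + rng.normal(0, np.sqrt(0.4), (n_id, k))
        df = pd.DataFrame({
            "y": y.ravel(), "x": (np.sqrt(1.0) * x).ravel(),
            "bear_id": np.repeat([f"i{j}" for j in range(n_id)], k),
        })
        spec = ModelSpec("y", fixed=(FixedTerm("x", ("x",), "linear", "X"),),
                         random=(RandomTerm("individual", "bear_id"),))
        res = ml.MixedModel(df, spec).fit(
            ml.McmcSettings(chains=4, iterations=800, warmup=400, thin=1, seed=6)
        )
        r2 = nakagawa_r2(res)
        assert r2["marginal"]["median"] == pytest.approx(0.3, abs=0.05)
        assert r2["conditional"]["median"] == pytest.approx(0.6, abs=0.05)
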