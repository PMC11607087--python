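"""Bayesian Gaussian mixed models with structured random effects.

The central object is :class:`MixedModel`, a Gaussian hierarchical model

    y = X β + Σ_k Z_k u_k + ε,   u_k ~ N(0, σ²_k K_k),   ε ~ N(0, σ²_R I)

where each random term k groups observations by a factor (individual
identity, mother identity, ...) and may carry a known covariance K_k among
its levels — the pedigree-derived additive relationship matrix A for the
breeding-value ("animal") term, or an environmental/spatial similarity
matrix. With K = I the term is an ordinary i.i.d. random intercept.

Fitting is by a blocked conjugate Gibbs sampler. Structured effects are
sampled on the whitened scale u_k = L_k v_k with L_k the Cholesky factor
of K_k, so every full conditional is Gaussian or inverse gamma:

* β has a wide Normal(0, τ²I) prior with τ = 10·sd(y);
* each variance σ²_k (and σ²_R) has a half-Student-t(3, 0, 2.5·sd(y))
  prior on the SD, implemented by the inverse-gamma scale-mixture
  expansion so its conditional stays inverse gamma.

Convergence (R-hat, effective sample size) and PSIS-LOO model comparison
are delegated to ``arviz``. Results refuse to produce a summary table when
any R-hat ≥ 1.01 or any bulk ESS ≤ 400; draws remain accessible for
diagnostic work on an unconverged fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .pedigree import RelationshipMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "FixedTerm",
    "RandomTerm",
    "ModelSpec",
    "McmcSettings",
    "MixedModel",
    "MixedModelResults",
    "ConvergenceError",
    "compare_models",
    "basic_repeatability_spec",
    "animal_model_spec",
    "population_tp_spec",
]

HALF_T_DF = 3.0


class ConvergenceError(RuntimeError):
    """Raised when a summary is requested from a non-converged fit."""


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedTerm:
    """One fixed-effect term.

    ``kind`` is one of:

    * ``"linear"`` — the covariate, centred and scaled by its SD;
    * ``"quadratic"`` — scaled covariate plus its square (2nd-order polynomial);
    * ``"interaction"`` — elementwise product of the two scaled covariates
      named in ``columns``;
    * ``"categorical"`` — treatment-coded dummies (first level reference).

    ``group`` tags the term for fixed-effect variance partitioning
    (e.g. all social-learning terms share group ``"SL"``).
    """

    name: str
    columns: tuple[str, ...]
    kind: str = "linear"
    group: str | None = None


def linear(column: str, group: str | None = None) -> FixedTerm:
    return FixedTerm(column, (column,), "linear", group)


def quadratic(column: str, group: str | None = None) -> FixedTerm:
    return FixedTerm(column, (column,), "quadratic", group)


def interaction(left: str, right: str, group: str | None = None) -> FixedTerm:
    return FixedTerm(f"{left}:{right}", (left, right), "interaction", group)


def categorical(column: str, group: str | None = None) -> FixedTerm:
    return FixedTerm(column, (column,), "categorical", group)


@dataclass(frozen=True)
class RandomTerm:
    """A random-intercept term grouped by ``group_col``.

    ``cov`` supplies a known level covariance (relationship or similarity
    matrix); its ids must cover every level appearing in the data. When
    ``levels`` is given, effects are sampled for all of them, including
    levels with no observations (those return prior-centred posteriors).
    """

    name: str
    group_col: str
    cov: RelationshipMatrix | SimilarityMatrix | None = None
    levels: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[FixedTerm, ...] = ()
    random: tuple[RandomTerm, ...] = ()

    def __post_init__(self) -> None:
        names = [t.name for t in self.fixed] + [t.name for t in self.random]
        if len(names) != len(set(names)):
            raise ValueError("duplicated term names in model spec")


@dataclass
class DesignRandom:
    name: str
    levels: list[str]
    codes: np.ndarray          # row -> level index
    z_tilde: np.ndarray        # n × q, indicator @ chol(K)
    chol: np.ndarray           # q × q Cholesky of K (identity if iid)


@dataclass
class Design:
    """Materialised design: fixed matrix, column groups, random structures."""

    y: np.ndarray
    x: np.ndarray
    x_names: list[str]
    x_groups: list[str | None]
    random: list[DesignRandom]
    scaling: dict[str, tuple[float, float]]  # column -> (mean, sd)

    @property
    def n(self) -> int:
        return self.y.size


def _scaled(data: pd.DataFrame, col: str, scaling: dict) -> np.ndarray:
    if col not in data.columns:
        raise ValueError(f"missing covariate column {col!r}")
    x = data[col].to_numpy(dtype=float)
    if np.isnan(x).any():
        rows = np.flatnonzero(np.isnan(x)).tolist()
        raise ValueError(f"missing values in covariate {col!r}, rows {rows}")
    if col not in scaling:
        sd = x.std(ddof=1)
        if sd <= 1e-10 * max(1.0, float(np.abs(x).max())):
            raise ValueError(f"covariate {col!r} has zero variance")
        scaling[col] = (x.mean(), sd)
    mean, sd = scaling[col]
    return (x - mean) / sd


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build design matrices and grouping indices for ``spec`` on ``data``.

    Continuous covariates are centred and divided by their sample SD once;
    quadratic terms square the scaled covariate; interactions multiply the
    scaled parents.
    """
    if spec.response not in data.columns:
        raise ValueError(f"missing response column {spec.response!r}")
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing values in response")

    scaling: dict[str, tuple[float, float]] = {}
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    groups: list[str | None] = [None]
    for term in spec.fixed:
        if term.kind == "linear":
            cols.append(_scaled(data, term.columns[0], scaling))
            names.append(term.name)
            groups.append(term.group)
        elif term.kind == "quadratic":
            z = _scaled(data, term.columns[0], scaling)
            cols.extend([z, z**2])
            names.extend([term.name, f"{term.name}_sq"])
            groups.extend([term.group, term.group])
        elif term.kind in ("interaction", "interaction_sq"):
            zl = _scaled(data, term.columns[0], scaling)
            zr = _scaled(data, term.columns[1], scaling)
            if term.kind == "interaction_sq":
                zr = zr**2
            cols.append(zl * zr)
            names.append(term.name)
            groups.append(term.group)
        elif term.kind == "categorical":
            col = term.columns[0]
            values = data[col].astype(str)
            levels = sorted(values.unique())
            for lev in levels[1:]:
                cols.append((values == lev).to_numpy(dtype=float))
                names.append(f"{term.name}[{lev}]")
                groups.append(term.group)
        else:
            raise ValueError(f"unknown fixed term kind {term.kind!r}")
    x = np.column_stack(cols)

    randoms: list[DesignRandom] = []
    for term in spec.random:
        if term.group_col not in data.columns:
            raise ValueError(f"missing grouping column {term.group_col!r}")
        obs_levels = data[term.group_col].astype(str).tolist()
        if term.levels is not None:
            levels = [str(l) for l in term.levels]
        elif term.cov is not None:
            levels = [str(l) for l in term.cov.ids]
        else:
            levels = list(dict.fromkeys(obs_levels))
        index = {l: k for k, l in enumerate(levels)}
        missing = sorted(set(obs_levels) - set(levels))
        if missing:
            raise ValueError(
                f"random term {term.name!r}: levels {missing} absent from its "
                "covariance/levels"
            )
        codes = np.array([index[l] for l in obs_levels])
        q = len(levels)
        if term.cov is not None:
            k_mat = term.cov.subset(levels).values
            try:
                chol = np.linalg.cholesky(k_mat)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"covariance of random term {term.name!r} is not positive "
                    "definite; project it (e.g. similarity.nearest_psd) first"
                ) from exc
        else:
            chol = np.eye(q)
        z = np.zeros((len(data), q))
        z[np.arange(len(data)), codes] = 1.0
        randoms.append(DesignRandom(term.name, levels, codes, z @ chol, chol))
    return Design(y, x, names, groups, randoms, scaling)


# ---------------------------------------------------------------------------
# MCMC settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcSettings:
    """Sampler run lengths. Defaults give 4 × (6000−3000)/10 = 1200 draws."""

    chains: int = 4
    iterations: int = 6000
    warmup: int = 3000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if (self.iterations - self.warmup) % self.thin:
            raise ValueError("(iterations - warmup) must be divisible by thin")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thin

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


#: shortened settings for permutation-test refits, where only a point
#: summary of the genetic variance proportion is needed per fit
REDUCED_MCMC = McmcSettings(chains=1, iterations=600, warmup=300, thin=1)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _sample_mvn(prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec⁻¹ lin, prec⁻¹) via the precision Cholesky."""
    low = np.linalg.cholesky(prec)
    mean = solve_triangular(
        low.T, solve_triangular(low, lin, lower=True, check_finite=False),
        lower=False, check_finite=False,
    )
    z = rng.standard_normal(lin.size)
    return mean + solve_triangular(low.T, z, lower=False, check_finite=False)


class MixedModel:
    """Gaussian mixed model bound to a data table (statsmodels-style).

    Parameters
    ----------
    data : DataFrame
        One row per observation.
    spec : ModelSpec
        Response, fixed terms and random terms.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.design = build_design(self.data, spec)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       fixed: Sequence[FixedTerm] = (),
                       random: Sequence[RandomTerm] = ()) -> "MixedModel":
        return cls(data, ModelSpec(response, tuple(fixed), tuple(random)))

    # -- Gibbs sampler ------------------------------------------------------

    #: above this joint-location dimension, fall back to sequential block
    #: updates with interweaved intercept recentering (cost grows cubically
    #: with the joint dimension, quadratically with the largest block)
    JOINT_LIMIT = 400

    def fit(self, settings: McmcSettings = McmcSettings()) -> "MixedModelResults":
        d = self.design
        n, p = d.x.shape
        sd_y = d.y.std(ddof=1) if n > 1 else 1.0
        if sd_y == 0:
            sd_y = 1.0
        tau2 = (10.0 * sd_y) ** 2
        prior_scale2 = (2.5 * sd_y) ** 2
        nu = HALF_T_DF
        n_terms = len(d.random)
        # joint location block: theta = (beta, w_1, ..., w_K)
        big = np.column_stack([d.x] + [r.z_tilde for r in d.random])
        big_gram = big.T @ big
        big_ty = big.T @ d.y
        m = big.shape[1]
        slices = [slice(0, p)]
        stop = p
        for r in d.random:
            slices.append(slice(stop, stop + len(r.levels)))
            stop += len(r.levels)
        use_joint = m <= self.JOINT_LIMIT
        gram = [r.z_tilde.T @ r.z_tilde for r in d.random]
        xtx = d.x.T @ d.x
        # L_k^{-1} 1, for the intercept-recentering interweave
        ones_white = [
            solve_triangular(r.chol, np.ones(len(r.levels)), lower=True,
                             check_finite=False)
            for r in d.random
        ]
        has_intercept = d.x_names and d.x_names[0] == "intercept"

        ss = np.random.SeedSequence(settings.seed)
        chain_seeds = ss.spawn(settings.chains)
        dpc = settings.draws_per_chain

        beta_out = np.empty((settings.chains, dpc, p))
        sigma2_out = {r.name: np.empty((settings.chains, dpc)) for r in d.random}
        sigma2_out["residual"] = np.empty((settings.chains, dpc))
        u_out = {r.name: np.empty((settings.chains, dpc, len(r.levels)))
                 for r in d.random}
        mu_out = np.empty((settings.chains, dpc, n))

        for c in range(settings.chains):
            rng = np.random.default_rng(chain_seeds[c])
            beta = np.zeros(p)
            # parameter-expanded representation of each random term:
            # u_k = xi_k · L_k w_k,  w_k ~ N(0, phi²_k I),  xi_k ~ N(0, A²),
            # phi²_k ~ InvGamma(nu/2, nu/2)  =>  sd σ_k = |xi_k|·phi_k is
            # half-t(nu, A); the redundant scale xi decouples the funnel.
            theta = np.zeros(m)
            w = [np.zeros(len(r.levels)) for r in d.random]
            xi = np.full(n_terms, 0.1 * sd_y)
            phi2 = np.ones(n_terms)
            sig2_r = max(sd_y**2, 1e-6)
            aux_r = 1.0
            keep = 0
            f = np.ones(m)
            prior_prec = np.zeros(m)
            prior_prec[:p] = 1.0 / tau2
            for it in range(settings.iterations):
                if use_joint or it % 10 == 9:
                    # joint draw of (beta, w_1..w_K) | scales
                    for k in range(n_terms):
                        f[slices[k + 1]] = xi[k]
                        prior_prec[slices[k + 1]] = 1.0 / phi2[k]
                    prec = big_gram * np.outer(f, f) / sig2_r
                    prec[np.diag_indices(m)] += prior_prec
                    theta = _sample_mvn(prec, f * big_ty / sig2_r, rng)
                    beta = theta[:p]
                    resid = d.y - big @ (f * theta)
                    for k in range(n_terms):
                        w[k] = theta[slices[k + 1]]
                else:
                    # sequential blocks: beta | rest, then each w_k | rest
                    fitted_random = np.zeros(n)
                    for k, r in enumerate(d.random):
                        fitted_random += xi[k] * (r.z_tilde @ w[k])
                    prec_b = xtx / sig2_r + np.eye(p) / tau2
                    lin_b = d.x.T @ (d.y - fitted_random) / sig2_r
                    beta = _sample_mvn(prec_b, lin_b, rng)
                    resid = d.y - d.x @ beta - fitted_random
                    for k, r in enumerate(d.random):
                        q = len(r.levels)
                        resid += xi[k] * (r.z_tilde @ w[k])
                        prec_k = (xi[k] ** 2 / sig2_r) * gram[k] + np.eye(q) / phi2[k]
                        lin_k = (xi[k] / sig2_r) * (r.z_tilde.T @ resid)
                        w[k] = _sample_mvn(prec_k, lin_k, rng)
                        resid -= xi[k] * (r.z_tilde @ w[k])
                for k, r in enumerate(d.random):
                    q = len(r.levels)
                    if not use_joint and has_intercept:
                        # interweave: shift delta between the intercept and
                        # the level effects of term k (likelihood-invariant)
                        h = ones_white[k]
                        scale = xi[k] if xi[k] != 0 else 1e-12
                        prec_d = (h @ h) / (scale**2 * phi2[k]) + 1.0 / tau2
                        lin_d = (h @ w[k]) / (scale * phi2[k]) - beta[0] / tau2
                        delta = lin_d / prec_d + rng.standard_normal() / np.sqrt(prec_d)
                        w[k] = w[k] - (delta / scale) * h
                        beta = beta.copy()
                        beta[0] += delta
                    # phi²_k | w_k
                    phi2[k] = 1.0 / rng.gamma(
                        (nu + q) / 2.0, 2.0 / (nu + w[k] @ w[k])
                    )
                    # xi_k | rest (scalar Gaussian)
                    s = big[:, slices[k + 1]] @ w[k]
                    resid += xi[k] * s
                    prec_xi = s @ s / sig2_r + 1.0 / prior_scale2
                    mean_xi = (s @ resid / sig2_r) / prec_xi
                    xi[k] = mean_xi + rng.standard_normal() / np.sqrt(prec_xi)
                    resid -= xi[k] * s
                # residual variance: half-t prior via inverse-gamma mixture;
                # floored so exactly-interpolating data cannot collapse the
                # location precision matrices
                sig2_r = 1.0 / rng.gamma(
                    (nu + n) / 2.0, 1.0 / (nu / aux_r + 0.5 * resid @ resid)
                )
                sig2_r = max(sig2_r, 1e-8 * sd_y**2)
                aux_r = 1.0 / rng.gamma(
                    (nu + 1) / 2.0, 1.0 / (nu / sig2_r + 1.0 / prior_scale2)
                )
                post = it - settings.warmup
                if post >= 0 and (post + 1) % settings.thin == 0:
                    beta_out[c, keep] = beta
                    for k, r in enumerate(d.random):
                        sigma2_out[r.name][c, keep] = xi[k] ** 2 * phi2[k]
                        u_out[r.name][c, keep] = xi[k] * (r.chol @ w[k])
                    sigma2_out["residual"][c, keep] = sig2_r
                    mu_out[c, keep] = d.y - resid
                    keep += 1

        return MixedModelResults(
            model=self,
            settings=settings,
            beta=beta_out,
            sigma2=sigma2_out,
            u=u_out,
            mu=mu_out,
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResults:
    """Posterior draws, diagnostics and derived quantities of a fitted model.

    Arrays are indexed (chain, draw, ...). ``sigma2`` holds one variance per
    random term plus ``"residual"``; ``u`` holds random-effect levels on the
    original (unwhitened) scale; ``mu`` is the per-observation linear
    predictor including random effects.
    """

    model: MixedModel
    settings: McmcSettings
    beta: np.ndarray
    sigma2: dict[str, np.ndarray]
    u: dict[str, np.ndarray]
    mu: np.ndarray
    _idata: az.InferenceData | None = field(default=None, repr=False)

    # -- basic accessors ----------------------------------------------------

    @property
    def design(self) -> Design:
        return self.model.design

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def sigma2_flat(self, name: str) -> np.ndarray:
        if name not in self.sigma2:
            raise KeyError(f"no variance component {name!r}; have {list(self.sigma2)}")
        return self.sigma2[name].reshape(-1)

    def fixed_linear_predictor(self) -> np.ndarray:
        """Per-draw population-level (fixed-effects-only) predictor, draws × n."""
        return self.beta_flat() @ self.design.x.T

    # -- arviz bridge -------------------------------------------------------

    def to_inference_data(self, include_loglik: bool = True) -> az.InferenceData:
        if self._idata is None or include_loglik:
            posterior = {"beta": self.beta}
            for name, arr in self.sigma2.items():
                posterior[f"sigma2_{name}"] = arr
            coords = {"coef": self.design.x_names}
            dims = {"beta": ["coef"]}
            groups = {}
            if include_loglik:
                c, dpc, n = self.mu.shape
                groups["log_likelihood"] = {
                    "y": self.pointwise_loglik().reshape(c, dpc, n)
                }
            self._idata = az.from_dict(
                posterior=posterior, coords=coords, dims=dims, **groups
            )
        return self._idata

    def diagnostics(self) -> pd.DataFrame:
        """R-hat and bulk effective sample size for every scalar parameter."""
        idata = self.to_inference_data(include_loglik=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rows = []
        for var in rhat.data_vars:
            r = np.atleast_1d(rhat[var].values)
            e = np.atleast_1d(ess[var].values)
            labels = (
                self.design.x_names if var == "beta" and r.size > 1 else [var]
            )
            if var == "beta" and r.size > 1:
                for lab, ri, ei in zip(labels, r, e):
                    rows.append({"parameter": f"beta[{lab}]", "rhat": ri, "ess": ei})
            else:
                rows.append({"parameter": var, "rhat": float(r.max()),
                             "ess": float(e.min())})
        return pd.DataFrame(rows)

    @property
    def converged(self) -> bool:
        """True when every R-hat < 1.01 and every bulk ESS > 400."""
        if self.settings.chains < 2:
            return False
        d = self.diagnostics()
        return bool((d["rhat"] < 1.01).all() and (d["ess"] > 400).all())

    def require_convergence(self) -> None:
        if not self.converged:
            d = self.diagnostics()
            worst = d.loc[d["rhat"].idxmax()]
            raise ConvergenceError(
                "fit has not converged "
                f"(worst rhat {worst['rhat']:.3f} at {worst['parameter']}, "
                f"min ESS {d['ess'].min():.0f}); refusing to summarize"
            )

    # -- summaries ----------------------------------------------------------

    def summary(self, check_convergence: bool = True) -> pd.DataFrame:
        """Posterior medians, means and 89% equal-tail CIs for β and σ²."""
        if check_convergence:
            self.require_convergence()
        rows = []
        bflat = self.beta_flat()
        for j, name in enumerate(self.design.x_names):
            rows.append(_summary_row(f"beta[{name}]", bflat[:, j]))
        for name, arr in self.sigma2.items():
            rows.append(_summary_row(f"sigma2[{name}]", arr.reshape(-1)))
        return pd.DataFrame(rows)

    def random_effect_table(self, term: str, include_intercept: bool = True) -> pd.DataFrame:
        """Posterior median per level of a random term.

        With ``include_intercept`` the per-draw population intercept is added
        before taking the median, giving each level's value on the response
        scale (e.g. an individual's posterior trophic position).
        """
        if term not in self.u:
            raise KeyError(f"no random term {term!r}; have {list(self.u)}")
        levels = next(r.levels for r in self.design.random if r.name == term)
        uflat = self.u[term].reshape(-1, len(levels))
        if include_intercept:
            uflat = uflat + self.beta_flat()[:, [0]]
        med = np.median(uflat, axis=0)
        return pd.DataFrame({"id": levels, "posterior_tp": med})

    def extract_individual_tp(self, individual_id: str, term: str) -> float:
        """Posterior median trophic position of one individual.

        Per-draw sum of the population intercept and the individual's random
        intercept, summarised by the median.
        """
        table = self.random_effect_table(term)
        match = table[table["id"] == str(individual_id)]
        if match.empty:
            raise KeyError(f"individual {individual_id!r} not in random term {term!r}")
        return float(match["posterior_tp"].iloc[0])

    # -- likelihood / LOO ---------------------------------------------------

    def pointwise_loglik(self) -> np.ndarray:
        """Per-draw, per-observation Gaussian log density (draws × n)."""
        c, dpc, n = self.mu.shape
        mu = self.mu.reshape(-1, n)
        s2 = self.sigma2_flat("residual")[:, None]
        y = self.design.y[None, :]
        return -0.5 * (np.log(2 * np.pi * s2) + (y - mu) ** 2 / s2)

    def loo(self):
        """PSIS-LOO expected log pointwise predictive density (arviz ELPDData)."""
        if self.n_draws < 100:
            raise ValueError("need >= 100 draws for PSIS-LOO")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.to_inference_data(include_loglik=True), pointwise=True)

    # -- variance partitioning (delegates to matriline.partition) ----------

    def variance_decomposition(self, fixed_groups: dict[str, list[str]] | None = None):
        from .partition import decompose
        return decompose(self, fixed_groups=fixed_groups)

    def repeatability(self, include_fixed: bool = True):
        from .partition import repeatability
        return repeatability(self, include_fixed=include_fixed)

    def nakagawa_r2(self):
        from .partition import nakagawa_r2
        return nakagawa_r2(self)


def _summary_row(name: str, draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.055, 0.945])
    return {
        "parameter": name,
        "median": float(np.median(draws)),
        "mean": float(np.mean(draws)),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def compare_models(results: dict[str, MixedModelResults]) -> pd.DataFrame:
    """PSIS-LOO comparison table (elpd differences and their SEs).

    Rows are sorted best-first; ``elpd_diff`` is relative to the best model.
    A difference below 4 is treated as no meaningful preference.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(
            {k: r.to_inference_data(include_loglik=True) for k, r in results.items()},
            ic="loo",
        )
    return cmp


# ---------------------------------------------------------------------------
# canonical model builders for the trophic-position analysis
# ---------------------------------------------------------------------------

def basic_repeatability_spec() -> ModelSpec:
    """Basic model: quadratic age + permanent individual intercepts.

    Estimates individual dietary specialization (V_I) from repeated annual
    trophic positions.
    """
    return ModelSpec(
        response="trophic_position",
        fixed=(quadratic("age", group="Age"),),
        random=(RandomTerm("individual", "bear_id"),),
    )


def animal_model_spec(
    a_matrix: RelationshipMatrix,
    env_matrix: SimilarityMatrix | None = None,
    *,
    social_learning: bool = True,
    maternal: bool = True,
    quadratic_interaction: bool = False,
) -> ModelSpec:
    """The hybrid animal model partitioning individual specialization.

    Fixed effects: 2nd-order polynomial of time since separation (group
    "Age"); when ``social_learning``, the mother's posterior trophic
    position and its interaction with time since separation (group "SL") —
    the interaction uses the first-order time term; set
    ``quadratic_interaction`` to also interact with the squared term.
    Random terms: permanent individual, breeding value with covariance A,
    mother identity (when ``maternal``), and environmental (or spatial)
    similarity when ``env_matrix`` is given.
    """
    fixed: list[FixedTerm] = [quadratic("years_since_separation", group="Age")]
    if social_learning:
        fixed.append(linear("maternal_tp", group="SL"))
        fixed.append(interaction("maternal_tp", "years_since_separation", group="SL"))
        if quadratic_interaction:
            fixed.append(
                FixedTerm(
                    "maternal_tp:years_since_separation_sq",
                    ("maternal_tp", "years_since_separation"),
                    "interaction_sq",
                    "SL",
                )
            )
    random: list[RandomTerm] = [
        RandomTerm("individual", "bear_id"),
        RandomTerm("genetic", "bear_id", cov=a_matrix),
    ]
    if maternal:
        random.append(RandomTerm("maternal", "mother_id"))
    if env_matrix is not None:
        name = "environment" if env_matrix.kind == "environment" else "spatial"
        random.append(RandomTerm(name, "bear_id", cov=env_matrix))
    return ModelSpec("trophic_position", tuple(fixed), tuple(random))


def population_tp_spec() -> ModelSpec:
    """Population-wide model used to extract parental posterior trophic
    positions: quadratic age + individual random intercepts."""
    return ModelSpec(
        response="trophic_position",
        fixed=(quadratic("age", group="Age"),),
        random=(RandomTerm("individual", "bear_id"),),
    )
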