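"""Posterior variance partitioning: proportions, repeatability, R².

Works on :class:`~matriline.model.MixedModelResults`. Per posterior draw,
the variance explained by the fixed effects is the variance of the
population-level fitted values across observations ("variance in fitted
values"); each random term contributes its σ²; the residual contributes
σ²_R. Total phenotypic variance V_P is their sum, and every component is
reported as a proportion of V_P with equal-tail 89% credible intervals
(5.5th–94.5th posterior percentiles). A component is flagged
*inconclusive* when the lower CI limit of its proportion falls below
0.001, i.e. the data cannot rule out a negligible contribution.

The fixed-effect variance is further split between term groups (e.g.
social learning = maternal trophic position + its interaction with time
since separation, vs. the time/age polynomial) by semi-partial
contributions: each group's contribution is the drop in fitted-value
variance when its coefficients are zeroed, rescaled so the group
contributions sum exactly to the total fixed-effect variance
(commonality-style partitioning). Negative semi-partials (suppression)
are clipped at zero before rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MixedModelResults

__all__ = [
    "VarianceDecomposition",
    "decompose",
    "partition_fixed",
    "repeatability",
    "nakagawa_r2",
]

ETI = (0.055, 0.945)  # 89% equal-tail interval
INCONCLUSIVE_LIMIT = 0.001


def summarize_draws(draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, ETI)
    return {
        "median": float(np.median(draws)),
        "mean": float(np.mean(draws)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "inconclusive": bool(lo < INCONCLUSIVE_LIMIT),
    }


@dataclass
class VarianceDecomposition:
    """Per-draw variance components and their proportions of V_P."""

    components: dict[str, np.ndarray]   # name -> per-draw variance
    total: np.ndarray                   # per-draw V_P

    @property
    def proportions(self) -> dict[str, np.ndarray]:
        return {k: v / self.total for k, v in self.components.items()}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, prop in self.proportions.items():
            row = {"component": name, **summarize_draws(prop)}
            rows.append(row)
        return pd.DataFrame(rows)

    def proportion_summary(self, name: str) -> dict:
        if name not in self.components:
            raise KeyError(f"no component {name!r}; have {list(self.components)}")
        return summarize_draws(self.proportions[name])


def _fixed_groups_from_design(results: MixedModelResults) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for j, tag in enumerate(results.design.x_groups):
        if tag is None and results.design.x_names[j] != "intercept":
            tag = "fixed_other"
        if tag is not None:
            groups.setdefault(tag, []).append(j)
    return groups


def partition_fixed(
    results: MixedModelResults,
    groups: dict[str, list[str]] | None = None,
) -> dict[str, np.ndarray]:
    """Per-draw semi-partial variance contributions of fixed-term groups.

    ``groups`` maps group name to design column names; by default the
    groups declared on the model's fixed terms are used. Contributions are
    rescaled per draw to sum to the full fixed-effect variance.
    """
    design = results.design
    if groups is None:
        idx_groups = _fixed_groups_from_design(results)
    else:
        idx_groups = {}
        for name, cols in groups.items():
            idx = [design.x_names.index(c) for c in cols]
            if not idx:
                raise ValueError(f"group {name!r} covers no design columns")
            idx_groups[name] = idx
    for name, idx in idx_groups.items():
        if not idx:
            raise ValueError(f"group {name!r} covers no design columns")

    beta = results.beta_flat()
    x = design.x
    full = (beta @ x.T).var(axis=1, ddof=1)
    raw = {}
    own = {}
    for name, idx in idx_groups.items():
        beta_red = beta.copy()
        beta_red[:, idx] = 0.0
        raw[name] = np.clip(full - (beta_red @ x.T).var(axis=1, ddof=1), 0.0, None)
        own[name] = (beta[:, idx] @ x[:, idx].T).var(axis=1, ddof=1)
    total_raw = np.sum(list(raw.values()), axis=0)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in raw:
            scaled = np.where(total_raw > 0, raw[name] * full / np.where(total_raw > 0, total_raw, 1.0), 0.0)
            out[name] = scaled
    # draws where every semi-partial vanished but V_fixed > 0: fall back to
    # each group's own predictor variance as weights
    dead = (total_raw <= 0) & (full > 0)
    if dead.any():
        own_total = np.sum(list(own.values()), axis=0)
        for name in out:
            w = np.where(own_total > 0, own[name] / np.where(own_total > 0, own_total, 1.0), 1.0 / len(out))
            out[name][dead] = (w * full)[dead]
    return out


def decompose(
    results: MixedModelResults,
    fixed_groups: dict[str, list[str]] | None = None,
) -> VarianceDecomposition:
    """Full variance decomposition of a fitted model.

    Components: one entry per fixed-term group (semi-partial split of the
    fitted-value variance), one per random term (its σ²) and the residual.
    Per draw the components sum to V_P exactly, so proportions sum to 1.
    """
    fixed_parts = (
        partition_fixed(results, fixed_groups)
        if (fixed_groups or _fixed_groups_from_design(results))
        else {}
    )
    components: dict[str, np.ndarray] = dict(fixed_parts)
    for name, arr in results.sigma2.items():
        if name == "residual":
            continue
        components[name] = arr.reshape(-1).copy()
    components["residual"] = results.sigma2_flat("residual").copy()
    total = np.sum(list(components.values()), axis=0)
    return VarianceDecomposition(components, total)


def repeatability(results: MixedModelResults, include_fixed: bool = True) -> dict:
    """Posterior repeatability V_I / (V_fixed + V_I + V_R).

    The among-individual variance divided by total phenotypic variance of
    the basic model. With ``include_fixed=False`` the fixed-effect
    (age) variance is dropped from the denominator; both variants are
    reported by the pipeline since the choice changes the denominator.
    """
    if "individual" not in results.sigma2:
        raise KeyError("model has no 'individual' random term")
    v_i = results.sigma2_flat("individual")
    v_r = results.sigma2_flat("residual")
    denom = v_i + v_r
    if include_fixed:
        denom = denom + results.fixed_linear_predictor().var(axis=1, ddof=1)
    draws = v_i / denom
    return {"draws": draws, **summarize_draws(draws)}


def nakagawa_r2(results: MixedModelResults) -> dict:
    """Marginal and conditional R² (variance-explained sense).

    marginal = V_fixed / V_P; conditional = (V_fixed + Σ V_random) / V_P,
    with V_P = V_fixed + Σ V_random + V_R, per draw.
    """
    v_fixed = results.fixed_linear_predictor().var(axis=1, ddof=1)
    v_random = np.zeros_like(v_fixed)
    for name, arr in results.sigma2.items():
        if name != "residual":
            v_random = v_random + arr.reshape(-1)
    v_p = v_fixed + v_random + results.sigma2_flat("residual")
    marginal = v_fixed / v_p
    conditional = (v_fixed + v_random) / v_p
    return {
        "marginal": summarize_draws(marginal),
        "conditional": summarize_draws(conditional),
        "marginal_draws": marginal,
        "conditional_draws": conditional,
    }
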