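"""Mother–offspring trophic-position analyses: social learning and its decay.

If offspring learn their dietary niche from their mother during rearing,
offspring trophic position should track maternal trophic position right
after family breakup and drift away as individual experience accumulates.
This module provides:

* windowed Pearson correlations between offspring and maternal trophic
  position over bands of years since separation (default bands 1–2, 3–4,
  5+, closed integer ranges);
* a sex-specificity test comparing mixed models {maternal TP × sex,
  maternal TP + sex, maternal TP} on the first two years after separation
  by PSIS-LOO, preferring the more complex model only when its elpd
  advantage exceeds 4;
* a paternal-effect analysis regressing offspring trophic position on the
  father's posterior trophic position.

The pair table has one row per offspring sample:
``offspring_id, offspring_tp, maternal_tp, paternal_tp (optional),
years_since_separation, sex``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    McmcSettings,
    MixedModel,
    ModelSpec,
    RandomTerm,
    categorical,
    compare_models,
    interaction,
    linear,
)
from .partition import nakagawa_r2

__all__ = [
    "CorrelationResult",
    "windowed_correlation",
    "correlation_by_window",
    "sex_model_comparison",
    "paternal_effect",
    "DEFAULT_WINDOWS",
]

#: closed integer year bands; None = unbounded above
DEFAULT_WINDOWS = ((1, 2), (3, 4), (5, None))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int


def _in_window(years: pd.Series, window) -> pd.Series:
    lo, hi = window
    mask = years >= lo
    if hi is not None:
        mask &= years <= hi
    return mask


def windowed_correlation(pairs: pd.DataFrame, window=(1, 2)) -> CorrelationResult:
    """Pearson correlation of offspring vs. maternal trophic position within
    a years-since-separation band (closed integer range; upper bound None
    means unbounded). Uses sample pairs as rows, so repeated measures of an
    offspring each count once; df = n − 2."""
    sub = pairs[_in_window(pairs["years_since_separation"], window)]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 pairs in window {window}, got {n}")
    x = sub["maternal_tp"].to_numpy(dtype=float)
    y = sub["offspring_tp"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in window")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), n - 2, float(p), n)


def correlation_by_window(
    pairs: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    individual_averaged: bool = False,
) -> pd.DataFrame:
    """Correlation table across year bands.

    ``individual_averaged`` first averages repeated samples per offspring
    within a window (sensitivity output; the headline numbers use raw
    sample pairs).
    """
    rows = []
    for window in windows:
        sub = pairs[_in_window(pairs["years_since_separation"], window)]
        if individual_averaged:
            sub = (
                sub.groupby("offspring_id", as_index=False)
                .agg(offspring_tp=("offspring_tp", "mean"),
                     maternal_tp=("maternal_tp", "first"),
                     years_since_separation=("years_since_separation", "min"))
            )
        try:
            res = windowed_correlation(
                sub.assign(years_since_separation=window[0]), (window[0], None)
            ) if individual_averaged else windowed_correlation(pairs, window)
        except ValueError:
            rows.append({"window": _wlabel(window), "r": np.nan, "df": np.nan,
                         "p": np.nan, "n": len(sub)})
            continue
        rows.append({"window": _wlabel(window), "r": res.r, "df": res.df,
                     "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def _wlabel(window) -> str:
    lo, hi = window
    return f"{lo}-{hi}" if hi is not None else f"{lo}+"


def _pair_model(pairs: pd.DataFrame, fixed, response="offspring_tp") -> MixedModel:
    data = pairs.rename(columns={"offspring_id": "bear_id"})
    spec = ModelSpec(response, tuple(fixed), (RandomTerm("individual", "bear_id"),))
    return MixedModel(data, spec)


def sex_model_comparison(
    pairs: pd.DataFrame,
    window=(1, 2),
    settings: McmcSettings = McmcSettings(),
) -> dict:
    """Is the social-learning effect sex-specific?

    Fits three mixed models to samples in the first years after separation
    (offspring TP ~ maternal TP [× / +] sex, individual random intercept)
    and compares them by PSIS-LOO. A model with more terms is chosen only
    when its elpd advantage over every simpler candidate exceeds 4;
    otherwise the simplest candidate wins. Also reports the marginal R² of
    the chosen model and the pooled Pearson correlation in the window.
    """
    sub = pairs[_in_window(pairs["years_since_separation"], window)].reset_index(drop=True)
    sexes = set(sub["sex"].unique())
    if not {"female", "male"} <= sexes:
        raise ValueError(f"both sexes required in window, found {sorted(sexes)}")
    sub = sub.assign(sex_male=(sub["sex"] == "male").astype(float))

    # complexity order: simplest first
    candidates = {
        "maternal_tp": [linear("maternal_tp", group="SL")],
        "maternal_tp+sex": [linear("maternal_tp", group="SL"), categorical("sex")],
        "maternal_tp*sex": [
            linear("maternal_tp", group="SL"),
            categorical("sex"),
            interaction("maternal_tp", "sex_male", group="SL"),
        ],
    }
    fits = {}
    for i, (name, fixed) in enumerate(candidates.items()):
        fits[name] = _pair_model(sub, fixed).fit(
            McmcSettings(**{**settings.__dict__, "seed": settings.seed + i})
        )
    cmp = compare_models(fits)
    elpd = {name: float(cmp.loc[name, "elpd_loo"]) for name in fits}
    chosen = "maternal_tp"
    for name in ["maternal_tp+sex", "maternal_tp*sex"]:
        if elpd[name] - elpd[chosen] > 4:
            chosen = name
    r2 = nakagawa_r2(fits[chosen])
    corr = windowed_correlation(sub, (window[0], None))
    return {
        "comparison": cmp,
        "elpd": elpd,
        "chosen": chosen,
        "marginal_r2": r2["marginal"],
        "pearson": corr,
        "fits": fits,
    }


def paternal_effect(
    pairs: pd.DataFrame,
    window=(1, 2),
    settings: McmcSettings = McmcSettings(),
) -> dict:
    """Effect of paternal posterior trophic position on offspring TP.

    Mixed model offspring TP ~ paternal TP + individual intercept in the
    window, compared against the intercept-only model by PSIS-LOO; the
    marginal R² of paternal TP and the Pearson correlation are reported.
    """
    sub = pairs[_in_window(pairs["years_since_separation"], window)]
    sub = sub.dropna(subset=["paternal_tp"]).reset_index(drop=True)
    if sub["offspring_id"].nunique() < 3:
        raise ValueError("need >= 3 offspring with known fathers")
    if sub["paternal_tp"].nunique() == 1:
        raise ValueError("all fathers have identical trophic position")
    fit = _pair_model(sub, [linear("paternal_tp", group="paternal")]).fit(settings)
    null = _pair_model(sub, []).fit(
        McmcSettings(**{**settings.__dict__, "seed": settings.seed + 1})
    )
    cmp = compare_models({"paternal": fit, "null": null})
    elpd_diff = float(cmp.loc["paternal", "elpd_loo"] - cmp.loc["null", "elpd_loo"])
    x = sub["paternal_tp"].to_numpy(dtype=float)
    y = sub["offspring_tp"].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    return {
        "marginal_r2": nakagawa_r2(fit)["marginal"],
        "pearson": CorrelationResult(float(r), len(sub) - 2, float(p), len(sub)),
        "elpd_diff_vs_null": elpd_diff,
        "preferred": "paternal" if elpd_diff > 4 else "null",
        "comparison": cmp,
    }
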