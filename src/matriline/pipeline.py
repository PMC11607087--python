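"""End-to-end study orchestration.

Ties the stages together the way the full analysis runs them:

1. convert δ15N to trophic position against the herbivore baseline;
2. fit the population-wide model (quadratic age + individual intercepts)
   per sex and extract each parent's posterior trophic position;
3. assemble the focal table of independent female offspring with maternal
   trophic position attached;
4. build the additive relationship matrix (pedigree pruned to phenotyped
   individuals and their ancestors) and the environmental or spatial
   similarity matrix;
5. fit the basic repeatability model and the hybrid animal model, then
   partition phenotypic variance and compute the windowed mother–offspring
   correlations.

`run_study` accepts either a :class:`~matriline.simulate.SimulatedDataset`
or the equivalent raw tables.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .isotopes import BaselineStats, add_trophic_position
from .model import (
    McmcSettings,
    MixedModel,
    animal_model_spec,
    basic_repeatability_spec,
    population_tp_spec,
)
from .partition import nakagawa_r2, repeatability
from .pedigree import Pedigree, additive_relationship_matrix
from .similarity import env_similarity_matrix, spatial_distance_matrix
from .social import correlation_by_window

__all__ = ["run_study", "attach_parental_tp", "focal_pair_table"]


def fit_population_model(samples: pd.DataFrame, sex: str,
                         settings: McmcSettings) -> pd.DataFrame:
    """Posterior trophic position per individual of one sex.

    Fits trophic position ~ quadratic(age) + (1 | individual) to all samples
    of that sex and returns the per-individual posterior medians
    (population intercept + random intercept).
    """
    sub = samples[samples["sex"] == sex].reset_index(drop=True)
    if sub.empty:
        return pd.DataFrame(columns=["id", "posterior_tp"])
    fit = MixedModel(sub, population_tp_spec()).fit(settings)
    return fit.random_effect_table("individual")


def attach_parental_tp(
    offspring: pd.DataFrame,
    maternal_table: pd.DataFrame,
    paternal_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    out = offspring.merge(
        maternal_table.rename(columns={"id": "mother_id", "posterior_tp": "maternal_tp"}),
        on="mother_id", how="left",
    )
    if paternal_table is not None:
        out = out.merge(
            paternal_table.rename(columns={"id": "father_id", "posterior_tp": "paternal_tp"}),
            on="father_id", how="left",
        )
    return out


def _observed_maternal_tp(focal: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Mother's measured trophic position nearest each offspring's rearing
    year (offspring sample year minus years since separation); NaN when the
    mother has no sample within two years of it."""
    by_mother: dict[str, pd.DataFrame] = {
        str(k): g for k, g in samples.groupby(samples["bear_id"].astype(str))
    }
    out = []
    for _, row in focal.iterrows():
        mother = str(row["mother_id"])
        rearing_year = row["year"] - row["years_since_separation"]
        g = by_mother.get(mother)
        if g is None or g.empty:
            out.append(float("nan"))
            continue
        gap = (g["year"] - rearing_year).abs()
        if gap.min() > 2:
            out.append(float("nan"))
        else:
            out.append(float(g.loc[gap.idxmin(), "trophic_position"]))
    return pd.Series(out, index=focal.index)


def focal_pair_table(focal: pd.DataFrame) -> pd.DataFrame:
    """Mother–offspring pair table for the social-learning analyses."""
    cols = {
        "bear_id": "offspring_id",
        "trophic_position": "offspring_tp",
    }
    keep = ["bear_id", "trophic_position", "maternal_tp",
            "years_since_separation", "sex"]
    if "paternal_tp" in focal.columns:
        keep.append("paternal_tp")
    return focal[keep].rename(columns=cols)


def run_study(
    dataset=None,
    *,
    samples: pd.DataFrame | None = None,
    baseline: BaselineStats | None = None,
    pedigree: Pedigree | None = None,
    home_ranges: pd.DataFrame | None = None,
    settings: McmcSettings = McmcSettings(),
    variant: str = "environment",          # "environment", "spatial", or "none"
    social_learning: bool = True,
    maternal: bool = True,
    use_modeled_maternal_tp: bool = True,
    maternal_tp_source: str | None = None,
    fit_males: bool = False,
    fit_basic: bool = True,
) -> dict:
    """Run the full variance-partitioning analysis; returns a result bundle.

    Reduced model variants: ``variant="none"`` drops the similarity term
    (collinearity check), ``social_learning=False`` drops the maternal-TP
    fixed effect, ``maternal=False`` drops the mother-identity term.

    ``maternal_tp_source`` selects the social-learning covariate:
    ``"modeled"`` (default) uses each mother's posterior trophic position
    from the population-wide model; ``"observed"`` uses the mother's own
    measured trophic position closest to the offspring's rearing year
    (a validation variant restricted to offspring whose mother was sampled);
    ``"true"`` uses the generator's latent value (simulated data only;
    equivalent to ``use_modeled_maternal_tp=False``).
    """
    if maternal_tp_source is None:
        maternal_tp_source = "modeled" if use_modeled_maternal_tp else "true"
    if dataset is not None:
        samples = dataset.all_samples
        baseline = dataset.baseline_stats()
        pedigree = dataset.pedigree
        home_ranges = dataset.home_ranges
    if samples is None or baseline is None or pedigree is None or home_ranges is None:
        raise ValueError("need samples, baseline, pedigree and home_ranges")

    samples = add_trophic_position(samples, baseline)

    pop_settings = replace(settings, seed=settings.seed + 11)
    if maternal_tp_source == "modeled":
        maternal_table = fit_population_model(samples, "female", pop_settings)
    else:
        maternal_table = pd.DataFrame(columns=["id", "posterior_tp"])
    paternal_table = (
        fit_population_model(samples, "male", replace(settings, seed=settings.seed + 12))
        if fit_males else None
    )

    # focal rows: independent female offspring with a known, sampled mother
    is_offspring = samples["mother_id"].fillna("").astype(str) != ""
    focal = samples[
        (samples["sex"] == "female")
        & is_offspring
        & samples["years_since_separation"].notna()
    ].reset_index(drop=True)
    focal = attach_parental_tp(focal, maternal_table, paternal_table)
    if maternal_tp_source == "true":
        if dataset is None:
            raise ValueError("true maternal TP requires a SimulatedDataset")
        latent = dataset.ledger["latent_tp"]
        focal["maternal_tp"] = focal["mother_id"].map(latent)
    elif maternal_tp_source == "observed":
        focal["maternal_tp"] = _observed_maternal_tp(focal, samples)
    elif maternal_tp_source != "modeled":
        raise ValueError(f"unknown maternal_tp_source {maternal_tp_source!r}")
    focal = focal.dropna(subset=["maternal_tp"]).reset_index(drop=True)

    focal_ids = focal["bear_id"].astype(str).unique().tolist()
    ped = pedigree.validate_and_sort().prune(focal_ids)
    a_matrix = additive_relationship_matrix(ped).subset(focal_ids)

    hr = home_ranges[home_ranges["bear_id"].astype(str).isin(focal_ids)]
    hr = hr.set_index("bear_id").loc[focal_ids].reset_index()
    env = None
    spatial_summary = None
    if variant == "environment":
        env = env_similarity_matrix(hr)
    elif variant == "spatial":
        _, env, spatial_summary = spatial_distance_matrix(hr)
    elif variant != "none":
        raise ValueError(f"unknown variant {variant!r}")

    basic = None
    if fit_basic:
        basic = MixedModel(focal, basic_repeatability_spec()).fit(
            replace(settings, seed=settings.seed + 21)
        )
    spec = animal_model_spec(
        a_matrix, env, social_learning=social_learning, maternal=maternal
    )
    animal = MixedModel(focal, spec).fit(replace(settings, seed=settings.seed + 22))
    decomposition = animal.variance_decomposition()

    return {
        "samples": samples,
        "focal": focal,
        "baseline": baseline,
        "maternal_table": maternal_table,
        "paternal_table": paternal_table,
        "a_matrix": a_matrix,
        "similarity": env,
        "spatial_summary": spatial_summary,
        "basic_fit": basic,
        "animal_fit": animal,
        "decomposition": decomposition,
        "repeatability": repeatability(basic) if basic is not None else None,
        "repeatability_no_age": (
            repeatability(basic, include_fixed=False) if basic is not None else None
        ),
        "nakagawa_r2": nakagawa_r2(animal),
        "correlations": correlation_by_window(focal_pair_table(focal)),
    }
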