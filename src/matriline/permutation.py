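"""Permutation test for additive genetic variance.

Pedigree-based heritability estimates at small sample sizes can assign
non-trivial posterior mass to σ²_A even when no genetic signal exists. The
permutation test calibrates this: a reduced "basic animal model"
(individual identity + pedigree-structured breeding values + residual,
no fixed effects beyond the intercept) is fitted to the observed data,
then refitted on many pedigrees whose dam–sire pairs were randomly
reassigned to sibships (see :func:`matriline.pedigree.permute_parentage`),
breaking the phenotype–pedigree link while keeping the pedigree
architecture. The p-value is the proportion of permuted fits whose
genetic explained-variance proportion meets or exceeds the observed one.

Permuted refits use shortened single-chain MCMC by default since only a
point summary (posterior mean proportion) is needed per fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import McmcSettings, MixedModel, ModelSpec, RandomTerm, REDUCED_MCMC
from .pedigree import Pedigree, additive_relationship_matrix, permute_parentage

__all__ = ["PermutationTestResult", "permutation_test", "genetic_variance_proportion"]


@dataclass
class PermutationTestResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float            # raw proportion (#permuted >= observed)/n_perm
    p_value_corrected: float  # (b+1)/(m+1) variant
    n_perm: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"permuted_genetic_proportion": self.null_distribution})


def _basic_animal_spec(a_matrix) -> ModelSpec:
    return ModelSpec(
        response="trophic_position",
        fixed=(),
        random=(
            RandomTerm("individual", "bear_id"),
            RandomTerm("genetic", "bear_id", cov=a_matrix),
        ),
    )


def genetic_variance_proportion(data: pd.DataFrame, a_matrix,
                                settings: McmcSettings) -> float:
    """Posterior mean of σ²_A / (σ²_I + σ²_A + σ²_R) under the reduced model."""
    results = MixedModel(data, _basic_animal_spec(a_matrix)).fit(settings)
    v_a = results.sigma2_flat("genetic")
    v_p = v_a + results.sigma2_flat("individual") + results.sigma2_flat("residual")
    return float(np.mean(v_a / v_p))


def permutation_test(
    data: pd.DataFrame,
    pedigree: Pedigree,
    n_perm: int = 1000,
    seed: int = 0,
    observed_settings: McmcSettings | None = None,
    permuted_settings: McmcSettings | None = None,
) -> PermutationTestResult:
    """Permutation p-value for the genetic variance proportion.

    Parameters
    ----------
    data : DataFrame
        Samples with ``bear_id`` and ``trophic_position`` columns.
    pedigree : Pedigree
        Validated pedigree covering every phenotyped individual.
    n_perm : int
        Number of parentage permutations (the full analysis uses 1000;
        smaller values support desk-scale runs).
    seed : int
        Drives both the MCMC and the pedigree permutations.

    Permuted fits that fail (non-finite summaries) are counted in
    ``n_failed`` and excluded from the proportion.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed_settings is None:
        observed_settings = McmcSettings(seed=seed)
    if permuted_settings is None:
        permuted_settings = McmcSettings(**{**REDUCED_MCMC.__dict__, "seed": seed})

    phenotyped = data["bear_id"].astype(str).unique().tolist()
    ped = pedigree.validate_and_sort().prune(phenotyped)
    a_full = additive_relationship_matrix(ped)
    observed = genetic_variance_proportion(
        data, a_full.subset(phenotyped), observed_settings
    )

    # permute parentage of phenotyped individuals that have recorded parents
    parents = ped.parents
    offspring = [i for i in phenotyped if parents.get(i, ("", ""))[0] != ""
                 or parents.get(i, ("", ""))[1] != ""]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    null = []
    n_failed = 0
    for b in range(n_perm):
        perm_ped = permute_parentage(ped, offspring, rng)
        a_perm = additive_relationship_matrix(perm_ped).subset(phenotyped)
        fit_settings = McmcSettings(
            **{**permuted_settings.__dict__, "seed": int(rng.integers(2**31 - 1))}
        )
        try:
            stat = genetic_variance_proportion(data, a_perm, fit_settings)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not np.isfinite(stat):
            n_failed += 1
            continue
        null.append(stat)
    null = np.asarray(null)
    m = null.size
    if m == 0:
        raise RuntimeError("all permuted fits failed")
    b_ge = int(np.sum(null >= observed))
    return PermutationTestResult(
        observed=observed,
        null_distribution=null,
        p_value=b_ge / m,
        p_value_corrected=(b_ge + 1) / (m + 1),
        n_perm=m,
        n_failed=n_failed,
    )
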