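import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import matriline as ml

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


#: short MCMC settings that still satisfy the convergence gate on easy models
FAST = ml.McmcSettings(chains=4, iterations=800, warmup=400, thin=1, seed=0)
#: moderate settings for the structured animal model
MEDIUM = ml.McmcSettings(chains=4, iterations=1500, warmup=700, thin=2, seed=0)


@pytest.fixture(scope="session")
def small_dataset() -> ml.SimulatedDataset:
    """Study-scale synthetic study (33 mothers, ~70 daughters, ~220 samples)."""
    return ml.simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def tiny_dataset() -> ml.SimulatedDataset:
    """Small, fast study for CLI/pipeline plumbing tests."""
    return ml.simulate_dataset(seed=5, n_mothers=10, n_sires=6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trio_pedigree() -> ml.Pedigree:
    """Two founders and two full-sib offspring."""
    return ml.Pedigree(
        [("dam", "", ""), ("sire", "", ""), ("kid1", "dam", "sire"),
         ("kid2", "dam", "sire")]
    ).validate_and_sort()


def random_pedigree(seed: int, n_founders: int = 10, n_gen: int = 2,
                    per_gen: int = 10) -> ml.Pedigree:
    """Random multi-generation pedigree (parents always from earlier cohorts)."""
    rng = np.random.default_rng(seed)
    records = [(f"f{i}", "", "") for i in range(n_founders)]
    pool = [r[0] for r in records]
    k = 0
    for _ in range(n_gen):
        new = []
        for _ in range(per_gen):
            dam, sire = rng.choice(len(pool), size=2, replace=False)
            k += 1
            records.append((f"x{k}", pool[dam], pool[sire]))
            new.append(f"x{k}")
        pool = pool + new
    return ml.Pedigree(records).validate_and_sort()


def gene_dropping_relatedness(ped: ml.Pedigree, n_rep: int, seed: int) -> np.ndarray:
    """Monte-Carlo additive relatedness: 2 × P(random alleles are IBD).

    Independent of the tabular method: founders get unique allele labels,
    alleles drop through the pedigree, and kinship between i and j is the
    average probability that one allele sampled from each is identical by
    descent.
    """
    rng = np.random.default_rng(seed)
    ids = ped.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    next_label = 0
    for i, dam, sire in ped.records:
        j = idx[i]
        for slot, parent in enumerate((dam, sire)):
            if parent == "":
                alleles[j, slot] = next_label
                next_label += 1
            else:
                pj = idx[parent]
                pick = rng.integers(0, 2, n_rep)
                alleles[j, slot] = alleles[pj, 0] * (pick == 0) + alleles[pj, 1] * (pick == 1)
    rel = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            share = np.zeros(n_rep)
            for s in range(2):
                for t in range(2):
                    share += alleles[a, s] == alleles[b, t]
            rel[a, b] = rel[b, a] = 0.5 * share.mean()
    return rel


def fabricate_results(df: pd.DataFrame, spec: ml.ModelSpec, *, beta, sigma2,
                      u=None, mu=None) -> ml.MixedModelResults:
    """Results object with hand-chosen draws, for closed-form checks.

    ``beta``: (chains, draws, p); ``sigma2``: dict name -> (chains, draws);
    ``u``: dict name -> (chains, draws, q); ``mu`` defaults to the
    fixed-effect predictor.
    """
    model = ml.MixedModel(df, spec)
    beta = np.asarray(beta, dtype=float)
    if mu is None:
        c, d, p = beta.shape
        mu = (beta.reshape(-1, p) @ model.design.x.T).reshape(c, d, -1)
    if u is None:
        u = {
            r.name: np.zeros((*beta.shape[:2], len(r.levels)))
            for r in model.design.random
        }
    settings = ml.McmcSettings(
        chains=beta.shape[0], iterations=2 * beta.shape[1],
        warmup=beta.shape[1], thin=1, seed=0,
    )
    return ml.MixedModelResults(
        model=model, settings=settings, beta=beta,
        sigma2={k: np.asarray(v, dtype=float) for k, v in sigma2.items()},
        u=u, mu=np.asarray(mu, dtype=float),
    )


@pytest.fixture(scope="session")
def focal_fit(small_dataset):
    """A converged animal-model fit of the study-scale synthetic study."""
    return ml.run_study(small_dataset, settings=MEDIUM)
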