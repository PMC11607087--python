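"""Environmental and spatial similarity matrices for home ranges.

Range-resident bears occupy home ranges differing in habitat composition;
environmental similarity between two individuals is summarised by the
Euclidean distance between their z-scored habitat features (proportion of
mature forest, proportion of disturbed forest, Simpson habitat diversity),
each feature weighted equally. Distances are mapped to similarities on
[0, 1] by ``1 − d/max(d)`` so identical ranges get similarity 1, and the
matrix is projected to the nearest positive semi-definite matrix with unit
diagonal so it can serve as a random-effect covariance.

A structurally parallel matrix is built from pairwise Euclidean distances
between home-range centroids (the spatial variant), so the model can swap
habitat similarity for plain spatial proximity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityMatrix",
    "simpson_diversity",
    "env_similarity_matrix",
    "spatial_distance_matrix",
    "nearest_psd",
    "read_home_ranges",
]

FEATURE_COLUMNS = ["prop_mature", "prop_disturbed", "simpson_diversity"]
HOME_RANGE_COLUMNS = ["bear_id", "centroid_x_km", "centroid_y_km"] + FEATURE_COLUMNS


@dataclass
class SimilarityMatrix:
    """Symmetric individual-by-individual similarity on [0, 1], unit diagonal."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "environment" or "spatial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("similarity matrix shape does not match ids")

    def subset(self, ids) -> "SimilarityMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return SimilarityMatrix(
            [str(i) for i in ids], self.values[np.ix_(idx, idx)], self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def simpson_diversity(proportions) -> float:
    """Simpson diversity 1 − Σ p_i² of habitat class fractions summing to 1."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1 (got {p.sum():.8f})")
    return float(1.0 - np.sum(p**2))


def read_home_ranges(path: str | Path) -> pd.DataFrame:
    """Read a home-range feature CSV (columns documented in the README)."""
    df = pd.read_csv(path, dtype={"bear_id": str})
    missing = [c for c in HOME_RANGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"home-range table missing columns: {missing}")
    if df["bear_id"].duplicated().any():
        raise ValueError("duplicate bear_id in home-range table")
    bad = df["prop_mature"] + df["prop_disturbed"] > 1 + 1e-9
    if bad.any():
        raise ValueError(
            f"prop_mature + prop_disturbed > 1 in rows {df.index[bad].tolist()}"
        )
    return df


def nearest_psd(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to PSD with unit diagonal.

    Eigenvalues are clipped at ``eig_floor``, the matrix reconstructed, and
    rows/columns rescaled to restore a unit diagonal. A matrix that is
    already PSD is returned unchanged (up to 1e−12).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(m)
    if w.min() >= eig_floor:
        return m
    w = np.clip(w, eig_floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    return (out + out.T) / 2


def _distance_to_similarity(dist: np.ndarray) -> np.ndarray:
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("all pairwise distances are zero")
    sim = 1.0 - dist / dmax
    np.fill_diagonal(sim, 1.0)
    return nearest_psd(sim)


def env_similarity_matrix(features: pd.DataFrame) -> SimilarityMatrix:
    """Environmental similarity (E matrix) from habitat features.

    Each of the three features is centred and scaled to unit variance
    (so the result is invariant to affine rescaling of any input feature),
    pairwise Euclidean distances are taken in that 3-D space, and distances
    are linearly mapped to similarities.
    """
    if len(features) < 2:
        raise ValueError("need >= 2 individuals")
    x = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    for name, s, col in zip(FEATURE_COLUMNS, sd, x.T):
        if s <= 1e-10 * max(1.0, float(np.abs(col).max())):
            raise ValueError(f"feature {name!r} has zero variance")
    z = (x - x.mean(axis=0)) / sd
    dist = squareform(pdist(z))
    return SimilarityMatrix(
        features["bear_id"].astype(str).tolist(),
        _distance_to_similarity(dist),
        "environment",
    )


def spatial_distance_matrix(
    features: pd.DataFrame,
) -> tuple[np.ndarray, SimilarityMatrix, dict]:
    """Pairwise centroid distances (km) and the derived spatial S matrix.

    Returns the raw distance matrix, the similarity matrix obtained through
    the same ``1 − d/max(d)`` transform used for habitat similarity, and a
    summary dict with min/median/max of the pairwise distances.
    """
    if len(features) < 2:
        raise ValueError("need >= 2 individuals")
    ids = features["bear_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bear_id")
    xy = features[["centroid_x_km", "centroid_y_km"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("centroids must be finite")
    condensed = pdist(xy)
    dist = squareform(condensed)
    summary = {
        "min_km": float(condensed.min()),
        "median_km": float(np.median(condensed)),
        "max_km": float(condensed.max()),
        "n_pairs": int(condensed.size),
    }
    sim = SimilarityMatrix(ids, _distance_to_similarity(dist), "spatial")
    return dist, sim, summary
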