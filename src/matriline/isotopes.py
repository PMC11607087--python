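"""Stable-isotope trophic position estimation.

Converts hair keratin δ15N measurements (per mil vs. AIR) into dimensionless
trophic positions relative to a strict-herbivore baseline consumer (moose
hair in the source population). A consumer one trophic enrichment factor
(TEF) above the baseline sits exactly one trophic level higher:

    TP = (δ15N_consumer − mean(δ15N_baseline)) / TEF + λ

with λ the trophic position of the baseline (2 for a primary consumer).
The TEF default of 3.4 ‰ per trophic level is the canonical cross-taxon
average for nitrogen.

Trophic position is affine in δ15N, so any constant offset between tissue
types (e.g. hair vs. meat of the baseline species) shifts all TP values
equally without changing their distribution; no tissue correction is
applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BaselineStats",
    "TrophicConfig",
    "baseline_summary",
    "trophic_position",
    "read_isotope_table",
    "read_baseline_table",
    "add_trophic_position",
]

#: mandatory columns of an isotope sample table
SAMPLE_COLUMNS = [
    "bear_id",
    "year",
    "d15n",
    "age",
    "years_since_separation",
    "mother_id",
    "father_id",
    "sex",
]


@dataclass(frozen=True)
class BaselineStats:
    """Summary of the baseline consumer's δ15N distribution.

    ``sd_d15n`` is the sample standard deviation (n−1 denominator); it is
    NaN when only a single baseline sample is available.
    """

    mean_d15n: float
    sd_d15n: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("baseline requires n >= 1")
        if not math.isfinite(self.mean_d15n):
            raise ValueError("baseline mean must be finite")
        if math.isfinite(self.sd_d15n) and self.sd_d15n < 0:
            raise ValueError("baseline sd must be >= 0")


@dataclass(frozen=True)
class TrophicConfig:
    """Trophic position calculation constants.

    Parameters
    ----------
    tef : float
        Trophic enrichment factor, ‰ δ15N per trophic level (default 3.4).
    baseline_trophic_level : float
        λ, the trophic position assigned to the baseline consumer
        (default 2, a strict herbivore).
    """

    tef: float = 3.4
    baseline_trophic_level: float = 2.0

    def __post_init__(self) -> None:
        if not (self.tef > 0):
            raise ValueError("tef must be > 0")
        if self.baseline_trophic_level < 1:
            raise ValueError("baseline trophic level must be >= 1")


def baseline_summary(samples: Sequence[float]) -> BaselineStats:
    """Arithmetic mean and sample standard deviation of baseline δ15N values."""
    values = np.asarray(list(samples), dtype=float)
    if values.size == 0:
        raise ValueError("no baseline samples")
    if not np.all(np.isfinite(values)):
        raise ValueError("baseline samples must be finite")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return BaselineStats(float(np.mean(values)), sd, int(values.size))


def trophic_position(d15n, baseline: BaselineStats, config: TrophicConfig = TrophicConfig()):
    """Trophic position of a consumer δ15N value (scalar or array)."""
    d15n = np.asarray(d15n, dtype=float)
    if not np.all(np.isfinite(d15n)):
        raise ValueError("d15n must be finite")
    tp = (d15n - baseline.mean_d15n) / config.tef + config.baseline_trophic_level
    return float(tp) if tp.ndim == 0 else tp


class TableValidationError(ValueError):
    """Raised when an input table violates its invariants; carries row context."""


def _validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing mandatory columns: {missing}")
    problems: list[str] = []
    if not np.all(np.isfinite(df["d15n"].to_numpy(dtype=float))):
        bad = df.index[~np.isfinite(df["d15n"].to_numpy(dtype=float))].tolist()
        problems.append(f"non-finite d15n in rows {bad}")
    dup = df.duplicated(subset=["bear_id", "year"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        problems.append(f"duplicate (bear_id, year) in rows {rows}")
    both = df["age"].notna() & df["years_since_separation"].notna()
    viol = both & (df["age"] < df["years_since_separation"])
    if viol.any():
        problems.append(
            f"age < years_since_separation in rows {df.index[viol].tolist()}"
        )
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        problems.append(f"sex not in {{female, male}} in rows {df.index[bad_sex].tolist()}")
    if problems:
        raise TableValidationError("; ".join(problems))
    return df


def read_isotope_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an isotope sample CSV.

    Expected comma-delimited UTF-8 columns: ``bear_id, year, d15n, age,
    years_since_separation, mother_id, father_id, sex``. Empty ``father_id``
    means unknown sire; empty ``years_since_separation`` marks a dependent
    offspring still with its mother. Row numbers in error messages refer to
    the CSV data rows (0-based, header excluded).
    """
    df = pd.read_csv(path, dtype={"bear_id": str, "mother_id": str, "father_id": str})
    return _validate_samples(df)


def read_baseline_table(path: str | Path) -> BaselineStats:
    """Read a baseline consumer CSV with a ``d15n`` column and summarize it."""
    df = pd.read_csv(path)
    if "d15n" not in df.columns:
        raise TableValidationError("baseline table needs a 'd15n' column")
    return baseline_summary(df["d15n"].tolist())


def add_trophic_position(
    df: pd.DataFrame,
    baseline: BaselineStats,
    config: TrophicConfig = TrophicConfig(),
) -> pd.DataFrame:
    """Return a copy of the sample table with a ``trophic_position`` column.

    Downstream modelling consumes only this column, never raw δ15N.
    """
    out = df.copy()
    out["trophic_position"] = trophic_position(out["d15n"].to_numpy(), baseline, config)
    return out
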