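"""Post-processing chain for aligned VOC feature tables.

Order of the default pipeline: blank/early-elution filter -> probabilistic
quotient normalization (PQN) -> 50% presence filter -> cortisol outlier
removal -> log10 transform, imputation, centering and scaling.  Sample-level
dilution correction runs before feature pruning; standardization is computed
once on the final analysis set and its parameters are stored so a frozen
model can be applied to new samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cortivoc.cohort import FeatureTable


@dataclass
class ProcessedMatrix:
    """Standardized analysis matrix plus the frozen transform parameters.

    ``z`` holds log10-transformed, centered and scaled abundances (samples x
    retained features; every column has mean 0, sd 1 with the n-1 sample sd).
    ``pqn_factor`` is the per-sample dilution quotient, ``feature_mean`` /
    ``feature_sd`` the per-feature standardization parameters on the log10
    scale, ``retained`` the surviving original feature names and
    ``dropped_samples`` the sample ids removed as cortisol outliers.
    """

    z: pd.DataFrame
    pqn_factor: pd.Series
    feature_mean: pd.Series
    feature_sd: pd.Series
    retained: list[str]
    dropped_samples: list[str] = field(default_factory=list)

    def save_params(self, path: str | Path) -> None:
        payload = {
            "pqn_factor": self.pqn_factor.to_dict(),
            "feature_mean": self.feature_mean.to_dict(),
            "feature_sd": self.feature_sd.to_dict(),
            "retained": self.retained,
            "dropped_samples": self.dropped_samples,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def pqn_normalize(table: FeatureTable) -> tuple[FeatureTable, pd.Series]:
    """Probabilistic quotient normalization (median-spectrum reference).

    The reference spectrum is the per-feature median over samples where the
    feature is observed; each sample's quotient is the median over its
    observed features of abundance/reference, and every observed abundance is
    divided by that quotient.  Missing entries stay missing.
    """
    x = table.abundance
    if x.shape[0] < 2:
        raise ValueError("PQN needs at least 2 samples")
    if table.mask.all(axis=1).any():
        bad = table.mask.all(axis=1).idxmax()
        raise ValueError(f"sample {bad!r} has no observed features")
    reference = x.median(axis=0, skipna=True)
    usable = reference > 0
    ratios = x.loc[:, usable] / reference[usable]
    quotient = ratios.median(axis=1, skipna=True)
    if quotient.isna().any():
        bad = quotient.index[quotient.isna()][0]
        raise ValueError(
            f"sample {bad!r}: all observed features have zero reference abundance"
        )
    normalized = x.div(quotient, axis=0)
    quotient = quotient.rename("pqn_factor")
    return FeatureTable(normalized, table.feature_meta.copy()), quotient


def presence_filter(table: FeatureTable, min_fraction: float = 0.5) -> FeatureTable:
    """Keep features observed in at least ``min_fraction`` of samples (>=)."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    observed = table.abundance.notna().sum(axis=0)
    threshold = min_fraction * table.n_samples
    keep = observed[observed >= threshold - 1e-9].index.tolist()
    return table.select_features(keep)


def blank_and_early_filter(table: FeatureTable, min_rt1_s: float = 358.0) -> FeatureTable:
    """Drop blank-associated features and peaks eluting before ``min_rt1_s``."""
    fm = table.feature_meta
    keep = fm.index[(fm["rt1_s"] >= min_rt1_s) & (~fm["blank_flag"].astype(bool))]
    return table.select_features(list(keep))


def outlier_filter(
    meta: pd.DataFrame,
    max_ug: float = 45.0,
    min_ug: float = 0.0,
    exclude: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sample metadata into (kept, dropped) by the cortisol range rule.

    Samples with ``cortisol_ug`` above ``max_ug`` (the adult 24-h reference
    ceiling) or at/below ``min_ug`` are dropped.  ``exclude`` is an explicit
    sample-id drop list for exclusions the range rule alone does not capture.
    """
    if meta["cortisol_ug"].isna().any():
        raise ValueError("cortisol_ug missing for some samples")
    out = (
        (meta["cortisol_ug"] > max_ug)
        | (meta["cortisol_ug"] < min_ug)
        | meta["sample_id"].isin(set(exclude))
    )
    return meta.loc[~out].copy(), meta.loc[out].copy()


_IMPUTE_STRATEGIES = ("half_min", "min", "value")


def log_standardize(
    table: FeatureTable,
    impute: str = "half_min",
    impute_value: float | None = None,
    pqn_factor: pd.Series | None = None,
    dropped_samples: Sequence[str] = (),
) -> ProcessedMatrix:
    """Impute missing entries, log10 transform, center and scale.

    Default imputation replaces a feature's missing entries with half its
    minimum observed value (left-censoring assumption); ``min`` uses the
    minimum itself and ``value`` a fixed ``impute_value``.  Scaling uses the
    n-1 sample standard deviation; a zero-variance feature is rejected by
    name.
    """
    if impute not in _IMPUTE_STRATEGIES:
        raise ValueError(f"unknown imputation strategy {impute!r}; use one of {_IMPUTE_STRATEGIES}")
    x = table.abundance.copy()
    if x.isna().any().any():
        if impute == "value":
            if impute_value is None or impute_value <= 0:
                raise ValueError("impute='value' requires a positive impute_value")
            fill = pd.Series(impute_value, index=x.columns)
        else:
            fill = x.min(axis=0, skipna=True)
            if impute == "half_min":
                fill = fill / 2.0
            if fill.isna().any():
                bad = fill.index[fill.isna()][0]
                raise ValueError(f"feature {bad!r} has no observed values to impute from")
        x = x.fillna(fill)
    if (x <= 0).any().any():
        bad = x.columns[(x <= 0).any(axis=0)][0]
        raise ValueError(f"feature {bad!r} has non-positive abundances; cannot log-transform")
    logged = np.log10(x)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = sd.index[(sd <= 0) | sd.isna()][0]
        raise ValueError(f"feature {bad!r} has zero variance after log transform")
    z = (logged - mean) / sd
    if pqn_factor is None:
        pqn_factor = pd.Series(1.0, index=x.index, name="pqn_factor")
    return ProcessedMatrix(
        z=z,
        pqn_factor=pqn_factor.loc[x.index],
        feature_mean=mean,
        feature_sd=sd,
        retained=list(x.columns),
        dropped_samples=list(dropped_samples),
    )


def apply_standardization(
    table: FeatureTable, params: ProcessedMatrix, impute: str = "half_min"
) -> pd.DataFrame:
    """Standardize new samples with frozen per-feature mean/sd parameters."""
    sub = table.select_features(params.retained)
    x = sub.abundance.copy()
    fill = x.min(axis=0, skipna=True)
    if impute == "half_min":
        fill = fill / 2.0
    x = x.fillna(fill)
    return (np.log10(x) - params.feature_mean) / params.feature_sd


def preprocess_pipeline(
    table: FeatureTable,
    meta: pd.DataFrame,
    min_fraction: float = 0.5,
    min_rt1_s: float = 358.0,
    max_ug: float = 45.0,
    exclude: Sequence[str] = (),
    impute: str = "half_min",
    impute_value: float | None = None,
) -> tuple[ProcessedMatrix, pd.DataFrame]:
    """Run the full default chain; returns the matrix and the kept metadata."""
    table = blank_and_early_filter(table, min_rt1_s=min_rt1_s)
    table, quotient = pqn_normalize(table)
    table = presence_filter(table, min_fraction=min_fraction)
    kept, dropped = outlier_filter(meta, max_ug=max_ug, exclude=exclude)
    table = FeatureTable(
        table.abundance.loc[kept["sample_id"]], table.feature_meta.copy()
    )
    processed = log_standardize(
        table,
        impute=impute,
        impute_value=impute_value,
        pqn_factor=quotient,
        dropped_samples=list(dropped["sample_id"]),
    )
    return processed, kept
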