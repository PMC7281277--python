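"""Synthetic urinary-VOC cohort generator.

Emulates the structure of a diurnal cortisol study: 60 subjects (30 male,
30 female) each contributing one urine sample at three timepoints
(morning, afternoon, evening), profiled on an aligned GCxGC-TOFMS feature
table of ~512 retained volatile compounds.  A small planted subset of
features carries a sparse log-linear relation to log10 total free urinary
cortisol, with sex and time-of-day interaction effects, left-censored
missingness (detection limit) and occasional out-of-range cortisol values.

The generator simulates in the causal direction cortisol = f(VOCs) + error
so that downstream regression has a well-specified target and support
recovery is a meaningful test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("morning", "afternoon", "evening")
#: dummy factor labels; reference cell is female evening (all dummies zero)
DUMMY_LEVELS = ("Male", "Morning", "Afternoon")

META_COLUMNS = ["sample_id", "subject_id", "sex", "timepoint", "cortisol_ug", "run_order"]
FEATURE_META_COLUMNS = ["feature", "rt1_s", "rt2_s", "spectral_match", "blank_flag"]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and effect-size parameters of a synthetic cohort.

    Defaults mirror the emulated study: 60 subjects split evenly by sex,
    three collection timepoints, 512 retained VOC features of which 14 are
    informative, coefficient magnitudes around 0.1 (log10 µg per SD of log10
    abundance), a declining diurnal mean profile, left-censored missingness
    and two out-of-range cortisol samples per 180.
    """

    n_subjects: int = 60
    male_fraction: float = 0.5
    timepoints: Sequence[str] = TIMEPOINTS
    n_features: int = 512
    n_informative: int = 14
    n_sex_interactions: int = 3
    n_time_interactions: int = 4
    effect_scale: float = 0.1
    effect_spread: float = 0.5  # magnitudes drawn U(1-spread, 1+spread) * effect_scale
    noise_sd: float = 0.2
    diurnal_means: Sequence[float] = (0.9, 0.6, 0.3)
    subject_sd: float = 0.1
    missing_rate: float = 0.2
    outlier_rate: float = 2.0 / 180.0
    outlier_ceiling_ug: float = 45.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError(f"male_fraction must lie in [0, 1], got {self.male_fraction}")
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_features ({self.n_features})"
            )
        if self.n_sex_interactions > self.n_informative:
            raise ValueError(
                f"n_sex_interactions ({self.n_sex_interactions}) exceeds "
                f"n_informative ({self.n_informative})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError(f"outlier_rate must lie in [0, 1), got {self.outlier_rate}")
        if len(self.diurnal_means) != len(self.timepoints):
            raise ValueError("diurnal_means must supply one mean per timepoint")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted generative model of a synthetic cohort, for recovery tests."""

    support: list[str]
    beta: dict[str, float]
    interactions: dict[tuple[str, str], float]
    diurnal_means: dict[str, float]
    intercept: float
    noise_sd: float
    subject_sd: float
    subject_effects: dict[str, float]
    outlier_samples: list[str]
    seed: int

    def to_json(self) -> str:
        payload = {
            "support": self.support,
            "beta": self.beta,
            "interactions": [
                {"feature": f, "factor": d, "coef": c}
                for (f, d), c in self.interactions.items()
            ],
            "diurnal_means": self.diurnal_means,
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "subject_sd": self.subject_sd,
            "subject_effects": self.subject_effects,
            "outlier_samples": self.outlier_samples,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            support=list(d["support"]),
            beta={k: float(v) for k, v in d["beta"].items()},
            interactions={
                (e["feature"], e["factor"]): float(e["coef"]) for e in d["interactions"]
            },
            diurnal_means={k: float(v) for k, v in d["diurnal_means"].items()},
            intercept=float(d["intercept"]),
            noise_sd=float(d["noise_sd"]),
            subject_sd=float(d["subject_sd"]),
            subject_effects={k: float(v) for k, v in d["subject_effects"].items()},
            outlier_samples=list(d["outlier_samples"]),
            seed=int(d["seed"]),
        )


class FeatureTable:
    """Samples x features abundance matrix with an explicit missingness mask.

    ``abundance`` is a float DataFrame (rows: sample ids, columns: feature
    names) where NaN marks a missing (censored) entry; ``feature_meta`` is a
    per-feature DataFrame indexed by feature name with columns ``rt1_s``,
    ``rt2_s``, ``spectral_match`` and ``blank_flag``.
    """

    def __init__(self, abundance: pd.DataFrame, feature_meta: pd.DataFrame):
        abundance = abundance.astype(float)
        if list(abundance.columns) != list(feature_meta.index):
            feature_meta = feature_meta.reindex(abundance.columns)
            if feature_meta.isna().any().any():
                raise ValueError("feature_meta does not cover every abundance column")
        observed = abundance.to_numpy()
        finite_ok = np.isfinite(observed) | np.isnan(observed)
        if not finite_ok.all():
            raise ValueError("abundance contains non-finite observed values")
        if (observed[~np.isnan(observed)] < 0).any():
            raise ValueError("abundance must be non-negative where observed")
        if (feature_meta["rt1_s"] <= 0).any():
            raise ValueError("rt1_s must be positive for every feature")
        self.abundance = abundance
        self.feature_meta = feature_meta

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the entry is missing."""
        return self.abundance.isna()

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def select_features(self, features: Sequence[str]) -> "FeatureTable":
        features = list(features)
        return FeatureTable(self.abundance[features], self.feature_meta.loc[features])

    def equals(self, other: "FeatureTable") -> bool:
        return self.abundance.equals(other.abundance) and self.feature_meta.equals(
            other.feature_meta
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.n_samples} samples x {self.n_features} features)"


def _draw_signed_effects(
    rng: np.random.Generator, n: int, scale: float, spread: float = 0.5
) -> np.ndarray:
    """Coefficients with magnitude U(1-spread, 1+spread)*scale, balanced signs."""
    mag = rng.uniform(1.0 - spread, 1.0 + spread, size=n) * scale
    signs = np.ones(n)
    signs[: n // 2] = -1.0
    rng.shuffle(signs)
    return mag * signs


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, FeatureTable, GroundTruth]:
    """Generate one synthetic cohort.

    Returns ``(meta, table, truth)`` where ``meta`` is the sample metadata
    DataFrame (columns :data:`META_COLUMNS`, indexed by ``sample_id``),
    ``table`` the abundance :class:`FeatureTable` and ``truth`` the planted
    :class:`GroundTruth`.  Fully deterministic given ``config.seed``; all
    randomness flows from one spawned ``numpy`` seed sequence.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_design, rng_feat, rng_model, rng_noise, rng_miss, rng_out = (
        np.random.default_rng(s) for s in streams
    )

    n_male = int(round(config.male_fraction * config.n_subjects))
    subjects = [f"M{i + 1:02d}" for i in range(n_male)] + [
        f"F{i + 1:02d}" for i in range(config.n_subjects - n_male)
    ]
    sexes = ["male"] * n_male + ["female"] * (config.n_subjects - n_male)

    timepoints = list(config.timepoints)
    rows = []
    for subj, sex in zip(subjects, sexes):
        for tp in timepoints:
            rows.append((f"{subj}_{tp}", subj, sex, tp))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "sex", "timepoint"])
    n_samples = len(meta)
    meta["run_order"] = rng_design.permutation(n_samples) + 1

    # latent log10 abundances: per-feature location/spread, lognormal peaks
    features = [f"V{j + 1:04d}" for j in range(config.n_features)]
    mu = rng_feat.uniform(4.5, 6.5, size=config.n_features)
    sigma = rng_feat.uniform(0.2, 0.5, size=config.n_features)
    latent = mu + sigma * rng_feat.standard_normal((n_samples, config.n_features))
    # standardized latent abundances enter the planted linear model
    z = (latent - latent.mean(axis=0)) / latent.std(axis=0, ddof=1)

    support_idx = np.sort(
        rng_model.choice(config.n_features, size=config.n_informative, replace=False)
    )
    support = [features[j] for j in support_idx]
    beta_vals = _draw_signed_effects(
        rng_model, config.n_informative, config.effect_scale, config.effect_spread
    )
    beta = dict(zip(support, beta_vals))

    # interactions attach to planted features only (hierarchical truth)
    interactions: dict[tuple[str, str], float] = {}
    sex_feats = rng_model.choice(support, size=config.n_sex_interactions, replace=False)
    inter_scale = 1.5 * config.effect_scale
    for f, c in zip(
        sex_feats,
        _draw_signed_effects(rng_model, config.n_sex_interactions, inter_scale, config.effect_spread),
    ):
        interactions[(str(f), "Male")] = float(c)
    time_dummies = rng_model.choice(["Morning", "Afternoon"], size=config.n_time_interactions)
    time_feats = rng_model.choice(support, size=config.n_time_interactions, replace=True)
    time_coefs = _draw_signed_effects(
        rng_model, config.n_time_interactions, inter_scale, config.effect_spread
    )
    for f, d, c in zip(time_feats, time_dummies, time_coefs):
        interactions[(str(f), str(d))] = float(c)

    diurnal = dict(zip(timepoints, (float(v) for v in config.diurnal_means)))
    subj_eff = dict(
        zip(subjects, config.subject_sd * rng_model.standard_normal(config.n_subjects))
    )

    male = (meta["sex"] == "male").to_numpy(dtype=float)
    dummies = {
        "Male": male,
        "Morning": (meta["timepoint"] == timepoints[0]).to_numpy(dtype=float),
        "Afternoon": (meta["timepoint"] == timepoints[1]).to_numpy(dtype=float)
        if len(timepoints) > 1
        else np.zeros(n_samples),
    }

    col = {f: j for j, f in enumerate(features)}
    y = np.array([diurnal[tp] for tp in meta["timepoint"]])
    y += np.array([subj_eff[s] for s in meta["subject_id"]])
    for f, b in beta.items():
        y += b * z[:, col[f]]
    for (f, d), c in interactions.items():
        y += c * z[:, col[f]] * dummies[d]
    y += config.noise_sd * rng_noise.standard_normal(n_samples)
    cortisol = 10.0 ** y

    n_out = int(round(config.outlier_rate * n_samples))
    out_idx = rng_out.choice(n_samples, size=n_out, replace=False) if n_out else np.array([], int)
    ceiling = config.outlier_ceiling_ug
    if n_out:
        # planted outliers are the exact out-of-range set: any non-injected
        # sample whose noisy draw strays above the physiologic ceiling is
        # truncated to it, so the truth labels match the range filter
        high = cortisol > ceiling
        high[out_idx] = False
        cortisol[high] = ceiling
    cortisol[out_idx] = rng_out.uniform(ceiling + 5.0, ceiling + 75.0, size=n_out)
    meta["cortisol_ug"] = cortisol
    meta = meta[META_COLUMNS]
    outlier_samples = sorted(meta["sample_id"].iloc[out_idx])

    abundance = 10.0 ** latent
    if config.missing_rate > 0:
        # left-censoring: per feature, the lowest entries fall below detection.
        # Non-support features draw heterogeneous rates (Beta, mean = missing_rate)
        # so the presence filter has real work; planted features are censored at
        # exactly the nominal rate to stay identifiable downstream.
        m = config.missing_rate
        a = 2.0
        b = a * (1.0 - m) / m
        rates = rng_miss.beta(a, b, size=config.n_features)
        rates[support_idx] = m
        for j in range(config.n_features):
            k = int(round(rates[j] * n_samples))
            if k <= 0:
                continue
            k = min(k, n_samples - 1)  # keep at least one observed entry
            lowest = np.argsort(abundance[:, j], kind="stable")[:k]
            abundance[lowest, j] = np.nan

    feature_meta = pd.DataFrame(
        {
            "rt1_s": rng_feat.uniform(380.0, 2380.0, size=config.n_features),
            "rt2_s": rng_feat.uniform(0.5, 2.0, size=config.n_features),
            "spectral_match": rng_feat.uniform(300.0, 950.0, size=config.n_features),
            "blank_flag": np.zeros(config.n_features, dtype=bool),
        },
        index=pd.Index(features, name="feature"),
    )
    table = FeatureTable(
        pd.DataFrame(
            abundance,
            index=pd.Index(meta["sample_id"].to_numpy(), name="sample_id"),
            columns=features,
        ),
        feature_meta,
    )
    meta = meta.set_index("sample_id", drop=False)

    truth = GroundTruth(
        support=support,
        beta={k: float(v) for k, v in beta.items()},
        interactions=interactions,
        diurnal_means=diurnal,
        intercept=diurnal[timepoints[-1]],
        noise_sd=config.noise_sd,
        subject_sd=config.subject_sd,
        subject_effects={k: float(v) for k, v in subj_eff.items()},
        outlier_samples=outlier_samples,
        seed=config.seed,
    )
    return meta, table, truth


def write_cohort(
    meta: pd.DataFrame,
    table: FeatureTable,
    path: str | Path,
    truth: GroundTruth | None = None,
) -> None:
    """Write a cohort to ``path`` as plain CSV/JSON files.

    Files: ``cohort_meta.csv``, ``features.csv`` (wide matrix, empty cell =
    missing), ``feature_meta.csv`` and optionally ``truth.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta[META_COLUMNS].to_csv(path / "cohort_meta.csv", index=False)
    table.abundance.rename_axis("sample_id").to_csv(path / "features.csv")
    table.feature_meta.rename_axis("feature").to_csv(path / "feature_meta.csv")
    if truth is not None:
        (path / "truth.json").write_text(truth.to_json())


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, FeatureTable]:
    """Read a cohort written by :func:`write_cohort` (lossless round-trip)."""
    path = Path(path)
    meta = pd.read_csv(path / "cohort_meta.csv")
    for colname in META_COLUMNS:
        if colname not in meta.columns:
            raise ValueError(f"cohort_meta.csv is missing required column {colname!r}")
    meta = meta.set_index("sample_id", drop=False)

    abundance = pd.read_csv(path / "features.csv", index_col="sample_id")
    bad = abundance.lt(0)
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"negative abundance at sample {r!r}, feature {c!r}")
    feature_meta = pd.read_csv(path / "feature_meta.csv", index_col="feature")
    for colname in FEATURE_META_COLUMNS[1:]:
        if colname not in feature_meta.columns:
            raise ValueError(f"feature_meta.csv is missing required column {colname!r}")
    return meta, FeatureTable(abundance, feature_meta)


def read_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json((Path(path) / "truth.json").read_text())
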