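"""Bootstrapped elastic-net stability selection.

Features are ranked by how often the elastic net assigns them a nonzero
coefficient over repeated random 80/20 subject-level train/test splits.
Within each iteration the penalty path is fitted on the training subjects
and the penalty minimizing held-out mean squared error decides which
features count as selected.  The procedure yields a per-feature selection
frequency from which top-k candidate subsets (default 25/35/50) are drawn.

The penalized objective is the glmnet parameterisation

    (1/2n)·RSS + lam·( alpha_mix·||b||_1 + (1-alpha_mix)/2·||b||_2^2 )

with an unpenalized intercept; scikit-learn's coordinate descent minimizes
exactly this objective (``alpha``=lam, ``l1_ratio``=alpha_mix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from cortivoc.preprocess import ProcessedMatrix


@dataclass(frozen=True)
class SelectionConfig:
    """Resampling and penalty settings for stability selection."""

    n_iter: int = 250
    train_fraction: float = 0.8
    alpha_mix: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    lambda_grid: tuple[float, ...] | None = None
    top_k: tuple[int, ...] = (25, 35, 50)
    with_replacement: bool = False
    include_factors: bool = False  # add Male/Morning/Afternoon dummies to the design
    path_tol: float = 1e-4
    max_skip_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must lie in (0, 1), got {self.train_fraction}")
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError(f"alpha_mix must lie in [0, 1], got {self.alpha_mix}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, float)
            if (grid <= 0).any() or not (np.diff(grid) < 0).all():
                raise ValueError("lambda_grid must be strictly positive and decreasing")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SelectionFrequency:
    """Per-feature selection counts over the bootstrap iterations."""

    counts: pd.Series  # integer count per feature
    n_iter: int  # completed (non-skipped) iterations
    coef_abs_sum: pd.Series  # Σ|coef| over the iterations where selected
    chosen_lambda: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    n_skipped: int = 0

    @property
    def frequency(self) -> pd.Series:
        return (self.counts / self.n_iter).rename("frequency")

    @property
    def mean_abs_coef(self) -> pd.Series:
        with np.errstate(invalid="ignore"):
            out = self.coef_abs_sum / self.counts
        return out.fillna(0.0).rename("mean_abs_coef")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.counts,
                "frequency": self.frequency,
                "mean_abs_coef": self.mean_abs_coef,
            }
        ).rename_axis("feature")


def elastic_net_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha_mix: float = 0.5,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Minimize the elastic-net objective; returns (intercept, coefficients).

    ``lam = 0`` reduces to ordinary least squares.  ``X`` is expected
    column-standardized (the penalty is applied to the given scale as-is).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if lam == 0:
        design = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(beta[0]), beta[1:]
    model = ElasticNet(
        alpha=lam, l1_ratio=alpha_mix, fit_intercept=True, tol=tol, max_iter=200_000
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return float(model.intercept_), model.coef_.copy()


def lambda_max(X: np.ndarray, y: np.ndarray, alpha_mix: float) -> float:
    """Smallest penalty at which every slope is exactly zero."""
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = max(alpha_mix, 1e-3)  # glmnet convention for near-ridge mixes
    return float(np.max(np.abs(Xc.T @ yc)) / (n * denom))


def make_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha_mix: float,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    lmax = lambda_max(X, y, alpha_mix)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _split_subjects(
    subjects: np.ndarray, rng: np.random.Generator, config: SelectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(config.train_fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    if config.with_replacement:
        drawn = rng.choice(subjects, size=len(subjects), replace=True)
        train = np.unique(drawn)
        test = np.setdiff1d(subjects, train)
        if len(test) == 0:  # degenerate draw; fall back to holding one out
            test = train[-1:]
            train = train[:-1]
        return train, test
    perm = rng.permutation(subjects)
    return perm[:n_train], perm[n_train:]


def bootstrap_select(
    z: ProcessedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> SelectionFrequency:
    """Selection frequency of each feature over subject-level 80/20 splits.

    Per iteration: subjects (never individual samples, so a subject's three
    timepoints stay together) are split into train/test; the elastic-net
    penalty path is fitted on the training samples; the penalty with minimum
    test-set MSE is chosen; features with nonzero coefficients there are
    counted as selected.  Deterministic given ``config.seed``.
    """
    config = config or SelectionConfig()
    config.validate()
    zdf = z.z if isinstance(z, ProcessedMatrix) else z
    meta = meta.loc[zdf.index]
    y_all = np.log10(meta["cortisol_ug"].to_numpy(dtype=float))
    subjects = np.unique(meta["subject_id"].to_numpy())
    if len(subjects) < 5:
        raise ValueError(f"need at least 5 subjects, got {len(subjects)}")
    subj_of = meta["subject_id"].to_numpy()
    X_all = zdf.to_numpy(dtype=float)
    n_feat = X_all.shape[1]
    if config.include_factors:
        # optional dummy columns absorb sex/diurnal mean structure during
        # selection; they are never counted as selectable features
        extras = np.column_stack(
            [
                (meta["sex"] == "male").to_numpy(dtype=float),
                (meta["timepoint"].str.lower() == "morning").to_numpy(dtype=float),
                (meta["timepoint"].str.lower() == "afternoon").to_numpy(dtype=float),
            ]
        )
        X_all = np.column_stack([X_all, extras])

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    counts = np.zeros(n_feat, dtype=int)
    coef_abs = np.zeros(n_feat)
    chosen_lambda: list[float] = []
    test_mse: list[float] = []
    n_skipped = 0

    for _ in range(config.n_iter):
        train_subj, test_subj = _split_subjects(subjects, rng, config)
        tr = np.isin(subj_of, train_subj)
        te = np.isin(subj_of, test_subj)
        y_tr, y_te = y_all[tr], y_all[te]
        if y_tr.std() == 0 or te.sum() == 0:
            n_skipped += 1
            continue
        X_tr, X_te = X_all[tr], X_all[te]
        if config.lambda_grid is not None:
            grid = np.asarray(config.lambda_grid, float)
        else:
            grid = make_lambda_grid(
                X_tr, y_tr, config.alpha_mix, config.n_lambda, config.lambda_min_ratio
            )
        # path solver works on centered data with an implicit intercept
        x_mean = X_tr.mean(axis=0)
        y_mean = y_tr.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = enet_path(
                X_tr - x_mean,
                y_tr - y_mean,
                l1_ratio=config.alpha_mix,
                alphas=grid,
                tol=config.path_tol,
            )
        preds = (X_te - x_mean) @ coefs + y_mean  # (n_test, n_lambda)
        mse = ((preds - y_te[:, None]) ** 2).mean(axis=0)
        best = int(np.argmin(mse))
        beta = coefs[:n_feat, best]
        nz = beta != 0
        counts[nz] += 1
        coef_abs[nz] += np.abs(beta[nz])
        chosen_lambda.append(float(grid[best]))
        test_mse.append(float(mse[best]))

    if n_skipped > config.max_skip_fraction * config.n_iter:
        raise RuntimeError(
            f"{n_skipped}/{config.n_iter} iterations skipped (degenerate training sets)"
        )
    completed = config.n_iter - n_skipped
    return SelectionFrequency(
        counts=pd.Series(counts, index=zdf.columns, name="count"),
        n_iter=completed,
        coef_abs_sum=pd.Series(coef_abs, index=zdf.columns, name="coef_abs_sum"),
        chosen_lambda=chosen_lambda,
        test_mse=test_mse,
        n_skipped=n_skipped,
    )


def top_k(freq: SelectionFrequency, k: int) -> list[str]:
    """The ``k`` most frequently selected features.

    Ties on frequency break by larger mean |coefficient| over the iterations
    where the feature was selected, then by earlier column position, so the
    output is deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(freq.counts):
        raise ValueError(f"k={k} exceeds the number of features ({len(freq.counts)})")
    order = pd.DataFrame(
        {
            "count": freq.counts,
            "mean_abs_coef": freq.mean_abs_coef,
            "position": np.arange(len(freq.counts)),
        }
    ).sort_values(
        by=["count", "mean_abs_coef", "position"], ascending=[False, False, True]
    )
    return order.index[:k].tolist()
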