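"""Regression diagnostics and subgroup comparisons.

Emits the diagnostic quantities usually read off plots — residual vs.
fitted, QQ pairs, residual histogram, lag and run-order drift pairs,
variance inflation factors, added-variable point sets and a predicted vs.
observed band — as plain data, plus formal backstops (Shapiro-Wilk
normality and Breusch-Pagan homoskedasticity at alpha = 0.01, VIF cutoff
5).  Subgroup Welch t-tests with Benjamini-Hochberg FDR cover the model
metabolites across sex and time-of-day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from cortivoc.model_select import FitResult, bh_adjust
from cortivoc.preprocess import ProcessedMatrix

VIF_CUTOFF = 5.0
_VIF_SENTINEL_FLOOR = 1e6


@dataclass
class DiagnosticsReport:
    fitted: np.ndarray
    residual: np.ndarray
    std_residual: np.ndarray  # internally studentized (leverage-adjusted)
    qq_pairs: np.ndarray  # (n, 2): theoretical, sample quantiles
    hist_bins: tuple[np.ndarray, np.ndarray]  # counts, bin edges
    lag_pairs: np.ndarray  # (n-1, 2): (r_t, r_{t+1})
    drift_pairs: np.ndarray  # (n, 2): (run_order, residual)
    vif: dict[str, float]
    av_data: dict[str, np.ndarray]  # term -> (n, 2) partial-residual pairs
    adj_r2: float
    flags: dict[str, bool] = field(default_factory=dict)
    shapiro_p: float = float("nan")
    breusch_pagan_p: float = float("nan")


def _vif_one(Xc: np.ndarray, j: int) -> float:
    others = np.delete(Xc, j, axis=1)
    others = np.column_stack([np.ones(len(Xc)), others])
    beta, *_ = np.linalg.lstsq(others, Xc[:, j], rcond=None)
    resid = Xc[:, j] - others @ beta
    tss = float(((Xc[:, j] - Xc[:, j].mean()) ** 2).sum())
    if tss <= 0:
        return 1.0
    r2 = 1.0 - float(resid @ resid) / tss
    denom = 1.0 - r2
    if denom < 1.0 / _VIF_SENTINEL_FLOOR:
        return 1.0 / max(denom, 1e-12)  # capped sentinel for (near-)perfect collinearity
    return 1.0 / denom


def compute_diagnostics(
    fit: FitResult,
    design: pd.DataFrame,
    y: pd.Series | np.ndarray,
    run_order: np.ndarray | pd.Series | None = None,
    alpha: float = 0.01,
) -> DiagnosticsReport:
    """Full diagnostics for an OLS fit produced on (design, y)."""
    yv = np.asarray(y, dtype=float)
    if design.shape[0] != len(yv):
        raise ValueError("design and response have mismatched lengths")
    X = np.column_stack([np.ones(len(yv)), design.to_numpy(dtype=float)])
    beta = np.array([fit.beta["Intercept"]] + [fit.beta[t] for t in fit.terms])
    fitted = X @ beta
    residual = yv - fitted

    q, _ = np.linalg.qr(X)
    leverage = (q**2).sum(axis=1)
    dof = fit.n - fit.k
    sigma = np.sqrt(fit.rss / dof) if dof > 0 else 0.0
    denom = sigma * np.sqrt(np.clip(1.0 - leverage, 1e-12, None))
    std_residual = residual / denom if sigma > 0 else np.zeros_like(residual)

    order = np.argsort(residual)
    theo = stats.norm.ppf((np.arange(1, len(yv) + 1) - 0.375) / (len(yv) + 0.25))
    qq_pairs = np.column_stack([theo, residual[order]])
    hist_bins = np.histogram(residual, bins="auto")
    lag_pairs = np.column_stack([residual[:-1], residual[1:]])
    if run_order is None:
        run_order = np.arange(1, len(yv) + 1)
    drift_pairs = np.column_stack([np.asarray(run_order, float), residual])

    Xc = design.to_numpy(dtype=float)
    vif = {t: _vif_one(Xc, j) for j, t in enumerate(design.columns)}

    av_data = {}
    for j, t in enumerate(design.columns):
        others = np.delete(X, j + 1, axis=1)
        b_y, *_ = np.linalg.lstsq(others, yv, rcond=None)
        b_x, *_ = np.linalg.lstsq(others, X[:, j + 1], rcond=None)
        av_data[t] = np.column_stack([X[:, j + 1] - others @ b_x, yv - others @ b_y])

    if len(yv) >= 3 and residual.std() > 0:
        shapiro_p = float(stats.shapiro(residual).pvalue)
        bp_p = float(het_breuschpagan(residual, X)[1])
    else:
        shapiro_p, bp_p = float("nan"), float("nan")
    flags = {
        "vif_ok": max(vif.values(), default=1.0) <= VIF_CUTOFF,
        "normal_residuals": (not np.isfinite(shapiro_p)) or shapiro_p > alpha,
        "homoskedastic": (not np.isfinite(bp_p)) or bp_p > alpha,
    }
    return DiagnosticsReport(
        fitted=fitted,
        residual=residual,
        std_residual=std_residual,
        qq_pairs=qq_pairs,
        hist_bins=hist_bins,
        lag_pairs=lag_pairs,
        drift_pairs=drift_pairs,
        vif=vif,
        av_data=av_data,
        adj_r2=fit.adj_r2,
        flags=flags,
        shapiro_p=shapiro_p,
        breusch_pagan_p=bp_p,
    )


def predicted_vs_observed(
    fit: FitResult, design: pd.DataFrame, y: pd.Series | np.ndarray
) -> pd.DataFrame:
    """(predicted, observed) pairs with the 95% mean-prediction CI band."""
    yv = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(yv)), design.to_numpy(dtype=float)])
    beta = np.array([fit.beta["Intercept"]] + [fit.beta[t] for t in fit.terms])
    yhat = X @ beta
    dof = fit.n - fit.k
    if fit.xtx_inv is not None and dof > 0 and fit.sigma2 > 0:
        se_mean = np.sqrt(fit.sigma2 * np.einsum("ij,jk,ik->i", X, fit.xtx_inv, X))
        tcrit = stats.t.ppf(0.975, dof)
    else:
        se_mean = np.zeros_like(yhat)
        tcrit = 0.0
    return pd.DataFrame(
        {
            "predicted": yhat,
            "observed": yv,
            "ci_low": yhat - tcrit * se_mean,
            "ci_high": yhat + tcrit * se_mean,
        },
        index=design.index,
    )


def subgroup_ttests(
    z: ProcessedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    features: list[str],
    fdr: float = 0.10,
    pooled: bool = False,
) -> pd.DataFrame:
    """Unpaired t-tests of model metabolites across sex and timepoint.

    Family: for each feature, male vs. female within each timepoint, and each
    timepoint pair within each sex (Welch by default).  One BH adjustment is
    applied over the whole family; ``significant`` marks p_bh <= fdr.
    Degenerate comparisons (a subgroup with < 2 samples or zero variance in
    both groups) are skipped.
    """
    zdf = z.z if isinstance(z, ProcessedMatrix) else z
    meta = meta.loc[zdf.index]
    timepoints = list(dict.fromkeys(meta["timepoint"]))
    sexes = list(dict.fromkeys(meta["sex"]))
    rows = []
    for f in features:
        v = zdf[f]
        for tp in timepoints:
            sel = meta["timepoint"] == tp
            groups = [v[sel & (meta["sex"] == s)].to_numpy() for s in sexes[:2]]
            rows.append((f, f"{sexes[0]} vs {sexes[1]}", f"timepoint={tp}", *groups))
        for s in sexes:
            for t1, t2 in combinations(timepoints, 2):
                sel = meta["sex"] == s
                g1 = v[sel & (meta["timepoint"] == t1)].to_numpy()
                g2 = v[sel & (meta["timepoint"] == t2)].to_numpy()
                rows.append((f, f"{t1} vs {t2}", f"sex={s}", g1, g2))

    records = []
    for f, comp, stratum, g1, g2 in rows:
        if len(g1) < 2 or len(g2) < 2:
            records.append((f, comp, stratum, np.nan, np.nan, "skipped: <2 samples"))
            continue
        if g1.std() == 0 and g2.std() == 0:
            if np.allclose(g1.mean(), g2.mean()):
                records.append((f, comp, stratum, 0.0, 1.0, "identical"))
            else:
                records.append((f, comp, stratum, np.nan, np.nan, "skipped: zero variance"))
            continue
        t, p = stats.ttest_ind(g1, g2, equal_var=pooled)
        records.append((f, comp, stratum, float(t), float(p), ""))
    out = pd.DataFrame(
        records, columns=["feature", "comparison", "stratum", "t", "p_raw", "note"]
    )
    tested = out["p_raw"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = bh_adjust(out.loc[tested, "p_raw"].to_numpy())
    out["significant"] = out["p_bh"] <= fdr
    return out


def residual_summary(
    residuals: pd.Series | np.ndarray,
    meta: pd.DataFrame,
    groupby: tuple[str, ...] = ("sex", "timepoint"),
) -> pd.DataFrame:
    """Per-group residual summaries with ratio-scale µg back-transforms.

    Residuals are on the log10 scale; the reported ``*_ug`` columns apply
    10^r, so a residual of 0 back-transforms to 1.0 (ratio scale).
    """
    meta = meta.copy()
    meta["_r"] = np.asarray(residuals, dtype=float)
    rows = []
    for keys, grp in meta.groupby(list(groupby), observed=True, sort=False):
        r = grp["_r"].to_numpy()
        if len(r) == 0:
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        se = float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else 0.0
        rows.append(
            dict(
                zip(groupby, keys),
                n=len(r),
                min=float(r.min()),
                max=float(r.max()),
                mean=float(r.mean()),
                se=se,
                min_ug=float(10.0 ** r.min()),
                max_ug=float(10.0 ** r.max()),
                mean_ug=float(10.0 ** r.mean()),
            )
        )
    return pd.DataFrame(rows)
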