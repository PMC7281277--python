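"""Two-way ANOVA screen for sex and time-of-day interaction factors.

A two-way ANOVA with replication on (log10) cortisol decides which of the
design factors — sex and collection timepoint — are significant sources of
variation and therefore eligible to form metabolite interaction terms in
the downstream regression.  Type-II sums of squares are used so that the
screen remains well-defined on designs unbalanced by outlier removal; on
balanced designs they coincide with the textbook sequential decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

FACTORS = ("sex", "time")


@dataclass(frozen=True)
class AnovaResult:
    factor: str  # one of "sex", "time", "sex×time", "residual"
    ss: float
    df: int
    F: float
    p: float


def two_way_anova(
    meta: pd.DataFrame,
    response: pd.Series | np.ndarray | None = None,
    log_response: bool = True,
) -> list[AnovaResult]:
    """Sex x timepoint ANOVA with replication on (log10) urinary cortisol.

    ``response`` defaults to cortisol from ``meta`` (log10-transformed when
    ``log_response``); a precomputed vector may be supplied instead.
    Requires at least two replicates per sex x timepoint cell.
    """
    df = meta[["sex", "timepoint"]].copy()
    if response is None:
        y = meta["cortisol_ug"].to_numpy(dtype=float)
        df["y"] = np.log10(y) if log_response else y
    else:
        df["y"] = np.asarray(response, dtype=float)

    counts = df.groupby(["sex", "timepoint"], observed=True).size()
    sexes = df["sex"].unique()
    tps = df["timepoint"].unique()
    for s in sexes:
        for t in tps:
            n_cell = counts.get((s, t), 0)
            if n_cell == 0:
                raise ValueError(f"empty design cell: sex={s!r}, timepoint={t!r}")
            if n_cell < 2:
                raise ValueError(
                    f"cell sex={s!r}, timepoint={t!r} has {n_cell} replicate; need >= 2"
                )

    fit = smf.ols("y ~ C(sex) * C(timepoint)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    name_map = {
        "C(sex)": "sex",
        "C(timepoint)": "time",
        "C(sex):C(timepoint)": "sex×time",
        "Residual": "residual",
    }
    results = []
    total_ss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    for row_name, row in tab.iterrows():
        factor = name_map.get(str(row_name), str(row_name))
        ss = float(row["sum_sq"])
        f_stat = float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan
        p = float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan
        # constant response: all SS vanish and the F ratio is 0/0 — report
        # "no evidence" (F = 0, p = 1) rather than NaN
        if factor != "residual" and total_ss <= 1e-12 * max(1.0, abs(df["y"].mean())) ** 2:
            f_stat, p = 0.0, 1.0
        results.append(AnovaResult(factor=factor, ss=ss, df=int(row["df"]), F=f_stat, p=p))
    return results


def screen_factors(results: list[AnovaResult], alpha: float = 0.05) -> set[str]:
    """Return the main factors ({'sex', 'time'}) significant at ``alpha``.

    Only factors returned here are used to build interaction terms downstream.
    """
    if not results:
        raise ValueError("no ANOVA results to screen")
    return {r.factor for r in results if r.factor in FACTORS and np.isfinite(r.p) and r.p < alpha}


def anova_report(results: list[AnovaResult]) -> dict:
    return {
        r.factor: {"ss": r.ss, "df": r.df, "F": r.F, "p": r.p} for r in results
    }
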