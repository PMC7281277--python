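"""Interaction design construction and stepwise AICc/BIC model search.

Candidate metabolites (from stability selection) enter as standardized main
effects together with binary dummies Male / Morning / Afternoon (reference
cell: female evening) and all metabolite x dummy products.  A greedy
forward/backward stepwise search minimizes AICc (or BIC) over single-term
add/drop moves; the surviving model is fitted by OLS with t-based confidence
intervals and Benjamini-Hochberg adjusted p-values.

Information criteria use the Gaussian profile log-likelihood form with the
constant dropped (consistent across compared models on the same samples):

    aic  = n·ln(rss/n) + 2k,   aicc = aic + 2k(k+1)/(n-k-1),
    bic  = n·ln(rss/n) + k·ln(n),

where k counts the intercept and slopes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from cortivoc.preprocess import ProcessedMatrix

FACTOR_DUMMIES = {"sex": ("Male",), "time": ("Morning", "Afternoon")}
_TIMEPOINT_DUMMY = {"morning": "Morning", "afternoon": "Afternoon"}


@dataclass
class FitResult:
    """A fitted linear model with inference and information criteria."""

    terms: list[str]  # non-intercept term labels, design order
    beta: dict[str, float]  # includes "Intercept"
    se: dict[str, float]
    ci95_low: dict[str, float]
    ci95_high: dict[str, float]
    p_raw: dict[str, float]
    p_bh: dict[str, float]
    rss: float
    n: int
    k: int  # estimated parameters including the intercept
    adj_r2: float
    aicc: float
    bic: float
    sample_index: tuple = ()
    sigma2: float = 0.0
    xtx_inv: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "beta": self.beta,
            "se": self.se,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p_raw": self.p_raw,
            "p_bh": self.p_bh,
            "rss": self.rss,
            "n": self.n,
            "k": self.k,
            "adj_r2": self.adj_r2,
            "aicc": self.aicc,
            "bic": self.bic,
        }


def build_design(
    z: ProcessedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    candidates: Sequence[str],
    factors: Iterable[str] = ("sex", "time"),
) -> pd.DataFrame:
    """Design matrix of candidate main effects, dummies and their products.

    Dummy coding follows the reference cell female/evening: Male = 1 for male
    subjects, Morning/Afternoon = 1 for the matching timepoint.  Interaction
    columns are labelled ``"<feature>:<Dummy>"``.  No intercept column is
    included (the fitters add it).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    factors = set(factors)
    unknown = factors - set(FACTOR_DUMMIES)
    if unknown:
        raise ValueError(f"unknown factor labels: {sorted(unknown)}; use 'sex' and/or 'time'")
    zdf = z.z if isinstance(z, ProcessedMatrix) else z
    meta = meta.loc[zdf.index]

    cols: dict[str, np.ndarray] = {}
    for f in candidates:
        cols[f] = zdf[f].to_numpy(dtype=float)
    dummies: dict[str, np.ndarray] = {}
    if "sex" in factors:
        dummies["Male"] = (meta["sex"] == "male").to_numpy(dtype=float)
    if "time" in factors:
        tp = meta["timepoint"].str.lower()
        dummies["Morning"] = (tp == "morning").to_numpy(dtype=float)
        dummies["Afternoon"] = (tp == "afternoon").to_numpy(dtype=float)
    cols.update(dummies)
    for f in candidates:
        for d, dv in dummies.items():
            cols[f"{f}:{d}"] = cols[f] * dv
    return pd.DataFrame(cols, index=zdf.index)


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC (Gaussian, constant dropped)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    aic = n * math.log(rss / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def bic(rss: float, n: int, k: int) -> float:
    """Bayesian information criterion (Gaussian, constant dropped)."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k:
        raise ValueError(f"BIC undefined for n={n}, k={k}")
    return n * math.log(rss / n) + k * math.log(n)


def bh_adjust(p_raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in the input)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_ols(
    design: pd.DataFrame, y: pd.Series | np.ndarray, add_intercept: bool = True
) -> FitResult:
    """Ordinary least squares with t-based inference on every term.

    Standard errors come from sigma2·(X'X)^-1 with sigma2 = rss/(n-k); 95%
    confidence intervals and two-sided p-values use the t(n-k) reference.
    A rank-deficient design is rejected with the collinear term labels named.
    """
    yv = np.asarray(y, dtype=float)
    terms = list(design.columns)
    X = design.to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(yv)), X])
        labels = ["Intercept"] + terms
    else:
        labels = terms
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} samples cannot identify k={k} parameters")
    if np.linalg.matrix_rank(X) < k:
        collinear = _collinear_labels(X, labels)
        raise ValueError(f"design is rank deficient; collinear terms: {collinear}")

    res = sm.OLS(yv, X).fit()
    rss = float(res.ssr)
    tss = float(((yv - yv.mean()) ** 2).sum())
    dof = n - k
    sigma2 = rss / dof
    adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1)) if tss > 0 else 1.0
    perfect = rss <= max(tss, 1.0) * 1e-14
    if perfect:
        adj_r2 = 1.0

    ci = res.conf_int(alpha=0.05)
    p_raw = np.nan_to_num(res.pvalues, nan=0.0) if perfect else np.asarray(res.pvalues)
    p_bh = bh_adjust(np.clip(p_raw, 0.0, 1.0))
    rss_safe = max(rss, 1e-300)
    return FitResult(
        terms=terms,
        beta=dict(zip(labels, (float(b) for b in res.params))),
        se=dict(zip(labels, (float(s) for s in res.bse))),
        ci95_low=dict(zip(labels, (float(v) for v in ci[:, 0]))),
        ci95_high=dict(zip(labels, (float(v) for v in ci[:, 1]))),
        p_raw=dict(zip(labels, (float(v) for v in p_raw))),
        p_bh=dict(zip(labels, (float(v) for v in p_bh))),
        rss=rss,
        n=n,
        k=k,
        adj_r2=float(adj_r2),
        aicc=aicc(rss_safe, n, k) if n > k + 1 else math.inf,
        bic=bic(rss_safe, n, k),
        sample_index=tuple(design.index),
        sigma2=sigma2,
        xtx_inv=np.linalg.pinv(X.T @ X),
    )


def _collinear_labels(X: np.ndarray, labels: list[str]) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    bad = []
    keep = list(range(X.shape[1]))
    for j in range(X.shape[1]):
        sub = [i for i in keep if i != j]
        if np.linalg.matrix_rank(X[:, sub]) == np.linalg.matrix_rank(X[:, keep]):
            bad.append(labels[j])
            keep = sub
    return bad


def _rss_of(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return math.nan  # rank-deficient candidate: caller skips the move
    r = y - X @ beta
    return float(r @ r)


def _criterion(rss: float, n: int, k: int, which: str) -> float:
    if not math.isfinite(rss) or rss <= 0:
        return math.nan
    if which == "aicc":
        return aicc(rss, n, k) if n > k + 1 else math.nan
    return bic(rss, n, k)


def _hierarchy_ok_add(term: str, current: set[str]) -> bool:
    if ":" not in term:
        return True
    feat = term.split(":", 1)[0]
    return feat in current


def _hierarchy_ok_drop(term: str, current: set[str]) -> bool:
    if ":" in term:
        return True
    return not any(t.startswith(f"{term}:") for t in current if ":" in t)


def stepwise(
    design: pd.DataFrame,
    y: pd.Series | np.ndarray,
    direction: str = "both",
    criterion: str = "aicc",
    hierarchy: bool = True,
    verbose: bool = False,
) -> FitResult:
    """Greedy stepwise minimization of AICc or BIC over single-term moves.

    ``forward`` starts from the intercept-only model and only adds terms;
    ``backward`` starts from the full design and only drops; ``both`` starts
    from the intercept and considers adds and drops at every step.  The move
    with the largest criterion decrease is accepted; ties break by earlier
    design-column order; the search stops when no move decreases the
    criterion.  With ``hierarchy`` an interaction may enter only while its
    metabolite main effect is present, and a main effect may not leave while
    one of its interactions remains.
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if criterion not in ("aicc", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    yv = np.asarray(y, dtype=float)
    all_terms = list(design.columns)
    X_full = design.to_numpy(dtype=float)
    n = len(yv)
    ones = np.ones((n, 1))
    col = {t: j for j, t in enumerate(all_terms)}

    if direction == "backward":
        current = list(all_terms)
    else:
        current = []

    def crit_of(terms: list[str]) -> float:
        X = np.column_stack([ones] + [X_full[:, col[t]] for t in terms]) if terms else ones
        rss = _rss_of(X, yv)
        return _criterion(rss, n, len(terms) + 1, criterion)

    best = crit_of(current)
    if math.isnan(best):
        raise ValueError("initial model is rank deficient or criterion undefined")
    trace = [(tuple(current), best)]
    allow_add = direction in ("forward", "both")
    allow_drop = direction in ("backward", "both")

    while True:
        moves: list[tuple[float, int, str, str]] = []  # (crit, order, kind, term)
        cur_set = set(current)
        if allow_add:
            for t in all_terms:
                if t in cur_set:
                    continue
                if hierarchy and not _hierarchy_ok_add(t, cur_set):
                    continue
                c = crit_of(current + [t])
                if not math.isnan(c):
                    moves.append((c, col[t], "add", t))
        if allow_drop:
            for t in current:
                if hierarchy and not _hierarchy_ok_drop(t, cur_set):
                    continue
                c = crit_of([u for u in current if u != t])
                if not math.isnan(c):
                    moves.append((c, col[t], "drop", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        c, _, kind, term = moves[0]
        if c >= best - 1e-10:
            break
        best = c
        if kind == "add":
            current = current + [term]
        else:
            current = [u for u in current if u != term]
        trace.append((tuple(current), best))
        if verbose:  # pragma: no cover - logging only
            print(f"{kind} {term}: {criterion}={best:.4f}")

    current_sorted = [t for t in all_terms if t in set(current)]
    fit = fit_ols(design[current_sorted] if current_sorted else design.iloc[:, :0], yv)
    fit.stepwise_trace = trace  # type: ignore[attr-defined]
    return fit


def exhaustive_best_subset(
    design: pd.DataFrame, y: pd.Series | np.ndarray, criterion: str = "aicc"
) -> tuple[tuple[str, ...], float]:
    """Enumerate every term subset; oracle companion to :func:`stepwise`."""
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    terms = list(design.columns)
    X_full = design.to_numpy(dtype=float)
    ones = np.ones((n, 1))
    best: tuple[tuple[str, ...], float] = ((), math.inf)
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(range(len(terms)), r):
            X = np.column_stack([ones, X_full[:, list(combo)]]) if combo else ones
            if X.shape[1] >= n:
                continue
            c = _criterion(_rss_of(X, yv), n, len(combo) + 1, criterion)
            if not math.isnan(c) and c < best[1]:
                best = (tuple(terms[j] for j in combo), c)
    return best


def compare_models(
    fits: Sequence[FitResult],
    names: Sequence[str] | None = None,
    overfit_k_fraction: float = 1 / 3,
    diagnostics_flags: Sequence[dict] | None = None,
) -> pd.DataFrame:
    """Rank fitted models by AICc, breaking near-ties by BIC.

    All fits must be on the same sample set.  Each row reports adjusted R²,
    term count, an overfitting flag (k > n·overfit_k_fraction) and optional
    diagnostics pass/fail annotations.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].sample_index
    for f in fits[1:]:
        if f.sample_index != ref:
            raise ValueError("fits were computed on differing sample sets")
    names = list(names) if names is not None else [f"model_{i}" for i in range(len(fits))]
    rows = []
    for i, f in enumerate(fits):
        row = {
            "name": names[i],
            "aicc": f.aicc,
            "bic": f.bic,
            "adj_r2": f.adj_r2,
            "n_terms": len(f.terms),
            "k": f.k,
            "overfit_flag": f.k > f.n * overfit_k_fraction,
        }
        if diagnostics_flags is not None:
            row.update(diagnostics_flags[i])
        rows.append(row)
    report = pd.DataFrame(rows)
    report = report.sort_values(by=["aicc", "bic"], kind="stable").reset_index(drop=True)
    report.index.name = "rank"
    return report
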