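"""Retention indices and MSI identification confidence levels.

First-dimension retention times are normalized against an n-alkane ladder
(C8-C20) on the temperature-programmed column: an alkane with n carbons is
anchored at index 100·n and unknowns interpolate linearly between the
bracketing rungs (van den Dool-Kratz convention).  Peaks outside the ladder
span extrapolate from the nearest rung pair and are flagged.

Cross-phase consistency of an experimental index against library non-polar
and polar indices is expressed as a polarity percentage,

    100 · (RI_exp - RI_nonpolar) / (RI_polar - RI_nonpolar),

expected in the 5-35% window for the mid-polar phase used here.  Evidence
then maps to Metabolomics Standards Initiative levels: 1 standard-verified,
2 spectral match >= 800/1000 with consistent RI, 3 spectral match >= 800
without RI confirmation, 4 otherwise (name replaced by a functional-group
label or "unknown").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

#: spectral-match score (0-1000 scale) at and above which a library name is trusted
MATCH_THRESHOLD = 800.0
POLARITY_WINDOW = (5.0, 35.0)
NONPOLAR_RI_TOL = 0.06


class RetentionIndex(NamedTuple):
    value: float
    extrapolated: bool


@dataclass(frozen=True)
class AlkaneLadder:
    """Carbon number -> first-dimension retention time (s) for the standards."""

    rungs: dict[int, float]

    def __post_init__(self):
        if len(self.rungs) < 2:
            raise ValueError("alkane ladder needs at least 2 rungs")
        ns = sorted(self.rungs)
        rts = [self.rungs[n] for n in ns]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must increase strictly with carbon number")
        if any(rt <= 0 for rt in rts):
            raise ValueError("retention times must be positive")

    @property
    def carbons(self) -> list[int]:
        return sorted(self.rungs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlkaneLadder":
        df = pd.read_csv(path)
        if not {"carbon_number", "rt1_s"} <= set(df.columns):
            raise ValueError("ladder CSV needs columns carbon_number, rt1_s")
        return cls({int(r.carbon_number): float(r.rt1_s) for r in df.itertuples()})


def retention_index(ladder: AlkaneLadder, rt1: float) -> RetentionIndex:
    """Linear retention index of a peak at ``rt1`` seconds.

    Between bracketing alkanes C_n and C_{n+1}:
    RI = 100·(n + (rt1 - t_n)/(t_{n+1} - t_n)); outside the ladder span the
    nearest rung pair extrapolates linearly and ``extrapolated`` is True.
    """
    ns = ladder.carbons
    rts = np.array([ladder.rungs[n] for n in ns], dtype=float)
    extrapolated = bool(rt1 < rts[0] or rt1 > rts[-1])
    if extrapolated:
        lo, hi = (0, 1) if rt1 < rts[0] else (len(ns) - 2, len(ns) - 1)
    else:
        hi = int(np.searchsorted(rts, rt1, side="left"))
        hi = max(1, min(hi, len(ns) - 1))
        lo = hi - 1
    n_lo, n_hi = ns[lo], ns[hi]
    frac = (rt1 - rts[lo]) / (rts[hi] - rts[lo])
    value = 100.0 * (n_lo + frac * (n_hi - n_lo))
    return RetentionIndex(float(value), extrapolated)


def polarity_percent(
    ri_exp: float,
    ri_nonpolar: float,
    ri_polar: float,
    window: tuple[float, float] = POLARITY_WINDOW,
) -> tuple[float, bool]:
    """Polarity percentage and whether it falls in the consistency window."""
    if ri_polar <= ri_nonpolar:
        raise ValueError(
            f"degenerate polarity span: ri_polar ({ri_polar}) <= ri_nonpolar ({ri_nonpolar})"
        )
    pct = 100.0 * (ri_exp - ri_nonpolar) / (ri_polar - ri_nonpolar)
    return pct, bool(window[0] <= pct <= window[1])


@dataclass
class CompoundAnnotation:
    """One peak's identification evidence and assigned confidence level."""

    name: str
    rt1_s: float
    rt2_s: float
    spectral_match: float  # 0-1000 forward-search similarity; 800 = 80%
    ri_experimental: float | None = None
    ri_nonpolar_ref: float | None = None
    ri_polar_ref: float | None = None
    standard_verified: bool = False
    extrapolated: bool = False
    functional_group: str | None = None
    id_level: int | None = None


def assign_id_level(
    a: CompoundAnnotation,
    window: tuple[float, float] = POLARITY_WINDOW,
    nonpolar_tol: float = NONPOLAR_RI_TOL,
) -> CompoundAnnotation:
    """Assign the MSI confidence level implied by the annotation's evidence.

    - spectral match below 800 -> level 4; the library name is replaced by
      the functional-group label if one is supported, else "unknown";
    - match >= 800 with a polarity percentage inside ``window`` -> level 2,
      upgraded to 1 when verified against an analytical standard;
    - match >= 800 without that confirmation -> level 3 (a non-polar library
      RI within ``nonpolar_tol`` relative difference supports the name but
      does not by itself reach level 2).

    Returns a copy with ``id_level`` (and possibly ``name``) set.
    """
    if a.spectral_match is None or not np.isfinite(a.spectral_match):
        raise ValueError("spectral_match is required")
    if a.spectral_match < MATCH_THRESHOLD:
        name = a.functional_group if a.functional_group else "unknown"
        return replace(a, id_level=4, name=name)

    ri_consistent = False
    if (
        a.ri_experimental is not None
        and a.ri_nonpolar_ref is not None
        and a.ri_polar_ref is not None
    ):
        _, ri_consistent = polarity_percent(
            a.ri_experimental, a.ri_nonpolar_ref, a.ri_polar_ref, window
        )
    if ri_consistent:
        return replace(a, id_level=1 if a.standard_verified else 2)
    return replace(a, id_level=3)


def nonpolar_ri_supported(
    a: CompoundAnnotation, nonpolar_tol: float = NONPOLAR_RI_TOL
) -> bool:
    """True when the experimental RI is within ``nonpolar_tol`` (relative)
    of the non-polar library RI — the supporting-evidence route for naming
    level-3 compounds."""
    if a.ri_experimental is None or a.ri_nonpolar_ref is None:
        return False
    return abs(a.ri_experimental - a.ri_nonpolar_ref) <= nonpolar_tol * a.ri_nonpolar_ref


def annotate_table(
    feature_meta: pd.DataFrame,
    ladder: AlkaneLadder,
    refs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute RI and ID level for every feature in a metadata table.

    ``refs`` may carry per-feature ``ri_nonpolar_ref``/``ri_polar_ref``/
    ``standard_verified`` columns; absent evidence degrades gracefully to
    levels 3/4.
    """
    rows = []
    for feat, row in feature_meta.iterrows():
        ri = retention_index(ladder, float(row["rt1_s"]))
        kwargs = {}
        if refs is not None and feat in refs.index:
            r = refs.loc[feat]
            kwargs = {
                "ri_nonpolar_ref": r.get("ri_nonpolar_ref"),
                "ri_polar_ref": r.get("ri_polar_ref"),
                "standard_verified": bool(r.get("standard_verified", False)),
            }
        ann = assign_id_level(
            CompoundAnnotation(
                name=str(feat),
                rt1_s=float(row["rt1_s"]),
                rt2_s=float(row["rt2_s"]),
                spectral_match=float(row["spectral_match"]),
                ri_experimental=ri.value,
                extrapolated=ri.extrapolated,
                **kwargs,
            )
        )
        rows.append(
            {
                "feature": feat,
                "name": ann.name,
                "ri": ri.value,
                "ri_extrapolated": ri.extrapolated,
                "id_level": ann.id_level,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
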