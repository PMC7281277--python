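"""The published 22-coefficient urinary cortisol predictor.

The final multiple regression model — 14 standardized log10 VOC abundances,
7 sex/time interaction terms and an intercept — is shipped as frozen data
(``data/published_model.json``, printed 3-decimal precision) and exposed as
an executable predictor:

    log10(cortisol_ug) = 0.496 + sum_j b_j x_j + sum_(j,d) c_jd x_j 1[d]

with dummies Male / Morning / Afternoon and reference cell female evening.
Unnamed compounds are addressed by variable label plus their chromatographic
coordinates so user feature tables can be mapped by retention matching.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_MAIN = 14
N_INTERACTIONS = 7
_VALID_SEX = ("male", "female")
_VALID_TIMEPOINT = ("morning", "afternoon", "evening")
#: retention-matching tolerances (first/second dimension, seconds)
RT_MATCH_TOL = (2.0, 0.2)


def to_micrograms(v: float | np.ndarray) -> float | np.ndarray:
    """Back-transform log10 µg (or a log10-scale residual) to µg.

    For residuals the result is on the ratio scale: 10^0 = 1 means the
    prediction was exact; 10^0.650 = 4.47 means the observation was 4.47x
    the prediction.
    """
    return 10.0**v


def format_3sig(x: float) -> str:
    """Three-significant-figure formatting used in reported summaries."""
    return f"{x:.3g}"


class PublishedModel:
    """Frozen predictor built from the published coefficient table."""

    def __init__(self, payload: dict):
        self._payload = payload
        self.intercept = float(payload["intercept"]["coef"])
        self.main_coefs = {t["label"]: float(t["coef"]) for t in payload["main_terms"]}
        self.compounds = {t["label"]: t["compound"] for t in payload["main_terms"]}
        self.interaction_coefs = {
            (t["label"], t["dummy"]): float(t["coef"])
            for t in payload["interaction_terms"]
        }
        if len(self.main_coefs) != N_MAIN:
            raise ValueError(f"expected {N_MAIN} main terms, got {len(self.main_coefs)}")
        if len(self.interaction_coefs) != N_INTERACTIONS:
            raise ValueError(
                f"expected {N_INTERACTIONS} interaction terms, got {len(self.interaction_coefs)}"
            )
        for (label, _dummy) in self.interaction_coefs:
            if label not in self.main_coefs:
                raise ValueError(f"interaction on {label} lacks a main term")
        self.labels = list(self.main_coefs)

    # -- prediction ---------------------------------------------------------

    def predict_log10_cortisol(
        self,
        x: Sequence[float] | Mapping[str, float],
        sex: str,
        timepoint: str,
    ) -> float:
        """Predicted log10 cortisol (µg) for one sample.

        ``x`` gives the 14 standardized log10 metabolite abundances either as
        a length-14 sequence in x1..x14 order or as a label->value mapping.
        """
        if isinstance(x, Mapping):
            unknown = set(x) - set(self.labels)
            if unknown:
                raise ValueError(f"unknown metabolite labels: {sorted(unknown)}")
            missing = set(self.labels) - set(x)
            if missing:
                raise ValueError(f"missing metabolite values: {sorted(missing)}")
            xv = {k: float(v) for k, v in x.items()}
        else:
            vals = list(x)
            if len(vals) != N_MAIN:
                raise ValueError(f"x must have exactly {N_MAIN} entries, got {len(vals)}")
            xv = dict(zip(self.labels, (float(v) for v in vals)))
        sex = sex.lower()
        timepoint = timepoint.lower()
        if sex not in _VALID_SEX:
            raise ValueError(f"unknown sex {sex!r}")
        if timepoint not in _VALID_TIMEPOINT:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        dummies = {
            "Male": 1.0 if sex == "male" else 0.0,
            "Morning": 1.0 if timepoint == "morning" else 0.0,
            "Afternoon": 1.0 if timepoint == "afternoon" else 0.0,
        }
        out = self.intercept
        for label, b in self.main_coefs.items():
            out += b * xv[label]
        for (label, dummy), c in self.interaction_coefs.items():
            out += c * xv[label] * dummies[dummy]
        return out

    def predict_micrograms(self, x, sex: str, timepoint: str) -> float:
        return float(to_micrograms(self.predict_log10_cortisol(x, sex, timepoint)))

    # -- introspection ------------------------------------------------------

    def model_card(self) -> dict:
        """Structural summary: term counts, labels and the printed columns."""
        mains = self._payload["main_terms"]
        inters = self._payload["interaction_terms"]
        return {
            "n_main": len(mains),
            "n_interactions": len(inters),
            "n_terms": len(mains) + len(inters),
            "n_coefficients": len(mains) + len(inters) + 1,
            "intercept": self._payload["intercept"],
            "main_terms": [
                {
                    "label": t["label"],
                    "compound": t["compound"],
                    "coef": t["coef"],
                    "ci95": t["ci95"],
                    "p_bh": t["p_bh"],
                    "rt1_s": t["rt1_s"],
                    "rt2_s": t["rt2_s"],
                    "ri": t["ri"],
                    "id_level": t["id_level"],
                }
                for t in mains
            ],
            "interaction_terms": [
                {
                    "label": t["label"],
                    "dummy": t["dummy"],
                    "compound": t["compound"],
                    "coef": t["coef"],
                    "ci95": t["ci95"],
                    "p_bh": t["p_bh"],
                }
                for t in inters
            ],
            "checksum": self.checksum(),
        }

    def checksum(self) -> str:
        blob = json.dumps(
            {
                "intercept": self.intercept,
                "main": self.main_coefs,
                "inter": {f"{a}:{b}": c for (a, b), c in self.interaction_coefs.items()},
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- cohort evaluation --------------------------------------------------

    def evaluate_on_cohort(
        self,
        z: pd.DataFrame,
        meta: pd.DataFrame,
        mapping: Mapping[str, str],
    ) -> pd.DataFrame:
        """Apply the frozen predictor to a standardized cohort matrix.

        ``mapping`` assigns each model variable x1..x14 a column of ``z``.
        Returns per-sample predicted log10 cortisol, predicted µg, observed
        values (when ``meta`` carries ``cortisol_ug``) and log10-scale
        residuals observed - predicted.
        """
        missing = [lab for lab in self.labels if lab not in mapping]
        if missing:
            desc = ", ".join(f"{m}/{self.compounds[m]}" for m in missing)
            raise ValueError(f"feature mapping is missing model variables: {desc}")
        meta = meta.loc[z.index]
        preds = np.array(
            [
                self.predict_log10_cortisol(
                    {lab: z.at[i, mapping[lab]] for lab in self.labels},
                    meta.at[i, "sex"],
                    meta.at[i, "timepoint"],
                )
                for i in z.index
            ]
        )
        out = pd.DataFrame({"predicted_log10": preds}, index=z.index)
        out["predicted_ug"] = to_micrograms(preds)
        if "cortisol_ug" in meta:
            obs = np.log10(meta["cortisol_ug"].to_numpy(dtype=float))
            out["observed_log10"] = obs
            out["residual_log10"] = obs - preds
            out["residual_ratio_ug"] = to_micrograms(out["residual_log10"].to_numpy())
        return out

    def map_by_retention(self, feature_meta: pd.DataFrame) -> dict[str, str]:
        """Map model variables to feature-table columns by retention matching.

        A column matches a model variable when |Δrt1| <= 2 s and
        |Δrt2| <= 0.2 s (the alignment windows); the closest rt1 wins.
        """
        mapping: dict[str, str] = {}
        for t in self._payload["main_terms"]:
            d1 = (feature_meta["rt1_s"] - t["rt1_s"]).abs()
            d2 = (feature_meta["rt2_s"] - t["rt2_s"]).abs()
            ok = (d1 <= RT_MATCH_TOL[0]) & (d2 <= RT_MATCH_TOL[1])
            if ok.any():
                mapping[t["label"]] = d1[ok].idxmin()
        return mapping


def load_published_model() -> PublishedModel:
    """Load the versioned coefficient JSON shipped with the package."""
    text = resources.files("cortivoc").joinpath("data/published_model.json").read_text()
    return PublishedModel(json.loads(text))
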