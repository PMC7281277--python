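#!/usr/bin/env python
"""Diagnostics and subgroup comparisons for the best-ranked model.

Re-fits the winning term set, emits residual/QQ/lag/drift data, VIFs (cutoff
5), normality and homoskedasticity backstops, the predicted-vs-observed CI
band, per-subgroup residual summaries with µg back-transforms, and the
Welch t-test family over the model metabolites at FDR 0.10.
"""

import json

import numpy as np
import pandas as pd

from cortivoc.cohort import read_cohort
from cortivoc.diagnostics import (
    compute_diagnostics,
    predicted_vs_observed,
    residual_summary,
    subgroup_ttests,
)
from cortivoc.model_select import build_design, fit_ols

meta, _ = read_cohort("results/cohort")
z = pd.read_csv("results/processed.csv", index_col=0)
kept = meta.loc[z.index]
factors = set(json.load(open("results/anova.json"))["factors"]) or {"sex", "time"}

ranking = pd.read_csv("results/model_comparison.csv")
best = ranking.iloc[0]["name"]
terms = json.load(open(f"results/fit_result_{best}.json"))["terms"]
print(f"best model: {best} with {len(terms)} terms")

dummy_labels = {"Male", "Morning", "Afternoon"}
mains = [t for t in terms if ":" not in t and t not in dummy_labels]
design = build_design(z, kept, mains or list(z.columns[:1]), factors)[terms]
y = np.log10(kept["cortisol_ug"].to_numpy())
fit = fit_ols(design, y)

diag = compute_diagnostics(fit, design, y, run_order=kept["run_order"].to_numpy())
print(f"adj R2 = {diag.adj_r2:.3f}")
print(f"max VIF = {max(diag.vif.values()):.2f} (cutoff 5) -> ok = {diag.flags['vif_ok']}")
print(f"Shapiro-Wilk p = {diag.shapiro_p:.3f} -> normal residuals = "
      f"{diag.flags['normal_residuals']}")
print(f"Breusch-Pagan p = {diag.breusch_pagan_p:.3f} -> homoskedastic = "
      f"{diag.flags['homoskedastic']}")

pvo = predicted_vs_observed(fit, design, y)
pvo.to_csv("results/predicted_vs_observed.csv")

summary = residual_summary(diag.residual, kept)
summary.to_csv("results/residual_summary.csv", index=False)
print("\nresidual summary by sex x timepoint (log10 scale and µg ratio):")
print(summary.round(3).to_string(index=False))

ttests = subgroup_ttests(z, kept, mains, fdr=0.10)
ttests.to_csv("results/subgroup_ttests.csv", index=False)
sig = ttests[ttests["significant"].fillna(False)]
print(f"\nsubgroup Welch t-tests: {len(ttests)} comparisons, "
      f"{len(sig)} significant at FDR 0.10")
if len(sig):
    print(sig[["feature", "comparison", "stratum", "p_bh"]].round(4).to_string(index=False))

with open("results/diagnostics.json", "w") as fh:
    json.dump(
        {"best_model": str(best), "flags": diag.flags, "vif": diag.vif,
         "adj_r2": diag.adj_r2, "shapiro_p": diag.shapiro_p,
         "breusch_pagan_p": diag.breusch_pagan_p},
        fh, indent=1,
    )
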