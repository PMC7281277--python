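#!/usr/bin/env python
"""Screen sex and time-of-day as interaction factors.

Two-way ANOVA with replication on log10 cortisol over the retained analysis
samples; factors significant at alpha = 0.05 are carried into the
interaction design downstream.
"""

import json

import pandas as pd

from cortivoc.factor_screen import anova_report, screen_factors, two_way_anova

kept = pd.read_csv("results/kept_meta.csv")
results = two_way_anova(kept)
factors = screen_factors(results, alpha=0.05)

print(f"{'factor':<10} {'SS':>9} {'df':>4} {'F':>8} {'p':>10}")
for r in results:
    print(f"{r.factor:<10} {r.ss:>9.4f} {r.df:>4d} "
          f"{r.F:>8.3f} {r.p:>10.4g}" if r.factor != "residual"
          else f"{r.factor:<10} {r.ss:>9.4f} {r.df:>4d}")
print(f"screened interaction factors (p < 0.05): {sorted(factors) or 'none'}")

with open("results/anova.json", "w") as fh:
    json.dump({"table": anova_report(results), "factors": sorted(factors)}, fh, indent=1)
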