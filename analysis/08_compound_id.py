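#!/usr/bin/env python
"""Retention indices and MSI identification levels for the cohort features.

Builds a synthetic C8-C20 alkane ladder consistent with the simulated
retention-time range, computes linear retention indices for every feature,
assigns MSI confidence levels from the available evidence (spectral match
only, in this synthetic setting), and demonstrates the level-1/2/3 evidence
routes on the published model's two standard-verified compounds.
"""

import pandas as pd

from cortivoc.cohort import read_cohort
from cortivoc.compound_id import (
    AlkaneLadder,
    CompoundAnnotation,
    annotate_table,
    assign_id_level,
    polarity_percent,
    retention_index,
)

# synthetic ladder spanning the simulated rt1 range (380-2380 s)
ladder = AlkaneLadder({n: 200.0 + 170.0 * (n - 8) for n in range(8, 21)})

_, table = read_cohort("results/cohort")
ann = annotate_table(table.feature_meta, ladder)
ann.to_csv("results/annotations.csv")
levels = ann["id_level"].value_counts().sort_index()
print("ID level distribution over cohort features (spectral evidence only):")
for lvl, cnt in levels.items():
    print(f"  level {lvl}: {cnt}")
print(f"extrapolated retention indices: {int(ann['ri_extrapolated'].sum())}")

# evidence routes on named compounds (experimental RIs as published)
pyrrole = CompoundAnnotation(
    name="Pyrrole", rt1_s=926.0, rt2_s=1.87, spectral_match=900.0,
    ri_experimental=833.0, ri_nonpolar_ref=750.0, ri_polar_ref=1500.0,
    standard_verified=True,
)
pct, ok = polarity_percent(pyrrole.ri_experimental, 750.0, 1500.0)
print(f"\npyrrole: RI = {pyrrole.ri_experimental:.0f}, polarity {pct:.1f}% "
      f"(window 5-35%: {ok}) -> level {assign_id_level(pyrrole).id_level}")

dodecane = CompoundAnnotation(
    name="4,6-Dimethyl-dodecane", rt1_s=1784.0, rt2_s=0.56,
    spectral_match=850.0, ri_experimental=1246.0, ri_nonpolar_ref=1250.0,
)
print(f"4,6-dimethyl-dodecane: non-polar support only -> "
      f"level {assign_id_level(dodecane).id_level}")
unknown = assign_id_level(
    CompoundAnnotation(name="hit", rt1_s=512.0, rt2_s=1.47, spectral_match=644.0)
)
print(f"spectral match 644/1000 -> level {unknown.id_level}, name {unknown.name!r}")
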