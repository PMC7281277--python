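#!/usr/bin/env python
"""Bootstrapped elastic-net stability selection.

100 iterations of subject-level 80/20 train/test splits (scaled down from
the canonical 250 for a quick desk run; pass --iters to change); per
iteration the penalty minimizing held-out MSE decides the selected set.
Writes per-feature selection frequencies and reports how the planted
support ranks.
"""

import argparse

import pandas as pd

from cortivoc.cohort import read_cohort, read_truth
from cortivoc.selection import SelectionConfig, bootstrap_select, top_k

parser = argparse.ArgumentParser()
parser.add_argument("--iters", type=int, default=100)
args = parser.parse_args()

SEED = 20260927

meta, _ = read_cohort("results/cohort")
truth = read_truth("results/cohort")
z = pd.read_csv("results/processed.csv", index_col=0)

config = SelectionConfig(n_iter=args.iters, seed=SEED + 1, include_factors=True)
freq = bootstrap_select(z, meta.loc[z.index], config)
freq.to_frame().to_csv("results/selection_frequency.csv")

frame = freq.to_frame().sort_values("count", ascending=False)
print(f"{args.iters} iterations; mean model size "
      f"{freq.counts.sum() / freq.n_iter:.1f} features")
print("top 10 by selection frequency:")
print(frame.head(10).to_string())

for k in (25, 35, 50):
    subset = set(top_k(freq, k))
    hit = len(subset & set(truth.support))
    print(f"planted support in top-{k}: {hit}/{len(truth.support)}")
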