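#!/usr/bin/env python
"""Colocalization of two traits over a +/-50 kb region: shared causal
variant, distinct causal variants, and a null region, each summarized by
the five posterior probabilities PP.H0-PP.H4.

Writes results/coloc_results.tsv.
"""

import os

import pandas as pd

import mrtriad as m

os.makedirs("results", exist_ok=True)

rows = []
scenarios = [
    ("shared_causal_variant", dict(shared=True)),
    ("distinct_causal_variants", dict(shared=False)),
    ("null_region", dict(shared=True, causal_beta=0.0)),
]
for name, kw in scenarios:
    region, truth = m.simulate_coloc_region(config=m.SimConfig(seed=42), **kw)
    res = m.coloc_posteriors(region)
    rows.append({"scenario": name, "n_variants": res.n_variants,
                 **{k: round(v, 4) for k, v in res.pp.items()}})

table = pd.DataFrame(rows)
table.to_csv("results/coloc_results.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print("\npriors: p1 = p2 = 1e-4, p12 = 1e-5; n = 50,000 per trait, "
      "200 variants, AR(1) LD rho = 0.9")
print("wrote results/coloc_results.tsv")
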