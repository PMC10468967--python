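#!/usr/bin/env python
"""Multivariable MR: adjust a mostly-mediated exposure for its mediator and
show the attenuation of its direct effect (univariate vs adjusted rows,
with OR and 95% CI).

Writes results/mvmr_results.tsv.
"""

import os

import pandas as pd

import mrtriad as m

os.makedirs("results", exist_ok=True)

# exposure_02 acts on the outcome almost entirely through exposure_01
cfg = m.SimConfig(n_exposures=2, n_causal=1, theta_causal=0.5,
                  k_min=15, k_max=15, n_satellites=0, n_null_variants=5,
                  chains=((1, 0, 0.6),), eaf_range=(0.3, 0.7),
                  instrument_effect_range=(0.08, 0.13),
                  outcome_n=2_000_000, case_fraction=0.3, seed=31)
study = m.simulate_exposure_outcome(cfg)

uni = m.run_univariable_mr(study.exposures["exposure_02"], study.outcome,
                           study.ld, levels=["e5"])[0]
adj = m.mvmr_adjusted_effect("exposure_02", ["exposure_01"],
                             study.exposures, study.outcome, study.ld)

rows = []
for label, r in (("univariate", uni), ("adjusted_by_exposure_01", adj)):
    rows.append({"status": label, "beta": round(r.beta, 3), "se": round(r.se, 3),
                 "or": round(r.or_, 3), "ci_low": round(r.ci_low, 3),
                 "ci_high": round(r.ci_high, 3), "p": round(r.pval, 4)})
table = pd.DataFrame(rows)
table.to_csv("results/mvmr_results.tsv", sep="\t", index=False)
print(table.to_string(index=False))
truth_total = study.truth.theta_total["exposure_02"]
print(f"\ntruth: total effect {truth_total:.2f}, direct effect "
      f"{study.truth.theta_direct['exposure_02']:.2f} - adjusting for the "
      f"mediator should leave no significant direct effect")
print(f"attenuation: |beta| {abs(uni.beta):.3f} -> {abs(adj.beta):.3f}; "
      f"p {uni.pval:.4f} -> {adj.pval:.3f}")
print("wrote results/mvmr_results.tsv")
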