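"""Differential-feature selection with PLS and VIP scores.

Plants 20 features with a 2-sigma log2 co-culture shift among 500 and checks
how many the PLS-VIP selector (components tuned by CV, 0.95 VIP quantile)
recovers.
"""

import warnings

import phycomet as pm

warnings.simplefilter("ignore")

cfg = pm.GeneratorConfig(n_features=500, n_differential=20, effect_size=2.0,
                         zero_inflation=0.0, exchange_design={},
                         design_seed=0, noise_seed=1)
table, pheno, truth = pm.generate_feature_dataset(cfg)

cols = pheno.samples_for(species="SM", compartment="exo")  # 8 mono vs 4 co
X = pm.log_transform(table).intensities[cols].T
sel = pm.select_features(X, pheno.table.loc[cols, "culture"],
                         components=5, tune_length=10, quantile=0.95, seed=0)

planted = set(truth.differential[("SM", "exo")])
hits = planted & set(sel.selected)
print(f"components used (CV-tuned, capped at 5): {sel.n_components}")
print(f"VIP threshold (0.95 quantile): {sel.threshold:.3f}")
print(f"selected features: {len(sel.selected)}  (planted: {len(planted)})")
print(f"planted features recovered: {len(hits)}  "
      f"sensitivity = {len(hits) / len(planted):.2f}")
print(f"direction counts: {sel.direction.value_counts().to_dict()}")

print(
    "\nReading: VIP > the 0.95 quantile keeps ~25 of 500 features; most "
    "planted co-culture-shifted features rank above the threshold and are "
    "flagged co-enriched (their class mean is higher in co-culture)."
)
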