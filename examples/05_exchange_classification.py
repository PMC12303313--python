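"""Metabolic-exchange classification of differential co-culture features.

For each planted differential feature of the haptophyte's co-culture
endometabolome, looks up its presence across the diatom partner's conditions
and assigns an exchange category.
"""

import warnings

import phycomet as pm

warnings.simplefilter("ignore")

cfg = pm.GeneratorConfig(noise_sd=0.0, zero_inflation=0.0, design_seed=0, noise_seed=0)
table, pheno, truth = pm.generate_feature_dataset(cfg)
transformed = pm.log_transform(table)
cutoff = pm.estimate_presence_cutoff(transformed.intensities)
presence = pm.to_presence_matrix(transformed, cutoff)
cond = pm.condition_presence(presence, pheno, min_fraction=0.5)

for focal, partner in (("PP", "SM"), ("SM", "PP")):
    cats = truth.exchange_categories[focal]
    results = pm.classify_exchange(sorted(cats), cond, focal=focal)
    summary = pm.summarize_exchange(results)
    recovered = sum(r.category == cats[r.feature_id] for r in results)
    print(f"\nfocal {focal} (partner {partner}): {len(results)} differential "
          f"endometabolome features")
    print(summary)
    print(f"planted categories recovered: {recovered}/{len(results)}")

print(
    "\nReading: EXCLUSIVE_CO features are made only in co-culture; "
    "PARTNER_RELEASED ones sit in the partner's mono-culture exometabolome "
    "(released, then taken up); PARTNER_ENDOGENOUS in its endometabolomes; "
    "SHARED_ALL everywhere. On noise-free data the planted partition "
    "(7/10/6/7 for the haptophyte) is recovered exactly."
)
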