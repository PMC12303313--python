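"""Feature-table preprocessing and chemodiversity.

Generates a synthetic LC-MS feature table (2 species x endo/exo x mono/co),
log2-transforms it, fits the 5% normal lower-tail presence cutoff, and
reports the Shannon index H' per sample origin.
"""

import warnings

import phycomet as pm

warnings.simplefilter("ignore")

table, pheno, truth = pm.generate_feature_dataset(pm.GeneratorConfig(design_seed=1, noise_seed=2))
transformed = pm.log_transform(table)  # log2; zeros stay 0 (missing code)
cutoff = pm.estimate_presence_cutoff(transformed.intensities, q=0.05)
presence = pm.to_presence_matrix(transformed, cutoff)

print(f"features x samples: {table.intensities.shape}")
print(f"presence cutoff (log2 intensity, 5% lower tail): {cutoff:.3f}")

print("\nShannon chemodiversity per sample origin (union pooling, nats):")
for r in pm.group_diversity(presence, pheno):
    print(f"  {r.species} {r.compartment:4s} {r.culture:4s}  "
          f"H' = {r.h_prime:.3f}  richness = {r.richness}")

print(
    "\nReading: with union pooling H' = ln(richness); co-culture origins "
    "score higher than their mono-culture counterparts because the generator "
    "plants extra co-culture-only features (the exchanged metabolites)."
)
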