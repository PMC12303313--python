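"""Growth-curve statistics: two-way ANOVA and per-day Welch tests.

Builds the synthetic fluorescence table (8 mono + 4 co replicates per
species, days 0-8) and asks whether co-culturing changed growth.
"""

import phycomet as pm

series = pm.s1_style_growth_table()
tables = pm.growth_statistics(series)

for sp, label in (("SM", "diatom (S. marinoi-like)"), ("PP", "haptophyte (P. parvum-like)")):
    anova = tables[f"anova_{sp}"]
    welch = tables[f"welch_{sp}"]
    print(f"\n=== {label} ===")
    print(anova.round(4))
    print(f"condition p-value: {anova.loc['sample', 'p']:.3g} "
          f"({'significant' if anova.loc['sample', 'p'] < 0.05 else 'not significant'} at 0.05)")
    print("per-day Welch p-values (mono vs co):")
    print(welch["p"].round(4).to_string())

print(
    "\nReading: the diatom's chlorophyll-a fluorescence is suppressed across "
    "the whole experiment (condition p << 0.05), while the haptophyte shows "
    "no overall condition effect (p > 0.05) but a significant day-8 "
    "difference - the planted late co-culture response."
)
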