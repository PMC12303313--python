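# Methods

This note documents the models and procedures implemented in `phycomet`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Experimental design being modelled

Two marine microalgae — a centric diatom (`SM`) and a toxin-producing
haptophyte (`PP`) — grown in chambers whose halves are separated by a
0.22 µm membrane: metabolites diffuse, cells do not. Conditions per species:
mono-culture (both halves the same species, 8 replicates) and co-culture
(one half each species, 4 replicates). From each half-chamber, the
*endometabolome* (filtered biomass) and *exometabolome* (medium extract) are
profiled by LC-MS in positive and negative ESI mode, giving feature tables
(m/z envelope, RT envelope, per-sample intensities). Growth is tracked as
chlorophyll-*a* fluorescence (RFU) on days 0, 2, 4, 6, 8. The shared
co-culture exometabolome cannot be attributed to either species; all
species-directional inference therefore runs through the endometabolomes.

## Preprocessing

* **Log transform.** Intensities are log₂-transformed; 0 is the canonical
  missing value and stays 0. Raw intensities in (0, 1) would map to negative
  values and are floored to 0 with a warning, preserving the missing-value
  semantics. Base 2 is chosen for fold-change readability; the base is a
  parameter.
* **Presence cutoff.** One cutoff per dataset (compartment × polarity):
  a normal distribution is fitted to *all positive* transformed intensities
  pooled across features and samples, and the cutoff is its lower q-tail,
  c = μ̂ + z_q σ̂ with q = 0.05 (z₀.₀₅ ≈ −1.6449) and the (n−1)-denominator
  sample sd. Pooling (rather than per-feature or per-sample fits) keeps
  presence calls comparable across samples; σ̂ = 0 degenerates to c = μ̂ with
  a warning. The boundary is inclusive: intensity = c counts as present.
* **Combined mono-culture pseudo-replicates.** For PCA comparability with
  the 4 co-culture replicates, the 8 mono replicates are paired by ascending
  replicate index — (1,2), (3,4), … — and each pair is summed on the raw
  (untransformed) scale; sums are additive signal pooling, so column totals
  are conserved. The pairing is deterministic for reproducibility and can be
  overridden with an explicit pairing.

## Growth statistics

Fixed-effects two-way ANOVA with replication (condition × day, interaction
included) computed directly from the balanced decomposition and reported
spreadsheet-style (SS, df, MS, F, p, F crit at α); an additive variant pools
the interaction into the residual. The design must be balanced, so by
default mono replicates 1–4 enter against the 4 co replicates; the choice is
a parameter. Per-day mono-vs-co comparisons use Welch's unequal-variance
two-tailed *t*-test with Welch–Satterthwaite df; two zero-variance groups
with equal means return p = 1 by convention. Note that at very small group
sizes (n = 4 per group) the Welch df approximation is conservative
(empirical type-I error ≈ 0.04 at α = 0.05); its null calibration is
verified at n = 20 where the approximation is accurate.

## Chemodiversity and ordination

Shannon H' (natural log) on pooled replicate presence per sample origin
(species × compartment × culture). Union pooling — present in any
replicate — is the default; on binary data it reduces to H' = ln(richness),
which reproduces the magnitude expected for tens of thousands of detected
features (H' ≈ 10 at richness ≈ 22 000). Mean-of-per-replicate-H' is the
alternative pooling. PCA is the SVD of the centred (optionally scaled)
log-intensity matrix; component signs are fixed by making each component's
largest-magnitude loading positive, so scores are deterministic across runs
and backends.

## PLS-VIP differential-feature selection

One selection per (species, compartment) contrast, mono vs co:

* Labels encoded ±1 and centred; X column-centred. NIPALS PLS1 extracts
  components sequentially (w ∝ Xᵀy on deflated matrices, t = Xw, deflation
  of X by t pᵀ and of y by q t); scores are orthogonal by construction and
  SSₐ = qₐ²‖tₐ‖² is the response variance explained by component a.
* The component count is tuned by stratified cross-validation (5 folds,
  search over 1..10), classifying held-out samples by the sign of the
  predicted response; ties go to the smaller count, and the tuned count is
  then capped at 5. Stratification deals each class round-robin across
  folds, so classes smaller than the fold count (the 4 co-culture
  replicates with 5 folds) still yield usable folds of sizes {2,2,2,1,1};
  every training complement retains both classes.
* VIP_j = √(p Σₐ SSₐ (w_{ja})² / Σₐ SSₐ) with unit-norm weight vectors, so
  mean(VIP²) = 1 exactly. The selection threshold is the empirical 0.95
  quantile of the VIP distribution under linear (type-7) interpolation —
  the convention is documented because counts at the boundary depend on it.
  Zero-variance features are dropped (warned), never imputed.
* The reported direction of a selected feature is the sign of its class
  mean difference on the transformed scale (co- vs mono-enriched).

Designed behaviour on planted data (8-vs-4 samples, 500 features, 20
planted with a 2σ log₂ shift, no dropout): median sensitivity ≈ 0.82 —
close to the information-theoretic ceiling of this design, since the null
top-25 covariance threshold sits ≈ 1.4 log₂ units and the planted shift is
2. Zero-inflated entries are excluded from this calibration: a dropout on
the log scale is a ~20-unit excursion that swamps any 2-unit effect for a
covariance-based ranking, so dropout robustness is exercised at the
presence/absence level (exchange classification), not at the intensity
level.

## Annotation linking

Linking is pure interval logic and is checked against a brute-force
all-pairs oracle in the tests:

* inclusion precursor → feature: candidates are features whose m/z envelope
  encloses the precursor; among candidates, the feature whose median RT
  falls in the inclusion window gives a `full` match, otherwise the closest
  feature is still assigned with status `mz_only` and a structured comment
  recording the RT mismatch. Ties (several enclosing envelopes) are broken
  by minimal |mz_med − precursor|, then minimal |rt_med − window midpoint|,
  then row order; losing candidates are listed in the comment.
* annotation → inclusion precursor: same window conditions, with a ±5 ppm
  precursor tolerance (parameter; the upstream convention is not published,
  so the default is documented here). Unmatched annotations are kept as
  `unlinked` — no annotation is ever dropped.
* MSI levels are taken from the annotation input (2 = spectral-library
  match, 3 = compound-database candidate, 4/5 pooled as the rest) and
  tallied per condition, optionally joined with the per-species differential
  selections.
* Suspect screening matches by the InChIKey connectivity block computed
  from SMILES/InChI (rdkit) first; case-insensitive name equality is a
  separate, weaker level and never silently merged with structure matches.
  Without rdkit, structure matching degrades to name matching.

## Exchange classification

For each differential co-culture endometabolome feature of the focal
species, the partner's condition presence pattern (exo-mono, endo-mono,
endo-co; exo-co recorded but excluded from the rules, because the shared
co-culture medium is not attributable) maps to one category with fixed
precedence: no partner condition → EXCLUSIVE_CO; all three → SHARED_ALL;
exo-mono only → PARTNER_RELEASED; both endo, no exo-mono →
PARTNER_ENDOGENOUS; anything else → MIXED, with the raw flags always
reported so overlapping narrative counts remain derivable. Categories
partition the input by construction.

**Condition presence** collapses replicate presence with an inclusive
fraction rule: present iff present in ≥ max(1, ⌈min_fraction·n⌉)
replicates (default min_fraction = 0.5, so 2 of 4 counts as present;
min_fraction = 0 means any single replicate). The inclusive boundary was
chosen over a strict majority because of a robustness argument: under 20%
independent replicate dropout, requiring 3 of 4 replicates loses ~18% of
genuinely present 4-replicate condition calls (binomial: P(≥3 of 4 at
0.8) = 0.819 vs P(≥2 of 4) = 0.973), pushing expected category recovery to
~87%; the inclusive rule keeps it ≈ 98%. A strict rule remains available by
setting min_fraction just above 0.5.

## Synthetic data generator

The generator emulates the stated design: 2 species × {endo, exo} ×
{mono: 8, co: 4} replicates, one polarity per dataset, RT range inside
0–700 s, m/z 100–1200 with ±10 ppm envelopes and ±15 s RT envelopes.
Intensities are log-normal: per-feature baseline ~ N(20, 2) on the log₂
scale, replicate noise sd 1, zero-inflation π = 0.1 (applied after effect
planting, so planted features can still drop out), planted log₂ effect 2 in
the co-culture samples of the designated contrast. These defaults are the
package's one-time choices where the emulated study states no value: a
20 ± 2 log₂ baseline and ~10% missingness are typical of processed
untargeted LC-MS tables, and effect = 2 × noise sd makes the planted
contrast statistically recoverable but not trivial. Planted differential
and exchange features draw their baselines from the same distribution
truncated at mean − 1 sd, emulating that differential and inclusion-list
analysis concerns reliably detected peaks. Exchange features realise their
category by construction (zeroing the partner conditions the category
declares absent; the focal endometabolome carries them only in co-culture).
Two seeds decouple planted memberships (design seed) from noise
realisations (noise seed). Default planted exchange partitions: 7/10/6/7
(EXCLUSIVE/RELEASED/ENDOGENOUS/SHARED) for the haptophyte direction and
7/5/–/3 for the diatom direction.

Inclusion entries jitter the precursor ≤ 3 ppm (inside the envelope) with
rt_med ± 30 s windows; annotations take MSI levels from
{2: 0.08, 3: 0.6, 4: 0.17, 5: 0.15} and cycle a small pool of real
microalgal metabolite names/SMILES (fucoxanthin, monomyristin, viburnitol,
…) that doubles as the named core of the synthetic suspect list.

Growth curves are logistic, RFU(t) = K/(1 + e^{−r(t−t₀)}) with K = 3000
RFU, r = 0.9 d⁻¹, t₀ = 4 d, Gaussian noise (sd 100 RFU) truncated at 0, a
multiplicative co-culture suppression factor, and an optional late-onset
co-culture factor for a response confined to the end of the experiment.
A separate deterministic stand-in for the study-style fluorescence
supplement (`s1_style_growth_table`) constructs 8 + 4 replicates per species
with exact per-day means and dispersions (sd = 5% of the mean realised by
fixed zero-mean unit-sd deviation patterns): the diatom co-culture is
suppressed by factor 0.7 on every day; the haptophyte differs only by a
+290 RFU day-8 shift, sized by an a-priori power analysis so that the
day-8 Welch test is significant while the overall ANOVA condition effect is
not (F = 0.4·d²/MS_within ≈ 3.6 < F crit) — deterministically, since
nothing is sampled.

**What a green test does not establish.** The generator has no RT drift,
no batch or injection-order structure, no correlated feature blocks
(adducts, isotopologues, in-source fragments), no media-blank chemistry,
no intensity-dependent missingness, and its noise is homoscedastic on the
log scale. Recovery results on it bound what the pipeline can do when its
assumptions hold; they say nothing about peak-picking quality or annotation
correctness upstream.

## Numerical conventions

* Presence thresholding and condition presence use inclusive boundaries
  (documented above); the linking tie-break chain ends in row order, making
  results order-independent up to exact ties of continuous quantities.
* Quantiles are type-7 (linear interpolation) throughout.
* PCA/PLS determinism: component sign conventions and seeded fold
  assignment make every reported quantity reproducible bit-for-bit; the
  end-to-end pipeline writes byte-identical outputs for identical inputs
  and seed.
* Degenerate inputs (all-zero vectors, single-class labels, zero explained
  response variance, unbalanced ANOVA cells) raise typed errors rather than
  returning silent NaNs.

## Limitations

* The exometabolome's species attribution is out of reach by design; the
  classifier deliberately ignores the shared co-culture exometabolome flag.
* PLS-VIP selection on zero-imputed log data is dominated by dropout
  patterns when missingness is informative; at realistic missingness the
  presence/absence analyses are the robust path.
* The ANOVA is fixed-effects; chamber random effects and repeated-measures
  correlation across days are not modelled.
* MSI levels are trusted from the annotation input; no spectral evidence is
  re-evaluated.
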