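# Methods

## The measurement and its model

In situ brain perfusion replaces the cerebral blood supply with an artificial
perfusate delivered through the carotid artery, so that the concentration of a
test tracer at the luminal face of the blood–brain barrier (BBB) is known and
constant.  After a short perfusion (120 s for the test tracer here; 60 s for
the flow marker) the animal is decapitated, brain structures (cerebrum,
cerebellum, brainstem) are dissected, and each specimen is counted for two
isotopes: the test tracer and a co-perfused vascular marker
([¹⁴C]-sucrose) that does not cross an intact BBB.

Per dissected tissue the package computes, in fixed units
(dpm g⁻¹, dpm µL⁻¹, s, µL g⁻¹, µL s⁻¹ g⁻¹):

| quantity | definition | meaning |
|---|---|---|
| V_v | X\*/C\*_perf | vascular (sucrose) space, µL g⁻¹; doubles as a BBB-integrity readout |
| X_tissue | X_tot − V_v·C_perf | tracer amount net of what merely sat in the vessels |
| V_tissue | X_tissue/C_perf | apparent distribution volume, µL g⁻¹ |
| K_in | V_tissue/T | initial (unidirectional) transport clearance, µL s⁻¹ g⁻¹ |
| E | 100·K_in/F | extraction, % of the regional perfusion flow F |

F is estimated per (region, species) as the mean K_in of animals perfused with
a ~100 %-extracted flow marker (diazepam), never pooled across regions or
species because flow differs among brain structures.  E < 30 % is treated as
flow independent; at or above 30 % the sample is flagged `flow_dependent`.
The single-time-point design assumes uptake is still in its linear phase at
120 s; no multi-time-point regression is attempted.

### Negative corrected amounts

Counting noise can push a low-uptake specimen below its own vascular
background, making X_tissue negative.  The signed value is retained for
diagnostics, the reported V_tissue (and hence K_in) is clamped at zero, and
the sample carries the `below_vascular_background` flag.  Silent negatives
would corrupt group means; silent zeros would hide the event.  A missing flow
reference is likewise an explicit `missing_flow_reference` flag with E absent
— E = 0 is a meaningful value and is never used as a placeholder.

## Synthetic-data generator

No raw scintillation data accompany the reference experiments, so the
generator is a first-class, tested component that stands in for them with
known ground truth.  It emulates the study design: design cells
(group × treatment × n animals) crossed with the three regions, flow-marker
animals per region at 60 s, and sucrose co-perfusion in every sample.

Generation physics, per animal:

1. **Efflux.** Apparent permeability
   `PS_app = PS_passive / (1 + Σ_t a_t · g_t · (1 − i_t))`, with activity
   a_t ≥ 0 per transporter, genotype indicator g_t (0 for a knockout) and
   fractional inhibition i_t ∈ [0, 1] by the co-perfused treatment.  The
   divisor form keeps PS_app > 0 for any parameters and makes a knockout
   exactly equivalent to complete inhibition.  A subtractive clearance form
   was rejected because it can go negative.
2. **Uptake.** Crone–Renkin single-capillary relation
   `K_in = F · (1 − exp(−PS_app/F))`: low-PS tracers are flow independent
   (K_in ≈ PS_app), the flow marker (PS_app = 50·F by default) is flow
   limited (E ≈ 100 %).
3. **Biological variability.** Independent mean-one lognormal factors
   (default CV 25 %, matching the magnitude of reported group SDs such as
   0.10 ± 0.03) on each animal's K_in and V_v.
4. **Counting noise.** Poisson on the total counts of each isotope in the
   weighed specimen (default mass 0.4 g), at dpm scales from the reference
   tracer levels (test tracer ≈ 660, sucrose ≈ 222 dpm µL⁻¹).  Specimen
   masses and raw count magnitudes are not reported in the reference work;
   the defaults are chosen so relative counting error is small next to the
   biological CV, and are config, not claims.  An optional constant
   background (default 0) can be added to both isotopes.

Both noise layers switch off independently, which is what makes exact
noiseless inversion (pipeline output = ground truth) a meaningful test.

Seeding is counter-based: each sample's generator derives from
(root seed, sample index), so row order never changes any animal's draws.

### Default physiology

Regional flows are back-calculated from the reported control clearances and
extractions of the test tracer (E ≈ 0.5 / 2 / 0.6 % at K_in ≈ 0.18 / 0.10 /
0.09 µL s⁻¹ g⁻¹ for cerebrum / cerebellum / brainstem), giving
F ≈ 36 / 5 / 15 µL s⁻¹ g⁻¹ — i.e. cerebrum > brainstem > cerebellum.  Default
vascular volumes put cerebellum and brainstem above cerebrum (16 / 14 /
10 µL g⁻¹), the physiologically expected ordering.  Passive permeabilities
are set as `PS_passive = D · (−F·ln(1 − E/100))` with D the control efflux
denominator, so the control operating point sits at extractions of
~0.55 / 1.8 / 0.65 % — inside the observed 0.5–2 % regime with margin for
the Crone–Renkin compression.

Transporter activities (rat: P-gp 0.6, Bcrp 0.6, Mrp 1.5, plus an
elacridar-sensitive "third" transporter 3.3; mouse: 1.0 / 1.0 / 0.2 / 1.7)
were chosen to preserve the qualitative structure of the reference results:
single P-gp or Bcrp inhibition ≈ no effect, dual inhibition with elacridar a
large increase, MRP inhibition a smaller increase, and the mouse ordering
WT < TKO < TKO + elacridar that implicates a third elacridar-sensitive
transporter still present in the triple knockout.  A limitation is inherent
to any single-divisor model: the reported elacridar (~8×) and MK-571 (~3×)
folds cannot both be reproduced from one shared control denominator — if MRP
activity is large enough for a 3× MK-571 fold, the remaining denominator
caps the elacridar fold well below 8×.  The observed effects are
super-additive in a way the model deliberately does not capture; rank order,
not fold magnitude, is the modeled claim.

The simulator also deliberately omits: spatial capillary heterogeneity,
tracer metabolism within the perfusion window, plasma-protein binding, and
tumor-compartment uptake.  It uses a single perfusate concentration for test
tracer and flow marker (the real experiments used 0.011 vs 0.01 MBq mL⁻¹);
this only rescales dpm and cancels in every derived quantity.  Passing
recovery tests therefore show the estimator chain is correct under the
modeled noise, not that real tissue obeys the single-capillary model.

## Statistical layer

Summaries are mean ± SD (n−1).  Two groups: unpaired Student t-test (pooled
variance, as in the reference analysis; Welch behind a flag).  Three or more:
one-way ANOVA, then Tukey HSD adjusted pairwise p-values (Tukey–Kramer for
unbalanced groups, which the n = 4–10 designs require).  α = 0.05 throughout.
Where the reference work reports two-way ANOVA across strata, this package
applies one-way ANOVA within each stratum; interaction terms are out of
scope and never reported.

`anova_tukey` also returns the unadjusted pairwise p-values computed in the
same pooled-variance frame (Fisher LSD, df = N−k).  In that frame
"adjusted ≥ raw" is a theorem of the studentized-range construction; against
two-sample t-tests with per-pair variances it can fail under variance
heterogeneity, which is why the raw values are provided in-frame.

### Fold-change confidence intervals

Inhibitor and genotype effects are reported as the ratio of group mean K_in.
The reference work prints folds without uncertainty; the CI is this package's
addition.  The default interval is a **studentized bootstrap (bootstrap-t) on
the log fold-change**: animals are resampled with replacement within each
group (stratified), each resample's log fold is studentized by its
delta-method standard error

`SE² = s²_ref/(n_ref · m²_ref) + s²_test/(n_test · m²_test)`,

and the quantiles of the studentized distribution are inverted around the
observed log fold.  The plain percentile interval is available via
`method="percentile"` but is not the default: at the study's own group sizes
(n = 5) its simulated 95 % coverage is ~86–89 %, the textbook first-order
undercoverage, while the studentized interval (second-order accurate) sits at
~94 %.  When the studentized interval is degenerate (zero within-group
variance) the percentile interval is used, which correctly collapses to a
point for constant data.  Default 10,000 resamples, seeded.

## Proteomics quantification

Isotope-dilution MRM quantification works from exported light/heavy peptide
area ratios; peak picking and transition selection are upstream.  A
calibration line of area ratio on known on-column amount is fitted by
weighted least squares, default weighting 1/x (the standard choice for
wide-range isotope-dilution curves; "none" gives OLS).  An accepted curve
must have positive slope.  The LOQ is operational: the lowest standard whose
back-calculated amount lies within ±20 % of nominal (replicate standards are
averaged per level first).  Back-calculated amounts below the LOQ — including
negative ones — are rendered as the token `<LOQ`, never as a number, and
concentrations are reported in fmol per µg of digested protein.  Replicate
measurements are emitted per-row rather than pre-aggregated, so downstream
consumers choose their own rounding.  A per-peptide `species_specificity`
attribute passes through to reports, preserving caveats about peptides shared
between species orthologs (e.g. human/rat BCRP).

The synthetic MRM generator draws area ratios from a latent linear response
with mean-one multiplicative lognormal noise, making the generate → fit →
quantify round trip exactly invertible at zero noise and unbiased under
noise.

## Numerical and design notes

- Floats are written with `%.17g` and read back with round-trip parsing, so
  report round trips are bit-exact; reports contain no timestamps and are
  byte-identical across reruns of identical inputs.
- The flow-dependence threshold is exactly 30 %, with ≥ 30 % flagged
  dependent.
- Strict monotonicity of the Crone–Renkin curve in PS holds numerically only
  below PS/F ≈ 30; beyond that the exponential saturates to double
  precision.  The flow marker's default PS/F = 50 exploits exactly this
  plateau.
- Region vocabulary is closed (cerebrum, cerebellum, brainstem) with an
  `other:<name>` escape hatch; species and tracer vocabularies are closed.
  The reader assumes per-gram dpm values are provided upstream (wet-weight
  normalization happens at the counter).
- Problem sizes in the test suite and acceptance script (e.g. 200 replicate
  studies with 1,000 inner bootstrap resamples for coverage, 10,000 null
  replicates for ANOVA calibration, 10,000-sample law-of-large-numbers
  checks) were chosen so Monte-Carlo error is several times smaller than the
  effects being checked while a full run stays in the tens of seconds.
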