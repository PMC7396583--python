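# Methods

## Study design assumed by the pipeline

Two peanut genotypes with contrasting cold tolerance (a tolerant and a
sensitive cultivar) are sampled at 0, 12 and 24 h of 6 °C cold stress, with
control plants held at normal temperature sampled at every timepoint, three
biological replicates per cell for expression and physiology and six for
lipidomics. Differential expression is always cold versus the
same-timepoint control within a genotype; the 0-h samples are a shared
baseline and are not used as a stress contrast.

## Physiological indices

EL, MDA and chlorophyll follow the standard assay formulas (see README).
Negative computed MDA or chlorophyll values indicate assay problems and are
reported as computed with a QC warning, never clamped, so problems surface
rather than hide. Relative change is always computed on group means and
reported at 4 decimal places in output tables (internal values keep full
precision). The genotype contrast per timepoint uses Welch's
unequal-variance t-test by default; the classic pooled-variance test is a
switch (`welch=False`) for users who want the textbook variant. Cells with
fewer than two replicates are flagged and excluded from testing.

## Differential-expression set construction

* **Expressed filter.** FPKM ≥ 1, evaluated by default on
  (genotype, timepoint, condition) replicate means, a gene being retained
  if any group passes. This is the most inclusive defensible reading of a
  bare "FPKM ≥ 1" criterion; `any-sample` and `all-samples` scopes are
  config options.
* **DE call.** Fold change is (mean cold + ε)/(mean control + ε) with
  ε = 0.01 FPKM guarding zero means (configurable). The p-value is a
  two-sample t-test on log₂(FPKM+1); FDR is Benjamini–Hochberg within each
  (genotype, timepoint) contrast. A gene is `up` iff FC ≥ 2 and FDR < 0.01,
  `down` iff FC ≤ 1/2 and FDR < 0.01. This simple engine deliberately
  replaces the read-alignment-era toolchain such data were originally
  processed with; genome-wide gene counts therefore depend on the engine
  and are not comparable across engines — only the set algebra downstream
  of the per-gene labels is the reusable analysis, and that is what the
  tests pin down. Degenerate zero-variance groups are resolved by the group
  means (different → p = 0, equal → p = 1) so zero-noise simulations behave
  deterministically.
* **CDEG detection.** Default mode `any` (differential at ≥ 1 stress
  timepoint); mode `all` (every stress timepoint) is exposed because the
  name "continuously differentially expressed" suggests the stricter
  reading. Genes differential in opposite directions at different
  timepoints are labelled `conflict` rather than silently assigned.
* **Enhancement.** A common CDEG is "enhanced" when
  |log₂FC_tolerant| − |log₂FC_sensitive| ≥ log₂(2) at a qualifying
  timepoint with direction agreement in both genotypes; ties at exactly
  2-fold are inclusive. Magnitudes (not signed ratios) are compared so that
  a stronger *down*-regulation in the tolerant genotype also qualifies;
  direction agreement excludes sign-discordant pairs, whose "ratio" is not
  meaningful.
* **Putative set.** tolerant_only ∪ enhanced_common; the parts are disjoint
  by construction, so its size is their sum.

## Lipidomics

* **Nomenclature.** Three dialects are parsed: total-composition
  (`C36:6-MGDG`), per-chain (`18:2/16:1-DAG`), and sphingolipid
  (`d18:1/24:0-Cer`, `t18:1/h22:0-GluCer`). Backbone letters are flags:
  `d`/`t` mark di-/tri-hydroxy long-chain bases and `h` a hydroxylated acyl
  chain; they are excluded from carbon counts, while backbone desaturation
  (the `:1` of `d18:1`) does count as a double bond.
* **DBI.** The double-bond index per class is the concentration-weighted
  double-bond count with the weight taken over the *whole* membrane panel:
  DBI_class = Σ_species n_db · c̄ / c̄_panel-total. The within-panel (rather
  than within-class) denominator is the formulation under which per-class
  DBIs are additive — they sum exactly to the total-membrane DBI — which is
  the behavior published per-class DBI tables display (the packaged
  reference column sums to its printed total to 4 decimal places). The
  panel is the 15 membrane classes (galactolipids, phospholipids,
  sphingolipids); lyso-lipids, DAG and TAG are excluded from the
  denominator by default and the panel is configurable.
* **Known reference-table caveat.** In the packaged reference DBI table the
  Cer and S1P rows print DBI pairs rounded near zero (0.0002 → 0.0003,
  0.0000 → 0.0000); the printed RCs for those rows (0.2827/0.3074, 0.0000)
  are evidently computed from unrounded source values and cannot be
  recovered from the printed pairs. Tests therefore check RC agreement for
  the 13 self-consistent classes plus the total, and the implementation
  always recomputes RC rather than reusing printed values.
* **Significance.** Stars per class from a cold-vs-control t-test; letter
  groups from one-way ANOVA followed by Tukey HSD at α = 0.05 (Fisher's
  protected LSD as a switch), rendered as a compact letter display computed
  from maximal cliques of the non-significance graph.
* **FFA.** Components are `Cxx:y`; saturation classes are SFA (y = 0),
  MUFA (y = 1), PUFA (y ≥ 2). Saturation sums, PUFA/SFA and RC are computed
  from group means. Summed rows reproduce published panel sums exactly when
  fed the published component means; totals can differ from printed totals
  by input rounding (±0.05).

## Synthetic-data generator

The generator emulates the study conditions, not arbitrary data:

* **Expression.** Full factorial design (2 genotypes × timepoints ×
  control/cold × replicates, default 3). All genes sit at a common baseline
  (default 20 FPKM); planted categories multiply the cold-group mean at
  every stress timepoint by 2^effect_log2fc (default effect 2, i.e. 4-fold),
  enhanced-common genes additionally by the enhancement ratio (default 4)
  in the tolerant genotype. `study_planted_config()` plants the published
  CDEG composition: 569 tolerant-exclusive (277 up/292 down), 2358 common
  of which 190 enhanced (158 up/32 down), 1344 sensitive-exclusive, nulls
  to 8000 genes — its true putative set is 759 genes. Replicate noise is
  multiplicative log-normal (default sd(log) 0 for oracle runs, 0.15 in the
  analysis scripts, a realistic replicate spread for FPKM).
* **Lipidome.** 168 species over the 20 classes (19 DAG species; the
  per-class counts are a fixed package constant). Species weights are a
  single Dirichlet draw from the seed; control grand totals default to the
  published 219.27 (tolerant) and 237.16 (sensitive) nmol mg⁻¹ DW; cold
  means apply per-class multipliers and are then rescaled genotype-wide so
  the grand-total RC equals the configured fraction exactly (defaults
  −7.32% / −22.14%). Replicate noise is Gaussian at a configurable CV
  truncated at zero (6 replicates by default).
* **FFA.** Group means in, replicates out — the packaged 22-component
  reference means are the default input.
* **Physiology.** Readings are generated by inverting the index formulas
  (EC2 fixed at 100, a fixed MDA assay geometry, a 2×2 linear solve for the
  chlorophyll absorbances), so in noise-free mode the physiology module
  recovers the planted indices exactly — a round-trip oracle.

What the generator does **not** model: biological covariance between omics
layers, gene-length or expression-level-dependent variance, count noise,
batch effects, or species-level lipid remodeling within a class. Passing
tests therefore demonstrate correctness of the formulas and the set
algebra under the stated noise models — not robustness to the full error
structure of real RNA-seq or LC-MS data.

## Numerical and scale choices

Simulation sizes in tests and drivers (8000 genes, 2000-gene null batteries
over 20 seeds, ≤100-gene oracle universes over 50 seeds) were chosen as the
smallest sizes at which the checked properties are stable; all complete in
seconds on one CPU. Heat-map grouping sorts genes before clustering so
results are invariant to input order; Ward/Euclidean on log₂ median-centered
condition means is the conventional heat-map default. All randomness flows
through `numpy.random.default_rng(seed)` (PCG64), recorded in output
headers.

## Known limitations

* The DE engine is a deliberate simplification; absolute CDEG counts from
  real data will differ from any published counts produced by other
  engines.
* The compact letter display resolves ties by descending group mean; with
  heavily overlapping groups several valid letterings exist.
* The DBI reconstruction, while validated by additivity against the
  reference table, is one of several formulations consistent with a bare
  "double-bond index" label; the panel scope switch covers the main
  alternative (within-class weighting is not offered because it breaks
  additivity).
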