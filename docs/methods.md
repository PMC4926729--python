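# Methods

## The assessment model

`pgxagree` treats a cross-study comparison as a measurement problem.  Two
studies assay the same cell lines; every published number — an AUC, a log
IC50, an expression value, a mutation call — is an observation of a latent
quantity through that study's own noise channel.  Agreement between
studies is then a property of the *pair of channels*, and any analysis
design that routes one study's observations into the other study's arm
(duplicated mutation matrices, shared genomic features) removes a channel
from the comparison and biases agreement upward.  The package makes this
operational in three layers: per-entity agreement statistics, response
binarization, and a simulation harness with known latent truth.

### Agreement statistics

* Pearson ρ is computed over pairwise-complete observations; a statistic
  is *undefined* (reported as missing, never coerced to 0) when fewer than
  `min_pairs` complete pairs remain or a vector is constant.
  `min_pairs` defaults to 10: correlations on fewer pairs are
  noise-dominated and would distort summary fractions.
* Cohen's κ uses the standard chance-corrected form with marginal
  expected agreement; it is undefined when the expected agreement is 1
  (both raters constant and equal).
* Classification: ρ ≥ 0.8 GOOD (boundary inclusive, matching the
  inter-laboratory reproducibility convention), 0.5 < ρ < 0.8 REASONABLE,
  else BELOW.  κ bands are Landis–Koch with left-closed edges:
  [0.4, 0.6) moderate, [0.6, 0.8) substantial, ≥ 0.8 almost perfect; the
  slight/poor bands below 0.2 are merged as POOR.
* Distribution comparisons between data types use the Wilcoxon rank-sum
  test, exact by full enumeration when the combined sample is ≤ 16 with no
  ties, otherwise a normal approximation with midrank tie correction and
  continuity correction.  The switch point keeps exact enumeration
  (C(16,8) = 12 870 outcomes) effectively free while the approximation
  error at n ≥ 17 is negligible for the p-value magnitudes of interest.
* Union-of-tests summaries ("passes the ρ bar OR the κ bar") are computed
  only on joint reports where every entity carries both statistics
  (`merge_reports`), where the union fraction provably dominates each
  individual fraction.  The summary always attaches a non-evidential
  label: a union can only grow as measures are added, so it cannot
  constitute evidence of agreement.

### Sensitivity calling

The waterfall cutoff for one drug sorts its non-missing values in
decreasing order, producing the response distribution curve:

1. linearity is measured as |r| between the sorted values and rank;
2. if |r| ≥ `waterfall_linearity_min` (default 0.95, the conventional
   choice; exposed in `ThresholdConfig`) the distribution has no elbow and
   the cutoff is the median;
3. otherwise the cutoff is the value at maximal perpendicular distance
   from the chord joining the curve's endpoints, with ranks and values
   each min–max scaled to [0, 1] first so the "inflection" is invariant to
   the measure's units;
4. ties in chord distance resolve to the smallest rank (the
   most-sensitive side), making the procedure deterministic;
5. a constant vector returns the constant with a degenerate flag; fewer
   than 3 values is an error.

Cutoffs are always computed on the full cell-line panel; restriction to
the lines shared with another study happens strictly after calling.  This
order matters: a cutoff estimated on the intersection would make each
study's calls depend on which study it is being compared against.

Boundary semantics for fixed cutoffs: AUC ≥ 0.2 is sensitive (inclusive);
IC50 ≤ 1 µM is sensitive, i.e. the strict "> 1 µM" side is insensitive.
The inequality directions are tied to the measure (AUC: higher = more
sensitive; IC50: lower = more sensitive), not to the sort direction.  AUC
here is the activity-area convention, a fraction in [0, 1] with higher
values meaning greater sensitivity.

### Identifier harmonization

Labels are matched across studies after uppercasing and stripping all
non-alphanumeric characters (`MCF-7` ≡ `MCF7`).  This reproduces common
cross-study cell-line matching without a synonym database; genuinely
different names that share a harmonized form raise a collision error, and
labels that fail to intersect are counted in the drop report rather than
fuzzily repaired.  IC50 values are stored and correlated on the log₁₀(µM)
scale; values above the maximum tested concentration (default 8 µM,
configurable per study) are set to the bound and counted, not dropped.

## The synthetic-data generator

The generator emulates the statistical skeleton of a paired screen:

* latent sensitivity s(cell, drug) ~ N(0, 1), shifted by `effect_beta`
  (latent SD units, default 1) in carriers of a causal gene;
* each study observes √R·s + √(1−R)·ε with independent noise, so the
  between-study correlation is √(R₁R₂) *by construction* — reliability is
  parameterized as the latent variance share precisely so the attenuation
  law is exact and testable;
* the AUC read-out is a fixed logistic squash (scale 1.5) of the
  latent-scale observation into [0, 1]; the scale was chosen so the map is
  nearly linear over the bulk of a standard normal and the attenuation law
  survives the transform to within ~0.005;
* the log IC50 read-out is a fixed decreasing map — affine for
  `auc_ic50_link='none'` (driven by an independent latent, so AUC and IC50
  genuinely measure different things) or cubic for `'monotone_nonlinear'`
  (same latent, nonlinearly distorted) — censored at `ic50_max_conc`
  (default 8 µM, the common maximum tested concentration);
* mutations are Bernoulli(prevalence) truths observed through per-study
  symmetric flip channels; expression and copy number are independent
  latent features with their own reliabilities;
* one global seed feeds fixed per-component substreams (truth, each
  study's noise per datatype), so adding a datatype never perturbs the
  others and output is byte-reproducible.

Default study conditions and why:

| parameter | default | rationale |
|---|---|---|
| `n_cell_lines` | 500 | scale of the overlap between large public screens |
| `n_drugs` | 20 | order of a shared drug panel |
| `n_genes` | 100 | a curated recurrently-mutated cancer-gene panel |
| `mutation_prevalence` | 0.3 | recurrent driver genes run ~20–50 % in pan-cancer panels |
| `mutation_flip_rate` | 0.1 | mutation calls are the least reproducible layer |
| `n_causal_pairs` | 100 | ~5 % of the gene×drug grid carries a real effect |
| reliability AUC/IC50 | 0.5 | same-protocol replicate correlations of ~0.4–0.6 |
| reliability EXPRESSION | 0.81 | expression arrays replicate near the 0.8–0.9 range |
| reliability CNV | 0.9 | copy number is the most reproducible layer |
| `effect_beta` | 1.0 | a one-SD shift, a strong but realistic biomarker |
| `study_bias` | 0.0 | pure-noise model; protocol-level bias is opt-in |

The sizes also reflect an explicit power consideration for the design
comparison: per-replicate concordance of significance calls (hit κ) is
only a meaningful statistic when each replicate yields a reasonable number
of discoveries.  At much smaller panels or sparser causal grids the
per-replicate κ becomes degenerate (often undefined), and the design
comparison degenerates with it.

What the generator does **not** emulate: real marginal distributions of
AUC/IC50, tissue-of-origin structure and its confounding, linkage between
mutations and expression, batch effects within a study, or non-random
missingness.  Passing tests therefore demonstrate that the *methods*
behave correctly under a controlled noise model — not that any particular
real study pair is or is not consistent.

## The association screen and design comparison

Each gene–drug test is a two-group comparison of a drug's response between
mutant and wild-type lines: effect = mean(mutant) − mean(wild-type),
equal-variance two-sided t (identical to one-way ANOVA on two groups,
F = t²), requiring `min_group` = 3 per group.  Tissue covariates are
deliberately omitted: the design comparison is about *which data are
shared between studies*, and covariate structure is orthogonal to that
question.  Benjamini–Hochberg q-values are computed per study across all
defined tests of the grid; significance defaults to q ≤ 0.05 and is
configurable (and reported) because published analyses rarely state their
threshold.  The grid screen is vectorized but is verified test-for-test
against the scalar implementation and an exact permutation oracle.

Between-study concordance is the Pearson correlation of effect sizes over
tests defined in both studies plus Cohen's κ of the significance calls.
`run_design_comparison` repeats generate → screen → concordance over
independent replicates (seeds derived deterministically from one master
seed) under designs A (independent), B (shared mutation matrix) and C
(shared genomics, IC50 vs AUC).  With zero mutation noise designs A and B
operate on identical inputs and their concordances coincide exactly; with
noisy mutation calls design B's concordance stochastically dominates A's —
the quantified information leak.  Design C additionally mixes measures; it
is reported alongside rather than folded into a single number because its
bias combines two distinct flaws.  The screen here is univariate by
design: the leak argument concerns the data-sharing topology, not the
predictor class, so a multivariate (e.g. penalized regression) extension
is out of scope.

## Numerical and reproducibility choices

* Simulation problem sizes in the shipped tests and the acceptance script
  (500 lines × 20 drugs for attenuation; 100 replicates at the default
  conditions for the leak comparison; 20 replicates at 300 lines for the
  power check) were chosen as the smallest sizes at which the targeted
  effects are estimated stably.
* All CSV output writes floats with Python's shortest round-tripping
  repr, and the readers convert through correctly-rounded `float()`, so
  write/read cycles are bit-exact and pipeline reruns are byte-identical.
* Undefined statistics propagate as NaN end to end; JSON output renders
  them as null.
* The pipeline writes no timestamps or environment-dependent values, and
  every number in the human-readable summary is sourced from the
  machine-readable outputs.

## Known limitations

* Exact-name (harmonized) matching only; drug synonym resolution across
  vendors is not attempted and surfaced mismatches must be curated by the
  user.
* Spearman correlation and concordance-index variants of the agreement
  statistics are not implemented; the report structure is the natural
  extension point.
* The waterfall linearity constant (0.95) is a convention, not an
  estimate; analyses sensitive to it should sweep `ThresholdConfig`.
* Censored IC50 values are clamped, which deflates correlations when a
  large fraction of a drug's values sit at the bound; the per-matrix
  censoring count is recorded so such drugs can be flagged.
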