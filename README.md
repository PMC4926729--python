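# pgxagree

Agreement assessment for paired cell-line pharmacogenomic screens.

When two groups independently screen the same cancer cell lines against the
same drugs and profile the same genomes, how consistent are their results —
and how much of any *apparent* consistency is manufactured by the way the
comparison is designed?  `pgxagree` is a library and command-line tool for
answering both questions.  It is aimed at computational biologists who
compare large drug-sensitivity resources (drug response as activity-area
AUC or IC50, molecular profiles as expression, copy number and mutation
calls) and at methodologists who need to audit a published comparison
design for information leaks.

## What it computes

**Per-entity agreement.**  For each drug (sensitivity) or gene (profile)
shared by two studies, the Pearson correlation ρ across common cell lines
for continuous data and Cohen's chance-corrected κ for binary data:

    κ = (p_o − p_e) / (1 − p_e)

with p_o the observed agreement and p_e the agreement expected from the
marginal call rates.  Results are classified against fixed bars: ρ ≥ 0.8
meets the inter-laboratory reproducibility standard (GOOD), ρ > 0.5 is
merely "reasonable"; κ is banded per Landis–Koch (≥ 0.4 moderate, ≥ 0.6
substantial).  Summaries report the fraction of entities passing each bar
separately; any union-of-tests fraction is printed but explicitly labelled
non-evidential, because a union can only grow as more measures are added.

**Sensitivity calling.**  Continuous response is binarized either by fixed
cutoffs (AUC ≥ 0.2 sensitive; IC50 ≤ 1 µM sensitive, on the log₁₀ scale)
or by the waterfall method: sort a drug's values into its response
distribution curve, use the median when the curve is linear (|r| ≥ 0.95
against rank), otherwise place the cutoff at the point of maximal
perpendicular distance from the chord between the curve's endpoints.
Cutoffs are always estimated on a study's full cell-line panel and only
then restricted to the lines shared with the other study, so the cutoff
never depends on the comparison.

**Noise attenuation.**  If two studies observe a common latent signal with
reliabilities R₁ and R₂ (latent share of observed variance), the expected
between-study correlation is √(R₁R₂), not 1.  The synthetic-data module
generates paired studies with exactly this structure — plus mutation
miscall channels, planted gene–drug effects, a configurable AUC↔IC50 link
and IC50 censoring at the maximum tested concentration — so the whole
pipeline can be validated against known truth.

**Information-leak designs.**  Gene–drug associations (two-group
equal-variance t, equivalent to one-way ANOVA; Benjamini–Hochberg q-values
over the gene × drug grid) are screened in both studies under three
designs: (A) fully independent — each study uses its own mutation calls
and the same response measure; (B) one study's mutation calls duplicated
onto both sides; (C) shared genomics *and* mismatched measures (IC50 vs
AUC).  Duplicating the genomic layer deletes its measurement noise from
the comparison, so design B inflates the apparent cross-study concordance
of biomarkers whenever mutation calls are noisy; `run_design_comparison`
quantifies that inflation by simulation.

## Worked example

```python
import pgxagree as pg

params = pg.SimulationParams(n_cell_lines=100, n_drugs=8, n_genes=20,
                             n_causal_pairs=10, mutation_flip_rate=0.2,
                             seed=42)
pair = pg.generate_pair(params).paired_study()

rep = pg.per_entity_consistency(pair, "AUC", min_pairs=10)
for k, v in rep.summary.items():
    print(f"{k}: {v}")

tab = pg.run_design_comparison(params, n_reps=20, seed=42, designs=("A", "B"))
print(tab.groupby("design_id")[["effect_rho", "hit_kappa"]].mean().round(3))
```

prints

```
n_entities: 8
n_rho_defined: 8
n_kappa_defined: 0
median_rho: 0.5653962778611742
fraction_rho_gt_0.5: 0.75
fraction_rho_ge_0.8: 0.0
fraction_pass_union: 0.75
union_note: union of tests: non-evidential (any union fraction >= each individual fraction by construction)

                    effect_rho  hit_kappa
design_id
A_INDEPENDENT            0.296     -0.001
B_SHARED_MUTATIONS       0.608      0.133
```

Both studies observe the same latent drug response with reliability 0.5,
so the median per-drug ρ lands near √(0.5·0.5) = 0.5: 6 of 8 drugs clear
the "reasonable" bar, none reach the 0.8 reproducibility standard.  With a
20 % mutation miscall rate, sharing one study's mutation matrix (design B)
roughly doubles the apparent effect-size correlation relative to the
honest independent design (A) — the information leak in action.

The same workflow is available from the shell:

```bash
pgxagree simulate --seed 42 --out fixture/          # writes CSVs + manifest
pgxagree compare  --pair fixture/manifest.yaml --datatype auc --out auc.csv
pgxagree call     --input fixture/a_AUC.csv --measure auc --method waterfall --out calls.csv
pgxagree screen   --pair fixture/manifest.yaml --design b --out assoc.csv
pgxagree leaksim  --reps 100 --seed 7 --out designs.csv
pgxagree report   --config run.yaml --out report/   # full assessment bundle
```

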