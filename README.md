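# survscreen

Transcriptome-wide survival screening of dichotomized expression biomarkers
in paired patient cohorts, built for the two-cohort design used to find
prognostic genes in microsatellite-instability (MSI) gastric cancer: each
gene is dichotomized at an ROC-optimal cutpoint, pushed through a sequential
chain of survival filters in every cohort independently, and only genes
passing everywhere with a consistent direction of effect are called robust
candidates.  The package also implements the downstream stages such a
screen feeds: clinical-characteristics association tables, preranked
gene-set enrichment with meet–min redundancy clustering, re-clustering of
molecular-subtype classifier scores, and cross-cohort comparison of
tumor-microenvironment deconvolution scores.  A synthetic cohort generator
with planted prognostic genes makes every stage testable end to end with no
external downloads.

## The screen

For each gene *g* with expression *x* and overall-survival (OS) event
indicator *δ*:

1. **Cutpoint** — candidate thresholds are midpoints between consecutive
   distinct expression values; among thresholds leaving ≥ 20% of samples in
   each group, choose the maximizer of Youden's *J* = sens + spec − 1 for
   classifying *δ*; ties resolved toward the median expression.  50
   bootstrap resamples report the cutpoint's stability.
2. **Univariate Cox** — OS and disease-free survival (DFS) proportional-
   hazards fits on the high/low group; require p < 0.05 for both with one
   direction.  The Cox fitter maximizes the Efron-corrected partial
   likelihood by Newton–Raphson with Wald inference.
3. **Multivariate Cox** — the same, adjusting for age, sex, Lauren class,
   T stage (T1/T2 vs T3/T4), nodal status (N0 vs N+), and primary site.
4. **Discrimination gates** — cumulative/dynamic time-dependent ROC at 36
   months with Kaplan–Meier censoring weights: require AUC(36) > 0.5 and
   sensitivity > 0.5 and specificity > 0.5 at the chosen cutoff.
5. **Power** — Schoenfeld power Φ(√(d·p(1−p))·|log HR| − z₀.₉₇₅) ≥ 80% for
   both endpoints at the observed event counts and effect sizes.

A gene is reported only if it passes all five stages in **every** cohort
with the same direction.  No multiple-testing correction is applied across
genes; the dual-cohort intersection and the AUC/power gates are the
robustness device (see `docs/methods.md` for what this does and does not
control).

## Worked example

```python
from survscreen import (SyntheticConfig, generate_cohort_pair,
                        screen_transcriptome, ScreenConfig)

cfg = SyntheticConfig(n_samples_per_cohort=200, n_genes=500, n_planted=1,
                      planted_hr=3.5, censor_rate=0.3, seed=1)
pair = generate_cohort_pair(cfg)
result = screen_transcriptome(
    [("A", *pair.cohorts[0]), ("B", *pair.cohorts[1])], ScreenConfig(seed=1))
print(result.intersection)
print(result.attrition)
```

prints

```
{'high-expression-worse': ['G00000']}
{'A': {'cutoff': 500, 'cox_uni': 68, 'cox_multi': 53, 'auc_gates': 9, 'power': 4},
 'B': {'cutoff': 500, 'cox_uni': 69, 'cox_multi': 52, 'auc_gates': 14, 'power': 6}}
```

The single planted prognostic gene (`G00000`, hazard ratio 3.5 between its
high and low expression components) is recovered as the only gene passing
in both cohorts, in the harmful direction.  The attrition counts show how
many of the 500 genes survived each successive filter per cohort: 68–69
null genes clear the univariate stage (an inflated rate caused by cutpoint
optimization — expected and documented), but the chain plus the cross-cohort
intersection reduce the false candidates to zero.

The same pipeline is available from the shell:

```bash
survscreen --out-dir work simulate --seed 1
survscreen --out-dir work screen \
    --expression work/expression_A.tsv --expression work/expression_B.tsv \
    --clinical work/clinical_A.tsv --clinical work/clinical_B.tsv --seed 1
```

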