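# p16foci

Digital quantification of p16-positive fibroblastic foci on annotated lung
biopsy slides, with the downstream diagnostic, survival, and spatial
transcriptomic analyses used to characterise the senescence-associated
phenotype of idiopathic pulmonary fibrosis (IPF).

## Who this is for

Pulmonary pathology and interstitial lung disease (ILD) research groups who
annotate whole-slide images (tissue outlines plus point marks on
p16-immunopositive fibroblastic foci) and want a reproducible, scriptable
pipeline from those annotations to:

- a standardized focus **density** per slide,
  `density = 100 · n_foci / tissue_area_mm²`, dichotomized into
  **p16-low** (≤ 2.1 foci / 100 mm²) vs **p16-high** (> 2.1),
- cohort-level **diagnostic performance** (sensitivity/specificity of p16
  scoring against the multidisciplinary-discussion diagnosis of IPF, with
  exact Clopper–Pearson 95% CIs) and ROC-based re-derivation of the cutoff
  (maximising sensitivity + specificity, the Youden criterion),
- **lung-transplant-free survival**: Kaplan–Meier curves with Greenwood
  standard errors, the log-rank test, and Cox proportional-hazards models
  (Newton–Raphson on the partial likelihood, Efron or Breslow ties) under the
  composite death-or-transplant endpoint,
- a GeoMX-style **digital spatial profiling (DSP)** analysis of ROI-level
  gene counts (fibroblastic focus / dense fibrosis / normal lung):
  housekeeping and upper-quartile (Q3) normalization, Welch-t differential
  expression with Benjamini–Hochberg q-values and a fold-change ≥ 1.5 filter,
  uncentered-Pearson average-linkage clustering, PCA, and gene set enrichment
  analysis with gene-set permutation,
- seeded **synthetic-data generators** for all three input kinds with
  serialized ground truth, so the whole pipeline is testable end to end
  without patient data.

Inputs are plain text: GeoJSON annotation files with a µm/px calibration,
a cohort TSV, genes × ROIs count TSVs, and GMT gene sets.

## Worked example

```python
import p16foci as p

# 1. slide quantification (synthetic slide with known ground truth)
slide, truth = p.gen_slide(seed=42, tissue_area_mm2=250.0,
                           n_foci_inside=5, n_foci_outside=1)
q = p.quantify_slide(slide)
print(f"{q.n_foci} foci in {q.tissue_area_mm2:.1f} mm^2 -> "
      f"{q.density:.2f} foci/100 mm^2 ({q.p16_class}); "
      f"{q.n_foci_excluded} mark(s) outside tissue")

# 2. diagnostics on the deterministic study-structure cohort
cohort = p.study_structure_cohort()
perf = p.diagnostic_performance(cohort, cohort["density"] > 0,
                                cohort["diagnosis"] == "IPF")
print(f"sensitivity {100*perf.sensitivity:.1f}%, "
      f"specificity {100*perf.specificity:.1f}%")
inc = p.outcome_incidence(cohort)
print(f"death-or-transplant {inc['combined_death_or_ltx_pct']}%, "
      f"mortality {inc['mortality_pct']}%")

# 3. survival on a simulated cohort generated at the published effect sizes
df, _ = p.gen_cohort(p.CohortSimSpec(n=3000, seed=1))
fit = p.cox_fit(p.ltx_free_records(df), ["p16_high", "antifibrotic"])
for c in fit.covariates:
    lo, hi = fit.wald_ci_95[c]
    print(f"HR[{c}] = {fit.hazard_ratios[c]:.2f} ({lo:.2f}-{hi:.2f})")
```

prints

```
5 foci in 250.0 mm^2 -> 2.00 foci/100 mm^2 (low); 1 mark(s) outside tissue
sensitivity 76.9%, specificity 91.2%
death-or-transplant 64%, mortality 49%
HR[p16_high] = 2.40 (2.15-2.68)
HR[antifibrotic] = 0.27 (0.24-0.31)
```

The slide quantifies to exactly 100·5/250 = 2.00 foci per 100 mm² (the
out-of-tissue mark is excluded, not counted).  On the 86-subject cohort
structure, any-focus positivity is 76.9% sensitive (40/52) and 91.2% specific
(31/34) for IPF.  The multivariate Cox fit on a 3000-subject simulated cohort
recovers the generating hazard ratios (2.40 for p16-high, 0.28 protective for
antifibrotic therapy) within sampling error.

## Command-line interface

All analyses are also exposed as subcommands of the `p16foci` console script:

```sh
p16foci simulate cohort --seed 1 --out sim/
p16foci study sim/cohort.tsv --out report/
p16foci quantify slides/*.geojson --mpp 0.5 --out quant/
p16foci dsp-de counts.tsv roi_meta.tsv --housekeeping hk.txt --out de/
p16foci gsea counts.tsv roi_meta.tsv sets.gmt --seed 7 --out gsea/
```

Each subcommand writes TSV/JSON results plus a `run_manifest.json` recording
inputs, configuration and seed.  Exit codes: 0 success, 1 usage error, 2 data
error.

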