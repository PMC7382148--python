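# proteorank

Cross-tissue quantitative-proteomics differential expression and
order-statistics rank integration for biofluid biomarker prioritization.

## The problem

Deep TMT (tandem-mass-tag) proteome profiling of Alzheimer's-disease
cohorts produces protein×sample intensity matrices from several tissues —
brain cortex, cerebrospinal fluid (CSF), serum — across independent
discovery and reference studies, in both human and mouse. No single cohort
is large enough to nominate biomarkers reliably: groups of ~10 vs ~10 give
per-protein tests little power, biofluids carry blood-contamination
artifacts, and disease-relevant low-abundance proteins (notably a
correlated block of mitochondrial proteins that falls in AD biofluids and
rises in cortex) are simply invisible unless profiling reaches thousands
of proteins. `proteorank` implements the full integration pipeline:

1. **Preprocessing** — log2 size-factor normalization, a per-sample blood
   contamination score (mean log2 of a hemoglobin-like marker panel),
   robust-SD outlier removal, and per-protein Huber residualization of
   the score (c = 1.345), plus PCA QC.
2. **Differential expression** — empirical-Bayes moderated two-sample t
   (AD vs control): s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) with (d₀, s₀²)
   estimated by digamma/trigamma moment matching on log s²; fold changes
   standardized across proteins (Z), Benjamini–Hochberg FDR, and DE calls
   such as |Z| > 2 & FDR < 0.05 (presets for |Z| > 5 & FDR < 0.01,
   |Z| > 2 & p < 0.05, |Z| > 2 & FDR < 0.2).
3. **Abundance-depth analysis** — concentration ranks and detection curves
   quantifying which protein sets a given profiling depth can see.
4. **Cross-tissue/species overlap** — exact Venn decomposition of DE sets,
   per-protein direction patterns (e.g. cortex-up/fluid-down),
   hypergeometric overlap tests, mitochondrial fractions per region.
5. **Rank integration** — per-dataset significance ranks normalized to
   (0,1]; for a protein with sorted ranks r₁ ≤ … ≤ r_N across N datasets,
   the order-statistics Q = N!·V_N with V_k = Σᵢ (−1)^{i−1} r_{N−k+1}^i/i! · V_{k−i}
   (the joint probability that N uniforms sit below those ranks);
   within-list label permutations give a null Q distribution per
   N-available stratum, add-one empirical p-values, BH FDR, and a 3-step
   tiered scheme (cohorts → tissue → final, with a pre-final filter
   keeping only proteins showing nominal change in some biofluid).
6. **Enrichment** — preranked weighted Kolmogorov–Smirnov enrichment
   scores with a set-permutation null (random same-size sets) and BH FDR.

Because the original cohort data are access-controlled, the package ships
a synthetic-study generator that emulates the study design — multi-cohort
structure, five-decade abundance dynamic range, per-cohort profiling
depth, planted cross-tissue signatures, a correlated mid/low-abundance
mitochondrial module, contamination covariates and outlier samples — with
a complete ground-truth manifest, so every stage is testable end to end.

## Worked example

```python
import numpy as np
import proteorank as pr

cfg = pr.default_study_config(n_proteins=2000, seed=1)   # 5 cohorts, 10v10
res = pr.run_study(sim_config=cfg, seed=1, B=200)        # full pipeline

tbl = res.ranking.table
planted = [p for p in res.truth.signature_ids if p in tbl.index]
print(len(tbl), "proteins in the final ranking")
print("planted signature median final rank:",
      np.median(tbl.loc[planted, "final_rank"]))
```

prints

```
386 proteins in the final ranking
planted signature median final rank: 56.0
```

— the 20 planted cross-tissue signature proteins (1.5 within-group SD,
hidden among 2000) concentrate in the top ~3% of the 2000-protein
integration universe even though each individual cohort calls only a
fraction of them. The same study is available as a narrative sequence of
drivers: `python analysis/01_simulate_cohorts.py` through
`analysis/06_pathway_enrichment.py`, which write their tables under
`results/study/` and print, per stage, outlier recovery, DE counts per
threshold preset, the module's depth-detection curve (0/60 detected at
depth 500, 60/60 at full depth, median abundance rank ≈ 1100), the
three-tissue overlap with its mitochondrial fraction, the integrated
top-25 with truth flags, and the enrichment table in which exactly the
two planted sets reach FDR < 0.05.

A CLI mirrors the stages (`proteorank simulate|preprocess|de|overlap|rank|gsea|all`).

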