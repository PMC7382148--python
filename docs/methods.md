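# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Study model

A study is a set of cohorts, each a protein×sample matrix of strictly
positive TMT-style reporter intensities with AD/MCI/Ctl group labels.
Cohorts differ in tissue (cortex, CSF, serum), species (human, mouse),
role (discovery, reference) and profiling depth (number of proteins
quantified). Analyses treat protein identifiers as opaque strings;
gene-level grouping and the mitochondrial flag live in a separate
annotation table, and cross-species comparisons assume an explicit
homolog map (identity by default).

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's operating characteristics are measured.

On the log2 scale, the value of protein *i* in sample *s* is

    x_is = b_i + sign(tissue)·δ·dose_s·1[i planted] + λ_i·c_s + ε_is

* **Baselines** `b_i` are evenly spaced on log10 over 5 decades
  (anchored at 10⁷), so abundance ranks are exact, depth censoring is
  deterministic (a cohort of depth d quantifies exactly the top-d
  proteins), and censoring is monotone across depths. Real proteome
  log-intensity distributions are peaked rather than uniform; the even
  grid trades that realism for exact rank arithmetic in tests.
* **Planted effects**: 20 cross-tissue signature proteins (drawn from the
  universally observed top stratum) and a 60-protein mitochondrial module
  (drawn from the 40–70% abundance band, median rank ≈ 0.55 of the
  universe) shift AD means by δ = 1.5 within-group SD (MCI receives half
  the shift), signed +1 in cortex and −1 in CSF/serum — the mirrored
  amyloid-like pattern. Module noise is equicorrelated (ρ = 0.3) through
  a shared per-sample factor, so module-wide significance rises and falls
  together across seeds, as correlated pathways do in real data.
* **Contamination**: a per-sample standard-normal covariate loads with
  strength 1.0 (log2 per SD) on an 8-protein high-abundance marker panel
  and bleeds weakly (2%) onto everything else; in the discovery CSF
  cohort three randomly chosen samples get a +5 SD score shift,
  emulating grossly contaminated samples.
* **Group sizes** default to 10 AD vs 10 Ctl (the discovery-cohort power
  regime), with 4 MCI in discovery CSF; the mouse counterpart is a
  ~1000-protein CSF cohort of 6 vs 5 with a configurable fraction of the
  signature shared.
* **Noise** is i.i.d. Gaussian, σ = 0.5 log2 units within group.

Not emulated: reporter-ion ratio compression, isotope impurity,
peptide-to-protein roll-up noise, batch structure, non-Gaussian tails,
and realistic (peaked) abundance densities. Passing recovery tests
therefore demonstrates the pipeline's statistical behavior under its own
assumptions, not clinical performance on real cohorts. The distributional
model itself (log-normal intensities + Gaussian effects) is an
assumption, not an estimate from data.

## Normalization

`log2_median_normalize` median-centers each sample column — adequate for
QC and PCA. The pipeline's preprocessing instead centers each column on
the **median of per-protein log-ratios to the row-mean reference**
(size-factor estimation on the log scale, as in median-of-ratios count
normalization). The distinction matters: a column median taken over a
wide, nearly uniform abundance distribution has low density at the
median, so (a) its sampling noise enters every protein as a shared
per-sample shift, and (b) an asymmetrically regulated block sitting near
mid-abundance drags the median and biases every null fold change away
from zero (at desk scale, 60/2000 down-regulated proteins shifted AD
medians by −0.14 log2 and inflated the observed false-discovery
proportion from ~0.05 to ~0.17). Log-ratios to a reference profile
concentrate their density at zero, making the offset estimate precise and
robust to regulation while removing loading differences identically.

## Contamination correction

The contamination score is the mean log2 level of the marker panel in
each sample — a simple, reproducible scalar (a fitted-factor variant
would be a natural extension). Samples with score above
median + k·1.4826·MAD (k = 3; SD fallback when MAD = 0) are removed; only
the upper tail is flagged because contamination only adds signal. Each
protein is then residualized on the centered score with a Huber
M-estimator (c = 1.345, IRLS to relative tolerance 1e-8, ≤ 100
iterations, MAD-about-zero scale), vectorized across proteins; a final
weighted solve with the converged weights makes weighted residuals
orthogonal to the design to machine precision. Residuals keep each
protein's intercept (its level at average contamination), so abundance
ranks survive correction. The covariate is centered because the raw
score sits ~22 log2 units from zero and an uncentered intercept would
extrapolate far outside the data. Huber was chosen over bisquare for its
convex loss (unique solution); the variant is configurable in principle
but not exposed. When the score itself separates disease groups
(two-sample t, α = 0.05) — possible in small cohorts — an optional
branch skips residualization and keeps only outlier removal, since
regressing out a group-correlated covariate absorbs disease signal.
Proteins observed in fewer than 3 samples pass through unfitted.

## Differential expression

AD vs Ctl only; MCI samples are carried for summaries but never enter
the contrast. Per protein the pooled two-sample statistic is moderated by
an inverse-gamma variance prior: s̃² = (d₀s₀² + d·s²)/(d₀+d),
t̃ = Δ/(s̃·√(1/n_AD+1/n_Ctl)), two-sided p on d+d₀ df. (d₀, s₀²) come
from moment matching on log s²: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
ψ′(d₀/2) equals the excess variance of e and s₀² follows from its mean;
the trigamma equation is inverted by monotone bisection (tolerance
1e-10), and a nonpositive excess yields d₀ = ∞ (full shrinkage, normal
reference). This reproduces the standard empirical-Bayes moderated t: on
random matrices the implementation agrees with R limma's `eBayes` to
1e-8 in t and p and to 1e-4 in d₀ (tested via Rscript), and reduces to
the ordinary pooled t exactly when d₀ is forced to 0.

Fold changes are standardized across the proteins of one dataset with
mean/SD (n−1); "Z" here is the Z of the log2 fold change, not a
difference of per-group Z scores. BH adjustment is delegated to
statsmodels and cross-checked against a hand-rolled step-up oracle. DE
calls combine |Z| > z_min with exactly one of an FDR or nominal-p
ceiling; an optional sign restriction gives directional calls.

Abundance ranks order proteins by mean log2 level (ties broken by
identifier, so ranking is total and deterministic); depth-detection
curves count query-set members within the top-d ranks over a depth grid.

## Rank integration

Each dataset contributes proteins ordered by ascending DE p-value (ties:
larger |Z| first, then identifier) with ranks normalized by that
dataset's size — so both directions of change compete on significance,
matching a prioritization in which increased and decreased proteins both
matter. For a protein observed in N lists the Q statistic is the joint
probability that N independent uniforms have their i-th order statistic
below the i-th observed rank, via the alternating recursion
V_k = Σᵢ (−1)^{i−1} r^i/i!·V_{k−i} (exact closed forms: q = r for N = 1,
q = 2ab − a² for N = 2; verified against 10⁶-draw Monte Carlo for
N = 3–5). Proteins absent from a list simply use N = n_available; the
framework needs no imputation.

Calibration is by permutation: protein labels are shuffled independently
within every list (membership patterns fixed), Q recomputed, and null
draws pooled per n-available stratum — Q's scale depends on N, so
strata prevent bias against sparsely observed proteins. Independent
(unsynchronized) shuffles are the stricter null. Empirical p-values use
the add-one rule, (1 + #{null ≤ q})/(1 + #null), never zero, so BH is
well-defined. Default B = 1000 permutations; recovery tests use B = 200
for speed.

Integration is tiered: cohort groups (tissue × role, mouse separate) →
tissue → final, each level combining its members' lists by Q and
re-ordering by empirical p. Before the final step, proteins without
nominal change (raw p < 0.05) in at least one CSF or serum dataset are
dropped and the tissue lists renormalized over the retained universe;
renormalization keeps the final permutation null calibrated (uniform
final p under a global null, KS-tested). The nominal-p bar is the
weakest defensible reading of "no change in the biofluids"; no stated
threshold exists for it. Recovery is reported as final rank relative to
the full integration universe (filtered-out proteins rank below every
retained one): the filter keeps only a few hundred candidates, so
quantiles of the filtered list alone would make even a perfect ranking
look mid-list once the planted module (60) plus signature (20) exceed
5% of it.

## Enrichment

Preranked GSEA-style: walking the final ranking, hits increment by
|score|^w (score = −log10 empirical p, w = 1; w = 0 recovers the
classical Kolmogorov–Smirnov statistic, verified against the two-sample
KS oracle), misses decrement 1/(N − n_set); ES is the signed maximum
deviation, leading edge the hits at or before (after, for negative ES)
the extremum. The null permutes **sets**, not phenotypes — random
same-size draws from the ranked universe — because an integrated ranking
has no per-sample labels to permute; nulls are shared across sets of
equal size, p-values use the add-one rule on |ES|, and FDR across sets is
BH on empirical p (simpler and better-defined than an NES-based FDR,
and consistent with BH usage elsewhere in the pipeline). Sets are
filtered to ≥ 5 members inside the ranked universe.

## Numerical conventions and degenerate inputs

* Missing is NaN in memory, `NA` (or empty) in files, never 0; any
  nonpositive intensity aborts with the offending protein/sample named.
* Tie-breaks are always lexicographic on identifiers after the primary
  keys, so every ordering is total and platform-independent.
* All randomness flows from explicit seeds through
  `numpy.random.default_rng`; permutation stages take a seed and record
  it in output manifests, and identical (config, seed, B) reproduce
  byte-identical outputs.
* PCA uses complete-case proteins only (no imputation), row-centering,
  SVD, and a sign convention (largest-magnitude loading positive).
* Degenerate cases raise: empty sample columns, constant score vectors,
  zero-SD fold-change vectors, empty permutation strata, sets equal to
  the universe, filters that remove everything.

## Problem sizes

Tests and the acceptance script run the study at 2000 proteins × 5–6
cohorts (5000 × 1 for the DE power check), B = 200 for recovery and
B = 1000 for calibration, with 3–20 seeds per property — sizes at which
the measured quantities (FDP ≈ 0.05, DE sensitivity ≈ 0.53 at 200/5000,
signature median final rank ≈ 1–3% of the universe, enrichment type-I
rate ≈ 5%) are stable to a few percent across seeds.

## Known limitations

* Desk-scale group sizes leave single-cohort DE underpowered by design
  (sensitivity ~0.2 per biofluid cohort at default thresholds); the
  pipeline's value is the integration step, and the tests measure exactly
  that.
* The equicorrelated module makes whole-module significance swing
  between seeds; FDP is controlled on average, not per seed.
* The contamination model is a single scalar covariate; multi-covariate
  batch correction is out of scope.
* Outlier detection at +5 SD with a 3-robust-SD threshold misses a
  planted outlier in a few percent of cases — inherent to the rule, not
  a bug; downstream residualization absorbs most of what a missed
  outlier leaves behind.
* GO/KEGG/Hallmark content is not bundled (licensing/versioning); any
  GMT file can be supplied.
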