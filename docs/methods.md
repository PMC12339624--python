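# Methods

This note documents the models, estimators, numerical choices, and the
synthetic study design behind `metabnet`, and what the test suite does and
does not establish.

## The decomposition model

Each metabolite is modeled independently by a random-intercepts linear
mixed model with fixed effects for Age (binarized at 50: screening-age
convention and average menopause onset), Sex, timepoint T (binary — two
visits), m diet factor scores F (assumed constant across visits; dietary
patterns are stable on a ~7-year horizon), a metabolite-specific polygenic
score G, and all two-way interactions among these blocks. With m factors
the design has q = 11 + 5m columns (41 for m = 6): five blocks are m-wide
(F, Age∘F, Sex∘F, T∘F, F∘G) and eleven are scalars. The subject-level
intercept u ~ N(0, σ²ᵤ) absorbs every stable subject-specific source not
captured by the covariates and is interpreted as lifestyle; ε ~ N(0, σ²)
is visit-level noise.

**Estimation.** REML via the profiled likelihood in the variance ratio
λ = σ²ᵤ/σ². Given λ, β̂ is generalized least squares with the closed-form
inverse V⁻¹ = I − λ/(1+λnᵢ)·J per subject, and the profiled REML criterion
(n−q)·log(r'V⁻¹r) + Σᵢ log(1+λnᵢ) + log|X'V⁻¹X| is minimized over log λ by
a coarse grid (47 points on [−15, 8]) followed by bounded Brent refinement,
with an explicit σ²ᵤ→0 boundary check. Variances are floored at 1e-10; ML
is the fallback if the REML surface degenerates, and the fit is flagged.
Empirical Bayes intercepts are ûᵢ = (nᵢλ̂/(1+nᵢλ̂))·(mean residual of
subject i); subjects seen only at baseline shrink harder. The suite
cross-checks β̂, σ̂²ᵤ, σ̂², û, and the log-likelihood against
statsmodels' MixedLM and against dense GLS/BLUP matrix algebra.

**Signal extraction.** The diet+lifestyle matrix Ỹ_L sums exactly the
F, Age∘F, Sex∘F, T∘F and F∘G fitted terms plus û; the time matrix Ỹ_T sums
the T, Age∘T, Sex∘T, T∘F and T∘G terms without û (every term carries T, so
Ỹ_T vanishes at baseline). Note the T∘F term belongs to both parts by
construction, so the two parts overlap rather than partition the linear
predictor. Rows of Ỹ_L from the same subject are dependent; the network
stage uses all rows by default (matching the study design) with a config
option to average within subject first.

**Exclusions.** Subjects with a diabetes diagnosis OR fasting glucose
strictly above 10 mmol/l OR incomplete age/sex/FFQ information are removed
entirely; glucose exactly 10.0 is retained.

## Diet factors

Principal-axis factoring of the FFQ item Pearson correlation matrix
(ordinal 1–8 items are treated as numeric; items are standardized, which
subsumes centering), with squared-multiple-correlation initial
communalities (ridge 1e-8 when the correlation matrix is singular, as in
noiseless simulations), iterated to a communality change below 1e-6, and
Heywood cases clipped at 1 and flagged. Rotation is direct quartimin
(oblimin, γ = 0) by oblique gradient projection, restarted from the
identity plus 10 seeded random orthonormal starts, keeping the lowest
criterion; factors are ordered by explained sum of squares and signed so
the largest-magnitude loading is positive. The number of factors is a user
input; eigenvalues and a Kaiser count are reported but never auto-selected.
Factor scores use the ten Berge construction, whose defining identity —
in-sample score correlations equal Φ̂ exactly — the suite asserts to 1e-6.

## Polygenic scores

G = Σⱼ ηⱼSⱼ per metabolite over its SNP effect sizes (inputs from an
external association study; no internal GWAS). With `top_l` below the SNP
count, SNPs are ranked by ascending p-value, ties by |η| descending, then
snp id. Scores are unstandardized by default (an option standardizes).

## Network estimation

The graphical lasso is solved by block coordinate descent with an inner
soft-thresholding lasso per column (numba-compiled), iterated until the
maximum covariance update falls below 1e-7. The ℓ₁ penalty applies to
off-diagonal entries only, so the fitted covariance matches K on the
diagonal and λ ≥ max|off-diagonal K| yields an exactly empty graph; a
config knob penalizes the diagonal too via the exact reduction to K + λI.
The stationarity conditions (Σ̂ᵢⱼ−Kᵢⱼ = λ·sign(Θ̂ᵢⱼ) on the support,
|Σ̂ᵢⱼ−Kᵢⱼ| ≤ λ off it) are asserted at 1e-4 across random problems, and
solutions are cross-checked against scikit-learn's solver. λ = 0 falls back
to the plain inverse. Input K is the covariance of Ỹ_L (correlation by
option). Warm starts across the descending λ grid make StARS paths cheap.

StARS: 100 subsamples without replacement of size ⌊10√n⌋ (capped at 0.8n),
50 log-spaced λ from λ_max = max|off-diagonal K| down to 0.01·λ_max, edge
frequencies ξ, instability D(λ) = 2/(p(p−1))·Σ 2ξ(1−ξ) monotonized by a
running maximum from the sparsest λ, and λ_opt the smallest λ with
monotonized instability ≤ 0.05. If nothing qualifies the sparsest λ is
returned with a warning. Subsampling draws observation rows by default; a
config option draws whole subjects. The final network takes A from the
full-data fit at λ_opt and W = A∘ξ(λ_opt).

## Module identification

The tree cut operates on D = 1 − W with average linkage (complete/single
by config). Stage 1 walks the dendrogram: a merge is a between-module join
when its height exceeds `cut_height` (0.99) or its *scaled* height — on
the (min, max) merge-height range — exceeds a deep-split preset (0.90 at
the default `deep_split=2`); a merge also splits when both children hold
at least `min_module_size` (3) leaves and are detached by a scaled gap
(0.15 at default). Surviving branches are modules; stage 2 assigns each
leftover node to the module with smallest average dissimilarity when that
distance is below `cut_height`, else it stays unassigned (label 0). This
follows the published two-stage hybrid logic but does not promise
label-for-label agreement with other implementations; its contract —
asserted in the suite — is planted-partition recovery.

Girvan–Newman removes the highest-betweenness edge (computed on the
unweighted adjacency; ties broken lexicographically; optional 1/W distance
weighting) until the graph is empty, and returns the partition of the
sequence maximizing modularity weighted by W. Isolated nodes are singleton
modules.

## Characterization

For a symmetric zero-diagonal M with strengths s: density
Σᵢ≠ⱼMᵢⱼ/(p(p−1)); centralization (max s − mean s)/p; heterogeneity
sd(s)/mean(s) with sample variance (p−1 divisor; a population-variance
option exists). Module rows are computed on induced W submatrices;
summaries report modules with ≥ 5 members (configurable), matching the
reporting convention for module tables. Diet-response profile curves fit a
cubic smoothing spline (GCV penalty) of Ỹ_L against each factor score on a
50-point grid, after averaging duplicate scores (the same subject
contributes identical scores at both visits); fewer than 10 distinct
scores triggers a flagged linear fallback.

## Synthetic study design

The generator reproduces the study's *shape and signal structure*, not its
biochemistry: 364 subjects at baseline, of whom a fixed fraction
(153/364) lack the 7-year follow-up; ages uniform 25–74 at baseline; 55
metabolites; 6 correlated diets (Φ off-diagonals 0.25) over 55 FFQ items
discretized to an equal-probability 1–8 scale; 48 independent SNPs with
MAF in [0.1, 0.5].

Ground truth is planted at every stage. Subject intercepts are drawn from
N(0, Θ⁻¹) with Θ sparse, SPD, unit-diagonal and block-diagonal over 12
modules (a spanning tree plus extra within-block edges, partial
correlations ≈ 0.3), so the conditional-independence graph and module
partition of the lifestyle signal are known. Diet responses are
module-structured: metabolites in a module share a module-level
coefficient (sd 0.25 per factor) plus small jitter (sd 0.05), keeping diet
a minority share of variance, as in cohort metabolomics. Noise is set to
σ_ε = σ_u/√2 (ICC 2/3, the long-interval stability of lipid-class
metabolites), which keeps the empirical Bayes intercepts informative
(corr(û, u) ≈ √(nᵢλ/(1+nᵢλ)) ≈ 0.86 for followed-up subjects). The
study-shaped simulation also adds a shared *visit-level* component
(loadings N(0, 0.5²), one latent N(0,1) per subject-visit): sample
handling and physiological state correlate all metabolites measured
together, which is precisely what single-timepoint analyses cannot remove
but the repeated-measures decomposition relegates to ε. This component is
optional and off by default in `simulate_metabolome` itself.

What passing tests show: the estimators recover their own generating
models (loadings up to oblique rotation on the correlation scale, variance
components, planted graphs and partitions) at realistic sizes and
signal-to-noise. What they do not show: behavior under real NMR noise,
lipoprotein correlation strength, non-Gaussian metabolite distributions,
or FFQ reporting bias — none of which the generator attempts to mimic.

## Problem sizes and determinism

Default analyses run at the study scale (575 observations × 55
metabolites; StARS with 100 × 50 glasso fits per network) in a few minutes
on one CPU; simulation studies in the suite use 200 replicates at n = 300
subjects with 5 metabolites and 2 factors, and planted-graph recovery uses
p = 20, n = 400 with 50 subsamples over 30 penalties. Every stochastic
stage consumes an explicit seed (the pipeline derives per-stage seeds from
the single config seed), so identical configurations reproduce identical
outputs, including subsampling paths.

## Known limitations

- The dynamic hybrid tree cut is a faithful two-stage re-implementation,
  not a bit-compatible port; label-level agreement with other software is
  not guaranteed.
- glasso support along a λ path is not strictly nested; rare one- or
  two-edge drops near λ → 0 are logged, not errors.
- The per-metabolite mixed models ignore cross-metabolite dependence of ε
  (fitting is marginal per metabolite by design).
- Girvan–Newman betweenness on large dense graphs is O(|E|²·p)-ish; at
  p = 55 this is seconds, but the implementation is not tuned for hundreds
  of nodes.
- Ỹ_L rows of a subject are dependent while glasso assumes i.i.d. rows;
  both the literal (all rows) and the within-subject-average modes are
  exposed, defaulting to the literal one.
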