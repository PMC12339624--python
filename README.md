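# metabnet

Metabolite networks *subject to* chosen sources of variation, from
repeated-measures cohort data.

Serum metabolite concentrations fluctuate with diet, genetics, demographics,
time, and a residual subject-specific component one can call *lifestyle*.
When the same subjects are measured at two timepoints, a random-intercepts
linear mixed model can separate these sources: for metabolite *p*,

    Y(p) = β₀ + β₁·Age + β₂·Sex + β₃·T + β₄·F + β₅·G
         + (all two-way interactions Age∘Sex, Age∘T, Age∘F, Age∘G,
            Sex∘T, Sex∘F, Sex∘G, T∘F, T∘G, F∘G)
         + u(p) + ε(p),

where **F** are diet factor scores from an exploratory factor analysis of a
food-frequency questionnaire (principal-axis factoring, oblimin rotation,
ten Berge scores), **G** is a metabolite-specific polygenic risk score
(Σⱼ ηⱼ Sⱼ over SNP dosages), T is the binary timepoint, Age is binarized at
50, and u(p) ~ N(0, σ²ᵤ) is the subject-level random intercept —
*lifestyle*, the stable subject signal not attributable to the measured
covariates.

The **diet + lifestyle part** of each metabolite,

    Ỹ_L(p) = β̂₄F + β̂₈(Age∘F) + β̂₁₁(Sex∘F) + β̂₁₃(T∘F) + β̂₁₅(F∘G) + û(p),

(or the analogous **time part** Ỹ_T) replaces the raw concentrations as
input to Gaussian graphical model estimation: the graphical lasso maximizes
`log|Θ| − tr(KΘ) − λ‖Θ‖₁` with K the sample covariance of Ỹ_L, λ selected
by StARS stability subsampling. Edges of the selected graph are weighted by
their subsampling frequency (intensity matrix **W**), modules are found by a
two-step dynamic hybrid tree cut on 1−W and by the Girvan–Newman algorithm,
and networks/modules are described by density, centralization, and
heterogeneity of node strengths.

Cohort data of this kind are typically restricted-access, so the package
ships a study-shaped synthetic generator (364 subjects at baseline, 211 at
follow-up, 55 metabolites, 6 latent diets over 55 FFQ items, 48 SNPs) with
planted ground truth for every stage — loadings, effect sizes, fixed
effects, and a sparse block-diagonal precision matrix for the intercepts —
so the whole pipeline is quantitatively testable.

## Worked example

```bash
metabnet run-all --outdir demo --seed 1
```

simulates the default cohort, runs every stage, and writes (among others)
`demo/network.graphml`, `demo/modules.tsv`, `demo/summary.tsv`, and
`demo/report.json`. A run at seed 1 prints a report containing

```
"lambda_opt": 0.392,  "n_edges": 127,
"density": 0.074,     "heterogeneity": 0.69,
"n_modules_treecut": 10,  "n_modules_girvan_newman": 9,
"benchmark": {"0": {"n_modules_reported": 5}, "1": {"n_modules_reported": 3}}
```

read as: StARS picked penalty λ ≈ 0.39 giving a 127-edge network over the
55 metabolites; the tree cut found 10 modules (7 with ≥ 5 metabolites)
against 12 planted ones, while the per-timepoint benchmark — OLS residuals
on Age, Sex, Age∘Sex within each timepoint, then the same network estimator
— supports at most 5 reported modules: correcting for diet, genetics, time
and lifestyle yields the more modular, better separated network.

The same stages are available programmatically:

```python
import metabnet as mn

cfg = mn.PipelineConfig(outdir="demo", seed=1)
res = mn.run_all(cfg)
res["network"].n_edges          # 127
res["partition_treecut"].n_modules
```

or piecewise (`simulate`, `diets`, `prs`, `decompose`, `network`,
`modules`, `characterize` subcommands, chained through `--outdir`).

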