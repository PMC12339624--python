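"""Synthetic cohort generator with full ground truth.

Emulates the shape of a two-timepoint population metabolomics study: 364
subjects at baseline of whom 211 return at follow-up seven years later,
~55 metabolites, 6 latent diet factors expressed through ~55 ordinal FFQ
items (1-8 scale), and 48 SNPs with known effect sizes. Subject-level
random intercepts are drawn from a known sparse block-diagonal precision
matrix, so the conditional-independence graph and module partition of the
diet+lifestyle signal are planted and every downstream stage (EFA, PRS,
mixed model, glasso/StARS, clustering) can be scored against truth.

The generator makes no attempt to mimic NMR noise physics or real
lipoprotein correlation values; it reproduces the study's design and
signal-to-noise structure, not its biochemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .decompose import CovariateBundle, build_design
from .efa import FFQTable
from .io_config import PipelineConfig, RepeatedMeasuresDataset
from .prs import EffectSizeTable, GenotypeMatrix, PRSMatrix, compute_prs


@dataclass
class SimulationTruth:
    L_true: np.ndarray
    Phi_true: np.ndarray
    f_true: pd.DataFrame  # subjects x factors
    eta_true: pd.DataFrame  # SNPs x metabolites
    beta_true: pd.DataFrame  # design labels x metabolites
    sigma_u_true: pd.Series
    sigma_eps_true: pd.Series
    Theta_true: np.ndarray
    u_true: pd.DataFrame  # subjects x metabolites
    module_labels_true: dict  # metabolite -> module id
    edges_true: list = field(default_factory=list)  # index pairs (i, j), i < j

    def adjacency_true(self) -> np.ndarray:
        p = self.Theta_true.shape[0]
        A = (self.Theta_true != 0).astype(int)
        np.fill_diagonal(A, 0)
        return A


def simulate_genotypes(
    n_subjects: int,
    n_snps: int = 48,
    maf_range=(0.1, 0.5),
    seed: int = 0,
    subject_ids=None,
) -> GenotypeMatrix:
    """Independent biallelic dosages: S_ij ~ Binomial(2, maf_j)."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    S = rng.binomial(2, maf, size=(n_subjects, n_snps))
    if subject_ids is None:
        subject_ids = [f"S{i + 1:04d}" for i in range(n_subjects)]
    cols = [f"snp{j + 1:02d}" for j in range(n_snps)]
    return GenotypeMatrix(pd.DataFrame(S, index=subject_ids, columns=cols))


def default_loadings(
    n_items: int = 55,
    n_factors: int = 6,
    seed: int = 0,
    cross_loadings: bool = True,
) -> np.ndarray:
    """Block-structured loading matrix: each factor owns a contiguous set of
    items with primary loadings in [0.5, 0.8]; with ``cross_loadings`` every
    third item also carries a modest loading on the next factor (FFQ tables
    are rarely perfectly simple-structured). ``cross_loadings=False`` gives
    the exactly identifiable simple-structure case."""
    rng = np.random.default_rng(seed)
    L = np.zeros((n_items, n_factors))
    owners = np.array_split(np.arange(n_items), n_factors)
    for j, idx in enumerate(owners):
        L[idx, j] = rng.uniform(0.5, 0.8, size=len(idx))
        if cross_loadings:
            for k, i in enumerate(idx):
                if k % 3 == 2:
                    L[i, (j + 1) % n_factors] = rng.uniform(0.2, 0.3)
    return L


def simulate_ffq(
    n_subjects: int,
    L_true: np.ndarray,
    Phi_true: np.ndarray,
    noise_sd: float = 0.7,
    n_levels: int | None = 8,
    seed: int = 0,
    subject_ids=None,
):
    """FFQ items from the linear factor model o = L f + eps, then discretized
    to 1..n_levels by equal-probability bins (n_levels=None keeps o continuous).
    Returns (FFQTable, true factor scores)."""
    L_true = np.asarray(L_true, float)
    Phi_true = np.asarray(Phi_true, float)
    try:
        chol = np.linalg.cholesky(Phi_true)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Phi_true must be positive definite") from exc
    rng = np.random.default_rng(seed)
    m = L_true.shape[1]
    f = rng.standard_normal((n_subjects, m)) @ chol.T
    o = f @ L_true.T + noise_sd * rng.standard_normal((n_subjects, L_true.shape[0]))
    if n_levels is not None:
        ranks = np.apply_along_axis(lambda c: rankdata(c, method="ordinal"), 0, o)
        o = np.ceil(ranks * n_levels / n_subjects).astype(int)
        o = np.clip(o, 1, n_levels)
    if subject_ids is None:
        subject_ids = [f"S{i + 1:04d}" for i in range(n_subjects)]
    items = pd.DataFrame(
        o, index=subject_ids,
        columns=[f"item{i + 1:02d}" for i in range(L_true.shape[0])],
    )
    f_frame = pd.DataFrame(
        f, index=subject_ids, columns=[f"F{j + 1}" for j in range(m)]
    )
    return FFQTable(items), f_frame


def make_block_precision(
    p: int = 55,
    n_modules: int = 12,
    partial: float = 0.35,
    extra_edge_prob: float = 0.5,
    seed: int = 0,
):
    """Sparse SPD precision matrix with block-diagonal (planted-module)
    support: a random spanning tree per block plus extra within-block edges.
    Returns (Theta, module labels per node, edge list)."""
    rng = np.random.default_rng(seed)
    sizes = [len(b) for b in np.array_split(np.arange(p), n_modules)]
    Theta = np.eye(p)
    labels = np.zeros(p, int)
    start = 0
    for b, size in enumerate(sizes):
        idx = np.arange(start, start + size)
        labels[idx] = b + 1
        for k in range(1, size):
            j = int(rng.integers(0, k))
            Theta[idx[j], idx[k]] = Theta[idx[k], idx[j]] = -partial * rng.uniform(
                0.8, 1.2
            )
        for a in range(size):
            for c in range(a + 1, size):
                if Theta[idx[a], idx[c]] == 0 and rng.random() < extra_edge_prob:
                    Theta[idx[a], idx[c]] = Theta[idx[c], idx[a]] = -partial * (
                        rng.uniform(0.8, 1.2)
                    )
        start += size
    evmin = float(np.linalg.eigvalsh(Theta).min())
    if evmin < 0.2:
        Theta += (0.2 - evmin) * np.eye(p)
    d = np.sqrt(np.diag(Theta))
    Theta = Theta / np.outer(d, d)
    iu = np.triu_indices(p, 1)
    edges = [(int(i), int(j)) for i, j in zip(*iu) if Theta[i, j] != 0]
    return Theta, labels, edges


def simulate_covariates(
    n_subjects: int = 364,
    followup_fraction: float = 153 / 364,
    seed: int = 0,
    interval_years: float = 7.0,
) -> pd.DataFrame:
    """Per-(subject, timepoint) covariate rows: age (uniform 25-74 at
    baseline, +interval at follow-up), sex, and clean exclusion fields.
    ``followup_fraction`` of subjects are measured only at baseline
    (0 = fully balanced: everyone returns)."""
    if not (0 <= followup_fraction <= 1):
        raise ValueError("followup_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    age0 = rng.uniform(25, 74, size=n_subjects)
    sex = rng.integers(0, 2, size=n_subjects)
    n_drop = int(round(followup_fraction * n_subjects))
    dropped = set(rng.choice(n_subjects, size=n_drop, replace=False))
    rows = []
    for i, sid in enumerate(subjects):
        base = {
            "subject_id": sid,
            "sex": int(sex[i]),
            "diabetes": 0,
            "glucose": float(np.minimum(rng.normal(5.3, 0.7), 9.9)),
            "ffq_complete": 1,
        }
        rows.append({**base, "timepoint": 0, "age": float(age0[i])})
        if i not in dropped:
            rows.append({**base, "timepoint": 1, "age": float(age0[i] + interval_years)})
    return pd.DataFrame(rows)


def default_effect_sizes(
    n_snps: int, metabolites, seed: int = 0, scale: float = 0.15
) -> EffectSizeTable:
    rng = np.random.default_rng(seed)
    snps = [f"snp{j + 1:02d}" for j in range(n_snps)]
    eta = pd.DataFrame(
        rng.normal(0.0, scale, size=(n_snps, len(metabolites))),
        index=snps, columns=list(metabolites),
    )
    pv = pd.DataFrame(
        rng.uniform(size=(n_snps, len(metabolites))), index=snps,
        columns=list(metabolites),
    )
    return EffectSizeTable(eta=eta, p_value=pv)


def default_fixed_effects(
    labels, metabolites, module_labels, factor_names, seed: int = 0
) -> pd.DataFrame:
    """Fixed-effect truth: metabolites in the same planted module share
    similar diet responses (module-level coefficient plus small jitter);
    other blocks carry modest effects.

    Scales keep diet a minority share of metabolite variance (diet typically
    explains well under a quarter of metabolite variation in cohort data),
    so the subject-level intercepts dominate the diet+lifestyle signal and
    its conditional-independence graph stays close to the planted precision.
    """
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(0.0, index=labels, columns=list(metabolites))
    module_diet = {
        m: rng.normal(0.0, 0.25, size=len(factor_names))
        for m in sorted(set(module_labels.values()))
    }
    for met in metabolites:
        for lab in labels:
            block = int(lab.split(":")[0][1:])
            if block == 0:
                beta.loc[lab, met] = rng.normal(0.0, 0.5)
            elif block in (1, 2, 3):
                beta.loc[lab, met] = rng.normal(0.0, 0.3)
            elif block == 4:
                j = factor_names.index(lab.split(":")[1])
                beta.loc[lab, met] = module_diet[module_labels[met]][j] + rng.normal(
                    0.0, 0.05
                )
            elif block == 5:
                beta.loc[lab, met] = rng.normal(0.0, 0.2)
            else:
                beta.loc[lab, met] = rng.normal(0.0, 0.05)
    return beta


def simulate_metabolome(
    bundle: CovariateBundle,
    beta_true: pd.DataFrame,
    Theta_true: np.ndarray,
    sigma_eps,
    followup_fraction: float | None = None,
    seed: int = 0,
    visit_loadings=None,
):
    """Metabolite concentrations under the random-intercepts model.

    Each subject's intercept vector u is drawn from N(0, inv(Theta_true));
    observations follow y = X beta + u + eps. If ``followup_fraction`` is
    given, that fraction of subjects is additionally reduced to baseline
    only. ``visit_loadings`` (length p, optional) adds a shared visit-level
    component w_p * v_it with v_it ~ N(0, 1) per (subject, timepoint) —
    sample-handling / physiological-state variation that correlates all
    metabolites measured at the same visit but carries no subject-level
    signal. Returns (RepeatedMeasuresDataset, u_true as subjects x
    metabolites).
    """
    if followup_fraction is not None and not (0 < followup_fraction <= 1):
        raise ValueError("followup_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    metabolites = list(beta_true.columns)
    p = len(metabolites)
    if Theta_true.shape != (p, p):
        raise ValueError("Theta_true shape does not match metabolite count")
    Sigma_u = np.linalg.inv(Theta_true)
    chol = np.linalg.cholesky(Sigma_u)
    subjects = list(pd.unique(bundle.subject_id))
    u = rng.standard_normal((len(subjects), p)) @ chol.T
    u_true = pd.DataFrame(u, index=subjects, columns=metabolites)
    sigma_eps = pd.Series(
        np.broadcast_to(np.asarray(sigma_eps, float), (p,)).copy(), index=metabolites
    )
    visit = rng.standard_normal(bundle.n_obs) if visit_loadings is not None else None
    cols = {}
    for i, met in enumerate(metabolites):
        design = build_design(bundle, met)
        mu = design.X @ beta_true.loc[design.labels, met].to_numpy()
        noise = sigma_eps[met] * rng.standard_normal(bundle.n_obs)
        if visit is not None:
            noise = noise + float(np.asarray(visit_loadings)[i]) * visit
        cols[met] = mu + u_true[met].reindex(bundle.subject_id).to_numpy() + noise
    frame = pd.DataFrame(
        {"subject_id": bundle.subject_id, "timepoint": bundle.timepoint, **cols}
    )
    if followup_fraction is not None:
        n_drop = int(round(followup_fraction * len(subjects)))
        dropped = set(
            np.asarray(subjects, object)[
                rng.choice(len(subjects), size=n_drop, replace=False)
            ]
        )
        keep = ~(frame["subject_id"].isin(dropped) & (frame["timepoint"] == 1))
        frame = frame[keep].reset_index(drop=True)
    return RepeatedMeasuresDataset(frame), u_true


@dataclass
class SimulatedStudy:
    dataset: RepeatedMeasuresDataset
    covariates: pd.DataFrame
    ffq: FFQTable
    genotypes: GenotypeMatrix
    effects: EffectSizeTable
    prs: PRSMatrix
    bundle: CovariateBundle
    truth: SimulationTruth


def simulate_study(config: PipelineConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Full study-shaped simulation driven by a PipelineConfig.

    All stage seeds derive from the single config seed, so identical configs
    give byte-identical outputs.
    """
    cfg = config or PipelineConfig()
    if seed is None:
        seed = cfg.seed
    master = np.random.default_rng(seed)
    sub = {
        k: int(s)
        for k, s in zip(
            ("cov", "ffq", "geno", "eta", "theta", "beta", "met", "visit"),
            master.integers(0, 2**31 - 1, size=8),
        )
    }
    covariates = simulate_covariates(
        cfg.n_subjects, cfg.followup_fraction, seed=sub["cov"]
    )
    subjects = list(covariates["subject_id"].unique())
    m = cfg.n_factors
    L_true = default_loadings(cfg.n_ffq_items, m, seed=sub["ffq"])
    Phi_true = np.full((m, m), 0.25)
    np.fill_diagonal(Phi_true, 1.0)
    ffq, f_true = simulate_ffq(
        len(subjects), L_true, Phi_true, seed=sub["ffq"], subject_ids=subjects
    )
    genotypes = simulate_genotypes(
        len(subjects), cfg.n_snps, seed=sub["geno"], subject_ids=subjects
    )
    metabolites = [f"M{i + 1:02d}" for i in range(cfg.n_metabolites)]
    effects = default_effect_sizes(cfg.n_snps, metabolites, seed=sub["eta"])
    prs = compute_prs(genotypes, effects, top_l=cfg.top_l)
    Theta_true, node_modules, edges = make_block_precision(
        cfg.n_metabolites, cfg.n_modules_true, seed=sub["theta"]
    )
    module_labels = {met: int(node_modules[i]) for i, met in enumerate(metabolites)}
    obs = covariates.sort_values(["subject_id", "timepoint"]).reset_index(drop=True)
    bundle = CovariateBundle(
        subject_id=obs["subject_id"].to_numpy(),
        age_years=obs["age"].to_numpy(float),
        sex=obs["sex"].to_numpy(int),
        timepoint=obs["timepoint"].to_numpy(int),
        F=f_true.loc[obs["subject_id"]].reset_index(drop=True),
        G=prs.G.loc[obs["subject_id"]].reset_index(drop=True),
    )
    labels = build_design(bundle, metabolites[0]).labels
    beta_true = default_fixed_effects(
        labels, metabolites, module_labels, list(f_true.columns), seed=sub["beta"]
    )
    sigma_u_true = pd.Series(
        np.sqrt(np.diag(np.linalg.inv(Theta_true))), index=metabolites
    )
    # ICC 2/3: the stable subject-level (lifestyle) component dominates the
    # within-subject noise, as for lipid-class metabolites over long
    # intervals; with <= 2 observations per subject this keeps the empirical
    # Bayes intercepts informative (corr(u_hat, u) ~ sqrt(n*lam/(1+n*lam)))
    sigma_eps_true = sigma_u_true / np.sqrt(2.0)
    # shared visit-level variation (sample handling, fasting state): pollutes
    # single-timepoint analyses but is not subject-level signal, so the
    # repeated-measures decomposition largely removes it
    visit_loadings = np.random.default_rng(sub["visit"]).normal(
        0.0, 0.5, size=cfg.n_metabolites
    )
    dataset, u_true = simulate_metabolome(
        bundle, beta_true, Theta_true, sigma_eps_true.to_numpy(), seed=sub["met"],
        visit_loadings=visit_loadings,
    )
    truth = SimulationTruth(
        L_true=L_true,
        Phi_true=Phi_true,
        f_true=f_true,
        eta_true=effects.eta,
        beta_true=beta_true,
        sigma_u_true=sigma_u_true,
        sigma_eps_true=sigma_eps_true,
        Theta_true=Theta_true,
        u_true=u_true,
        module_labels_true=module_labels,
        edges_true=edges,
    )
    return SimulatedStudy(
        dataset=dataset,
        covariates=covariates,
        ffq=ffq,
        genotypes=genotypes,
        effects=effects,
        prs=prs,
        bundle=bundle,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write all tables in the formats the readers expect, plus the ground
    truth as a JSON sidecar for test harnesses."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.dataset.data.to_csv(out / "metabolites.csv", index=False)
    study.covariates.to_csv(out / "covariates.csv", index=False)
    study.ffq.items.rename_axis("subject_id").to_csv(out / "ffq.tsv", sep="\t")
    study.genotypes.S.rename_axis("subject_id").to_csv(out / "genotypes.tsv", sep="\t")
    eta_long = (
        study.effects.eta.rename_axis("snp_id")
        .reset_index()
        .melt(id_vars="snp_id", var_name="metabolite", value_name="eta")
    )
    pv_long = (
        study.effects.p_value.rename_axis("snp_id")
        .reset_index()
        .melt(id_vars="snp_id", var_name="metabolite", value_name="p_value")
    )
    eta_long.merge(pv_long, on=["snp_id", "metabolite"]).to_csv(
        out / "effects.tsv", sep="\t", index=False
    )
    t = study.truth
    payload = {
        "L_true": t.L_true.tolist(),
        "Phi_true": t.Phi_true.tolist(),
        "f_true": t.f_true.to_dict(orient="index"),
        "beta_true": t.beta_true.to_dict(orient="index"),
        "sigma_u_true": t.sigma_u_true.to_dict(),
        "sigma_eps_true": t.sigma_eps_true.to_dict(),
        "Theta_true": t.Theta_true.tolist(),
        "u_true": t.u_true.to_dict(orient="index"),
        "module_labels_true": t.module_labels_true,
        "edges_true": t.edges_true,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh)
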