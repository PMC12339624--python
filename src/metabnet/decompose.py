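"""Per-metabolite random-intercept mixed models and variance-part extraction.

Each metabolite is modeled independently as

    Y = X beta + u_subject + eps,

where X contains intercept, Age (binarized at 50), Sex, time T, the m diet
factor scores F, the metabolite-specific polygenic score G, and all two-way
interactions Age*Sex, Age*T, Age*F, Age*G, Sex*T, Sex*F, Sex*G, T*F, T*G,
F*G (q = 11 + 5m columns). The random intercept u is the subject-specific
deviation shared across timepoints and is interpreted as lifestyle: it is
conditioned on diet, genetics, demographics and time, so it collects the
unmeasured subject-level sources of variation.

Estimation is REML by profiling the variance ratio lam = sigma_u^2/sigma_eps^2:
given lam, beta has a closed-form GLS solution and the profiled criterion is
a smooth scalar function minimized numerically, with an ML fallback on
failure. Empirical Bayes intercepts are u_i = (n_i lam / (1 + n_i lam)) *
mean residual of subject i — subjects observed once shrink harder.

Two signal matrices are reconstructed from a fit:
 - diet+lifestyle part: beta4 F + beta8 Age*F + beta11 Sex*F + beta13 T*F
   + beta15 F*G + u (exactly these terms);
 - time part: beta3 T + beta7 Age*T + beta10 Sex*T + beta13 T*F + beta14 T*G
   (no u; every term carries T).
These are the inputs to network estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize_scalar

from .io_config import RepeatedMeasuresDataset
from .prs import PRSMatrix

logger = logging.getLogger("metabnet")

DIET_LIFESTYLE_BLOCKS = (4, 8, 11, 13, 15)
TIME_BLOCKS = (3, 7, 10, 13, 14)


def binarize_age(age_years):
    """0 for age < 50, 1 for age >= 50 (0/1 coding of the 1/2 convention)."""
    a = np.asarray(age_years, float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite age")
    if np.any(a <= 0):
        raise ValueError("age must be positive")
    out = (a >= 50).astype(int)
    return int(out) if np.isscalar(age_years) else out


# ---------------------------------------------------------------------------
# exclusion filters

EXCLUSION_COLUMNS = ("subject_id", "diabetes", "glucose", "age", "sex", "ffq_complete")


def apply_exclusions(dataset: RepeatedMeasuresDataset, covariates: pd.DataFrame):
    """Remove subjects with a diabetes diagnosis, fasting glucose > 10 mmol/l
    (strict), or incomplete age/sex/FFQ information. Returns the filtered
    dataset and a per-criterion count report."""
    missing = [c for c in EXCLUSION_COLUMNS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks required columns: {missing}")
    by_subj = covariates.groupby("subject_id")
    diabetic = set(by_subj["diabetes"].max().pipe(lambda s: s[s > 0]).index)
    high_glucose = set(by_subj["glucose"].max().pipe(lambda s: s[s > 10.0]).index)
    incomplete = set()
    for sid, grp in by_subj:
        if (
            grp["age"].isna().any()
            or grp["sex"].isna().any()
            or grp["ffq_complete"].isna().any()
            or (grp["ffq_complete"] == 0).any()
        ):
            incomplete.add(sid)
    excluded = diabetic | high_glucose | incomplete
    keep = ~dataset.data["subject_id"].isin(excluded)
    out = RepeatedMeasuresDataset(
        dataset.data[keep].reset_index(drop=True), dataset.timepoint_labels
    )
    report = {
        "diabetes": len(diabetic),
        "glucose_over_10": len(high_glucose),
        "incomplete_information": len(incomplete),
        "excluded_subjects": len(excluded),
        "retained_subjects": int(out.data["subject_id"].nunique()),
    }
    return out, report


# ---------------------------------------------------------------------------
# covariates and design


@dataclass
class CovariateBundle:
    """Per-observation covariates aligned with a dataset's rows.

    F and G are replicated across a subject's timepoints (diet scores are
    assumed constant over the study interval; genotypes do not change).
    Age is binarized from the age at each measurement.
    """

    subject_id: np.ndarray
    age_years: np.ndarray
    sex: np.ndarray
    timepoint: np.ndarray
    F: pd.DataFrame  # n_obs x m
    G: pd.DataFrame  # n_obs x p (one column per metabolite)

    def __post_init__(self):
        n = len(self.subject_id)
        for name in ("age_years", "sex", "timepoint"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} misaligned with subject_id")
        if len(self.F) != n or len(self.G) != n:
            raise ValueError("F/G misaligned with observations")
        for sid in np.unique(self.subject_id):
            rows = np.where(self.subject_id == sid)[0]
            if len(rows) > 1:
                if not np.allclose(
                    self.F.iloc[rows].to_numpy(), self.F.iloc[rows[0]].to_numpy()
                ):
                    raise ValueError(f"factor scores differ across timepoints: {sid}")
                if not np.allclose(
                    self.G.iloc[rows].to_numpy(), self.G.iloc[rows[0]].to_numpy()
                ):
                    raise ValueError(f"PRS differs across timepoints: {sid}")

    @property
    def age_binary(self) -> np.ndarray:
        return binarize_age(self.age_years)

    @property
    def n_obs(self) -> int:
        return len(self.subject_id)

    @property
    def factor_names(self) -> list:
        return list(self.F.columns)


def build_covariate_bundle(
    dataset: RepeatedMeasuresDataset,
    covariates: pd.DataFrame,
    factor_scores: pd.DataFrame,
    prs: PRSMatrix,
) -> CovariateBundle:
    """Align per-(subject, timepoint) covariates and per-subject F, G with
    the dataset's observation rows."""
    obs = dataset.data[["subject_id", "timepoint"]]
    cov = obs.merge(
        covariates[["subject_id", "timepoint", "age", "sex"]],
        on=["subject_id", "timepoint"],
        how="left",
        validate="one_to_one",
    )
    if cov["age"].isna().any() or cov["sex"].isna().any():
        raise ValueError("covariate table missing rows for some observations")
    F = factor_scores.loc[obs["subject_id"]].reset_index(drop=True)
    G = prs.G.loc[obs["subject_id"]].reset_index(drop=True)
    return CovariateBundle(
        subject_id=obs["subject_id"].to_numpy(),
        age_years=cov["age"].to_numpy(float),
        sex=cov["sex"].to_numpy(int),
        timepoint=obs["timepoint"].to_numpy(int),
        F=F,
        G=G,
    )


@dataclass
class DesignMatrix:
    X: np.ndarray  # n_obs x q
    labels: list  # per-column "b<block>:<name>"
    blocks: dict  # block index -> list of column indices

    @property
    def q(self) -> int:
        return self.X.shape[1]


def build_design(bundle: CovariateBundle, metabolite: str) -> DesignMatrix:
    """Fixed-effects design for one metabolite (its own PRS column).

    Interaction columns are elementwise products of their parent columns.
    Warns on rank deficiency naming the offending columns.
    """
    age = bundle.age_binary.astype(float)
    sex = np.asarray(bundle.sex, float)
    T = np.asarray(bundle.timepoint, float)
    F = bundle.F.to_numpy(float)
    fnames = bundle.factor_names
    g = bundle.G[metabolite].to_numpy(float)
    n = bundle.n_obs
    cols, labels = [], []

    def add(vec, label):
        cols.append(np.asarray(vec, float))
        labels.append(label)

    add(np.ones(n), "b0:intercept")
    add(age, "b1:Age")
    add(sex, "b2:Sex")
    add(T, "b3:T")
    for j, fn in enumerate(fnames):
        add(F[:, j], f"b4:{fn}")
    add(g, "b5:G")
    add(age * sex, "b6:Age*Sex")
    add(age * T, "b7:Age*T")
    for j, fn in enumerate(fnames):
        add(age * F[:, j], f"b8:Age*{fn}")
    add(age * g, "b9:Age*G")
    add(sex * T, "b10:Sex*T")
    for j, fn in enumerate(fnames):
        add(sex * F[:, j], f"b11:Sex*{fn}")
    add(sex * g, "b12:Sex*G")
    for j, fn in enumerate(fnames):
        add(T * F[:, j], f"b13:T*{fn}")
    add(T * g, "b14:T*G")
    for j, fn in enumerate(fnames):
        add(F[:, j] * g, f"b15:{fn}*G")
    X = np.column_stack(cols)
    blocks: dict = {}
    for i, lab in enumerate(labels):
        b = int(lab.split(":")[0][1:])
        blocks.setdefault(b, []).append(i)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True, mode="economic")
        dropped = [labels[i] for i in piv[rank:]]
        warnings.warn(f"design is rank deficient; dependent columns: {dropped}",
                      stacklevel=2)
    return DesignMatrix(X=X, labels=labels, blocks=blocks)


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class LMMFit:
    metabolite: str
    beta_hat: np.ndarray
    beta_labels: list
    blocks: dict
    sigma2_u: float
    sigma2_eps: float
    u_hat: pd.Series  # one entry per subject
    loglik: float
    converged: bool
    method: str = "reml"
    cov_beta: np.ndarray | None = None
    identifiable: bool = True

    def wald_ci(self, level: float = 0.95):
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.cov_beta))
        return np.column_stack([self.beta_hat - z * se, self.beta_hat + z * se])


def _profiled_criterion(log_lam, XtX, Xty, yty, S, ysum, n_i, n, q, reml):
    lam = np.exp(log_lam)
    c = lam / (1.0 + lam * n_i)
    XtViX = XtX - (S * c[:, None]).T @ S
    XtViy = Xty - S.T @ (c * ysum)
    yViy = yty - float(c @ ysum**2)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf, None
    quad = yViy - 2 * beta @ XtViy + beta @ XtViX @ beta
    # equals r' V*^{-1} r with r = y - X beta
    if quad <= 0:
        return np.inf, None
    logdet_v = float(np.sum(np.log1p(lam * n_i)))
    dof = n - q if reml else n
    crit = dof * np.log(quad) + logdet_v
    if reml:
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None
        crit += logdet_x
    return crit, (beta, quad, XtViX)


def fit_random_intercept_lmm(
    y,
    design: DesignMatrix,
    subject_ids,
    method: str = "reml",
    metabolite: str = "y",
) -> LMMFit:
    """REML fit of the random-intercept model via profiled likelihood.

    The variance ratio is optimized on the log scale (floored at 1e-10 on the
    variance scale); ML is used as a fallback if the REML surface is
    degenerate, and the fit is flagged accordingly.
    """
    y = np.asarray(y, float)
    X = design.X
    n, q = X.shape
    subject_ids = np.asarray(subject_ids)
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        _, _, piv = qr(X, pivoting=True, mode="economic")
        dropped = [design.labels[i] for i in piv[rank:]]
        raise ValueError(f"singular design; dependent columns: {dropped}")
    subjects, idx = np.unique(subject_ids, return_inverse=True)
    n_subj = len(subjects)
    n_i = np.bincount(idx).astype(float)
    identifiable = int(np.sum(n_i >= 2)) >= 2
    if not identifiable:
        warnings.warn(
            "fewer than 2 subjects with repeated observations; "
            "sigma_u is not identifiable",
            stacklevel=2,
        )
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    S = np.zeros((n_subj, q))
    np.add.at(S, idx, X)
    ysum = np.bincount(idx, weights=y)

    def run(reml):
        def f(u):
            return _profiled_criterion(u, XtX, Xty, yty, S, ysum, n_i, n, q, reml)[0]

        grid = np.linspace(-15.0, 8.0, 47)
        vals = np.array([f(u) for u in grid])
        if not np.isfinite(vals).any():
            return None
        u0 = grid[int(np.nanargmin(vals))]
        res = minimize_scalar(
            f, bounds=(max(-15.0, u0 - 1.5), min(8.0, u0 + 1.5)),
            method="bounded", options={"xatol": 1e-10},
        )
        u_best = res.x if res.fun <= vals.min() else grid[int(np.nanargmin(vals))]
        crit, parts = _profiled_criterion(
            u_best, XtX, Xty, yty, S, ysum, n_i, n, q, reml
        )
        # boundary check: sigma_u ~ 0
        crit0, parts0 = _profiled_criterion(
            -30.0, XtX, Xty, yty, S, ysum, n_i, n, q, reml
        )
        if crit0 < crit:
            u_best, crit, parts = -30.0, crit0, parts0
        if parts is None:
            return None
        return u_best, crit, parts

    used = method.lower()
    out = run(used == "reml")
    if out is None and used == "reml":
        used = "ml"
        out = run(False)
    if out is None:
        raise RuntimeError("mixed-model optimization failed")
    u_best, crit, (beta, quad, XtViX) = out
    lam = np.exp(u_best)
    dof = n - q if used == "reml" else n
    sigma2_eps = max(quad / dof, 1e-10)
    sigma2_u = max(lam * sigma2_eps, 0.0)
    if lam < 1e-9:
        sigma2_u = max(sigma2_u, 0.0)
    resid = y - X @ beta
    rsum = np.bincount(idx, weights=resid)
    shrink = lam * n_i / (1.0 + lam * n_i)
    u_hat = shrink * (rsum / n_i)
    cov_beta = sigma2_eps * np.linalg.inv(XtViX)
    const = dof * (1 + np.log(2 * np.pi)) - dof * np.log(dof)
    loglik = -0.5 * (crit + const)
    return LMMFit(
        metabolite=metabolite,
        beta_hat=beta,
        beta_labels=design.labels,
        blocks=design.blocks,
        sigma2_u=float(sigma2_u),
        sigma2_eps=float(sigma2_eps),
        u_hat=pd.Series(u_hat, index=subjects),
        loglik=float(loglik),
        converged=True,
        method=used,
        cov_beta=cov_beta,
        identifiable=identifiable,
    )


def fit_metabolome(
    dataset: RepeatedMeasuresDataset,
    bundle: CovariateBundle,
    log_transform: bool = False,
    zscore: bool = False,
    method: str = "reml",
) -> dict:
    """Fit the random-intercept model independently for every metabolite."""
    fits = {}
    for met in dataset.metabolites:
        y = dataset.data[met].to_numpy(float)
        if log_transform:
            if np.any(y <= 0):
                raise ValueError(f"log transform needs positive values: {met}")
            y = np.log(y)
        if zscore:
            y = (y - y.mean()) / y.std(ddof=1)
        design = build_design(bundle, met)
        fits[met] = fit_random_intercept_lmm(
            y, design, bundle.subject_id, method=method, metabolite=met
        )
    return fits


# ---------------------------------------------------------------------------
# variance-part extraction


@dataclass
class DecomposedMatrix:
    frame: pd.DataFrame  # subject_id, timepoint, then metabolite columns
    part: str  # 'diet_lifestyle' or 'time'
    provenance: str = ""

    @property
    def metabolites(self) -> list:
        return [c for c in self.frame.columns if c not in ("subject_id", "timepoint")]

    def values(self) -> np.ndarray:
        return self.frame[self.metabolites].to_numpy(float)

    def averaged_within_subject(self) -> pd.DataFrame:
        """One row per subject (mean over timepoints); optional glasso input."""
        return self.frame.groupby("subject_id")[self.metabolites].mean()


def _block_sum(fit: LMMFit, X: np.ndarray, blocks) -> np.ndarray:
    cols = [c for b in blocks for c in fit.blocks.get(b, [])]
    return X[:, cols] @ fit.beta_hat[cols]


def _extract(fits, bundle: CovariateBundle, blocks, include_u, part) -> DecomposedMatrix:
    if not isinstance(fits, dict):
        fits = {fits.metabolite: fits}
    cols = {}
    for met, fit in fits.items():
        design = build_design(bundle, met)
        if fit.beta_labels != design.labels:
            raise ValueError(f"covariates misaligned with fit for {met}")
        v = _block_sum(fit, design.X, blocks)
        if include_u:
            v = v + fit.u_hat.reindex(bundle.subject_id).to_numpy()
        cols[met] = v
    frame = pd.DataFrame(
        {"subject_id": bundle.subject_id, "timepoint": bundle.timepoint, **cols}
    )
    return DecomposedMatrix(frame=frame, part=part)


def extract_diet_lifestyle_part(fits, bundle: CovariateBundle) -> DecomposedMatrix:
    """Diet+lifestyle signal: F, Age*F, Sex*F, T*F and F*G terms plus the
    empirical Bayes intercept, replicated over each subject's observations."""
    return _extract(fits, bundle, DIET_LIFESTYLE_BLOCKS, True, "diet_lifestyle")


def extract_time_part(fits, bundle: CovariateBundle) -> DecomposedMatrix:
    """Time signal: T, Age*T, Sex*T, T*F and T*G terms (no random intercept);
    identically zero wherever T = 0."""
    return _extract(fits, bundle, TIME_BLOCKS, False, "time")


# ---------------------------------------------------------------------------
# per-timepoint benchmark


def residualize_per_timepoint(
    dataset: RepeatedMeasuresDataset, bundle: CovariateBundle
) -> dict:
    """OLS residuals of each metabolite on [1, Age, Sex, Age*Sex], separately
    per timepoint — the benchmark that ignores the repeated-measures design."""
    out = {}
    for t in sorted(np.unique(bundle.timepoint)):
        rows = np.where(bundle.timepoint == t)[0]
        if len(rows) < 5:
            raise ValueError(f"timepoint {t}: need >= 5 observations")
        age = bundle.age_binary[rows].astype(float)
        sex = np.asarray(bundle.sex, float)[rows]
        X = np.column_stack([np.ones(len(rows)), age, sex, age * sex])
        Y = dataset.data.iloc[rows][dataset.metabolites].to_numpy(float)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        out[int(t)] = pd.DataFrame(
            resid,
            columns=dataset.metabolites,
            index=dataset.data.iloc[rows]["subject_id"],
        )
    return out


def fit_summary_frame(fits: dict) -> pd.DataFrame:
    """One row per metabolite: variance components and labeled coefficients."""
    rows = []
    for met, fit in fits.items():
        row = {
            "metabolite": met,
            "sigma2_u": fit.sigma2_u,
            "sigma2_eps": fit.sigma2_eps,
            "loglik": fit.loglik,
            "method": fit.method,
            "converged": fit.converged,
        }
        row.update(dict(zip(fit.beta_labels, fit.beta_hat)))
        rows.append(row)
    return pd.DataFrame(rows)
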