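"""Gaussian graphical model estimation: glasso, StARS selection, stability weights.

The estimator maximizes the penalized Gaussian log-likelihood
``log|Theta| - tr(K Theta) - lambda * ||Theta||_1`` (penalty on off-diagonal
entries; the diagonal is unpenalized, so the fitted covariance matches K on
the diagonal). Regularization is chosen by StARS: graphs are re-estimated on
random subsamples over a descending lambda grid, per-edge selection
frequencies xi give a total edge instability

    D(lambda) = 2 / (p (p-1)) * sum_{i<j} 2 xi_ij (1 - xi_ij),

and the optimal lambda is the smallest (densest graph) whose monotonized
instability stays below the ``beta_stars`` threshold. The selected graph's
edges are weighted by xi, giving the intensity matrix W used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import glasso_cd

logger = logging.getLogger("metabnet")


@dataclass
class GlassoFit:
    Theta_hat: np.ndarray
    Sigma_hat: np.ndarray
    lam: float
    K: np.ndarray
    penalized_loglik: float
    converged: bool = True


@dataclass
class StabilityPath:
    lambda_grid: np.ndarray  # descending
    xi: np.ndarray  # (n_lambda, p, p) edge frequencies
    instability: np.ndarray
    monotone_instability: np.ndarray
    lambda_opt: float
    opt_index: int
    n_subsamples: int
    subsample_size: int
    seed: int
    sparsity: np.ndarray | None = None


@dataclass
class Network:
    A: np.ndarray  # binary adjacency, zero diagonal
    W: np.ndarray  # edge stability intensity in [0, 1]
    nodes: list = field(default_factory=list)
    lambda_opt: float | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, int)
        self.W = np.asarray(self.W, float)
        if not self.nodes:
            self.nodes = [f"n{i}" for i in range(self.A.shape[0])]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum() // 2)


def _as_matrix(values):
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(float), list(values.columns)
    arr = np.asarray(values, float)
    return arr, [f"v{i}" for i in range(arr.shape[1])]


def sample_covariance(values, standardize: bool = False) -> np.ndarray:
    """Unbiased sample covariance (divisor n-1), or correlation if standardized."""
    X, names = _as_matrix(values)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant column(s): {bad}")
    if standardize:
        return np.corrcoef(X, rowvar=False)
    return np.cov(X, rowvar=False, ddof=1)


def penalized_loglik(Theta: np.ndarray, K: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return -np.inf
    off = ~np.eye(Theta.shape[0], dtype=bool)
    return float(logdet - np.trace(K @ Theta) - lam * np.abs(Theta[off]).sum())


def glasso_fit(
    K: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 200,
    penalize_diagonal: bool = False,
    warm=None,
) -> GlassoFit:
    """Graphical lasso at a single penalty.

    ``penalize_diagonal=True`` applies the l1 penalty to the diagonal as well,
    via the exact reduction to the off-diagonal problem on K + lam*I
    (the fitted covariance then has Sigma_ii = K_ii + lam).
    """
    K = np.asarray(K, float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    scale = max(1.0, float(np.max(np.abs(np.diag(K)))))
    evmin = float(np.linalg.eigvalsh(K).min())
    if evmin < -1e-8 * scale:
        raise ValueError(f"K is not positive semidefinite (min eigenvalue {evmin:.3e})")
    if evmin < 0:
        K = K + (-evmin + 1e-12) * np.eye(K.shape[0])
    Kwork = K + lam * np.eye(K.shape[0]) if penalize_diagonal else K
    if lam == 0:
        theta = np.linalg.inv(Kwork)
        return GlassoFit(theta, Kwork.copy(), 0.0, K, penalized_loglik(theta, K, 0.0))
    W0, B0 = (None, None) if warm is None else warm
    theta, W, B, n_sweeps, converged = glasso_cd(
        Kwork, lam, W=W0, B=B0, tol=tol, max_iter=max_iter
    )
    if not converged:
        warnings.warn(f"glasso did not converge at lambda={lam:.4g}", stacklevel=2)
    fit = GlassoFit(theta, W.copy(), float(lam), K, penalized_loglik(theta, K, lam), converged)
    fit._warm = (W, B)  # reusable warm-start state
    return fit


def kkt_residual(fit: GlassoFit, use_inverse: bool = True) -> float:
    """Max violation of the glasso stationarity conditions.

    For off-diagonal entries: Sigma_ij - K_ij = lam * sign(Theta_ij) where
    Theta_ij != 0, |Sigma_ij - K_ij| <= lam where Theta_ij = 0; on the
    diagonal Sigma_ii = K_ii (unpenalized diagonal convention).
    """
    K, lam = fit.K, fit.lam
    Sigma = np.linalg.inv(fit.Theta_hat) if use_inverse else fit.Sigma_hat
    R = Sigma - K
    p = K.shape[0]
    off = ~np.eye(p, dtype=bool)
    nz = (fit.Theta_hat != 0) & off
    z = (~nz) & off
    res = float(np.max(np.abs(np.diag(R))))
    if nz.any():
        res = max(res, float(np.max(np.abs(R[nz] - lam * np.sign(fit.Theta_hat[nz])))))
    if z.any():
        res = max(res, max(0.0, float(np.max(np.abs(R[z])) - lam)))
    return res


def make_lambda_grid(K: np.ndarray, n_lambda: int = 50, min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max off-diagonal |K|."""
    off = ~np.eye(K.shape[0], dtype=bool)
    lam_max = float(np.max(np.abs(K[off])))
    if lam_max <= 0:
        raise ValueError("all off-diagonal covariances are zero")
    return np.exp(np.linspace(np.log(lam_max), np.log(min_ratio * lam_max), n_lambda))


def _edge_support(theta: np.ndarray) -> np.ndarray:
    A = (theta != 0).astype(np.int64)
    np.fill_diagonal(A, 0)
    return A


def _glasso_path(K, lambda_grid, tol, max_iter, penalize_diagonal):
    """Warm-started fits along a descending lambda grid; yields supports."""
    supports = np.empty((len(lambda_grid), K.shape[0], K.shape[0]), np.int64)
    warm = None
    for g, lam in enumerate(lambda_grid):
        fit = glasso_fit(
            K, lam, tol=tol, max_iter=max_iter,
            penalize_diagonal=penalize_diagonal, warm=warm,
        )
        warm = fit._warm
        supports[g] = _edge_support(fit.Theta_hat)
    return supports


def stars_select(
    values,
    lambda_grid=None,
    n_subsamples: int = 100,
    subsample_size: int | None = None,
    beta_stars: float = 0.05,
    seed: int = 0,
    standardize: bool = False,
    subsample_unit: str = "observation",
    subject_ids=None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 200,
    penalize_diagonal: bool = False,
) -> StabilityPath:
    """StARS regularization selection by subsampling without replacement.

    Default subsample size is floor(10 sqrt(n)) capped at 0.8 n. With
    ``subsample_unit='subject'`` all rows of a subject enter together.
    """
    X, _ = _as_matrix(values)
    n, p = X.shape
    if not (0 < beta_stars < 1):
        raise ValueError("beta_stars must be in (0, 1)")
    if subsample_unit == "subject":
        if subject_ids is None:
            raise ValueError("subject_ids required when subsampling subjects")
        units = np.unique(np.asarray(subject_ids))
        n_units = len(units)
    else:
        n_units = n
    if subsample_size is None:
        subsample_size = min(int(10 * np.sqrt(n_units)), int(0.8 * n_units))
        subsample_size = max(subsample_size, p + 1) if n_units > p + 1 else subsample_size
    if subsample_size >= n_units:
        raise ValueError("subsample_size must be < number of sampling units")
    K_full = sample_covariance(X, standardize=standardize)
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(K_full, n_lambda, lambda_min_ratio)
    lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(lambda_grid), p, p), np.int64)
    for _ in range(n_subsamples):
        if subsample_unit == "subject":
            chosen = rng.choice(n_units, size=subsample_size, replace=False)
            mask = np.isin(np.asarray(subject_ids), units[chosen])
            rows = np.where(mask)[0]
        else:
            rows = rng.choice(n, size=subsample_size, replace=False)
        Ks = sample_covariance(X[rows], standardize=standardize)
        counts += _glasso_path(Ks, lambda_grid, tol, max_iter, penalize_diagonal)
    xi = counts / float(n_subsamples)
    iu = np.triu_indices(p, 1)
    inst = np.array(
        [2.0 / (p * (p - 1)) * np.sum(2 * x[iu] * (1 - x[iu])) for x in xi]
    )
    mono = np.maximum.accumulate(inst)  # running max from sparsest lambda down
    ok = np.where(mono <= beta_stars)[0]
    if len(ok) == 0:
        logger.warning(
            "no lambda meets instability threshold %.3g; returning sparsest", beta_stars
        )
        opt_index = 0
    else:
        opt_index = int(ok.max())  # smallest lambda still stable
    supports_full = _glasso_path(K_full, lambda_grid, tol, max_iter, penalize_diagonal)
    sparsity = supports_full.sum(axis=(1, 2)) / 2
    return StabilityPath(
        lambda_grid=lambda_grid,
        xi=xi,
        instability=inst,
        monotone_instability=mono,
        lambda_opt=float(lambda_grid[opt_index]),
        opt_index=opt_index,
        n_subsamples=n_subsamples,
        subsample_size=subsample_size,
        seed=seed,
        sparsity=sparsity,
    )


def build_network(
    path: StabilityPath,
    values,
    standardize: bool = False,
    nodes=None,
    tol: float = 1e-7,
    max_iter: int = 200,
    penalize_diagonal: bool = False,
) -> Network:
    """Adjacency from the full-data glasso at lambda_opt; W = A * xi(lambda_opt)."""
    X, names = _as_matrix(values)
    K = sample_covariance(X, standardize=standardize)
    fit = glasso_fit(
        K, path.lambda_opt, tol=tol, max_iter=max_iter,
        penalize_diagonal=penalize_diagonal,
    )
    A = _edge_support(fit.Theta_hat)
    W = A * path.xi[path.opt_index]
    return Network(A=A, W=W, nodes=list(nodes) if nodes is not None else names,
                   lambda_opt=path.lambda_opt)


def stability_path_frame(path: StabilityPath) -> pd.DataFrame:
    """Stability path as a table: lambda, sparsity, instability, monotonized."""
    return pd.DataFrame(
        {
            "lambda": path.lambda_grid,
            "sparsity": path.sparsity if path.sparsity is not None else np.nan,
            "instability": path.instability,
            "monotone_instability": path.monotone_instability,
        }
    )
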