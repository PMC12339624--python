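"""Exploratory factor analysis of food-frequency data.

Dietary patterns are extracted from the item correlation matrix by principal
axis factoring: the reduced correlation matrix (communalities on the
diagonal, initialized at squared multiple correlations) is repeatedly
eigendecomposed until the communalities stabilize. The unrotated solution is
made interpretable by direct quartimin (oblimin with gamma = 0) rotation via
gradient projection, which allows correlated factors with correlation Phi.
Factor scores use the ten Berge construction, whose defining property is
that in-sample score correlations reproduce Phi exactly.

The number of factors is a user input; ``scree_eigenvalues`` supports the
choice but nothing here auto-selects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class FFQTable:
    """Food-frequency items (ordinal or continuous), subjects in rows."""

    items: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.items)

    @property
    def item_names(self) -> list:
        return list(self.items.columns)

    def matrix(self) -> np.ndarray:
        return self.items.to_numpy(float)


@dataclass
class EFAModel:
    loadings: np.ndarray  # pattern matrix, items x m
    factor_correlation: np.ndarray  # Phi, m x m
    uniquenesses: np.ndarray  # Psi diagonal, length items
    rotation: str = "oblimin"
    rotation_params: dict = field(default_factory=dict)
    n_iter: int = 0
    converged: bool = True
    heywood: bool = False
    item_names: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        # communality + uniqueness = 1 on the correlation scale
        return 1.0 - self.uniquenesses


@dataclass
class FactorScores:
    scores: np.ndarray  # subjects x m
    method: str = "tenberge"


def _item_matrix(ffq) -> tuple[np.ndarray, list]:
    if isinstance(ffq, FFQTable):
        return ffq.matrix(), ffq.item_names
    if isinstance(ffq, pd.DataFrame):
        return ffq.to_numpy(float), list(ffq.columns)
    arr = np.asarray(ffq, float)
    return arr, [f"item{i}" for i in range(arr.shape[1])]


def _correlation(X: np.ndarray, names) -> np.ndarray:
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant item(s), correlation undefined: {bad}")
    return np.corrcoef(X, rowvar=False)


def scree_eigenvalues(ffq) -> np.ndarray:
    """Eigenvalues of the item correlation matrix, descending (sum = n_items)."""
    X, names = _item_matrix(ffq)
    R = _correlation(X, names)
    return np.sort(np.linalg.eigvalsh(R))[::-1]


def kaiser_count(ffq) -> int:
    """Number of correlation-matrix eigenvalues above 1 (reported, never auto-used)."""
    return int(np.sum(scree_eigenvalues(ffq) > 1.0))


# ---------------------------------------------------------------------------
# principal axis factoring


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations; ridge fallback for singular R."""
    try:
        Rinv = np.linalg.inv(R)
        d = np.diag(Rinv)
        if np.any(d <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(R.shape[0]))
        d = np.diag(Rinv)
    return np.clip(1.0 - 1.0 / d, 0.0, 1.0)


def _principal_axis(R: np.ndarray, m: int, max_iter: int, tol: float):
    h2 = _smc(R)
    converged = False
    heywood = False
    L = None
    for it in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        w, V = np.linalg.eigh(Rr)
        order = np.argsort(w)[::-1][:m]
        w_m = np.clip(w[order], 0.0, None)
        L = V[:, order] * np.sqrt(w_m)
        h2_new = np.sum(L**2, axis=1)
        if np.any(h2_new > 1.0):
            heywood = True
            h2_new = np.minimum(h2_new, 1.0)
        delta = float(np.max(np.abs(h2_new - h2)))
        h2 = h2_new
        if delta < tol:
            converged = True
            break
    return L, h2, it, converged, heywood


# ---------------------------------------------------------------------------
# oblimin (direct quartimin) rotation by oblique gradient projection


def _quartimin(L: np.ndarray):
    L2 = L**2
    m = L.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    M = L2 @ N
    f = float(np.sum(L2 * M)) / 4.0
    return f, L * M


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, tol: float = 1e-6, max_iter: int = 1000):
    """Gradient projection rotation (oblique); returns (L, Phi, criterion, ok)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    ok = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = float(np.sqrt(np.sum(Gp**2)))
        if s < tol:
            ok = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _quartimin(Lt)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T = X
        f = ft
        L = Lt
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi, f, ok


def _order_and_sign(L: np.ndarray, Phi: np.ndarray):
    """Factors ordered by sum of squared loadings; largest |loading| positive."""
    order = np.argsort(np.sum(L**2, axis=0))[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            signs[j] = -1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    return L, Phi


def fit_efa(
    ffq,
    n_factors: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    rotate: bool = True,
    n_restarts: int = 10,
    rotation_seed: int = 0,
) -> EFAModel:
    """Principal-axis EFA with oblimin(0) rotation.

    Rotation restarts from the identity plus ``n_restarts`` random orthonormal
    starts (seeded); the solution with the lowest quartimin criterion wins.
    """
    X, names = _item_matrix(ffq)
    R = _correlation(X, names)
    n_items = R.shape[0]
    if not (1 <= n_factors <= n_items):
        raise ValueError("n_factors must be in [1, n_items]")
    if n_factors > n_items / 3:
        warnings.warn(
            f"n_factors={n_factors} is large for {n_items} items", stacklevel=2
        )
    L0, h2, it, converged, heywood = _principal_axis(R, n_factors, max_iter, tol)
    if not converged:
        warnings.warn("principal axis iteration did not converge", stacklevel=2)
    if rotate and n_factors > 1:
        rng = np.random.default_rng(rotation_seed)
        best = None
        starts = [np.eye(n_factors)]
        for _ in range(n_restarts):
            Q, _ = np.linalg.qr(rng.normal(size=(n_factors, n_factors)))
            starts.append(Q)
        for T0 in starts:
            L, Phi, f, ok = _gpa_oblique(L0, T0)
            if best is None or f < best[2]:
                best = (L, Phi, f, ok)
        L, Phi, _, rot_ok = best
        converged = converged and rot_ok
        rotation = "oblimin"
    else:
        L, Phi = L0, np.eye(n_factors)
        rotation = "none"
    L, Phi = _order_and_sign(L, Phi)
    psi = np.clip(1.0 - h2, 1e-12, 1.0)
    return EFAModel(
        loadings=L,
        factor_correlation=Phi,
        uniquenesses=psi,
        rotation=rotation,
        rotation_params={"gamma": 0.0, "n_restarts": n_restarts},
        n_iter=it,
        converged=converged,
        heywood=heywood,
        item_names=names,
    )


# ---------------------------------------------------------------------------
# ten Berge factor scores


def _sym_power(M: np.ndarray, power: float, ridge: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh(M + ridge * np.eye(M.shape[0]))
    if power < 0 and np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    w = np.clip(w, 0.0, None) if power > 0 else w
    return (V * w**power) @ V.T


def tenberge_scores(model: EFAModel, ffq) -> FactorScores:
    """Correlation-preserving factor scores.

    With R the item correlation, Lambda the pattern loadings and Phi the
    factor correlation: C = R^(-1/2) Lambda Phi^(1/2), scores =
    Z R^(-1/2) C (C'C)^(-1/2) Phi^(1/2). In-sample score correlations equal
    Phi exactly when R is nonsingular.
    """
    X, names = _item_matrix(ffq)
    R = _correlation(X, names)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cond = np.linalg.cond(R)
    ridge = 1e-8 if cond > 1e10 else 0.0
    if ridge:
        warnings.warn("near-singular item correlation; using ridge", stacklevel=2)
    R_isqrt = _sym_power(R, -0.5, ridge=ridge)
    Phi_sqrt = _sym_power(model.factor_correlation, 0.5)
    C = R_isqrt @ model.loadings @ Phi_sqrt
    CtC = C.T @ C
    w = np.linalg.eigvalsh(CtC)
    if w.min() < 1e-12 * max(1.0, w.max()):
        raise np.linalg.LinAlgError(
            "singular C'C in ten Berge scoring; reduce n_factors"
        )
    F = Z @ R_isqrt @ C @ _sym_power(CtC, -0.5) @ Phi_sqrt
    return FactorScores(scores=F, method="tenberge")


# ---------------------------------------------------------------------------
# comparison helpers (used by tests and simulation checks)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(np.abs(a @ b) / np.sqrt((a @ a) * (b @ b)))


def match_factors(L_est: np.ndarray, L_true: np.ndarray):
    """Match estimated to true factors by maximal congruence (Hungarian).

    Returns (permutation, per-factor congruences after matching).
    """
    m = L_true.shape[1]
    cost = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            cost[i, j] = -tucker_congruence(L_est[:, i], L_true[:, j])
    ri, ci = linear_sum_assignment(cost)
    perm = np.empty(m, int)
    cong = np.empty(m)
    for i, j in zip(ri, ci):
        perm[j] = i
        cong[j] = -cost[i, j]
    return perm, cong


def loadings_frame(model: EFAModel, threshold: float | None = None) -> pd.DataFrame:
    """Loadings as a table (items x factors); small entries blanked if thresholded."""
    cols = [f"F{j + 1}" for j in range(model.n_factors)]
    df = pd.DataFrame(model.loadings, index=model.item_names, columns=cols)
    if threshold is not None:
        df = df.where(df.abs() >= threshold)
    return df
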