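"""Network and module characterization, and diet-response profile curves.

For a square symmetric zero-diagonal matrix M (adjacency or intensity) with
node strengths s_i = sum_j M_ij:

* density        = sum_{i != j} M_ij / (p (p-1))   — mean edge intensity;
* centralization = (max(s) - mean(s)) / p          — star-likeness;
* heterogeneity  = sd(s) / mean(s)                 — coefficient of variation
  of strengths (sample variance, divisor p-1, by default).

Profile curves summarize how each metabolite's diet+lifestyle signal varies
with each diet factor score, using a cubic smoothing spline with
GCV-selected penalty evaluated on a 50-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .modules import ModulePartition
from .network import Network


def _check_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return M


def node_degrees_strengths(network: Network):
    """(degree, strength) per node: row sums of A and of W."""
    return network.A.sum(axis=1), network.W.sum(axis=1)


def density(M) -> float:
    M = _check_square(M)
    p = M.shape[0]
    off = ~np.eye(p, dtype=bool)
    return float(M[off].sum() / (p * (p - 1)))


def centralization(M) -> float:
    M = _check_square(M)
    s = M.sum(axis=1)
    return float((s.max() - s.mean()) / M.shape[0])


def heterogeneity(M, population_variance: bool = False) -> float:
    M = _check_square(M)
    s = M.sum(axis=1)
    if s.mean() == 0:
        raise ValueError("heterogeneity undefined: mean strength is zero")
    ddof = 0 if population_variance else 1
    return float(np.sqrt(s.var(ddof=ddof)) / s.mean())


@dataclass
class NetworkSummary:
    table: pd.DataFrame  # one row per network/module
    degrees: pd.Series
    strengths: pd.Series


def summarize(
    network: Network,
    partition: ModulePartition | None = None,
    min_report_size: int = 5,
) -> NetworkSummary:
    """Whole-network measures plus one row per module of size >= min_report_size.

    Module measures are computed on the induced W submatrix. Smaller modules
    stay in the partition but are not reported; singletons are skipped.
    """
    deg, stren = node_degrees_strengths(network)
    rows = [
        {
            "module": "complete_network",
            "density": density(network.W),
            "centralization": centralization(network.W),
            "heterogeneity": heterogeneity(network.W)
            if network.W.sum() > 0
            else np.nan,
            "n_nodes": network.p,
        }
    ]
    if partition is not None:
        missing = [n for n in network.nodes if n not in partition.labels]
        if missing:
            raise ValueError(f"partition does not cover nodes: {missing}")
        idx = {n: i for i, n in enumerate(network.nodes)}
        for mid, members in sorted(partition.module_members().items()):
            if mid == 0 or len(members) < max(2, min_report_size):
                continue
            sub = network.W[np.ix_([idx[n] for n in members], [idx[n] for n in members])]
            rows.append(
                {
                    "module": f"module_{mid}",
                    "density": density(sub),
                    "centralization": centralization(sub),
                    "heterogeneity": heterogeneity(sub) if sub.sum() > 0 else np.nan,
                    "n_nodes": len(members),
                }
            )
    return NetworkSummary(
        table=pd.DataFrame(rows),
        degrees=pd.Series(deg, index=network.nodes, name="degree"),
        strengths=pd.Series(stren, index=network.nodes, name="strength"),
    )


def profile_curves(
    decomposed,
    factor_scores: pd.DataFrame,
    partition: ModulePartition | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Smoothed metabolite-vs-diet response curves, grouped by module.

    For every (metabolite, diet factor) pair, a cubic smoothing spline of the
    decomposed signal on the factor score (duplicate scores averaged first)
    evaluated on an n_grid-point grid over the observed score range. With
    fewer than 10 distinct scores a linear fit is used and flagged.
    """
    Y = decomposed.frame[decomposed.metabolites]
    if len(factor_scores) != len(Y):
        raise ValueError("factor scores misaligned with decomposed rows")
    rows = []
    for fac in factor_scores.columns:
        x = factor_scores[fac].to_numpy(float)
        grid = np.linspace(x.min(), x.max(), n_grid)
        for met in decomposed.metabolites:
            y = Y[met].to_numpy(float)
            agg = pd.DataFrame({"x": x, "y": y}).groupby("x")["y"].mean()
            xu, yu = agg.index.to_numpy(), agg.to_numpy()
            linear = len(xu) < 10
            if np.allclose(yu, yu[0]):
                fitted = np.full(n_grid, yu[0])
            elif linear:
                c = np.polyfit(xu, yu, 1)
                fitted = np.polyval(c, grid)
            else:
                spl = make_smoothing_spline(xu, yu)
                fitted = spl(grid)
            module = partition.labels.get(met) if partition is not None else None
            for g, f in zip(grid, fitted):
                rows.append(
                    {
                        "metabolite": met,
                        "diet": fac,
                        "x": g,
                        "fitted_y": f,
                        "module": module,
                        "linear_fallback": linear,
                    }
                )
    return pd.DataFrame(rows)
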