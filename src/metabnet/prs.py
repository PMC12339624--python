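"""Polygenic risk scores: per-metabolite weighted allele-dosage sums.

For subject i and a metabolite, G_i = sum_j eta_j S_ij over the top-ranked
SNPs for that metabolite, with dosages S in {0, 1, 2} and effect sizes eta
taken from an external association study. G enters the mixed model as a
metabolite-specific covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    S: pd.DataFrame  # subjects x SNPs, entries in {0, 1, 2}

    def __post_init__(self):
        vals = self.S.to_numpy()
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be in {0, 1, 2}")

    @property
    def snp_ids(self) -> list:
        return list(self.S.columns)

    @property
    def subjects(self) -> list:
        return list(self.S.index)


@dataclass
class EffectSizeTable:
    """Per-SNP, per-metabolite effect sizes, optional ranking p-values."""

    eta: pd.DataFrame  # SNPs x metabolites
    p_value: pd.DataFrame | None = None

    def __post_init__(self):
        if not np.isfinite(self.eta.to_numpy(float)).all():
            raise ValueError("effect sizes must be finite")
        if self.p_value is not None:
            if list(self.p_value.index) != list(self.eta.index) or list(
                self.p_value.columns
            ) != list(self.eta.columns):
                raise ValueError("p_value table must align with eta")

    @property
    def snp_ids(self) -> list:
        return list(self.eta.index)

    @property
    def metabolites(self) -> list:
        return list(self.eta.columns)


@dataclass
class PRSMatrix:
    G: pd.DataFrame  # subjects x metabolites
    standardized: bool = False
    selected_snps: dict = field(default_factory=dict)


def compute_prs(
    genotypes: GenotypeMatrix, effects: EffectSizeTable, top_l: int | None = None
) -> PRSMatrix:
    """PRS per metabolite over the top_l ranked SNPs (default: all).

    Ranking is by ascending p-value, ties by |eta| descending, then snp_id.
    """
    if list(genotypes.snp_ids) != list(effects.snp_ids):
        raise ValueError("snp_ids differ between genotype and effect tables")
    n_snps = len(effects.snp_ids)
    if top_l is None:
        top_l = n_snps
    if not (1 <= top_l <= n_snps):
        raise ValueError("top_l must be in [1, number of SNPs]")
    if top_l < n_snps and effects.p_value is None:
        raise ValueError("ranking statistic (p_value) required when top_l < l")
    S = genotypes.S.to_numpy(float)
    G = {}
    selected = {}
    for met in effects.metabolites:
        eta = effects.eta[met].to_numpy(float)
        if top_l == n_snps:
            keep = np.arange(n_snps)
        else:
            pv = effects.p_value[met].to_numpy(float)
            order = sorted(
                range(n_snps),
                key=lambda j: (pv[j], -abs(eta[j]), str(effects.snp_ids[j])),
            )
            keep = np.array(order[:top_l])
        G[met] = S[:, keep] @ eta[keep]
        selected[met] = [effects.snp_ids[j] for j in keep]
    frame = pd.DataFrame(G, index=genotypes.subjects)[effects.metabolites]
    return PRSMatrix(G=frame, selected_snps=selected)


def standardize_prs(prs: PRSMatrix) -> PRSMatrix:
    """Center and scale each PRS column to unit variance (idempotent)."""
    G = prs.G
    sd = G.std(axis=0, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance PRS column(s): {list(zero.index)}")
    out = (G - G.mean(axis=0)) / sd
    return PRSMatrix(G=out, standardized=True, selected_snps=prs.selected_snps)
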