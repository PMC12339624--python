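"""Tabular and graph I/O, pipeline configuration.

Long (tidy) format is the canonical representation for repeated-measures
observations: one row per (subject, timepoint). Wide metabolite matrices are
derived views. Networks round-trip through GraphML or a 3-column TSV edge
list; adjacency is reproduced exactly and edge weights to 1e-12.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metabnet")

RESERVED_COLUMNS = ("subject_id", "timepoint")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _write_table(df: pd.DataFrame, path, index=False) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=index)


@dataclass
class RepeatedMeasuresDataset:
    """Metabolite concentrations keyed by (subject, timepoint).

    ``data`` holds subject_id, timepoint (coerced to {0,1}) and one numeric
    column per metabolite. Unbalanced follow-up (subjects present at a single
    timepoint) is allowed and expected.
    """

    data: pd.DataFrame
    timepoint_labels: dict = field(default_factory=dict)

    @property
    def metabolites(self) -> list:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    def values(self) -> np.ndarray:
        return self.data[self.metabolites].to_numpy(float)

    def timepoint_slice(self, t: int) -> "RepeatedMeasuresDataset":
        sub = self.data[self.data["timepoint"] == t].reset_index(drop=True)
        return RepeatedMeasuresDataset(sub, self.timepoint_labels)


def read_long_table(path) -> RepeatedMeasuresDataset:
    """Read a long-format metabolite table (CSV/TSV).

    Requires subject_id and timepoint columns plus >= 1 metabolite column.
    Timepoint labels (e.g. 2007/2014) map to {0,1} by sort order. Duplicate
    (subject, timepoint) rows and non-numeric metabolite cells are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long table {path} lacks required columns: {missing}")
    mets = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not mets:
        raise ValueError(f"long table {path} has no metabolite columns")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        rows = df.loc[dup, ["subject_id", "timepoint"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, timepoint) rows, first at subject_id="
            f"{rows['subject_id']!r} timepoint={rows['timepoint']!r}"
        )
    for c in mets:
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any() and not df[c].isna().all():
            bad = df.index[col.isna() & df[c].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric metabolite value in column {c!r}, row {bad[0]}"
                )
        if col.isna().any():
            raise ValueError(f"missing metabolite value in column {c!r}")
        df[c] = col.astype(float)
    levels = sorted(df["timepoint"].unique())
    if len(levels) > 2:
        raise ValueError(f"timepoint must be binary, got levels {levels}")
    mapping = {lab: i for i, lab in enumerate(levels)}
    df = df.copy()
    df["timepoint"] = df["timepoint"].map(mapping).astype(int)
    return RepeatedMeasuresDataset(
        df.reset_index(drop=True), timepoint_labels={v: k for k, v in mapping.items()}
    )


def write_long_table(dataset: RepeatedMeasuresDataset, path) -> None:
    _write_table(dataset.data, path)


# ---------------------------------------------------------------------------
# network writers/readers


def _check_network_matrices(A: np.ndarray, W: np.ndarray) -> None:
    if A.shape != W.shape or A.shape[0] != A.shape[1]:
        raise ValueError("A and W must be square matrices of the same shape")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency A must be symmetric")
    if not np.array_equal(W, W.T):
        raise ValueError("intensity W must be symmetric")
    if np.any(np.diag(A) != 0) or np.any(np.diag(W) != 0):
        raise ValueError("A and W must have zero diagonal")


def write_network(network, path, format: str = "graphml") -> None:
    """Write a network (adjacency A + intensity W) to GraphML or TSV edge list.

    The edge list has columns node_i, node_j, weight; isolated nodes are kept
    as self-rows with weight 0 so that round-tripping preserves the node set.
    """
    A = np.asarray(network.A)
    W = np.asarray(network.W, float)
    _check_network_matrices(A, W)
    nodes = list(network.nodes)
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if A[i, j]:
                    g.add_edge(nodes[i], nodes[j], weight=float(W[i, j]))
        nx.write_graphml(g, path)
    elif format == "edgelist_tsv":
        rows = []
        deg = A.sum(axis=1)
        for i in range(len(nodes)):
            if deg[i] == 0:
                rows.append((nodes[i], nodes[i], 0.0))
            for j in range(i + 1, len(nodes)):
                if A[i, j]:
                    rows.append((nodes[i], nodes[j], repr(float(W[i, j]))))
        pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml"):
    from .network import Network

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        p = len(nodes)
        A = np.zeros((p, p), int)
        W = np.zeros((p, p))
        for u, v, d in g.edges(data=True):
            i, j = idx[u], idx[v]
            A[i, j] = A[j, i] = 1
            W[i, j] = W[j, i] = float(d.get("weight", 0.0))
        return Network(A=A, W=W, nodes=nodes)
    elif format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"node_i": str, "node_j": str})
        nodes: list = []
        for col in ("node_i", "node_j"):
            for n in df[col]:
                if n not in nodes:
                    nodes.append(n)
        idx = {n: i for i, n in enumerate(nodes)}
        p = len(nodes)
        A = np.zeros((p, p), int)
        W = np.zeros((p, p))
        for _, r in df.iterrows():
            i, j = idx[r["node_i"]], idx[r["node_j"]]
            if i == j:
                continue
            A[i, j] = A[j, i] = 1
            W[i, j] = W[j, i] = float(r["weight"])
        return Network(A=A, W=W, nodes=nodes)
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All knobs for the pipeline, overridable from the CLI.

    StARS settings follow the convention of selecting the densest graph whose
    monotonized edge instability stays below ``beta_stars``.
    """

    # input paths (None -> simulate)
    metabolite_table: str | None = None
    covariate_table: str | None = None
    ffq_table: str | None = None
    genotype_table: str | None = None
    effects_table: str | None = None
    outdir: str = "metabnet_out"

    # dietary factors
    n_factors: int = 6

    # PRS
    top_l: int | None = None
    standardize_prs: bool = False

    # decomposition
    log_transform: bool = False
    zscore_metabolites: bool = False
    average_within_subject: bool = False

    # network / StARS
    standardize_yl: bool = False
    n_subsamples: int = 100
    subsample_size: int | None = None
    beta_stars: float = 0.05
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    subsample_unit: str = "observation"
    penalize_diagonal: bool = False

    # clustering
    min_module_size: int = 3
    deep_split: int = 2
    cut_height: float = 0.99
    linkage: str = "average"
    gn_weighted_betweenness: bool = False

    # characterization
    min_report_size: int = 5

    # simulation defaults (DILGOM-shaped)
    n_subjects: int = 364
    followup_fraction: float = 153 / 364
    n_metabolites: int = 55
    n_ffq_items: int = 55
    n_snps: int = 48
    n_modules_true: int = 12

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0 < self.beta_stars < 1):
            raise ValueError("beta_stars must be in (0, 1)")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.followup_fraction <= 1):
            raise ValueError("followup_fraction must be in (0, 1]")
        if self.subsample_unit not in ("observation", "subject"):
            raise ValueError("subsample_unit must be 'observation' or 'subject'")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def check_subsample_size(self, n_obs: int) -> None:
        if self.subsample_size is not None and self.subsample_size >= n_obs:
            raise ValueError("subsample_size must be < n_observations")


def setup_logging(outdir=None, level=logging.INFO) -> logging.Logger:
    logger.setLevel(level)
    logger.handlers = [logging.StreamHandler()]
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(outdir) / "metabnet.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger
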