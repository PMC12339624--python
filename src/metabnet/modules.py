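"""Module identification on the stability-weighted network.

Two complementary algorithms:

* a two-step dynamic hybrid tree cut on the dendrogram built from 1 - W as
  dissimilarity: stage 1 detects branches of the average-linkage tree that
  are tight (merge height below ``cut_height``), well separated (merge gap
  criterion controlled by ``deep_split``) and large enough
  (``min_module_size``); stage 2 assigns leftover nodes to the module with
  the smallest average dissimilarity when that distance is below
  ``cut_height``, otherwise they stay unassigned (label 0);
* the Girvan-Newman divisive algorithm: edges of highest betweenness
  (computed on the adjacency; ties broken by lexicographic node pair) are
  removed iteratively, and the partition of the removal sequence maximizing
  Newman-Girvan modularity (weighted by W) is returned.

The tree cut follows the published two-stage logic but does not promise
label-for-label agreement with other implementations; its contract is
planted-partition recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import squareform

from .network import Network

# deep_split presets: thresholds on the scaled merge-height range
# (higher preset = more aggressive splitting). ``split`` is the scaled height
# above which a merge is considered a between-module join; ``gap`` is the
# minimum scaled separation between a merge and its children for a deep split.
_DEEP_SPLIT = {
    0: {"split": 0.95, "gap": 0.30},
    1: {"split": 0.92, "gap": 0.22},
    2: {"split": 0.90, "gap": 0.15},
    3: {"split": 0.85, "gap": 0.08},
    4: {"split": 0.80, "gap": 0.04},
}


@dataclass
class ModulePartition:
    labels: dict  # node -> module id (0 = unassigned, tree cut only)
    algorithm: str
    parameters: dict = field(default_factory=dict)
    modularity: float | None = None

    @property
    def n_modules(self) -> int:
        return len({m for m in self.labels.values() if m != 0})

    def module_members(self) -> dict:
        out: dict = {}
        for node, m in self.labels.items():
            out.setdefault(m, []).append(node)
        return out

    def labels_array(self, nodes) -> np.ndarray:
        return np.array([self.labels[n] for n in nodes])


def dissimilarity_from_W(W: np.ndarray) -> np.ndarray:
    """D = 1 - W off-diagonal, zero diagonal."""
    W = np.asarray(W, float)
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if np.any(W < 0) or np.any(W > 1):
        raise ValueError("W entries must lie in [0, 1]")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have zero diagonal")
    D = 1.0 - W
    np.fill_diagonal(D, 0.0)
    return D


def _relabel_by_size(groups: list, nodes) -> dict:
    """Contiguous ids 1.. ordered by decreasing size then smallest member."""
    order = sorted(groups, key=lambda g: (-len(g), sorted(str(nodes[i]) for i in g)[0]))
    labels = {n: 0 for n in nodes}
    for mid, g in enumerate(order, start=1):
        for i in g:
            labels[nodes[i]] = mid
    return labels


def dynamic_hybrid_cut(
    D: np.ndarray,
    linkage: str = "average",
    min_module_size: int = 3,
    deep_split: int = 2,
    cut_height: float = 0.99,
    nodes=None,
) -> ModulePartition:
    """Two-step dynamic hybrid module detection on a dissimilarity matrix."""
    D = np.asarray(D, float)
    p = D.shape[0]
    if nodes is None:
        nodes = [f"n{i}" for i in range(p)]
    if deep_split not in _DEEP_SPLIT:
        raise ValueError("deep_split must be in 0..4")
    if p < 2:
        return ModulePartition({nodes[0]: 1} if p else {}, "dynamic_hybrid")
    if p < min_module_size:
        # degenerate: too few nodes for any module
        import warnings

        warnings.warn("fewer nodes than min_module_size; single module", stacklevel=2)
        return ModulePartition({n: 1 for n in nodes}, "dynamic_hybrid")
    preset = _DEEP_SPLIT[deep_split]
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    root = to_tree(Z)
    h_min = float(Z[:, 2].min())
    h_max = float(Z[:, 2].max())
    h_range = h_max - h_min

    def scaled(h: float) -> float:
        return (h - h_min) / h_range if h_range > 0 else 1.0

    modules: list = []
    unassigned: list = []

    def height(node):
        return 0.0 if node.is_leaf() else node.dist

    def walk(node):
        leaves = node.pre_order(lambda x: x.id)
        if len(leaves) < min_module_size:
            unassigned.extend(leaves)
            return
        if node.is_leaf():
            unassigned.append(node.id)
            return
        left, right = node.left, node.right
        # a merge high on the scaled dendrogram joins distinct branches;
        # a deep split separates two sizeable, well-detached children
        high_join = scaled(node.dist) > preset["split"] or node.dist > cut_height
        deep = (
            left.count >= min_module_size
            and right.count >= min_module_size
            and scaled(node.dist) - max(scaled(height(left)), scaled(height(right)))
            >= preset["gap"]
        )
        if high_join or deep:
            walk(left)
            walk(right)
            return
        modules.append(leaves)

    walk(root)

    # stage 2: attach stragglers to the nearest module if close enough
    for i in list(unassigned):
        best, best_d = None, np.inf
        for k, mod in enumerate(modules):
            d = float(np.mean(D[i, mod]))
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d <= cut_height:
            modules[best].append(i)
            unassigned.remove(i)

    labels = _relabel_by_size(modules, nodes)
    return ModulePartition(
        labels,
        "dynamic_hybrid",
        parameters={
            "linkage": linkage,
            "min_module_size": min_module_size,
            "deep_split": deep_split,
            "cut_height": cut_height,
        },
    )


# ---------------------------------------------------------------------------
# Girvan-Newman


def _graph_from_network(network: Network, weighted: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    p = network.p
    for i in range(p):
        for j in range(i + 1, p):
            if network.A[i, j]:
                attrs = {"weight": float(network.W[i, j])}
                if weighted and network.W[i, j] > 0:
                    attrs["distance"] = 1.0 / float(network.W[i, j])
                g.add_edge(network.nodes[i], network.nodes[j], **attrs)
    return g


def _most_valuable_edge(g: nx.Graph, weighted: bool):
    bt = nx.edge_betweenness_centrality(
        g, weight="distance" if weighted else None
    )
    best = max(bt.values())
    candidates = sorted(
        tuple(sorted(map(str, e))) for e, v in bt.items() if v >= best - 1e-12
    )
    u, v = candidates[0]
    for e in bt:
        if tuple(sorted(map(str, e))) == (u, v):
            return e
    raise AssertionError("tie-break failed")  # pragma: no cover


def girvan_newman(network: Network, weighted_betweenness: bool = False) -> ModulePartition:
    """Divisive community detection; partition chosen by weighted modularity.

    Isolated nodes become singleton modules. Betweenness is computed on the
    unweighted adjacency by default; with ``weighted_betweenness`` edges use
    distance 1/W.
    """
    g = _graph_from_network(network, weighted_betweenness)
    gm = _graph_from_network(network, False)  # modularity graph keeps W weights
    if g.number_of_edges() == 0:
        groups = [[network.nodes.index(n)] for n in network.nodes]
        return ModulePartition(
            _relabel_by_size(groups, network.nodes), "girvan_newman", modularity=None
        )
    partitions = [list(nx.connected_components(g))]
    gw = g.copy()
    while gw.number_of_edges() > 0:
        gw.remove_edge(*_most_valuable_edge(gw, weighted_betweenness))
        comps = list(nx.connected_components(gw))
        if len(comps) > len(partitions[-1]):
            partitions.append(comps)
    total_w = sum(d["weight"] for _, _, d in gm.edges(data=True))
    weight_key = "weight" if total_w > 0 else None
    best_part, best_q = None, -np.inf
    for part in partitions:
        q = nx.community.modularity(gm, part, weight=weight_key)
        if q > best_q + 1e-12:
            best_part, best_q = part, q
    idx = {n: i for i, n in enumerate(network.nodes)}
    groups = [[idx[n] for n in comp] for comp in best_part]
    return ModulePartition(
        _relabel_by_size(groups, network.nodes),
        "girvan_newman",
        parameters={"weighted_betweenness": weighted_betweenness},
        modularity=float(best_q),
    )


def partition_frame(partitions: list):
    """Long table: node, module_id, algorithm."""
    import pandas as pd

    rows = []
    for part in partitions:
        for node, mid in part.labels.items():
            rows.append({"node": node, "module_id": mid, "algorithm": part.algorithm})
    return pd.DataFrame(rows)
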