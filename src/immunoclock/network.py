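"""Feature correlation network, communities, layout and trend summary.

Nodes are immune features; an undirected edge joins two features whose
absolute Pearson correlation across samples strictly exceeds the
construction threshold (default 0.8), storing the signed r.  Communities
are found by weighted modularity maximization (Louvain) on the subgraph
induced by a node subset — typically the bootstrap-informative features —
with |r| edge weights; isolated nodes form singleton communities.  The 2-D
layout is classical metric multidimensional scaling on distances
``1 - |r|`` (non-adjacent pairs at distance 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import louvain_communities

from .errors import DegenerateNetworkError, ValidationError
from .features import FeatureMatrix

__all__ = [
    "build_network",
    "detect_communities",
    "community_coverage",
    "mds_layout",
    "direction_summary",
]


def build_network(
    X: FeatureMatrix | pd.DataFrame,
    threshold: float = 0.8,
    node_weights: pd.Series | None = None,
) -> nx.Graph:
    """All-pairs Pearson correlation graph with |r| strictly above
    ``threshold``.

    Zero-variance features cannot be correlated and are excluded.  Node
    attributes carry ``feature_class`` (when a :class:`FeatureMatrix` is
    given) and optional ``weight`` (e.g. bootstrap selection counts); edge
    attributes carry the signed ``r`` and ``weight = |r|``.
    """
    values = X.values if isinstance(X, FeatureMatrix) else X
    classes = X.classes() if isinstance(X, FeatureMatrix) else None
    if len(values) < 3:
        raise ValidationError("need >= 3 samples to estimate correlations")
    sd = values.std(axis=0, ddof=1)
    usable = list(sd.index[sd > 0])
    if len(usable) < 2:
        raise DegenerateNetworkError("fewer than 2 non-constant features")
    arr = values[usable].to_numpy(float)
    r = np.clip(np.corrcoef(arr, rowvar=False), -1.0, 1.0)

    g = nx.Graph()
    for fid in usable:
        attrs = {}
        if classes is not None:
            attrs["feature_class"] = classes.get(fid, "")
        if node_weights is not None:
            attrs["weight"] = float(node_weights.get(fid, 0.0))
        g.add_node(fid, **attrs)
    iu, ju = np.triu_indices(len(usable), k=1)
    hit = np.abs(r[iu, ju]) > threshold
    for i, j in zip(iu[hit], ju[hit]):
        rij = float(r[i, j])
        g.add_edge(usable[i], usable[j], r=rij, weight=abs(rij))
    return g


def detect_communities(
    net: nx.Graph, nodes=None, seed: int = 0, resolution: float = 1.0
) -> pd.Series:
    """Louvain communities of the subgraph induced by ``nodes``.

    Returns a Series mapping node -> integer community label, labels
    ordered by decreasing community size.  Isolated nodes come out as
    singleton communities.  Deterministic for a fixed seed.
    """
    if nodes is None:
        nodes = list(net.nodes)
    nodes = [v for v in nodes if v in net]
    if not nodes:
        raise ValidationError("empty node subset")
    sub = net.subgraph(nodes)
    comms = louvain_communities(sub, weight="weight", resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    labels = {}
    for label, members in enumerate(comms):
        for v in members:
            labels[v] = label
    return pd.Series(labels, name="community").sort_index()


def community_coverage(labels: pd.Series, k: int) -> float:
    """Fraction of labelled nodes inside the ``k`` largest communities."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(labels) == 0:
        raise ValidationError("no community labels")
    sizes = labels.value_counts().sort_values(ascending=False)
    return float(sizes.iloc[:k].sum() / sizes.sum())


def mds_layout(net: nx.Graph, seed: int = 0) -> pd.DataFrame:
    """Classical (Torgerson) MDS layout of the network in 2-D.

    Distances are ``1 - |r|`` along edges and 1 for non-adjacent pairs.
    Classical MDS is an eigendecomposition and is deterministic; ``seed``
    is accepted for interface uniformity and only fixes the (arbitrary)
    axis orientation.
    """
    nodes = list(net.nodes)
    if not nodes:
        raise ValidationError("empty network")
    m = len(nodes)
    d = np.ones((m, m))
    np.fill_diagonal(d, 0.0)
    index = {v: i for i, v in enumerate(nodes)}
    for u, v, attrs in net.edges(data=True):
        dij = 1.0 - abs(attrs.get("r", 0.0))
        d[index[u], index[v]] = d[index[v], index[u]] = max(dij, 0.0)

    # Torgerson double centering
    d2 = d**2
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:2]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)[None, :]
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    # deterministic sign convention
    for c in range(2):
        col = coords[:, c]
        if col.size and (col[np.argmax(np.abs(col))] < 0):
            coords[:, c] = -col
    return pd.DataFrame(coords, index=pd.Index(nodes, name="feature_id"), columns=["x", "y"])


def direction_summary(
    informative_ids,
    univariate: pd.DataFrame,
    classes: pd.Series,
    fdr_cut: float = 0.1,
) -> dict:
    """GA-direction pattern among informative, FDR-significant features.

    Restricted to informative features with ``q < fdr_cut``, returns the
    share of basal-class features whose Spearman rho is negative
    (basal signalling falling with GA) and the share of response-class
    features whose rho is positive (stimulation responses rising with GA).
    An empty class yields ``nan`` for its fraction.
    """
    ids = [f for f in informative_ids if f in univariate.index]
    sig = univariate.loc[ids]
    sig = sig[sig["q"] < fdr_cut]
    cls = classes.reindex(sig.index)
    basal = sig[cls == "basal"]
    resp = sig[cls == "response"]
    return {
        "basal_decreasing_frac": float((basal["rho"] < 0).mean()) if len(basal) else float("nan"),
        "response_increasing_frac": float((resp["rho"] > 0).mean()) if len(resp) else float("nan"),
        "n_basal": int(len(basal)),
        "n_response": int(len(resp)),
    }
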