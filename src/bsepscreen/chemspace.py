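"""Chemical-space networks and Euclidean-distance applicability domain.

A chemical-space network (CSN) puts compounds on nodes and draws an edge
wherever the fingerprint Tanimoto similarity reaches a threshold (0.7 for
MACCS keys is the conventional choice). Communities are detected with
seeded Louvain modularity maximization; "major" communities are those with
at least five members.

The applicability-domain model follows the APD construction: descriptors
are auto-scaled, all pairwise training distances are computed, and the
domain radius is ``d_bar + z * sigma`` where ``d_bar`` and ``sigma`` are
the mean and standard deviation of the pairwise distances not exceeding
the global mean. A query is in domain when its nearest training neighbor
lies within that radius.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .descriptors import tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "build_csn",
    "detect_communities",
    "export_csn",
    "ApplicabilityDomain",
    "fit_apd",
    "in_domain",
]


def build_csn(fingerprints: Mapping[str, Sequence[int]], threshold: float = 0.7,
              pic50: Optional[Mapping[str, float]] = None) -> nx.Graph:
    """Build a chemical-space network from binary fingerprints.

    Nodes are compound ids (with a ``pic50`` attribute when provided, used
    by viewers as a node-size proxy for potency); an undirected edge with a
    ``similarity`` attribute connects every pair whose Tanimoto similarity
    is >= ``threshold``. No self-edges.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    items = list(fingerprints.items())
    ids = [cid for cid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    if len(ids) < 2:
        raise ValueError("need at least two compounds for a network")
    graph = nx.Graph()
    for cid, _ in items:
        attrs = {}
        if pic50 is not None and cid in pic50:
            attrs["pic50"] = float(pic50[cid])
        graph.add_node(cid, **attrs)
    mat = np.asarray([np.asarray(fp, dtype=bool) for _, fp in items])
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            sim = tanimoto(mat[i], mat[j])
            if sim >= threshold:
                graph.add_edge(ids[i], ids[j], similarity=float(sim))
    return graph


def detect_communities(graph: nx.Graph, min_size: int = 5,
                       seed: int = 0) -> tuple[dict, list[set]]:
    """Seeded Louvain community detection.

    Returns (node -> community id, list of major communities). Communities
    are numbered by decreasing size (ties broken by smallest member id);
    major communities have at least ``min_size`` members. Isolated nodes end
    up in singleton communities.
    """
    if graph.number_of_nodes() == 0:
        return {}, []
    parts = nx.community.louvain_communities(graph, seed=seed)
    parts = sorted(parts, key=lambda c: (-len(c), min(map(str, c))))
    membership = {node: cid for cid, comm in enumerate(parts) for node in comm}
    major = [set(c) for c in parts if len(c) >= min_size]
    return membership, major


def export_csn(graph: nx.Graph, membership: Mapping, edges_path, nodes_path) -> None:
    """Write edge-list and node-attribute CSVs for external viewers."""
    edges = pd.DataFrame(
        [{"id_a": a, "id_b": b, "similarity": d["similarity"]}
         for a, b, d in graph.edges(data=True)]
    )
    edges.to_csv(edges_path, index=False)
    nodes = pd.DataFrame(
        [{"id": n, "pic50": d.get("pic50", ""), "community": membership.get(n, "")}
         for n, d in graph.nodes(data=True)]
    )
    nodes.to_csv(nodes_path, index=False)


class ApplicabilityDomain(BaseEstimator):
    """Euclidean-distance applicability domain (APD) estimator.

    Parameters
    ----------
    z : float, default 0.5
        Multiplier on the spread of below-mean pairwise distances; larger z
        widens the domain.

    Attributes
    ----------
    apd_threshold_ : float
        Fitted domain radius in scaled descriptor space.
    mean_, scale_ : ndarray
        Column scaling fitted on the training data only.
    """

    def __init__(self, z: float = 0.5):
        self.z = z

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("need a 2-D descriptor matrix with >= 2 training compounds")
        if not np.isfinite(arr).all():
            raise ValueError("descriptor matrix contains non-finite values")
        spread = arr.std(axis=0)
        keep = spread > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant descriptor column(s)",
                          stacklevel=2)
        if not keep.any():
            raise ValueError("all descriptor columns are constant")
        self.columns_kept_ = np.flatnonzero(keep)
        sub = arr[:, keep]
        self.mean_ = sub.mean(axis=0)
        self.scale_ = sub.std(axis=0)
        self.training_ = (sub - self.mean_) / self.scale_
        dists = pdist(self.training_)
        below = dists[dists <= dists.mean()]
        d_bar = float(below.mean())
        sigma = float(below.std(ddof=0))
        self.apd_threshold_ = d_bar + self.z * sigma
        return self

    def _scale(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            arr = np.atleast_2d(arr)
        if arr.shape[1] != len(self.columns_kept_):
            if arr.shape[1] >= self.columns_kept_.max() + 1:
                arr = arr[:, self.columns_kept_]
            else:
                raise ValueError(
                    f"query has {arr.shape[1]} columns; model needs "
                    f"{len(self.columns_kept_)} (after dropping constants)")
        return (arr - self.mean_) / self.scale_

    def nn_distance(self, X) -> np.ndarray:
        """Distance of each query to its nearest training compound."""
        check_is_fitted(self, "apd_threshold_")
        return cdist(self._scale(X), self.training_).min(axis=1)

    def predict(self, X) -> np.ndarray:
        """True where the query is inside the applicability domain."""
        return self.nn_distance(X) <= self.apd_threshold_

    def report(self, X, ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Per-query AD report: nearest-neighbor distance, radius, verdict."""
        nn = self.nn_distance(X)
        return pd.DataFrame({
            "id": list(ids) if ids is not None else list(range(len(nn))),
            "nn_distance": nn,
            "apd_threshold": self.apd_threshold_,
            "in_domain": nn <= self.apd_threshold_,
        })

    def training_nn_report(self) -> pd.DataFrame:
        """Nearest-neighbor distance of every training compound to the rest."""
        check_is_fitted(self, "apd_threshold_")
        d = cdist(self.training_, self.training_)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        return pd.DataFrame({
            "nn_distance": nn,
            "apd_threshold": self.apd_threshold_,
            "in_domain": nn <= self.apd_threshold_,
        })


def fit_apd(training_descriptors, z: float = 0.5) -> ApplicabilityDomain:
    """Fit the Euclidean-distance applicability domain on training descriptors."""
    return ApplicabilityDomain(z=z).fit(training_descriptors)


def in_domain(query_descriptors, model: ApplicabilityDomain) -> tuple[np.ndarray, np.ndarray]:
    """(in-domain flags, nearest-neighbor distances) for query compounds."""
    nn = model.nn_distance(query_descriptors)
    return nn <= model.apd_threshold_, nn
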