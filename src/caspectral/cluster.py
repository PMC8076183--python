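"""Spectral clustering of the similarity network and recursive ordination.

A spectrum with several eigenvalues close to 1 followed by a sharp drop
signals weakly connected clusters: the eigengap heuristic estimates the
cluster count K as the number of eigenvalues preceding the largest
consecutive drop (the trivial eigenvalue is included in the count, so two
near-disconnected blocks give K = 2).  Discrete labels come from k-means on
the K-1 nontrivial principal-coordinate axes — spectral clustering with the
normalized-cut relaxation.

Because within-cluster gradients hide in higher-order axes of the pooled
table, gradient analysis is run *after* clustering: ``recursive_scca`` splits
a table by the eigengap estimate, recurses into each cluster's row-subset
table, and stops where K = 1 (or a cluster is too small to split).  Each leaf
keeps its own spectrum and embedding, whose smooth leading axes are the
within-cluster gradients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .incidence import IncidenceTable
from .spectrum import CASpectrum, Embedding, ca_spectrum, embed

__all__ = [
    "EigengapDecision",
    "ClusterNode",
    "ClusterTree",
    "eigengap_count",
    "partition_quality",
    "kmeans_partition",
    "recursive_scca",
]

DEFAULT_MAX_K = 20
DEFAULT_MIN_SIZE = 3
KMEANS_RESTARTS = 50


@dataclass(frozen=True)
class EigengapDecision:
    """Outcome of the eigengap heuristic on a descending spectrum prefix."""

    spectrum_prefix: np.ndarray
    gap_position: int
    K: int

    @property
    def gaps(self) -> np.ndarray:
        return -np.diff(self.spectrum_prefix)


def eigengap_count(eigenvalues, max_k: int = DEFAULT_MAX_K) -> EigengapDecision:
    """Estimate the cluster count K from the sorted eigenvalue spectrum.

    K is the number of eigenvalues (trivial included) that precede the
    largest difference between two subsequent eigenvalues within the first
    ``max_k``.  Ties between equally large gaps are broken toward the
    smaller K: imposing too many clusters risks artificial cuts, so the
    conservative estimate is preferred.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        warnings.warn("fewer than 2 eigenvalues; defaulting to K=1", stacklevel=2)
        return EigengapDecision(lam, gap_position=1, K=1)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted in descending order")
    prefix = lam[: max_k + 1]  # K can be at most max_k
    gaps = -np.diff(prefix)
    g = int(np.argmax(gaps))  # first maximum -> smallest K on ties
    return EigengapDecision(spectrum_prefix=prefix, gap_position=g + 1, K=g + 1)


def partition_quality(eigenvalues, K: int) -> float:
    """Normalized-cut quality of a K-way partition: mean of the top K
    eigenvalues.  Equals 1 exactly when the K clusters are fully
    disconnected, and decreases as they become more interconnected."""
    lam = np.asarray(eigenvalues, dtype=float)
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > lam.size:
        raise ValueError(f"K={K} exceeds the {lam.size} available eigenvalues")
    return float(np.mean(lam[:K]))


def kmeans_partition(
    embedding: Embedding,
    K: int,
    seed: int = 0,
    n_restarts: int = KMEANS_RESTARTS,
) -> np.ndarray:
    """Discrete K-way labels from k-means on the first K-1 embedding axes.

    The trivial eigenvector is constant and cannot influence k-means, so the
    K-1 nontrivial principal-coordinate axes carry all the cluster signal.
    Best of ``n_restarts`` k-means++ runs by within-cluster sum of squares;
    deterministic given ``seed``.
    """
    if K < 2:
        raise ValueError("partitioning needs K >= 2")
    n_nodes = embedding.coordinates.shape[0]
    if K > n_nodes:
        raise ValueError(f"K={K} exceeds the {n_nodes} nodes to partition")
    if embedding.n_axes < K - 1:
        raise ValueError(
            f"embedding has {embedding.n_axes} axes; K={K} needs {K - 1}"
        )
    X = embedding.coordinates[:, : K - 1]
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


@dataclass
class ClusterNode:
    """One node of the recursive partition tree."""

    node_id: str
    members: tuple[str, ...]
    K: int
    quality: float
    eigenvalues: np.ndarray
    children: list["ClusterNode"] = field(default_factory=list)
    spectrum: CASpectrum | None = None
    embedding: Embedding | None = None
    note: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    """Recursive spectral-CA partition of an incidence table's rows."""

    root: ClusterNode
    max_k: int
    min_size: int
    seed: int

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def _walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            for ch in node.children:
                _walk(ch)

        _walk(self.root)
        return out

    def leaf_assignments(self) -> dict[str, str]:
        """Row label -> leaf node id."""
        return {m: leaf.node_id for leaf in self.leaves() for m in leaf.members}

    # -- export ----------------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []

        def _walk(node: ClusterNode, parent: str | None) -> None:
            nodes.append(
                {
                    "id": node.node_id,
                    "parent": parent,
                    "members": list(node.members),
                    "K": node.K,
                    "quality": node.quality,
                    "eigenvalues": [float(x) for x in node.eigenvalues],
                    "is_leaf": node.is_leaf,
                    "note": node.note,
                }
            )
            for ch in node.children:
                _walk(ch, node.node_id)

        _walk(self.root, None)
        return {
            "max_k": self.max_k,
            "min_size": self.min_size,
            "seed": self.seed,
            "nodes": nodes,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def leaf_scores_frame(self):
        """Flat table of (row label, leaf id, within-leaf CA axis-1 score)."""
        import pandas as pd

        records = []
        for leaf in self.leaves():
            if leaf.embedding is not None and leaf.embedding.n_axes >= 1:
                axis1 = leaf.embedding.axis(1)
            else:
                axis1 = np.zeros(len(leaf.members))
            for label, score in zip(leaf.members, axis1):
                records.append({"label": label, "leaf": leaf.node_id, "axis1": score})
        return pd.DataFrame.from_records(records, columns=["label", "leaf", "axis1"])


def _child_seed(seed: int, path: tuple[int, ...]) -> int:
    """Stable per-node RNG seed below 2**31, derived from the tree path."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=path)
    return int(ss.generate_state(1)[0] % (2**31))


def recursive_scca(
    table: IncidenceTable,
    max_k: int = DEFAULT_MAX_K,
    min_size: int = DEFAULT_MIN_SIZE,
    seed: int = 0,
    normalization: str = "unit-variance",
    _trace: list | None = None,
) -> ClusterTree:
    """Cluster first, ordinate within clusters, recursively.

    At each node the CA spectrum of the node's (re-pruned) table is computed,
    the eigengap heuristic estimates K, and if K > 1 the rows are split by
    k-means on the K-1 leading nontrivial axes.  The procedure recurses into
    each child's row-subset table (columns that become empty are dropped) and
    stops where K = 1 or fewer than ``min_size`` rows remain.  Leaves retain
    their spectrum and embedding so their smooth axes can be read as
    within-cluster gradients.

    ``_trace``, if a list, collects one dict per node recording the examined
    spectrum prefix and the gap decision (the heuristic is partly subjective,
    so the evidence is kept auditable).
    """

    def _build(node_table: IncidenceTable, node_id: str, path: tuple[int, ...]) -> ClusterNode:
        n_r = node_table.n_rows
        k_avail = min(node_table.n_rows, node_table.n_cols)
        k_want = min(max_k + 1, k_avail)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny leaves trigger degenerate-table warnings
            spec = ca_spectrum(node_table, k_max=k_want, normalization=normalization)
        decision = eigengap_count(spec.eigenvalues, max_k=max_k)
        K = decision.K
        quality = partition_quality(spec.eigenvalues, K)
        if _trace is not None:
            _trace.append(
                {
                    "node": node_id,
                    "n_rows": n_r,
                    "n_cols": node_table.n_cols,
                    "spectrum_prefix": [float(x) for x in decision.spectrum_prefix],
                    "gap_position": decision.gap_position,
                    "K": K,
                    "quality": quality,
                }
            )
        node = ClusterNode(
            node_id=node_id,
            members=node_table.row_labels,
            K=K,
            quality=quality,
            eigenvalues=spec.eigenvalues,
        )
        splittable = K > 1 and n_r >= max(min_size, K) and spec.n_axes >= K - 1
        if not splittable:
            node.spectrum = spec
            node.embedding = embed(spec, side="row") if spec.n_axes >= 1 else None
            if K > 1:
                node.note = f"K={K} but node too small to split (min_size={min_size})"
                warnings.warn(
                    f"node {node_id}: {node.note}", stacklevel=2
                )
            return node

        emb = embed(spec, n_axes=max(K - 1, 1), side="row")
        labels = kmeans_partition(emb, K, seed=_child_seed(seed, path))
        for g in range(K):
            members = [node_table.row_labels[i] for i in np.flatnonzero(labels == g)]
            child_table = node_table.subset_rows(members)
            child = _build(child_table, f"{node_id}.{g}", path + (g,))
            node.children.append(child)
        return node

    root = _build(table, "0", ())
    return ClusterTree(root=root, max_k=max_k, min_size=min_size, seed=seed)
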