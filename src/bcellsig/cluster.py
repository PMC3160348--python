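"""Hierarchical clustering of samples and patient-subgroup detection.

The study design this mirrors: cluster all samples on the expressed
genes with an unforced (unsupervised) agglomerative procedure, then
look for a subtree made up exclusively of patients that separates
cleanly from the remaining samples.  Subgroup detection is made
reproducible by an explicit rule: enumerate all maximal patient-only
subtrees of at least ``min_size`` leaves, score each by the mean
silhouette width of its members against the rest, and return the
best-scoring call provided it clears a silhouette floor.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .containers import ConfigurationError, ExpressionMatrix, SampleAnnotation

__all__ = [
    "sample_distances",
    "Dendrogram",
    "agglomerate",
    "SubgroupCall",
    "find_patient_subgroup",
]


def sample_distances(
    matrix: ExpressionMatrix, metric: str = "euclidean"
) -> pd.DataFrame:
    """Pairwise sample distances across all retained genes."""
    if matrix.n_samples < 3:
        raise ConfigurationError("need at least 3 samples for clustering")
    D = squareform(pdist(matrix.values.to_numpy(float).T, metric=metric))
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over samples.

    ``merges`` follows the standard linkage convention: row ``i``
    merges nodes ``a`` and ``b`` (leaves are ``0..n-1``, internal
    nodes ``n + i``) at ``height`` into a cluster of ``size`` leaves.
    """

    merges: np.ndarray  # (n-1, 4): node_a, node_b, height, size
    leaf_ids: list[str]
    linkage_method: str
    metric: str
    distances: pd.DataFrame = field(repr=False, default=None)  # type: ignore

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_order(self) -> list[str]:
        order = leaves_list(self.merges)
        return [self.leaf_ids[i] for i in order]

    def node_leaves(self) -> dict[int, list[int]]:
        """Leaf indices under every node (leaves and internal)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.merges):
            members[n + i] = members[int(a)] + members[int(b)]
        return members

    def parent_of(self) -> dict[int, int]:
        n = self.n_leaves
        parent: dict[int, int] = {}
        for i, (a, b, _, _) in enumerate(self.merges):
            parent[int(a)] = n + i
            parent[int(b)] = n + i
        return parent

    def to_newick(self) -> str:
        """Newick string with heights converted to branch lengths."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for i, (_, _, h, _) in enumerate(self.merges):
            height[n + i] = float(h)

        def render(node: int, parent_h: float) -> str:
            length = max(parent_h - height[node], 0.0)
            if node < n:
                name = str(self.leaf_ids[node]).replace(" ", "_")
                return f"{name}:{length:.6g}"
            a, b, h, _ = self.merges[node - n]
            inner = f"({render(int(a), h)},{render(int(b), h)})"
            return f"{inner}:{length:.6g}"

        root = n + len(self.merges) - 1
        a, b, h, _ = self.merges[-1]
        return f"({render(int(a), float(h))},{render(int(b), float(h))});"


def agglomerate(distances: pd.DataFrame, method: str = "complete") -> Dendrogram:
    """Standard agglomerative clustering of a distance matrix.

    Deterministic: equal-distance merge candidates resolve by the
    order of the condensed distance vector, i.e. by smallest leaf
    index.
    """
    D = distances.to_numpy(float)
    if not np.isfinite(D).all():
        raise ConfigurationError("distance matrix contains NaN/inf")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ConfigurationError("distance matrix must be symmetric with zero diagonal")
    Z = linkage(squareform(D, checks=False), method=method)
    return Dendrogram(
        merges=Z,
        leaf_ids=list(distances.index),
        linkage_method=method,
        metric="precomputed",
        distances=distances,
    )


@dataclass
class SubgroupCall:
    """A detected patient-only cluster."""

    member_sample_ids: list[str]
    silhouette: float
    separation_height: float
    all_patient: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "member_sample_ids": self.member_sample_ids,
                    "silhouette": self.silhouette,
                    "separation_height": self.separation_height,
                    "all_patient": self.all_patient,
                },
                indent=1,
                sort_keys=True,
            )
        )


def find_patient_subgroup(
    dendrogram: Dendrogram,
    annotation: SampleAnnotation,
    min_size: int = 3,
    silhouette_floor: float = 0.05,
) -> SubgroupCall | None:
    """Best-separated maximal patient-only subtree, or ``None``.

    Candidates are maximal subtrees whose leaves are exclusively
    patients with at least ``min_size`` members.  Each is scored by
    the mean silhouette width of its members against all remaining
    samples (precomputed distances); the highest-scoring candidate is
    returned if its silhouette exceeds the floor.
    """
    if dendrogram.distances is None:
        raise ConfigurationError("dendrogram carries no distance matrix")
    patients = set(annotation.patients)
    leaf_ids = dendrogram.leaf_ids
    is_patient = np.array([s in patients for s in leaf_ids])
    members = dendrogram.node_leaves()
    n = dendrogram.n_leaves

    pure = {
        node: leaves
        for node, leaves in members.items()
        if is_patient[leaves].all()
    }
    parent = dendrogram.parent_of()
    heights = {n + i: float(h) for i, (_, _, h, _) in enumerate(dendrogram.merges)}

    candidates = []
    for node, leaves in pure.items():
        if len(leaves) < min_size or len(leaves) == n:
            continue
        if parent.get(node) in pure:  # not maximal
            continue
        candidates.append((node, leaves))
    if not candidates:
        return None

    D = dendrogram.distances.loc[leaf_ids, leaf_ids].to_numpy(float)
    best: SubgroupCall | None = None
    for node, leaves in candidates:
        labels = np.zeros(n, dtype=int)
        labels[leaves] = 1
        sil = silhouette_samples(D, labels, metric="precomputed")
        score = float(sil[leaves].mean())
        sep = heights.get(parent.get(node, -1), float(dendrogram.merges[-1, 2]))
        call = SubgroupCall(
            member_sample_ids=sorted(leaf_ids[i] for i in leaves),
            silhouette=score,
            separation_height=float(sep),
        )
        if best is None or call.silhouette > best.silhouette:
            best = call
    if best is not None and best.silhouette <= silhouette_floor:
        return None
    return best
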