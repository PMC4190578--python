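"""Expression-profile correlation and clustering.

Three analyses mirror the study's profile work: (i) Pearson correlation
between library expression profiles over genes expressed in more than half
of the libraries; (ii) SOTA (self-organizing tree algorithm) clustering of
log2-transformed TPM profiles — a divisive, neural-network-inspired binary
tree whose leaves are clusters; (iii) average-linkage hierarchical
clustering of DEG profiles under correlation distance, cut into k groups.

SOTA here follows the published algorithm: the tree starts as a root with
two leaf children; profiles are presented cyclically and the winning leaf
centroid (plus, when its sister is a leaf, the sister and parent) adapts
toward the profile with separate learning rates; when the error stabilizes
the leaf with the highest *resource* (mean member-to-centroid distance) is
split, until the requested number of clusters is reached or every resource
falls below threshold. Distance is correlation-based: profiles are
row-centered and L2-normalized so 1 - r equals half the squared Euclidean
distance, and centroid refinement is exact on that sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "filter_expressed",
    "pcc_matrix",
    "SotaParams",
    "SotaResult",
    "sota_cluster",
    "hierarchical_cluster",
]


def filter_expressed(
    tpm_matrix: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Retain genes with TPM > 0 in strictly more than ``min_fraction`` of
    libraries and return their log2(TPM+1) profiles.

    With 24 libraries and the default fraction, a gene must be expressed in
    at least 13 libraries (12 of 24 is not "more than half").
    """
    if tpm_matrix.empty:
        raise ValueError("empty TPM matrix")
    n_lib = tpm_matrix.shape[1]
    expressed = (tpm_matrix > 0).sum(axis=1)
    keep = expressed > min_fraction * n_lib
    if not keep.any():
        raise ValueError("no genes pass the expressed-library filter")
    profiles = np.log2(tpm_matrix.loc[keep] + 1.0)
    profiles.attrs["min_fraction"] = min_fraction
    return profiles


def pcc_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Library × library Pearson correlation of expression profiles."""
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 libraries")
    zero_var = profiles.std(axis=0, ddof=0) == 0
    if zero_var.any():
        warnings.warn(
            "zero-variance library column(s): "
            + ", ".join(profiles.columns[zero_var]),
            stacklevel=2,
        )
    corr = profiles.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class SotaParams:
    max_clusters: int = 6
    resource_threshold: float = 0.0
    lr_winner: float = 0.01
    lr_parent: float = 0.005
    lr_sister: float = 0.001
    max_epochs: int = 50
    converge_tol: float = 1e-4
    seed: int = 0


@dataclass
class SotaResult:
    assignments: pd.Series  # gene -> leaf cluster id
    centroids: pd.DataFrame  # cluster id × libraries (on the original scale)
    resource_history: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.nunique())


class _Node:
    __slots__ = ("idx", "centroid", "parent", "children")

    def __init__(self, idx: int, centroid: np.ndarray, parent: "_Node | None"):
        self.idx = idx
        self.centroid = centroid
        self.parent = parent
        self.children: list[_Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return centered / norms


def sota_cluster(
    profiles: pd.DataFrame, params: SotaParams | None = None
) -> SotaResult:
    """Grow a SOTA tree over gene profiles; leaves are the clusters.

    Deterministic for a fixed seed (presentation order is the row order;
    ties break toward the earliest-created leaf). The total resource (mean
    member-to-centroid correlation distance) recorded per growth cycle is
    non-increasing.
    """
    params = params or SotaParams()
    n, d = profiles.shape
    if params.max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if n < params.max_clusters:
        raise ValueError(f"{n} genes < {params.max_clusters} clusters requested")
    z = _normalize_rows(profiles.to_numpy(dtype=float))
    rng = np.random.default_rng(params.seed)

    if params.max_clusters == 1:
        assignments = pd.Series(0, index=profiles.index, name="cluster")
        centroid = profiles.mean(axis=0).to_frame().T
        centroid.index = [0]
        return SotaResult(assignments, centroid, [float(np.mean(1.0 - z @ _normalize_rows(centroid.to_numpy())[0]))])

    def _unit(v: np.ndarray) -> np.ndarray:
        c = v - v.mean()
        nv = np.linalg.norm(c)
        return c / nv if nv > 0 else c

    next_idx = 0

    def _new_node(centroid: np.ndarray, parent: _Node | None) -> _Node:
        nonlocal next_idx
        node = _Node(next_idx, centroid, parent)
        next_idx += 1
        if parent is not None:
            parent.children.append(node)
        return node

    mean_profile = _unit(z.mean(axis=0))
    root = _new_node(mean_profile.copy(), None)

    def _split(node: _Node) -> None:
        # children start as jittered copies of the parent centroid
        for _ in range(2):
            jitter = rng.normal(scale=1e-3, size=d)
            _new_node(_unit(node.centroid + jitter), node)

    _split(root)

    def _leaves() -> list[_Node]:
        out: list[_Node] = []
        stack = [root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.extend(reversed(nd.children))
        return sorted(out, key=lambda nd: nd.idx)

    def _assign(leaves: list[_Node]) -> tuple[np.ndarray, np.ndarray]:
        cents = np.vstack([nd.centroid for nd in leaves])
        sims = z @ cents.T
        best = np.argmax(sims, axis=1)  # argmax takes the earliest on ties
        dists = 1.0 - sims[np.arange(n), best]
        return best, dists

    def _adapt_cycle() -> None:
        prev_err = np.inf
        for _ in range(params.max_epochs):
            leaves = _leaves()
            err = 0.0
            for i in range(n):
                sims = [float(z[i] @ nd.centroid) for nd in leaves]
                wi = int(np.argmax(sims))
                winner = leaves[wi]
                err += 1.0 - sims[wi]
                winner.centroid = _unit(
                    winner.centroid + params.lr_winner * (z[i] - winner.centroid)
                )
                parent = winner.parent
                if parent is not None:
                    sisters = [c for c in parent.children if c is not winner]
                    if sisters and all(s.is_leaf for s in sisters):
                        parent.centroid = _unit(
                            parent.centroid
                            + params.lr_parent * (z[i] - parent.centroid)
                        )
                        for s in sisters:
                            s.centroid = _unit(
                                s.centroid + params.lr_sister * (z[i] - s.centroid)
                            )
            err /= n
            if abs(prev_err - err) <= params.converge_tol * max(prev_err, 1e-12):
                break
            prev_err = err

    def _polish(leaves: list[_Node]) -> tuple[np.ndarray, np.ndarray]:
        """Exact centroid refinement on the correlation sphere (monotone)."""
        for _ in range(100):
            best, dists = _assign(leaves)
            moved = False
            for j, nd in enumerate(leaves):
                members = z[best == j]
                if len(members) == 0:
                    continue
                new_c = _unit(members.mean(axis=0))
                if not np.allclose(new_c, nd.centroid, atol=1e-12):
                    nd.centroid = new_c
                    moved = True
            if not moved:
                break
        return _assign(leaves)

    resource_history: list[float] = []
    while True:
        _adapt_cycle()
        leaves = _leaves()
        best, dists = _polish(leaves)
        resource_history.append(float(dists.mean()))
        per_leaf = np.array(
            [dists[best == j].mean() if (best == j).any() else 0.0 for j in range(len(leaves))]
        )
        if len(leaves) >= params.max_clusters:
            break
        if per_leaf.max() <= params.resource_threshold:
            break
        _split(leaves[int(np.argmax(per_leaf))])

    leaves = _leaves()
    best, _ = _assign(leaves)
    # renumber clusters 0..k-1 in leaf order
    assignments = pd.Series(best, index=profiles.index, name="cluster")
    cent_rows = []
    for j, nd in enumerate(leaves):
        members = profiles.to_numpy()[best == j]
        cent_rows.append(
            members.mean(axis=0) if len(members) else profiles.to_numpy().mean(axis=0)
        )
    centroids = pd.DataFrame(cent_rows, columns=profiles.columns)
    return SotaResult(assignments, centroids, resource_history)


def hierarchical_cluster(
    deg_profiles: pd.DataFrame, k: int, *, linkage: str = "average"
) -> pd.Series:
    """Average-linkage hierarchical clustering under 1 - Pearson distance.

    Returns cluster labels 1..k (scipy ``fcluster`` convention). Merge
    order is deterministic: scipy breaks distance ties by cluster index.
    """
    n = deg_profiles.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return pd.Series(
            np.arange(1, n + 1), index=deg_profiles.index, name="group"
        )
    dists = pdist(deg_profiles.to_numpy(dtype=float), metric="correlation")
    link = hierarchy.linkage(dists, method=linkage)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=deg_profiles.index, name="group")
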