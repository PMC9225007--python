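"""Clustering of community metabolite trajectories.

Communities are embedded as flattened metabolite trajectories (e.g. 4
metabolites × 3 time points = 12 dimensions) and clustered by divisive
cutting of the minimum spanning tree of their complete Euclidean-distance
graph: the largest remaining MST edge is removed repeatedly, skipping any
edge whose removal would create a component smaller than the minimum
cluster size, until the requested number of clusters exists.  A decision
tree on species presence/absence then distills each cluster into its most
specific design rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.tree import DecisionTreeClassifier


@dataclass
class ClusterResult:
    labels: np.ndarray
    removed_edges: list[tuple[int, int, float]]
    skipped_edges: list[tuple[int, int, float]]
    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _mst_edges(D: np.ndarray) -> list[tuple[int, int, float]]:
    """MST edges of the complete graph; ties resolved by index order."""
    mst = minimum_spanning_tree(D).tocoo()
    edges = [(int(min(i, j)), int(max(i, j)), float(w))
             for i, j, w in zip(mst.row, mst.col, mst.data)]
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def _component_labels(n: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _ in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    # label components 0..k-1 in order of their smallest member index
    order: dict[int, int] = {}
    for r in roots:
        if r not in order:
            order[r] = len(order)
    return np.array([order[r] for r in roots])


def mst_cluster(vectors: np.ndarray, n_clusters: int = 6,
                min_cluster_size: int = 5) -> ClusterResult:
    """Divisive MST clustering with a minimum-cluster-size constraint.

    At each step the largest remaining edge whose removal leaves every
    component at least *min_cluster_size* strong is cut (largest weight
    first; equal weights broken by smallest (i, j)); edges that would
    violate the constraint are logged as skipped.  Raises if the requested
    cluster count cannot be reached, reporting the partial partition.
    """
    V = np.asarray(vectors, dtype=float)
    n = V.shape[0]
    if n < n_clusters * min_cluster_size:
        raise ValueError("not enough communities for the requested partition")
    D = squareform(pdist(V))
    edges = _mst_edges(D)
    active = list(edges)
    removed: list[tuple[int, int, float]] = []
    skipped: list[tuple[int, int, float]] = []
    while len(removed) < n_clusters - 1:
        # candidates in decreasing weight, index pair breaking ties
        candidates = sorted(active, key=lambda e: (-e[2], e[0], e[1]))
        cut = None
        for edge in candidates:
            trial = [e for e in active if e != edge]
            labels = _component_labels(n, trial)
            sizes = np.bincount(labels)
            if sizes.min() >= min_cluster_size:
                cut = edge
                break
            if edge not in skipped:
                skipped.append(edge)
        if cut is None:
            labels = _component_labels(n, active)
            sizes = np.bincount(labels)
            raise RuntimeError(
                f"no removable edge left at {len(sizes)} clusters "
                f"(partial sizes {sizes.tolist()})")
        active.remove(cut)
        removed.append(cut)
    labels = _component_labels(n, active)
    sizes = np.bincount(labels).tolist()
    return ClusterResult(labels=labels, removed_edges=removed,
                         skipped_edges=skipped, sizes=sizes)


def mean_intracluster_distance(vectors: np.ndarray, labels: np.ndarray,
                               size_weighted: bool = True) -> float:
    """Average within-cluster pairwise Euclidean distance.

    Size-weighted by default (each cluster's mean pairwise distance weighted
    by its size); singletons contribute zero.
    """
    V = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    vals, weights = [], []
    for c in np.unique(labels):
        members = V[labels == c]
        m = len(members)
        d = pdist(members).mean() if m >= 2 else 0.0
        vals.append(d)
        weights.append(m if size_weighted else 1.0)
    return float(np.average(vals, weights=weights))


def elbow_curve(vectors: np.ndarray,
                cluster_range: range | list[int],
                min_size_range: range | list[int],
                size_weighted: bool = True) -> pd.DataFrame:
    """Mean intracluster distance over a (n_clusters, min_size) grid.

    Infeasible grid cells are recorded with NaN rather than raising."""
    rows = []
    for ms in min_size_range:
        for k in cluster_range:
            try:
                res = mst_cluster(vectors, n_clusters=k, min_cluster_size=ms)
                d = mean_intracluster_distance(vectors, res.labels, size_weighted)
            except (ValueError, RuntimeError):
                d = float("nan")
            rows.append({"n_clusters": k, "min_cluster_size": ms,
                         "mean_intracluster_distance": d})
    return pd.DataFrame(rows)


def pick_elbow(curve: pd.DataFrame, min_cluster_size: int) -> int:
    """Elbow = cluster count with the maximum second difference of the
    mean intracluster distance for a given minimum cluster size."""
    sub = (curve[curve["min_cluster_size"] == min_cluster_size]
           .dropna().sort_values("n_clusters"))
    ks = sub["n_clusters"].to_numpy()
    ds = sub["mean_intracluster_distance"].to_numpy()
    if len(ks) < 3:
        raise ValueError("need at least 3 feasible cluster counts")
    second = ds[:-2] - 2 * ds[1:-1] + ds[2:]
    return int(ks[1:-1][np.argmax(second)])


@dataclass
class ClusterRule:
    """Presence/absence conjunction describing one cluster."""

    cluster: int
    conditions: list[tuple[str, bool]]   # (species code, must be present?)
    coverage: float
    deviating: list[int] = field(default_factory=list)

    def __str__(self) -> str:
        if not self.conditions:
            return "always"
        return " & ".join(f"{sp}{'+' if req else '-'}"
                          for sp, req in self.conditions)


def decision_tree_rules(labels: np.ndarray, presence: np.ndarray,
                        pool: tuple[str, ...]) -> dict[int, ClusterRule]:
    """Fit an unpruned CART tree (Gini) on presence bits and read, per
    cluster, the conjunction of conditions along the path to its majority
    leaf.  Coverage is the fraction of the cluster's communities satisfying
    that rule; the rest are reported as deviating."""
    labels = np.asarray(labels)
    Z = np.asarray(presence, dtype=float)
    classes = np.unique(labels)
    rules: dict[int, ClusterRule] = {}
    if len(classes) == 1:
        c = int(classes[0])
        rules[c] = ClusterRule(cluster=c, conditions=[], coverage=1.0)
        return rules
    tree = DecisionTreeClassifier(criterion="gini", random_state=0)
    tree.fit(Z, labels)
    leaf_of = tree.apply(Z)
    t = tree.tree_
    # path (list of (feature, is_right)) to every leaf
    paths: dict[int, list[tuple[int, bool]]] = {}

    def walk(node: int, path: list[tuple[int, bool]]) -> None:
        if t.children_left[node] == -1:
            paths[node] = path
            return
        f = int(t.feature[node])
        walk(int(t.children_left[node]), path + [(f, False)])   # value <= 0.5: absent
        walk(int(t.children_right[node]), path + [(f, True)])   # present

    walk(0, [])
    for c in classes:
        members = np.where(labels == c)[0]
        leaves, counts = np.unique(leaf_of[members], return_counts=True)
        major = int(leaves[np.argmax(counts)])
        conds = [(pool[f], req) for f, req in paths[major]]
        # most specific rule: drop repeated tests of the same species
        seen: dict[str, bool] = {}
        for sp, req in conds:
            seen[sp] = req
        conds = [(sp, req) for sp, req in seen.items()]
        satisfied = np.ones(len(members), dtype=bool)
        for sp, req in conds:
            col = pool.index(sp)
            satisfied &= (Z[members, col] > 0.5) == req
        rules[int(c)] = ClusterRule(
            cluster=int(c), conditions=conds,
            coverage=float(satisfied.mean()),
            deviating=[int(m) for m in members[~satisfied]])
    return rules
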