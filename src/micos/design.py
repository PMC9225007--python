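"""Model-guided community design.

Given a model that predicts the four-metabolite profile of any
presence/absence community, this module (i) enumerates all qualifying
high-richness communities, (ii) selects a "distributed" panel spanning the
predicted metabolite space via k-means, and (iii) selects "corner"
communities whose predicted profiles sit in the joint 5% tails of the
metabolite distribution, diversified by Hamming distance — plus diagnostics
treating the corners as classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .types import DEFAULT_POOL, METABOLITES, CommunityDesign


def enumerate_designs(
    pool_size: int,
    min_richness: int,
    must_include: frozenset[int] | set[int] = frozenset(),
    pool: tuple[str, ...] | None = None,
) -> tuple[Iterator[CommunityDesign], int]:
    """All designs with richness >= *min_richness* containing *must_include*.

    Returns a streaming iterator (never materialized) and the exact
    combinatorial count sum_k C(pool - |must|, k - |must|).  Exhaustive mode
    is limited to pools of <= 30 species.
    """
    if pool_size > 30:
        raise ValueError("pool too large for exhaustive enumeration; "
                         "sample designs instead")
    pool = tuple(pool) if pool is not None else DEFAULT_POOL[:pool_size]
    must = frozenset(int(i) for i in must_include)
    if any(i < 0 or i >= pool_size for i in must):
        raise ValueError("must_include indices out of range")
    free = [i for i in range(pool_size) if i not in must]
    n_free = len(free)
    count = sum(comb(n_free, k - len(must))
                for k in range(max(min_richness, len(must), 1), pool_size + 1))

    def gen() -> Iterator[CommunityDesign]:
        for k in range(max(min_richness, len(must), 1), pool_size + 1):
            for extra in itertools.combinations(free, k - len(must)):
                members = must.union(extra)
                present = tuple(1 if i in members else 0 for i in range(pool_size))
                yield CommunityDesign(present, pool)

    return gen(), count


@dataclass
class PredictionTable:
    """Predicted metabolite profiles for a set of designs.

    ``presence`` is the (N, S) binary design matrix and ``metabolites`` the
    (N, 4) predicted concentrations in mM, columns ordered butyrate,
    lactate, acetate, succinate.
    """

    presence: np.ndarray
    metabolites: np.ndarray
    pool: tuple[str, ...] = DEFAULT_POOL

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        self.metabolites = np.asarray(self.metabolites, dtype=float)
        if self.presence.shape[0] != self.metabolites.shape[0]:
            raise ValueError("presence and metabolites must have equal rows")
        if not np.all(np.isfinite(self.metabolites)):
            raise ValueError("metabolite predictions must be finite")

    def design(self, row: int) -> CommunityDesign:
        return CommunityDesign(tuple(int(v) for v in self.presence[row]), self.pool)

    def column(self, metabolite: str) -> np.ndarray:
        return self.metabolites[:, METABOLITES.index(metabolite)]


def select_distributed(predictions: PredictionTable, k: int = 100,
                       seed: int = 0) -> list[CommunityDesign]:
    """k-means (k clusters, k-means++ with 10 restarts) on the predicted
    4-D metabolite space; returns the unique design nearest each centroid,
    resolving collisions to the next-nearest row."""
    M = predictions.metabolites
    uniq = np.unique(predictions.presence, axis=0)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds {len(uniq)} distinct designs")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(M)
    chosen: list[int] = []
    used: set[int] = set()
    for centroid in km.cluster_centers_:
        d2 = np.sum((M - centroid) ** 2, axis=1)
        for row in np.argsort(d2, kind="stable"):
            if int(row) not in used:
                used.add(int(row))
                chosen.append(int(row))
                break
    return [predictions.design(r) for r in chosen]


@dataclass
class CornerSpec:
    """Two-level extreme-tail binning specification.

    The four primary corners live on the (lactate, butyrate) plane and the
    four sub-corners within each on (acetate, succinate); each level takes
    the stated *percentile* tail (default 5%) with closed boundaries.
    """

    primary: tuple[str, str] = ("lactate", "butyrate")
    secondary: tuple[str, str] = ("acetate", "succinate")
    percentile: float = 5.0
    per_subcorner: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 50.0:
            raise ValueError("percentile must be in (0, 50)")


#: the (anchor variable tail, then secondary tail) pattern used at each level
_CORNER_PATTERN = (
    (0, "low", 1, "low"),
    (0, "low", 1, "high"),
    (1, "low", 0, "low"),
    (1, "low", 0, "high"),
)


def _tail(values: np.ndarray, side: str, percentile: float,
          floor: int = 1) -> np.ndarray:
    """Boolean mask of the *percentile*% most extreme values on *side*.

    At least *floor* rows are always kept (the tables the procedure was
    designed for have tens of millions of rows, so a 5%-of-5% cascade still
    leaves hundreds; on smaller tables the count floor keeps every bin
    selectable).  Boundary ties are closed on the extreme side.
    """
    m = max(int(np.ceil(percentile / 100.0 * len(values))), min(floor, len(values)))
    if side == "low":
        thr = np.partition(values, m - 1)[m - 1]
        return values <= thr
    thr = np.partition(values, len(values) - m)[len(values) - m]
    return values >= thr


def _bin_two_level(values_a: np.ndarray, values_b: np.ndarray,
                   rows: np.ndarray, pattern, percentile: float,
                   names: tuple[str, str], floor: int = 1) -> dict[str, np.ndarray]:
    out = {}
    for ia, sa, ib, sb in pattern:
        vals = (values_a, values_b)
        first = _tail(vals[ia][rows], sa, percentile, floor)
        sub_rows = rows[first]
        second = _tail(vals[ib][sub_rows], sb, percentile, floor)
        label = f"{names[ia]}_{sa},{names[ib]}_{sb}"
        out[label] = sub_rows[second]
    return out


def _hamming_diversify(presence: np.ndarray, rows: np.ndarray, n_extra: int,
                       rng: np.random.Generator,
                       exhaustive: bool = False) -> list[int]:
    """Pick one random row then *n_extra* rows maximizing Hamming distance.

    Greedy sequential max-min selection; ties broken by lexicographic order
    of the presence vector.  The exhaustive variant searches all subsets
    (only sensible for small candidate sets) for the max-min-distance
    selection.
    """
    if len(rows) <= n_extra + 1:
        return [int(r) for r in rows]
    order = np.array(sorted(rows, key=lambda r: tuple(presence[r])))
    seed_row = int(rng.choice(rows))
    candidates = [int(r) for r in order if r != seed_row]
    if exhaustive:
        best, best_score = None, -1
        for combo in itertools.combinations(candidates, n_extra):
            sel = [seed_row, *combo]
            dmin = min(np.sum(presence[a] != presence[b])
                       for a, b in itertools.combinations(sel, 2))
            if dmin > best_score:
                best, best_score = list(sel), dmin
        return best
    chosen = [seed_row]
    while len(chosen) < n_extra + 1:
        best_row, best_d = None, -1
        for r in candidates:
            if r in chosen:
                continue
            dmin = min(int(np.sum(presence[r] != presence[c])) for c in chosen)
            if dmin > best_d:
                best_row, best_d = r, dmin
        chosen.append(best_row)
    return chosen


def select_corners(predictions: PredictionTable,
                   spec: CornerSpec | None = None,
                   seed: int = 0,
                   exhaustive: bool = False) -> dict[str, list[CommunityDesign]]:
    """The two-level corner design: 4 primary corners × 4 sub-corners, each
    contributing one random design plus (per_subcorner − 1) designs chosen
    to maximize Hamming distance to it.  Returns 16 labelled groups."""
    spec = spec or CornerSpec()
    rng = np.random.default_rng(seed)
    all_rows = np.arange(predictions.metabolites.shape[0])
    pa = predictions.column(spec.primary[0])
    pb = predictions.column(spec.primary[1])
    sa = predictions.column(spec.secondary[0])
    sb = predictions.column(spec.secondary[1])
    floor = spec.per_subcorner
    primary_bins = _bin_two_level(pa, pb, all_rows, _CORNER_PATTERN,
                                  spec.percentile, spec.primary, floor)
    groups: dict[str, list[CommunityDesign]] = {}
    for p_label, p_rows in primary_bins.items():
        if len(p_rows) == 0:
            raise ValueError(f"empty primary corner {p_label!r}")
        sub_bins = _bin_two_level(sa, sb, p_rows, _CORNER_PATTERN,
                                  spec.percentile, spec.secondary, floor)
        for s_label, s_rows in sub_bins.items():
            label = f"{p_label}|{s_label}"
            if len(s_rows) == 0:
                raise ValueError(f"empty sub-corner {label!r}")
            picked = _hamming_diversify(predictions.presence, s_rows,
                                        spec.per_subcorner - 1, rng, exhaustive)
            groups[label] = [predictions.design(r) for r in picked]
    return groups


@dataclass
class CornerClassification:
    """Confusion diagnostics when corners are treated as classes."""

    assigned: np.ndarray                # measured-nearest class index per row
    confusion: pd.DataFrame             # true class × assigned class counts
    distance_table: pd.DataFrame        # per class pair: centroid distance, rate
    misclassification_rate: float


def classify_corners(predicted_class: np.ndarray,
                     predicted_metabolites: np.ndarray,
                     measured_metabolites: np.ndarray) -> CornerClassification:
    """Assign each community to its nearest class in measured metabolite
    space and report misclassification versus inter-class centroid distance.

    Class centroids are the per-class means of the *predicted* profiles;
    each community's measured profile is assigned to the nearest centroid.
    """
    pred_cls = np.asarray(predicted_class)
    P = np.asarray(predicted_metabolites, dtype=float)
    Mx = np.asarray(measured_metabolites, dtype=float)
    if P.shape != Mx.shape:
        raise ValueError("predicted and measured tables must align")
    classes = sorted(set(pred_cls.tolist()))
    centroids = np.stack([P[pred_cls == c].mean(axis=0) for c in classes])
    d2 = ((Mx[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assigned = np.argmin(d2, axis=1)
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for pc, ac in zip(pred_cls, assigned):
        conf[cls_index[pc], ac] += 1
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    rows = []
    for i in range(k):
        n_i = conf[i].sum()
        for j in range(k):
            if i == j or n_i == 0:
                continue
            dist = float(np.linalg.norm(centroids[i] - centroids[j]))
            rows.append({"true_class": classes[i], "assigned_class": classes[j],
                         "centroid_distance": dist,
                         "rate": conf[i, j] / n_i})
    rate = float(1.0 - np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    return CornerClassification(assigned=assigned, confusion=confusion,
                                distance_table=pd.DataFrame(rows),
                                misclassification_rate=rate)
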