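"""Neighbor retrieval and the four query-time local models (LLR, SA, SR, GP).

All four models are "lazy": nothing is fitted until a query arrives, and each
prediction uses only the query's nearest reference compounds under one
similarity metric.  LLR fits a univariate line on the neighbors with automatic
descriptor and neighbor-count selection; SA/SR average neighbor activities
(plain / similarity-weighted); GP averages geometric projections of the query
onto the lines joining neighbor pairs in distance space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from lazytox.features import (
    EUCLIDEAN,
    TANIMOTO,
    FeatureMatrix,
    distance_matrix,
    distances_to,
)

ZERO_DISTANCE_TOL = 1e-12
_Q2_SENTINEL = -1e8  # arbitrary very negative start for the improvement loop


class LLLError(ValueError):
    pass


@dataclass(frozen=True)
class Neighbor:
    id: str
    index: int
    distance: float
    similarity: float
    activity: float


@dataclass
class NeighborSet:
    """A query's nearest reference compounds, ascending by distance.

    Ties in distance are broken by reference id (ascending) so rankings are
    reproducible across runs and platforms.  Similarity is 1 - distance for
    both distance kinds (Tanimoto complement; the normalized Euclidean
    distance is bounded by 1 on [0,1]-scaled vectors).
    """

    query_id: str
    metric_name: str
    kind: str
    neighbors: list[Neighbor]

    def __len__(self) -> int:
        return len(self.neighbors)

    def __iter__(self):
        return iter(self.neighbors)

    @property
    def k(self) -> int:
        return len(self.neighbors)

    @property
    def distances(self) -> np.ndarray:
        return np.array([n.distance for n in self.neighbors])

    @property
    def similarities(self) -> np.ndarray:
        return np.array([n.similarity for n in self.neighbors])

    @property
    def activities(self) -> np.ndarray:
        return np.array([n.activity for n in self.neighbors])

    @property
    def indices(self) -> list[int]:
        return [n.index for n in self.neighbors]

    @property
    def ids(self) -> list[str]:
        return [n.id for n in self.neighbors]

    def head(self, n: int) -> "NeighborSet":
        return NeighborSet(self.query_id, self.metric_name, self.kind, self.neighbors[:n])


@dataclass
class LLRFit:
    chosen_descriptor: int
    k: int
    q2: float
    slope: float
    intercept: float


@dataclass
class PredictionResult:
    query_id: str
    model_kind: str
    metric_name: str
    value: float
    k_used: int
    neighbor_ids: list[str] = field(default_factory=list)
    chosen_descriptor: Optional[int] = None
    status: str = "ok"  # ok | fallback | failed

    def __post_init__(self) -> None:
        if self.status != "failed" and not math.isfinite(self.value):
            raise LLLError(
                f"non-finite prediction for {self.query_id!r} ({self.model_kind})"
            )


def rank_reference(
    query_vec: np.ndarray,
    features: FeatureMatrix,
    query_id: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full ascending-distance ranking of the reference set for one query.

    Returns (ordered reference indices, distances in that order).  Rows whose
    id equals ``query_id`` (the query itself present in the reference) are
    excluded.  Equal distances are broken by reference id.
    """
    dist = distances_to(query_vec, features)
    ids = np.asarray(features.ids)
    mask = np.ones(len(ids), dtype=bool)
    if query_id is not None:
        mask &= ids != query_id
    idx = np.nonzero(mask)[0]
    order = idx[np.lexsort((ids[idx], dist[idx]))]
    return order, dist[order]


def find_neighbors(
    query_vec: np.ndarray,
    features: FeatureMatrix,
    activities: Sequence[float],
    k: int,
    query_id: str = "query",
) -> NeighborSet:
    """Retrieve the min(k, reference size) nearest reference compounds."""
    if len(features) == 0:
        raise LLLError("empty reference set")
    if k < 1:
        raise LLLError(f"k must be >= 1, got {k}")
    activities = np.asarray(activities, dtype=float)
    order, dists = rank_reference(query_vec, features, query_id=query_id)
    order = order[:k]
    dists = dists[:k]
    neighbors = [
        Neighbor(
            id=features.ids[i],
            index=int(i),
            distance=float(d),
            similarity=max(0.0, 1.0 - float(d)),
            activity=float(activities[i]),
        )
        for i, d in zip(order, dists)
    ]
    return NeighborSet(
        query_id=query_id,
        metric_name=features.metric_name,
        kind=features.kind,
        neighbors=neighbors,
    )


# ---------------------------------------------------------------------------
# SA / SR


def predict_sa(neighbors: NeighborSet, n: int) -> PredictionResult:
    """Arithmetic mean of the n nearest neighbor activities."""
    if len(neighbors) == 0:
        raise LLLError("empty neighbor set")
    n_used = min(n, len(neighbors))
    if n_used < 1:
        raise LLLError(f"n must be >= 1, got {n}")
    sub = neighbors.head(n_used)
    return PredictionResult(
        query_id=neighbors.query_id,
        model_kind="SA",
        metric_name=neighbors.metric_name,
        value=float(np.mean(sub.activities)),
        k_used=n_used,
        neighbor_ids=sub.ids,
    )


def predict_sr(neighbors: NeighborSet, n: int) -> PredictionResult:
    """Similarity-weighted mean of the n nearest neighbor activities.

    Weights are S_i / sum_j S_j; reduces to the SA prediction when all
    similarities are equal.  All-zero weights raise.
    """
    if len(neighbors) == 0:
        raise LLLError("empty neighbor set")
    n_used = min(n, len(neighbors))
    sub = neighbors.head(n_used)
    weights = sub.similarities
    total = weights.sum()
    if total <= 0:
        raise LLLError(f"all similarity weights zero for query {neighbors.query_id!r}")
    value = float(np.dot(weights, sub.activities) / total)
    return PredictionResult(
        query_id=neighbors.query_id,
        model_kind="SR",
        metric_name=neighbors.metric_name,
        value=value,
        k_used=n_used,
        neighbor_ids=sub.ids,
    )


# ---------------------------------------------------------------------------
# GP (geometric projection)


def gp_project(yA: float, yB: float, dAB: float, dAC: float, dBC: float) -> float:
    """Activity at the projection of query C onto the line through neighbors A, B.

    d_AD = d_AC * cos(angle CAB) with the law-of-cosines cosine clamped to
    [-1, 1]; y_D interpolates (or extrapolates) linearly along AB.  A
    degenerate A==B edge (d_AB == 0) returns the midpoint (y_A + y_B) / 2.
    """
    if dAB <= ZERO_DISTANCE_TOL:
        return 0.5 * (yA + yB)
    if dAC <= ZERO_DISTANCE_TOL:
        return yA
    cos_cab = (dAC * dAC + dAB * dAB - dBC * dBC) / (2.0 * dAC * dAB)
    cos_cab = min(1.0, max(-1.0, cos_cab))
    dAD = dAC * cos_cab
    return yA - (dAD / dAB) * (yA - yB)


def _gp_projections(
    y: np.ndarray, dnn: np.ndarray, dq: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized projections over all neighbor pairs.

    Returns (y_D per pair, pair index i, pair index j) for the C(k,2) pairs.
    """
    k = len(y)
    i, j = np.triu_indices(k, k=1)
    dab = dnn[i, j]
    dac = dq[i]
    dbc = dq[j]
    safe_ab = np.where(dab > ZERO_DISTANCE_TOL, dab, 1.0)
    safe_ac = np.where(dac > ZERO_DISTANCE_TOL, dac, 1.0)
    cos_cab = (dac**2 + dab**2 - dbc**2) / (2.0 * safe_ac * safe_ab)
    np.clip(cos_cab, -1.0, 1.0, out=cos_cab)
    dad = dac * cos_cab
    yd = y[i] - (dad / safe_ab) * (y[i] - y[j])
    yd = np.where(dac <= ZERO_DISTANCE_TOL, y[i], yd)
    yd = np.where(dab <= ZERO_DISTANCE_TOL, 0.5 * (y[i] + y[j]), yd)
    return yd, i, j


def _gp_point(
    y: np.ndarray, dnn: np.ndarray, dq: np.ndarray
) -> tuple[float, bool]:
    """GP estimate for one point given neighbor activities, their pairwise
    distances, and the point's distances to them.

    Applies the zero-distance rule (a coincident neighbor decides directly,
    several coincident neighbors are averaged).  Returns (value, fallback)
    where fallback means the similarity-product weights were all zero and an
    unweighted mean of projections was used instead.
    """
    zero = dq <= ZERO_DISTANCE_TOL
    if zero.any():
        return float(np.mean(y[zero])), False
    if len(y) == 1:
        return float(y[0]), True
    yd, i, j = _gp_projections(y, dnn, dq)
    sims = np.maximum(0.0, 1.0 - dq)
    w = sims[i] * sims[j]
    total = w.sum()
    if total <= 0:
        return float(np.mean(yd)), True
    return float(np.dot(w, yd) / total), False


def _gp_loo_q2(y: np.ndarray, dnn: np.ndarray) -> float:
    """Leave-one-out Q^2 of the GP predictor over a neighbor clique.

    Each neighbor is predicted from the remaining ones using their mutual
    distances.  Degenerate cases (no activity variance) give -inf.
    """
    k = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if k < 3 or ss_tot <= 0:
        return -math.inf
    preds = np.empty(k)
    for c in range(k):
        others = np.arange(k) != c
        yo = y[others]
        sub = dnn[np.ix_(others, others)]
        dq = dnn[c, others]
        preds[c], _ = _gp_point(yo, sub, dq)
    ss_res = float(np.sum((y - preds) ** 2))
    return 1.0 - ss_res / ss_tot


def predict_gp(
    neighbors: NeighborSet,
    features: FeatureMatrix,
    k_init: int = 3,
    k_max: int = 20,
) -> PredictionResult:
    """Geometric-projection prediction with per-query neighbor-count selection.

    A zero-distance neighbor short-circuits to its activity (several such
    neighbors are averaged).  Otherwise all C(k,2) neighbor pairs are
    projected and averaged with similarity-product weights S_AC * S_BC.  k is
    chosen per query by the improvement-gated loop: start at ``k_init``,
    accept k while the leave-one-out Q^2 of the GP predictor over the k
    neighbors strictly improves, stop at the first non-improvement (or at
    ``k_max`` / the available neighbor count).
    """
    dq_all = neighbors.distances
    zero = dq_all <= ZERO_DISTANCE_TOL
    if zero.any():
        value = float(np.mean(neighbors.activities[zero]))
        used = [nb.id for nb, z in zip(neighbors, zero) if z]
        return PredictionResult(
            query_id=neighbors.query_id,
            model_kind="GP",
            metric_name=neighbors.metric_name,
            value=value,
            k_used=len(used),
            neighbor_ids=used,
        )
    if len(neighbors) < 2:
        raise LLLError(
            f"GP needs >= 2 neighbors (or one at zero distance); "
            f"got {len(neighbors)} for query {neighbors.query_id!r}"
        )

    avail = len(neighbors)
    idx = neighbors.indices
    dnn = distance_matrix(
        features.vectors[idx], features.vectors[idx], features.kind
    )
    y = neighbors.activities

    k_cap = min(k_max, avail)
    k = min(k_init, k_cap)
    best_k = k
    best_q2 = _Q2_SENTINEL
    while k <= k_cap:
        q2 = _gp_loo_q2(y[:k], dnn[:k, :k])
        if q2 > best_q2:
            best_q2, best_k = q2, k
            k += 1
        else:
            break

    value, fallback = _gp_point(y[:best_k], dnn[:best_k, :best_k], dq_all[:best_k])
    return PredictionResult(
        query_id=neighbors.query_id,
        model_kind="GP",
        metric_name=neighbors.metric_name,
        value=value,
        k_used=best_k,
        neighbor_ids=neighbors.ids[:best_k],
        status="fallback" if fallback else "ok",
    )


# ---------------------------------------------------------------------------
# LLR (local lazy regression)


def loo_q2(x: Sequence[float], y: Sequence[float]) -> float:
    """Leave-one-out Q^2 of a univariate least-squares line.

    Q^2 = 1 - sum((y_i - yhat_(i))^2) / sum((y_i - ybar)^2) where yhat_(i)
    comes from the line refitted without point i.  Implemented by explicit
    refits; requires >= 3 points and non-constant y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LLLError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise LLLError(f"need >= 3 points, got {n}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise LLLError("zero variance in y; Q^2 undefined")
    ss_res = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        sxx = float(np.sum((xi - xi.mean()) ** 2))
        if sxx <= 0:
            raise LLLError("descriptor constant after leaving one out")
        slope = float(np.sum((xi - xi.mean()) * (yi - yi.mean())) / sxx)
        intercept = float(yi.mean() - slope * xi.mean())
        ss_res += (y[i] - (slope * x[i] + intercept)) ** 2
    return 1.0 - ss_res / ss_tot


def _loo_q2_batch(X: np.ndarray, y: np.ndarray, query_vec: np.ndarray) -> np.ndarray:
    """LOO Q^2 for every descriptor column at once (hat-matrix identity).

    Columns where the query value falls outside the neighbors' range, or with
    (near-)constant values, are masked to -inf — the disregard rule that
    prevents extrapolated regressions.
    """
    n, d = X.shape
    q2 = np.full(d, -np.inf)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0 or n < 3:
        return q2
    in_range = (query_vec >= X.min(axis=0)) & (query_vec <= X.max(axis=0))
    xbar = X.mean(axis=0)
    xc = X - xbar
    sxx = np.sum(xc**2, axis=0)
    usable = in_range & (sxx > 1e-30)
    if not usable.any():
        return q2
    xc = xc[:, usable]
    sxx_u = sxx[usable]
    yc = y - y.mean()
    slope = (xc * yc[:, None]).sum(axis=0) / sxx_u
    resid = yc[:, None] - xc * slope[None, :]
    hat = 1.0 / n + xc**2 / sxx_u[None, :]
    denom = 1.0 - hat
    ok_cols = (denom > 1e-12).all(axis=0)
    loo_resid = np.where(denom > 1e-12, resid / np.where(denom > 1e-12, denom, 1.0), np.inf)
    ss_res = np.sum(loo_resid**2, axis=0)
    vals = np.where(ok_cols, 1.0 - ss_res / ss_tot, -np.inf)
    q2[usable] = vals
    return q2


def fit_predict_llr(
    query_desc: np.ndarray,
    descriptors: FeatureMatrix,
    activities: Sequence[float],
    neighbor_order: Optional[Sequence[int]] = None,
    query_id: str = "query",
    metric_name: str = "DES",
    k_min: int = 5,
    k_max: int = 20,
) -> tuple[PredictionResult, Optional[LLRFit]]:
    """Local lazy regression: one descriptor, one line, fitted per query.

    Starting at k = ``k_min`` with Q^2 = -1e8: at each k the best descriptor
    (highest LOO Q^2 among those whose query value lies inside the neighbors'
    value range) is recorded; while the best Q^2 strictly improves, one more
    neighbor is added, up to ``k_max``.  On the first non-improvement the
    previous (descriptor, k) pair is kept and the query is predicted by the
    corresponding least-squares line.

    ``neighbor_order`` is the query's full distance ranking of the reference
    set under the retrieval metric (defaults to Euclidean ranking on the
    descriptor space itself); the regression always runs on ``descriptors``.
    """
    query_desc = np.asarray(query_desc, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if len(descriptors) < k_min:
        raise LLLError(f"reference smaller than k_min={k_min}")
    if neighbor_order is None:
        neighbor_order, _ = rank_reference(query_desc, descriptors, query_id=query_id)
    neighbor_order = np.asarray(neighbor_order, dtype=int)

    best_q2 = _Q2_SENTINEL
    accepted: Optional[tuple[int, int]] = None  # (descriptor index, k)
    k = k_min
    k_cap = min(k_max, len(neighbor_order))
    while k <= k_cap:
        idx = neighbor_order[:k]
        q2s = _loo_q2_batch(descriptors.vectors[idx], activities[idx], query_desc)
        j = int(np.argmax(q2s))
        if q2s[j] > best_q2:
            best_q2 = float(q2s[j])
            accepted = (j, k)
            k += 1
        else:
            break

    if accepted is None:
        return (
            PredictionResult(
                query_id=query_id,
                model_kind="LLR",
                metric_name=metric_name,
                value=math.nan,
                k_used=0,
                status="failed",
            ),
            None,
        )

    j, k_used = accepted
    idx = neighbor_order[:k_used]
    x = descriptors.vectors[idx, j]
    yv = activities[idx]
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (yv - yv.mean())) / sxx)
    intercept = float(yv.mean() - slope * x.mean())
    value = slope * float(query_desc[j]) + intercept
    fit = LLRFit(chosen_descriptor=j, k=k_used, q2=best_q2, slope=slope, intercept=intercept)
    result = PredictionResult(
        query_id=query_id,
        model_kind="LLR",
        metric_name=metric_name,
        value=value,
        k_used=k_used,
        neighbor_ids=[descriptors.ids[i] for i in idx],
        chosen_descriptor=j,
    )
    return result, fit


# ---------------------------------------------------------------------------
# Neighbor-count selection for SA / SR


def select_n_by_cv(
    features: FeatureMatrix,
    activities: Sequence[float],
    model_kind: str,
    n_grid: Optional[Sequence[int]] = None,
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the SA/SR neighbor count n by k-fold cross-validation on the
    reference set, minimizing mean absolute error.  Ties go to the smallest n.
    """
    from sklearn.model_selection import KFold

    model_kind = model_kind.upper()
    if model_kind not in ("SA", "SR"):
        raise LLLError(f"select_n_by_cv supports SA/SR, got {model_kind!r}")
    activities = np.asarray(activities, dtype=float)
    n_comp = len(features)
    if n_comp < folds:
        raise LLLError(f"reference size {n_comp} smaller than {folds} folds")
    if n_grid is None:
        n_grid = range(1, 21)
    n_grid = sorted(set(int(n) for n in n_grid))
    if min(n_grid) < 1:
        raise LLLError("n_grid entries must be >= 1")

    ids = np.asarray(features.ids)
    abs_err = {n: [] for n in n_grid}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(np.arange(n_comp)):
        D = distance_matrix(
            features.vectors[test_idx], features.vectors[train_idx], features.kind
        )
        train_ids = ids[train_idx]
        y_train = activities[train_idx]
        for row, ti in enumerate(test_idx):
            order = np.lexsort((train_ids, D[row]))
            y_sorted = y_train[order]
            counts = np.arange(1, len(order) + 1)
            if model_kind == "SA":
                preds = np.cumsum(y_sorted) / counts
            else:
                sims = np.maximum(0.0, 1.0 - D[row][order])
                cw = np.cumsum(sims)
                cwy = np.cumsum(sims * y_sorted)
                with np.errstate(invalid="ignore", divide="ignore"):
                    preds = np.where(cw > 0, cwy / np.where(cw > 0, cw, 1.0), np.nan)
                # no usable weights yet: fall back to the plain running mean
                sa = np.cumsum(y_sorted) / counts
                preds = np.where(np.isnan(preds), sa, preds)
            for n in n_grid:
                pred = preds[min(n, len(order)) - 1]
                abs_err[n].append(abs(pred - activities[ti]))

    maes = {n: float(np.mean(errs)) for n, errs in abs_err.items()}
    return min(n_grid, key=lambda n: (maes[n], n))
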