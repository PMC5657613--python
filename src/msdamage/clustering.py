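"""Clustering of EDSS disability trajectories into phenotype groups.

Series are snapped to a common month grid, normalized per time point by the
column maximum, and missing cells are filled by K-nearest-neighbour
imputation.  Multi-start k-means proposes partitions for each candidate k,
fuzzy c-means (fuzzifier m=2) refines the centers into soft memberships, and
the average silhouette over hard labels picks k.  Short-follow-up assignment
and its per-cluster error rate quantify how early a patient's long-term
phenotype group can be recognized.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.impute import KNNImputer
from sklearn.metrics import silhouette_score

from .io_cohort import Cohort, PatientRecord

__all__ = [
    "TrajectoryMatrix",
    "ClusterModel",
    "preprocess_matrix",
    "fit_clusters",
    "assign_series",
    "clustering_error_rate",
    "match_labels",
]


@dataclass
class TrajectoryMatrix:
    """Patients x grid-months matrix of normalized EDSS with missingness mask."""

    values: np.ndarray  # (n, p), in [0, 1], fully imputed
    time_grid: np.ndarray  # months
    mask: np.ndarray  # (n, p) bool, True where originally observed
    col_max: np.ndarray  # per-column raw EDSS maximum used for normalization
    patient_ids: list[str]


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray  # (k, p) on the common normalized grid
    hard_labels: np.ndarray  # (n,)
    memberships: np.ndarray  # (n, k), rows sum to 1
    silhouette: dict[int, float]  # candidate k -> average silhouette
    time_grid: np.ndarray
    col_max: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if not np.array_equal(self.hard_labels, np.argmax(self.memberships, axis=1)):
            raise ValueError("hard labels must be the membership argmax")


def _snap_to_grid(patient: PatientRecord, grid: np.ndarray) -> np.ndarray:
    """Average a patient's EDSS onto the nearest grid months; NaN where no
    visit maps to a column."""
    col = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid))
    sums = np.zeros(len(grid))
    for v in patient.visits:
        j = int(np.argmin(np.abs(grid - v.time)))
        sums[j] += v.edss
        counts[j] += 1
    has = counts > 0
    col[has] = sums[has] / counts[has]
    return col


def preprocess_matrix(
    cohort: Cohort, grid: np.ndarray, knn_k: int = 3
) -> TrajectoryMatrix:
    """Build the normalized, KNN-imputed trajectory matrix on ``grid`` months."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid must cover at least 2 timepoints")
    raw = np.vstack([_snap_to_grid(p, grid) for p in cohort])
    mask = ~np.isnan(raw)
    if not mask.any(axis=1).all():
        bad = [p.patient_id for p, m in zip(cohort, mask) if not m.any()]
        raise ValueError(f"patients with zero observations on the grid: {bad}")
    if not mask.any(axis=0).all():
        empty = grid[~mask.any(axis=0)]
        raise ValueError(f"grid columns with no observations: {empty.tolist()}")
    col_max = np.nanmax(raw, axis=0)
    col_max = np.where(col_max > 0, col_max, 1.0)
    norm = raw / col_max
    imputer = KNNImputer(n_neighbors=min(knn_k, len(cohort) - 1) or 1)
    values = imputer.fit_transform(norm)
    values = np.clip(values, 0.0, 1.0)
    return TrajectoryMatrix(
        values=values,
        time_grid=grid,
        mask=mask,
        col_max=col_max,
        patient_ids=[p.patient_id for p in cohort],
    )


def _fuzzy_cmeans(
    x: np.ndarray,
    centers: np.ndarray,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> tuple[np.ndarray, np.ndarray]:
    """Bezdek fuzzy c-means refinement from initial centers.

    Returns (centers, memberships).  Exact-hit points get crisp membership.
    """
    k = centers.shape[0]
    expo = 2.0 / (m - 1.0)
    u = np.empty((x.shape[0], k))
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-expo / 2.0 * 1.0)  # d^{-2/(m-1)}
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    d2 = np.maximum(d2, 1e-300)
    inv = d2 ** (-expo / 2.0)
    u = inv / inv.sum(axis=1, keepdims=True)
    return centers, u


def fit_clusters(
    matrix: TrajectoryMatrix,
    k_range: tuple[int, int] = (3, 8),
    n_starts: int = 10,
    rng: np.random.Generator | int | None = 0,
    fixed_k: int | None = None,
) -> ClusterModel:
    """Multi-start k-means per candidate k, fuzzy refinement, silhouette pick.

    Patient order does not affect the result: rows are canonicalized
    (lexicographic sort) before initialization and mapped back, and clusters
    are relabelled by ascending center severity.
    """
    rng = np.random.default_rng(rng)
    x = matrix.values
    n = x.shape[0]
    ks = [fixed_k] if fixed_k is not None else list(range(k_range[0], k_range[1] + 1))
    if n < max(ks):
        raise ValueError(f"need at least {max(ks)} patients, got {n}")

    order = np.lexsort(x.T[::-1])  # canonical row order
    xs = x[order]
    best: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    sil: dict[int, float] = {}
    for k in ks:
        best_inertia = np.inf
        best_centers = None
        for _ in range(n_starts):
            seed = int(rng.integers(2**31 - 1))
            km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(xs)
            if km.inertia_ < best_inertia:
                best_inertia = km.inertia_
                best_centers = km.cluster_centers_
        centers, u_sorted = _fuzzy_cmeans(xs, best_centers)
        # relabel by ascending mean center value (severity ordering)
        rank = np.argsort(centers.mean(axis=1), kind="stable")
        centers = centers[rank]
        u_sorted = u_sorted[:, rank]
        u = np.empty_like(u_sorted)
        u[order] = u_sorted
        labels = np.argmax(u, axis=1)
        sil[k] = (
            float(silhouette_score(x, labels)) if len(np.unique(labels)) > 1 else -1.0
        )
        best[k] = (centers, u, sil[k])
    k_sel = max(ks, key=lambda k: sil[k])
    centers, u, _ = best[k_sel]
    return ClusterModel(
        k=k_sel,
        centers=centers,
        hard_labels=np.argmax(u, axis=1),
        memberships=u,
        silhouette=sil,
        time_grid=matrix.time_grid,
        col_max=matrix.col_max,
    )


def assign_series(
    model: ClusterModel, patient: PatientRecord, max_months: float = np.inf
) -> int:
    """Nearest-center assignment using only grid columns observed before
    ``max_months``."""
    raw = _snap_to_grid(patient, model.time_grid)
    usable = (~np.isnan(raw)) & (model.time_grid <= max_months)
    if not usable.any():
        raise ValueError(
            f"patient {patient.patient_id}: no usable visits before {max_months}"
        )
    v = raw[usable] / model.col_max[usable]
    d2 = ((model.centers[:, usable] - v[None, :]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def match_labels(
    labels_a: np.ndarray, labels_b: np.ndarray, k: int
) -> np.ndarray:
    """Permutation p minimizing mismatches of p[labels_b] against labels_a.

    Exhaustive for k <= 6, Hungarian assignment on the confusion matrix
    otherwise.
    """
    conf = np.zeros((k, k), dtype=int)
    for a, b in zip(labels_a, labels_b):
        conf[a, b] += 1
    if k <= 6:
        best_perm, best_hits = None, -1
        for perm in itertools.permutations(range(k)):
            hits = sum(conf[perm[b], b] for b in range(k))
            if hits > best_hits:
                best_hits, best_perm = hits, perm
        return np.array(best_perm)
    rows, cols = linear_sum_assignment(-conf.T)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def clustering_error_rate(
    model: ClusterModel,
    cohort: Cohort,
    horizon: float,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Per-cluster misassignment % of horizon-truncated vs full-series labels.

    Reference label: full-series nearest-center assignment.  Test label:
    assignment truncated at ``horizon`` months, matched to the reference by
    the optimal label permutation.  Returns per-cluster error percentages and
    their mean +/- sd; clusters left empty by the reference assignment are
    reported as NaN rather than raising.
    """
    ref, test = [], []
    for p in cohort:
        ref.append(assign_series(model, p))
        test.append(assign_series(model, p, max_months=horizon))
    ref_arr, test_arr = np.array(ref), np.array(test)
    perm = match_labels(ref_arr, test_arr, model.k)
    test_arr = perm[test_arr]
    per_cluster = {}
    rates = []
    for c in range(model.k):
        sel = ref_arr == c
        if not sel.any():
            per_cluster[c] = float("nan")
            continue
        rate = 100.0 * float(np.mean(test_arr[sel] != c))
        per_cluster[c] = rate
        rates.append(rate)
    rates_arr = np.array(rates)
    return {
        "per_cluster_percent": per_cluster,
        "mean_percent": float(rates_arr.mean()) if rates_arr.size else float("nan"),
        "sd_percent": float(rates_arr.std(ddof=1)) if rates_arr.size > 1 else 0.0,
    }
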