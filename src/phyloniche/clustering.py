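"""Fuzzy C-means niche clustering: distances, classical MDS, the FCM
estimator, seven cluster-validity indices and the (K, m) model-selection
sweep that defines the macroecological niches.

Clustering runs on raw (unstandardized) environmental values by default —
mirroring an analysis of raw climate layers, where precipitation (mm)
dominates the metric — with ``standardize=True`` as an escape hatch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger("phyloniche")


def euclidean_distances(X: np.ndarray) -> np.ndarray:
    """Full n×n Euclidean distance matrix (symmetric, zero diagonal)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    return squareform(pdist(X))


def classical_mds(D: np.ndarray, dims="auto") -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers −½D² and eigendecomposes it.  ``dims="auto"`` retains all
    dimensions with eigenvalue > 1e-8 × the largest, which for a distance
    matrix of Euclidean origin makes the embedding distance-preserving.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("D must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if dims == "auto":
        top = max(evals.max(), 0.0)
        keep = evals > 1e-8 * top if top > 0 else np.zeros(n, bool)
        k = int(keep.sum())
    else:
        k = int(dims)
    if k == 0:
        return np.zeros((n, 1))
    return evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0.0, None))


# ---------------------------------------------------------------------------
# Fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyPartition:
    """Membership matrix U (rows sum to 1), centroids, fuzziness exponent m,
    final objective J and iterations used."""

    memberships: np.ndarray
    centroids: np.ndarray
    m: float
    objective: float
    n_iter: int

    def __post_init__(self):
        rowsum = self.memberships.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clusterer (scikit-learn estimator interface).

    Alternates the membership update
    ``u_ik = [sum_j (d_ik/d_ij)^(2/(m-1))]^-1`` and the centroid update
    ``c_k = sum_i u_ik^m x_i / sum_i u_ik^m``, minimizing
    ``J = sum_ik u_ik^m ||x_i - c_k||^2`` until ``|dJ| < tol`` or
    ``max_iter``.  Memberships are initialized from a symmetric Dirichlet(1)
    draw.  A point coinciding with one or more centroids gets its membership
    mass split equally over the zero-distance centroids.

    Attributes (after fit): ``cluster_centers_``, ``memberships_``,
    ``labels_``, ``objective_``, ``n_iter_``, ``objective_path_``.
    """

    def __init__(self, n_clusters=3, m=2.0, max_iter=200, tol=1e-9,
                 random_state=None, n_restarts=1):
        self.n_clusters = n_clusters
        self.m = m
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.n_restarts = n_restarts

    @staticmethod
    def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
        """U from squared distances; handles zero distances exactly."""
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        zero = d2 <= 0.0
        U = np.empty_like(d2)
        finite = ~zero.any(axis=1)
        U[finite] = inv[finite] / inv[finite].sum(axis=1, keepdims=True)
        rows = np.where(~finite)[0]
        for i in rows:
            U[i] = zero[i] / zero[i].sum()
        return U

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        n, _ = X.shape
        K = self.n_clusters
        if K > n:
            raise ValueError(f"n_clusters={K} exceeds n_samples={n}")
        if K < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.m <= 1.0:
            raise ValueError("fuzziness m must be > 1")
        base = 0 if self.random_state is None else int(self.random_state)
        best = None
        for restart in range(max(1, self.n_restarts)):
            seed = None if self.random_state is None and restart == 0 \
                else base + restart
            rng = np.random.default_rng(seed)
            U = rng.dirichlet(np.ones(K), size=n)
            prev_J = np.inf
            path = []
            for it in range(1, self.max_iter + 1):
                W = U ** self.m
                centers = (W.T @ X) / W.sum(axis=0)[:, None]
                d2 = cdist(X, centers, "sqeuclidean")
                J = float((W * d2).sum())
                path.append(J)
                U = self._memberships(d2, self.m)
                if abs(prev_J - J) < self.tol:
                    break
                prev_J = J
            if best is None or J < best[2]:
                best = (centers, U, J, np.array(path), it)
        self.cluster_centers_, self.memberships_, self.objective_, \
            self.objective_path_, self.n_iter_ = best
        self.labels_ = hard_assign(self.partition_)
        return self

    @property
    def partition_(self) -> FuzzyPartition:
        return FuzzyPartition(self.memberships_, self.cluster_centers_,
                              self.m, self.objective_, self.n_iter_)

    def predict(self, X):
        d2 = cdist(np.asarray(X, float), self.cluster_centers_, "sqeuclidean")
        return np.argmax(self._memberships(d2, self.m), axis=1)


def fcm(X, K, m, seed=None, max_iter=200, tol=1e-9) -> FuzzyPartition:
    """Functional wrapper over :class:`FuzzyCMeans`."""
    est = FuzzyCMeans(n_clusters=K, m=m, max_iter=max_iter, tol=tol,
                      random_state=seed).fit(X)
    return est.partition_


def hard_assign(part: FuzzyPartition) -> np.ndarray:
    """Maximum-membership labels; ties resolved to the lowest cluster index
    (count logged)."""
    U = part.memberships
    labels = np.argmax(U, axis=1)
    ties = (U == U.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("hard_assign: %d membership ties broken to lowest index",
                    int(ties.sum()))
    return labels


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------

@dataclass
class IndexValue:
    value: float
    maximize: bool
    note: str | None = None


INDEX_DIRECTIONS = {
    "partition_coefficient": True,
    "partition_entropy": False,
    "xie_beni": False,
    "dunn": True,
    "fukuyama_sugeno": False,
    "fuzzy_hypervolume": False,
    "average_partition_density": True,
}


def _fuzzy_cov_dets(X, U, centers, m):
    W = U ** m
    dets = []
    for k in range(centers.shape[0]):
        diff = X - centers[k]
        F = (W[:, k, None] * diff).T @ diff / W[:, k].sum()
        sign, logdet = np.linalg.slogdet(F)
        dets.append(np.exp(logdet) if sign > 0 else np.nan)
    return np.array(dets)


def validity_indices(part: FuzzyPartition, X: np.ndarray) -> dict[str, IndexValue]:
    """The seven fuzzy validity indices used by the model-selection sweep.

    Bezdek's partition coefficient (max) and entropy (min), Xie–Beni (min),
    Dunn's separation on the hard partition (max), Fukuyama–Sugeno (min),
    fuzzy hypervolume (min) and average partition density (max).  Indices
    needing an inter-centroid distance are NaN-flagged at K = 1 rather than
    raised.
    """
    X = np.asarray(X, dtype=float)
    U, C, m = part.memberships, part.centroids, part.m
    n, K = U.shape
    out: dict[str, IndexValue] = {}

    out["partition_coefficient"] = IndexValue(float((U ** 2).sum() / n), True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(U > 0, U * np.log(U), 0.0)
    out["partition_entropy"] = IndexValue(float(-plogp.sum() / n), False)

    d2 = cdist(X, C, "sqeuclidean")
    J = float(((U ** m) * d2).sum())

    if K < 2:
        out["xie_beni"] = IndexValue(np.nan, False, "undefined for K=1")
        out["dunn"] = IndexValue(np.nan, True, "undefined for K=1")
    else:
        sep = pdist(C, "sqeuclidean").min()
        out["xie_beni"] = IndexValue(J / (n * sep), False)
        labels = hard_assign(part)
        D = squareform(pdist(X))
        inter = np.inf
        intra = 0.0
        for k in range(K):
            mask_k = labels == k
            if mask_k.sum() > 1:
                intra = max(intra, D[np.ix_(mask_k, mask_k)].max())
            for l in range(k + 1, K):
                mask_l = labels == l
                if mask_k.any() and mask_l.any():
                    inter = min(inter, D[np.ix_(mask_k, mask_l)].min())
        if not np.isfinite(inter) or intra == 0.0:
            out["dunn"] = IndexValue(np.nan, True, "degenerate hard partition")
        else:
            out["dunn"] = IndexValue(float(inter / intra), True)

    xbar = X.mean(axis=0)
    c_dev = ((C - xbar) ** 2).sum(axis=1)
    out["fukuyama_sugeno"] = IndexValue(
        float(((U ** m) * (d2 - c_dev[None, :])).sum()), False)

    dets = _fuzzy_cov_dets(X, U, C, m)
    if np.any(~np.isfinite(dets)) or np.any(dets <= 0):
        out["fuzzy_hypervolume"] = IndexValue(np.nan, False, "singular fuzzy covariance")
        out["average_partition_density"] = IndexValue(np.nan, True,
                                                      "singular fuzzy covariance")
    else:
        root = np.sqrt(dets)
        out["fuzzy_hypervolume"] = IndexValue(float(root.sum()), False)
        out["average_partition_density"] = IndexValue(
            float((U.sum(axis=0) / root).mean()), True)
    return out


# ---------------------------------------------------------------------------
# Model-selection sweep
# ---------------------------------------------------------------------------

DEFAULT_K_RANGE = tuple(range(2, 16))
DEFAULT_M_GRID = tuple(round(1.1 + 0.1 * i, 1) for i in range(10))


@dataclass
class ValidityReport:
    """Sweep table of index values per (K, m), per-index optima and the
    consensus combination."""

    table: pd.DataFrame                    # index (K, m), columns = index names
    per_index_optimal: dict[str, tuple]
    consensus: tuple
    support: pd.Series                     # (K, m) → number of supporting indices
    failures: list

    def __len__(self) -> int:
        return len(self.table)


def model_selection_sweep(X, K_range=DEFAULT_K_RANGE, m_grid=DEFAULT_M_GRID,
                          seed=0, max_iter=200, tol=1e-9) -> ValidityReport:
    """One FCM run per (K, m) combination, scored by all seven indices.

    The run for combination number j uses seed ``seed + j``.  An index
    "supports" a combination whose value ranks in that index's top two
    (optimal or next-to-optimal); the consensus (K*, m*) is the combination
    supported by the most indices, ties broken toward smaller K then
    smaller m.  Failed combinations are flagged and the sweep continues.
    """
    X = np.asarray(X, dtype=float)
    combos = list(itertools.product(K_range, m_grid))
    if not combos:
        raise ValueError("empty sweep grids")
    rows, failures = {}, []
    for j, (K, m) in enumerate(combos):
        try:
            part = fcm(X, K, m, seed=seed + j, max_iter=max_iter, tol=tol)
            rows[(K, m)] = {name: iv.value
                            for name, iv in validity_indices(part, X).items()}
        except Exception as exc:  # noqa: BLE001 — sweep must continue
            logger.warning("sweep combination (K=%d, m=%.1f) failed: %s", K, m, exc)
            failures.append((K, m, str(exc)))
            rows[(K, m)] = {name: np.nan for name in INDEX_DIRECTIONS}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["K", "m"])

    support = pd.Series(0, index=table.index)
    per_index_optimal = {}
    for name, maximize in INDEX_DIRECTIONS.items():
        col = table[name]
        valid = col.dropna()
        if valid.empty:
            per_index_optimal[name] = None
            continue
        ranked = valid.sort_values(ascending=not maximize)
        per_index_optimal[name] = tuple(ranked.index[0])
        for combo in ranked.index[:2]:
            support.loc[combo] += 1
    best = support.max()
    candidates = sorted(support[support == best].index)   # smaller K, then m
    return ValidityReport(table, per_index_optimal, candidates[0], support, failures)
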