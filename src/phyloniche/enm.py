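"""Presence–background maximum-entropy niche models, AUC evaluation,
max-SSS thresholding, binary range overlap and predicted-niche-occupancy
(PNO) profiles.

The model is a deliberately small maximum-entropy variant: linear and
quadratic feature classes only, features min–max standardized to [0, 1]
over the background (all masked grid cells), and an L1 penalty with
per-feature scaling ``beta * sd_j(presences) / sqrt(n_presences)``.  The
penalized log likelihood

    (1/|P|) sum_i lam·f(x_i) - log Z(lam) - beta * sum_j s_j |lam_j|

is concave, and is maximized by L-BFGS-B on the split ``lam = a - b``
(a, b >= 0), which turns the L1 term into a smooth bound-constrained
problem.  The raw output exp(lam·f)/Z sums to one over the background; the
logistic output is the entropy transform ``e^H·raw / (1 + e^H·raw)``.
Background cells stand in for absences wherever specificity or an AUC is
needed, because only presences exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .core_io import EnvGrid

logger = logging.getLogger("phyloniche")


class ModelError(ValueError):
    pass


def _features(env: np.ndarray, mins, ptp) -> np.ndarray:
    """Linear + quadratic features of min–max standardized variables."""
    z = (env - mins) / ptp
    return np.hstack([z, z ** 2])


@dataclass
class NicheModel:
    """A fitted suitability surface for one niche cluster."""

    lam: np.ndarray                       # 40 feature weights
    feature_names: list
    mins: np.ndarray                      # background min per variable
    ptp: np.ndarray                       # background range per variable
    log_z: float
    entropy: float                        # H of the raw distribution
    raw: np.ndarray                       # over masked cells, sums to 1
    logistic: np.ndarray                  # over masked cells, in (0, 1)
    threshold: float | None = None
    auc_summary: tuple | None = None      # (mean, sd, n_replicates)
    beta: float = 1.0

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative output: for each cell, 100 × the raw mass of all cells
        with raw suitability not exceeding its own."""
        order = np.argsort(self.raw)
        cum = np.empty_like(self.raw)
        cum[order] = np.cumsum(self.raw[order])
        return 100.0 * cum

    def suitability_grid(self, grid: EnvGrid, kind: str = "logistic") -> np.ndarray:
        """Paint the masked-cell suitability back onto the 2-D grid (NaN off-mask)."""
        out = np.full((grid.height, grid.width), np.nan)
        out[grid.mask] = getattr(self, kind)
        return out

    def score_cells(self, grid: EnvGrid, cells: np.ndarray,
                    kind: str = "logistic") -> np.ndarray:
        """Suitability of (row, col) cells (must be masked cells)."""
        env = grid.values[cells[:, 0], cells[:, 1]]
        f = _features(env, self.mins, self.ptp)
        raw = np.exp(f @ self.lam - self.log_z)
        if kind == "raw":
            return raw
        eh = np.exp(self.entropy) * raw
        return eh / (1.0 + eh)


def fit_maxent(presence_cells: np.ndarray, grid: EnvGrid, beta: float = 1.0,
               max_iter: int = 100_000) -> NicheModel:
    """Fit the penalized maximum-entropy model for one set of presence cells.

    ``presence_cells`` is an array of (row, col) pairs (duplicates allowed —
    several records may share a cell); every cell must lie on the grid mask
    and at least 5 presences are required.  Convergence requires the
    projected-gradient infinity norm to fall below 1e-6.
    """
    presence_cells = np.atleast_2d(np.asarray(presence_cells, dtype=int))
    if len(presence_cells) < 5:
        raise ModelError("need at least 5 presence cells")
    if beta < 0:
        raise ValueError("regularization beta must be >= 0")
    if not grid.mask[presence_cells[:, 0], presence_cells[:, 1]].all():
        raise ModelError("presence cells must lie on the grid mask")

    bg_env = grid.masked_env()
    mins = bg_env.min(axis=0)
    rng_ = np.ptp(bg_env, axis=0)
    ptp = np.where(rng_ > 0, rng_, 1.0)
    F_bg = _features(bg_env, mins, ptp)                       # (n_bg, 40)
    pres_env = grid.values[presence_cells[:, 0], presence_cells[:, 1]]
    F_p = _features(pres_env, mins, ptp)
    emp = F_p.mean(axis=0)
    s = beta * F_p.std(axis=0) / np.sqrt(len(F_p))            # per-feature L1 scale
    nf = F_bg.shape[1]

    def objective(theta):
        lam = theta[:nf] - theta[nf:]
        eta = F_bg @ lam
        c = eta.max()
        log_z = c + np.log(np.exp(eta - c).sum())
        p = np.exp(eta - log_z)
        expct = F_bg.T @ p
        nll = -(emp @ lam) + log_z + s @ (theta[:nf] + theta[nf:])
        grad = np.concatenate([-(emp - expct) + s, (emp - expct) + s])
        return nll, grad

    theta = np.zeros(2 * nf)
    proj = None
    for _ in range(6):   # L-BFGS-B restarts reset the Hessian approximation
        res = optimize.minimize(objective, theta, jac=True, method="L-BFGS-B",
                                bounds=[(0.0, None)] * (2 * nf),
                                options={"maxiter": max_iter, "ftol": 0.0,
                                         "gtol": 1e-8, "maxfun": max_iter})
        theta = res.x
        _, g = objective(theta)
        proj = np.where(theta <= 0.0, np.minimum(g, 0.0), g)
        if np.abs(proj).max() <= 1e-6:
            break
    if np.abs(proj).max() > 1e-6:
        raise ModelError(
            f"maxent did not converge: projected gradient {np.abs(proj).max():.2e}, "
            f"status={res.status} ({res.message})")
    lam = theta[:nf] - theta[nf:]
    eta = F_bg @ lam
    c = eta.max()
    log_z = float(c + np.log(np.exp(eta - c).sum()))
    raw = np.exp(eta - log_z)
    entropy = float(-special.xlogy(raw, raw).sum())
    eh = np.exp(entropy) * raw
    names = [f"{n}:{cls}" for cls in ("linear", "quadratic")
             for n in grid.env_set.names]
    return NicheModel(lam, names, mins, ptp, log_z, entropy, raw,
                      eh / (1.0 + eh), beta=beta)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def auc(scores_presence, scores_background) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([sp, sb]))
    r1 = ranks[: sp.size].sum()
    return float((r1 - sp.size * (sp.size + 1) / 2) / (sp.size * sb.size))


def bootstrap_eval(presence_cells: np.ndarray, grid: EnvGrid,
                   replicates: int = 100, train_frac: float = 0.7,
                   seed: int = 0, beta: float = 1.0):
    """Bootstrap model evaluation: per replicate a random train/test presence
    split (70/30 by default), a fit on the training share, and the AUC of the
    held-out presences against all background cells.

    Returns ``(mean_auc, sd_auc, flag, aucs)`` with flag "remove" iff the
    mean AUC falls below 0.7, mirroring the usual SDM screening rule.
    """
    presence_cells = np.atleast_2d(np.asarray(presence_cells, dtype=int))
    n = len(presence_cells)
    if n < 10:
        raise ModelError("need at least 10 presences for bootstrap evaluation")
    rng = np.random.default_rng(seed)
    bg = grid.masked_cells()
    aucs = []
    for _ in range(replicates):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train, test = presence_cells[perm[:n_train]], presence_cells[perm[n_train:]]
        if len(test) == 0 or len(train) < 5:
            logger.warning("bootstrap replicate skipped: empty split")
            continue
        model = fit_maxent(train, grid, beta=beta)
        aucs.append(auc(model.score_cells(grid, test),
                        model.score_cells(grid, bg)))
    aucs = np.array(aucs)
    mean = float(aucs.mean())
    flag = "remove" if mean < 0.7 else "keep"
    return mean, float(aucs.std(ddof=1)), flag, aucs


def max_sss_threshold(model: NicheModel, presence_cells: np.ndarray,
                      grid: EnvGrid) -> float:
    """Logistic threshold maximizing sensitivity (on presences) plus
    specificity (background as pseudo-absence); candidate thresholds are the
    observed logistic values, ties broken toward the larger threshold."""
    pres = model.score_cells(grid, np.atleast_2d(presence_cells))
    bg = model.logistic
    cand = np.unique(np.concatenate([pres, bg]))
    pres_sorted = np.sort(pres)
    bg_sorted = np.sort(bg)
    # sensitivity: fraction of presences with score >= tau
    sens = 1.0 - np.searchsorted(pres_sorted, cand, side="left") / pres.size
    spec = np.searchsorted(bg_sorted, cand, side="left") / bg.size
    total = sens + spec
    best = total.max()
    return float(cand[np.nonzero(total == best)[0][-1]])


def binarize(model: NicheModel, tau: float) -> np.ndarray:
    """Boolean presence prediction over masked cells (logistic ≥ τ)."""
    return model.logistic >= tau


def range_overlap(map_x: np.ndarray, map_y: np.ndarray,
                  metric: str = "jaccard") -> float:
    """Overlap percentage between two binary maps on the same mask.

    ``jaccard`` (default): 100·|X∩Y|/|X∪Y|; ``smaller``: 100·|X∩Y|/min(|X|,|Y|).
    Undefined (NaN, flagged) when both maps are empty.
    """
    x = np.asarray(map_x, bool)
    y = np.asarray(map_y, bool)
    if x.shape != y.shape:
        raise ValueError("maps must share one mask")
    inter = np.logical_and(x, y).sum()
    if metric == "jaccard":
        denom = np.logical_or(x, y).sum()
    elif metric == "smaller":
        denom = min(x.sum(), y.sum())
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    if denom == 0:
        logger.warning("range_overlap undefined: both maps empty")
        return float("nan")
    logger.info("range_overlap metric=%s", metric)
    return float(100.0 * inter / denom)


# ---------------------------------------------------------------------------
# Predicted niche occupancy
# ---------------------------------------------------------------------------

@dataclass
class PnoProfile:
    """Unit-area histogram of one environmental variable weighted by raw
    suitability."""

    variable: str
    edges: np.ndarray
    weights: np.ndarray
    note: str | None = None

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def median(self) -> float:
        """Weighted median of the profile (by bin midpoint)."""
        cum = np.cumsum(self.weights)
        return float(self.midpoints()[np.searchsorted(cum, 0.5)])


def pno_profile(model: NicheModel, grid: EnvGrid, variable: str,
                bins: int = 50) -> PnoProfile:
    """PNO profile: bin the variable over masked cells and weight each bin by
    the raw suitability mass it contains, renormalized to unit area."""
    if variable not in grid.env_set.names:
        raise ValueError(f"unknown variable {variable!r}")
    vals = grid.masked_env()[:, grid.env_set.names.index(variable)]
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        logger.warning("pno_profile: %s constant over mask; single-bin profile",
                       variable)
        return PnoProfile(variable, np.array([lo, hi]), np.array([1.0]),
                          note="constant variable")
    edges = np.linspace(lo, hi, bins + 1)
    weights, _ = np.histogram(vals, bins=edges, weights=model.raw)
    total = weights.sum()
    return PnoProfile(variable, edges, weights / total)
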