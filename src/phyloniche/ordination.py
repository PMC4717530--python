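"""PCA of the environmental matrix, cluster centroids in component space,
and the nonparametric tests used to compare niche clusters (Mann–Whitney U
on PC scores; a Kolmogorov–Smirnov normality check motivating them)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("phyloniche")


@dataclass
class PcaResult:
    """Orthonormal loadings (d×d), scores (n×d), variance fractions and the
    column means (and scales) used for centering."""

    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


def pca(X: np.ndarray, center: bool = True, scale: bool = False) -> PcaResult:
    """Principal component analysis via eigendecomposition of the covariance
    (or correlation, if ``scale``) matrix.

    Sign convention: the largest-magnitude entry of each loading column is
    made positive, so results are deterministic.  Rank-deficient input is
    fine (trailing eigenvalues are zero).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    mean = X.mean(axis=0) if center else np.zeros(d)
    Xc = X - mean
    sd = Xc.std(axis=0, ddof=1) if n > 1 else np.ones(d)
    if scale:
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValueError(f"zero-variance column(s) {zero.tolist()} with scale=True")
        Xc = Xc / sd
    else:
        sd = np.ones(d)
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full(d, 1.0 / d)
    return PcaResult(evecs, Xc @ evecs, fractions, mean, sd)


def cluster_centroids_in_pc_space(result: PcaResult, labels) -> dict:
    """Per-cluster mean of the PC1 and PC2 scores.  Empty clusters are
    reported as NaN centroids with a log flag."""
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        sel = labels == lab
        if not sel.any():
            logger.warning("cluster %r is empty; centroid undefined", lab)
            out[lab] = (np.nan, np.nan)
        else:
            sc = result.scores[sel]
            out[lab] = (float(sc[:, 0].mean()), float(sc[:, 1].mean()))
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Returns the smaller of the two U statistics and the two-sided p —
    by exact enumeration when n1·n2 ≤ 400 and the data are tie-free,
    otherwise by the normal approximation with tie-corrected variance and
    continuity correction.  Identical constant samples return p = 1 with a
    log flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("mann_whitney_u: all values identical; p = 1 by convention")
        return float(x.size * y.size / 2), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u = min(float(res.statistic), x.size * y.size - float(res.statistic))
    return u, float(res.pvalue)


def ks_normality(x) -> tuple[float, float]:
    """One-sample KS test of x against Normal(mean(x), sd(x)).

    Parameters are estimated from the sample, so the asymptotic p is
    conservative-biased (Lilliefors); a caveat is logged.  Requires n ≥ 5
    and nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    logger.info("ks_normality: parameters estimated from data; "
                "p-value has Lilliefors bias")
    D, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(D), float(p)
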