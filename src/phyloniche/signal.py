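"""Phylogenetic signal: Blomberg's K with a permutation test on the
variance of phylogenetically independent contrasts, evaluated per trait
over a tree ensemble.

K compares the observed ratio of tip variance (around the phylogenetic
mean) to contrast-implied variance against its Brownian-motion expectation;
K = 1 under Brownian evolution on the given tree, K < 1 means less
similarity among relatives than Brownian expectation.  Significance comes
from shuffling trait values across tips: the one-sided test asks whether
the observed contrast variance is smaller than in the permuted data
(signal ⇒ small contrasts).

Traits are either per-species medians of the environmental variables or
the PC1/PC2 centroid of the species' niche cluster — the latter gives all
species of one cluster identical trait values, a deliberate feature of the
trait construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DatedTree, OccurrenceTable, TreeEnsemble
from .ordination import PcaResult

logger = logging.getLogger("phyloniche")


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

def build_trait_table(occ: OccurrenceTable, labels, pca_result: PcaResult,
                      primary: dict | None = None) -> pd.DataFrame:
    """Per-species trait table: the median of each environmental variable
    over the species' localities, plus PC1/PC2 set to the centroid score of
    the species' primary niche cluster (so species sharing a cluster share
    identical PC traits).

    ``labels`` assigns a cluster id to every occurrence record; ``primary``
    optionally overrides the majority rule for a species' primary cluster.
    """
    labels = np.asarray(labels)
    df = occ.df
    primary = dict(primary or {})
    centroids = {}
    for lab in np.unique(labels):
        sel = labels == lab
        centroids[lab] = (pca_result.scores[sel, 0].mean(),
                          pca_result.scores[sel, 1].mean())
    rows = {}
    for sp, sub in df.groupby("species", sort=False):
        idx = sub.index.to_numpy()
        med = sub[list(occ.env_set.names)].median()
        if sp not in primary:
            lab_counts = pd.Series(labels[idx]).value_counts().sort_index()
            primary[sp] = lab_counts.idxmax()
        pc1, pc2 = centroids[primary[sp]]
        rows[sp] = {"PC1": pc1, "PC2": pc2, **med.to_dict()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.isna().any().any():
        raise ValueError("trait table contains missing values")
    return table


# ---------------------------------------------------------------------------
# Covariance and K
# ---------------------------------------------------------------------------

def phylo_covariance(tree: DatedTree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance: V_ij = root-to-MRCA(i,j) path length,
    V_ii = the tip's depth (root age on an ultrametric tree).  Returns the
    matrix and the tip-label order of its rows."""
    tips = list(tree.tree.leaf_node_iter())
    order = {t.taxon.label: i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    depths, tipsets = {}, {}
    for node in tree.tree.preorder_node_iter():
        parent = depths.get(node.parent_node, 0.0)
        depths[node] = parent + (node.edge.length or 0.0)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = order[node.taxon.label]
            V[i, i] = depths[node]
            tipsets[node] = [i]
        else:
            children = node.child_nodes()
            merged = []
            for c in children:
                for prev in merged:
                    for i in tipsets[c]:
                        for j in prev:
                            V[i, j] = V[j, i] = depths[node]
                merged.append(tipsets[c])
            tipsets[node] = [i for grp in merged for i in grp]
    return V, [t.taxon.label for t in tips]


def blomberg_k(tree: DatedTree, trait) -> float:
    """Blomberg's K for one trait (dict or Series keyed by tip label, or a
    vector in the tree's tip order)."""
    V, order = phylo_covariance(tree)
    x = _trait_vector(trait, order)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    if np.var(x) == 0:
        raise ValueError("trait has zero variance")
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    denom_a = one @ Vi @ one
    a_hat = (one @ Vi @ x) / denom_a
    dev = x - a_hat
    mse0 = dev @ dev / (n - 1)
    mse = dev @ Vi @ dev / (n - 1)
    if mse == 0:
        logger.warning("blomberg_k: zero phylogenetic MSE; K undefined")
        return float("nan")
    expected = (np.trace(V) - n / denom_a) / (n - 1)
    return float((mse0 / mse) / expected)


def _trait_vector(trait, order: list[str]) -> np.ndarray:
    if isinstance(trait, (dict, pd.Series)):
        return np.array([float(trait[lab]) for lab in order])
    x = np.asarray(trait, dtype=float)
    if x.size != len(order):
        raise ValueError("trait vector length does not match tip count")
    return x


# ---------------------------------------------------------------------------
# Independent contrasts and the permutation test
# ---------------------------------------------------------------------------

def contrast_matrix(tree: DatedTree) -> tuple[np.ndarray, list[str]]:
    """The (n−1)×n linear map from tip values to standardized independent
    contrasts (contrasts are linear in the trait for a fixed tree, which
    lets permutations run as one matrix product).  Polytomies are resolved
    arbitrarily with zero-length internal edges."""
    rows = []
    order = tree.tip_labels
    n = len(order)
    idx = {lab: i for i, lab in enumerate(order)}
    wvec = {}
    vlen = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            w = np.zeros(n)
            w[idx[node.taxon.label]] = 1.0
            wvec[node] = w
            vlen[node] = node.edge.length or 0.0
        else:
            children = node.child_nodes()
            w1, v1 = wvec[children[0]], vlen[children[0]]
            for c in children[1:]:      # left-fold resolves polytomies
                w2, v2 = wvec[c], vlen[c]
                denom = v1 + v2
                if denom <= 0:
                    denom = 1e-12       # zero-length cherry: contrast unscaled
                rows.append((w1 - w2) / np.sqrt(denom))
                w1 = (v2 * w1 + v1 * w2) / denom
                v1 = v1 * v2 / denom
            wvec[node] = w1
            vlen[node] = (node.edge.length or 0.0) + v1
    return np.array(rows), order


def permutation_p(tree: DatedTree, trait, n_perm: int = 999, seed: int = 0,
                  two_sided: bool = False) -> float:
    """Permutation p-value for phylogenetic signal.

    Statistic: variance of the standardized contrasts; null distribution
    from shuffling trait values across tips.  One-sided by default
    (signal ⇔ observed variance low): p = (1 + #{var_perm ≤ var_obs}) /
    (n_perm + 1).
    """
    C, order = contrast_matrix(tree)
    x = _trait_vector(trait, order)
    rng = np.random.default_rng(seed)
    obs = np.var(C @ x, ddof=1)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    null = np.var(perms @ C.T, axis=1, ddof=1)
    less = int((null <= obs).sum())
    p_less = (1 + less) / (n_perm + 1)
    if not two_sided:
        return float(p_less)
    greater = int((null >= obs).sum())
    p_greater = (1 + greater) / (n_perm + 1)
    return float(min(1.0, 2 * min(p_less, p_greater)))


# ---------------------------------------------------------------------------
# Ensemble summary
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Per-trait medians of K and p over the ensemble plus the percentage
    of trees not rejecting the random-signal null (p > 0.05)."""

    table: pd.DataFrame        # trait × (median_k, median_p, pct_not_rejecting)
    n_trees_used: int


def signal_over_trees(ensemble: TreeEnsemble, traits: pd.DataFrame,
                      n_perm: int = 999, seed: int = 0) -> SignalResult:
    """K and its permutation p for every trait on every tree of the
    ensemble; per-tree seeds derive from ``seed`` + the tree index so runs
    are reproducible and order-independent.  Trees failing on a trait are
    skipped (logged) and the denominator adjusted."""
    missing = set(traits.index).symmetric_difference(ensemble.tip_labels)
    if missing:
        raise ValueError(f"traits/tips mismatch: {sorted(missing)}")
    ks = {c: [] for c in traits.columns}
    ps = {c: [] for c in traits.columns}
    for i, tree in enumerate(ensemble):
        C, order = contrast_matrix(tree)
        V, orderV = phylo_covariance(tree)
        for col in traits.columns:
            try:
                ks[col].append(blomberg_k(tree, traits[col]))
                ps[col].append(permutation_p(tree, traits[col], n_perm=n_perm,
                                             seed=seed + i))
            except Exception as exc:   # noqa: BLE001 — per-tree skip
                logger.warning("signal: tree %d skipped for %s (%s)", i, col, exc)
    rows = {}
    for col in traits.columns:
        p = np.array(ps[col])
        rows[col] = {
            "median_k": float(np.median(ks[col])) if ks[col] else np.nan,
            "median_p": float(np.median(p)) if p.size else np.nan,
            "pct_not_rejecting": float(100.0 * (p > 0.05).mean()) if p.size else np.nan,
            "n_trees": int(p.size),
        }
    return SignalResult(pd.DataFrame.from_dict(rows, orient="index"),
                        len(ensemble))
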