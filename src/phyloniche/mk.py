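"""Mk-model machinery: 3-state continuous-time Markov likelihood with
ambiguous (polymorphic) tips, MCMC over transition rates with an
exponential hyperprior, marginal ancestral states, harmonic-mean marginal
likelihoods, Bayes-factor model comparison and transition counting on a
chronogram.

States are A, B, C; the six directed rates are ordered
(q_AB, q_AC, q_BA, q_BC, q_CA, q_CB), in events per Ma.  Constrained
models fix a subset of rates to exactly zero.  The root prior is uniform
by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm as scipy_expm
from scipy.special import logsumexp

from . import _mk_kernels as kern
from .coding import TipStateCoding
from .core_io import STATES, DatedTree, TreeEnsemble
from .synthetic import RATE_ORDER

logger = logging.getLogger("phyloniche")

UNIFORM_PI = np.full(3, 1.0 / 3.0)


@dataclass
class MkParameters:
    """Six transition rates, a constraint mask (rates pinned to 0), the
    exponential-hyperprior mean and the root state prior."""

    rates: dict = field(default_factory=lambda: {p: 1.0 for p in RATE_ORDER})
    constraint_mask: frozenset = frozenset()
    mu: float = 10.0
    root_prior: np.ndarray = field(default_factory=lambda: UNIFORM_PI.copy())

    def __post_init__(self):
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if not np.isclose(self.root_prior.sum(), 1.0):
            raise ValueError("root prior must sum to 1")
        for pair in RATE_ORDER:
            self.rates.setdefault(pair, 0.0)
            if self.rates[pair] < 0:
                raise ValueError(f"rate q_{pair} must be >= 0")
        for pair in self.constraint_mask:
            if self.rates[pair] != 0.0:
                raise ValueError(f"constrained rate q_{pair} must be exactly 0")
        if not 0.0 < self.mu <= 30.0:
            raise ValueError("hyperprior mean must lie in (0, 30]")

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rates[p] for p in RATE_ORDER])

    def q_matrix(self) -> np.ndarray:
        Q = np.zeros((3, 3))
        kern.build_q(self.rate_vector(), Q)
        return Q


def transition_matrix(params: MkParameters, t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to 1, entries non-negative."""
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    P = scipy_expm(params.q_matrix() * t)
    return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _tip_partials(tip_order: list[str], tips: dict) -> np.ndarray:
    """Indicator partials over each tip's coded state subset."""
    part = np.zeros((len(tip_order), 3))
    for i, label in enumerate(tip_order):
        if label not in tips:
            raise ValueError(f"tip {label!r} has no state coding")
        states = tips[label]
        states = states.states if isinstance(states, TipStateCoding) else states
        for s in states:
            part[i, STATES.index(s)] = 1.0
    return part


def pruning_log_likelihood(tree: DatedTree, tips: dict,
                           params: MkParameters) -> float:
    """Felsenstein-pruning log likelihood; ``tips`` maps tip label to a
    coded state subset (or :class:`TipStateCoding`)."""
    n_tips, left, right, blen, postorder, _ = tree.to_arrays()
    part = _tip_partials(tree.tip_labels, tips)
    return float(kern.prune_ll(left, right, blen, postorder, part,
                               params.q_matrix(), params.root_prior))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class MkPosterior:
    """Post-burn-in MCMC samples plus bookkeeping.

    ``samples`` columns: generation, q_AB..q_CB, mu, tree, log_likelihood.
    """

    samples: pd.DataFrame
    constraint_mask: frozenset
    settings: dict
    acceptance: pd.DataFrame
    signature: tuple

    @property
    def log_likelihoods(self) -> np.ndarray:
        return self.samples["log_likelihood"].to_numpy()

    def rate_means(self) -> dict:
        return {p: float(self.samples[f"q_{p}"].mean()) for p in RATE_ORDER}


def _ensemble_arrays(trees: TreeEnsemble, tips: dict):
    tip_order = sorted(trees.tip_labels)
    lefts, rights, blens, posts = [], [], [], []
    for t in trees:
        _, left, right, blen, postorder, _ = t.to_arrays(tip_order)
        lefts.append(left)
        rights.append(right)
        blens.append(blen)
        posts.append(postorder)
    part = _tip_partials(tip_order, tips)
    tip_parts = np.broadcast_to(part, (len(trees), *part.shape)).copy()
    return (np.array(lefts), np.array(rights), np.array(blens),
            np.array(posts), tip_parts, tip_order)


def _signature(trees: TreeEnsemble, tips: dict) -> tuple:
    items = []
    for label in sorted(trees.tip_labels):
        states = tips[label]
        states = states.states if isinstance(states, TipStateCoding) else states
        items.append((label, "".join(sorted(states))))
    return (len(trees), tuple(items))


def mcmc(trees: TreeEnsemble, tips: dict, constraint_mask=frozenset(),
         generations: int = 5_050_000, burn_in: int = 50_000,
         thin: int = 1_000, ratedev: float = 250.0, mu_window: float = 5.0,
         hyperprior_upper: float = 30.0, seed: int = 0,
         root_prior: np.ndarray = UNIFORM_PI, power: float = 1.0) -> MkPosterior:
    """Sample transition rates (and trees) from the Mk posterior.

    Per generation one of three moves is chosen uniformly: a rate
    perturbation (window ``ratedev``, negative proposals rejected), a
    hyperprior-mean perturbation within (0, ``hyperprior_upper``], or a
    uniform tree switch.  Each unconstrained rate has an Exponential(mean μ)
    prior.  Samples are retained post burn-in every ``thin`` generations.
    ``power`` tempers the likelihood (power posteriors for stepping-stone
    estimation); recorded log likelihoods are always untempered.
    """
    constraint_mask = frozenset(constraint_mask)
    free = [i for i, p in enumerate(RATE_ORDER) if p not in constraint_mask]
    if not free:
        raise ValueError("at least one rate must be unconstrained")
    lefts, rights, blens, posts, tip_parts, _ = _ensemble_arrays(trees, tips)
    samples, accepts, proposals = kern.mcmc_chain(
        lefts, rights, blens, posts, tip_parts,
        np.asarray(root_prior, dtype=float), np.array(free, dtype=np.int64),
        float(ratedev), float(mu_window), float(hyperprior_upper),
        int(generations), int(burn_in), int(thin), int(seed) & 0x7FFFFFFF,
        float(power))
    cols = ["generation"] + [f"q_{p}" for p in RATE_ORDER] \
        + ["mu", "tree", "log_likelihood"]
    df = pd.DataFrame(samples, columns=cols)
    df["generation"] = df["generation"].astype(int)
    df["tree"] = df["tree"].astype(int)
    acc = pd.DataFrame({"move": ["rate", "hyperprior", "tree"],
                        "proposals": proposals, "accepts": accepts})
    acc["rate"] = acc["accepts"] / acc["proposals"].clip(lower=1)
    for _, row in acc.iterrows():
        if row["proposals"] > 1_000 and row["accepts"] == 0:
            logger.warning(
                "MCMC move %r accepted nothing over %d proposals; consider "
                "shrinking its proposal window", row["move"], row["proposals"])
    settings = {"generations": generations, "burn_in": burn_in, "thin": thin,
                "ratedev": ratedev, "mu_window": mu_window,
                "hyperprior_upper": hyperprior_upper, "seed": seed,
                "power": power}
    return MkPosterior(df, constraint_mask, settings, acc,
                       _signature(trees, tips))


# ---------------------------------------------------------------------------
# Ancestral states
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Node (identified by its extant tip set) → posterior state probabilities."""

    node_probs: dict      # frozenset of tip labels → (3,) probability vector

    def modal_state(self, node_spec: frozenset) -> tuple[str, float]:
        p = self.node_probs[frozenset(node_spec)]
        k = int(np.argmax(p))
        return STATES[k], float(p[k])


def _node_marginals(left, right, blen, postorder, tip_part, Q, pi):
    """Two-pass (down/up) conditional-likelihood marginals per internal node."""
    n_nodes = left.shape[0]
    n_tips = tip_part.shape[0]
    P = np.empty((n_nodes, 3, 3))
    for v in range(n_nodes):
        P[v] = scipy_expm(Q * blen[v])
    down = np.zeros((n_nodes, 3))
    down[:n_tips] = tip_part
    for v in postorder:
        l, r = left[v], right[v]
        down[v] = (P[l] @ down[l]) * (P[r] @ down[r])
        m = down[v].max()
        if m > 0:
            down[v] /= m
    up = np.zeros((n_nodes, 3))
    root = postorder[-1]
    up[root] = pi
    for v in postorder[::-1]:
        l, r = left[v], right[v]
        for c, s in ((l, r), (r, l)):
            vec = P[c].T @ (up[v] * (P[s] @ down[s]))
            tot = vec.sum()
            up[c] = vec / tot if tot > 0 else vec
    marg = {}
    for v in postorder:
        p = up[v] * down[v]
        marg[int(v)] = p / p.sum()
    return marg


def marginal_ancestral_states(posterior: MkPosterior, trees: TreeEnsemble,
                              tips: dict, node_specs: list) -> AncestralReconstruction:
    """Average per-node marginal state probabilities over posterior samples.

    Each node is located as the MRCA of its extant tip set on each sample's
    tree (on discordant trees the MRCA may subsume extra tips; this is
    logged per node).
    """
    node_specs = [frozenset(s) for s in node_specs]
    for spec in node_specs:
        if not spec:
            raise ValueError("empty node spec")
        if not spec <= set(trees.tip_labels):
            raise ValueError(f"node spec {sorted(spec)} not a subset of the tips")
    tip_order = sorted(trees.tip_labels)
    part = _tip_partials(tip_order, tips)
    pi = UNIFORM_PI
    prepared = []
    for t in trees:
        n_tips, left, right, blen, postorder, index = t.to_arrays(tip_order)
        spec_to_node = {}
        for spec in node_specs:
            mrca = t.tree.mrca(taxon_labels=list(spec))
            clade = {lf.taxon.label for lf in mrca.leaf_iter()}
            if clade != spec:
                logger.info("node %s subsumes %d extra tip(s) on one tree",
                            sorted(spec)[:3], len(clade - spec))
            spec_to_node[spec] = index[mrca]
        prepared.append((left, right, blen, postorder, spec_to_node))
    sums = {spec: np.zeros(3) for spec in node_specs}
    for _, row in posterior.samples.iterrows():
        Q = np.zeros((3, 3))
        kern.build_q(np.array([row[f"q_{p}"] for p in RATE_ORDER]), Q)
        left, right, blen, postorder, spec_to_node = prepared[int(row["tree"])]
        marg = _node_marginals(left, right, blen, postorder, part, Q, pi)
        for spec, node in spec_to_node.items():
            sums[spec] += marg[node]
    probs = {spec: s / s.sum() for spec, s in sums.items()}
    return AncestralReconstruction(probs)


# ---------------------------------------------------------------------------
# Marginal likelihood and Bayes factors
# ---------------------------------------------------------------------------

def harmonic_mean_log_ml(log_likelihoods, n_bootstrap: int = 1_000,
                         seed: int = 0, min_samples: int = 100) -> tuple[float, float]:
    """Harmonic-mean estimate of the log marginal likelihood with a
    block-bootstrap standard error.

    logML = −logmeanexp(−logL).  The estimator is known to be high-variance;
    it is kept for comparability with the classical phylogenetics workflow.
    Requires ≥ 100 samples.
    """
    if isinstance(log_likelihoods, MkPosterior):
        log_likelihoods = log_likelihoods.log_likelihoods
    logl = np.asarray(log_likelihoods, dtype=float)
    if logl.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} post-burn-in samples, got {logl.size}")
    n = logl.size
    log_ml = -(logsumexp(-logl) - np.log(n))
    rng = np.random.default_rng(seed)
    block = max(1, int(np.sqrt(n)))
    n_blocks = int(np.ceil(n / block))
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)).ravel()[:n]
        reps[b] = -(logsumexp(-logl[idx]) - np.log(n))
    return float(log_ml), float(reps.std(ddof=1))


def stepping_stone_log_ml(trees: TreeEnsemble, tips: dict,
                          constraint_mask=frozenset(), n_steps: int = 16,
                          alpha: float = 0.3, seed: int = 0,
                          **mcmc_kwargs) -> float:
    """Stepping-stone estimate of the log marginal likelihood.

    Runs one power-posterior chain per β step (β_k = (k/K)^{1/α}, the usual
    Beta-quantile spacing) and sums log-mean-exp ratios between adjacent
    powers.  This is the recommended, lower-variance estimator; the
    harmonic mean remains the one used where comparability with the
    classical Bayes-factor workflow matters.
    """
    betas = (np.arange(n_steps + 1) / n_steps) ** (1.0 / alpha)
    log_ml = 0.0
    for k in range(n_steps):
        post = mcmc(trees, tips, constraint_mask=constraint_mask,
                    power=float(betas[k]), seed=seed + k, **mcmc_kwargs)
        logl = post.log_likelihoods
        log_ml += float(logsumexp((betas[k + 1] - betas[k]) * logl)
                        - np.log(logl.size))
    return log_ml


BF_CATEGORIES = ((2.0, "none"), (6.0, "positive"), (10.0, "strong"))


def bf_category(bf: float) -> str:
    for bound, label in BF_CATEGORIES:
        if bf < bound:
            return label
    return "very strong"


@dataclass
class ModelComparison:
    table: pd.DataFrame   # label, constraints, log_ml, se, bf, category


def bayes_factor_table(full: MkPosterior,
                       constrained: list[tuple[str, MkPosterior]]) -> ModelComparison:
    """BF = 2·(logML_full − logML_constrained) for each constrained model,
    with the evidence category on the 2–6 / 6–10 / >10 scale.  Negative BFs
    (a constrained model estimated better than the full one) are reported
    as-is.  All models must have been run on the same trees and tip data."""
    rows = []
    lml_full, se_full = harmonic_mean_log_ml(full.log_likelihoods)
    rows.append({"label": "full", "constraints": "",
                 "log_ml": lml_full, "se": se_full, "bf": 0.0,
                 "category": "none"})
    for label, post in constrained:
        if post.signature != full.signature:
            raise ValueError(f"model {label!r} was run on different data")
        lml, se = harmonic_mean_log_ml(post.log_likelihoods)
        bf = 2.0 * (lml_full - lml)
        rows.append({"label": label,
                     "constraints": "+".join(sorted(post.constraint_mask)),
                     "log_ml": lml, "se": se, "bf": bf,
                     "category": bf_category(bf)})
    return ModelComparison(pd.DataFrame(rows))


# the study's model set: six single-rate-zero models plus the
# no-reversal-out-of-C model
STANDARD_MODELS = tuple([(f"q_{p}=0", frozenset({p})) for p in RATE_ORDER]
                        + [("q_CB=0,q_CA=0", frozenset({"CA", "CB"}))])


# ---------------------------------------------------------------------------
# Transition counting
# ---------------------------------------------------------------------------

@dataclass
class TransitionSummary:
    """Edge-by-edge niche shifts on the chronogram."""

    table: pd.DataFrame
    pp_filter: float
    q_boundary: float

    def filtered(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    def counts(self) -> dict:
        out = {}
        for _, row in self.filtered().iterrows():
            key = f"{row['from']}->{row['to']}"
            out[key] = out.get(key, 0) + 1
        return out

    @property
    def total(self) -> int:
        return int(self.table["included"].sum())


def _tip_modal(coding) -> str:
    """A tip's modal state: its single coded state, or the coded state with
    the higher locality count if polymorphic."""
    if isinstance(coding, TipStateCoding):
        states = sorted(coding.states)
        if len(states) == 1:
            return states[0]
        counts = dict(zip(STATES, coding.counts))
        return max(states, key=lambda s: (counts[s], -STATES.index(s)))
    states = sorted(coding)
    if len(states) > 1:
        raise ValueError("polymorphic tip without counts; pass a TipStateCoding")
    return states[0]


def count_transitions(recon: AncestralReconstruction, chronogram: DatedTree,
                      tips: dict, pp_filter: float = 0.95,
                      q_boundary: float = 2.6) -> TransitionSummary:
    """Scan every parent→child edge for a change of modal state.

    A transition's age is the child node's age (0 on terminal edges), its
    Quaternary flag is ``age ≤ q_boundary``, and it is counted (included)
    only when the child clade's posterior support exceeds ``pp_filter``
    (terminal edges pass by convention).
    """
    chronogram.tree.calc_node_ages(ultrametricity_precision=False)
    rows = []
    for node in chronogram.tree.preorder_node_iter():
        if node is chronogram.tree.seed_node:
            continue
        parent = node.parent_node
        parent_spec = frozenset(lf.taxon.label for lf in parent.leaf_iter())
        if parent_spec not in recon.node_probs:
            raise ValueError(f"reconstruction missing node {sorted(parent_spec)[:3]}")
        p_state, _ = recon.modal_state(parent_spec)
        if node.is_leaf():
            label = node.taxon.label
            c_state = _tip_modal(tips[label])
            branch_class, age, support = "terminal", 0.0, None
        else:
            spec = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if spec not in recon.node_probs:
                raise ValueError(f"reconstruction missing node {sorted(spec)[:3]}")
            c_state, _ = recon.modal_state(spec)
            branch_class = "internal"
            age = float(node.age)
            support = chronogram.node_support(node)
        if c_state == p_state:
            continue
        passes = branch_class == "terminal" or (support is not None
                                                and support > pp_filter)
        rows.append({"from": p_state, "to": c_state, "branch_class": branch_class,
                     "age_ma": age, "quaternary": age <= q_boundary,
                     "support": support, "included": passes})
    cols = ["from", "to", "branch_class", "age_ma", "quaternary", "support",
            "included"]
    return TransitionSummary(pd.DataFrame(rows, columns=cols), pp_filter,
                             q_boundary)
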