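"""Numba kernels for the 3-state Mk likelihood and its MCMC sampler.

The transition-probability routine is a hand-rolled scaling-and-squaring
Taylor expansion specialized to 3×3 generators, because it has to run inside
jitted code on every branch of every likelihood evaluation; scipy's expm is
the oracle it is tested against.  Trees arrive flattened (children arrays +
post-order schedule) via :meth:`DatedTree.to_arrays`.  All inner routines
work on caller-provided scratch buffers — the MCMC loop performs no heap
allocation per generation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

K = 3


@njit(cache=False, inline="always")
def _expm3(Q, t, out, B, term, tmp):
    """out = exp(Q t); B, term, tmp are 3×3 scratch buffers."""
    norm = 0.0
    for i in range(K):
        for j in range(K):
            a = abs(Q[i, j] * t)
            if a > norm:
                norm = a
    s = 0
    while norm > 0.5:
        norm *= 0.5
        s += 1
    inv = t / (2.0 ** s)
    for i in range(K):
        for j in range(K):
            B[i, j] = Q[i, j] * inv
            term[i, j] = 1.0 if i == j else 0.0
            out[i, j] = term[i, j]
    for k in range(1, 13):   # 0.5^12/12! ≈ 5e-13 truncation at the scaled norm
        fac = 1.0 / k
        for i in range(K):
            for j in range(K):
                acc = 0.0
                for l in range(K):
                    acc += term[i, l] * B[l, j]
                tmp[i, j] = acc * fac
        for i in range(K):
            for j in range(K):
                term[i, j] = tmp[i, j]
                out[i, j] += tmp[i, j]
    for _ in range(s):
        for i in range(K):
            for j in range(K):
                acc = 0.0
                for l in range(K):
                    acc += out[i, l] * out[l, j]
                tmp[i, j] = acc
        for i in range(K):
            for j in range(K):
                out[i, j] = tmp[i, j]
    for i in range(K):
        for j in range(K):
            if out[i, j] < 0.0:
                out[i, j] = 0.0


def expm3(Q, t, out):
    """Convenience wrapper (allocates its own scratch)."""
    B = np.empty((K, K))
    term = np.empty((K, K))
    tmp = np.empty((K, K))
    _expm3(np.asarray(Q, dtype=np.float64), float(t), out, B, term, tmp)


@njit(cache=False)
def build_q(rates, Q):
    """Fill the generator from the rate vector (AB, AC, BA, BC, CA, CB)."""
    Q[0, 1] = rates[0]
    Q[0, 2] = rates[1]
    Q[1, 0] = rates[2]
    Q[1, 2] = rates[3]
    Q[2, 0] = rates[4]
    Q[2, 1] = rates[5]
    for i in range(K):
        Q[i, i] = 0.0
        acc = 0.0
        for j in range(K):
            if j != i:
                acc += Q[i, j]
        Q[i, i] = -acc


@njit(cache=False)
def _prune_ll_ws(left, right, blen, postorder, tip_part, Q, pi,
                 part, P, B, term, tmp):
    """Felsenstein pruning log likelihood with per-node rescaling."""
    n_tips = tip_part.shape[0]
    for i in range(n_tips):
        for k in range(K):
            part[i, k] = tip_part[i, k]
    logscale = 0.0
    for n in range(postorder.shape[0]):
        v = postorder[n]
        for k in range(K):
            part[v, k] = 1.0
        for side in range(2):
            c = left[v] if side == 0 else right[v]
            _expm3(Q, blen[c], P, B, term, tmp)
            for x in range(K):
                acc = 0.0
                for y in range(K):
                    acc += P[x, y] * part[c, y]
                tmp[0, x] = acc          # row 0 of tmp doubles as a 3-vector
            for x in range(K):
                part[v, x] *= tmp[0, x]
        m = 0.0
        for k in range(K):
            if part[v, k] > m:
                m = part[v, k]
        if m <= 0.0:
            return -np.inf
        for k in range(K):
            part[v, k] /= m
        logscale += np.log(m)
    root = postorder[postorder.shape[0] - 1]
    lik = 0.0
    for k in range(K):
        lik += pi[k] * part[root, k]
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logscale


@njit(cache=False)
def prune_ll(left, right, blen, postorder, tip_part, Q, pi):
    part = np.empty((left.shape[0], K))
    P = np.empty((K, K))
    B = np.empty((K, K))
    term = np.empty((K, K))
    tmp = np.empty((K, K))
    return _prune_ll_ws(left, right, blen, postorder, tip_part, Q, pi,
                        part, P, B, term, tmp)


@njit(cache=False)
def mcmc_chain(lefts, rights, blens, postorders, tip_parts, pi, free_idx,
               ratedev, mu_window, mu_upper, n_gens, burn_in, thin, seed,
               power):
    """Metropolis–Hastings over (rates, hyperprior mean, tree index).

    Moves, chosen uniformly per generation:
      0. perturb one random unconstrained rate by Uniform(±ratedev/2);
         negative proposals are rejected outright;
      1. perturb the exponential-hyperprior mean by Uniform(±mu_window/2),
         constrained to (0, mu_upper];
      2. switch to a uniformly drawn tree of the ensemble.
    Each unconstrained rate has prior Exponential(mean μ), and the
    likelihood enters acceptance ratios raised to ``power`` (1 for ordinary
    posterior sampling; fractional powers give the power posteriors of the
    stepping-stone estimator).  Rates start at
    Exponential(1) draws — a deliberately modest scale: the Mk likelihood
    has a quasi-stationary ridge at implausibly high rates which a chain
    seeded from the diffuse hyperprior can take very long to leave.

    Returns (samples, accepts, proposals): samples has one row per retained
    generation with columns [generation, q_AB..q_CB, μ, tree, logL].
    """
    np.random.seed(seed)
    n_trees = lefts.shape[0]
    n_free = free_idx.shape[0]
    rates = np.zeros(6)
    mu = np.random.uniform(0.0, mu_upper)
    for a in range(n_free):
        rates[free_idx[a]] = np.random.exponential(1.0)
    Q = np.zeros((K, K))
    build_q(rates, Q)
    part = np.empty((lefts.shape[1], K))
    P = np.empty((K, K))
    B = np.empty((K, K))
    term = np.empty((K, K))
    tmp = np.empty((K, K))
    tree = 0
    cur_ll = _prune_ll_ws(lefts[tree], rights[tree], blens[tree],
                          postorders[tree], tip_parts[tree], Q, pi,
                          part, P, B, term, tmp)
    n_keep = (n_gens - burn_in) // thin
    samples = np.empty((n_keep, 10))
    accepts = np.zeros(3, dtype=np.int64)
    proposals = np.zeros(3, dtype=np.int64)
    kept = 0
    for gen in range(1, n_gens + 1):
        move = np.random.randint(0, 3)
        proposals[move] += 1
        if move == 0:
            j = free_idx[np.random.randint(0, n_free)]
            old = rates[j]
            prop = old + (np.random.random() - 0.5) * ratedev
            if prop >= 0.0:
                rates[j] = prop
                build_q(rates, Q)
                new_ll = _prune_ll_ws(lefts[tree], rights[tree], blens[tree],
                                      postorders[tree], tip_parts[tree], Q, pi,
                                      part, P, B, term, tmp)
                dprior = -(prop - old) / mu
                if np.log(np.random.random()) < power * (new_ll - cur_ll) + dprior:
                    cur_ll = new_ll
                    accepts[0] += 1
                else:
                    rates[j] = old
                    build_q(rates, Q)
        elif move == 1:
            prop_mu = mu + (np.random.random() - 0.5) * mu_window
            if 0.0 < prop_mu <= mu_upper:
                dprior = 0.0
                for a in range(n_free):
                    q = rates[free_idx[a]]
                    dprior += (-np.log(prop_mu) - q / prop_mu) \
                        - (-np.log(mu) - q / mu)
                if np.log(np.random.random()) < dprior:
                    mu = prop_mu
                    accepts[1] += 1
        else:
            prop_tree = np.random.randint(0, n_trees)
            if prop_tree == tree:
                accepts[2] += 1
            else:
                new_ll = _prune_ll_ws(lefts[prop_tree], rights[prop_tree],
                                      blens[prop_tree], postorders[prop_tree],
                                      tip_parts[prop_tree], Q, pi,
                                      part, P, B, term, tmp)
                if np.log(np.random.random()) < power * (new_ll - cur_ll):
                    tree = prop_tree
                    cur_ll = new_ll
                    accepts[2] += 1
        if gen > burn_in and (gen - burn_in) % thin == 0 and kept < n_keep:
            samples[kept, 0] = gen
            for a in range(6):
                samples[kept, 1 + a] = rates[a]
            samples[kept, 7] = mu
            samples[kept, 8] = tree
            samples[kept, 9] = cur_ll
            kept += 1
    return samples[:kept], accepts, proposals
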