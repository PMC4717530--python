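# Methods

This note documents the models, defaults and numerical choices behind
`phyloniche`, and what the synthetic data can and cannot show.

## Niche clustering

Records are clustered on **raw environmental values** (altitude in m,
temperatures in °C×10, precipitation in mm).  On raw WorldClim-style units
the metric is dominated by precipitation; this is deliberate — the method
is defined on raw layers — and `standardize=True` is available where a
balanced metric is wanted.  Distances are plain Euclidean; classical MDS
(double-centering + eigendecomposition) retains, under `dims="auto"`, every
dimension with eigenvalue > 1e-8 × the largest, which makes the embedding
distance-preserving for Euclidean input.  Clustering the MDS coordinates or
the raw matrix therefore yields identical hard labels (a tested property),
so the ambiguity between the two pipelines is immaterial.

Fuzzy C-means alternates the standard membership and centroid updates and
stops when |ΔJ| < 1e-9 or 200 iterations.  Memberships are initialized
from a symmetric Dirichlet(1) draw under the run seed; the sweep runs a
single start per combination (seed + combination index), with restarts
available on the estimator.  If a point coincides with one or more
centroids its membership mass is split equally over the zero-distance
centroids.

**Validity indices.**  Four are fixed by the analysis design (partition
coefficient, partition entropy, Xie–Beni, Dunn on the hard partition); the
remaining three (Fukuyama–Sugeno, fuzzy hypervolume, average partition
density) were chosen from the same classical index family, and the registry
is pluggable.  Indices needing an inter-centroid separation are reported as
NaN-with-flag at K = 1; singular fuzzy covariances (common at large K with
few points) NaN-flag the hypervolume-based indices rather than aborting the
sweep.  "Next to optimal" support is operationalized as rank ≤ 2 per index;
consensus ties break toward smaller K, then smaller m.

## Ordination and tests

PCA defaults to the covariance matrix (center, no scale; `scale` exposed),
with a deterministic sign convention (largest-|loading| entry positive).
Mann–Whitney U uses exact enumeration when n₁·n₂ ≤ 400 and the data are
tie-free, otherwise the tie-corrected normal approximation with continuity
correction; the reported p is two-sided.  The KS normality check estimates
mean and sd from the sample, so its p carries the Lilliefors bias — it is
logged as such and used only as a screening step.

## Maximum-entropy niche models

The ENM is a deliberately small maximum-entropy variant: linear and
quadratic features only, min–max standardized over the background (all
masked grid cells), and an L1 penalty β·sd_presence(f_j)/√|P| per feature.
The penalized log likelihood is concave; it is maximized by L-BFGS-B on the
split λ = λ⁺ − λ⁻ (bounds ≥ 0), declared converged when the projected
gradient ∞-norm < 1e-6 (the optimizer is restarted up to five times to
reset its Hessian approximation, which matters in the β = 0 flat-ridge
case).  Raw output is the normalized exp(λ·f) over the background; the
logistic output is the entropy transform e^H·raw/(1 + e^H·raw).  Background
cells serve as pseudo-absences for specificity and AUC because the data
contain no true absences.  Range overlap is Jaccard ×100 by default
(`smaller` = intersection over the smaller range is available).  PNO
profiles weight a 50-bin histogram of a variable by raw suitability and
renormalize to unit area; raw — not cumulative — output is used, with a
cumulative transform available.

## Tip-state coding

The majority/one-third rule: primary state = argmax locality count (ties
keep all tied states); any other state with ≥ ⅓ of the localities is added.
The packaged *Bulbophyllum* reference table ships both counts and the
published codes.  For a few species the published codes deviate from the
mechanical rule (e.g. a 31/0/43 species published as "C" although
31/74 ≥ ⅓); the published codes are applied as explicit overrides, and
`apply_coding` reports every disagreement rather than resolving it
silently.  Frequency accounting assigns each species 1/|coded states| to
each coded state, so masses always sum to the species count.

## Mk model and MCMC

The likelihood is Felsenstein pruning over 3 states with indicator partials
on each tip's coded subset (polymorphic tips are ambiguous observations,
not frequency-weighted) and per-node rescaling.  The transition matrix
inside the sampler is a scaling-and-squaring Taylor expansion specialized
to 3×3 generators (order 12 at scaled norm ≤ 0.5, truncation ≈ 5e-13),
tested against scipy's Padé expm and an eigendecomposition oracle; the
public `transition_matrix` uses scipy directly.

The sampler is Metropolis–Hastings with three uniformly chosen moves: a
single-rate perturbation (window `ratedev`; negative proposals rejected —
a simple detailed-balance-preserving choice), a hyperprior-mean
perturbation (window `mu_window`, constrained to (0, 30]), and a uniform
tree switch over the ensemble.  Each unconstrained rate has an
Exponential(mean μ) prior.  Defaults mirror the reference workflow
(5,050,000 generations, 50,000 burn-in, ratedev 250); thinning defaults to
1,000, giving 5,000 retained samples.  Rates are initialized from
Exponential(1) rather than from the diffuse hyperprior: the Mk likelihood
has a quasi-stationary ridge at implausibly high rates, and a chain seeded
there can take very long to find the mode.  The root prior is uniform.

Two empirical facts about this sampler shaped the defaults used in tests:
(i) all six rates are coupled through the shared hyperprior mean, so
prior-only marginals need heavy thinning (the prior-recovery check retains
every 1,600th generation) — the long-run marginals then match the
Exponential-mixture prior and μ is uniform; (ii) `ratedev` must match the
rate scale of the data — 250 suits rate magnitudes of real-data runs, while
the synthetic recovery experiments (rates of order 1/Ma) use a window of 2.

Marginal likelihoods use the harmonic-mean estimator (log-sum-exp
stabilized) for comparability with the classical Bayes-factor workflow,
with a block-bootstrap SE (1,000 resamples, block length √n); it is
high-variance and documented as such.  A stepping-stone estimator
(power-posterior chains at Beta-quantile-spaced temperatures, α = 0.3,
16 steps) is provided as the recommended lower-variance alternative, but
is never substituted where harmonic-mean comparability is the point.
The "reversible-jump hyperprior" phrasing of the reference workflow is
implemented as the exponential hyperprior with a resampled mean — the
mechanism that carries the model comparison; full reversible-jump
averaging over rate-class partitions is out of scope and listed as a known
limitation.  BF = 2·(logML_full −
logML_constrained), categories positive 2–6, strong 6–10, very strong >10.
The standard model set is the six single-rate-zero models plus the
no-reversal-out-of-C model (q_CA = q_CB = 0).

Ancestral states are marginal (two-pass conditional likelihoods) per
posterior sample, with nodes identified as the MRCA of their extant tip
set on each sampled tree (extra subsumed tips on discordant trees are
logged), then averaged and renormalized.  Transition counting compares
modal states along each edge of the chronogram; a transition's age is the
child node's age (0 on terminal edges, hence terminal transitions are
trivially Quaternary under the 2.6 Ma boundary), and only edges whose child
clade has posterior support > 0.95 are counted (terminal edges pass by
convention).  Polymorphic tips contribute their higher-count coded state as
the modal tip state.

## Phylogenetic signal

Blomberg's K uses the Brownian tip covariance V (root-to-MRCA path
lengths): K = (MSE₀/MSE)/E[MSE₀/MSE] with the GLS root estimate â.  On a
star tree K = 1 identically, which serves as an exact test oracle.
Significance is one-sided by default (signal ⇔ contrast variance low),
p = (1 + #{var_perm ≤ var_obs})/(n_perm + 1), with a two-sided option.  For
a fixed tree the standardized contrasts are a linear map of the trait
vector, so the 999 permutations run as one matrix product; polytomies are
resolved arbitrarily with zero-length edges.  Per-tree seeds derive from
the master seed plus the tree index, making ensemble runs reproducible and
order-independent.  Cluster-centroid PC traits deliberately tie species of
one niche to identical values; with phylogenetically clumped niche states
this drives the strong rejection pattern the PC1 trait shows.

## Synthetic data

The generator emulates a Madagascar-like region: a smooth central altitude
ridge, temperature following a lapse rate (altitude and annual mean
temperature anticorrelated by construction), rainfall increasing and
seasonality decreasing west→east, and all bioclim layers as fixed linear
maps of four latent fields plus smoothed seeded noise.  Three regimes (A
west lowland, B east lowland, C highland band) are separable by
construction (pairwise centroid distance ≫ 5× mean within-regime spread).
The default "paper-mimic" scenario has 33 species (30 ingroup + 3
outgroup-like) with log-normal per-species locality counts matched to the
reference moments (mean 18.84, SD 28.71, clipped to [1, 148]), niche
occupancies near 125/249/229, and a minority of two-niche species.  Trees
are pure-birth with Exponential(kλ) waiting times plus an Exponential(nλ)
tail before present (so no zero-length terminal branches) and are rescaled
to an exact root age; posterior-like ensembles jitter node ages of one base
topology, because independently simulated topologies are far more variable
than a Bayesian posterior sample and would miscalibrate ensemble summaries.
Characters evolve by exponential waiting times under arbitrary (including
absorbing) rate matrices.

What the synthetic data do **not** emulate: spatial autocorrelation beyond
smooth gradients, sampling bias in collections, georeferencing error,
coastline/topography realism, palaeoclimate layers, and topological
uncertainty between posterior trees.  Passing tests therefore demonstrate
algorithmic correctness and recoverability under clean conditions, not
robustness to the observational noise of herbarium data.

## Problem sizes in the test suite

The suite exercises the pipeline at deliberately reduced sizes chosen as
the smallest that still make each property decidable: 30–40-cell grids,
200-record sweeps with 25 FCM iterations per combination, 200-tip trees
with 5×10⁵-generation chains (20 replicates) for the Bayes-factor recovery
experiment, 8×10⁶-generation data-free chains thinned to 5,000 samples for
prior recovery, and 500 Brownian replicates for the K calibration.
Full-scale defaults (paper-scale generations, 100 bootstrap replicates,
999 permutations, 100 trees) remain the library defaults.
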