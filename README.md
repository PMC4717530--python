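# phyloniche

Phyloclimatic analysis of macroecological niche evolution in species-poor
tropical clades, built around the Madagascan *Bulbophyllum* "clade C"
study system (30 orchid species plus three outgroups, crown age ≈ 5.3 Ma).

The package answers a chained set of questions a niche-evolution study asks:

1. **Which macroecological niches exist?**  Occurrence records (species,
   coordinates, altitude + 19 bioclim layers in WorldClim v1.4 units) are
   fuzzy-clustered on Euclidean distances in environmental space.  Fuzzy
   C-means minimizes J = Σᵢₖ uᵢₖᵐ‖xᵢ−cₖ‖² with memberships uᵢₖ summing to 1
   per record; a sweep of K = 2..15 × m = 1.1..2.0 (140 combinations) is
   scored by seven cluster-validity indices (partition coefficient and
   entropy, Xie–Beni, Dunn, Fukuyama–Sugeno, fuzzy hypervolume, average
   partition density), and the consensus (K\*, m\*) is the combination most
   indices rank optimal or next-to-optimal.  Records are hard-assigned by
   maximum membership; clusters are interpreted as niches *A* (hot,
   rain-seasonal lowland), *B* (warm, wet, aseasonal lowland) and *C*
   (cold highland).
2. **What do the niches look like in space and climate?**  PCA of the raw
   environmental matrix with per-cluster PC centroids and Mann–Whitney U
   tests; per-niche presence–background maximum-entropy distribution
   models (linear + quadratic features, L1-penalized, background = all
   grid cells) evaluated by bootstrap AUC, thresholded by maximizing
   sensitivity + specificity, and summarized as binary range overlap and
   predicted-niche-occupancy (PNO) profiles — unit-area histograms of an
   environmental variable weighted by raw suitability.
3. **How did the niches evolve?**  Species are coded *A/B/C* (polymorphic
   when ≥ ⅓ of a species' localities fall in a second niche) and evolved
   along dated phylogenies under a 3-state continuous-time Markov (Mk)
   model.  An MCMC samples the six transition rates q_AB … q_CB under an
   exponential prior whose mean is itself sampled from Uniform(0, 30];
   marginal likelihoods (harmonic mean) of the unconstrained model versus
   models with rates pinned to zero give Bayes factors
   BF = 2·(log ML_full − log ML_constrained), read on the 2–6 / 6–10 / >10
   evidence scale.  Marginal ancestral states are averaged over the
   posterior and niche shifts are counted edge-by-edge on the chronogram
   (clade support filter > 0.95; Quaternary = ages ≤ 2.6 Ma).
4. **Is there phylogenetic signal in niche variables?**  Blomberg's K per
   trait (per-species medians of the 20 variables plus cluster-centroid
   PC1/PC2), with significance from 999 tip shuffles of the variance of
   phylogenetically independent contrasts, summarized over a 100-tree
   ensemble.

Because real occurrence coordinates for such studies are typically not
redistributable, a first-class synthetic module generates environmental
grids with the three regimes, occurrence clouds, pure-birth chronogram
ensembles and simulated discrete characters, so the entire pipeline is
testable end-to-end.  The per-species niche-state locality counts and
published state codes of the *Bulbophyllum* reference dataset are packaged
as a fixture.

## Worked example

Run the full pipeline on the synthetic "paper-mimic" scenario at demo
scale (the library defaults mirror a full-scale study — 5,050,000 MCMC
generations, 999 permutations — so a demo should shrink them via a config):

```bash
cat > run.yaml <<'YAML'
seed: 7
k_min: 2
k_max: 4
m_grid: [1.3, 2.0]
generations: 30000
burn_in: 3000
thin: 30
ratedev: 2.0
enm_replicates: 8
n_permutations: 99
signal_trees: 5
YAML
phyloniche run --config run.yaml --synthetic paper-mimic \
    --workdir demo --grid-size 30
```

Python equivalent (finishes in seconds):

```python
from phyloniche.core_io import AnalysisConfig
from phyloniche.pipeline import run_pipeline

cfg = AnalysisConfig(seed=7, k_min=2, k_max=4, m_grid=(1.3, 2.0),
                     generations=30_000, burn_in=3_000, thin=30,
                     ratedev=2.0, enm_replicates=8, n_permutations=99,
                     signal_trees=5)
run_pipeline(cfg, "demo", grid_size=30)
```

The run writes, among others, `sweep.json`, `state_frequencies.json` and
`signal.csv`.  With the configuration above the sweep reports

```
consensus: K = 3, m = 1.3
state_frequencies: {"A": 6.0, "B": 14.5, "C": 12.5}
```

— the validity indices recover the three generating regimes, and the
species-frequency masses (each species contributes 1/|coded states| per
coded state) sum to the 33 synthetic species.  `signal.csv` lists per-trait
median K (here ≈ 0.1, i.e. no phylogenetic signal, as expected when niches
are assigned independently of the tree), median permutation p and the
percentage of trees not rejecting the random-signal null.

The packaged reference coding reproduces the published accounting exactly:

```python
from phyloniche.coding import reference_codings, state_frequencies
freqs = state_frequencies(reference_codings()[0])
# {'A': 9.5, 'B': 11.5, 'C': 12.0}
```

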