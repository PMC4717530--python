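"""Synthetic study systems: environmental grids, occurrence clouds, dated trees
and simulated discrete characters.

The generator emulates the statistical structure of a Madagascar-like study
region with three macroecological regimes on one rectangular grid:

* a hot, rain-seasonal western lowland (niche **A**),
* a warm, wet, aseasonal eastern lowland (niche **B**),
* a cold high-elevation central band (niche **C**).

Altitude is a smooth central ridge; temperature follows a lapse rate
(so altitude and annual mean temperature are negatively correlated by
construction); rainfall amount increases west→east while rainfall/temperature
seasonality decrease west→east.  All 19 bioclim layers are deterministic
functions of these latent fields plus seeded noise, in WorldClim v1.4 units
(°C×10, mm).  The three default regime centroids are separable by
construction (pairwise centroid distance ≫ within-regime spread), which is
what the downstream clustering stage assumes of real data.

Trees are pure-birth (Yule) and rescaled to an exact root age; discrete
characters evolve by exponential waiting times under an arbitrary —
including absorbing — 3-state rate matrix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import STATES, DatedTree, EnvGrid, OccurrenceTable

RATE_ORDER = ("AB", "AC", "BA", "BC", "CA", "CB")


@dataclass
class NicheSpec:
    """One macroecological regime: a label, its environmental centroid and
    spread, and the rectangle of grid cells it occupies."""

    label: str
    centroid: np.ndarray
    spread: np.ndarray
    anchor: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        if np.any(self.spread <= 0):
            raise ValueError("spreads must be positive")

    def anchor_cells(self, grid: EnvGrid) -> np.ndarray:
        r0, r1, c0, c1 = self.anchor
        sub = np.zeros_like(grid.mask)
        sub[r0:r1, c0:c1] = True
        cells = np.argwhere(sub & grid.mask)
        if len(cells) == 0:
            raise ValueError(f"anchor of niche {self.label!r} contains no valid cells")
        return cells


@dataclass
class SimQ:
    """Six directed transition rates (events/Ma) and a root state or
    distribution for forward character simulation."""

    rates: dict = field(default_factory=dict)
    root: str | np.ndarray = "A"

    def __post_init__(self):
        for pair in RATE_ORDER:
            self.rates.setdefault(pair, 0.0)
            if self.rates[pair] < 0:
                raise ValueError(f"rate q_{pair} must be non-negative")

    def to_matrix(self) -> np.ndarray:
        """3×3 generator: off-diagonals = rates, diagonal = −row sum."""
        Q = np.zeros((3, 3))
        idx = {s: i for i, s in enumerate(STATES)}
        for pair in RATE_ORDER:
            Q[idx[pair[0]], idx[pair[1]]] = self.rates[pair]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def root_distribution(self) -> np.ndarray:
        if isinstance(self.root, str):
            p = np.zeros(3)
            p[STATES.index(self.root)] = 1.0
            return p
        p = np.asarray(self.root, dtype=float)
        return p / p.sum()


# ---------------------------------------------------------------------------
# Environmental grid
# ---------------------------------------------------------------------------

def _smooth_noise(rng, shape, passes=3, width=5):
    """White noise smoothed by repeated moving averages → bounded increments."""
    z = rng.standard_normal(shape)
    kernel = np.ones(width) / width
    for _ in range(passes):
        z = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, z)
        z = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, z)
    z /= max(z.std(), 1e-12)
    return z


def gen_env_grid(size: int, seed: int, cellsize: float = 0.05) -> EnvGrid:
    """Generate a ``size``×``size`` environmental grid (see module docstring).

    Deterministic for a fixed seed.  ``size`` must be at least 10.
    """
    if size < 10:
        raise ValueError("grid size must be >= 10")
    rng = np.random.default_rng(seed)
    grid = EnvGrid(np.zeros((size, size, 20)), np.ones((size, size), bool),
                   cellsize=cellsize)
    col = np.arange(size)
    x = np.broadcast_to(col / (size - 1), (size, size))          # 0 west → 1 east
    lat = np.array([[grid.cell_center(r, c)[1] for c in range(size)]
                    for r in range(size)])

    alt = 1500.0 * np.exp(-(((x - 0.5) / 0.16) ** 2)) + 120.0 * _smooth_noise(rng, (size, size))
    alt = np.clip(alt, 0.0, None)

    temp_c = 26.5 - 5.8 * alt / 1000.0 + 0.25 * (lat + 20.0) \
        + 0.3 * _smooth_noise(rng, (size, size))
    season = np.clip(1.05 - 1.1 * x + 0.08 * _smooth_noise(rng, (size, size)), 0.0, 1.2)
    precip = 850.0 + 1450.0 * x + 250.0 * alt / 1000.0 + 40.0 * _smooth_noise(rng, (size, size))

    v = {}
    v["alt"] = alt
    v["bio1"] = 10.0 * temp_c
    v["bio4"] = 100.0 * (0.8 + 2.6 * season)
    v["bio5"] = v["bio1"] + 25.0 + 0.25 * v["bio4"]
    v["bio6"] = v["bio1"] - 25.0 - 0.35 * v["bio4"]
    v["bio7"] = v["bio5"] - v["bio6"]
    v["bio2"] = (0.30 + 0.10 * season) * v["bio7"] \
        + 3.0 * _smooth_noise(rng, (size, size))
    v["bio3"] = np.clip(100.0 * v["bio2"] / v["bio7"], 20.0, 100.0)
    v["bio8"] = v["bio1"] + 0.02 * v["bio4"]
    v["bio9"] = v["bio1"] - 0.03 * v["bio4"]
    v["bio10"] = v["bio1"] + 0.045 * v["bio4"]
    v["bio11"] = v["bio1"] - 0.055 * v["bio4"]
    v["bio12"] = precip
    v["bio15"] = 25.0 + 75.0 * season
    v["bio13"] = v["bio12"] * (0.11 + 0.10 * season)
    v["bio14"] = v["bio12"] * np.maximum(0.075 - 0.07 * season, 0.002)
    v["bio16"] = 2.8 * v["bio13"]
    v["bio17"] = 3.1 * v["bio14"]
    v["bio18"] = 0.33 * v["bio12"] * (1.0 - 0.25 * season)
    v["bio19"] = 0.22 * v["bio12"] * (0.4 + 0.5 * season)

    for i, name in enumerate(grid.env_set.names):
        grid.values[:, :, i] = v[name]

    # a south-western "ocean" corner exercises mask handling downstream
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    grid.mask = ~((rr > 0.82 * size) & (cc < 0.15 * size))
    grid.values[~grid.mask] = 0.0
    return grid


def default_niche_specs(grid: EnvGrid) -> list[NicheSpec]:
    """The three regimes (A west lowland, B east lowland, C central highland)
    with centroids/spreads measured from the grid itself."""
    size = grid.height
    anchors = {
        "A": (0, int(0.80 * size), 0, int(0.25 * size)),
        "B": (0, size, int(0.78 * size), size),
        "C": (0, size, int(0.43 * size), int(0.57 * size)),
    }
    specs = []
    for label in STATES:
        r0, r1, c0, c1 = anchors[label]
        sub = np.zeros_like(grid.mask)
        sub[r0:r1, c0:c1] = True
        env = grid.values[sub & grid.mask]
        spread = env.std(axis=0)
        specs.append(NicheSpec(label, env.mean(axis=0),
                               np.where(spread > 0, spread, 1e-6), anchors[label]))
    return specs


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def gen_occurrences(grid: EnvGrid, specs: list[NicheSpec], species_plan: dict,
                    seed: int) -> tuple[OccurrenceTable, np.ndarray]:
    """Sample per-species occurrence records from niche anchors.

    ``species_plan`` maps species id → (label, count) or a list of such
    pairs for species occupying several niches.  Each record's environmental
    vector is the env of a grid cell sampled uniformly inside the niche's
    anchor; per-species counts are exactly as requested.

    Returns the occurrence table and the generating niche label per record
    (index-aligned), for recovery checks.
    """
    rng = np.random.default_rng(seed)
    by_label = {s.label: s for s in specs}
    rows, truth = [], []
    for species, plan in species_plan.items():
        if isinstance(plan, tuple):
            plan = [plan]
        for label, count in plan:
            if count < 1:
                raise ValueError(f"count for {species!r} in {label!r} must be >= 1")
            if label not in by_label:
                raise ValueError(f"unknown niche label {label!r}")
            cells = by_label[label].anchor_cells(grid)
            picks = cells[rng.integers(0, len(cells), size=count)]
            for r, c in picks:
                lon, lat = grid.cell_center(r, c)
                rows.append([species, lon, lat, *grid.values[r, c]])
                truth.append(label)
    df = pd.DataFrame(rows, columns=["species", "lon", "lat", *grid.env_set.names])
    return OccurrenceTable(df, grid.env_set), np.array(truth)


# lognormal matched to the observed per-species locality-count moments
_COUNT_MEAN, _COUNT_SD, _COUNT_CLIP = 18.84, 28.71, (1, 148)


def paper_mimic_plan(seed: int, n_ingroup: int = 30, n_outgroup: int = 3,
                     occupancy=(125, 249, 229)) -> dict:
    """A species plan shaped like the reference dataset: 33 species,
    log-normal per-species counts (mean 18.84, SD 28.71, clipped to [1, 148]),
    niche occupancies near 125/249/229, and a handful of two-niche species."""
    rng = np.random.default_rng(seed)
    sigma2 = np.log(1.0 + (_COUNT_SD / _COUNT_MEAN) ** 2)
    mu = np.log(_COUNT_MEAN) - sigma2 / 2.0
    n = n_ingroup + n_outgroup
    counts = np.clip(np.round(rng.lognormal(mu, np.sqrt(sigma2), size=n)),
                     *_COUNT_CLIP).astype(int)
    names = [f"sp{i + 1:02d}" for i in range(n_ingroup)] + \
            [f"out{i + 1}" for i in range(n_outgroup)]
    target = np.array(occupancy, dtype=float)
    target /= target.sum()
    filled = np.zeros(3)
    plan = {}
    order = np.argsort(-counts)
    for rank, i in enumerate(order):
        deficit = target - filled / max(filled.sum(), 1.0)
        k = int(np.argmax(deficit))
        label = STATES[k]
        if rank % 8 == 3 and counts[i] >= 6:     # a minority of two-niche species
            other = STATES[(k + 1) % 3]
            c2 = counts[i] // 3
            plan[names[i]] = [(label, int(counts[i] - c2)), (other, int(c2))]
            filled[k] += counts[i] - c2
            filled[STATES.index(other)] += c2
        else:
            plan[names[i]] = (label, int(counts[i]))
            filled[k] += counts[i]
    return {name: plan[name] for name in names}


def paper_mimic_dataset(seed: int, grid_size: int = 40) -> dict:
    """Full synthetic scenario: grid, niche specs, occurrences with generating
    labels, species plan and a dated tree over all species (root age 5.3 Ma)."""
    grid = gen_env_grid(grid_size, seed)
    specs = default_niche_specs(grid)
    plan = paper_mimic_plan(seed + 1)
    occ, truth = gen_occurrences(grid, specs, plan, seed + 2)
    tree = sim_tree(len(plan), root_age=5.3, seed=seed + 3, labels=list(plan))
    return {"grid": grid, "specs": specs, "plan": plan, "occurrences": occ,
            "true_labels": truth, "tree": tree, "seed": seed}


# ---------------------------------------------------------------------------
# Trees and characters
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, root_age: float, seed: int,
             labels: list[str] | None = None) -> DatedTree:
    """Pure-birth (Yule) tree rescaled so the root age equals ``root_age``
    exactly; internal-node support drawn Uniform(0.5, 1.0).

    Waiting times while k lineages exist are Exponential(k·λ), with one
    further Exponential(n·λ) interval before the present so every terminal
    branch has positive length.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if labels is not None and len(labels) != n_tips:
        raise ValueError("labels must have length n_tips")
    rng = np.random.default_rng(seed)
    pyrng = random.Random(seed)

    tree = dendropy.Tree()
    depth = 0.0
    birth_depth = {tree.seed_node: 0.0}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth_depth[child] = 0.0
        active.append(child)
    for k in range(2, n_tips):
        depth += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = depth - birth_depth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_depth[child] = depth
            active.append(child)
    depth += rng.exponential(1.0 / n_tips)          # tail to the present
    for node in active:
        node.edge.length = depth - birth_depth[node]

    scale = root_age / depth
    for edge in tree.edges():
        if edge.length is not None:
            edge.length *= scale
    tns = tree.taxon_namespace
    tip_labels = labels if labels is not None \
        else [f"t{i + 1}" for i in range(n_tips)]
    for leaf, lab in zip(tree.leaf_node_iter(), tip_labels):
        leaf.taxon = tns.new_taxon(label=lab)
    for node in tree.preorder_internal_node_iter():
        node.label = f"{pyrng.uniform(0.5, 1.0):.4f}"
    return DatedTree(tree)


def posterior_like_ensemble(base: DatedTree, n_trees: int, seed: int,
                            age_jitter: float = 0.1) -> list[DatedTree]:
    """An ensemble of trees emulating a Bayesian posterior sample: the base
    topology with each internal node age perturbed by a log-normal factor
    (sd ``age_jitter``), clipped below its parent's age, root age kept
    fixed.  Posterior tree samples of one data set are strongly correlated;
    independently simulated topologies are not a good stand-in for them."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        tree = dendropy.Tree(base.tree)   # deep clone
        tree.calc_node_ages(ultrametricity_precision=False)
        new_age = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                new_age[node] = 0.0
            elif node.parent_node is None:
                new_age[node] = float(node.age)
            else:
                jitter = float(node.age) * np.exp(age_jitter * rng.standard_normal())
                new_age[node] = min(jitter, 0.995 * new_age[node.parent_node])
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_age[node.parent_node] - new_age[node]
        out.append(DatedTree(tree))
    return out


def sim_discrete_character(tree: DatedTree, q: SimQ, seed: int) -> dict:
    """Simulate a 3-state character down the tree by exponential waiting
    times; returns tip label → state letter."""
    rng = np.random.default_rng(seed)
    Q = q.to_matrix()
    root_state = int(rng.choice(3, p=q.root_distribution()))
    states = {tree.tree.seed_node: root_state}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        s = states[node.parent_node]
        t_left = node.edge.length or 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0.0:
                break                     # absorbing state
            wait = rng.exponential(1.0 / rate)
            if wait >= t_left:
                break
            t_left -= wait
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(3, p=probs / probs.sum()))
        states[node] = s
    return {lf.taxon.label: STATES[states[lf]] for lf in tree.tree.leaf_node_iter()}
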