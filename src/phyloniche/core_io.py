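"""Domain types and plain-text I/O.

The package moves four kinds of data between stages:

* occurrence tables — one row per georeferenced locality with a species id,
  coordinates (decimal degrees, WGS84 assumed) and 20 environmental values
  (altitude in m plus the 19 bioclim layers in WorldClim v1.4 units:
  temperatures in °C×10, precipitation in mm).  Units are metadata only;
  no conversion is ever applied — analyses run on raw layer values.
* environmental grids — rectangular rasters holding the same 20 variables,
  row-major and 0-based with the origin at the north-west corner, stored as
  a stacked ASCII-grid text format (one block per variable).
* dated trees — rooted ultrametric phylogenies with branch lengths in Ma
  and optional clade posterior probabilities, read from Newick or Nexus.
* analysis configuration — every tunable of the pipeline in one record.

Distances downstream are always environmental, never geographic, so no
projection handling exists anywhere in the package.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, fields

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phyloniche")

STATES = ("A", "B", "C")


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable cell."""


class FormatError(ValueError):
    """A grid or tree file does not match its declared layout."""


class EnsembleError(ValueError):
    """Trees in an ensemble do not share one tip set."""


# ---------------------------------------------------------------------------
# Environmental variable registry
# ---------------------------------------------------------------------------

ENV_NAMES: tuple[str, ...] = ("alt",) + tuple(f"bio{i}" for i in range(1, 20))

_UNITS = {"alt": "m"}
_UNITS.update({f"bio{i}": "degC x10" for i in (1, 2, 5, 6, 7, 8, 9, 10, 11)})
_UNITS["bio3"] = "index"       # isothermality
_UNITS["bio4"] = "sd x100"     # temperature seasonality
_UNITS.update({f"bio{i}": "mm" for i in (12, 13, 14, 16, 17, 18, 19)})
_UNITS["bio15"] = "cv"         # precipitation seasonality


@dataclass(frozen=True)
class EnvVariableSet:
    """Ordered registry of the 20 environmental variables and their units."""

    names: tuple[str, ...] = ENV_NAMES
    units: dict = field(default_factory=lambda: dict(_UNITS))

    def __post_init__(self):
        if len(self.names) != 20:
            raise ValueError(f"expected exactly 20 variable names, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")


DEFAULT_ENV_SET = EnvVariableSet()


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

class OccurrenceTable:
    """Per-record species id, lon/lat and 20 environmental values.

    Thin wrapper around a :class:`pandas.DataFrame` with a validated schema:
    columns ``species, lon, lat`` followed by the 20 variable names of the
    attached :class:`EnvVariableSet`, no missing values, at least one record
    per species.
    """

    COLUMNS = ("species", "lon", "lat")

    def __init__(self, df: pd.DataFrame, env_set: EnvVariableSet = DEFAULT_ENV_SET):
        self.env_set = env_set
        required = list(self.COLUMNS) + list(env_set.names)
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"missing column {col!r}")
        df = df[required].reset_index(drop=True)
        if (df["species"].astype(str).str.len() == 0).any():
            raise SchemaError("empty species id")
        num = df[list(("lon", "lat") + env_set.names)]
        if num.isna().any().any():
            row = int(num.isna().any(axis=1).idxmax())
            raise SchemaError(f"missing value in row {row}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, OccurrenceTable) and self.df.equals(other.df)

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.df["species"]))

    def env_matrix(self) -> np.ndarray:
        """The n×20 matrix of raw environmental values, in registry order."""
        return self.df[list(self.env_set.names)].to_numpy(dtype=float)

    def per_species_counts(self) -> pd.Series:
        return self.df["species"].value_counts()

    def subset(self, index) -> "OccurrenceTable":
        return OccurrenceTable(self.df.iloc[index].reset_index(drop=True), self.env_set)


def read_occurrences(path, env_set: EnvVariableSet = DEFAULT_ENV_SET) -> OccurrenceTable:
    """Read an occurrence CSV (comma-delimited, UTF-8, header required).

    Raises :class:`SchemaError` naming the column if one is missing, or the
    row number if a numeric cell fails to parse.
    """
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    for col in list(OccurrenceTable.COLUMNS) + list(env_set.names):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}")
    for col in ("lon", "lat") + env_set.names:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"non-numeric value in column {col!r}, row {row}")
        df[col] = coerced
    return OccurrenceTable(df, env_set)


def write_occurrences(table: OccurrenceTable, path) -> None:
    # %.17g keeps the write∘read round trip lossless for float64
    table.df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Environmental grids
# ---------------------------------------------------------------------------

NODATA = -9999.0


@dataclass
class EnvGrid:
    """A 20-layer environmental raster on a rectangular grid.

    ``values`` has shape (height, width, 20); ``mask`` is True on valid
    (land) cells.  Indexing is row-major and 0-based with row 0 at the
    north-west corner.  ``cellsize`` is in decimal degrees.
    """

    values: np.ndarray
    mask: np.ndarray
    cellsize: float = 0.05
    xll: float = 44.0
    yll: float = -25.0
    env_set: EnvVariableSet = field(default_factory=lambda: DEFAULT_ENV_SET)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape[2] != 20:
            raise ValueError("values must have shape (height, width, 20)")
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must match grid shape")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def masked_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of valid cells, row-major order."""
        return np.argwhere(self.mask)

    def masked_env(self) -> np.ndarray:
        """(k, 20) environmental matrix over valid cells, row-major order."""
        return self.values[self.mask]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center — the single cell↔coordinate conversion."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.height - row - 0.5) * self.cellsize
        return lon, lat

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EnvGrid)
            and self.values.shape == other.values.shape
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(self.values[self.mask], other.values[other.mask])
            and math.isclose(self.cellsize, other.cellsize)
            and math.isclose(self.xll, other.xll)
            and math.isclose(self.yll, other.yll)
        )


def write_grid(grid: EnvGrid, path) -> None:
    """Write a grid as stacked ASCII-grid blocks, one per variable."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.width}\n")
        fh.write(f"nrows {grid.height}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for v, name in enumerate(grid.env_set.names):
            fh.write(f"VARIABLE {name}\n")
            layer = np.where(grid.mask, grid.values[:, :, v], NODATA)
            buf = io.StringIO()
            np.savetxt(buf, layer, fmt="%.17g")
            fh.write(buf.getvalue())


def read_grid(path, env_set: EnvVariableSet = DEFAULT_ENV_SET) -> EnvGrid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = {}
    pos = 0
    try:
        for _ in range(6):
            key, val = lines[pos].split()
            header[key.lower()] = val
            pos += 1
        width = int(header["ncols"])
        height = int(header["nrows"])
    except (ValueError, KeyError, IndexError) as exc:
        raise FormatError(f"corrupted grid header: {exc}") from exc
    values = np.empty((height, width, 20))
    for v, name in enumerate(env_set.names):
        if pos >= len(lines) or not lines[pos].startswith("VARIABLE"):
            raise FormatError(f"expected 'VARIABLE {name}' block at line {pos + 1}")
        declared = lines[pos].split(None, 1)[1]
        if declared != name:
            raise FormatError(f"expected variable {name!r}, found {declared!r}")
        pos += 1
        block = lines[pos : pos + height]
        if len(block) < height:
            raise FormatError(f"truncated block for {name!r}")
        try:
            layer = np.loadtxt(io.StringIO("\n".join(block)), ndmin=2)
        except ValueError as exc:
            raise FormatError(f"unparseable block for {name!r}: {exc}") from exc
        if layer.shape != (height, width):
            raise FormatError(
                f"dimension mismatch for {name!r}: got {layer.shape}, "
                f"expected {(height, width)}"
            )
        values[:, :, v] = layer
        pos += height
    nodata = float(header["nodata_value"])
    mask = ~np.any(values == nodata, axis=2)
    values[~mask] = 0.0
    return EnvGrid(
        values,
        mask,
        cellsize=float(header["cellsize"]),
        xll=float(header["xllcorner"]),
        yll=float(header["yllcorner"]),
        env_set=env_set,
    )


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------

ULTRAMETRIC_TOL = 1e-6


class DatedTree:
    """A rooted, ultrametric, binary phylogeny with branch lengths in Ma.

    Wraps a :class:`dendropy.Tree`.  Node ages are measured back from the
    tips (0 at tips, ``root_age`` at the root).  Internal nodes may carry a
    clade posterior probability in [0, 1] parsed from node labels or
    ``posterior`` annotations.
    """

    def __init__(self, tree: dendropy.Tree, strict: bool = False,
                 renormalize: bool = True):
        self.tree = tree
        self.tree.is_rooted = True
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("unlabeled tip in tree")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate tip labels")
        if renormalize:
            self._normalize_ultrametric(strict)
        self.tree.calc_node_ages(ultrametricity_precision=False)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, strict: bool = False,
                    renormalize: bool = True) -> "DatedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, strict=strict, renormalize=renormalize)

    def _normalize_ultrametric(self, strict: bool) -> None:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = depths.get(node.parent_node, 0.0)
            depths[node] = parent_depth + (node.edge.length or 0.0)
        tip_depths = [depths[lf] for lf in self.tree.leaf_node_iter()]
        max_depth = max(tip_depths)
        if max_depth - min(tip_depths) > ULTRAMETRIC_TOL:
            if strict:
                raise FormatError(
                    f"tree is not ultrametric (tip depth spread "
                    f"{max_depth - min(tip_depths):g} Ma)"
                )
            logger.warning(
                "tree not ultrametric (spread %g Ma); re-normalizing by tip extension",
                max_depth - min(tip_depths),
            )
            for leaf in self.tree.leaf_node_iter():
                leaf.edge.length = (leaf.edge.length or 0.0) + (max_depth - depths[leaf])

    # -- accessors ------------------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return float(self.tree.seed_node.age)

    def node_support(self, node) -> float | None:
        """Clade posterior probability for an internal node, if present."""
        for source in (node.label, getattr(node, "posterior", None)):
            if source is not None:
                try:
                    return float(source)
                except (TypeError, ValueError):
                    pass
        anns = node.annotations.get_value("posterior")
        if anns is not None:
            try:
                return float(anns)
            except (TypeError, ValueError):
                pass
        return None

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def total_branch_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.edges())

    # -- array form for likelihood kernels ------------------------------------

    def to_arrays(self, tip_order: list[str] | None = None):
        """Flatten the tree for the pruning kernels.

        Returns ``(n_tips, left, right, blen, postorder, tip_index)`` where
        nodes 0..n_tips-1 are the tips in ``tip_order`` (default: tree order),
        internal nodes follow in post-order, ``left``/``right`` give children
        of internal nodes (-1 for tips), ``blen[i]`` is the branch length above
        node i (0 for the root) and ``postorder`` lists internal node indices
        ending with the root.  The tree must be binary.
        """
        tips = list(self.tree.leaf_node_iter())
        if tip_order is None:
            tip_order = [t.taxon.label for t in tips]
        label_to_slot = {lab: i for i, lab in enumerate(tip_order)}
        if set(label_to_slot) != {t.taxon.label for t in tips}:
            raise ValueError("tip_order does not match the tree's tip set")
        n_tips = len(tips)
        index = {}
        for tip in tips:
            index[tip] = label_to_slot[tip.taxon.label]
        internals = [nd for nd in self.tree.postorder_node_iter() if not nd.is_leaf()]
        n_nodes = n_tips + len(internals)
        left = np.full(n_nodes, -1, dtype=np.int64)
        right = np.full(n_nodes, -1, dtype=np.int64)
        blen = np.zeros(n_nodes)
        for k, nd in enumerate(internals):
            index[nd] = n_tips + k
        for nd in self.tree.postorder_node_iter():
            i = index[nd]
            if nd.edge.length is not None:
                blen[i] = nd.edge.length
            if not nd.is_leaf():
                children = nd.child_nodes()
                if len(children) != 2:
                    raise ValueError("likelihood kernels require a binary tree")
                left[i], right[i] = index[children[0]], index[children[1]]
        postorder = np.array([index[nd] for nd in internals], dtype=np.int64)
        return n_tips, left, right, blen, postorder, index


class TreeEnsemble:
    """A list of :class:`DatedTree` over one shared tip set."""

    def __init__(self, trees: list[DatedTree]):
        if not trees:
            raise EnsembleError("ensemble must contain at least one tree")
        ref = set(trees[0].tip_labels)
        for i, t in enumerate(trees[1:], start=1):
            tips = set(t.tip_labels)
            if tips != ref:
                diff = sorted(tips.symmetric_difference(ref))
                raise EnsembleError(f"tree {i} tip set differs: {diff}")
        self.trees = trees

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i) -> DatedTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def read_trees(path, strict: bool = False) -> TreeEnsemble:
    """Read one or more trees from a Newick or Nexus file.

    Trees deviating from ultrametricity by more than 1e-6 Ma are
    re-normalized by tip extension with a logged warning (or rejected when
    ``strict``); trees with differing tip sets raise :class:`EnsembleError`.
    """
    text = open(path).read()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(data=text, schema=schema)
    if len(trees) == 0:
        raise FormatError(f"no trees found in {path}")
    return TreeEnsemble([DatedTree(t, strict=strict) for t in trees])


def write_trees(ensemble: TreeEnsemble, path) -> None:
    with open(path, "w") as fh:
        for t in ensemble:
            fh.write(t.as_newick() + "\n")


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with defaults mirroring the study design."""

    seed: int = 0
    # clustering sweep
    k_min: int = 2
    k_max: int = 15
    m_grid: tuple = tuple(round(1.1 + 0.1 * i, 1) for i in range(10))
    fcm_max_iter: int = 200
    fcm_tol: float = 1e-9
    standardize: bool = False
    # MCMC
    generations: int = 5_050_000
    burn_in: int = 50_000
    thin: int = 1_000
    ratedev: float = 250.0
    mu_window: float = 5.0
    hyperprior_upper: float = 30.0
    # ENM
    enm_replicates: int = 100
    train_fraction: float = 0.7
    regularization: float = 1.0
    pno_bins: int = 50
    # transition counting / binning
    pp_filter: float = 0.95
    quaternary_boundary_ma: float = 2.6
    # phylogenetic signal
    n_permutations: int = 999
    signal_trees: int = 100

    def __post_init__(self):
        for name in ("k_min", "k_max", "fcm_max_iter", "generations", "burn_in",
                     "thin", "enm_replicates", "pno_bins", "n_permutations",
                     "signal_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.quaternary_boundary_ma <= 0:
            raise ValueError("quaternary_boundary_ma must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "m_grid" in raw:
            raw["m_grid"] = tuple(raw["m_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["m_grid"] = list(self.m_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
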