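"""Synthetic phyloclimatic datasets.

Generates everything the pipeline consumes, with known ground truth:

* spatially autocorrelated climate layers (Gaussian random fields rescaled to
  bioclim-like ranges),
* a Yule ultrametric tree with labeled monophyletic clades,
* species climatic optima evolving by Brownian motion along the tree,
* a Gaussian-response suitability surface per species, and
* occurrence points sampled proportional to suitability, spatially unique at
  cell resolution.

The defaults emulate the study system scale: 29 taxa in 4 clades, 19 climate
layers at 0.0417-degree resolution, at least 10 occurrence points per species.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .occurrences import OccurrenceSet, write_occurrences
from .phylo import CladeMap, Phylogeny, write_newick
from .rasters import GridSpec, Raster, RasterStack, write_ascii_grid
from .surfaces import SuitabilitySurface

__all__ = [
    "SimulationConfig",
    "NicheSpec",
    "simulate_yule_tree",
    "simulate_climate_layers",
    "evolve_niche_optima",
    "suitability_from_niche",
    "sample_occurrences",
    "assign_clades",
    "make_dataset",
]

# Plausible (low, high) ranges per layer in WorldClim units (temperatures in
# 0.1 degC, precipitation in mm); cycled if more layers are requested.
BIOCLIM_RANGES: tuple[tuple[float, float], ...] = (
    (-30.0, 290.0),   # bio01 annual mean temperature
    (40.0, 180.0),    # bio02 mean diurnal range
    (10.0, 95.0),     # bio03 isothermality
    (50.0, 1100.0),   # bio04 temperature seasonality
    (100.0, 420.0),   # bio05 max temp of warmest month
    (-150.0, 250.0),  # bio06 min temp of coldest month
    (90.0, 420.0),    # bio07 temperature annual range
    (-50.0, 300.0),   # bio08 mean temp of wettest quarter
    (-60.0, 300.0),   # bio09 mean temp of driest quarter
    (0.0, 320.0),     # bio10 mean temp of warmest quarter
    (-120.0, 260.0),  # bio11 mean temp of coldest quarter
    (100.0, 6000.0),  # bio12 annual precipitation
    (20.0, 1200.0),   # bio13 precipitation of wettest month
    (0.0, 200.0),     # bio14 precipitation of driest month
    (10.0, 150.0),    # bio15 precipitation seasonality
    (50.0, 3000.0),   # bio16 precipitation of wettest quarter
    (0.0, 600.0),     # bio17 precipitation of driest quarter
    (20.0, 2500.0),   # bio18 precipitation of warmest quarter
    (0.0, 1500.0),    # bio19 precipitation of coldest quarter
)

DEFAULT_CLADE_NAMES = ("ruficollis", "schisticeps", "ferruginosus", "hypoleucos")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system.

    ``bm_sd_frac`` sets the Brownian rate per variable so that the standard
    deviation accrued over the whole tree height is that fraction of the
    variable's range width; ``tau_frac`` sets each species' tolerance width
    as a fraction of the range width. Together they fix the ratio of
    within-species niche breadth to among-species climatic spread.
    """

    n_taxa: int = 29
    n_clades: int = 4
    n_layers: int = 19
    n_rows: int = 60
    n_cols: int = 80
    cell_size: float = 0.0417
    x_ll: float = 92.0
    y_ll: float = 20.0
    nodata: float = -9999.0
    autocorr_length: float = 6.0  # cells
    birth_rate: float = 1.0  # per lineage per Myr (before rescaling)
    tree_height: float = 10.0  # Myr
    bm_sd_frac: float = 0.12
    tau_frac: float = 0.25
    points_per_species: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_taxa",
            "n_clades",
            "n_layers",
            "n_rows",
            "n_cols",
            "cell_size",
            "autocorr_length",
            "birth_rate",
            "tree_height",
            "bm_sd_frac",
            "tau_frac",
            "points_per_species",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.points_per_species < 10:
            raise ValueError("points_per_species must be at least 10")
        if self.n_clades > self.n_taxa:
            raise ValueError("cannot have more clades than taxa")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            x_ll=self.x_ll,
            y_ll=self.y_ll,
            nodata=self.nodata,
        )

    @property
    def layer_names(self) -> list[str]:
        return [f"bio{i + 1:02d}" for i in range(self.n_layers)]

    def layer_range(self, index: int) -> tuple[float, float]:
        return BIOCLIM_RANGES[index % len(BIOCLIM_RANGES)]

    def sigma2(self, index: int) -> float:
        """BM rate for layer ``index`` (variable units^2 per Myr)."""
        lo, hi = self.layer_range(index)
        return (self.bm_sd_frac * (hi - lo)) ** 2 / self.tree_height

    def tau(self, index: int) -> float:
        lo, hi = self.layer_range(index)
        return self.tau_frac * (hi - lo)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


@dataclass
class NicheSpec:
    """One species' Gaussian climatic response: optimum and tolerance width
    per climate variable (variable units)."""

    species: str
    variables: tuple[str, ...]
    mu: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if not (self.mu.size == self.tau.size == len(self.variables)):
            raise ValueError("mu/tau/variables length mismatch")
        if (self.tau <= 0).any():
            raise ValueError("tolerance widths must be positive")


# -- tree -------------------------------------------------------------------

def _yule_split_times(n_taxa: int, birth_rate: float, rng: np.random.Generator):
    """Split times of a crown Yule process run until ``n_taxa`` lineages,
    plus the present time (one extra exponential wait after the last split)."""
    times = [0.0]
    t = 0.0
    for k in range(2, n_taxa):
        t += rng.exponential(1.0 / (birth_rate * k))
        times.append(t)
    present = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    return np.array(times), present


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    height: float | None = 1.0,
    labels: list[str] | None = None,
) -> Phylogeny:
    """Simulate an ultrametric pure-birth (Yule) tree.

    Lineages split at rate ``birth_rate`` starting from the crown (2 lineages
    at the root); the process stops when ``n_taxa`` lineages exist and the
    present is one further exponential wait later. ``height=None`` keeps the
    simulated time scale; otherwise the tree is rescaled to that height.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    split_times, present = _yule_split_times(n_taxa, birth_rate, rng)
    if labels is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length mismatch")

    # grow node records: (parent, height); tips filled at the end
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=int)
    node_height = np.zeros(n_nodes)
    next_internal = n_taxa  # internal ids n_taxa .. n_nodes-1, root assigned last
    # assign internal ids so that the root is last: create splits in reverse
    internal_ids = list(range(n_nodes - 1, n_taxa - 1, -1))
    root_id = internal_ids[0]
    node_height[root_id] = 0.0
    active = [root_id, root_id]  # two crown lineages, recorded by their parent id
    # 'active' holds, per open lineage, the id of the node the lineage hangs from
    next_id = 1
    for k in range(1, n_taxa - 1):
        new_node = internal_ids[k]
        j = int(rng.integers(len(active)))
        parent[new_node] = active[j]
        node_height[new_node] = split_times[k]
        active[j] = new_node
        active.append(new_node)
    order = rng.permutation(n_taxa)
    for tip_slot, j in enumerate(order):
        tip = int(j)
        parent[tip] = active[tip_slot]
        node_height[tip] = present
    blen = np.zeros(n_nodes)
    for i in range(n_nodes):
        if parent[i] >= 0:
            blen[i] = node_height[i] - node_height[parent[i]]
    tree = Phylogeny.from_arrays(labels, parent, blen)
    if height is not None:
        tree = tree.rescale(height)
    return tree


def assign_clades(
    tree: Phylogeny, n_clades: int, names: tuple[str, ...] | None = None
) -> CladeMap:
    """Partition the tips into the ``n_clades`` oldest subtrees.

    The tree is cut just below its n_clades-1 oldest internal nodes; the
    resulting subtrees are monophyletic by construction. Clades are named
    after the four study clades when ``n_clades == 4``.
    """
    if names is None:
        names = (
            DEFAULT_CLADE_NAMES
            if n_clades == 4
            else tuple(f"clade{i + 1:02d}" for i in range(n_clades))
        )
    if len(names) != n_clades:
        raise ValueError("clade names length mismatch")
    open_nodes = [tree.root]
    while len(open_nodes) < n_clades:
        splittable = [i for i in open_nodes if tree.children[i]]
        if not splittable:
            raise ValueError("not enough tips to form the requested clades")
        oldest = min(splittable, key=lambda i: (tree.heights[i], i))
        open_nodes.remove(oldest)
        open_nodes.extend(tree.children[oldest])
    # stable clade order: by subtree's smallest tip index
    open_nodes.sort(key=lambda i: int(tree.tips_below(i)[0]))
    assignments: dict[str, str] = {}
    for name, node in zip(names, open_nodes):
        for t in tree.tips_below(node):
            assignments[tree.tip_labels[t]] = name
    cmap = CladeMap({lab: assignments[lab] for lab in tree.tip_labels})
    cmap.validate(tree)
    return cmap


# -- climate layers ---------------------------------------------------------

def gaussian_random_field(
    n_rows: int,
    n_cols: int,
    autocorr_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean, unit-variance field with isotropic Gaussian autocorrelation.

    White noise is smoothed with a Gaussian kernel of scale
    ``autocorr_length`` cells (reflective boundaries) and restandardized.
    """
    noise = rng.standard_normal((n_rows, n_cols))
    field = ndimage.gaussian_filter(noise, sigma=autocorr_length, mode="reflect")
    field -= field.mean()
    sd = field.std()
    if sd == 0:
        raise ValueError("degenerate field (grid too small for the kernel)")
    return field / sd


def simulate_climate_layers(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> RasterStack:
    """Simulate the climate layer stack.

    Each layer is an independent Gaussian random field affinely rescaled to
    its bioclim-like range: mean at the range midpoint, standard deviation a
    sixth of the range width (so +/-3 sd spans the range).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    spec = config.grid_spec
    layers = []
    for i, name in enumerate(config.layer_names):
        lo, hi = config.layer_range(i)
        field = gaussian_random_field(
            config.n_rows, config.n_cols, config.autocorr_length, rng
        )
        values = 0.5 * (lo + hi) + field * (hi - lo) / 6.0
        layers.append(Raster(spec, values, name=name))
    return RasterStack(layers)


# -- niches -----------------------------------------------------------------

def evolve_niche_optima(
    tree: Phylogeny,
    n_vars: int,
    sigma2: float | np.ndarray,
    root_state: float | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Brownian-motion tip optima: (n_tips, n_vars) array.

    Each variable evolves independently; along a branch of length t the
    change is Normal(0, sigma2 * t).
    """
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (n_vars,))
    if (sigma2 < 0).any():
        raise ValueError("sigma2 must be nonnegative")
    root_state = np.broadcast_to(np.asarray(root_state, dtype=float), (n_vars,))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.zeros((tree.n_nodes, n_vars))
    values[tree.root] = root_state
    for i in tree.preorder():
        if i == tree.root:
            continue
        t = tree.branch_lengths[i]
        values[i] = values[tree.parent[i]] + rng.standard_normal(n_vars) * np.sqrt(
            sigma2 * t
        )
    return values[: tree.n_tips]


def suitability_from_niche(
    niche: NicheSpec, raster_stack: RasterStack
) -> SuitabilitySurface:
    """Gaussian-response truth surface: cell weight proportional to
    prod_v exp(-(x_v - mu_v)^2 / (2 tau_v^2)) over valid cells, unit mass."""
    mask = raster_stack.valid_mask
    if not mask.any():
        raise ValueError("no valid cells in the stack")
    log_w = np.zeros(mask.shape)
    for v, name in enumerate(niche.variables):
        x = raster_stack[name].values
        log_w = log_w - (x - niche.mu[v]) ** 2 / (2.0 * niche.tau[v] ** 2)
    log_w = np.where(mask, log_w, -np.inf)
    log_w -= log_w[mask].max()
    raw = np.where(mask, np.exp(log_w), 0.0)
    return SuitabilitySurface.from_unnormalized(
        raster_stack.spec, raw, mask, species=niche.species
    )


def sample_occurrences(
    surface: SuitabilitySurface,
    n_points: int,
    seed: int | np.random.Generator = 0,
) -> OccurrenceSet:
    """Sample occurrence cells proportional to suitability, without
    replacement across cells; points are placed at cell centers.

    Successive draws renormalize over the remaining cells (implemented by
    Gumbel top-k perturbation), so each draw's marginal follows the current
    weights and the result is spatially unique by construction.
    """
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = surface.weights.ravel()
    positive = np.flatnonzero(flat > 0)
    if n_points > positive.size:
        raise ValueError(
            f"requested {n_points} points but only {positive.size} cells have "
            "positive suitability"
        )
    gumbel = rng.gumbel(size=positive.size)
    keys = np.log(flat[positive]) + gumbel
    chosen = positive[np.argsort(keys)[::-1][:n_points]]
    rows, cols = np.unravel_index(chosen, surface.weights.shape)
    pts = [surface.spec.cell_center(int(r), int(c)) for r, c in zip(rows, cols)]
    return OccurrenceSet(surface.species or "species", pts)


# -- orchestration ----------------------------------------------------------

def make_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete dataset on disk and return the paths written.

    Writes the climate layers (.asc), the tree (newick), spatially unique
    occurrences (CSV), clade membership (CSV) and a ground-truth JSON with
    the generating optima, tolerances, BM rates and root states. Rerunning
    with the same config is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    tree_ss, layers_ss, optima_ss, occ_ss = master.spawn(4)

    tree = simulate_yule_tree(
        config.n_taxa,
        config.birth_rate,
        np.random.default_rng(tree_ss),
        height=config.tree_height,
    )
    clades = assign_clades(tree, config.n_clades)
    stack = simulate_climate_layers(config, np.random.default_rng(layers_ss))
    sigma2 = np.array([config.sigma2(i) for i in range(config.n_layers)])
    tau = np.array([config.tau(i) for i in range(config.n_layers)])
    root_state = np.array(
        [0.5 * sum(config.layer_range(i)) for i in range(config.n_layers)]
    )
    optima = evolve_niche_optima(
        tree, config.n_layers, sigma2, root_state, np.random.default_rng(optima_ss)
    )

    occ_rngs = [np.random.default_rng(s) for s in occ_ss.spawn(config.n_taxa)]
    occ_sets = []
    for s, species in enumerate(tree.tip_labels):
        niche = NicheSpec(
            species, tuple(config.layer_names), optima[s], tau
        )
        surface = suitability_from_niche(niche, stack)
        occ_sets.append(
            sample_occurrences(surface, config.points_per_species, occ_rngs[s])
        )

    paths: dict[str, Path] = {}
    for layer in stack:
        p = out_dir / f"{layer.name}.asc"
        write_ascii_grid(layer, p)
        paths[layer.name] = p
    paths["tree"] = out_dir / "tree.nwk"
    write_newick(tree, paths["tree"])
    paths["occurrences"] = out_dir / "occurrences.csv"
    write_occurrences(occ_sets, paths["occurrences"])
    paths["clades"] = out_dir / "clades.csv"
    clades.write_csv(paths["clades"])
    truth = {
        "seed": config.seed,
        "species": list(tree.tip_labels),
        "variables": config.layer_names,
        "tree_height": config.tree_height,
        "ranges": [list(config.layer_range(i)) for i in range(config.n_layers)],
        "sigma2": sigma2.tolist(),
        "tau": tau.tolist(),
        "root_state": root_state.tolist(),
        "optima": optima.tolist(),
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    paths["config"] = out_dir / "config.yaml"
    config.to_yaml(paths["config"])
    return paths
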