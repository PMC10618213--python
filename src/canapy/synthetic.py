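"""Synthetic scenarios: phylogeny, ranges, environment, protection.

The generator emulates the statistical structure the pipeline is built to
detect, with no downloads:

* a birth-death phylogeny carrying both deep long branches and recent
  radiations. Planted endemic lineages are grafted onto the base tree so
  the planted contrast is explicit: paleo lineages are single tips
  attached near the root (long isolated pendant branches), neo lineages
  are compact recent radiations (short stem, short crown branches);
* spatially cohesive ranges grown by a spreading-dye process (rook
  adjacency) from clade-clustered seed cells, with a heavy-tailed
  (lognormal) range-size distribution for background species. Planted
  lineages are range-restricted to small refugium blocks of the grid;
* Gaussian-random-field environmental surfaces with a configurable
  autocorrelation length, where planted hotspot cells receive stated mean
  offsets (higher MAT/AP/elevation range, paleoclimate anomalies pulled
  toward zero, higher human modification and future anomalies);
* an existing-protected-area mask at a stated coverage fraction plus a
  priority ranking correlated with the planted diversity, from which
  nested top-k% masks are cut.

All randomness derives from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.ndimage import gaussian_filter

from .grid import GridCell, OccurrenceGrid, build_grid
from .protection import ProtectionScheme, priority_mask

__all__ = [
    "RefugiumBlock",
    "ScenarioSpec",
    "Scenario",
    "simulate_phylogeny",
    "build_scenario_tree",
    "simulate_ranges",
    "simulate_env_layers",
    "simulate_protection",
    "generate_scenario",
    "gaussian_random_field",
    "empirical_correlation_length",
    "ENV_LAYER_OFFSETS",
]

# Default hotspot-minus-background mean offsets, in units of each layer's
# spatial standard deviation. Signs mirror the contrasts the pipeline is
# meant to detect: hotspots are warmer, wetter, more rugged, closer to
# zero paleoclimate anomaly, more human-modified and face larger future
# anomalies.
ENV_LAYER_OFFSETS: dict[str, float] = {
    "MAT": 1.0,
    "AP": 1.0,
    "elev_range": 1.0,
    "LGM_MAT_anom": 0.8,
    "LGM_AP_anom": 0.8,
    "Miocene_MAT_anom": -0.8,
    "Miocene_AP_anom": -0.8,
    "HMI": 0.75,
    "future_MAT_anom": 0.75,
    "future_AP_anom": 0.75,
}

# Base (mean, sd) on natural layer scales; anomaly bases are signed so the
# positive/negative offsets above pull them toward zero.
_LAYER_BASE: dict[str, tuple[float, float]] = {
    "MAT": (18.0, 6.0),
    "AP": (1200.0, 500.0),
    "elev_range": (600.0, 400.0),
    "LGM_MAT_anom": (-5.0, 2.0),
    "LGM_AP_anom": (-150.0, 80.0),
    "Miocene_MAT_anom": (3.5, 1.5),
    "Miocene_AP_anom": (120.0, 60.0),
    "HMI": (0.4, 0.15),
    "future_MAT_anom": (2.5, 0.8),
    "future_AP_anom": (60.0, 40.0),
}


@dataclass(frozen=True)
class RefugiumBlock:
    """A rectangular refugium of grid cells with a planted endemism type."""

    kind: str  # "paleo" | "neo" | "mixed"
    x0: int
    y0: int
    width: int = 3
    height: int = 3
    n_species: int = 12

    def cells(self) -> list[tuple[int, int]]:
        return [
            (self.x0 + i, self.y0 + j)
            for i in range(self.width)
            for j in range(self.height)
        ]


@dataclass
class ScenarioSpec:
    """Resolved parameters of one synthetic study scenario.

    Defaults define the package's demo conditions: a 18 x 14 lattice
    (252 cells), 140 species of which 104 are wide-ranging background and
    36 are planted endemics split over three 3 x 3 refugium blocks
    (paleo / neo / mixed). Effect sizes are chosen so every downstream
    stage has detectable signal at this scale.
    """

    nx: int = 18
    ny: int = 14
    n_species: int = 140
    birth: float = 1.0
    death: float = 0.3
    blocks: tuple[RefugiumBlock, ...] = (
        RefugiumBlock("paleo", 2, 2),
        RefugiumBlock("neo", 13, 2),
        RefugiumBlock("mixed", 7, 9, n_species=16),
    )
    # planted branch-length contrasts (fractions of base tree height)
    paleo_attach_depth: float = 0.05  # grafted near the root
    neo_crown_depth: float = 0.03  # radiation crown age
    neo_stem_depth: float = 0.08  # radiation stem attachment depth below tips
    mixed_attach_depth: float = 0.40  # mixed-block old lineages: mid-depth grafts
    mixed_radiation_fraction: float = 0.6  # share of mixed species in the radiation
    # background range-size distribution (lognormal, cells)
    range_median: float = 14.0
    range_sigma: float = 1.0
    clade_spread: float = 5.0  # sd of clade-clustered seed placement
    restricted_min_range: int = 3  # planted species occupy min..max cells
    restricted_max_range: int = 6
    env_corr_length: float = 2.0  # Gaussian-field autocorrelation (cells)
    env_offsets: dict = field(default_factory=lambda: dict(ENV_LAYER_OFFSETS))
    pa_coverage: float = 0.10
    priority_weight: float = 2.0
    min_richness: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.blocks:
            if not (0 <= b.x0 and b.x0 + b.width <= self.nx):
                raise ValueError(f"block {b.kind}: x extent outside grid")
            if not (0 <= b.y0 and b.y0 + b.height <= self.ny):
                raise ValueError(f"block {b.kind}: y extent outside grid")
            if b.n_species > 0 and b.width * b.height < 1:
                raise ValueError(f"block {b.kind}: zero capacity")
        if not 0 <= self.pa_coverage <= 1:
            raise ValueError("pa_coverage must lie in [0, 1]")
        if self.death >= self.birth:
            raise ValueError("need birth > death")
        if self.neo_stem_depth <= self.neo_crown_depth:
            raise ValueError("neo_stem_depth must exceed neo_crown_depth")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def n_planted(self) -> int:
        return sum(b.n_species for b in self.blocks)

    def block_cell_ids(self) -> dict[str, list[str]]:
        return {
            b.kind: [f"c{i}_{j}" for i, j in b.cells()] for b in self.blocks
        }

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["blocks"] = [dataclasses.asdict(b) for b in self.blocks]
        return json.dumps(d, indent=2)


@dataclass
class Scenario:
    """A fully realised scenario: inputs for the whole pipeline."""

    spec: ScenarioSpec
    tree: dendropy.Tree
    grid: OccurrenceGrid  # unfiltered
    layers: pd.DataFrame  # indexed by cell_id
    planted: pd.Series  # cell_id -> block kind, for planted cells only
    planted_species: pd.Series  # species -> block kind
    protection: dict[str, ProtectionScheme]
    priority_rank: pd.Series


# -- phylogeny ------------------------------------------------------------


def simulate_phylogeny(
    n_tips: int, birth: float, death: float, seed: int, max_tries: int = 20
) -> dendropy.Tree:
    """Ultrametric birth-death tree conditioned on the number of extant tips."""
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = random.Random(int(seed))
    last_exc: Exception | None = None
    for _ in range(max_tries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                rng=rng,
                repeat_until_success=True,
            )
            break
        except Exception as exc:  # pragma: no cover - simulator hiccup
            last_exc = exc
    else:  # pragma: no cover
        raise RuntimeError(f"birth-death simulation failed: {last_exc}")
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i:04d}"
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return tree


def _node_depths(tree: dendropy.Tree) -> dict[int, float]:
    depths = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[id(nd)] = depths[id(nd.parent_node)] + (nd.edge.length or 0.0)
    return depths


def _insert_on_edge(child: dendropy.Node, at_below_parent: float) -> dendropy.Node:
    """Subdivide the edge above ``child``, returning the new midpoint node."""
    parent = child.parent_node
    length = child.edge.length
    if not 0 < at_below_parent < length:
        raise ValueError("insertion point outside the edge")
    mid = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(mid)
    mid.edge.length = at_below_parent
    mid.add_child(child)
    child.edge.length = length - at_below_parent
    return mid


def _graft_tip(
    tree: dendropy.Tree, on: dendropy.Node, at_below_parent: float,
    pendant: float, label: str,
) -> None:
    mid = _insert_on_edge(on, at_below_parent)
    leaf = dendropy.Node()
    leaf.taxon = tree.taxon_namespace.new_taxon(label=label)
    leaf.edge.length = pendant
    mid.add_child(leaf)


def _build_radiation(
    tree: dendropy.Tree, labels: list[str], crown: float
) -> dendropy.Node:
    """A compact ultrametric caterpillar clade, crown depth ``crown``.

    Internal nodes are evenly spaced within the crown; every tip sits at
    depth ``crown`` below the returned clade root.
    """

    def leaf(label: str, pendant: float) -> dendropy.Node:
        nd = dendropy.Node()
        nd.taxon = tree.taxon_namespace.new_taxon(label=label)
        nd.edge.length = pendant
        return nd

    k = len(labels)
    if k == 1:
        return leaf(labels[0], crown)
    root = dendropy.Node()
    node, depth = root, 0.0
    step = crown / (k - 1)
    for i in range(k - 1):
        node.add_child(leaf(labels[i], crown - depth))
        if i < k - 2:
            inner = dendropy.Node()
            inner.edge.length = step
            node.add_child(inner)
            node, depth = inner, depth + step
        else:
            node.add_child(leaf(labels[k - 1], crown - depth))
    return root


def build_scenario_tree(
    spec: ScenarioSpec, seed: int
) -> tuple[dendropy.Tree, pd.Series]:
    """Base birth-death tree plus grafted planted lineages.

    Paleo lineages: single tips attached to a root-adjacent edge at a
    shallow depth, giving near-tree-height isolated pendant branches.
    Neo lineages: a short-stemmed caterpillar radiation with a small crown
    depth grafted onto a random background pendant edge. Mixed blocks get
    half of each. Returns the tree and a species -> block-kind map.
    """
    n_background = spec.n_species - spec.n_planted
    if n_background < 10:
        raise ValueError("too few background species")
    rng = np.random.default_rng(seed)
    tree = simulate_phylogeny(
        n_background, spec.birth, spec.death, int(rng.integers(2**31 - 1))
    )
    depths = _node_depths(tree)
    height = max(depths[id(l)] for l in tree.leaf_node_iter())
    planted: dict[str, str] = {}
    counter = 0

    def fresh_labels(k: int, kind: str) -> list[str]:
        nonlocal counter
        out = []
        for _ in range(k):
            lab = f"p{counter:03d}_{kind}"
            counter += 1
            planted[lab] = kind
            out.append(lab)
        return out

    def graft_paleo(labels: list[str], depth_frac: float) -> None:
        """Graft isolated tips whose attachment depth is ~depth_frac * height."""
        depths.update(_node_depths(tree))
        for lab in labels:
            target = depth_frac * height * (0.75 + 0.5 * rng.random())
            candidates = [
                nd
                for nd in tree.preorder_node_iter()
                if nd is not tree.seed_node
                and depths[id(nd.parent_node)] < target < depths[id(nd)]
            ]
            if not candidates:
                candidates = tree.seed_node.child_nodes()
            on = candidates[int(rng.integers(len(candidates)))]
            at = np.clip(
                target - depths[id(on.parent_node)],
                1e-6 * height,
                0.9 * on.edge.length,
            )
            _graft_tip(tree, on, float(at), height - (depths[id(on.parent_node)] + float(at)), lab)
            depths.update(_node_depths(tree))

    def graft_radiation(labels: list[str]) -> None:
        stem_depth = spec.neo_stem_depth * height
        crown = spec.neo_crown_depth * height
        leaves = [
            l
            for l in tree.leaf_node_iter()
            if l.taxon.label.startswith("s") and l.edge.length > 2 * stem_depth
        ]
        if not leaves:  # fall back to the longest background pendant edge
            leaves = sorted(
                (l for l in tree.leaf_node_iter() if l.taxon.label.startswith("s")),
                key=lambda l: -l.edge.length,
            )[:1]
        host = leaves[int(rng.integers(len(leaves)))]
        at = max(host.edge.length - stem_depth, 0.5 * host.edge.length)
        mid = _insert_on_edge(host, at)
        clade = _build_radiation(tree, labels, crown)
        mid_depth = _node_depths(tree)[id(mid)]
        clade.edge.length = max(height - mid_depth - crown, 1e-6 * height)
        mid.add_child(clade)

    for block in spec.blocks:
        labels = fresh_labels(block.n_species, block.kind)
        if block.kind == "paleo":
            graft_paleo(labels, spec.paleo_attach_depth)
        elif block.kind == "neo":
            graft_radiation(labels)
        elif block.kind == "mixed":
            n_rad = round(spec.mixed_radiation_fraction * len(labels))
            graft_paleo(labels[n_rad:], spec.mixed_attach_depth)
            graft_radiation(labels[:n_rad])
        else:
            raise ValueError(f"unknown block kind {block.kind!r}")
    return tree, pd.Series(planted, name="block", dtype=object)


# -- ranges ---------------------------------------------------------------


def _spreading_dye(
    rng: np.random.Generator,
    start: tuple[int, int],
    target: int,
    allowed: set[tuple[int, int]],
) -> set[tuple[int, int]]:
    """Grow a rook-connected cell set from ``start`` within ``allowed``."""
    occupied = {start}
    frontier = {start}
    while len(occupied) < target:
        candidates = set()
        for (i, j) in frontier:
            for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (i + d[0], j + d[1])
                if nb in allowed and nb not in occupied:
                    candidates.add(nb)
        if not candidates:
            break
        pick = sorted(candidates)[int(rng.integers(len(candidates)))]
        occupied.add(pick)
        frontier.add(pick)
    return occupied


def _background_range_sizes(rng: np.random.Generator, spec: ScenarioSpec, k: int) -> np.ndarray:
    raw = rng.lognormal(mean=np.log(spec.range_median), sigma=spec.range_sigma, size=k)
    return np.clip(np.round(raw), 1, spec.n_cells).astype(int)


def simulate_ranges(
    tree: dendropy.Tree,
    spec: ScenarioSpec,
    seed: int,
    planted_species: pd.Series | None = None,
) -> OccurrenceGrid:
    """Spreading-dye ranges over the lattice.

    Background species draw a lognormal target range size and grow from a
    seed cell clustered around their top-level clade's centroid, so
    related species co-occur regionally. Planted species are confined to
    their refugium block with small ranges (1 to
    ``spec.restricted_max_range`` cells).
    """
    rng = np.random.default_rng(seed)
    all_cells = {(i, j) for i in range(spec.nx) for j in range(spec.ny)}
    cell_list = [
        GridCell(f"c{i}_{j}", float(i), float(j))
        for i in range(spec.nx)
        for j in range(spec.ny)
    ]
    if planted_species is None:
        planted_species = pd.Series(dtype=object)
    block_by_kind = {b.kind: b for b in spec.blocks}
    for kind, blk in block_by_kind.items():
        n_assigned = int((planted_species == kind).sum())
        if n_assigned > 0 and blk.width * blk.height * spec.restricted_max_range < n_assigned:
            raise ValueError(f"refugium {kind}: capacity below assigned species")

    # clade centroids for background clustering
    clades: dict[str, int] = {}
    for ci, child in enumerate(tree.seed_node.child_nodes()):
        for leaf in child.leaf_iter():
            clades[leaf.taxon.label] = ci
    n_clades = max(clades.values()) + 1
    centroids = np.column_stack(
        [rng.uniform(0, spec.nx, n_clades), rng.uniform(0, spec.ny, n_clades)]
    )

    records: list[tuple[str, str]] = []
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    background = [l for l in labels if l not in planted_species.index]
    sizes = _background_range_sizes(rng, spec, len(background))
    for label, size in zip(background, sizes):
        cx, cy = centroids[clades.get(label, 0)]
        while True:
            i = int(np.clip(round(rng.normal(cx, spec.clade_spread)), 0, spec.nx - 1))
            j = int(np.clip(round(rng.normal(cy, spec.clade_spread)), 0, spec.ny - 1))
            if (i, j) in all_cells:
                break
        cells = _spreading_dye(rng, (i, j), int(size), all_cells)
        records += [(label, f"c{i}_{j}") for (i, j) in cells]

    for label in planted_species.index:
        blk = block_by_kind[planted_species[label]]
        allowed = set(blk.cells())
        start = sorted(allowed)[int(rng.integers(len(allowed)))]
        size = int(rng.integers(spec.restricted_min_range, spec.restricted_max_range + 1))
        cells = _spreading_dye(rng, start, size, allowed)
        records += [(label, f"c{i}_{j}") for (i, j) in cells]

    return build_grid(records, cell_list)


# -- environment ----------------------------------------------------------


def gaussian_random_field(
    rng: np.random.Generator, nx: int, ny: int, corr_length: float
) -> np.ndarray:
    """Unit-variance Gaussian random field on an nx x ny lattice.

    White noise smoothed with a Gaussian kernel of scale ``corr_length``
    (cells); the resulting correlation function is exp(-h^2 / (4 s^2)).
    """
    white = rng.normal(size=(nx, ny))
    smooth = gaussian_filter(white, sigma=corr_length, mode="wrap")
    return (smooth - smooth.mean()) / smooth.std()


def empirical_correlation_length(field: np.ndarray, max_lag: int | None = None) -> float:
    """Semivariogram-based correlation length estimate.

    Returns the lag at which the empirical semivariogram first reaches
    (1 - 1/e) of the sill; for the smoothed-noise field above the
    theoretical value is 2 * corr_length.
    """
    nx, ny = field.shape
    if max_lag is None:
        max_lag = min(nx, ny) // 2
    sill = field.var()
    target = (1 - np.exp(-1.0)) * sill
    prev_lag, prev_gamma = 0, 0.0
    for h in range(1, max_lag + 1):
        dx = 0.5 * ((field[h:, :] - field[:-h, :]) ** 2).mean()
        dy = 0.5 * ((field[:, h:] - field[:, :-h]) ** 2).mean()
        gamma = 0.5 * (dx + dy)
        if gamma >= target:
            # linear interpolation between lags
            frac = (target - prev_gamma) / (gamma - prev_gamma)
            return prev_lag + frac * (h - prev_lag)
        prev_lag, prev_gamma = h, gamma
    return float(max_lag)


def simulate_env_layers(
    spec: ScenarioSpec, seed: int, hotspot_cells: list[str] | None = None
) -> pd.DataFrame:
    """All environmental / threat layers as a cell-indexed frame.

    Each layer is base_mean + base_sd * (field + offset * hotspot), with
    the field a unit-variance autocorrelated surface, so the configured
    offsets are effect sizes in spatial-sd units. HMI is clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    ids = [f"c{i}_{j}" for i in range(spec.nx) for j in range(spec.ny)]
    if hotspot_cells is None:
        hotspot_cells = [cid for v in spec.block_cell_ids().values() for cid in v]
    hot = pd.Series(0.0, index=ids)
    hot.loc[[c for c in hotspot_cells if c in hot.index]] = 1.0
    out = {}
    for layer, (base, sd) in _LAYER_BASE.items():
        f = gaussian_random_field(rng, spec.nx, spec.ny, spec.env_corr_length).ravel()
        offset = spec.env_offsets.get(layer, 0.0)
        vals = base + sd * (f + offset * hot.to_numpy())
        if layer == "HMI":
            vals = np.clip(vals, 0.0, 1.0)
        if layer == "elev_range":
            vals = np.abs(vals)
        out[layer] = vals
    frame = pd.DataFrame(out, index=pd.Index(ids, name="cell_id"))
    return frame


# -- protection -----------------------------------------------------------


def simulate_protection(
    spec: ScenarioSpec, seed: int, hotspot_cells: list[str] | None = None
) -> tuple[dict[str, ProtectionScheme], pd.Series]:
    """Existing-PA mask plus a priority ranking and its nested top-k masks.

    The PA mask protects the top ``pa_coverage`` fraction of a smooth
    random surface (spatially clustered, uncorrelated with the planted
    signal). The priority score adds ``priority_weight`` (in surface-sd
    units) on planted cells, so top-k coverage of hotspots exceeds the
    baseline.
    """
    rng = np.random.default_rng(seed)
    ids = [f"c{i}_{j}" for i in range(spec.nx) for j in range(spec.ny)]
    idx = pd.Index(ids, name="cell_id")
    if hotspot_cells is None:
        hotspot_cells = [cid for v in spec.block_cell_ids().values() for cid in v]
    hot = pd.Series(0.0, index=idx)
    hot.loc[[c for c in hotspot_cells if c in idx]] = 1.0

    pa_field = gaussian_random_field(rng, spec.nx, spec.ny, spec.env_corr_length).ravel()
    pa_rank = pd.Series(
        pd.Series(-pa_field, index=idx).rank(method="first").astype(int), index=idx
    )
    schemes: dict[str, ProtectionScheme] = {}
    if spec.pa_coverage > 0:
        schemes["existing_PA"] = priority_mask(pa_rank, spec.pa_coverage, name="existing_PA")
    else:
        schemes["existing_PA"] = ProtectionScheme(
            "existing_PA", pd.Series(False, index=idx)
        )

    score = (
        gaussian_random_field(rng, spec.nx, spec.ny, spec.env_corr_length).ravel()
        + spec.priority_weight * hot.to_numpy()
    )
    priority_rank = pd.Series(
        pd.Series(-score, index=idx).rank(method="first").astype(int), index=idx
    )
    for frac, name in ((0.17, "top17"), (0.30, "top30"), (0.50, "top50")):
        schemes[name] = priority_mask(priority_rank, frac, name=name)
    return schemes, priority_rank


# -- scenario assembly ----------------------------------------------------


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Realise a full scenario from its spec, deterministically by seed."""
    seeds = np.random.SeedSequence(spec.seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    tree, planted_species = build_scenario_tree(spec, sub[0])
    grid = simulate_ranges(tree, spec, sub[1], planted_species)
    block_cells = spec.block_cell_ids()
    hotspot_cells = [c for v in block_cells.values() for c in v]
    layers = simulate_env_layers(spec, sub[2], hotspot_cells)
    schemes, priority_rank = simulate_protection(spec, sub[3], hotspot_cells)
    planted = pd.Series(
        {c: kind for kind, cells in block_cells.items() for c in cells},
        name="planted",
        dtype=object,
    )
    return Scenario(
        spec=spec,
        tree=tree,
        grid=grid,
        layers=layers,
        planted=planted,
        planted_species=planted_species,
        protection=schemes,
        priority_rank=priority_rank,
    )
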