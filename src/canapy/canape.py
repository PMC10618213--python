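"""Randomization null, significance ranks, and CANAPE classification.

CANAPE (categorical analysis of neo- and paleo-endemism) asks, cell by
cell, whether endemism is significantly concentrated and whether the
concentrated branches are old (long) or young (short). The null model
shuffles the tip labels of the phylogeny, which preserves topology, the
multiset of branch lengths, per-cell species richness and per-species
range size exactly — only the mapping of species onto evolutionary history
is randomized.

Classification is a two-step rule. A cell is an endemism candidate if
either PE on the original tree or PE on the equal-branch-length comparison
tree is significantly high (upper 2.5% tail of the null at alpha = 0.05).
Among candidates, significantly high RPE means paleo-endemism
(concentration of rare long branches), significantly low RPE means
neo-endemism (rare short branches), and otherwise the cell is a mixed
endemism centre. Cells failing the gate are non-significant. Neo, paleo
and mixed cells together form the endemism *hotspots*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .grid import OccurrenceGrid
from .phylo import (
    branch_species_matrix,
    _branch_cell_incidence,
    _pe_from_incidence,
    tree_branches,
)

__all__ = [
    "METRICS",
    "CATEGORIES",
    "shuffle_tips",
    "RandomizationResult",
    "randomization_test",
    "CanapeClassification",
    "canape_classify",
    "group_hotspots",
    "round_half_away",
    "percentage",
    "category_percentages",
    "OverlapSummary",
    "overlap_percentages",
    "overlap_summary",
]

METRICS = ("PE_original", "PE_equal", "RPE")
CATEGORIES = ("neo", "paleo", "mixed", "non_significant", "excluded")
HOTSPOT_CATEGORIES = frozenset({"neo", "paleo", "mixed"})

_TIE_RTOL = 1e-9


def shuffle_tips(tree: dendropy.Tree, rng: np.random.Generator) -> dendropy.Tree:
    """Return a copy of the tree with tip labels permuted uniformly.

    Topology and the multiset of branch lengths are untouched; only which
    species sits at which tip changes.
    """
    clone = tree.clone(depth=1)
    leaves = list(clone.leaf_node_iter())
    taxa = [leaf.taxon for leaf in leaves]
    perm = rng.permutation(len(taxa))
    # reassign taxon *pointers* (taxa are shared with the source tree and
    # must never be mutated)
    for leaf, j in zip(leaves, perm):
        leaf.taxon = taxa[j]
    return clone


@dataclass
class RandomizationResult:
    """Observed endemism metrics plus their null exceedance counts.

    For each metric and cell, ``count_greater`` is the number of null
    draws strictly above the observed value and ``count_equal`` the number
    of (numerical) ties; ties count against significance. One-tailed rates
    use the add-one convention p = (1 + #extreme) / (n_iter + 1), so a
    value never reaches p = 0 from a finite Monte-Carlo sample.
    """

    n_iter: int
    observed: pd.DataFrame  # cells x METRICS
    count_greater: pd.DataFrame
    count_equal: pd.DataFrame
    p_high: pd.DataFrame = field(init=False)
    p_low: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        cg, ce = self.count_greater, self.count_equal
        if ((cg + ce) > self.n_iter).any().any():
            raise ValueError("exceedance counts exceed n_iter")
        cl = self.n_iter - cg - ce
        self.p_high = (1 + cg + ce) / (self.n_iter + 1)
        self.p_low = (1 + cl + ce) / (self.n_iter + 1)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.observed.index)


def randomization_test(
    tree: dendropy.Tree,
    grid: OccurrenceGrid,
    n_iter: int = 999,
    seed: int | np.random.Generator = 0,
    scaled: bool = True,
) -> RandomizationResult:
    """Tip-shuffle null for PE_original, PE_equal and RPE.

    The branch x species descendant matrix is computed once; a tip shuffle
    is a column permutation of that matrix, so each iteration costs one
    sparse aggregation rather than a tree traversal. Results are identical
    to shuffling the tree and recomputing from scratch.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = branch_species_matrix(tree, grid.species)
    presence64 = grid.presence.astype(np.float64)
    desc64 = table.desc.astype(np.float64)
    n_b = table.n_branches
    equal_lengths = np.full(n_b, table.total_length() / n_b)

    def metrics_from_desc(d: np.ndarray) -> np.ndarray:
        inc = (d @ presence64) > 0.5
        pe_o = _pe_from_incidence(table.lengths, inc, scaled)
        pe_e = _pe_from_incidence(equal_lengths, inc, scaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            rpe = np.where(pe_e == 0, np.nan, pe_o / pe_e)
        return np.stack([pe_o, pe_e, rpe])  # (3, n_cells)

    obs = metrics_from_desc(desc64)
    tol = _TIE_RTOL * np.maximum(1.0, np.abs(obs))
    cg = np.zeros_like(obs)
    ce = np.zeros_like(obs)
    for _ in range(n_iter):
        perm = rng.permutation(grid.n_species)
        null = metrics_from_desc(desc64[:, perm])
        diff = null - obs
        with np.errstate(invalid="ignore"):
            cg += diff > tol
            ce += np.abs(diff) <= tol
    idx = pd.Index(grid.cell_ids, name="cell_id")
    as_frame = lambda a: pd.DataFrame(a.T, index=idx, columns=list(METRICS))
    return RandomizationResult(
        n_iter=n_iter,
        observed=as_frame(obs),
        count_greater=as_frame(cg),
        count_equal=as_frame(ce),
    )


@dataclass
class CanapeClassification:
    """Per-cell endemism category and hotspot flag."""

    table: pd.DataFrame  # index cell_id; columns category, hotspot

    def __post_init__(self) -> None:
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    @property
    def hotspot(self) -> pd.Series:
        return self.table["hotspot"]

    @property
    def analysed_cells(self) -> pd.Index:
        return self.table.index[self.table["category"] != "excluded"]

    def hotspot_cells(self) -> set[str]:
        return set(self.table.index[self.table["hotspot"]])


def canape_classify(
    rand: RandomizationResult, alpha: float = 0.05, strict_mixed: bool = False
) -> CanapeClassification:
    """Classify cells into neo / paleo / mixed / non-significant.

    Step 1 (gate): the cell is an endemism candidate iff PE_original or
    PE_equal is significantly high at the one-tailed alpha/2 level (above
    the 97.5% null quantile for the default alpha = 0.05).
    Step 2: among candidates, RPE significantly high -> paleo; RPE
    significantly low -> neo; otherwise mixed. With ``strict_mixed`` the
    mixed category additionally requires *both* PE metrics significantly
    high; candidate cells failing that demotion rule are non-significant.

    Cells whose RPE is undefined (comparison-tree PE of zero) are excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    thr = alpha / 2.0
    ph, pl = rand.p_high, rand.p_low
    hi_orig = ph["PE_original"] < thr
    hi_eq = ph["PE_equal"] < thr
    hi_rpe = ph["RPE"] < thr
    lo_rpe = pl["RPE"] < thr
    undefined = rand.observed["RPE"].isna()

    gate = hi_orig | hi_eq
    categories = pd.Series("non_significant", index=rand.observed.index, dtype=object)
    categories[gate & hi_rpe] = "paleo"
    categories[gate & ~hi_rpe & lo_rpe] = "neo"
    mixed = gate & ~hi_rpe & ~lo_rpe
    if strict_mixed:
        mixed &= hi_orig & hi_eq
    categories[mixed] = "mixed"
    categories[undefined] = "excluded"
    table = pd.DataFrame(
        {
            "category": categories,
            "hotspot": categories.isin(HOTSPOT_CATEGORIES),
        }
    )
    table.index.name = "cell_id"
    return CanapeClassification(table)


def group_hotspots(classification: CanapeClassification) -> pd.Series:
    """Hotspot flag per cell: true iff category is neo, paleo or mixed."""
    return classification.categories.isin(HOTSPOT_CATEGORIES).rename("hotspot")


# -- summaries ------------------------------------------------------------


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """100 * count / total, rounded half away from zero for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, decimals)


def category_percentages(classification: CanapeClassification) -> pd.DataFrame:
    """Counts and percentages of analysed cells per category (plus hotspots).

    Percentages are relative to the analysed (non-excluded) cell count and
    rounded to one decimal half away from zero; the raw fraction is kept.
    """
    analysed = classification.table.loc[classification.analysed_cells]
    n = len(analysed)
    if n == 0:
        raise ValueError("no analysed cells")
    rows = []
    for cat in ("neo", "paleo", "mixed", "non_significant"):
        count = int((analysed["category"] == cat).sum())
        rows.append((cat, count))
    rows.append(("hotspot", int(analysed["hotspot"].sum())))
    out = pd.DataFrame(rows, columns=["category", "count"])
    out["fraction"] = out["count"] / n
    out["percentage"] = [percentage(c, n) for c in out["count"]]
    out.attrs["n_analysed"] = n
    return out


@dataclass
class OverlapSummary:
    """Hotspot overlap between two classifications (Venn-style)."""

    a_only: int
    b_only: int
    shared: int
    pct_shared_of_a: float
    pct_shared_of_b: float
    union_hotspots: int
    n_analysed_union: int
    pct_union: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def overlap_percentages(
    n_hotspots_a: int, n_hotspots_b: int, shared: int
) -> tuple[float, float]:
    """Shared hotspot cells as a percentage of each group's hotspots."""
    if shared > min(n_hotspots_a, n_hotspots_b):
        raise ValueError("shared exceeds a group's hotspot count")
    pct_a = percentage(shared, n_hotspots_a) if n_hotspots_a else float("nan")
    pct_b = percentage(shared, n_hotspots_b) if n_hotspots_b else float("nan")
    return pct_a, pct_b


def overlap_summary(
    class_a: CanapeClassification, class_b: CanapeClassification
) -> OverlapSummary:
    """Hotspot overlap between two groups analysed on overlapping universes.

    Per-group shared percentages use each group's own hotspot count as the
    denominator; the union percentage is over all analysed cells of either
    group.
    """
    hot_a, hot_b = class_a.hotspot_cells(), class_b.hotspot_cells()
    analysed_a = set(class_a.analysed_cells)
    analysed_b = set(class_b.analysed_cells)
    if not analysed_a & analysed_b:
        raise ValueError("classifications share no analysed cells")
    shared = len(hot_a & hot_b)
    union_hot = len(hot_a | hot_b)
    n_union = len(analysed_a | analysed_b)
    pct_a, pct_b = overlap_percentages(len(hot_a), len(hot_b), shared)
    return OverlapSummary(
        a_only=len(hot_a - hot_b),
        b_only=len(hot_b - hot_a),
        shared=shared,
        pct_shared_of_a=pct_a,
        pct_shared_of_b=pct_b,
        union_hotspots=union_hot,
        n_analysed_union=n_union,
        pct_union=percentage(union_hot, n_union),
    )
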