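"""Phylogeny handling and range-weighted endemism metrics.

Trees are ``dendropy.Tree`` objects (rooted, branch lengths in
time-proportional units, polytomies allowed). The root carries no branch:
any stem length on the root is ignored in totals, since a root branch would
have the full species set as descendants and no defined complement.

Metrics
-------
PD
    Phylogenetic diversity: sum of branch lengths spanned by a cell's
    species.
PE
    Phylogenetic endemism: per-cell sum of branch lengths, each divided by
    the branch's geographic range (the number of cells occupied by any
    descendant tip). Optionally scaled by total tree length so that values
    are proportions of the tree.
RPE
    Relative phylogenetic endemism: PE on the original tree divided by PE
    on a comparison tree with the same topology whose branch lengths are
    all equal while preserving total length — a pure branch-length-shape
    ratio. High RPE marks concentrations of rare long branches
    (paleo-endemism); low RPE marks rare short branches (neo-endemism).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .grid import OccurrenceGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_newick",
    "write_newick",
    "tree_branches",
    "total_tree_length",
    "equalize_branch_lengths",
    "BranchTable",
    "branch_species_matrix",
    "branch_ranges",
    "phylogenetic_diversity",
    "phylogenetic_endemism",
    "relative_phylogenetic_endemism",
    "endemism_table",
    "prune_to_shared",
]


class NewickError(ValueError):
    """Raised on malformed Newick input."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree, validating the contract.

    Requires unique tip labels and a branch length on every non-root edge.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "an internal node"
            raise NewickError(f"missing branch length on edge to {who}")
        if node.edge.length < 0:
            raise NewickError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_branches(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Non-root nodes in stable preorder; each carries one branch (its edge)."""
    return [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all non-root branch lengths (root stem excluded)."""
    return float(sum(nd.edge.length or 0.0 for nd in tree_branches(tree)))


def equalize_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Comparison tree: same topology, every branch length equal.

    Each non-root branch gets (original total length) / (branch count), so
    the total length — and hence the scale of PE — is preserved and RPE is
    a pure shape ratio.
    """
    clone = tree.clone(depth=1)
    branches = tree_branches(clone)
    if not branches:
        raise ValueError("tree has no branches")
    equal = total_tree_length(clone) / len(branches)
    for nd in branches:
        nd.edge.length = equal
    return clone


# -- branch x species structure ------------------------------------------


@dataclass
class BranchTable:
    """Branch lengths plus the branch x species descendant-tip incidence.

    ``desc[b, s]`` is True iff species ``s`` (in ``species`` order) is a
    descendant tip of branch ``b``. A tip shuffle of the phylogeny is a
    column permutation of ``desc``, which is what makes the randomization
    null cheap: no re-traversal, just re-aggregation.
    """

    lengths: np.ndarray  # (n_branches,)
    desc: np.ndarray  # (n_branches, n_species) bool
    species: list[str]

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    def total_length(self) -> float:
        return float(self.lengths.sum())


def branch_species_matrix(tree: dendropy.Tree, species: list[str]) -> BranchTable:
    """Build the :class:`BranchTable` for a tree over a species order.

    Raises
    ------
    KeyError
        If a tip label is absent from ``species``.
    """
    index = {s: i for i, s in enumerate(species)}
    branches = tree_branches(tree)
    n_b, n_s = len(branches), len(species)
    desc = np.zeros((n_b, n_s), dtype=bool)
    row = {id(nd): i for i, nd in enumerate(branches)}
    # postorder: a node's tip set is the union of its children's
    for nd in tree.postorder_node_iter():
        if nd is tree.seed_node:
            continue
        i = row[id(nd)]
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in index:
                raise KeyError(f"tip {label!r} absent from the occurrence grid")
            desc[i, index[label]] = True
        else:
            for child in nd.child_nodes():
                desc[i] |= desc[row[id(child)]]
    lengths = np.array([nd.edge.length for nd in branches], dtype=float)
    return BranchTable(lengths=lengths, desc=desc, species=species)


def _branch_cell_incidence(table: BranchTable, presence: np.ndarray) -> np.ndarray:
    """(n_branches, n_cells) bool: branch has >= 1 descendant tip in cell."""
    counts = table.desc.astype(np.float64) @ presence.astype(np.float64)
    return counts > 0.5


def branch_ranges(tree: dendropy.Tree, grid: OccurrenceGrid) -> pd.DataFrame:
    """Per-branch geographic range: the cells where any descendant tip occurs.

    Returns a frame with one row per non-root branch (preorder) holding the
    branch length, range count, and the occupied cell ids. A tip branch's
    range equals that species' range; an internal branch's range is the
    union of its children's.
    """
    table = branch_species_matrix(tree, grid.species)
    inc = _branch_cell_incidence(table, grid.presence)
    ids = np.array(grid.cell_ids, dtype=object)
    return pd.DataFrame(
        {
            "length": table.lengths,
            "range_size": inc.sum(axis=1).astype(np.int64),
            "cells": [frozenset(ids[r]) for r in inc],
        }
    )


def _pe_from_incidence(
    lengths: np.ndarray, inc: np.ndarray, scaled: bool
) -> np.ndarray:
    """PE per cell given branch lengths and branch x cell incidence."""
    ranges = inc.sum(axis=1).astype(np.float64)
    active = ranges > 0
    weights = np.zeros_like(lengths)
    weights[active] = lengths[active] / ranges[active]
    pe = weights @ inc
    if scaled:
        total = lengths.sum()
        if total <= 0:
            raise ValueError("cannot scale PE: total tree length is zero")
        pe = pe / total
    return pe


def phylogenetic_endemism(
    tree: dendropy.Tree, grid: OccurrenceGrid, scaled: bool = True
) -> pd.Series:
    """Range-weighted phylogenetic endemism per cell.

    PE(cell) = sum over branches b present in the cell of L_b / R_b, where
    R_b counts the cells holding any descendant tip of b. With
    ``scaled=True`` the sum is divided by total tree length, giving the
    proportion of the tree restricted to the cell.
    """
    table = branch_species_matrix(tree, grid.species)
    inc = _branch_cell_incidence(table, grid.presence)
    pe = _pe_from_incidence(table.lengths, inc, scaled)
    return pd.Series(pe, index=grid.cell_ids, name="PE")


def phylogenetic_diversity(tree: dendropy.Tree, grid: OccurrenceGrid) -> pd.Series:
    """Unweighted PD per cell: total branch length spanned by a cell's species."""
    table = branch_species_matrix(tree, grid.species)
    inc = _branch_cell_incidence(table, grid.presence)
    return pd.Series(table.lengths @ inc, index=grid.cell_ids, name="PD")


def relative_phylogenetic_endemism(
    pe_original: pd.Series, pe_equal: pd.Series
) -> pd.Series:
    """RPE per cell: PE on the original tree over PE on the comparison tree.

    Cells where the comparison-tree PE is zero are returned as NaN
    (undefined) rather than raising.
    """
    if not pe_original.index.equals(pe_equal.index):
        raise ValueError("PE series are over different cell sets")
    with np.errstate(divide="ignore", invalid="ignore"):
        rpe = pe_original.to_numpy() / pe_equal.to_numpy()
    rpe = np.where(pe_equal.to_numpy() == 0, np.nan, rpe)
    return pd.Series(rpe, index=pe_original.index, name="RPE")


def endemism_table(
    tree: dendropy.Tree, grid: OccurrenceGrid, scaled: bool = True
) -> pd.DataFrame:
    """Per-cell PE_original, PE_equal and RPE in one pass.

    Both PE variants share one branch x cell incidence (the comparison
    tree differs only in branch lengths), so the expensive aggregation is
    done once.
    """
    table = branch_species_matrix(tree, grid.species)
    inc = _branch_cell_incidence(table, grid.presence)
    n_b = table.n_branches
    equal_lengths = np.full(n_b, table.total_length() / n_b)
    pe_orig = _pe_from_incidence(table.lengths, inc, scaled)
    pe_eq = _pe_from_incidence(equal_lengths, inc, scaled)
    with np.errstate(divide="ignore", invalid="ignore"):
        rpe = np.where(pe_eq == 0, np.nan, pe_orig / pe_eq)
    return pd.DataFrame(
        {"PE_original": pe_orig, "PE_equal": pe_eq, "RPE": rpe},
        index=pd.Index(grid.cell_ids, name="cell_id"),
    )


def prune_to_shared(
    tree: dendropy.Tree, grid: OccurrenceGrid
) -> tuple[dendropy.Tree, OccurrenceGrid]:
    """Intersect tree tips and grid species, warning about the discards.

    Mirrors the usual pruning of a megatree "to contain only species with
    distribution data" and, symmetrically, drops gridded species missing
    from the tree.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    shared = [s for s in grid.species if s in tips]
    if not shared:
        raise ValueError("tree and grid share no species")
    missing_from_tree = len(grid.species) - len(shared)
    missing_from_grid = len(tips) - len(shared)
    if missing_from_tree or missing_from_grid:
        logger.warning(
            "intersecting tree and grid: dropping %d gridded species not in "
            "the tree and %d tips without distribution data",
            missing_from_tree,
            missing_from_grid,
        )
    if missing_from_grid:
        tree = tree.clone(depth=1)
        keep = set(shared)
        tree.retain_taxa_with_labels(sorted(keep))
    if missing_from_tree:
        keep_rows = np.array([s in tips for s in grid.species])
        grid = OccurrenceGrid(
            species=[s for s in grid.species if s in tips],
            cells=grid.cells,
            presence=grid.presence[keep_rows],
        )
    return tree, grid
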