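"""Species-by-cell presence-absence grids.

The central container is :class:`OccurrenceGrid`: a binary species x cell
incidence matrix over an ordered set of grid cells with planar centre
coordinates (equal-area units are the caller's responsibility; the
synthetic module uses a unit square lattice). All endemism metrics, the
randomization null and the driver tables consume this structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridCell",
    "OccurrenceGrid",
    "build_grid",
    "filter_min_richness",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "cells_to_geojson",
]


class GridError(ValueError):
    """Raised on malformed or inconsistent grid inputs."""


@dataclass(frozen=True)
class GridCell:
    """A grid cell: opaque id plus planar centre coordinates."""

    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise GridError(f"cell {self.id!r}: non-finite coordinates")


@dataclass
class OccurrenceGrid:
    """Binary species x cell incidence over an indexed set of cells.

    Attributes
    ----------
    species : list of str
        Ordered species labels (rows of ``presence``).
    cells : pandas.DataFrame
        One row per cell, columns ``id``, ``x``, ``y`` (columns of
        ``presence``), in column order.
    presence : numpy.ndarray
        ``(n_species, n_cells)`` array with entries in {0, 1}.
    """

    species: list[str]
    cells: pd.DataFrame
    presence: np.ndarray
    _cell_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.uint8)
        if self.presence.ndim != 2:
            raise GridError("presence must be 2-D (species x cells)")
        if self.presence.shape != (len(self.species), len(self.cells)):
            raise GridError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.species)} species x {len(self.cells)} cells"
            )
        if not np.isin(self.presence, (0, 1)).all():
            raise GridError("presence entries must be 0 or 1")
        if len(set(self.species)) != len(self.species):
            raise GridError("duplicate species labels")
        ids = list(self.cells["id"])
        if len(set(ids)) != len(ids):
            raise GridError("duplicate cell ids")
        self._cell_index = {c: i for i, c in enumerate(ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["id"])

    def coords(self) -> np.ndarray:
        """Cell centre coordinates, shape ``(n_cells, 2)``."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def range_sizes(self) -> np.ndarray:
        """Per-species occupied-cell counts (row sums)."""
        return self.presence.sum(axis=1).astype(np.int64)

    def richness(self) -> np.ndarray:
        """Per-cell species counts (column sums)."""
        return self.presence.sum(axis=0).astype(np.int64)

    def subset_cells(self, keep: np.ndarray) -> "OccurrenceGrid":
        """Grid restricted to a boolean mask of cells; drops orphaned species."""
        keep = np.asarray(keep, dtype=bool)
        pres = self.presence[:, keep]
        occupied = pres.sum(axis=1) > 0
        dropped = [s for s, k in zip(self.species, occupied) if not k]
        if dropped:
            logger.info("dropping %d species with no retained cells", len(dropped))
        return OccurrenceGrid(
            species=[s for s, k in zip(self.species, occupied) if k],
            cells=self.cells.loc[keep].reset_index(drop=True),
            presence=pres[occupied],
        )


def build_grid(
    records: Iterable[tuple[str, str]], cells: Sequence[GridCell]
) -> OccurrenceGrid:
    """Assemble an :class:`OccurrenceGrid` from long-format records.

    Parameters
    ----------
    records
        Iterable of ``(species, cell_id)`` pairs; duplicates collapse to a
        single presence.
    cells
        Full cell universe (cells may end up empty).

    Raises
    ------
    GridError
        If a record names an unknown cell id or the record list is empty.
    """
    cells = list(cells)
    ids = [c.id for c in cells]
    if len(set(ids)) != len(ids):
        raise GridError("duplicate cell ids in cell universe")
    cell_index = {c.id: i for i, c in enumerate(cells)}
    records = list(records)
    if not records:
        raise GridError("empty record list")
    species: list[str] = []
    sp_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for sp, cid in records:
        if cid not in cell_index:
            raise GridError(f"record ({sp!r}, {cid!r}): unknown cell id {cid!r}")
        if sp not in sp_index:
            sp_index[sp] = len(species)
            species.append(sp)
        pairs.add((sp_index[sp], cell_index[cid]))
    presence = np.zeros((len(species), len(cells)), dtype=np.uint8)
    rows, cols = zip(*pairs)
    presence[list(rows), list(cols)] = 1
    frame = pd.DataFrame({"id": ids, "x": [c.x for c in cells], "y": [c.y for c in cells]})
    return OccurrenceGrid(species=species, cells=frame, presence=presence)


def filter_min_richness(grid: OccurrenceGrid, min_species: int = 5) -> OccurrenceGrid:
    """Drop cells holding fewer than ``min_species`` species.

    Low-richness cells are a known source of noise in endemism analyses, so
    cells below the threshold (default: keep cells with >= 5 species) are
    removed before any metric computation. Species left with no occupied
    cell are dropped and logged.

    Raises
    ------
    GridError
        If ``min_species < 1`` or no cell survives the filter.
    """
    if min_species < 1:
        raise GridError("min_species must be >= 1")
    keep = grid.richness() >= min_species
    if not keep.any():
        raise GridError(
            f"no cell has >= {min_species} species "
            f"(max richness {int(grid.richness().max(initial=0))})"
        )
    return grid.subset_cells(keep)


# -- I/O ------------------------------------------------------------------

def read_occurrences_csv(
    occ_path: str, cells_path: str | None = None
) -> OccurrenceGrid:
    """Read a long-format occurrence CSV (columns: species, cell_id).

    If ``cells_path`` is given it must be a CSV with columns
    ``id, x, y`` defining the cell universe; otherwise cells are taken
    from the occurrence file (in order of first appearance) with
    coordinates parsed from ids of the form ``"x_y"`` when possible,
    else indexed along a line.
    """
    occ = pd.read_csv(occ_path, dtype=str)
    if not {"species", "cell_id"} <= set(occ.columns):
        raise GridError(f"{occ_path}: expected columns species, cell_id")
    if cells_path is not None:
        cf = pd.read_csv(cells_path)
        cells = [GridCell(str(r.id), float(r.x), float(r.y)) for r in cf.itertuples()]
    else:
        seen: list[str] = list(dict.fromkeys(occ["cell_id"]))
        cells = []
        for i, cid in enumerate(seen):
            parts = cid.split("_")
            try:
                x, y = float(parts[-2]), float(parts[-1])
            except (ValueError, IndexError):
                x, y = float(i), 0.0
            cells.append(GridCell(cid, x, y))
    return build_grid(zip(occ["species"], occ["cell_id"]), cells)


def write_occurrences_csv(grid: OccurrenceGrid, occ_path: str, cells_path: str | None = None) -> None:
    """Write long-format occurrences (and optionally the cell table)."""
    sp_idx, cell_idx = np.nonzero(grid.presence)
    ids = grid.cell_ids
    pd.DataFrame(
        {
            "species": [grid.species[i] for i in sp_idx],
            "cell_id": [ids[j] for j in cell_idx],
        }
    ).to_csv(occ_path, index=False)
    if cells_path is not None:
        grid.cells.to_csv(cells_path, index=False)


def cells_to_geojson(grid: OccurrenceGrid, cell_size: float = 1.0) -> str:
    """GeoJSON FeatureCollection of square cell polygons (for visualisation)."""
    half = cell_size / 2.0
    feats = []
    rich = grid.richness()
    for i, row in enumerate(grid.cells.itertuples()):
        ring = [
            [row.x - half, row.y - half],
            [row.x + half, row.y - half],
            [row.x + half, row.y + half],
            [row.x - half, row.y + half],
            [row.x - half, row.y - half],
        ]
        feats.append(
            {
                "type": "Feature",
                "properties": {"id": row.id, "richness": int(rich[i])},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})
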