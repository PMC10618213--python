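"""Protected-area and priority-area coverage of endemism hotspots.

A :class:`ProtectionScheme` is a binary per-cell protected flag — either
an existing protected-area mask (any-overlap at cell level) or the
best-ranked top-k% cells of a conservation priority ranking (top 17%,
30% and 50% correspond to the CBD 2020, COP15 30x30 and Half-Earth
targets). Coverage is reported per hotspot class: A-only hotspots, B-only
hotspots, joint hotspots, and non-hotspots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .canape import CanapeClassification, round_half_away

logger = logging.getLogger(__name__)

__all__ = ["ProtectionScheme", "priority_mask", "coverage_by_class", "hotspot_classes"]


@dataclass
class ProtectionScheme:
    """Binary per-cell protected flag with provenance metadata.

    For real protected-area masks the upstream filtering rules (e.g. IUCN
    categories I-VI, designated/inscribed/established status, no UNESCO
    MAB reserves, no point-only records) belong in ``metadata``; they are
    provenance, not behaviour.
    """

    name: str
    protected: pd.Series  # bool, indexed by cell_id
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protected = self.protected.astype(bool)

    @property
    def coverage_fraction(self) -> float:
        return float(self.protected.mean())


def priority_mask(priority_rank: pd.Series, fraction: float, name: str | None = None) -> ProtectionScheme:
    """Protect the best-ranked ``ceil(fraction * n)`` cells of a ranking.

    ``priority_rank`` gives rank 1 to the highest-priority cell. Ties are
    resolved by stable cell order (and logged); nested fractions give
    nested masks.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(priority_rank)
    n_protect = ceil(fraction * n)
    if priority_rank.duplicated().any():
        logger.info("priority ranking has ties; resolving by stable cell order")
    order = priority_rank.reset_index(drop=True).sort_values(kind="stable").index
    flags = np.zeros(n, dtype=bool)
    flags[order[:n_protect]] = True
    return ProtectionScheme(
        name=name or f"top{round(100 * fraction)}",
        protected=pd.Series(flags, index=priority_rank.index),
    )


def hotspot_classes(
    class_a: CanapeClassification, class_b: CanapeClassification
) -> pd.Series:
    """Partition the shared analysed cells into four hotspot classes.

    Classes: ``A_only``, ``B_only``, ``joint`` (hotspot in both) and
    ``non_hotspot``. Only cells analysed in both classifications are
    labelled.
    """
    cells = class_a.analysed_cells.intersection(class_b.analysed_cells)
    if len(cells) == 0:
        raise ValueError("classifications share no analysed cells")
    hot_a = class_a.hotspot.reindex(cells).fillna(False)
    hot_b = class_b.hotspot.reindex(cells).fillna(False)
    out = pd.Series("non_hotspot", index=cells, dtype=object)
    out[hot_a & ~hot_b] = "A_only"
    out[~hot_a & hot_b] = "B_only"
    out[hot_a & hot_b] = "joint"
    return out.rename("hotspot_class")


def coverage_by_class(
    class_a: CanapeClassification,
    class_b: CanapeClassification,
    scheme: ProtectionScheme,
) -> pd.DataFrame:
    """Protected percentage of each hotspot class under one scheme.

    Classes with zero cells are reported with NaN coverage (undefined),
    never dropped. The report always carries its denominators.
    """
    classes = hotspot_classes(class_a, class_b)
    missing = classes.index.difference(scheme.protected.index)
    if len(missing):
        raise ValueError(f"scheme lacks {len(missing)} analysed cells")
    prot = scheme.protected.reindex(classes.index)
    rows = []
    for cls in ("A_only", "B_only", "joint", "non_hotspot"):
        mask = classes == cls
        n_cls = int(mask.sum())
        n_prot = int((mask & prot).sum())
        pct = round_half_away(100.0 * n_prot / n_cls) if n_cls else float("nan")
        rows.append((scheme.name, cls, n_cls, n_prot, pct))
    return pd.DataFrame(
        rows, columns=["scheme", "class", "n_cells", "n_protected", "pct_protected"]
    )
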