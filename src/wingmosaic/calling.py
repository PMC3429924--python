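"""Scoring rules: identify mwh cells and merge them into clones.

The two field rules implemented here:

* a single cell is scored mwh if it carries at least two trichomes pointing
  in different directions (operationalised as distinct 45-degree orientation
  sectors); cells with three or more trichomes are scored mwh regardless of
  orientation;
* two mwh cells belong to one clone when they lie on the same wing surface
  and are separated by no more than ``max_gap`` (default 3) normal cells.
  The separation is measured as the Chebyshev gap
  ``max(|dx|, |dy|) - 1`` — the number of intervening lattice cells along
  the widest axis — and clone membership is the transitive closure of the
  pairwise link relation.

The hinge region is excluded from the screen before any scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .records import SURFACES, WingRecord
from .stats import size_class

__all__ = [
    "CloneCall",
    "MalformedCellError",
    "EmptyScreenError",
    "call_mwh_cells",
    "merge_clones",
    "apply_hinge_mask",
    "call_wing",
    "call_wings",
]


class MalformedCellError(ValueError):
    """A cell without trichomes cannot be scored."""


class EmptyScreenError(ValueError):
    """The hinge mask removed every cell; nothing left to screen."""


@dataclass(frozen=True)
class CloneCall:
    """One called mwh clone: a merge-component of mwh cells on one surface."""

    wing_id: str
    group: str
    surface: str
    clone_id: int
    cells: tuple[tuple[int, int], ...]

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def size_class(self) -> int:
        return size_class(self.size)


def _is_mwh(n: int, orientations: Sequence[int], min_trichomes_solo: int) -> bool:
    if n < 1:
        raise MalformedCellError(f"cell with {n} trichomes cannot be scored")
    if n > min_trichomes_solo:
        return True
    if n == min_trichomes_solo:
        return len(set(orientations)) >= 2
    return False


def call_mwh_cells(
    wing: WingRecord, min_trichomes_solo: int = 2
) -> dict[str, np.ndarray]:
    """Score every screened cell; return mwh coordinates per surface.

    A cell is mwh iff it has more than ``min_trichomes_solo`` trichomes, or
    exactly that many pointing into at least two distinct sectors. Hinge
    (excluded) cells are ignored entirely.
    """
    scr = wing.screened()
    counts = scr["n_trichomes"].to_numpy()
    if (counts < 1).any():
        idx = int(np.argmax(counts < 1))
        row = scr.iloc[idx]
        raise MalformedCellError(
            f"wing {wing.wing_id}: cell ({row['surface']},{row['x']},{row['y']}) "
            f"has {row['n_trichomes']} trichomes"
        )
    called = counts > min_trichomes_solo
    at_threshold = np.flatnonzero(counts == min_trichomes_solo)
    orients = scr["orientations"].to_numpy(dtype=object)
    for i in at_threshold.tolist():
        called[i] = len(set(orients[i])) >= 2

    out: dict[str, np.ndarray] = {}
    surfaces = scr["surface"].to_numpy()
    xy = scr[["x", "y"]].to_numpy(dtype=np.int64)
    for surface in SURFACES:
        mask = called & (surfaces == surface)
        out[surface] = xy[mask]
    return out


def _components(coords: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Connected components under Chebyshev gap <= max_gap.

    Two cells link when ``max(|dx|, |dy|) <= max_gap + 1``. Uses a KD-tree
    with the infinity norm for the candidate pairs and a disjoint-set union
    for the closure.
    """
    n = len(coords)
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_gap + 1, p=np.inf, output_type="ndarray")

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    comps = [np.flatnonzero(roots == r) for r in np.unique(roots)]
    return comps


def merge_clones(
    mwh_cells: dict[str, np.ndarray],
    max_gap: int = 3,
    wing_id: str = "",
    group: str = "",
) -> list[CloneCall]:
    """Merge called cells into clones by the separation rule.

    Cells at Chebyshev gap <= ``max_gap`` (i.e. at most ``max_gap``
    intervening normal cells) on the same surface are linked; clones are the
    transitive closure. Output is sorted by (surface, minimum member
    coordinate) with member cells sorted, so the call is order-invariant.
    """
    calls: list[CloneCall] = []
    clone_counter = 0
    for surface in SURFACES:
        coords = np.asarray(mwh_cells.get(surface, np.empty((0, 2), dtype=np.int64)))
        comps = _components(coords, max_gap)
        members = [
            tuple(sorted(map(tuple, coords[comp].tolist()))) for comp in comps
        ]
        for cells in sorted(members):
            calls.append(
                CloneCall(
                    wing_id=wing_id,
                    group=group,
                    surface=surface,
                    clone_id=clone_counter,
                    cells=tuple((int(x), int(y)) for x, y in cells),
                )
            )
            clone_counter += 1
    return calls


def apply_hinge_mask(
    wing: WingRecord,
    mask: Callable[[np.ndarray, np.ndarray], np.ndarray] | int | None,
) -> WingRecord:
    """Flag hinge cells as excluded from the screen.

    ``mask`` is either an x-threshold (cells with ``x < mask`` excluded, the
    usual proximal-hinge geometry) or a vectorised predicate ``(x, y) ->
    bool array`` marking excluded cells; ``None`` is the identity.
    """
    out = wing.copy()
    if mask is None:
        return out
    x = out.cells["x"].to_numpy()
    y = out.cells["y"].to_numpy()
    excluded = x < mask if isinstance(mask, (int, np.integer)) else np.asarray(
        mask(x, y), dtype=bool
    )
    out.cells["excluded"] = excluded
    out.hinge_excluded = True
    if out.screened_cells == 0:
        raise EmptyScreenError(
            f"wing {wing.wing_id}: hinge mask excludes every cell"
        )
    return out


def call_wing(
    wing: WingRecord,
    max_gap: int = 3,
    hinge_mask: Callable | int | None = None,
    min_trichomes_solo: int = 2,
) -> list[CloneCall]:
    """Full scoring of one wing: mask, call cells, merge into clones."""
    masked = apply_hinge_mask(wing, hinge_mask)
    cells = call_mwh_cells(masked, min_trichomes_solo=min_trichomes_solo)
    return merge_clones(cells, max_gap=max_gap, wing_id=wing.wing_id, group=wing.group)


def call_wings(
    wings: Iterable[WingRecord],
    max_gap: int = 3,
    hinge_mask: Callable | int | None = None,
    min_trichomes_solo: int = 2,
) -> list[CloneCall]:
    """Score a cohort of wings; concatenated, deterministic clone list."""
    calls: list[CloneCall] = []
    for wing in wings:
        calls.extend(
            call_wing(
                wing,
                max_gap=max_gap,
                hinge_mask=hinge_mask,
                min_trichomes_solo=min_trichomes_solo,
            )
        )
    return calls
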