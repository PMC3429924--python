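"""Core data containers: one wing's cell table and its invariants."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WingRecord", "CELL_COLUMNS", "SURFACES"]

SURFACES = ("D", "V")  # dorsal / ventral wing-blade surfaces

#: canonical column order of the per-cell table
CELL_COLUMNS = [
    "surface",
    "x",
    "y",
    "n_trichomes",
    "orientations",
    "true_label",
    "true_clone_id",
]


@dataclass
class WingRecord:
    """One wing: per-cell lattice records on two surfaces.

    ``cells`` columns:

    surface : {"D", "V"}
    x, y : int
        0-based lattice coordinates, unique per surface.
    n_trichomes : int
        Number of trichomes on the cell (>= 1 once rendered; 0 marks a
        not-yet-rendered cell).
    orientations : tuple[int, ...]
        Orientation sector (0-7, 45 degrees each) of every trichome;
        length equals ``n_trichomes``.
    true_label : int
        Ground truth, 1 for a labeled (mwh) cell, 0 for wild type, -1 when
        unknown (hand-curated data).
    true_clone_id : int
        Ground-truth clone id (-1 for wild type / unknown).
    excluded : bool
        True for hinge-region cells removed from the screen.
    """

    wing_id: str
    group: str
    cells: pd.DataFrame
    hinge_excluded: bool = field(default=False)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"wing {self.wing_id}: missing cell columns {missing}")
        if "excluded" not in self.cells.columns:
            self.cells = self.cells.assign(excluded=False)
        bad_surface = set(self.cells["surface"].unique()) - set(SURFACES)
        if bad_surface:
            raise ValueError(
                f"wing {self.wing_id}: unknown surface token(s) {sorted(bad_surface)}"
            )
        dup = self.cells.duplicated(subset=["surface", "x", "y"])
        if dup.any():
            row = self.cells[dup].iloc[0]
            raise ValueError(
                f"wing {self.wing_id}: duplicate coordinate "
                f"({row['surface']},{row['x']},{row['y']})"
            )

    @property
    def screened_cells(self) -> int:
        """C: the number of cells entering the clone screen (hinge excluded)."""
        return int((~self.cells["excluded"]).sum())

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def screened(self) -> pd.DataFrame:
        return self.cells[~self.cells["excluded"]]

    def true_clone_sizes(self) -> dict[int, int]:
        """Ground-truth clone sizes among screened cells (empty if unknown)."""
        scr = self.screened()
        labeled = scr[scr["true_label"] == 1]
        if labeled.empty:
            return {}
        return labeled.groupby("true_clone_id").size().to_dict()

    def copy(self) -> "WingRecord":
        return WingRecord(
            wing_id=self.wing_id,
            group=self.group,
            cells=self.cells.copy(),
            hinge_excluded=self.hinge_excluded,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_lab = int((self.cells["true_label"] == 1).sum())
        return (
            f"WingRecord({self.wing_id!r}, group={self.group!r}, "
            f"cells={self.n_cells}, labeled={n_lab})"
        )


def surface_coords(record: WingRecord, surface: str) -> np.ndarray:
    """(n, 2) int array of screened coordinates on one surface."""
    scr = record.screened()
    sub = scr[scr["surface"] == surface]
    return sub[["x", "y"]].to_numpy(dtype=np.int64)
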