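"""Tab-separated on-disk formats for wing-cell and clone tables.

Wing-cell tables are TSV with a versioned ``#wingmosaic wing-table v1``
comment line followed by a header row. Columns::

    wing_id  group  surface  x  y  n_trichomes  orientations  true_label  true_clone_id

``orientations`` holds comma-separated sector indices 0-7 (empty for an
unrendered cell). The truth columns may be empty in hand-curated tables and
are then read back as -1 (unknown).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import CELL_COLUMNS, SURFACES, WingRecord

__all__ = [
    "WING_TABLE_VERSION",
    "write_wing_table",
    "read_wing_table",
    "write_clone_table",
    "read_clone_table",
]

WING_TABLE_VERSION = "v1"
_WING_MAGIC = f"#wingmosaic wing-table {WING_TABLE_VERSION}"
_CLONE_MAGIC = f"#wingmosaic clone-table {WING_TABLE_VERSION}"

_WING_HEADER = [
    "wing_id",
    "group",
    "surface",
    "x",
    "y",
    "n_trichomes",
    "orientations",
    "true_label",
    "true_clone_id",
]


class WingTableError(ValueError):
    """Malformed wing/clone table; the message carries a row diagnostic."""


def write_wing_table(wings: Iterable[WingRecord], path: str | Path) -> None:
    """Serialise wings to one TSV; round-trips all fields including truth."""
    frames = []
    for wing in wings:
        df = wing.cells[CELL_COLUMNS].copy()
        df.insert(0, "wing_id", wing.wing_id)
        df.insert(1, "group", wing.group)
        df["orientations"] = [
            ",".join(str(s) for s in o) for o in df["orientations"]
        ]
        frames.append(df)
    buf = _io.StringIO()
    buf.write(_WING_MAGIC + "\n")
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_WING_HEADER)
    table.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def _fail(path: str | Path, row: int | str, msg: str) -> None:
    raise WingTableError(f"{path}, row {row}: {msg}")


def read_wing_table(path: str | Path) -> list[WingRecord]:
    """Parse a wing-cell TSV back into :class:`WingRecord` objects.

    Rejects unknown versions, missing columns, duplicate coordinates,
    unknown surface tokens and malformed orientation lists, each with a
    row-level diagnostic.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _WING_MAGIC:
            _fail(path, 1, f"expected header {_WING_MAGIC!r}, got {first!r}")
        table = pd.read_csv(
            fh,
            sep="\t",
            dtype={
                "wing_id": str,
                "group": str,
                "surface": str,
                "orientations": str,
            },
            keep_default_na=False,
            na_values=[],
        )
    missing = [c for c in _WING_HEADER[:7] if c not in table.columns]
    if missing:
        _fail(path, 2, f"missing required columns {missing}")
    for col in ("true_label", "true_clone_id"):
        if col not in table.columns:
            table[col] = -1
    if table.empty:
        return []

    for col in ("x", "y", "n_trichomes", "true_label", "true_clone_id"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & (table[col].astype(str).str.strip() != "")
        if bad.any():
            _fail(path, int(bad.idxmax()) + 3, f"non-integer value in column {col!r}")
        table[col] = coerced.fillna(-1).astype(np.int64)

    bad_surface = ~table["surface"].isin(SURFACES)
    if bad_surface.any():
        row = int(bad_surface.idxmax())
        _fail(path, row + 3, f"unknown surface token {table['surface'].iloc[row]!r}")

    dup = table.duplicated(subset=["wing_id", "surface", "x", "y"])
    if dup.any():
        row = int(dup.idxmax())
        r = table.iloc[row]
        _fail(
            path,
            row + 3,
            f"duplicate coordinate ({r['surface']},{r['x']},{r['y']}) "
            f"in wing {r['wing_id']!r}",
        )

    def parse_orient(value: str, row: int) -> tuple[int, ...]:
        value = value.strip()
        if not value:
            return ()
        try:
            sectors = tuple(int(v) for v in value.split(","))
        except ValueError:
            _fail(path, row + 3, f"malformed orientations {value!r}")
        if any(not 0 <= s <= 7 for s in sectors):
            _fail(path, row + 3, f"orientation sector out of range in {value!r}")
        return sectors

    table["orientations"] = [
        parse_orient(v, i) for i, v in enumerate(table["orientations"])
    ]
    mismatch = table["n_trichomes"] != table["orientations"].map(len)
    mismatch &= table["n_trichomes"] > 0
    if mismatch.any():
        _fail(path, int(mismatch.idxmax()) + 3, "n_trichomes != len(orientations)")

    wings = []
    for (wing_id, group), sub in table.groupby(["wing_id", "group"], sort=True):
        cells = sub[CELL_COLUMNS].reset_index(drop=True)
        wings.append(WingRecord(wing_id=str(wing_id), group=str(group), cells=cells))
    return wings


def write_clone_table(clones: Sequence, path: str | Path) -> None:
    """Write called clones as TSV (one row per clone, cells packed)."""
    rows = []
    for c in clones:
        rows.append(
            {
                "wing_id": c.wing_id,
                "group": c.group,
                "surface": c.surface,
                "clone_id": c.clone_id,
                "size": c.size,
                "size_class": c.size_class,
                "cells": ";".join(f"{x},{y}" for x, y in c.cells),
            }
        )
    buf = _io.StringIO()
    buf.write(_CLONE_MAGIC + "\n")
    pd.DataFrame(
        rows,
        columns=["wing_id", "group", "surface", "clone_id", "size", "size_class", "cells"],
    ).to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_clone_table(path: str | Path) -> pd.DataFrame:
    """Read a clone table as a tidy DataFrame (cells parsed to tuples)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _CLONE_MAGIC:
            _fail(path, 1, f"expected header {_CLONE_MAGIC!r}, got {first!r}")
        table = pd.read_csv(
            fh, sep="\t", dtype={"wing_id": str, "group": str, "surface": str, "cells": str},
            keep_default_na=False, na_values=[],
        )
    if table.empty:
        return table
    table["cells"] = [
        tuple(tuple(int(v) for v in xy.split(",")) for xy in s.split(";")) if s else ()
        for s in table["cells"]
    ]
    return table
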