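"""File I/O: TIFF stacks with JSON sidecars, layout and result tables.

Stacks are written as multi-page TIFF in time x channel x y x x order with a
sidecar JSON (same basename, ``.json``) declaring axis order, channel names,
frame times and the dispense index. Tables are UTF-8 comma-separated CSV
with a header row; well ids are zero-padded (A01). Pixel coordinates are
0-based (row, col).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layout import PlateLayout, Well
from .stacks import CHANNELS, Timebase, TimeLapseStack

__all__ = [
    "write_stack",
    "read_stack",
    "read_layout",
    "write_layout",
    "write_results",
]

LAYOUT_COLUMNS = ("well_id", "role", "compound_id", "concentration_uM", "replicate")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: TimeLapseStack, path) -> Path:
    """Write a stack as TIFF plus sidecar JSON; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(stack.frames), photometric="minisblack"
    )  # dtype preserved; channel axis is spectral, not RGB
    sidecar = {
        "axes": "TCYX",
        "channels": list(stack.channels),
        "times_s": [float(t) for t in stack.timebase.times],
        "dispense_index": int(stack.timebase.dispense_index),
        "well_id": stack.well_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> TimeLapseStack:
    """Read a TIFF + sidecar pair back into a validated stack."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"stack sidecar {sidecar_path.name} missing next to {path.name}"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("axes", "channels", "times_s", "dispense_index"):
        if key not in meta:
            raise ValueError(f"stack sidecar {sidecar_path.name} lacks field {key!r}")
    frames = tifffile.imread(path)
    if frames.ndim == 3:  # single-channel page collapse guard
        raise ValueError(f"{path.name}: expected 4-D TCYX data")
    axes = meta["axes"]
    if set(axes) != set("TCYX"):
        raise ValueError(f"unsupported axis order {axes!r}")
    frames = np.moveaxis(
        frames, [axes.index(a) for a in "TCYX"], [0, 1, 2, 3]
    )
    channels = tuple(meta["channels"])
    missing = [c for c in CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"{path.name}: stack missing channel(s) {missing}")
    # normalize channel order to the canonical one
    order = [channels.index(c) for c in CHANNELS]
    frames = frames[:, order]
    tb = Timebase(
        times=np.asarray(meta["times_s"], dtype=float),
        dispense_index=int(meta["dispense_index"]),
    )
    return TimeLapseStack(
        frames=frames, timebase=tb, well_id=meta.get("well_id", path.stem)
    )


def write_layout(layout: PlateLayout, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    layout.to_frame().to_csv(path, index=False)
    return path


def read_layout(path, plate_id: str | None = None) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    Rejects unknown roles and duplicate well ids with the offending row
    number (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str}, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path.name}: layout is empty")
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: layout lacks column(s) {missing}")
    layout = PlateLayout(plate_id=plate_id or path.stem)
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            layout.add(
                Well(
                    well_id=str(row.well_id),
                    role=str(row.role),
                    compound_id=str(row.compound_id),
                    concentration_um=float(row.concentration_uM or 0.0),
                    replicate=int(row.replicate or 0),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} row {row_no}: {exc}") from None
    layout.validate()
    return layout


def write_results(tables: dict, outdir) -> dict:
    """Write named DataFrames as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
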