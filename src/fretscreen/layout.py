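"""384-well plate layouts: well roles, compounds, concentrations, replicates."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognized well roles. TP (thapsigargin), CPA (cyclopiazonic acid) and
#: TMB-8 are pharmacological positive controls that suppress agonist-evoked
#: ER calcium release; DMSO is the vehicle negative control.
ROLES = ("compound", "DMSO", "untreated", "TP", "CPA", "TMB-8")
CONTROL_ROLES = ("TP", "CPA", "TMB-8")

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24


def well_name(index: int) -> str:
    """Row-major well id on a 384-well plate: 0 -> 'A01', 383 -> 'P24'."""
    if not 0 <= index < len(ROWS) * N_COLS:
        raise ValueError(f"well index {index} outside a 384-well plate")
    return f"{ROWS[index // N_COLS]}{index % N_COLS + 1:02d}"


@dataclass
class Well:
    well_id: str
    role: str
    compound_id: str = ""
    concentration_um: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for well {self.well_id}")


@dataclass
class PlateLayout:
    """Ordered mapping well_id -> :class:`Well` for one plate."""

    wells: dict = field(default_factory=dict)
    plate_id: str = "plate01"

    def add(self, well: Well) -> None:
        if well.well_id in self.wells:
            raise ValueError(f"duplicate well {well.well_id}")
        self.wells[well.well_id] = well

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells.values())

    def by_role(self, role: str) -> list:
        return [w for w in self if w.role == role]

    @property
    def compounds(self) -> list:
        seen: dict = {}
        for w in self:
            if w.role == "compound" and w.compound_id not in seen:
                seen[w.compound_id] = None
        return list(seen)

    def validate(self) -> None:
        if len(self) > len(ROWS) * N_COLS:
            raise ValueError("more than 384 wells on a plate")
        if not self.by_role("DMSO"):
            raise ValueError("plate has no DMSO (vehicle) well")
        if not self.by_role("TP"):
            raise ValueError("plate has no TP positive-control well")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well_id": w.well_id,
                    "role": w.role,
                    "compound_id": w.compound_id,
                    "concentration_uM": w.concentration_um,
                    "replicate": w.replicate,
                }
                for w in self
            ]
        )


def make_layout(
    compound_ids,
    n_replicates: int = 4,
    concentration_um: float = 10.0,
    n_dmso: int = 16,
    n_tp: int = 16,
    n_cpa: int = 4,
    n_tmb8: int = 4,
    n_untreated: int = 4,
    plate_id: str = "plate01",
) -> PlateLayout:
    """Lay out a screening plate: each compound in ``n_replicates`` wells at a
    single concentration (10 µM by default, the primary-screen dose), plus
    vehicle, untreated and suppressor-control wells.
    """
    layout = PlateLayout(plate_id=plate_id)
    cursor = 0

    def take() -> str:
        nonlocal cursor
        name = well_name(cursor)
        cursor += 1
        return name

    for role, count in (
        ("DMSO", n_dmso),
        ("TP", n_tp),
        ("CPA", n_cpa),
        ("TMB-8", n_tmb8),
        ("untreated", n_untreated),
    ):
        for i in range(count):
            layout.add(Well(take(), role, replicate=i + 1))
    for cid in compound_ids:
        for rep in range(1, n_replicates + 1):
            layout.add(
                Well(take(), "compound", str(cid), concentration_um, rep)
            )
    layout.validate()
    return layout
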