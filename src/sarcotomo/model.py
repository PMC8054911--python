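"""In-memory container for a sarcomere coordinate model.

Tables are pandas DataFrames; coordinates are in Å with the filament
axis along +Y.  Thin-filament polarity follows the tomographic
observation that the actin barbed end faces the Z-disc, so in A/I-band
models the +Y direction points from the M-band toward the Z-disc.

Table schemas
-------------
filaments : id (index), kind {thin, thick}, polarity, x, z (lateral Å),
    y0 (axial start Å), length (Å), ax/ay/az (unit axis), neighbors
    (comma-joined thick-filament ids for thin filaments, else "").
subunits : subunit_id (index), filament_id, k, x, y, z, azimuth (deg),
    strand {0, 1}, optionally tpm_offset (deg).
heads : myosin_id, head_slot {a, b}, origin_thick_id, subunit_id,
    klass {double, single, split}, x, y, z.
crosslinks : id (index), fil_a, fil_b, sub_a, sub_b, cx, cy, cz,
    ux, uy, uz (unit link axis), center_distance_nm, length_nm, angle_deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

FILAMENT_COLUMNS = ["kind", "polarity", "x", "z", "y0", "length",
                    "ax", "ay", "az", "neighbors"]
SUBUNIT_COLUMNS = ["filament_id", "k", "x", "y", "z", "azimuth", "strand"]
HEAD_COLUMNS = ["myosin_id", "head_slot", "origin_thick_id", "subunit_id",
                "klass", "x", "y", "z"]
CROSSLINK_COLUMNS = ["fil_a", "fil_b", "sub_a", "sub_b", "ya", "yb",
                     "cx", "cy", "cz", "ux", "uy", "uz",
                     "center_distance_nm", "length_nm", "angle_deg"]


def empty_filaments() -> pd.DataFrame:
    df = pd.DataFrame(columns=FILAMENT_COLUMNS)
    df.index.name = "id"
    return df


def empty_subunits() -> pd.DataFrame:
    df = pd.DataFrame(columns=SUBUNIT_COLUMNS)
    df.index.name = "subunit_id"
    return df


def empty_heads() -> pd.DataFrame:
    return pd.DataFrame(columns=HEAD_COLUMNS)


def empty_crosslinks() -> pd.DataFrame:
    df = pd.DataFrame(columns=CROSSLINK_COLUMNS)
    df.index.name = "id"
    return df


@dataclass
class SarcomereModel:
    """Ground-truth (or imported) sarcomere coordinate model."""

    filaments: pd.DataFrame = field(default_factory=empty_filaments)
    subunits: pd.DataFrame = field(default_factory=empty_subunits)
    heads: pd.DataFrame = field(default_factory=empty_heads)
    crosslinks: pd.DataFrame = field(default_factory=empty_crosslinks)
    meta: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def thin_ids(self) -> np.ndarray:
        return self.filaments.index[self.filaments["kind"] == "thin"].to_numpy()

    def thick_ids(self) -> np.ndarray:
        return self.filaments.index[self.filaments["kind"] == "thick"].to_numpy()

    def neighbors_of(self, thin_id: int) -> list[int]:
        s = self.filaments.loc[thin_id, "neighbors"]
        return [int(t) for t in str(s).split(",") if t != ""]

    def filament_axis_point(self, fil_id: int, y: float) -> np.ndarray:
        """Point on a (straight) filament axis at axial coordinate y (Å)."""
        row = self.filaments.loc[fil_id]
        return np.array([row["x"], y, row["z"]], dtype=float)

    def validate(self) -> None:
        """Raise AssertionError on referential-integrity violations."""
        if len(self.heads):
            assert self.heads["subunit_id"].isin(self.subunits.index).all(), \
                "head references a missing subunit"
            assert not self.heads["subunit_id"].duplicated().any(), \
                "a subunit is bound by more than one head"
            per_myosin = self.heads.groupby("myosin_id")["origin_thick_id"].nunique()
            assert (per_myosin == 1).all(), \
                "two heads of one myosin disagree on their origin thick filament"
        if len(self.subunits):
            assert self.subunits["filament_id"].isin(self.filaments.index).all(), \
                "subunit references a missing filament"
        if len(self.crosslinks):
            for col in ("fil_a", "fil_b"):
                assert self.crosslinks[col].isin(self.filaments.index).all(), \
                    f"crosslink {col} references a missing filament"
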