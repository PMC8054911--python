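"""File I/O: MRC2014 volumes, model TSV/JSON bundles, STAR particle tables.

Coordinates in files are Å with 0-based voxel indices and axis order
(x, y, z); the filament axis is +Y.  Volumes go through gemmi's
CCP4/MRC reader-writer (mode 2, voxel size in the header); particle
tables are parsed with gemmi's STAR/CIF parser.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, SchemaError
from .model import (CROSSLINK_COLUMNS, FILAMENT_COLUMNS, HEAD_COLUMNS,
                    SUBUNIT_COLUMNS, SarcomereModel, empty_crosslinks,
                    empty_heads, empty_subunits)
from .tracing import FilamentTrace


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """Density grid indexed [x, y, z]; voxel_size in Å; origin in Å."""

    data: np.ndarray
    voxel_size: float
    origin: tuple = (0.0, 0.0, 0.0)


def write_volume(volume: Volume, path: str) -> None:
    """Write a volume as MRC2014 mode 2 (float32), voxel size in the header."""
    import gemmi

    data = np.ascontiguousarray(volume.data.astype(np.float32))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    nx, ny, nz = data.shape
    vs = volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * vs, ny * vs, nz * vs, 90, 90, 90)
    m.update_ccp4_header()
    # MRC2014 ORIGIN field: header words 50-52
    for w, v in zip((50, 51, 52), volume.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(path)


def read_volume(path: str) -> Volume:
    """Read an MRC2014 volume; voxel size and origin come from the header."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC volume {path!r}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    vs = cell.a / data.shape[0]
    origin = tuple(m.header_float(w) for w in (50, 51, 52))
    return Volume(data=data, voxel_size=float(vs), origin=origin)


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

_TABLES = {
    "filaments.tsv": ("filaments", FILAMENT_COLUMNS, "id"),
    "subunits.tsv": ("subunits", SUBUNIT_COLUMNS, "subunit_id"),
    "heads.tsv": ("heads", HEAD_COLUMNS, None),
    "crosslinks.tsv": ("crosslinks", CROSSLINK_COLUMNS, "id"),
}


def write_model(model: SarcomereModel, out_dir: str) -> None:
    """Serialize a model as one JSON metadata file plus TSV tables."""
    os.makedirs(out_dir, exist_ok=True)
    meta = dict(model.meta)
    meta["seed"] = model.seed
    with open(os.path.join(out_dir, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    for fname, (attr, _cols, index) in _TABLES.items():
        df = getattr(model, attr)
        df.to_csv(os.path.join(out_dir, fname), sep="\t",
                  index=index is not None)


def read_model(in_dir: str) -> SarcomereModel:
    """Read a serialized model, validating schema and referential integrity."""
    meta_path = os.path.join(in_dir, "model.json")
    if not os.path.exists(meta_path):
        raise FormatError(f"missing model.json in {in_dir!r}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    seed = meta.pop("seed", None)
    tables = {}
    for fname, (attr, cols, index) in _TABLES.items():
        path = os.path.join(in_dir, fname)
        if not os.path.exists(path):
            raise FormatError(f"missing table {fname!r} in {in_dir!r}")
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in cols if c not in df.columns]
        # tpm_offset is optional; core columns are not
        if missing:
            raise SchemaError(f"{fname}: missing column(s) {missing}")
        if index is not None:
            if index not in df.columns:
                raise SchemaError(f"{fname}: missing index column {index!r}")
            df = df.set_index(index)
        if "neighbors" in df.columns:
            df["neighbors"] = df["neighbors"].fillna("").astype(str)
        tables[attr] = df
    model = SarcomereModel(seed=seed, meta=meta, **tables)
    _check_integrity(model)
    return model


def _check_integrity(model: SarcomereModel) -> None:
    problems = []
    if len(model.subunits):
        bad = model.subunits.index[
            ~model.subunits["filament_id"].isin(model.filaments.index)]
        if len(bad):
            problems.append(f"subunits with dangling filament_id: {list(bad[:10])}")
    if len(model.heads):
        ok = (model.heads["subunit_id"] == -1) | \
            model.heads["subunit_id"].isin(model.subunits.index)
        if not ok.all():
            problems.append(
                f"heads rows with dangling subunit_id: {list(model.heads.index[~ok][:10])}")
    if len(model.crosslinks):
        for col in ("fil_a", "fil_b"):
            bad = model.crosslinks.index[
                ~model.crosslinks[col].isin(model.filaments.index)]
            if len(bad):
                problems.append(f"crosslinks with dangling {col}: {list(bad[:10])}")
    if problems:
        raise IntegrityError("; ".join(problems))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_traces(traces: Sequence[FilamentTrace], path: str) -> None:
    rows = []
    for tr in traces:
        for i, p in enumerate(tr.points):
            rows.append(dict(trace_id=tr.id, kind=tr.kind, point_index=i,
                             x=p[0], y=p[1], z=p[2]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_traces(path: str) -> list[FilamentTrace]:
    df = pd.read_csv(path, sep="\t")
    for col in ("trace_id", "point_index", "x", "y", "z"):
        if col not in df.columns:
            raise SchemaError(f"traces file missing column {col!r}")
    out = []
    for tid, grp in df.groupby("trace_id"):
        grp = grp.sort_values("point_index")
        kind = grp["kind"].iloc[0] if "kind" in grp.columns else "unknown"
        out.append(FilamentTrace(id=int(tid),
                                 points=grp[["x", "y", "z"]].to_numpy(float),
                                 kind=str(kind)))
    return out


# ---------------------------------------------------------------------------
# STAR interop
# ---------------------------------------------------------------------------

def read_star_particles(path: str, angpix: float = 1.0) -> pd.DataFrame:
    """Import particle coordinates from a RELION-style STAR file.

    Reads _rlnCoordinateX/Y/Z (multiplied by ``angpix`` to get Å) and,
    when present, _rlnOriginX/Y/ZAngst shifts; Euler angles are ignored,
    positions used.  Returns a table with x, y, z columns in Å.
    """
    import gemmi

    try:
        doc = gemmi.cif.read_file(path)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse STAR file {path!r}: {exc}") from exc
    for block in doc:
        xs = block.find_loop("_rlnCoordinateX")
        if len(list(xs)):
            cols = {}
            for name, tag in (("x", "_rlnCoordinateX"),
                              ("y", "_rlnCoordinateY"),
                              ("z", "_rlnCoordinateZ")):
                vals = list(block.find_loop(tag))
                if not vals:
                    raise SchemaError(f"STAR file missing {tag}")
                cols[name] = np.asarray(vals, dtype=float) * angpix
            df = pd.DataFrame(cols)
            for ax, tag in (("x", "_rlnOriginXAngst"),
                            ("y", "_rlnOriginYAngst"),
                            ("z", "_rlnOriginZAngst")):
                vals = list(block.find_loop(tag))
                if vals:
                    df[ax] -= np.asarray(vals, dtype=float)
            return df
    raise SchemaError("no _rlnCoordinateX loop found in STAR file")
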