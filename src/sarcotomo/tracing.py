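"""Filament tracing in density volumes.

Mirrors the tomographic picking workflow: an equatorial Fourier filter
on XY slices removes cross-bridge signal, filaments then appear as dense
dots in cross-section (XZ) views, a Laplacian-of-Gaussian detector finds
them per plane, and a greedy plane-to-plane linker assembles the
detections into 3D traces.  Volumes are indexed [x, y, z] with the
filament axis along +Y (see :class:`sarcotomo.io.Volume`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, ParameterError

__all__ = ["equator_filter", "lowpass_filter", "detect_cross_sections",
           "link_detections", "measure_lattice", "FilamentTrace",
           "traces_from_model"]


# ---------------------------------------------------------------------------
# Fourier filters
# ---------------------------------------------------------------------------

def equator_filter(data: np.ndarray, keep_halfwidth: float = 0.05) -> np.ndarray:
    """Equatorial band mask in the Fourier transform of every XY slice.

    Filaments run along Y, so their slice spectra concentrate on the
    equator (ky ~ 0) while transverse cross-bridge features spread along
    ky.  Components with |ky| > keep_halfwidth (cycles/voxel, Nyquist =
    0.5) are zeroed; the DC component always survives.  The filter is a
    projection: applying it twice equals applying it once, and
    keep_halfwidth = 0.5 is the identity.
    """
    if not 0.0 < keep_halfwidth <= 0.5:
        raise ParameterError("keep_halfwidth must be in (0, 0.5]")
    f = np.fft.fft2(data, axes=(0, 1))
    ky = np.abs(np.fft.fftfreq(data.shape[1]))
    keep = ky <= keep_halfwidth + 1e-12
    f *= keep[None, :, None]
    return np.real(np.fft.ifft2(f, axes=(0, 1)))


def lowpass_filter(data: np.ndarray, voxel_size: float,
                   cutoff: float = 60.0) -> np.ndarray:
    """Gaussian low-pass at the given resolution cutoff (Å)."""
    sigma = cutoff / (2.0 * math.pi * voxel_size)
    return ndimage.gaussian_filter(data, sigma)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_cross_sections(volume, blob_sigma: float, threshold: float,
                          plane: str = "XZ",
                          plane_step: int = 1) -> pd.DataFrame:
    """Per-plane blob detection of filament cross-sections.

    Runs a scale-normalized Laplacian-of-Gaussian on every XZ plane
    (fixed y index) and keeps local maxima above ``threshold``, refined
    to sub-voxel precision by a separable quadratic fit.  Returns a
    table with plane_index, x, z (Å, volume frame) and response.
    """
    if plane != "XZ":
        raise ParameterError("only XZ cross-section planes are supported")
    if blob_sigma < volume.voxel_size:
        raise ParameterError("blob_sigma must be >= voxel size")
    s = blob_sigma / volume.voxel_size
    rows = []
    for iy in range(0, volume.data.shape[1], plane_step):
        img = volume.data[:, iy, :].astype(np.float64)
        resp = -(s ** 2) * ndimage.gaussian_laplace(img, s)
        mx = ndimage.maximum_filter(resp, size=3, mode="nearest")
        peaks = np.argwhere((resp == mx) & (resp > threshold))
        for px, pz in peaks:
            dx = _quadratic_offset(resp, px, pz, axis=0)
            dz = _quadratic_offset(resp, px, pz, axis=1)
            rows.append(dict(plane_index=iy,
                             x=volume.origin[0] + (px + dx) * volume.voxel_size,
                             y=volume.origin[1] + iy * volume.voxel_size,
                             z=volume.origin[2] + (pz + dz) * volume.voxel_size,
                             response=float(resp[px, pz])))
    return pd.DataFrame(rows, columns=["plane_index", "x", "y", "z", "response"])


def _quadratic_offset(resp: np.ndarray, i: int, j: int, axis: int) -> float:
    if axis == 0:
        if i == 0 or i == resp.shape[0] - 1:
            return 0.0
        fm, f0, fp = resp[i - 1, j], resp[i, j], resp[i + 1, j]
    else:
        if j == 0 or j == resp.shape[1] - 1:
            return 0.0
        fm, f0, fp = resp[i, j - 1], resp[i, j], resp[i, j + 1]
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:
        return 0.0
    return float(0.5 * (fm - fp) / denom)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

@dataclass
class FilamentTrace:
    """Ordered 3D polyline of one filament axis (Å)."""

    id: int
    points: np.ndarray                      # (n, 3), monotone in y
    kind: str = "unknown"                   # thin / thick / unknown
    polarity: str = "unknown"

    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def position_at(self, y: float) -> Optional[np.ndarray]:
        """Linear interpolation of the lateral position at axial height y."""
        ys = self.points[:, 1]
        if y < ys[0] or y > ys[-1]:
            return None
        i = int(np.searchsorted(ys, y, side="right")) - 1
        i = min(i, len(ys) - 2)
        t = 0.0 if ys[i + 1] == ys[i] else (y - ys[i]) / (ys[i + 1] - ys[i])
        return self.points[i] + t * (self.points[i + 1] - self.points[i])


def link_detections(detections: pd.DataFrame, plane_spacing: Optional[float] = None,
                    max_step: Optional[float] = None, max_kink: float = 20.0,
                    min_length: float = 500.0,
                    max_gap_planes: int = 2) -> list[FilamentTrace]:
    """Greedy nearest-neighbour linking of per-plane detections into traces.

    Detections are consumed plane by plane in axial order; each is
    appended to the open trace whose head is within ``max_step``
    (default 1.5 x inter-plane spacing, scaled by the plane gap) and
    whose direction change stays below ``max_kink`` degrees.  Ambiguities
    are resolved by smallest step, then smallest direction change, then
    lower x, which makes the output deterministic.  Gaps of up to
    ``max_gap_planes`` missing planes are bridged; traces shorter than
    ``min_length`` (Å, axial extent) are discarded.

    ``plane_spacing`` (Å between consecutive analysed planes) is
    inferred from the detections' y coordinates when omitted.
    """
    if detections is None or len(detections) < 1:
        return []
    planes = sorted(detections["plane_index"].unique())
    if "y" not in detections.columns:
        if plane_spacing is None:
            raise ParameterError("detections lack a y column; pass plane_spacing")
        detections = detections.assign(
            y=detections["plane_index"] * plane_spacing)
    if plane_spacing is None:
        ys = np.sort(detections["y"].unique())
        plane_spacing = float(np.median(np.diff(ys))) if len(ys) > 1 else 1.0
    if max_step is None:
        max_step = 1.5 * plane_spacing

    open_traces: list[dict] = []
    closed: list[dict] = []

    for rank, ip in enumerate(planes):
        dets = detections[detections["plane_index"] == ip]
        pts = [np.array([r["x"], r["y"], r["z"]]) for _, r in dets.iterrows()]
        # close stale traces
        still = []
        for tr in open_traces:
            if rank - tr["last_rank"] > max_gap_planes + 1:
                closed.append(tr)
            else:
                still.append(tr)
        open_traces = still

        cands = []
        for ti, tr in enumerate(open_traces):
            head = tr["points"][-1]
            gap = rank - tr["last_rank"]
            for pi, p in enumerate(pts):
                lat = math.hypot(p[0] - head[0], p[2] - head[2])
                if lat > max_step * gap:
                    continue
                step = p - head
                if len(tr["points"]) >= 2:
                    prev = tr["points"][-1] - tr["points"][-2]
                    cosk = np.dot(step, prev) / (np.linalg.norm(step)
                                                 * np.linalg.norm(prev))
                    kink = math.degrees(math.acos(np.clip(cosk, -1, 1)))
                    if kink > max_kink:
                        continue
                else:
                    kink = 0.0
                cands.append((lat, kink, p[0], ti, pi))
        cands.sort()
        used_t, used_p = set(), set()
        for lat, kink, _x, ti, pi in cands:
            if ti in used_t or pi in used_p:
                continue
            open_traces[ti]["points"].append(pts[pi])
            open_traces[ti]["last_rank"] = rank
            used_t.add(ti)
            used_p.add(pi)
        for pi, p in enumerate(pts):
            if pi not in used_p:
                open_traces.append(dict(points=[p], last_rank=rank))

    closed.extend(open_traces)
    traces = []
    tid = 0
    for tr in closed:
        pts = np.asarray(tr["points"])
        if len(pts) < 2:
            continue
        if pts[-1, 1] - pts[0, 1] < min_length:
            continue
        traces.append(FilamentTrace(id=tid, points=pts))
        tid += 1
    return traces


def traces_from_model(model) -> list[FilamentTrace]:
    """Two-point axis traces for every (straight) filament of a model."""
    out = []
    for fid, row in model.filaments.iterrows():
        p0 = np.array([row["x"], row["y0"], row["z"]])
        axis = np.array([row["ax"], row["ay"], row["az"]])
        p1 = p0 + row["length"] * axis
        pts = np.array(sorted([p0, p1], key=lambda p: p[1]))
        out.append(FilamentTrace(id=int(fid), points=pts, kind=row["kind"],
                                 polarity=row["polarity"]))
    return out


# ---------------------------------------------------------------------------
# lattice statistics
# ---------------------------------------------------------------------------

def measure_lattice(traces: Sequence[FilamentTrace], plane_position: float) -> dict:
    """Cross-sectional lattice statistics at one axial height.

    Returns nearest-neighbour distance distributions (nm) per kind pair
    (thick-thick, thin-any) and the 6-fold bond-orientational order
    score psi6 = mean over points of |mean_j exp(6 i theta_j)| over the
    six nearest neighbours (1.0 for a perfect hexagonal lattice).
    """
    pts, kinds = [], []
    for tr in traces:
        p = tr.position_at(plane_position)
        if p is not None:
            pts.append([p[0], p[2]])
            kinds.append(tr.kind)
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 traces crossing the plane")
    pts = np.asarray(pts)
    kinds = np.asarray(kinds)

    def nn_distances(sub_from: np.ndarray, sub_to: np.ndarray, same: bool):
        tree = cKDTree(sub_to)
        k = 2 if same else 1
        d, _ = tree.query(sub_from, k=k)
        return (d[:, -1] if d.ndim > 1 else d) / 10.0

    out: dict = {}
    thick = pts[kinds == "thick"]
    thin = pts[kinds == "thin"]
    if len(thick) >= 2:
        out["thick_thick_nn_nm"] = nn_distances(thick, thick, True)
    if len(thin) >= 1 and len(pts) >= 2:
        others = pts  # nearest neighbour of any kind
        out["thin_neighbor_nn_nm"] = nn_distances(thin, others, True)

    # psi6 over the densest population (thick if present, else all);
    # neighbours = first shell by radius (<= 1.25 x the minimal spacing),
    # so boundary points of a finite patch do not pull in second-shell
    # vectors at 30-degree angles
    ref = thick if len(thick) >= 4 else pts
    if len(ref) >= 4:
        tree = cKDTree(ref)
        d, _ = tree.query(ref, k=2)
        shell = 1.25 * float(np.median(d[:, 1]))
        psis = []
        for i, p in enumerate(ref):
            nbrs = [j for j in tree.query_ball_point(p, shell) if j != i]
            if not nbrs:
                continue
            vecs = ref[nbrs] - p
            theta = np.arctan2(vecs[:, 1], vecs[:, 0])
            psis.append(np.abs(np.exp(6j * theta).mean()))
        out["hexagonal_order"] = float(np.mean(psis)) if psis else np.nan
    else:
        out["hexagonal_order"] = np.nan
    return out
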