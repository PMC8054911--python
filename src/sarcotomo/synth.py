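"""Synthetic sarcomere generator.

Builds ground-truth coordinate models with the statistical structure a
rigor-state vertebrate sarcomere shows in cryo-electron tomograms:

* hexagonal A-band lattice (45 nm thick-thick spacing, thin filaments on
  the two trigonal interstitial sites, ~26 nm from their three thick
  neighbours);
* actin filaments grown with the genetic helix (-166.6 deg / 27.9 Å);
* orientation-gated stochastic myosin binding with double-, single- and
  split-head topology, driven by the thick filament's theoretical head
  budget of 6 heads per 14.3 nm crown;
* antiparallel Z-disc arrays cross-linked by ~33 nm alpha-actinins,
  including 6 nm-spaced doublets on adjacent same-strand subunits;
* tropomyosin azimuthal state labels (M in the A-band, C in the I-band,
  ~21 deg apart);
* optional rasterization to a density volume with noise and a hard
  missing-wedge mask, for exercising the tracing stage.

All randomness flows from a single integer seed per model.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
import pandas as pd

from . import zdisc as _zdisc
from .errors import GeometryError, ParameterError
from .helix import HelicalParams, crossover_repeat, frame_from_axis, wrap180, wrap360
from .model import (SarcomereModel, empty_crosslinks, empty_heads,
                    empty_subunits)
from .specs import (CROWN_SPACING_NM, HEADS_PER_CROWN, BindingSpec,
                    HelixSpec, LatticeSpec, ZdiscSpec, spec_dict)

logger = logging.getLogger(__name__)

SQ3 = math.sqrt(3.0)


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def build_lattice(spec: LatticeSpec, seed: int) -> SarcomereModel:
    """Hexagonal filament lattice (filaments only, no subunits yet).

    Thick filaments sit on a triangular lattice with constant
    ``thick_spacing``; thin filaments occupy the two interstitial
    (triangle-centre) sites per unit cell, each recording its three
    nearest thick neighbours.  Only interior thin sites, whose three
    neighbours all exist, are kept.  Jitter is an isotropic in-plane
    Gaussian displacement per filament.  For band "I" the thick
    filaments are dropped (they end at the A-band).
    """
    rng = np.random.default_rng(seed)
    a = spec.thick_spacing * 10.0  # Å
    length = spec.axis_length * 10.0

    rows = []
    thick_key = {}
    next_id = 0
    for j in range(spec.n_rows):
        for i in range(spec.n_cols):
            x = i * a + j * a / 2.0
            z = j * a * SQ3 / 2.0
            thick_key[(i, j)] = next_id
            rows.append(dict(id=next_id, kind="thick", polarity="none",
                             x=x, z=z, y0=0.0, length=length,
                             ax=0.0, ay=1.0, az=0.0, neighbors=""))
            next_id += 1

    for j in range(spec.n_rows - 1):
        for i in range(spec.n_cols - 1):
            base_x = i * a + j * a / 2.0
            base_z = j * a * SQ3 / 2.0
            sites = [
                ((base_x + a / 2.0, base_z + a / (2.0 * SQ3)),
                 [(i, j), (i + 1, j), (i, j + 1)]),
                ((base_x + a, base_z + a / SQ3),
                 [(i + 1, j), (i, j + 1), (i + 1, j + 1)]),
            ]
            for (x, z), tri in sites:
                nbrs = [thick_key[t] for t in tri]
                rows.append(dict(id=next_id, kind="thin",
                                 polarity="plus_toward_z_disc",
                                 x=x, z=z, y0=0.0, length=length,
                                 ax=0.0, ay=1.0, az=0.0,
                                 neighbors=",".join(map(str, nbrs))))
                next_id += 1

    df = pd.DataFrame(rows).set_index("id")
    if spec.jitter_sd > 0:
        df[["x", "z"]] += rng.normal(0.0, spec.jitter_sd * 10.0, (len(df), 2))
    if spec.band == "I":
        df = df[df["kind"] == "thin"].copy()

    return SarcomereModel(filaments=df, meta={"lattice": spec_dict(spec)},
                          seed=seed)


# ---------------------------------------------------------------------------
# filament growth
# ---------------------------------------------------------------------------

def grow_filament(origin, axis, n_subunits: int, helix: HelixSpec) -> pd.DataFrame:
    """Grow one actin filament from its pointed end toward the barbed end.

    Subunit ``k`` sits at ``origin + k * rise * axis`` on the axis, offset
    radially by ``helix.radius`` in the direction of its azimuth
    ``theta0 + k * twist`` (mod 360).  Strand parity is ``k mod 2``.
    """
    if n_subunits < 1:
        raise ParameterError("n_subunits must be >= 1")
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise GeometryError("zero-length axis vector")
    axis = axis / nrm
    origin = np.asarray(origin, dtype=float)
    e1, e2 = frame_from_axis(axis)

    k = np.arange(n_subunits)
    az = wrap360(helix.theta0 + k * helix.twist_per_subunit)
    on_axis = origin[None, :] + np.outer(k * helix.rise_per_subunit, axis)
    rad = np.radians(az)
    pos = on_axis + helix.radius * (np.outer(np.cos(rad), e1)
                                    + np.outer(np.sin(rad), e2))
    return pd.DataFrame({
        "k": k, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "azimuth": az, "strand": k % 2,
    })


def populate_subunits(model: SarcomereModel, helix: HelixSpec,
                      register: bool = True,
                      rng: Optional[np.random.Generator] = None) -> SarcomereModel:
    """Grow subunits on every thin filament of the model (in place).

    With ``register=True`` all filaments share theta0 (thin filaments in
    the A-band are observed in helical register); otherwise each filament
    draws a uniform phase from ``rng``.
    """
    frames = []
    next_id = 0
    thin = model.filaments[model.filaments["kind"] == "thin"]
    for fid, row in thin.iterrows():
        h = helix
        if not register:
            if rng is None:
                raise ParameterError("register=False requires an rng")
            h = HelixSpec(helix.twist_per_subunit, helix.rise_per_subunit,
                          theta0=float(rng.uniform(0, 360)), radius=helix.radius)
        n = int(row["length"] // h.rise_per_subunit) + 1
        df = grow_filament([row["x"], row["y0"], row["z"]],
                           [row["ax"], row["ay"], row["az"]], n, h)
        df["filament_id"] = fid
        df.index = pd.RangeIndex(next_id, next_id + len(df), name="subunit_id")
        next_id += len(df)
        frames.append(df)
    model.subunits = pd.concat(frames)[["filament_id", "k", "x", "y", "z",
                                        "azimuth", "strand"]]
    model.meta["helix"] = spec_dict(helix)
    return model


# ---------------------------------------------------------------------------
# myosin binding
# ---------------------------------------------------------------------------

def theoretical_head_budget(length_nm: float) -> int:
    """6 heads per full 14.3 nm crown: budget = 6 * floor(length / 14.3)."""
    return HEADS_PER_CROWN * int(length_nm // CROWN_SPACING_NM)


class _SiteIndex:
    """Per (thick, thin) pools of eligible, still-free subunits."""

    def __init__(self, model: SarcomereModel, gate: float):
        self.free = pd.Series(True, index=model.subunits.index)
        self.sub = model.subunits
        # thick_id -> list of (thin_id, eligible subunit table)
        self.pools: dict[int, list[tuple[int, pd.DataFrame]]] = {}
        fil = model.filaments
        for thin_id in model.thin_ids():
            fx, fz = fil.loc[thin_id, ["x", "z"]]
            subs = model.subunits[model.subunits["filament_id"] == thin_id]
            for t in model.neighbors_of(thin_id):
                tx, tz = fil.loc[t, ["x", "z"]]
                bearing = math.degrees(math.atan2(tz - fz, tx - fx))
                rel = wrap180(subs["azimuth"].to_numpy() - bearing)
                elig = subs[np.abs(rel) <= gate]
                if len(elig):
                    self.pools.setdefault(t, []).append((thin_id, elig))

    def candidates(self, thick_id: int, thin_id: int, y: float, reach: float):
        """Free eligible subunit ids of one pool within |y - site| <= reach."""
        for tid, elig in self.pools.get(thick_id, []):
            if tid != thin_id:
                continue
            m = (np.abs(elig["y"].to_numpy() - y) <= reach) \
                & self.free.loc[elig.index].to_numpy()
            return elig[m]
        return None

    def thin_pool_ids(self, thick_id: int) -> list[int]:
        return [tid for tid, _ in self.pools.get(thick_id, [])]


def _closest(df: pd.DataFrame, y: float):
    i = (df["y"] - y).abs().to_numpy().argmin()
    return df.iloc[i]


def simulate_binding(model: SarcomereModel, spec: BindingSpec,
                     seed: int) -> pd.DataFrame:
    """Attach myosin heads to eligible actin subunits.

    The draw is head-budget-driven: every thick filament carries
    ``6 * floor(length / 14.3 nm)`` theoretical heads organised in crowns
    of 3 myosin molecules; each molecule attaches with a probability
    chosen so the expected attached/theoretical occupancy equals
    ``p_attach`` given the single-head fraction.  An attaching molecule
    draws its topology (split / single / double) and then searches its
    thick filament's neighbouring thin filaments for free eligible
    subunits within ``reach`` of the crown, greedily from the barbed end
    (ties by lower subunit index).  Doubles occupy same-strand adjacent
    subunits (k, k + min_pair_gap); splits occupy two different thin
    filaments.  When no compatible site exists the molecule degrades
    (split -> double -> single -> unattached); degradations are logged.
    """
    thick_ids = model.thick_ids()
    if len(model.thin_ids()) < 1 or len(thick_ids) < 3:
        raise ParameterError("need an A-band model with >= 1 thin and >= 3 thick filaments")
    if len(model.subunits) == 0:
        raise ParameterError("model has no subunits; call populate_subunits first")

    rng = np.random.default_rng(seed)
    reach = spec.reach * 10.0
    # frac_single / frac_split are attached-HEAD fractions; convert to the
    # per-molecule topology probabilities that realize them (a single
    # contributes 1 head, doubles and splits 2)
    s_mol = 2.0 * spec.frac_single / (1.0 + spec.frac_single)
    p_split_mol = spec.frac_split * (2.0 - s_mol) / 2.0

    sites = _SiteIndex(model, spec.gate_halfwidth)
    fil = model.filaments
    rows = []
    myosin_id = 0
    degradations = 0

    def place(subunit_row, thick_id, slot, klass):
        sid = subunit_row.name
        sites.free.loc[sid] = False
        tx, tz = fil.loc[thick_id, ["x", "z"]]
        p = np.array([subunit_row["x"], subunit_row["y"], subunit_row["z"]])
        lat = np.array([tx - p[0], 0.0, tz - p[2]])
        lat /= max(np.linalg.norm(lat), 1e-9)
        hp = p + 20.0 * lat
        rows.append(dict(myosin_id=myosin_id, head_slot=slot,
                         origin_thick_id=int(thick_id), subunit_id=int(sid),
                         klass=klass, x=hp[0], y=hp[1], z=hp[2]))

    for t in sorted(thick_ids):
        length_nm = fil.loc[t, "length"] / 10.0
        n_crowns = int(length_nm // CROWN_SPACING_NM)
        y0 = fil.loc[t, "y0"]
        pool = sites.thin_pool_ids(t)
        if not pool:
            continue
        # a full crown's 6 heads face the 6 surrounding thin filaments; only
        # those with a modeled thin neighbour contribute to this model's
        # census, so the head budget scales with the pool size
        n_pool = min(len(pool), HEADS_PER_CROWN)
        budget = n_crowns * n_pool
        n_target = int(rng.binomial(budget, spec.p_attach))
        heads_placed = 0
        attempts = 0
        max_attempts = 4 * max(budget, 1)
        while heads_placed < n_target and attempts < max_attempts:
            j = attempts % n_crowns  # round-robin over crowns
            attempts += 1
            crown_y = y0 + (j + 0.5) * CROWN_SPACING_NM * 10.0
            if True:
                n_before = len(rows)
                u = rng.random()
                topo = ("split" if u < p_split_mol
                        else "single" if u < p_split_mol + s_mol
                        else "double")
                order = list(rng.permutation(pool))
                placed = False
                if topo == "split":
                    found = []
                    for tid in order:
                        cand = sites.candidates(t, tid, crown_y, reach)
                        if cand is not None and len(cand):
                            found.append(_closest(cand, crown_y))
                        if len(found) == 2:
                            break
                    if len(found) == 2:
                        place(found[0], t, "a", "split")
                        place(found[1], t, "b", "split")
                        placed = True
                    else:
                        topo = "double"
                        degradations += 1
                if topo == "double" and not placed:
                    for tid in order:
                        cand = sites.candidates(t, tid, crown_y, reach)
                        if cand is None or len(cand) < 2:
                            continue
                        by_k = {int(k): sid for sid, k in cand["k"].items()}
                        pairs = sorted(k for k in by_k
                                       if k + spec.min_pair_gap in by_k)
                        if not pairs:
                            continue
                        # pair whose centre is closest to the crown; ties by lower k
                        best = min(pairs, key=lambda k: (
                            abs((cand.loc[by_k[k], "y"]
                                 + cand.loc[by_k[k + spec.min_pair_gap], "y"]) / 2
                                - crown_y), k))
                        place(cand.loc[by_k[best]], t, "a", "double")
                        place(cand.loc[by_k[best + spec.min_pair_gap]], t, "b", "double")
                        placed = True
                        break
                    if not placed:
                        topo = "single"
                        degradations += 1
                if topo == "single" and not placed:
                    best = None
                    for tid in order:
                        cand = sites.candidates(t, tid, crown_y, reach)
                        if cand is not None and len(cand):
                            c = _closest(cand, crown_y)
                            if best is None or abs(c["y"] - crown_y) < abs(best["y"] - crown_y):
                                best = c
                    if best is not None:
                        place(best, t, "a", "single")
                        placed = True
                if placed:
                    myosin_id += 1
                    heads_placed += len(rows) - n_before
                else:
                    degradations += 1

    if degradations:
        logger.info("simulate_binding: %d molecules degraded or unplaced "
                    "for lack of free eligible sites", degradations)
    heads = pd.DataFrame(rows, columns=empty_heads().columns)
    model.heads = heads
    model.meta["binding"] = spec_dict(spec)
    model.meta["theoretical_heads"] = int(sum(
        theoretical_head_budget(fil.loc[t, "length"] / 10.0)
        * min(len(sites.thin_pool_ids(t)), HEADS_PER_CROWN) / HEADS_PER_CROWN
        for t in thick_ids))
    return heads


# ---------------------------------------------------------------------------
# Z-disc
# ---------------------------------------------------------------------------

def build_zdisc(spec: ZdiscSpec, lattice: LatticeSpec, seed: int,
                helix: Optional[HelixSpec] = None) -> SarcomereModel:
    """Two interdigitated antiparallel thin-filament arrays with cross-links.

    Filament columns alternate polarity along X; the lateral spacing is
    ``(actinin_length + actin_diameter) * sin(actinin_angle)`` so every
    cross-link has the prescribed length and obtuse angle to the pointed
    end.  Cross-link sites repeat every half-helical repeat (~37 nm)
    along each opposite-polarity pair; with probability ``doublet_prob``
    a second link lands on the same-strand adjacent subunit (2 x rise =
    5.58 nm away, randomly before or after).  Z-disc thickness emerges
    from the overlap length and the axial throw of the links.
    """
    helix = helix or HelixSpec()
    rng = np.random.default_rng(seed)
    link_len = (spec.actinin_length + spec.actin_diameter) * 10.0  # Å
    alpha = math.radians(spec.actinin_angle)
    s_lat = link_len * math.sin(alpha)         # lateral spacing, Å
    dy = -link_len * math.cos(alpha)           # axial throw, Å (> 0)
    ov = spec.overlap_length * 10.0
    L = lattice.axis_length * 10.0

    rows = []
    fid = 0
    for j in range(lattice.n_rows):
        for i in range(lattice.n_cols):
            up = i % 2 == 0
            rows.append(dict(
                id=fid, kind="thin",
                polarity="plus_toward_z_disc" if up else "minus",
                x=i * s_lat, z=j * s_lat,
                y0=(ov / 2.0 - L) if up else (-ov / 2.0 + L),
                length=L,
                ax=0.0, ay=1.0 if up else -1.0, az=0.0, neighbors=""))
            fid += 1
    fil = pd.DataFrame(rows).set_index("id")
    if lattice.jitter_sd > 0:
        fil[["x", "z"]] += rng.normal(0, lattice.jitter_sd * 10.0, (len(fil), 2))

    model = SarcomereModel(filaments=fil, seed=seed,
                           meta={"zdisc": spec_dict(spec),
                                 "lattice": spec_dict(lattice)})
    # grow subunits along each filament's own axis
    frames = []
    nid = 0
    for f, row in fil.iterrows():
        n = int(row["length"] // helix.rise_per_subunit) + 1
        df = grow_filament([row["x"], row["y0"], row["z"]],
                           [row["ax"], row["ay"], row["az"]], n, helix)
        df["filament_id"] = f
        df.index = pd.RangeIndex(nid, nid + len(df), name="subunit_id")
        nid += len(df)
        frames.append(df)
    model.subunits = pd.concat(frames)[["filament_id", "k", "x", "y", "z",
                                        "azimuth", "strand"]]

    repeat = crossover_repeat(HelicalParams(
        helix.twist_per_subunit, helix.rise_per_subunit)).repeat_length_nm * 10.0
    two_rise = 2.0 * helix.rise_per_subunit

    links = []
    for j in range(lattice.n_rows):
        for i in range(lattice.n_cols - 1):
            a_id = j * lattice.n_cols + i
            b_id = a_id + 1
            if fil.loc[a_id, "ay"] < 0:       # orient pair so A points up
                a_id, b_id = b_id, a_id
            # site grid with a random phase per pair (real Z-discs do not
            # synchronize cross-link heights across filament pairs)
            phase = float(rng.uniform(0.0, repeat))
            y = -ov / 2.0 + phase
            while y <= ov / 2.0:
                site_ys = [y]
                if rng.random() < spec.doublet_prob:
                    site_ys.append(y + two_rise * (1 if rng.random() < 0.5 else -1))
                for y_site in site_ys:
                    if not (-ov / 2.0 <= y_site <= ov / 2.0):
                        continue
                    # anchor on the A subunit grid, keep the throw exact
                    sa = _nearest_subunit(model, a_id, y_site)
                    y_a = float(model.subunits.loc[sa, "y"])
                    links.append((a_id, b_id, sa, y_a, y_a + dy))
                y += repeat

    cl_rows = []
    seen = set()
    for a_id, b_id, sub_a, y_a, y_b in links:
        if (a_id, b_id, sub_a) in seen:      # doublet offset may collide
            continue
        seen.add((a_id, b_id, sub_a))
        cid = len(cl_rows)
        sub_b = _nearest_subunit(model, b_id, y_b)
        pa = model.filament_axis_point(a_id, y_a)
        pb = model.filament_axis_point(b_id, y_b)
        cl_rows.append(dict(id=cid, fil_a=a_id, fil_b=b_id,
                            sub_a=sub_a, sub_b=sub_b, ya=y_a, yb=y_b,
                            cx=(pa[0] + pb[0]) / 2, cy=(pa[1] + pb[1]) / 2,
                            cz=(pa[2] + pb[2]) / 2,
                            ux=np.nan, uy=np.nan, uz=np.nan,
                            center_distance_nm=np.nan, length_nm=np.nan,
                            angle_deg=np.nan))
    cl = (pd.DataFrame(cl_rows).set_index("id") if cl_rows
          else empty_crosslinks())
    model.crosslinks = cl
    if len(cl):
        # fill geometry through the measurement code: one source of truth
        _zdisc.annotate_geometry(model, actin_diameter=spec.actin_diameter)
    return model


def _nearest_subunit(model: SarcomereModel, fil_id: int, y: float) -> int:
    subs = model.subunits[model.subunits["filament_id"] == fil_id]
    return int((subs["y"] - y).abs().idxmin())


# ---------------------------------------------------------------------------
# tropomyosin
# ---------------------------------------------------------------------------

def assign_tropomyosin(model: SarcomereModel, boundary_axial: float,
                       state_offset: float = 21.0, noise_sd: float = 0.0,
                       ref_m: float = 0.0,
                       seed: Optional[int] = None) -> pd.Series:
    """Label every subunit with a tropomyosin azimuth offset (deg).

    Subunits on the A-band side of ``boundary_axial`` (smaller y; +Y runs
    from the M-band toward the Z-disc) carry the M-state mean ``ref_m``,
    subunits beyond it the C-state mean ``ref_m + state_offset``
    (~21 deg away); Gaussian angular noise is added on top.  The offsets
    are stored in the ``tpm_offset`` column and returned.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    y = model.subunits["y"].to_numpy()
    off = np.where(y <= boundary_axial, ref_m, ref_m + state_offset).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(model.seed if seed is None else seed)
        off = off + rng.normal(0.0, noise_sd, off.shape)
    model.subunits["tpm_offset"] = off
    model.meta["tpm"] = dict(boundary_axial=boundary_axial,
                             state_offset=state_offset, noise_sd=noise_sd,
                             ref_m=ref_m)
    return model.subunits["tpm_offset"]


# ---------------------------------------------------------------------------
# convenience: full A-band model
# ---------------------------------------------------------------------------

def build_aband_model(lattice: Optional[LatticeSpec] = None,
                      helix: Optional[HelixSpec] = None,
                      binding: Optional[BindingSpec] = None,
                      seed: int = 0,
                      n_thin: Optional[int] = None) -> SarcomereModel:
    """Lattice + subunits + myosin binding in one call.

    ``n_thin`` restricts the model to the first n thin filaments (the
    analyses in the source study annotated a 30-filament subset).
    """
    lattice = lattice or LatticeSpec()
    helix = helix or HelixSpec()
    binding = binding or BindingSpec()
    model = build_lattice(lattice, seed)
    if n_thin is not None:
        thin = model.thin_ids()
        if len(thin) < n_thin:
            raise ParameterError(
                f"lattice provides only {len(thin)} thin filaments, need {n_thin}")
        drop = thin[n_thin:]
        model.filaments = model.filaments.drop(index=drop)
    populate_subunits(model, helix)
    simulate_binding(model, binding, seed=seed + 1)
    return model


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_volume(model: SarcomereModel, voxel_size: float = 10.0,
                     filament_radius: float = 40.0, snr: Optional[float] = None,
                     missing_wedge_halfangle: Optional[float] = None,
                     seed: int = 0, margin: Optional[float] = None):
    """Render the model as a density volume (filament axis along +Y).

    Filaments become Gaussian tubes of sigma ``filament_radius`` and peak
    ~1, heads and cross-links Gaussian blobs; Gaussian noise of standard
    deviation ``rms(signal) / snr`` is added when ``snr`` is finite; the
    missing wedge, when requested, is a hard angular mask in Fourier
    space zeroing components within ``missing_wedge_halfangle`` of the kz
    axis in the (ky, kz) plane (single-tilt geometry, tilt axis X).

    Returns a :class:`sarcotomo.io.Volume` with data indexed [x, y, z].
    """
    from .io import Volume  # local import to avoid a cycle

    if voxel_size <= 0:
        raise ParameterError("voxel_size must be > 0")
    if voxel_size > filament_radius:
        logger.warning("voxel size %.1f Å exceeds filament radius %.1f Å; "
                       "tubes will be undersampled", voxel_size, filament_radius)

    fil = model.filaments
    if margin is None:
        margin = 3.0 * filament_radius
    pts = []
    for _, row in fil.iterrows():
        p0 = np.array([row["x"], row["y0"], row["z"]])
        p1 = p0 + row["length"] * np.array([row["ax"], row["ay"], row["az"]])
        pts.extend([p0, p1])
    pts = np.asarray(pts)
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 4)
    vol = np.zeros(shape, dtype=np.float64)

    sigma_vox = filament_radius / voxel_size
    step = max(filament_radius / 2.0, voxel_size / 2.0)

    def splat(points, sigma, amplitude):
        """Add Gaussian blobs at the given Å points."""
        svox = sigma / voxel_size
        r = int(math.ceil(3.0 * svox))
        offs = np.arange(-r, r + 1)
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        for p in points:
            c = (p - lo) / voxel_size
            ci = np.round(c).astype(int)
            if np.any(ci < -r) or np.any(ci >= shape + r):
                continue
            d2 = ((ci[0] + ox - c[0]) ** 2 + (ci[1] + oy - c[1]) ** 2
                  + (ci[2] + oz - c[2]) ** 2)
            g = amplitude * np.exp(-d2 / (2.0 * svox ** 2))
            xs = slice(max(ci[0] - r, 0), min(ci[0] + r + 1, shape[0]))
            ys = slice(max(ci[1] - r, 0), min(ci[1] + r + 1, shape[1]))
            zs = slice(max(ci[2] - r, 0), min(ci[2] + r + 1, shape[2]))
            gx = slice(xs.start - (ci[0] - r), (2 * r + 1) - ((ci[0] + r + 1) - xs.stop))
            gy = slice(ys.start - (ci[1] - r), (2 * r + 1) - ((ci[1] + r + 1) - ys.stop))
            gz = slice(zs.start - (ci[2] - r), (2 * r + 1) - ((ci[2] + r + 1) - zs.stop))
            vol[xs, ys, zs] += g[gx, gy, gz]

    # tube amplitude normalization: samples at spacing `step` along the axis
    # sum to ~sqrt(2*pi)*sigma/step on the ridge
    tube_amp = step / (math.sqrt(2.0 * math.pi) * filament_radius)
    for _, row in fil.iterrows():
        axis = np.array([row["ax"], row["ay"], row["az"]])
        p0 = np.array([row["x"], row["y0"], row["z"]])
        n = int(row["length"] / step) + 1
        samples = p0[None, :] + np.outer(np.arange(n) * step, axis)
        splat(samples, filament_radius, tube_amp)

    if len(model.heads):
        splat(model.heads[["x", "y", "z"]].to_numpy(),
              0.7 * filament_radius, 0.8)
    if len(model.crosslinks):
        for _, row in model.crosslinks.iterrows():
            ya, yb = _zdisc._bind_heights(model, row)
            pa = model.filament_axis_point(row["fil_a"], ya)
            pb = model.filament_axis_point(row["fil_b"], yb)
            seg = pb - pa
            n = int(np.linalg.norm(seg) / step) + 2
            ts = np.linspace(0, 1, n)
            sig_c = 0.4 * filament_radius
            seg_step = np.linalg.norm(seg) / (n - 1)
            splat(pa[None, :] + ts[:, None] * seg[None, :], sig_c,
                  0.9 * seg_step / (math.sqrt(2.0 * math.pi) * sig_c))

    if snr is not None and np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sig_rms = float(np.sqrt(np.mean(vol ** 2)))
        vol = vol + rng.normal(0.0, sig_rms / snr, vol.shape)

    if missing_wedge_halfangle is not None:
        vol = _apply_missing_wedge(vol, missing_wedge_halfangle)

    return Volume(data=vol.astype(np.float32), voxel_size=float(voxel_size),
                  origin=tuple(lo))


def _apply_missing_wedge(vol: np.ndarray, halfangle: float) -> np.ndarray:
    """Zero Fourier components within `halfangle` of kz in the (ky, kz) plane."""
    f = np.fft.fftn(vol)
    ky = np.fft.fftfreq(vol.shape[1])[None, :, None]
    kz = np.fft.fftfreq(vol.shape[2])[None, None, :]
    ang = np.degrees(np.arctan2(np.abs(ky), np.abs(kz)))
    wedge = (ang < halfangle) & ~((ky == 0) & (kz == 0))
    f = f * ~wedge
    return np.real(np.fft.ifftn(f))
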