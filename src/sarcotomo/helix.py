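"""Actin-helix arithmetic.

The actin filament is a left-handed genetic helix: successive subunits
are rotated by the twist (default -166.6 deg) and translated by the rise
(default 27.9 Å) along the axis.  Because the twist is close to 180 deg
the filament appears as two long-pitch strands (even / odd subunits)
that cross over every half-repeat of ~13 subunits (~37 nm).

Conventions used throughout the package:

* azimuths are degrees in [0, 360), measured in the plane normal to the
  filament axis, counter-clockwise from the in-plane projection of +X;
  with the filament along +Y the azimuth theta maps to the in-plane
  direction (cos theta, sin theta) in (x, z);
* wrapped angle differences live in (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import GeometryError, InputError, ParameterError

__all__ = [
    "HelicalParams",
    "wrap360",
    "wrap180",
    "subunit_azimuth",
    "crossover_repeat",
    "relative_orientation",
    "estimate_helical_params",
    "frame_from_axis",
]


@dataclass(frozen=True)
class HelicalParams:
    """Twist (deg per subunit, sign = handedness) and rise (Å per subunit)."""

    twist: float = -166.6
    rise: float = 27.9

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ParameterError("rise must be > 0")
        if abs(self.twist) > 180.0:
            raise ParameterError("twist must satisfy |twist| <= 180")


def wrap360(angle):
    """Wrap angle(s) into [0, 360)."""
    a = np.asarray(angle) % 360.0
    # tiny negative inputs can round to exactly 360.0
    return np.where(a >= 360.0, 0.0, a)


def wrap180(angle):
    """Wrap angle difference(s) into (-180, 180]."""
    a = np.asarray(angle, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


def subunit_azimuth(k, theta0: float, params: HelicalParams):
    """Azimuth of subunit ``k``: (theta0 + k * twist) wrapped to [0, 360).

    ``k`` may be an integer or an integer array.
    """
    return wrap360(theta0 + np.asarray(k) * params.twist)


class CrossoverRepeat(NamedTuple):
    repeat_length_nm: float
    subunits_per_half_repeat: float


def crossover_repeat(params: HelicalParams) -> CrossoverRepeat:
    """Half-helical (crossover) repeat of the two-strand description.

    The apparent long-pitch strands rotate by ``180 - |twist|`` degrees per
    subunit, so one half-repeat (a 180 deg turn of the crossover pattern,
    the ~37 nm "target region" period) spans ``180 / (180 - |twist|)``
    subunits.  For twist -166.6 deg and rise 27.9 Å this gives 13.43
    subunits and 37.5 nm.
    """
    dev = 180.0 - abs(params.twist)
    if dev == 0.0:
        raise ParameterError("crossover repeat undefined for twist = +-180 deg")
    n_half = 180.0 / dev
    return CrossoverRepeat(n_half * params.rise / 10.0, n_half)


def frame_from_axis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed in-plane basis (e1, e2) for a filament axis.

    e1 is the projection of global +X onto the plane normal to the axis
    (falls back to +Z when the axis is parallel to X); e2 = e1 x axis is
    chosen so that for the canonical +Y axis (e1, e2) = (+X, +Z), matching
    the azimuth convention in the module docstring.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("zero-length axis vector")
    axis = axis / n
    e1 = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([0.0, 0.0, 1.0]) - axis[2] * axis
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(e1, axis)
    return e1, e2


def relative_orientation(azimuth, thin_point, thick_point, axis=(0.0, 1.0, 0.0)):
    """Subunit azimuth relative to the bearing toward a thick filament.

    Parameters
    ----------
    azimuth : float or array
        Subunit azimuth(s), degrees.
    thin_point, thick_point : (3,) array
        Points on the thin- and thick-filament axes at the same axial
        height, in Å.
    axis : (3,) array
        Local thin-filament tangent; the bearing is measured in the plane
        normal to it, so gently curved traces are supported.

    Returns
    -------
    float or array in (-180, 180].
    """
    thin_point = np.asarray(thin_point, dtype=float)
    thick_point = np.asarray(thick_point, dtype=float)
    e1, e2 = frame_from_axis(np.asarray(axis, dtype=float))
    d = thick_point - thin_point
    u, v = float(np.dot(d, e1)), float(np.dot(d, e2))
    if abs(u) < 1e-9 and abs(v) < 1e-9:
        raise GeometryError("thin and thick axes coincide at this height")
    bearing = np.degrees(np.arctan2(v, u))
    return wrap180(np.asarray(azimuth) - bearing)


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(np.asarray(angles_deg, dtype=float)))
    m = z.mean()
    if abs(m) < 1e-12:
        raise InputError("circular mean undefined (isotropic angles)")
    return float(np.degrees(np.angle(m)))


def estimate_helical_params(coords, azimuths=None) -> HelicalParams:
    """Recover twist and rise from ordered subunit coordinates.

    The filament axis is fit by principal-component analysis, oriented
    along the subunit ordering, and refined by subtracting the estimated
    helical radial offsets and re-fitting (a single PCA pass leaves a
    small axis tilt when the subunits do not sample whole turns); the
    rise is the mean consecutive axial spacing and the twist the
    circular mean of consecutive azimuth increments (sign preserved).
    Azimuths are computed from the radial residuals unless given
    explicitly (``azimuths=`` also enables the degenerate 2-subunit
    single-interval estimate).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be an (n, 3) array")
    n = coords.shape[0]
    if n < 2 or (azimuths is None and n < 3):
        raise InputError("need >= 3 subunits (>= 2 when azimuths are given)")

    centred = coords - coords.mean(axis=0)

    def fit_axis(points):
        if n >= 3:
            _, _, vt = np.linalg.svd(points - points.mean(axis=0),
                                     full_matrices=False)
            ax = vt[0]
        else:
            ax = coords[-1] - coords[0]
            ax = ax / np.linalg.norm(ax)
        if np.dot(coords[-1] - coords[0], ax) < 0:
            ax = -ax
        return ax

    axis = fit_axis(coords)

    def radial_azimuths(ax):
        e1, e2 = frame_from_axis(ax)
        radial = centred - np.outer(centred @ ax, ax)
        rad_norm = np.linalg.norm(radial, axis=1)
        if np.any(rad_norm < 1e-9):
            raise InputError("on-axis subunit: azimuth undefined; pass azimuths")
        return (np.degrees(np.arctan2(radial @ e2, radial @ e1)),
                radial, rad_norm)

    if azimuths is None:
        # refine axis direction and centre: on the true axis every subunit
        # sits at the same radius, so minimize the spread of radial
        # distances (a PCA-only axis is slightly tilted when the chain
        # does not sample whole turns)
        from scipy.optimize import least_squares

        e1_0, e2_0 = frame_from_axis(axis)
        centroid = coords.mean(axis=0)

        def residuals(p):
            ax = axis + p[0] * e1_0 + p[1] * e2_0
            ax = ax / np.linalg.norm(ax)
            c = centroid + p[2] * e1_0 + p[3] * e2_0
            d = coords - c
            rad = d - np.outer(d @ ax, ax)
            rn = np.linalg.norm(rad, axis=1)
            return rn - rn.mean()

        if n >= 6:
            sol = least_squares(residuals, np.zeros(4), method="lm")
            axis = axis + sol.x[0] * e1_0 + sol.x[1] * e2_0
            axis = axis / np.linalg.norm(axis)
            centred = coords - (centroid + sol.x[2] * e1_0 + sol.x[3] * e2_0)
        azimuths, _, _ = radial_azimuths(axis)
    azimuths = np.asarray(azimuths, dtype=float)
    if azimuths.shape[0] != n:
        raise InputError("azimuths length must match coords")

    t = coords @ axis
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InputError("subunits must be ordered and strictly monotone along the axis")
    rise = float(dt.mean())

    increments = wrap180(np.diff(azimuths))
    twist = _circular_mean_deg(increments)
    return HelicalParams(twist=twist, rise=rise)
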