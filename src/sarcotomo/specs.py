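"""Parameter blocks for the synthetic sarcomere generator.

All lengths at the user surface are in nanometres except helical rise,
which follows the field convention of Ångström per subunit.  Internally
every coordinate is stored in Å (see :mod:`sarcotomo.model`).

Defaults encode the geometry of a vertebrate skeletal sarcomere in the
rigor state: a hexagonal A-band lattice with 45 nm between thick
filaments, the actin genetic helix (-166.6 deg twist, 27.9 Å rise), an
orientation gate of +-60 deg for myosin binding, and ~33 nm long
alpha-actinin cross-links in the Z-disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import ParameterError

# Thick-filament crown geometry: 6 myosin heads every 14.3 nm.
CROWN_SPACING_NM = 14.3
HEADS_PER_CROWN = 6


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class LatticeSpec:
    """Cross-sectional filament lattice of one sarcomere band.

    thick_spacing
        Nearest-neighbour distance between thick filaments (nm).  The two
        trigonal interstitial sites that host thin filaments then sit at
        ``thick_spacing / sqrt(3)`` (~26 nm for the default 45 nm).
    jitter_sd
        Isotropic in-plane Gaussian displacement applied per filament (nm).
    band
        Which sarcomere zone the lattice represents: "A" (thick + thin),
        "I" (thin only, typically with larger jitter) or "Z".
    axis_length
        Filament length along the axis (nm).
    """

    thick_spacing: float = 45.0
    n_rows: int = 4
    n_cols: int = 4
    jitter_sd: float = 0.0
    band: str = "A"
    axis_length: float = 300.0

    def __post_init__(self) -> None:
        _check(self.thick_spacing > 0, "thick_spacing must be > 0")
        _check(self.jitter_sd >= 0, "jitter_sd must be >= 0")
        _check(self.n_rows >= 1 and self.n_cols >= 1, "lattice needs >= 1 row/col")
        _check(self.band in ("A", "I", "Z"), "band must be one of A, I, Z")
        _check(self.axis_length > 0, "axis_length must be > 0")


@dataclass
class HelixSpec:
    """Actin genetic-helix parameters plus the filament's phase origin."""

    twist_per_subunit: float = -166.6   # deg per subunit
    rise_per_subunit: float = 27.9      # Å per subunit
    theta0: float = 0.0                 # deg, azimuth of subunit k=0
    radius: float = 25.0                # Å, subunit centre off-axis distance

    def __post_init__(self) -> None:
        _check(self.rise_per_subunit > 0, "rise_per_subunit must be > 0")
        # store twist wrapped into (-180, 180]
        t = self.twist_per_subunit % 360.0
        if t > 180.0:
            t -= 360.0
        self.twist_per_subunit = t
        _check(self.radius > 0, "radius must be > 0")


@dataclass
class BindingSpec:
    """Stochastic myosin-binding model for the A-band.

    gate_halfwidth
        Half-width (deg) of the orientation gate: an actin subunit is an
        eligible binding site for a thick filament only when its azimuth
        points within +-gate_halfwidth of the bearing to that filament.
        The default 60 deg reproduces the observed ~120 deg angular range
        of bound subunits per thick filament.
    p_attach
        Probability that a head of the thick filament's theoretical budget
        (6 per 14.3 nm crown) ends up bound; the rigor-state default is
        0.825 so the attached/theoretical occupancy is ~82.5%.
    frac_single / frac_split
        Fractions of attached heads that are lone single heads or that
        belong to a split pair (the two heads of one myosin on two
        different thin filaments).
    min_pair_gap
        Subunit-index gap between the two heads of a double: 2 means
        same-strand neighbours (55.8 Å apart), the only pairing compatible
        with both heads facing the same thick filament.
    reach
        Axial search window (nm) around a crown within which a head can
        find a binding site (S2 flexibility).
    """

    gate_halfwidth: float = 60.0
    p_attach: float = 0.825
    frac_single: float = 0.083
    frac_split: float = 0.006
    min_pair_gap: int = 2
    reach: float = 20.0

    def __post_init__(self) -> None:
        for name in ("p_attach", "frac_single", "frac_split"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be a probability")
        _check(self.frac_single + self.frac_split <= 1.0,
               "frac_single + frac_split must not exceed 1")
        _check(0.0 < self.gate_halfwidth <= 180.0,
               "gate_halfwidth must be in (0, 180]")
        _check(self.min_pair_gap >= 1, "min_pair_gap must be >= 1")
        _check(self.reach > 0, "reach must be > 0")


@dataclass
class ZdiscSpec:
    """Z-disc cross-link geometry.

    actinin_length
        Rod length of one alpha-actinin cross-link (nm); the axis-to-axis
        distance between the two filaments it connects is
        ``actinin_length + actin_diameter``.
    actinin_angle
        Obtuse angle (deg) between the cross-link and the actin filament
        tangent toward the pointed end.  ~128 deg in the thin (low-strain)
        form of the Z-disc, ~158 deg in the thick form.
    doublet_prob
        Probability that a cross-link is accompanied by a second one on
        the longitudinally adjacent same-strand subunit (2 x rise =
        5.58 nm away).
    overlap_length
        Axial interdigitation depth of the two antiparallel thin-filament
        arrays (nm).
    """

    actinin_length: float = 33.0
    actinin_angle: float = 128.0
    doublet_prob: float = 0.5
    actin_diameter: float = 6.0
    overlap_length: float = 60.0

    def __post_init__(self) -> None:
        _check(90.0 < self.actinin_angle < 180.0,
               "actinin_angle must be obtuse, in (90, 180)")
        _check(self.actinin_length > self.actin_diameter,
               "actinin_length must exceed actin_diameter")
        _check(0.0 <= self.doublet_prob <= 1.0, "doublet_prob must be a probability")
        _check(self.overlap_length > 0, "overlap_length must be > 0")


def spec_dict(spec) -> dict:
    """Serializable dict view of any spec dataclass."""
    return asdict(spec)
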