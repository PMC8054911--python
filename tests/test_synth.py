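"""Synthetic generator: lattice geometry, binding statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from sarcotomo.errors import GeometryError, ParameterError
from sarcotomo.helix import wrap180
from sarcotomo.model import SarcomereModel
from sarcotomo.specs import BindingSpec, HelixSpec, LatticeSpec, ZdiscSpec
from sarcotomo.synth import (assign_tropomyosin, build_aband_model,
                             build_lattice, build_zdisc, grow_filament,
                             populate_subunits, rasterize_volume,
                             simulate_binding, theoretical_head_budget)


def lateral_distance(fil, a, b):
    return np.hypot(fil.loc[a, "x"] - fil.loc[b, "x"],
                    fil.loc[a, "z"] - fil.loc[b, "z"])


class TestLattice:
    def test_jitter_free_distances_closed_form(self):
        m = build_lattice(LatticeSpec(thick_spacing=45.0, jitter_sd=0.0), 0)
        fil = m.filaments
        # every thin filament sits 45/sqrt(3) = 25.98 nm from each of its
        # three thick neighbours
        for thin_id in m.thin_ids():
            d = [lateral_distance(fil, thin_id, t) / 10.0
                 for t in m.neighbors_of(thin_id)]
            assert np.allclose(d, 45.0 / np.sqrt(3.0), atol=1e-9)
            assert round(np.mean(d)) == 26  # the ~26 nm interstitial spacing

    def test_nearest_thick_thick_is_lattice_constant(self):
        m = build_lattice(LatticeSpec(), 0)
        thick = m.filaments.loc[m.thick_ids()]
        pts = thick[["x", "z"]].to_numpy()
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(450.0, abs=1e-9)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ParameterError):
            LatticeSpec(thick_spacing=-1.0)

    def test_i_band_drops_thick(self):
        m = build_lattice(LatticeSpec(band="I", jitter_sd=3.0), 0)
        assert len(m.thick_ids()) == 0
        assert len(m.thin_ids()) > 0


class TestGrowFilament:
    def test_axial_offsets_and_strand(self):
        subs = grow_filament([0, 0, 0], [0, 1, 0], 20, HelixSpec())
        assert subs.loc[13, "y"] == pytest.approx(13 * 27.9)  # 362.7 Å
        same_strand = subs.loc[15, "y"] - subs.loc[13, "y"]
        assert same_strand == pytest.approx(55.8)
        assert (subs["strand"] == subs["k"] % 2).all()

    def test_azimuth_sequence(self):
        subs = grow_filament([0, 0, 0], [0, 1, 0], 5, HelixSpec(theta0=0.0))
        assert subs.loc[2, "azimuth"] == pytest.approx(26.8)

    def test_zero_axis_rejected(self):
        with pytest.raises(GeometryError):
            grow_filament([0, 0, 0], [0, 0, 0], 5, HelixSpec())

    def test_recorded_azimuth_matches_radial_offset(self):
        subs = grow_filament([0, 0, 0], [0, 1, 0], 50, HelixSpec())
        recomputed = np.degrees(np.arctan2(subs["z"], subs["x"])) % 360.0
        assert np.allclose(recomputed, subs["azimuth"], atol=1e-9)


class TestBinding:
    def test_head_budget(self):
        assert theoretical_head_budget(14.3) == 6
        assert theoretical_head_budget(700.0) == 6 * 48
        # 294 heads correspond to 49 crowns of 6
        assert theoretical_head_budget(49 * 14.3) == 294

    def test_occupancy_near_p_attach(self, aband30):
        occ = len(aband30.heads) / aband30.meta["theoretical_heads"]
        assert occ == pytest.approx(0.825, abs=0.02)

    def test_gate_constrains_orientations(self, aband_model):
        from sarcotomo.binding import bound_orientations
        rel = bound_orientations(aband_model)["rel_orientation"]
        assert (rel.abs() <= 60.0 + 1e-9).all()

    def test_tiny_gate_attaches_nothing(self):
        m = build_lattice(LatticeSpec(n_rows=3, n_cols=3), 0)
        populate_subunits(m, HelixSpec())
        heads = simulate_binding(m, BindingSpec(gate_halfwidth=1e-6), seed=0)
        assert len(heads) == 0

    def test_fraction_validation(self):
        with pytest.raises(ParameterError):
            BindingSpec(frac_single=0.7, frac_split=0.5)

    def test_conservation_and_sharing(self, aband30):
        heads = aband30.heads
        # each subunit bound at most once; each myosin <= 2 heads with one origin
        assert not heads["subunit_id"].duplicated().any()
        per = heads.groupby("myosin_id")
        assert (per.size() <= 2).all()
        assert (per["origin_thick_id"].nunique() == 1).all()
        klass = heads.groupby("myosin_id")["klass"].first()
        n_double = (klass == "double").sum() * 2
        n_split = (klass == "split").sum() * 2
        n_single = (klass == "single").sum()
        assert n_double + n_split + n_single == len(heads)

    def test_topology_fractions_within_2se(self):
        # pool several seeds for a tighter binomial check on head fractions
        singles, splits, total = 0, 0, 0
        for seed in range(4):
            m = build_aband_model(seed=seed)
            singles += (m.heads["klass"] == "single").sum()
            splits += (m.heads["klass"] == "split").sum()
            total += len(m.heads)
        for frac, target in ((singles / total, 0.083), (splits / total, 0.006)):
            se = np.sqrt(target * (1 - target) / total)
            assert abs(frac - target) <= 2 * se + 0.01

    def test_same_seed_bitwise_identical(self):
        a = build_aband_model(seed=7)
        b = build_aband_model(seed=7)
        assert a.filaments.equals(b.filaments)
        assert a.subunits.equals(b.subunits)
        assert a.heads.equals(b.heads)

    def test_requires_subunits(self):
        m = build_lattice(LatticeSpec(), 0)
        with pytest.raises(ParameterError):
            simulate_binding(m, BindingSpec(), 0)


class TestZdiscGenerator:
    def test_doublet_axial_offset(self, zdisc_thin_form):
        from sarcotomo.zdisc import spacing_and_doublets
        sp = spacing_and_doublets(zdisc_thin_form)
        # ideal doublet spacing 2 x 27.9 Å = 5.58 nm
        d = sp["spacings_nm"][sp["spacings_nm"] < 9]
        assert len(d) > 0
        assert np.allclose(d, 5.58, atol=0.01)

    def test_angle_validation(self):
        with pytest.raises(ParameterError):
            ZdiscSpec(actinin_angle=80.0)

    def test_thickness_orders_with_angle(self, zdisc_pair):
        from sarcotomo.zdisc import zdisc_thickness
        thin_form, thick_form = zdisc_pair
        assert zdisc_thickness(thick_form) > zdisc_thickness(thin_form)

    def test_crosslink_length_exact(self, zdisc_pair):
        for m in zdisc_pair:
            cl = m.crosslinks
            assert np.allclose(cl["length_nm"], 33.0, atol=1e-9)
            assert np.allclose(cl["length_nm"] + 6.0,
                               cl["center_distance_nm"], atol=1e-12)


class TestTropomyosin:
    def test_states_split_at_boundary(self):
        m = build_aband_model(seed=3)
        boundary = 1500.0
        assign_tropomyosin(m, boundary, noise_sd=0.0)
        off = m.subunits["tpm_offset"]
        a_side = m.subunits["y"] <= boundary
        assert (off[a_side] == 0.0).all()
        assert (off[~a_side] == 21.0).all()

    def test_midpoint_boundary_halves_even_counts(self):
        m = SarcomereModel()
        m.filaments = pd.DataFrame(
            [dict(kind="thin", polarity="plus_toward_z_disc", x=0.0, z=0.0,
                  y0=0.0, length=100 * 27.9, ax=0.0, ay=1.0, az=0.0,
                  neighbors="")], index=pd.Index([0], name="id"))
        populate_subunits(m, HelixSpec())
        m.subunits = m.subunits.iloc[:100]
        mid = (m.subunits["y"].iloc[49] + m.subunits["y"].iloc[50]) / 2
        assign_tropomyosin(m, mid, noise_sd=0.0)
        assert (m.subunits["tpm_offset"] == 0.0).sum() == 50
        assert (m.subunits["tpm_offset"] == 21.0).sum() == 50


class TestRasterize:
    def test_noiseless_peak_on_axis(self):
        m = build_lattice(LatticeSpec(n_rows=2, n_cols=2, axis_length=60), 0)
        vol = rasterize_volume(m, voxel_size=20.0, filament_radius=40.0)
        idx = np.unravel_index(np.argmax(vol.data), vol.data.shape)
        p = np.asarray(vol.origin) + np.asarray(idx) * vol.voxel_size
        lat = np.hypot(m.filaments["x"] - p[0], m.filaments["z"] - p[2])
        assert lat.min() <= vol.voxel_size

    def test_noise_volume_mean_near_zero(self):
        m = SarcomereModel()
        m.filaments = pd.DataFrame(
            [dict(kind="thin", polarity="plus_toward_z_disc", x=0.0, z=0.0,
                  y0=0.0, length=500.0, ax=0.0, ay=1.0, az=0.0, neighbors="")],
            index=pd.Index([0], name="id"))
        vol = rasterize_volume(m, voxel_size=20.0, filament_radius=40.0,
                               snr=0.5, seed=0)
        noise = vol.data - rasterize_volume(m, voxel_size=20.0,
                                            filament_radius=40.0).data
        assert abs(noise.mean()) < 3 * noise.std() / np.sqrt(noise.size)

    def test_rendered_lattice_spacing(self):
        # line profile across a noiseless render reproduces the 45 nm
        # thick-thick spacing
        m = build_lattice(LatticeSpec(n_rows=1, n_cols=3, axis_length=60,
                                      band="A"), 0)
        m.filaments = m.filaments[m.filaments["kind"] == "thick"]
        vol = rasterize_volume(m, voxel_size=15.0, filament_radius=40.0)
        iy = vol.data.shape[1] // 2
        iz = int(round((0.0 - vol.origin[2]) / vol.voxel_size))
        profile = vol.data[:, iy, iz]
        peaks = [i for i in range(1, len(profile) - 1)
                 if profile[i] >= profile[i - 1] and profile[i] >= profile[i + 1]
                 and profile[i] > 0.5 * profile.max()]
        spac = np.diff([vol.origin[0] + i * vol.voxel_size for i in peaks])
        assert np.allclose(spac, 450.0, atol=vol.voxel_size)

    def test_missing_wedge_attenuates(self):
        m = build_lattice(LatticeSpec(n_rows=2, n_cols=2, axis_length=60), 0)
        clean = rasterize_volume(m, voxel_size=20.0, filament_radius=40.0)
        wedged = rasterize_volume(m, voxel_size=20.0, filament_radius=40.0,
                                  missing_wedge_halfangle=30.0)
        assert wedged.data.shape == clean.data.shape
        assert not np.allclose(wedged.data, clean.data)
        # DC survives: overall mass preserved
        assert wedged.data.sum() == pytest.approx(clean.data.sum(), rel=1e-6)
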