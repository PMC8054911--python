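"""Tracing: equator filter, blob detection, linking, lattice statistics."""

import numpy as np
import pandas as pd
import pytest

from sarcotomo.errors import InsufficientDataError, ParameterError
from sarcotomo.io import Volume
from sarcotomo.specs import LatticeSpec
from sarcotomo.synth import build_lattice, rasterize_volume
from sarcotomo.tracing import (FilamentTrace, detect_cross_sections,
                               equator_filter, link_detections,
                               measure_lattice, traces_from_model)


@pytest.fixture(scope="module")
def hex_volume():
    lat = LatticeSpec(n_rows=3, n_cols=3, axis_length=150)
    model = build_lattice(lat, seed=0)
    vol = rasterize_volume(model, voxel_size=20.0, filament_radius=40.0)
    return model, vol


class TestEquatorFilter:
    def test_full_band_is_identity(self, hex_volume):
        _, vol = hex_volume
        out = equator_filter(vol.data, 0.5)
        assert np.allclose(out, vol.data, atol=1e-5 * vol.data.max())

    def test_idempotent_projection(self, hex_volume):
        _, vol = hex_volume
        once = equator_filter(vol.data, 0.07)
        twice = equator_filter(once, 0.07)
        # single-precision FFT round trip: tolerance at float32 epsilon scale
        assert np.allclose(once, twice, atol=1e-5 * max(vol.data.max(), 1.0))

    def test_dc_preserved_exactly(self, hex_volume):
        _, vol = hex_volume
        out = equator_filter(vol.data, 0.03)
        for iz in range(vol.data.shape[2]):
            assert out[:, :, iz].sum() == pytest.approx(
                float(vol.data[:, :, iz].sum()), rel=1e-5, abs=1e-7)

    def test_suppresses_transverse_keeps_axial(self):
        # an axial tube plus transverse cross-bridge blobs: the filter
        # must flatten the blobs while keeping the tube ridge
        nx, ny, nz = 40, 64, 9
        x = (np.arange(nx) - 20.0)[:, None, None]
        y = np.arange(ny)[None, :, None]
        tube = np.exp(-x ** 2 / (2 * 2.0 ** 2)) * np.ones((1, ny, nz))
        bridges = (np.exp(-(x - 8) ** 2 / (2 * 1.5 ** 2))
                   * np.exp(-((y % 16) - 8.0) ** 2 / (2 * 1.5 ** 2))
                   * np.ones((1, 1, nz)))
        data = tube + bridges
        out = equator_filter(data, 0.04)
        ridge_in = data[20, :, 4].mean()
        ridge_out = out[20, :, 4].mean()
        assert ridge_out == pytest.approx(ridge_in, rel=0.10)
        bridge_peak_in = data[28, 8, 4]
        bridge_peak_out = out[28, 8, 4]
        assert bridge_peak_out < 0.5 * bridge_peak_in

    def test_bad_halfwidth(self, hex_volume):
        with pytest.raises(ParameterError):
            equator_filter(hex_volume[1].data, 0.0)


class TestDetect:
    def test_single_filament_one_detection_per_plane(self):
        model = build_lattice(LatticeSpec(n_rows=1, n_cols=1, axis_length=100), 0)
        vol = rasterize_volume(model, voxel_size=20.0, filament_radius=40.0)
        dets = detect_cross_sections(vol, blob_sigma=50.0,
                                     threshold=0.05 * vol.data.max())
        per_plane = dets.groupby("plane_index").size()
        assert (per_plane == 1).all()
        # sub-voxel accuracy against the known axis
        err = np.hypot(dets["x"] - model.filaments.iloc[0]["x"],
                       dets["z"] - model.filaments.iloc[0]["z"])
        assert (err <= 0.5 * vol.voxel_size).all()

    def test_empty_volume_no_detections(self):
        vol = Volume(np.zeros((16, 16, 16), dtype=np.float32), 20.0)
        dets = detect_cross_sections(vol, blob_sigma=40.0, threshold=0.1)
        assert len(dets) == 0

    def test_hexagonal_count_matches_filaments(self, hex_volume):
        model, vol = hex_volume
        filt = equator_filter(vol.data, 0.05)
        fvol = Volume(filt, vol.voxel_size, vol.origin)
        dets = detect_cross_sections(fvol, blob_sigma=50.0,
                                     threshold=0.05 * filt.max(), plane_step=4)
        # interior planes cross every filament
        interior = dets[(dets["y"] > 200) & (dets["y"] < 1300)]
        counts = interior.groupby("plane_index").size()
        assert (counts == len(model.filaments)).all()

    def test_sigma_below_voxel_rejected(self, hex_volume):
        with pytest.raises(ParameterError):
            detect_cross_sections(hex_volume[1], blob_sigma=5.0, threshold=0.1)


class TestLink:
    def test_recovers_all_filaments(self, hex_volume):
        model, vol = hex_volume
        filt = equator_filter(vol.data, 0.05)
        fvol = Volume(filt, vol.voxel_size, vol.origin)
        dets = detect_cross_sections(fvol, blob_sigma=50.0,
                                     threshold=0.05 * filt.max(), plane_step=4)
        traces = link_detections(dets, min_length=750.0)
        assert len(traces) == len(model.filaments)
        # mean axis error below one voxel; endpoints inside the box
        for tr in traces:
            err = min(np.hypot(tr.points[:, 0] - row["x"],
                               tr.points[:, 2] - row["z"]).mean()
                      for _, row in model.filaments.iterrows())
            assert err < vol.voxel_size
            lo = np.asarray(vol.origin)
            hi = lo + np.asarray(vol.data.shape) * vol.voxel_size
            assert (tr.points >= lo - 1e-6).all() and (tr.points <= hi + 1e-6).all()

    def test_separated_filaments_never_merged(self):
        rows = []
        for ip in range(10):
            rows.append(dict(plane_index=ip, x=0.0, y=ip * 100.0, z=0.0,
                             response=1.0))
            rows.append(dict(plane_index=ip, x=1000.0, y=ip * 100.0, z=0.0,
                             response=1.0))
        traces = link_detections(pd.DataFrame(rows), max_step=150.0,
                                 min_length=500.0)
        assert len(traces) == 2
        for tr in traces:
            assert np.ptp(tr.points[:, 0]) < 1.0

    def test_gap_bridged(self):
        rows = [dict(plane_index=ip, x=0.0, y=ip * 100.0, z=0.0, response=1.0)
                for ip in range(10) if ip != 5]
        traces = link_detections(pd.DataFrame(rows), max_step=150.0,
                                 min_length=500.0)
        assert len(traces) == 1
        assert len(traces[0].points) == 9

    def test_empty_input(self):
        assert link_detections(pd.DataFrame(), 100.0) == []


class TestLattice:
    def test_perfect_lattice_statistics(self):
        model = build_lattice(LatticeSpec(), 0)
        stats = measure_lattice(traces_from_model(model), 1500.0)
        assert stats["hexagonal_order"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(stats["thick_thick_nn_nm"], 45.0)
        assert np.allclose(stats["thin_neighbor_nn_nm"], 45.0 / np.sqrt(3.0))
        assert round(float(np.median(stats["thin_neighbor_nn_nm"]))) == 26

    def test_jitter_lowers_order(self):
        ordered = build_lattice(LatticeSpec(jitter_sd=0.0), 0)
        disordered = build_lattice(LatticeSpec(band="I", jitter_sd=6.0), 1)
        s_a = measure_lattice(traces_from_model(ordered), 1500.0)
        s_i = measure_lattice(traces_from_model(disordered), 1500.0)
        assert s_i["hexagonal_order"] < s_a["hexagonal_order"]

    def test_too_few_traces(self):
        model = build_lattice(LatticeSpec(n_rows=1, n_cols=2), 0)
        model.filaments = model.filaments.iloc[:2]
        with pytest.raises(InsufficientDataError):
            measure_lattice(traces_from_model(model), 1500.0)
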