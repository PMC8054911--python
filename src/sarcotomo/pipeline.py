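"""End-to-end pipeline: simulate -> (rasterize + trace) -> analyses -> report.

The run configuration is a plain nested dict (round-trips through YAML);
every stage draws its randomness from the single top-level seed and the
final JSON report aggregates the headline metrics of every enabled
stage, so the same config + seed always produces an identical report.
"""

from __future__ import annotations

import copy
import json
import logging
import os
from typing import Optional

import numpy as np

from . import binding as _binding
from . import synth as _synth
from . import tpm as _tpm
from . import tracing as _tracing
from . import zdisc as _zdisc
from .errors import SarcotomoError
from .helix import HelicalParams, estimate_helical_params
from .io import write_model, write_traces, write_volume
from .specs import BindingSpec, HelixSpec, LatticeSpec, ZdiscSpec

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "lattice": {},            # LatticeSpec overrides
    "helix": {},              # HelixSpec overrides
    "binding": {},            # BindingSpec overrides
    "zdisc": {"thin_form_angle": 128.0, "thick_form_angle": 158.0},
    "tpm": {"noise_sd": 3.0, "state_offset": 21.0},
    "rasterize": {"enabled": False, "voxel_size": 20.0,
                  "filament_radius": 40.0, "snr": None,
                  "missing_wedge_halfangle": None},
    "analyses": {"binding": True, "zdisc": True, "tpm": True},
    "plots": True,
}


def merge_config(overrides: Optional[dict]) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: Optional[dict], out_dir: str) -> dict:
    """Run the configured stages and write results under ``out_dir``.

    Stage failures abort with a stage-tagged error; outputs written by
    earlier stages are kept.
    """
    cfg = merge_config(config)
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed}

    stage = "simulate"
    try:
        lattice = LatticeSpec(**cfg["lattice"])
        helix = HelixSpec(**cfg["helix"])
        bspec = BindingSpec(**cfg["binding"])
        model = _synth.build_aband_model(lattice, helix, bspec, seed=seed)
        write_model(model, os.path.join(out_dir, "aband_model"))
        report["simulate"] = dict(
            n_thin=len(model.thin_ids()), n_thick=len(model.thick_ids()),
            n_subunits=len(model.subunits), n_heads=len(model.heads),
            theoretical_heads=model.meta.get("theoretical_heads"))

        if cfg["rasterize"]["enabled"]:
            stage = "rasterize+trace"
            r = cfg["rasterize"]
            vol = _synth.rasterize_volume(
                model, voxel_size=r["voxel_size"],
                filament_radius=r["filament_radius"], snr=r["snr"],
                missing_wedge_halfangle=r["missing_wedge_halfangle"],
                seed=seed + 10)
            write_volume(vol, os.path.join(out_dir, "aband.mrc"))
            filt = _tracing.equator_filter(vol.data, 0.05)
            fvol = type(vol)(data=filt, voxel_size=vol.voxel_size,
                             origin=vol.origin)
            dets = _tracing.detect_cross_sections(
                fvol, blob_sigma=1.2 * r["filament_radius"],
                threshold=0.1 * float(filt.max()), plane_step=4)
            traces = _tracing.link_detections(
                dets, plane_spacing=4 * vol.voxel_size,
                min_length=0.5 * lattice.axis_length * 10.0)
            write_traces(traces, os.path.join(out_dir, "traces.tsv"))
            report["trace"] = dict(n_detections=len(dets),
                                   n_traces=len(traces),
                                   n_filaments_true=len(model.filaments))

        plot_dir = out_dir if cfg.get("plots") else None
        if cfg["analyses"]["binding"]:
            stage = "analyze-binding"
            report["binding"] = _analyze_binding(model, seed, plot_dir)

        if cfg["analyses"]["zdisc"]:
            stage = "analyze-zdisc"
            report["zdisc"] = _analyze_zdisc(cfg, lattice, seed, plot_dir)

        if cfg["analyses"]["tpm"]:
            stage = "analyze-tpm"
            report["tpm"] = _analyze_tpm(cfg, model, seed, plot_dir)
    except SarcotomoError as exc:
        raise SarcotomoError(f"stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _analyze_binding(model, seed: int, plot_dir: Optional[str] = None) -> dict:
    heads, summary = _binding.assign_heads(model.heads, model)
    topo = _binding.classify_head_topology(heads, model)
    orient = _binding.bound_orientations(model)
    spans = {}
    if len(orient):
        dist = _binding.angular_distribution(
            orient["rel_orientation"].to_numpy(), orient["group"].to_numpy())
        spans = {g: d["span"] for g, d in dist.items()}
        if plot_dir:
            from .plots import plot_angular_distribution
            plot_angular_distribution(
                dist, os.path.join(plot_dir, "angular_distribution.png"))
    bound, free = _binding.measure_thin_thick_distances(model)
    dstats = _binding.distance_statistics(bound, free, seed=seed)
    if plot_dir and len(bound) and len(free):
        from .plots import plot_distance_histograms
        plot_distance_histograms(
            bound, free, os.path.join(plot_dir, "distance_histograms.png"))
    # helical parameters recovered from the first thin filament
    thin0 = model.thin_ids()[0]
    subs = model.subunits[model.subunits["filament_id"] == thin0]
    params = estimate_helical_params(subs[["x", "y", "z"]].to_numpy())
    return dict(
        occupancy=summary["occupancy"], n_assigned=summary["n_assigned"],
        n_theoretical=summary["n_theoretical"], topology=topo,
        angular_span_by_group=spans,
        mean_angular_span=(float(np.mean(list(spans.values())))
                           if spans else None),
        bound_mean_nm=dstats["bound"]["mean"],
        free_mean_nm=dstats["free"]["mean"],
        distance_difference_nm=dstats["difference"]["mean"],
        distance_difference_ci=dstats["difference"]["ci"],
        estimated_twist_deg=params.twist,
        estimated_rise_A=params.rise,
    )


def _analyze_zdisc(cfg, lattice, seed: int,
                   plot_dir: Optional[str] = None) -> dict:
    zcfg = cfg["zdisc"]
    extra = {k: v for k, v in zcfg.items()
             if k not in ("thin_form_angle", "thick_form_angle")}
    zlat = LatticeSpec(n_rows=2, n_cols=max(4, lattice.n_cols), band="Z",
                       thick_spacing=lattice.thick_spacing,
                       axis_length=lattice.axis_length)
    models = []
    for i, ang in enumerate((zcfg["thin_form_angle"], zcfg["thick_form_angle"])):
        spec = ZdiscSpec(actinin_angle=ang, **extra)
        models.append(_synth.build_zdisc(spec, zlat, seed=seed + 20 + i))
    sp = _zdisc.spacing_and_doublets(models[0])
    hinge = _zdisc.thickness_and_hinge(models)
    if plot_dir:
        from .plots import plot_spacing_histogram
        plot_spacing_histogram(sp, os.path.join(plot_dir, "crosslink_spacings.png"))
    return dict(
        mean_length_nm=float(models[0].crosslinks["length_nm"].mean()),
        mean_angle_deg=[float(m.crosslinks["angle_deg"].mean()) for m in models],
        thickness_nm=hinge.thickness_nm,
        doublet_count=sp["doublet_count"],
        spacing_peaks_nm=sp["peak_bins_nm"],
        thickness_angle_pearson=hinge.pearson_r,
    )


def _analyze_tpm(cfg, model, seed: int,
                 plot_dir: Optional[str] = None) -> dict:
    tcfg = cfg["tpm"]
    # boundary at 2/3 of the axis: the A-band occupies the M-band side
    boundary = float(model.filaments["length"].iloc[0]) * 2.0 / 3.0
    _synth.assign_tropomyosin(model, boundary,
                              state_offset=tcfg["state_offset"],
                              noise_sd=tcfg["noise_sd"], seed=seed + 30)
    thin0 = model.thin_ids()[0]
    subs = model.subunits[model.subunits["filament_id"] == thin0]
    sections = _tpm.section_and_classify(subs, boundary,
                                         ref_c=tcfg["state_offset"])
    trans = _tpm.locate_transition(sections)
    if plot_dir:
        from .plots import plot_tpm_sections
        plot_tpm_sections(sections, os.path.join(plot_dir, "tpm_sections.png"))
    return dict(
        sections=[dict(index=s.section_index, state=s.state,
                       mean_offset=round(s.mean_offset, 2), n=s.n_subunits)
                  for s in sections],
        transition_section=trans,
    )
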