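"""Matplotlib figures for the standard analyses (Agg backend, file output)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

GROUP_COLORS = {"R": "tab:red", "G": "tab:green", "B": "tab:blue"}


def plot_angular_distribution(dist: dict, path: str) -> None:
    """Circular histogram of bound-subunit orientations per thick group."""
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(5, 5))
    for g, d in dist.items():
        edges = np.radians(d["bin_edges"])
        centers = (edges[:-1] + edges[1:]) / 2
        ax.bar(centers, d["histogram"], width=np.diff(edges), alpha=0.6,
               color=GROUP_COLORS.get(g), label=f"{g} (n={d['n']})")
    ax.set_title("bound actin subunit orientations")
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_spacing_histogram(spacing: dict, path: str) -> None:
    """3 nm-binned histogram of consecutive cross-link spacings."""
    fig, ax = plt.subplots(figsize=(5, 3))
    if len(spacing["spacings_nm"]):
        ax.hist(spacing["spacings_nm"], bins=spacing["bin_edges"],
                color="tab:blue", edgecolor="k")
    ax.set_xlabel("spacing between adjacent cross-links (nm)")
    ax.set_ylabel("count")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_tpm_sections(sections, path: str) -> None:
    """State strip along the filament: M (yellow), intermediate, C (blue)."""
    color = {"M": "gold", "intermediate": "lightgray", "C": "tab:blue"}
    fig, ax = plt.subplots(figsize=(6, 1.6))
    for s in sections:
        ax.barh(0, s.y_end - s.y_start, left=s.y_start,
                color=color.get(s.state, "white"), edgecolor="k")
        ax.text((s.y_start + s.y_end) / 2, 0, str(s.section_index),
                ha="center", va="center", fontsize=8)
    ax.set_yticks([])
    ax.set_xlabel("axial position (nm)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_distance_histograms(bound, free, path: str, bins: int = 40) -> None:
    """Overlaid bound / free thin-to-thick distance histograms."""
    both = np.concatenate([np.asarray(bound), np.asarray(free)])
    lo, hi = float(both.min()), float(both.max())
    if hi - lo < 1e-9:          # degenerate (e.g. jitter-free lattice)
        lo, hi = lo - 1.0, hi + 1.0
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(free, bins=bins, range=(lo, hi), alpha=0.6, color="tab:green",
            label="free", density=True)
    ax.hist(bound, bins=bins, range=(lo, hi), alpha=0.6, color="tab:orange",
            label="bound", density=True)
    ax.set_xlabel("thin-to-thick filament distance (nm)")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
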