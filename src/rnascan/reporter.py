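"""Graphic and text outputs: per-nucleotide line plots, structure-count
histogram and position list, and the binned % structure content profile with
its 1D heatmap strip and ranked table.

All tables are plain TSV with one header line and 1-based closed coordinates.
Plots are written in both raster (PNG) and vector (SVG) form.  The heat strip
uses a fixed sequential colormap over 0-100 % so plots of different RNAs are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import Normalize

from .profiler import (
    BIN_TABLE_COLUMNS,
    NucleotideProfile,
    ScanResult,
    StructureCountMask,
    rank_bins,
)

__all__ = [
    "PlotWindow",
    "render_tracks",
    "render_count_histogram",
    "render_heatmap_profile",
    "write_outputs",
]

HEAT_CMAP = "viridis"
IMAGE_FORMATS = ("png", "svg")


@dataclass(frozen=True)
class PlotWindow:
    """Inclusive 1-based nucleotide bounds restricting all visual output."""

    lower: int
    upper: int

    def validate(self, n: int) -> None:
        if not 1 <= self.lower <= self.upper <= n:
            raise ValueError(
                f"plot bounds ({self.lower}, {self.upper}) invalid for length {n}: "
                f"need 1 <= lower <= upper <= N"
            )


def _save(fig, stem: Path) -> list[Path]:
    paths = []
    for fmt in IMAGE_FORMATS:
        p = stem.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def _line_plot(x, y, ylabel: str, title: str, stem: Path, color: str) -> list[Path]:
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(x, y, lw=0.8, color=color)
    ax.set_xlabel("Nucleotide position")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    return _save(fig, stem)


def render_tracks(
    profile: NucleotideProfile, bounds: PlotWindow, out_dir, run_name: str
) -> list[Path]:
    """Line plots of windowed BPC and smoothed SE against nucleotide position."""
    bounds.validate(profile.length)
    out_dir = Path(out_dir)
    sl = slice(bounds.lower - 1, bounds.upper)
    x = np.arange(bounds.lower, bounds.upper + 1)
    paths = _line_plot(
        x, profile.bpc[sl], "Base-pair content (%)",
        f"{run_name}: windowed base-pair content (W={profile.window})",
        out_dir / f"{run_name}_bpc", "tab:blue",
    )
    paths += _line_plot(
        x, profile.se_smooth[sl], "Smoothed Shannon entropy",
        f"{run_name}: median-smoothed Shannon entropy (W={profile.window})",
        out_dir / f"{run_name}_entropy", "tab:orange",
    )
    return paths


def render_count_histogram(
    mask: StructureCountMask, bin_size: int, bounds: PlotWindow, out_dir, run_name: str
) -> list[Path]:
    """Histogram of structure-count positions plus the plain-text position list."""
    bounds.validate(mask.mask.size)
    out_dir = Path(out_dir)
    positions = mask.positions
    txt = out_dir / f"{run_name}_structure_counts.txt"
    txt.write_text("".join(f"{p}\n" for p in positions))

    in_bounds = positions[(positions >= bounds.lower) & (positions <= bounds.upper)]
    edges = np.arange(bounds.lower, bounds.upper + bin_size + 1, bin_size)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.hist(in_bounds, bins=edges, color="tab:green", edgecolor="none")
    ax.set_xlabel("Nucleotide position")
    ax.set_ylabel(f"Structure counts / {bin_size} nt")
    ax.set_title(f"{run_name}: structure-count histogram")
    fig.tight_layout()
    return [txt] + _save(fig, out_dir / f"{run_name}_structure_counts_hist")


def render_heatmap_profile(
    table: pd.DataFrame, bounds: PlotWindow, out_dir, run_name: str
) -> list[Path]:
    """Line plot of % structure content per bin with a 1D heat strip underneath,
    plus the ranked TSV table (descending % structure content, ties by start).
    """
    n = int(table["bin_end"].iloc[-1])
    bounds.validate(n)
    out_dir = Path(out_dir)

    ranked = rank_bins(table)
    tsv = out_dir / f"{run_name}_structure_content.tsv"
    _write_table(ranked, tsv)

    vis = table[
        (table["bin_end"] >= bounds.lower) & (table["bin_start"] <= bounds.upper)
    ]
    centers = (vis["bin_start"] + vis["bin_end"]) / 2.0
    pct = vis["pct_structure_content"].to_numpy()

    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(10, 3.8), sharex=True,
        gridspec_kw={"height_ratios": [5, 1], "hspace": 0.08},
    )
    ax.plot(centers, pct, lw=1.2, color="black", marker="o", ms=2.5)
    ax.set_ylabel("% structure content")
    ax.set_ylim(-3, 103)
    ax.set_title(f"{run_name}: binned structure content")

    norm = Normalize(vmin=0.0, vmax=100.0)
    cmap = plt.get_cmap(HEAT_CMAP)
    for row in vis.itertuples(index=False):
        axh.axvspan(
            row.bin_start - 0.5, row.bin_end + 0.5,
            color=cmap(norm(row.pct_structure_content)),
        )
    axh.set_yticks([])
    axh.set_xlabel("Nucleotide position")
    axh.set_xlim(bounds.lower - 0.5, bounds.upper + 0.5)
    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap=cmap),
        ax=[ax, axh], pad=0.01, label="% structure content",
    )
    return [tsv] + _save(fig, out_dir / f"{run_name}_structure_content")


def _write_table(table: pd.DataFrame, path: Path) -> None:
    out = table[BIN_TABLE_COLUMNS].copy()
    out["pct_structure_content"] = out["pct_structure_content"].map(
        lambda v: f"{v:.4f}"
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_outputs(
    result: ScanResult, bounds: PlotWindow, out_dir, run_name: str
) -> list[Path]:
    """Write the complete output set for one scan; returns all paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    # per-nucleotide tracks as text alongside the line plots
    from .structure_io import write_track

    bpc_txt = out_dir / f"{run_name}_bpc.tsv"
    bpc_txt.write_text(write_track(result.profile.bpc))
    se_txt = out_dir / f"{run_name}_entropy.tsv"
    se_txt.write_text(write_track(result.profile.se_smooth))
    paths += [bpc_txt, se_txt]
    paths += render_tracks(result.profile, bounds, out_dir, run_name)
    paths += render_count_histogram(
        result.counts, result.bin_size, bounds, out_dir, run_name
    )
    paths += render_heatmap_profile(result.bins, bounds, out_dir, run_name)
    return paths
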