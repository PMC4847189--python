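"""Report figures: enrichment bars, sequence logo, RNA counts, fibre traces.

Rendering is a side product — the tested objects are the tables and
matrices these figures are drawn from.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from satcen.consensus import BaseFrequencyMatrix
from satcen.fibres import FibreProfile

_BASE_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}


def plot_enrichment(table, path: str | Path, title: str = "IP/input enrichment") -> None:
    """Bar chart of per-family enrichment ratios."""
    df = table.frame if hasattr(table, "frame") else table
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(df.entry, df.ratio.fillna(0.0), color="#4c72b0")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("normalized IP / input ratio")
    ax.set_title(title)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_logo(matrix: BaseFrequencyMatrix, path: str | Path, per_row: int = 60) -> None:
    """Sequence logo: letters stacked per position, scaled by frequency times
    information content (bits)."""
    freq = np.nan_to_num(matrix.frequencies)
    info = matrix.information_bits
    L = matrix.monomer_length
    n_rows = int(np.ceil(L / per_row))
    fig, axes = plt.subplots(n_rows, 1, figsize=(min(per_row, L) * 0.14, 1.2 * n_rows), squeeze=False)
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for r in range(n_rows):
        ax = axes[r][0]
        lo, hi = r * per_row, min((r + 1) * per_row, L)
        for pos in range(lo, hi):
            order = np.argsort(freq[pos])  # small letters at the bottom
            y = 0.0
            for b in order:
                h = freq[pos, b] * info[pos]
                if h <= 1e-3:
                    continue
                base = "ACGT"[b]
                tp = TextPath((0, 0), base, size=1.0, prop=font)
                bb = tp.get_extents()
                trans = (
                    Affine2D()
                    .translate(-bb.x0, -bb.y0)
                    .scale(0.9 / bb.width, h / bb.height)
                    .translate(pos - lo + 0.05, y)
                )
                ax.add_patch(PathPatch(trans.transform_path(tp), color=_BASE_COLORS[base], lw=0))
                y += h
        ax.set_xlim(0, per_row)
        ax.set_ylim(0, 2)
        ax.set_ylabel("bits", fontsize=7)
        ax.set_xticks([0, hi - lo])
        ax.set_xticklabels([lo + 1, hi], fontsize=7)
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rna_counts(counts, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(counts.window, counts.raw_count, color="#55a868")
    ax.set_ylabel(f"reads per {int(counts.window_length.iloc[0])} bp window")
    ax.set_title("satellite vs gene transcription")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fibre(profile: FibreProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 2.2))
    ax.plot(profile.positions, profile.red, color="#d62728", lw=1, label="satellite (red)")
    ax.plot(profile.positions, profile.green, color="#2ca02c", lw=1, label="CENP-A (green)")
    if profile.red_stretch:
        ax.axvspan(*profile.red_stretch, color="#d62728", alpha=0.08)
    for g0, g1 in profile.green_blocks:
        ax.axvspan(g0, g1, color="#2ca02c", alpha=0.15)
    label = profile.pattern_class or "?"
    ax.set_title(f"{profile.fibre_id} — pattern {label}", fontsize=9)
    ax.set_xlabel("position along fibre")
    ax.set_ylabel("intensity")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
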