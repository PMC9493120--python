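"""Optional matplotlib figures for the main panels (length distribution,
positional base frequencies, overlap histogram)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_length_distribution(length_dist: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, col, label in zip(axes, ("read_count", "tag_count"), ("reads", "tags")):
        ax.bar(length_dist.index, length_dist[col], color="#4878d0")
        ax.set_xlabel("length (nt)")
        ax.set_ylabel(label)
    fig.suptitle(title or "candidate piRNA length distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_base_freq(base_freq: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(8, 3.2))
    bottom = None
    for base, color in zip("ACGT", ("#2ca02c", "#1f77b4", "#ff7f0e", "#d62728")):
        vals = base_freq[base]
        ax.bar(base_freq.index, vals, bottom=bottom, label=base, color=color)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("position (5' -> 3')")
    ax.set_ylabel("frequency")
    ax.legend(ncol=4, fontsize=8)
    ax.set_title(title or "positional base frequencies")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_overlap_histogram(hist_frame: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.2))
    colors = ["#d62728" if o == 10 else "#4878d0" for o in hist_frame["overlap"]]
    ax.bar(hist_frame["overlap"], hist_frame["weight"], color=colors)
    ax.set_xlabel("5' overlap (nt)")
    ax.set_ylabel("pair weight")
    ax.set_title(title or "ping-pong 5' overlap histogram")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
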