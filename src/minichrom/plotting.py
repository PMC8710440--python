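"""Figure-style plots: CNV ratio along chr9 and B deficiency dot tracks."""
from __future__ import annotations

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cnv import RatioTrack
from .deficiency import DeficiencyTrack


def plot_ratio_track(track: RatioTrack, path, scale_factor: float, title: str = "") -> None:
    """log2 sample:reference ratio per gene window along the chromosome."""
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ok = track.unmasked
    x = track.window_starts()[ok] / scale_factor
    ax.scatter(x, track.log2_ratio[ok], s=6, c="crimson")
    ax.axhline(0.0, lw=0.5, c="grey")
    ax.set_xlabel("position (paper-Mb)")
    ax.set_ylabel("log2 ratio")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deficiency_track(track: DeficiencyTrack, path, scale_factor: float,
                          title: str = "") -> None:
    """log10 B-specific read counts per 1 paper-kb window."""
    fig, ax = plt.subplots(figsize=(8, 2.5))
    x = (track.window_size * (0.5 + np.arange(len(track.counts)))) / scale_factor
    ax.scatter(x, track.log10_counts, s=3, c="black")
    ax.set_xlabel("position (paper-Mb)")
    ax.set_ylabel("log10(reads + 1)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
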