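"""Minimal plotting: the genome-wide ED track with threshold and intervals."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd


def plot_ed_track(frame: pd.DataFrame, threshold: float,
                  intervals: Sequence = (), path: Optional[str] = None):
    """Raw/fitted ED per chromosome with the significance threshold.

    ``frame`` must carry chrom, pos, ed_raw, ed_fitted. Returns the figure;
    saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(frame["chrom"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(2.2 * len(chroms), 3),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = frame[frame["chrom"] == chrom]
        ax.scatter(sub["pos"] / 1e6, sub["ed_raw"], s=2, alpha=0.3,
                   color="tab:blue")
        ax.plot(sub["pos"] / 1e6, sub["ed_fitted"], color="black", lw=1)
        ax.axhline(threshold, color="red", ls="--", lw=0.8)
        for iv in intervals:
            if iv.chrom == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="orange",
                           alpha=0.3)
        ax.set_title(chrom, fontsize=8)
        ax.set_xlabel("Mb", fontsize=7)
    axes[0][0].set_ylabel("ED")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
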