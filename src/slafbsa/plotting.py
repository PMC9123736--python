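"""Three-panel scan plot: per-bulk SNP-index and Δ(SNP-index) with the
sliding-window curve and the significance threshold."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scan import NullThreshold, SnpIndexPoint, WindowPoint


def plot_scan(
    points: Sequence[SnpIndexPoint],
    windows: Sequence[WindowPoint],
    threshold: NullThreshold | None,
    path: str | Path,
) -> None:
    chroms = sorted({p.chrom for p in points if not p.masked})
    fig, axes = plt.subplots(
        3, len(chroms), figsize=(4 * max(len(chroms), 1), 8),
        sharex="col", squeeze=False,
    )
    for ci, chrom in enumerate(chroms):
        pts = [p for p in points if p.chrom == chrom and not p.masked]
        ws = [w for w in windows if w.chrom == chrom]
        x = [p.pos / 1e6 for p in pts]
        wx = [w.midpoint_pos / 1e6 for w in ws]
        panels = (
            ("SNP-index (high)", [p.index_high for p in pts], None),
            ("SNP-index (low)", [p.index_low for p in pts], None),
            ("Δ(SNP-index)", [p.delta for p in pts], [w.m for w in ws]),
        )
        for ri, (label, y, wy) in enumerate(panels):
            ax = axes[ri][ci]
            ax.scatter(x, y, s=2, alpha=0.4, color="tab:blue")
            if wy is not None and wx:
                ax.plot(wx, wy, color="black", lw=1)
            if ri == 2 and threshold is not None:
                ax.axhline(threshold.threshold, color="red", ls="--", lw=0.8)
                ax.axhline(-threshold.threshold, color="red", ls="--", lw=0.8)
            ax.set_ylabel(label)
            if ri == 0:
                ax.set_title(chrom)
            if ri == 2:
                ax.set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
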