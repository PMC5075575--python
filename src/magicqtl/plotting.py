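"""Minimal plotting hooks for scan tracks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless environments
import matplotlib.pyplot as plt
import numpy as np

from .scan import ScanResult
from .significance import FDRResult

__all__ = ["plot_scan"]


def plot_scan(
    scan: ScanResult,
    fdr: FDRResult | None = None,
    threshold_logp: float = 4.0,
    path=None,
):
    """Per-chromosome -log10 P tracks with the FDR line.

    The dashed line marks the -log10 P whose q-value equals 0.05 and is
    omitted when no q-value falls below 0.05.
    """
    chroms = list(dict.fromkeys(scan.table["chrom"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(4 * len(chroms), 3),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = scan.table[scan.table["chrom"] == chrom]
        ax.plot(sub["cM"], sub["neg_log10_p"], lw=0.8, color="steelblue")
        ax.axhline(threshold_logp, color="grey", lw=0.6)
        if fdr is not None and fdr.p_at_q05 is not None:
            ax.axhline(-np.log10(max(fdr.p_at_q05, 1e-300)),
                       linestyle="--", color="firebrick", lw=0.8)
        ax.set_title(f"{scan.trait} {chrom}".strip())
        ax.set_xlabel("cM")
    axes[0][0].set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
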