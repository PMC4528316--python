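"""Genome-wide scan profile plots."""

from __future__ import annotations

import numpy as np

from .regions import RegionSet
from .scan import ScanResult


def _chrom_panels(scan: ScanResult):
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(scan.df["chrom"]))
    fig, axes = plt.subplots(
        1, max(len(chroms), 1), figsize=(3.2 * max(len(chroms), 1), 3.2),
        sharey=True, squeeze=False,
    )
    return fig, axes[0], chroms


def plot_scan_profile(
    scan: ScanResult,
    threshold: float | None = None,
    regions: RegionSet | None = None,
    ax=None,
):
    """-log10(p) along each chromosome, with the outlier threshold dashed
    and called regions shaded."""
    fig, axes, chroms = _chrom_panels(scan)
    for ax_, chrom in zip(axes, chroms):
        grp = scan.df[scan.df["chrom"] == chrom]
        ax_.plot(grp["pos"] / 1e6, grp["neglogp"], lw=0.7, color="steelblue")
        if threshold is not None and np.isfinite(threshold):
            ax_.axhline(threshold, ls=":", color="green")
        if regions is not None:
            for r in regions:
                if r.chrom == chrom:
                    ax_.axvspan(r.left / 1e6, r.right / 1e6, color="gray", alpha=0.3)
        ax_.set_title(str(chrom))
        ax_.set_xlabel("position (Mb)")
    axes[0].set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    return fig


def plot_freq_difference(scan: ScanResult, ax=None):
    """Windowed top-minus-bottom reference-allele frequency difference."""
    fig, axes, chroms = _chrom_panels(scan)
    for ax_, chrom in zip(axes, chroms):
        grp = scan.df[scan.df["chrom"] == chrom]
        ax_.plot(grp["pos"] / 1e6, grp["wdiff"], lw=0.7, color="steelblue")
        ax_.axhline(0.0, color="gray", lw=0.5)
        ax_.set_title(str(chrom))
        ax_.set_xlabel("position (Mb)")
    axes[0].set_ylabel("windowed freq. difference")
    fig.tight_layout()
    return fig
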