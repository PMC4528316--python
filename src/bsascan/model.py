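"""Model/Results surface for the bulked-segregant sequencing scan.

:class:`BsaScan` wraps a pool count table plus the filtering and scan
configuration; :meth:`BsaScan.fit` runs SNP calling, coverage and control
filtering, the windowed Z scan, empirical outlier thresholding and region
calling, and returns a :class:`BsaScanResults` carrying the per-SNP scan
table, the threshold, the called regions and per-stage filter counts.

Typical use::

    model = BsaScan.from_tsv("counts.tsv", top_pool="high", bottom_pool="low")
    res = model.fit()
    print(res.summary())
    res.regions.to_bed("regions.bed")
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .filtering import FilterConfig, FilterReport, run_filters
from .io import PoolCountTable, read_counts
from .regions import RegionSet, call_regions, outlier_threshold
from .scan import ScanConfig, ScanResult, window_scan

__all__ = ["BsaScan", "BsaScanResults"]


class BsaScan:
    """A BSA sequencing scan model over a pool count table.

    Parameters
    ----------
    counts : PoolCountTable
        Per-SNP, per-pool reference-allele and total read counts.
    top_pool, bottom_pool : str
        Names of the two contrast pools (phenotypic tails).  Positive
        statistics mean the reference-parent allele is elevated in
        ``top_pool``.
    control_pool : str or None
        Name of the random control pool; ``None`` disables the control
        frequency filter.
    filter_config, scan_config : optional
        Override the default filtering thresholds / window size.
    """

    def __init__(
        self,
        counts: PoolCountTable,
        top_pool: str,
        bottom_pool: str,
        control_pool: str | None = "control",
        filter_config: FilterConfig | None = None,
        scan_config: ScanConfig | None = None,
    ):
        for p in (top_pool, bottom_pool) + ((control_pool,) if control_pool else ()):
            if p not in counts.pools:
                raise ConfigError(f"pool {p!r} not in table pools {counts.pools}")
        if len(counts.pools) < 2:
            raise ConfigError("a scan needs at least two pools")
        self.counts = counts
        self.top_pool = top_pool
        self.bottom_pool = bottom_pool
        self.control_pool = control_pool
        if filter_config is None:
            filter_config = FilterConfig(control_pool=control_pool or "control")
        elif control_pool is not None:
            filter_config = replace(filter_config, control_pool=control_pool)
        self.filter_config = filter_config
        self.scan_config = scan_config or ScanConfig(
            top_pool=top_pool, bottom_pool=bottom_pool
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, top_pool: str, bottom_pool: str, **kw):
        return cls(PoolCountTable(df), top_pool, bottom_pool, **kw)

    @classmethod
    def from_tsv(cls, path: str | Path, top_pool: str, bottom_pool: str, **kw):
        return cls(read_counts(path), top_pool, bottom_pool, **kw)

    def fit(
        self,
        quantile: float = 0.005,
        flank_snps: int = 7,
        merge_bp: int = 5_000_000,
    ) -> "BsaScanResults":
        """Run the full scan and call regions at the empirical threshold."""
        freqs, report = run_filters(
            self.counts, self.filter_config,
            control_filter=self.control_pool is not None,
        )
        scan = window_scan(freqs, self.counts, self.scan_config)
        nlp = scan.df["neglogp"].to_numpy()
        nlp = nlp[~np.isnan(nlp)]
        if nlp.size:
            threshold = outlier_threshold(nlp, q=quantile)
            regions = call_regions(scan, threshold, flank_snps, merge_bp)
        else:
            threshold = float("nan")
            regions = RegionSet([], float("inf"))
        return BsaScanResults(self, scan, threshold, regions, report)


class BsaScanResults:
    """Fitted scan: per-SNP statistics, threshold, regions, diagnostics."""

    def __init__(
        self,
        model: BsaScan,
        scan: ScanResult,
        threshold: float,
        regions: RegionSet,
        filter_report: FilterReport,
    ):
        self.model = model
        self.scan = scan
        self.threshold = threshold
        self.regions = regions
        self.filter_report = filter_report

    @property
    def n_significant(self) -> int:
        nlp = self.scan.df["neglogp"].to_numpy()
        return int(np.nansum(nlp > self.threshold))

    def summary(self) -> str:
        """Human-readable account of the fit, region table included."""
        m = self.model
        rep = self.filter_report
        lines = [
            "BSA sequencing scan",
            "=" * 67,
            f"contrast: {m.top_pool} vs {m.bottom_pool}"
            + (f"  (control: {m.control_pool})" if m.control_pool else ""),
            f"window size d: {m.scan_config.d} SNPs   "
            f"-log10(p) threshold: {self.threshold:.4f}",
            f"input SNPs: {rep.n_input}   called: {rep.n_called}   "
            f"retained after filters: {rep.n_after_control}",
            f"scanned SNPs: {len(self.scan)}   significant: {self.n_significant}   "
            f"regions: {len(self.regions)}",
            "-" * 67,
        ]
        if len(self.regions):
            lines.append(self.regions.to_frame().to_string(index=False))
        else:
            lines.append("no regions called")
        return "\n".join(lines)

    def plot(self, **kw):
        """Genome-wide -log10(p) profile with the threshold line."""
        from .plotting import plot_scan_profile

        return plot_scan_profile(self.scan, self.threshold, self.regions, **kw)

    def plot_freq_difference(self, **kw):
        """Windowed top-minus-bottom allele-frequency difference profile."""
        from .plotting import plot_freq_difference

        return plot_freq_difference(self.scan, **kw)
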