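"""SNP calling and retention filters for pooled allele-frequency estimation.

Three rules, applied in order, mirror a standard pool-seq BSA workflow:

1. *SNP calling*: a site is a usable SNP when its depth summed across all
   pools is at least ``min_call_depth`` (default 10) and the minor-allele
   frequency of the pooled counts is at least ``min_call_maf`` (default
   0.25).
2. *Coverage filter*: within each pool, a site whose depth is strictly
   below ``min_cov`` (default 20) or strictly above mean + k*SD of depth
   (k = ``max_cov_k``, default 1; mean/SD pooled over all pools jointly,
   sample SD) is marked missing *in that pool* — too-high coverage flags
   collapsed repeats, too-low coverage gives unstable frequency estimates.
3. *Control filter*: sites whose reference-allele frequency in the random
   control pool is missing, strictly below ``control_low`` (0.25) or
   strictly above ``control_high`` (0.75) are discarded entirely — such
   sites segregate aberrantly and are suspect before any selection is
   applied.

All bound comparisons are strict, so boundary values survive.  Allele
frequencies are plug-in ratios ref_count / total_count; missingness is an
explicit state (NaN), never a silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io import PoolCountTable

__all__ = [
    "FilterConfig",
    "FreqTable",
    "pool_frequencies",
    "call_snps",
    "coverage_bounds",
    "apply_coverage_filter",
    "apply_control_filter",
    "run_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for SNP calling and retention.

    Attributes
    ----------
    min_call_depth : int
        Minimum depth summed across pools for a site to be called a SNP.
    min_call_maf : float
        Minimum minor-allele frequency of the pooled counts.
    min_cov : int
        Per-pool lower coverage bound (strict: depth < min_cov is missing).
    max_cov_k : float
        Upper bound multiplier: depth > mean + k*SD is missing.
    control_low, control_high : float
        Retained band (inclusive) of control-pool reference-allele frequency.
    control_pool : str
        Name of the random control pool.
    """

    min_call_depth: int = 10
    min_call_maf: float = 0.25
    min_cov: int = 20
    max_cov_k: float = 1.0
    control_low: float = 0.25
    control_high: float = 0.75
    control_pool: str = "control"

    def __post_init__(self):
        if not (0 <= self.control_low < self.control_high <= 1):
            raise ConfigError(
                f"need 0 <= control_low < control_high <= 1, got "
                f"({self.control_low}, {self.control_high})"
            )
        if self.min_cov < 0 or self.max_cov_k < 0 or self.min_call_depth < 0:
            raise ConfigError("coverage thresholds must be non-negative")


class FreqTable:
    """Per-SNP, per-pool allele-frequency estimates with explicit missingness.

    Wraps a DataFrame with columns ``chrom``, ``pos`` and, per pool,
    ``{pool}_freq`` (reference-parent allele frequency in [0, 1], NaN when
    missing) and ``{pool}_depth`` (total read count carried through).
    """

    def __init__(self, df: pd.DataFrame, pools: Sequence[str]):
        self.df = df.reset_index(drop=True)
        self.pools = list(pools)
        for p in self.pools:
            for c in (f"{p}_freq", f"{p}_depth"):
                if c not in df.columns:
                    raise ValidationError(f"FreqTable missing column {c!r}")

    def __len__(self) -> int:
        return len(self.df)

    def freq(self, pool: str) -> np.ndarray:
        return self.df[f"{pool}_freq"].to_numpy()

    def depth(self, pool: str) -> np.ndarray:
        return self.df[f"{pool}_depth"].to_numpy()

    def copy(self) -> "FreqTable":
        return FreqTable(self.df.copy(), self.pools)


def pool_frequencies(table: PoolCountTable) -> FreqTable:
    """Plug-in frequencies ref/total per pool; zero depth yields NaN."""
    out = table.df[["chrom", "pos"]].copy()
    for p in table.pools:
        tot = table.tot(p).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, table.ref(p) / np.where(tot > 0, tot, 1), np.nan)
        out[f"{p}_freq"] = f
        out[f"{p}_depth"] = table.tot(p)
    return FreqTable(out, table.pools)


def call_snps(table: PoolCountTable, config: FilterConfig) -> set[tuple[str, int]]:
    """SNP-calling rule on pooled counts across all pools.

    A site is called when summed depth >= ``min_call_depth`` and the pooled
    minor-allele frequency >= ``min_call_maf``.  Returns the set of
    (chrom, pos) keys; an empty table yields an empty set.
    """
    if len(table) == 0:
        return set()
    ref = sum(table.ref(p) for p in table.pools).astype(float)
    tot = sum(table.tot(p) for p in table.pools).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(tot > 0, ref / np.where(tot > 0, tot, 1), np.nan)
    maf = np.minimum(pr, 1 - pr)
    called = (tot >= config.min_call_depth) & (maf >= config.min_call_maf)
    df = table.df
    return {
        (c, int(p))
        for c, p, ok in zip(df["chrom"], df["pos"], called)
        if ok
    }


def coverage_bounds(
    table: PoolCountTable, config: FilterConfig
) -> tuple[int, float]:
    """Lower bound from config; upper bound mean + k*SD of depth.

    Mean and sample SD (n-1 denominator) are computed over all (SNP, pool)
    depth cells jointly.  A single cell has undefined sample SD; its SD is
    taken as 0.
    """
    if len(table) == 0:
        raise ValidationError("cannot compute coverage bounds on an empty table")
    depths = np.concatenate([table.tot(p) for p in table.pools]).astype(float)
    mean = depths.mean()
    sd = depths.std(ddof=1) if depths.size > 1 else 0.0
    return config.min_cov, float(mean + config.max_cov_k * sd)


def apply_coverage_filter(
    freqs: FreqTable, min_cov: int, max_cov: float
) -> FreqTable:
    """Mark per-(SNP, pool) cells with depth outside (min_cov, max_cov) missing.

    Both comparisons are strict: depth < min_cov or depth > max_cov.
    Marking is per cell; other pools at the same SNP are untouched.
    """
    if not np.isfinite(max_cov) or min_cov > max_cov:
        raise ConfigError(f"bad coverage bounds ({min_cov}, {max_cov})")
    out = freqs.copy()
    for p in out.pools:
        d = out.df[f"{p}_depth"].to_numpy()
        bad = (d < min_cov) | (d > max_cov)
        col = out.df[f"{p}_freq"].to_numpy(dtype=float, copy=True)
        col[bad] = np.nan
        out.df[f"{p}_freq"] = col
    return out


def apply_control_filter(freqs: FreqTable, config: FilterConfig) -> FreqTable:
    """Drop whole rows whose control-pool frequency is missing or outside band.

    A row survives only when the control frequency is present and lies in
    [control_low, control_high] (the strict "< low or > high" discard rule,
    so boundary values survive).
    """
    if config.control_pool not in freqs.pools:
        raise ConfigError(
            f"control pool {config.control_pool!r} not among {freqs.pools}"
        )
    f = freqs.df[f"{config.control_pool}_freq"].to_numpy()
    keep = ~(np.isnan(f) | (f < config.control_low) | (f > config.control_high))
    return FreqTable(freqs.df[keep], freqs.pools)


@dataclass
class FilterReport:
    """Row/cell counts removed by each rule, for logging and audit."""

    n_input: int = 0
    n_called: int = 0
    max_cov: float = float("nan")
    cells_masked: dict = field(default_factory=dict)
    n_after_control: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_input),
            ("called_snps", self.n_called),
            ("max_cov_bound", self.max_cov),
        ]
        rows += [(f"cells_masked_{p}", n) for p, n in self.cells_masked.items()]
        rows.append(("retained_after_control", self.n_after_control))
        return pd.DataFrame(rows, columns=["stage", "value"])


def run_filters(
    table: PoolCountTable, config: FilterConfig, control_filter: bool = True
) -> tuple[FreqTable, FilterReport]:
    """Full filter pipeline: call SNPs, coverage-mask, control-filter.

    Returns the retained :class:`FreqTable` and a :class:`FilterReport`
    with per-stage counts.
    """
    report = FilterReport(n_input=len(table))
    called = call_snps(table, config)
    table = table.subset(called)
    report.n_called = len(table)
    if len(table) == 0:
        empty = pool_frequencies(table)
        return empty, report
    min_cov, max_cov = coverage_bounds(table, config)
    report.max_cov = max_cov
    freqs = pool_frequencies(table)
    masked = apply_coverage_filter(freqs, min_cov, max_cov)
    for p in freqs.pools:
        report.cells_masked[p] = int(
            np.isnan(masked.freq(p)).sum() - np.isnan(freqs.freq(p)).sum()
        )
    if control_filter:
        masked = apply_control_filter(masked, config)
    report.n_after_control = len(masked)
    return masked, report
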