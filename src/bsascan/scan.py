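"""The two-pool allele-frequency Z statistic and its sliding-window scan.

For SNP j with reference-allele read counts x and total depths n in the
top and bottom phenotypic pools, the per-SNP statistic is the standard
two-proportion z

    z_j = (p_top - p_bottom) / sqrt( phat (1 - phat) (1/n_top + 1/n_bottom) )

with the pooled estimate phat = (x_top + x_bottom) / (n_top + n_bottom).
The window statistic Z' at SNP j is the plain mean of z over a centered
window of d participating SNPs (d odd, default 15) on the same
chromosome, and is referred, unscaled, to a standard normal for a
two-sided p-value.  Because the mean of d near-independent standard
normals has variance ~1/d, this is deliberately conservative; a
``scale_window`` switch multiplies Z' by sqrt(d) before the tail lookup
for users who want the calibrated variant (off by default).

Windows run over the sequence of participating SNPs (non-missing in both
pools, informative phat), not over physical distance, and never span
chromosomes; SNPs without a full window on each side get no Z'.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .filtering import FreqTable
from .io import PoolCountTable

logger = logging.getLogger(__name__)

__all__ = ["ScanConfig", "ScanResult", "per_snp_z", "window_scan"]

_P_FLOOR = 1e-300  # two-sided p floored before log10

SCAN_COLUMNS = ["chrom", "pos", "z", "zprime", "p", "neglogp", "wdiff"]


@dataclass(frozen=True)
class ScanConfig:
    """Window size and pool orientation for a scan.

    ``top_pool`` is the first-listed phenotypic tail (e.g. early / tall);
    positive z means the reference-parent allele is elevated in it.
    """

    top_pool: str
    bottom_pool: str
    d: int = 15
    scale_window: bool = False

    def __post_init__(self):
        if self.d < 1 or self.d % 2 == 0:
            raise ConfigError(f"window size d must be odd and >= 1, got {self.d}")
        if self.top_pool == self.bottom_pool:
            raise ConfigError("top and bottom pools must differ")


def per_snp_z(x_top: int, n_top: int, x_bottom: int, n_bottom: int) -> float:
    """Two-proportion z for one SNP; NaN when undefined.

    Undefined (NaN) when either pool has zero depth or when the pooled
    frequency is 0 or 1 (monomorphic across both pools); such SNPs do not
    participate in the window scan.  A zero numerator with an informative
    pooled frequency gives exactly 0.
    """
    if n_top <= 0 or n_bottom <= 0:
        return math.nan
    if not (0 <= x_top <= n_top and 0 <= x_bottom <= n_bottom):
        raise ValueError("need 0 <= x <= n in both pools")
    phat = (x_top + x_bottom) / (n_top + n_bottom)
    if phat <= 0.0 or phat >= 1.0:
        return math.nan
    diff = x_top / n_top - x_bottom / n_bottom
    se = math.sqrt(phat * (1.0 - phat) * (1.0 / n_top + 1.0 / n_bottom))
    return diff / se


def _z_vector(
    x_top: np.ndarray,
    n_top: np.ndarray,
    x_bottom: np.ndarray,
    n_bottom: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`per_snp_z`."""
    x_top = x_top.astype(float)
    x_bottom = x_bottom.astype(float)
    n_top = n_top.astype(float)
    n_bottom = n_bottom.astype(float)
    ok = (n_top > 0) & (n_bottom > 0)
    denom_n = np.where(ok, n_top + n_bottom, 1.0)
    phat = (x_top + x_bottom) / denom_n
    ok &= (phat > 0.0) & (phat < 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = x_top / n_top - x_bottom / n_bottom
        se = np.sqrt(phat * (1 - phat) * (1 / n_top + 1 / n_bottom))
        z = diff / se
    return np.where(ok, z, np.nan)


class ScanResult:
    """Per-SNP scan output.

    ``df`` holds one row per participating SNP: ``z`` (per-SNP statistic),
    ``zprime`` (windowed mean, NaN at chromosome edges), ``p`` / ``neglogp``
    (two-sided normal tail of Z'), and ``wdiff`` (windowed mean of the
    top-minus-bottom frequency difference).
    """

    def __init__(self, df: pd.DataFrame, config: ScanConfig):
        self.df = df.reset_index(drop=True)
        self.config = config

    def __len__(self) -> int:
        return len(self.df)

    @property
    def neglogp(self) -> np.ndarray:
        return self.df["neglogp"].to_numpy()

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, config: ScanConfig | None = None) -> "ScanResult":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        if config is None:
            config = ScanConfig(top_pool="top", bottom_pool="bottom")
        return cls(df[SCAN_COLUMNS], config)


def window_scan(
    freqs: FreqTable, counts: PoolCountTable, config: ScanConfig
) -> ScanResult:
    """Run the windowed Z scan over all participating SNPs.

    A SNP participates when its frequency is non-missing in both contrast
    pools (post-filter) and its per-SNP z is defined.  Chromosomes with
    fewer than d participating SNPs contribute rows with missing Z'
    (warning logged).
    """
    for p in (config.top_pool, config.bottom_pool):
        if p not in freqs.pools or p not in counts.pools:
            raise ConfigError(f"pool {p!r} absent from inputs")
    merged = freqs.df[["chrom", "pos"]].copy()
    merged["f_top"] = freqs.freq(config.top_pool)
    merged["f_bot"] = freqs.freq(config.bottom_pool)
    cdf = counts.df.set_index(["chrom", "pos"])
    key = pd.MultiIndex.from_frame(merged[["chrom", "pos"]])
    for col, src in [
        ("x_top", f"{config.top_pool}_ref"),
        ("n_top", f"{config.top_pool}_tot"),
        ("x_bot", f"{config.bottom_pool}_ref"),
        ("n_bot", f"{config.bottom_pool}_tot"),
    ]:
        merged[col] = cdf[src].reindex(key).to_numpy()
    participating = merged.dropna(
        subset=["f_top", "f_bot", "x_top", "n_top", "x_bot", "n_bot"]
    ).copy()
    z = _z_vector(
        participating["x_top"].to_numpy(),
        participating["n_top"].to_numpy(),
        participating["x_bot"].to_numpy(),
        participating["n_bot"].to_numpy(),
    )
    participating["z"] = z
    participating = participating[~np.isnan(z)]

    half = config.d // 2
    out_parts = []
    for chrom, grp in participating.groupby("chrom", sort=False):
        grp = grp.sort_values("pos").reset_index(drop=True)
        if len(grp) < config.d:
            logger.warning(
                "chromosome %s has %d participating SNPs < window %d; no Z' assigned",
                chrom, len(grp), config.d,
            )
            zp = np.full(len(grp), np.nan)
            wd = np.full(len(grp), np.nan)
        else:
            zp = (
                grp["z"].rolling(config.d, center=True, min_periods=config.d)
                .mean().to_numpy()
            )
            wd = (
                (grp["f_top"] - grp["f_bot"])
                .rolling(config.d, center=True, min_periods=config.d)
                .mean().to_numpy()
            )
        part = grp[["chrom", "pos", "z"]].copy()
        part["zprime"] = zp
        part["wdiff"] = wd
        out_parts.append(part)
    if out_parts:
        out = pd.concat(out_parts, ignore_index=True)
    else:
        out = pd.DataFrame(columns=["chrom", "pos", "z", "zprime", "wdiff"])
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    ref = out["zprime"].to_numpy()
    if config.scale_window:
        ref = ref * math.sqrt(config.d)
    with np.errstate(invalid="ignore"):
        p = 2.0 * norm.sf(np.abs(ref))
    p = np.where(np.isnan(ref), np.nan, np.maximum(p, _P_FLOOR))
    out["p"] = p
    with np.errstate(invalid="ignore"):
        out["neglogp"] = -np.log10(p)
    out["pos"] = out["pos"].astype(np.int64)
    return ScanResult(out[SCAN_COLUMNS], config)
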