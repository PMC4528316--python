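"""Empirical outlier thresholding and QTL-region calling.

Significant SNPs are those whose -log10(p) lies strictly above the
empirical (1-q) quantile of the scanned values (q = 0.005: a 0.5% outlier
rule used instead of formal multiple-testing correction, which is either
too conservative or too liberal for windowed statistics over unknown
linkage disequilibrium).  Maximal runs of significant SNPs are extended by
``flank_snps`` scan SNPs on each side (the window half-width: those
neighbours supported the last significant SNP), and regions whose boundary
SNPs lie within ``merge_bp`` of each other are merged into one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scan import ScanResult

__all__ = [
    "Region",
    "RegionSet",
    "outlier_threshold",
    "call_regions",
    "summarize_region",
    "summarize_regions",
    "compare_region_sets",
    "recovery_metrics",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 535.5 -> 536)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class Region:
    """A called QTL interval (1-based inclusive physical coordinates).

    ``direction`` is the sign of the windowed top-minus-bottom frequency
    difference at the peak SNP: +1 means the reference-parent allele is
    elevated in the top pool.
    """

    chrom: str
    left: int
    right: int
    peak_pos: int
    peak_p: float
    direction: int

    def __post_init__(self):
        if not (self.left <= self.peak_pos <= self.right):
            raise ValidationError(
                f"peak {self.peak_pos} outside [{self.left}, {self.right}]"
            )

    @property
    def length_kb(self) -> int:
        """Interval length in kb, rounded half away from zero."""
        return round_half_away((self.right - self.left) / 1000.0)


class RegionSet:
    """An ordered, non-overlapping list of regions plus the threshold used."""

    def __init__(self, regions: Sequence[Region], threshold: float):
        self.regions = sorted(regions, key=lambda r: (r.chrom, r.left))
        self.threshold = float(threshold)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def to_frame(self) -> pd.DataFrame:
        return summarize_regions(self.regions)

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# threshold_neglogp\t{self.threshold:.10g}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def to_bed(self, path: str | Path) -> None:
        """BED output: 0-based half-open intervals, score = peak -log10 p."""
        with open(path, "w") as fh:
            for i, r in enumerate(self.regions):
                score = -math.log10(max(r.peak_p, 1e-300))
                fh.write(
                    f"{r.chrom}\t{r.left - 1}\t{r.right}\tregion_{i + 1}\t"
                    f"{score:.4f}\t.\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionSet":
        threshold = math.nan
        with open(path) as fh:
            for line in fh:
                if line.startswith("# threshold_neglogp"):
                    threshold = float(line.split("\t")[1])
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        regions = [
            Region(
                chrom=row["chrom"],
                left=int(row["left"]),
                right=int(row["right"]),
                peak_pos=int(row["peak_pos"]),
                peak_p=float(row["peak_p"]),
                direction=1 if row["direction"] == "+" else (-1 if row["direction"] == "-" else 0),
            )
            for _, row in df.iterrows()
        ]
        return cls(regions, threshold)


def outlier_threshold(neglogp: np.ndarray, q: float = 0.005) -> float:
    """Empirical (1-q) quantile by the nearest-rank rule.

    Returns the value at rank ceil((1-q) * N) of the ascending sorted
    vector (1-based ranks); SNPs strictly above this value are declared
    significant.  q = 0 returns the maximum.
    """
    arr = np.asarray(neglogp, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValidationError("cannot take a quantile of an empty vector")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in the -log10(p) vector")
    if not (0 <= q <= 1):
        raise ValidationError(f"quantile fraction q must be in [0, 1], got {q}")
    rank = max(1, math.ceil((1.0 - q) * arr.size))
    return float(np.sort(arr)[rank - 1])


def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as inclusive (start, stop)."""
    if indices.size == 0:
        return []
    breaks = np.nonzero(np.diff(indices) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [indices.size - 1]])
    return [(int(indices[a]), int(indices[b])) for a, b in zip(starts, stops)]


def call_regions(
    scan: ScanResult | pd.DataFrame,
    threshold: float,
    flank_snps: int = 7,
    merge_bp: int = 5_000_000,
) -> RegionSet:
    """Call QTL regions from a scan at a given -log10(p) threshold.

    Per chromosome: (1) maximal runs of SNPs with neglogp strictly above
    the threshold; (2) each run extended by ``flank_snps`` scan SNPs on
    each side, clipped at the chromosome's first/last scan SNP; (3) left to
    right, a region is merged into the previous one when the bp gap between
    its left boundary SNP and the previous region's right boundary SNP is
    < ``merge_bp``; (4) the peak is the SNP of maximum neglogp in the
    region (leftmost on ties) and the direction is the sign of wdiff there.
    """
    df = scan.df if isinstance(scan, ScanResult) else scan
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    regions: list[Region] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos").reset_index(drop=True)
        nlp = grp["neglogp"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            sig = np.nonzero(nlp > threshold)[0]
        if sig.size == 0:
            continue
        pos = grp["pos"].to_numpy()
        wdiff = grp["wdiff"].to_numpy(dtype=float)
        n = len(grp)
        # extend runs by flank_snps scan SNPs, clipped at chromosome ends
        spans = [
            (max(0, a - flank_snps), min(n - 1, b + flank_snps))
            for a, b in _runs(sig)
        ]
        # merge overlapping index spans, then apply the bp merge rule
        merged: list[list[int]] = []
        for a, b in spans:
            if merged and (
                a <= merged[-1][1] or pos[a] - pos[merged[-1][1]] < merge_bp
            ):
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        for a, b in merged:
            window = nlp[a : b + 1]
            peak_rel = int(np.nanargmax(window))  # first occurrence on ties
            peak_i = a + peak_rel
            wd = wdiff[peak_i]
            direction = 0 if (np.isnan(wd) or wd == 0) else (1 if wd > 0 else -1)
            p_peak = float(grp["p"].iat[peak_i])
            regions.append(
                Region(
                    chrom=str(chrom),
                    left=int(pos[a]),
                    right=int(pos[b]),
                    peak_pos=int(pos[peak_i]),
                    peak_p=p_peak,
                    direction=direction,
                )
            )
    return RegionSet(regions, threshold)


def summarize_region(region: Region) -> dict:
    """One summary row: boundaries, peak, rounded kb length, direction."""
    return {
        "chrom": region.chrom,
        "left": region.left,
        "right": region.right,
        "peak_pos": region.peak_pos,
        "length_kb": region.length_kb,
        "peak_p": region.peak_p,
        "direction": {1: "+", -1: "-", 0: "."}[region.direction],
    }


def summarize_regions(regions: Sequence[Region]) -> pd.DataFrame:
    cols = ["chrom", "left", "right", "peak_pos", "length_kb", "peak_p", "direction"]
    if not regions:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([summarize_region(r) for r in regions])[cols]


def _interval_relationship(
    la: int, ra: int, lb: int, rb: int
) -> tuple[str, int]:
    """Relationship and overlap length (bp difference convention)."""
    overlap = max(0, min(ra, rb) - max(la, lb))
    if overlap == 0 and not (la <= lb <= ra or lb <= la <= rb):
        return "disjoint", 0
    if la <= lb and rb <= ra:
        return "a-contains-b", overlap
    if lb <= la and ra <= rb:
        return "b-contains-a", overlap
    return "partial-overlap", overlap


def compare_region_sets(
    a: RegionSet | Sequence[tuple[str, int, int]],
    b: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    """Overlap report between called regions and external intervals.

    ``b`` is a list of (chrom, left, right) in the same 1-based coordinate
    system (e.g. 1.5-LOD support intervals from linkage mapping).  For every
    same-chromosome pair the report gives the relationship (disjoint /
    partial-overlap / a-contains-b / b-contains-a), the overlap length in
    bp, and a ``shared`` flag (overlap > 0).
    """
    a_intervals = (
        [(r.chrom, r.left, r.right) for r in a] if isinstance(a, RegionSet) else list(a)
    )
    rows = []
    for ca, la, ra in a_intervals:
        for cb, lb, rb in b:
            if str(ca) != str(cb):
                continue
            rel, ov = _interval_relationship(int(la), int(ra), int(lb), int(rb))
            rows.append(
                {
                    "chrom": str(ca),
                    "a_left": int(la),
                    "a_right": int(ra),
                    "b_left": int(lb),
                    "b_right": int(rb),
                    "relationship": rel,
                    "overlap_bp": ov,
                    "shared": ov > 0,
                }
            )
    cols = [
        "chrom", "a_left", "a_right", "b_left", "b_right",
        "relationship", "overlap_bp", "shared",
    ]
    return pd.DataFrame(rows, columns=cols)


def recovery_metrics(
    called: RegionSet,
    truth,
    slack_bp: int = 0,
) -> tuple[float, int, list[int]]:
    """Evaluate called regions against planted QTL positions.

    ``truth`` is a ``SimTruth`` (or anything with a ``qtls`` attribute of
    objects carrying ``chrom`` and ``pos``).  A QTL is recovered when some
    region's [left - slack, right + slack] contains it; sensitivity is the
    recovered fraction; false regions are those containing no planted QTL
    within slack; peak offsets are |peak_pos - true position| for recovered
    QTL.
    """
    qtls = list(truth.qtls)
    recovered = 0
    offsets: list[int] = []
    hit_regions: set[int] = set()
    for q in qtls:
        best = None
        for i, r in enumerate(called):
            if r.chrom == str(q.chrom) and r.left - slack_bp <= q.pos <= r.right + slack_bp:
                hit_regions.add(i)
                off = abs(r.peak_pos - q.pos)
                best = off if best is None else min(best, off)
        if best is not None:
            recovered += 1
            offsets.append(best)
    sensitivity = recovered / len(qtls) if qtls else float("nan")
    false_regions = len(called) - len(hit_regions)
    return sensitivity, false_regions, offsets
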