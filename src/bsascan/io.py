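"""Per-SNP, per-pool allele-count tables and their on-disk formats.

The canonical interchange format is a tab-separated table with header

    chrom  pos  <pool>_ref  <pool>_tot  [<pool>_ref  <pool>_tot ...]

where ``pos`` is a 1-based physical coordinate, ``<pool>_ref`` counts
quality-prefiltered reads carrying the reference-parent allele and
``<pool>_tot`` counts all quality-prefiltered reads at the site.  SNP
alleles are parent-coded (reference parent vs. alternate parent); there is
no strand concept.  VCF (per-sample AD subfields) and PoPoolation2 sync
records can be imported; both are conveniences, the TSV dialect is the
bit-exact round-trip format.  All readers accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PoolCountTable", "read_counts", "write_counts"]

_KEY_COLS = ["chrom", "pos"]
_SYNC_BASES = "ATCGN"  # sync column order is A:T:C:G:N:del


class PoolCountTable:
    """A validated, sorted table of per-SNP, per-pool allele counts.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based) and, for each pool
        ``p``, integer columns ``{p}_ref`` and ``{p}_tot``.
    pools : sequence of str, optional
        Pool names; inferred from the columns when omitted.

    The constructor sorts rows by (chrom, pos) and enforces the table
    invariants: positions >= 1, unique (chrom, pos), and
    0 <= ref_count <= total_count in every cell.
    """

    def __init__(self, df: pd.DataFrame, pools: Sequence[str] | None = None):
        df = df.copy()
        if pools is None:
            pools = infer_pools(df.columns)
        pools = list(pools)
        if len(pools) != len(set(pools)):
            raise ValidationError(f"duplicate pool names: {pools}")
        if not pools:
            raise ValidationError("a count table needs at least one pool")
        missing_cols = [
            c for p in pools for c in (f"{p}_ref", f"{p}_tot") if c not in df.columns
        ]
        if missing_cols:
            raise ValidationError(f"missing count columns: {missing_cols}")
        for c in _KEY_COLS:
            if c not in df.columns:
                raise ValidationError(f"missing key column {c!r}")
        count_cols = [c for p in pools for c in (f"{p}_ref", f"{p}_tot")]
        df = df[_KEY_COLS + count_cols]
        df["chrom"] = df["chrom"].astype(str)
        for c in ["pos"] + count_cols:
            values = pd.to_numeric(df[c], errors="coerce")
            bad = values.isna() | (values != np.floor(values))
            if bad.any():
                raise ValidationError(
                    f"non-integer value in column {c!r} at row {int(np.nonzero(bad.to_numpy())[0][0])}"
                )
            df[c] = values.astype(np.int64)
        df = df.sort_values(_KEY_COLS, kind="stable").reset_index(drop=True)
        if (df["pos"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based coordinates)")
        if df.duplicated(_KEY_COLS).any():
            dup = df[df.duplicated(_KEY_COLS)].iloc[0]
            raise ValidationError(f"duplicate SNP {dup['chrom']}:{dup['pos']}")
        for p in pools:
            ref, tot = df[f"{p}_ref"], df[f"{p}_tot"]
            if (ref < 0).any() or (tot < 0).any():
                raise ValidationError(f"negative count in pool {p!r}")
            if (ref > tot).any():
                i = int((ref > tot).idxmax())
                raise ValidationError(
                    f"ref_count > total_count for pool {p!r} at "
                    f"{df['chrom'].iat[i]}:{df['pos'].iat[i]}"
                )
        self.df = df
        self.pools = pools

    # -- basic container behaviour -------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PoolCountTable)
            and self.pools == other.pools
            and self.df.equals(other.df)
        )

    def __repr__(self) -> str:
        return f"PoolCountTable({len(self)} SNPs, pools={self.pools})"

    def ref(self, pool: str) -> np.ndarray:
        return self.df[f"{pool}_ref"].to_numpy()

    def tot(self, pool: str) -> np.ndarray:
        return self.df[f"{pool}_tot"].to_numpy()

    def keys(self) -> set[tuple[str, int]]:
        return set(zip(self.df["chrom"], self.df["pos"].astype(int)))

    def subset(self, keys: Iterable[tuple[str, int]]) -> "PoolCountTable":
        """Restrict to the given (chrom, pos) keys."""
        keyset = set(keys)
        mask = [
            (c, int(p)) in keyset for c, p in zip(self.df["chrom"], self.df["pos"])
        ]
        return PoolCountTable(self.df[mask], self.pools)


def infer_pools(columns: Iterable[str]) -> list[str]:
    """Infer pool names from paired ``<pool>_ref`` / ``<pool>_tot`` columns."""
    cols = list(columns)
    refs = [c[:-4] for c in cols if c.endswith("_ref")]
    tots = {c[:-4] for c in cols if c.endswith("_tot")}
    pools = [p for p in refs if p in tots]
    if not pools:
        raise ParseError(f"no <pool>_ref/<pool>_tot column pairs among {cols}")
    return pools


def read_counts(
    path: str | Path,
    format: str = "tsv",
    pool_names: Sequence[str] | None = None,
) -> PoolCountTable:
    """Read a :class:`PoolCountTable` from ``path``.

    ``format`` is one of ``tsv`` (canonical dialect), ``vcf_ad`` (per-sample
    AD allelic depths; samples are mapped to pools by name through
    ``pool_names``) or ``sync`` (PoPoolation2; ``pool_names`` names the
    pool columns in file order).  Requesting a pool that is not present in
    the file is an error.  Multi-allelic sites (more than two observed
    alleles) are rejected and logged.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path, pool_names)
    if format == "vcf_ad":
        return _read_vcf_ad(path, pool_names)
    if format == "sync":
        if pool_names is None:
            raise ParseError("sync format requires pool_names (columns are unnamed)")
        return _read_sync(path, pool_names)
    raise ParseError(f"unknown counts format {format!r}")


def write_counts(table: PoolCountTable, path: str | Path) -> None:
    """Write the canonical TSV dialect; ``read_counts`` round-trips exactly.

    A ``.gz`` suffix selects gzip compression.
    """
    table.df.to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path, pool_names: Sequence[str] | None) -> PoolCountTable:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty and pool_names is not None:
        cols = ["chrom", "pos"] + [
            c for p in pool_names for c in (f"{p}_ref", f"{p}_tot")
        ]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
    file_pools = infer_pools(df.columns)
    if pool_names is not None:
        unknown = [p for p in pool_names if p not in file_pools]
        if unknown:
            raise ParseError(f"{path}: pools {unknown} not present (has {file_pools})")
        file_pools = list(pool_names)
    try:
        return PoolCountTable(df, file_pools)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_vcf_ad(path: Path, pool_names: Sequence[str] | None) -> PoolCountTable:
    from cyvcf2 import VCF  # deferred: only needed for this import path

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pools = list(pool_names) if pool_names is not None else samples
    unknown = [p for p in pools if p not in samples]
    if unknown:
        raise ParseError(f"{path}: pools {unknown} not among VCF samples {samples}")
    idx = [samples.index(p) for p in pools]
    rows: list[list] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            raise ParseError(
                f"{path}: no AD field at {variant.CHROM}:{variant.POS}"
            )
        row: list = [variant.CHROM, variant.POS]
        for si in idx:
            depths = np.clip(ad[si].astype(np.int64), 0, None)  # -1 encodes missing
            row += [int(depths[0]), int(depths.sum())]
        rows.append(row)
    if n_multi:
        logger.info("rejected %d multi-allelic VCF records", n_multi)
    cols = ["chrom", "pos"] + [c for p in pools for c in (f"{p}_ref", f"{p}_tot")]
    return PoolCountTable(pd.DataFrame(rows, columns=cols), pools)


def _read_sync(path: Path, pool_names: Sequence[str]) -> PoolCountTable:
    """Import a PoPoolation2 sync file.

    Columns: chrom, pos, reference base, then one ``A:T:C:G:N:del`` count
    field per pool.  The reference-parent allele is taken as the reference
    base; the alternate-parent allele as the non-reference base with the
    highest summed count across pools.  Sites where more than two bases
    carry reads are rejected and logged (the two parental alleles are not
    resolvable there).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    rows: list[list] = []
    n_multi = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + len(pool_names):
                raise ParseError(
                    f"{path}:{lineno}: expected {3 + len(pool_names)} fields, got {len(fields)}"
                )
            chrom, pos_s, ref_base = fields[:3]
            ref_base = ref_base.upper()
            if ref_base not in _SYNC_BASES[:4]:
                raise ParseError(f"{path}:{lineno}: bad reference base {ref_base!r}")
            try:
                pos = int(pos_s)
                counts = np.array(
                    [[int(x) for x in f.split(":")] for f in fields[3:]], dtype=np.int64
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if counts.shape[1] != 6:
                raise ParseError(f"{path}:{lineno}: sync fields need 6 colon counts")
            base_totals = counts[:, :4].sum(axis=0)  # A,T,C,G summed over pools
            ref_i = _SYNC_BASES.index(ref_base)
            observed = np.nonzero(base_totals > 0)[0]
            non_ref = [i for i in observed if i != ref_i]
            if len(non_ref) > 1:
                n_multi += 1
                continue
            alt_i = non_ref[0] if non_ref else int(np.argmin(base_totals == 0))
            if not non_ref:  # monomorphic in this file; alt carries zero reads
                alt_i = next(i for i in range(4) if i != ref_i)
            row: list = [chrom, pos]
            for k in range(len(pool_names)):
                ref_c = int(counts[k, ref_i])
                row += [ref_c, ref_c + int(counts[k, alt_i])]
            rows.append(row)
    if n_multi:
        logger.info("rejected %d multi-allelic sync records", n_multi)
    cols = ["chrom", "pos"] + [
        c for p in pool_names for c in (f"{p}_ref", f"{p}_tot")
    ]
    return PoolCountTable(pd.DataFrame(rows, columns=cols), list(pool_names))
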