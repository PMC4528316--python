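"""End-to-end orchestration with a single config and reproducible outputs.

``run_scan`` executes filtering -> windowed scan -> empirical threshold ->
region calling from one :class:`RunConfig`, writing every artifact with a
provenance header (config hash + seed), so identical config and inputs
give byte-identical outputs.  ``run_compare`` writes the overlap report
between a called region set and an external interval file (e.g. 1.5-LOD
linkage support intervals).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, ParseError
from .filtering import FilterConfig
from .io import read_counts
from .model import BsaScan
from .regions import RegionSet, compare_region_sets
from .scan import ScanConfig
from .simulate import GenomeMap, QtlSpec, SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_scan", "run_compare", "run_simulate"]


@dataclass
class RunConfig:
    """Composite configuration of a full scan run."""

    counts_path: str = ""
    counts_format: str = "tsv"
    out_dir: str = "bsascan_out"
    top_pool: str = "high"
    bottom_pool: str = "low"
    control_pool: str | None = "control"
    quantile: float = 0.005
    flank_snps: int = 7
    merge_bp: int = 5_000_000
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        scan_raw = raw.pop("scan", None)
        cfg = cls(filter=filt, **raw)
        if scan_raw is not None:
            scan_raw.setdefault("top_pool", cfg.top_pool)
            scan_raw.setdefault("bottom_pool", cfg.bottom_pool)
            cfg.scan = ScanConfig(**scan_raw)
        return cfg

    def effective_scan_config(self) -> ScanConfig:
        return self.scan or ScanConfig(
            top_pool=self.top_pool, bottom_pool=self.bottom_pool
        )

    def digest(self) -> str:
        """Hash of the scientific configuration (paths excluded, so the
        same analysis into two directories hashes identically)."""
        payload = asdict(self)
        payload.pop("counts_path", None)
        payload.pop("out_dir", None)
        payload["scan"] = asdict(self.effective_scan_config())
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> list[str]:
    return [f"bsascan run", f"config_hash={config.digest()}", f"seed={config.seed}"]


def run_scan(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns paths of the written artifacts.

    Fails fast on configuration errors (missing pools, unreadable counts)
    before any stage computes; on a stage error, partial outputs are
    removed.
    """
    counts = read_counts(config.counts_path, format=config.counts_format)
    for p in (config.top_pool, config.bottom_pool) + (
        (config.control_pool,) if config.control_pool else ()
    ):
        if p not in counts.pools:
            raise ConfigError(f"pool {p!r} not in counts table pools {counts.pools}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scan": out_dir / "scan.tsv",
        "regions": out_dir / "regions.tsv",
        "regions_bed": out_dir / "regions.bed",
        "filter_report": out_dir / "filter_report.tsv",
    }
    header = _provenance(config)
    try:
        model = BsaScan(
            counts,
            top_pool=config.top_pool,
            bottom_pool=config.bottom_pool,
            control_pool=config.control_pool,
            filter_config=config.filter,
            scan_config=config.effective_scan_config(),
        )
        res = model.fit(
            quantile=config.quantile,
            flank_snps=config.flank_snps,
            merge_bp=config.merge_bp,
        )
        logger.info(
            "scan: %d input SNPs, %d called, %d retained, %d scanned, %d regions",
            res.filter_report.n_input, res.filter_report.n_called,
            res.filter_report.n_after_control, len(res.scan), len(res.regions),
        )
        res.scan.to_tsv(paths["scan"], header_lines=header)
        res.regions.to_tsv(paths["regions"], header_lines=header)
        res.regions.to_bed(paths["regions_bed"])
        with open(paths["filter_report"], "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            res.filter_report.to_frame().to_csv(
                fh, sep="\t", index=False, float_format="%.10g"
            )
    except Exception as exc:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise type(exc)(f"scan pipeline failed: {exc}") from exc
    return paths


def read_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Read an interval file as 1-based inclusive (chrom, left, right).

    ``.bed`` files are treated as 0-based half-open and converted; any
    other extension is read as a headered or headerless TSV with chrom /
    left / right in the first three columns, already 1-based.
    """
    path = Path(path)
    zero_based = path.suffix.lower() == ".bed"
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: need >= 3 columns")
            try:
                left, right = int(fields[1]), int(fields[2])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}:{lineno}: non-integer interval bounds")
            if zero_based:
                left += 1
            out.append((fields[0], left, right))
    return out


def run_compare(
    regions_path: str | Path, intervals_path: str | Path, out_path: str | Path
) -> pd.DataFrame:
    """Overlap report between a region-set TSV and an interval file."""
    regions = RegionSet.from_tsv(regions_path)
    intervals = read_intervals(intervals_path)
    report = compare_region_sets(regions, intervals)
    report.to_csv(out_path, sep="\t", index=False)
    return report


def run_simulate(
    out_dir: str | Path,
    genome: GenomeMap,
    qtls: list[QtlSpec],
    config: SimConfig,
) -> dict[str, Path]:
    """Generate one synthetic experiment and write its artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_experiment(genome, qtls, config)
    paths = {
        "counts": out_dir / "counts.tsv",
        "true_freqs": out_dir / "true_freqs.tsv",
        "qtl": out_dir / "qtl_truth.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
    }
    from .io import write_counts

    write_counts(sim["counts"], paths["counts"])
    sim["truth"].true_freqs.to_csv(
        paths["true_freqs"], sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        [
            {"chrom": q.chrom, "pos": q.pos, "a": q.a, "k": q.k}
            for q in sim["truth"].qtls
        ],
        columns=["chrom", "pos", "a", "k"],
    ).to_csv(paths["qtl"], sep="\t", index=False)
    pools = sim["pools"]
    membership = pd.DataFrame(
        {
            "individual": range(len(sim["phenotypes"])),
            "phenotype": sim["phenotypes"],
        }
    )
    for name, idx in pools.as_dict().items():
        flags = pd.Series(False, index=membership.index)
        flags.iloc[idx] = True
        membership[f"in_{name}"] = flags.to_numpy()
    membership.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6g")
    return paths
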