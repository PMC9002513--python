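"""End-to-end orchestration: read → convert → QC → LOD → trend → distribution.

:func:`run_pipeline` takes a manifest of monitor CSVs, runs every analysis
stage with one configuration, and writes a machine-readable
:class:`RunSummary` (JSON) plus per-table CSVs.  Runs are deterministic
given identical inputs and configuration; any stage failure aborts with a
stage-labelled error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .algorithms import AltMassConverter, count_reported_zeros
from .io import COUNT_COLUMNS, MonitorSeries, pair_channels, read_purpleair_csv
from .lod import LodEstimator
from .precision import apply_precision_filter, precision_summary
from .trend import lognormal_probability_stats, precision_trend, zero_exclusion_report

__all__ = ["PipelineConfig", "RunSummary", "run_pipeline"]

logger = logging.getLogger("paqc")


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings shared by every stage (reproduce-by-default values)."""

    density: float = 1.0
    calibration_factor: float = 3.0
    diameter_rule: str = "geometric"
    saturation_limit: float = 1000.0
    precision_cutoff: float = 0.2
    pairing_tolerance_seconds: float = 60.0
    lod_block_size: int = 100
    lod_ratio_threshold: float = 3.0
    lod_method: str = "block"
    positions_rule: str = "blom"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load settings from a JSON config file (unknown keys rejected)."""
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class MonitorReport:
    """All per-monitor stage outputs."""

    monitor_id: str
    location: str
    n_records: int
    pairing: dict
    precision_summaries: dict
    loss_reports: dict
    zero_reports: dict
    lod_results: dict
    trend: dict | None
    distribution: dict | None
    zero_exclusion: dict | None


@dataclass
class RunSummary:
    """Machine-readable record of one pipeline run."""

    software_version: str
    config: dict
    input_digests: dict
    monitors: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analyze_monitor(series: MonitorSeries, config: PipelineConfig) -> MonitorReport:
    frame = series.frame
    converter = AltMassConverter(
        density=config.density,
        calibration_factor=config.calibration_factor,
        diameter_rule=config.diameter_rule,
        saturation_limit=config.saturation_limit,
    ).fit()
    alt_values = converter.transform(frame[COUNT_COLUMNS].to_numpy())

    streams = {"ALT_CF3": alt_values}
    if frame["pm25_cf1"].notna().any():
        streams["CF1"] = frame["pm25_cf1"].to_numpy(dtype=float)

    pairing_info: dict = {}
    summaries: dict = {}
    losses: dict = {}
    lods: dict = {}
    paired_by_alg: dict = {}
    for name, values in streams.items():
        paired, pairing = pair_channels(
            series, values, tolerance_seconds=config.pairing_tolerance_seconds, algorithm=name
        )
        paired_by_alg[name] = paired
        pairing_info[name] = json.loads(pairing.to_json())
        filtered, loss = apply_precision_filter(paired, cutoff=config.precision_cutoff)
        losses[name] = loss.to_dict()
        if len(filtered):
            summaries[name] = precision_summary(
                filtered["precision"], algorithm=name,
                filter_description=f"precision < {config.precision_cutoff}",
            ).to_dict()
        if len(paired) >= config.lod_block_size:
            est = LodEstimator(
                method=config.lod_method,
                block_size=config.lod_block_size,
                ratio_threshold=config.lod_ratio_threshold,
            ).fit(paired.dropna(subset=["mu"]))
            lods[name] = est.result_.to_dict()
        logger.info(
            "monitor %s %s: %d pairs, %d after precision filter",
            series.monitor_id, name, len(paired), len(filtered),
        )

    zero_reports = {}
    if "CF1" in streams:
        for channel in ("a", "b"):
            ch = series.channel(channel)
            vals = ch["pm25_cf1"].dropna()
            if len(vals):
                zero_reports[channel] = asdict(
                    count_reported_zeros(vals, sensor_id=f"{series.monitor_id}{channel}",
                                         location=series.location)
                ) | {"fraction_zero": count_reported_zeros(vals).fraction_zero}

    alt_paired = paired_by_alg["ALT_CF3"]
    trend = None
    if len(alt_paired) >= 3 and alt_paired["timestamp"].nunique() > 1:
        trend = precision_trend(alt_paired["timestamp"], alt_paired["precision"]).to_dict()

    distribution = None
    zero_excl = None
    mu = alt_paired["mu"].to_numpy(dtype=float)
    positive, n_excl, frac = zero_exclusion_report(mu)
    zero_excl = {"n_excluded": n_excl, "fraction_excluded": frac}
    if positive.size >= 3 and np.ptp(positive) > 0:
        distribution = lognormal_probability_stats(positive, config.positions_rule).to_dict()

    return MonitorReport(
        monitor_id=series.monitor_id,
        location=series.location,
        n_records=len(series),
        pairing=pairing_info,
        precision_summaries=summaries,
        loss_reports=losses,
        zero_reports=zero_reports,
        lod_results=lods,
        trend=trend,
        distribution=distribution,
        zero_exclusion=zero_excl,
    )


def run_pipeline(manifest: dict[str, dict] | Path | str, out_dir, config: PipelineConfig | None = None) -> RunSummary:
    """Run every analysis stage over a manifest of monitor files.

    ``manifest`` maps monitor ids to ``{"path": csv, "location": ...,
    "dialect": ...}`` entries (or is a path to such a mapping in JSON).
    Writes ``run_summary.json`` and per-table CSVs into ``out_dir``; on any
    stage error, partial outputs are removed and the error re-raised with
    the failing stage in its message.
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, dict):
        manifest_path = Path(manifest)
        manifest = json.loads(manifest_path.read_text())
        base = manifest_path.parent
    else:
        base = Path(".")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary = RunSummary(software_version=__version__, config=asdict(config), input_digests={})
    try:
        reports = []
        for monitor_id, entry in manifest.items():
            path = Path(entry["path"])
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                raise FileNotFoundError(f"stage=read monitor={monitor_id}: missing input file {path}")
            summary.input_digests[monitor_id] = _digest(path)
            stage = "read"
            try:
                series = read_purpleair_csv(
                    path,
                    dialect=entry.get("dialect", "simple"),
                    monitor_id=entry.get("monitor_id", monitor_id),
                    location=entry.get("location"),
                )
                stage = "analyze"
                reports.append(_analyze_monitor(series, config))
            except Exception as exc:
                raise RuntimeError(f"stage={stage} monitor={monitor_id}: {exc}") from exc
        summary.monitors = [asdict(r) for r in reports]

        summary_path = out / "run_summary.json"
        summary_path.write_text(summary.to_json())
        written.append(summary_path)
        tables = {
            "precision_summaries.csv": [
                {"monitor_id": r.monitor_id, "location": r.location, **s}
                for r in reports for s in r.precision_summaries.values()
            ],
            "loss_reports.csv": [
                {"monitor_id": r.monitor_id, "algorithm": alg, **d}
                for r in reports for alg, d in r.loss_reports.items()
            ],
            "lod_results.csv": [
                {"monitor_id": r.monitor_id, "algorithm": alg, **d}
                for r in reports for alg, d in r.lod_results.items()
            ],
            "zero_reports.csv": [
                {"monitor_id": r.monitor_id, **d}
                for r in reports for d in r.zero_reports.values()
            ],
            "trend_results.csv": [
                {"monitor_id": r.monitor_id, "location": r.location, **r.trend}
                for r in reports if r.trend
            ],
            "distribution_results.csv": [
                {"monitor_id": r.monitor_id, "location": r.location, **r.distribution}
                for r in reports if r.distribution
            ],
        }
        for name, rows in tables.items():
            if rows:
                p = out / name
                pd.DataFrame(rows).to_csv(p, index=False)
                written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return summary
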