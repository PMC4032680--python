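"""File formats and pipeline configuration.

A recording is a directory of plain delimited text: one two-column file per
channel (``time_s<TAB>value``) with ``# fs=<Hz>`` / ``# units=<u>`` header
comments, an ``epochs.json`` with the epoch markers, and a ``profile.json``
with the ground-truth generator targets when known.  The NN channel
(``ecg_nn``) is an event series: ``beat_time_s<TAB>nn_ms`` rows, one per
interval end.  Index tables are CSV; batteries and reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (ChannelTrace, EpochPlan, NNSeries, Recording,
                     SubjectProfile, SAMPLED_CHANNELS, MEASURES,
                     validate_epochs)
from .features import validate_index_table
from .stats import RmBattery, PowerSpec

log = logging.getLogger("felicity")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything the four-stage pipeline needs; JSON round-trip stable."""

    alpha: float = 0.05
    quorum: float = 0.5
    epoch_order: tuple[str, str, str] = ("relax", "happiness", "stress")
    pairs: tuple[tuple[str, str], ...] = (("relax", "happiness"),
                                          ("happiness", "stress"))
    seed: int = 0
    power: PowerSpec = dataclasses.field(default_factory=PowerSpec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epoch_order"] = list(self.epoch_order)
        d["pairs"] = [list(p) for p in self.pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "power" in d and isinstance(d["power"], dict):
            d["power"] = PowerSpec(**d["power"])
        if "epoch_order" in d:
            d["epoch_order"] = tuple(d["epoch_order"])
        if "pairs" in d:
            d["pairs"] = tuple(tuple(p) for p in d["pairs"])
        return cls(**d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Recording directories
# ---------------------------------------------------------------------------

def _write_channel(path: Path, times: np.ndarray, values: np.ndarray,
                   fs: Optional[float], units: str,
                   event_series: bool = False) -> None:
    with open(path, "w") as fh:
        if fs is not None:
            fh.write(f"# fs={fs:g}\n")
        fh.write(f"# units={units}\n")
        if event_series:
            fh.write("# event_series=true\n")
        np.savetxt(fh, np.column_stack([times, values]), fmt="%.9g",
                   delimiter="\t")


def _read_header(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_header


def write_recording(rec: Recording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_channel(out / "ecg_nn.tsv", rec.nn.beat_times_s[1:], rec.nn.nn_ms,
                   None, "ms", event_series=True)
    for name, tr in rec.channels.items():
        _write_channel(out / f"{name}.tsv", tr.times(), tr.samples,
                       tr.fs, tr.units)
    epochs = [{"label": e.label, "start_s": e.start_s,
               "duration_s": e.duration_s} for e in rec.epochs]
    (out / "epochs.json").write_text(json.dumps(
        {"subject_id": rec.subject_id, "seed": rec.seed, "epochs": epochs},
        indent=2))
    if rec.profile is not None:
        (out / "profile.json").write_text(json.dumps(rec.profile.to_dict(),
                                                     indent=2))
    return out


def read_recording(path: str | Path) -> Recording:
    """Load a recording directory, validating layout and channel headers."""
    root = Path(path)
    ep_file = root / "epochs.json"
    if not ep_file.exists():
        raise FileNotFoundError(f"missing epochs.json in {root}")
    meta = json.loads(ep_file.read_text())
    epochs = validate_epochs([EpochPlan(**e) for e in meta["epochs"]])

    nn_file = root / "ecg_nn.tsv"
    if not nn_file.exists():
        raise FileNotFoundError(f"missing channel file {nn_file}")
    _, n_header = _read_header(nn_file)
    arr = np.loadtxt(nn_file, skiprows=n_header, ndmin=2)
    beat_times = np.concatenate([[arr[0, 0] - arr[0, 1] / 1000.0], arr[:, 0]])
    nn = NNSeries(beat_times, arr[:, 1])

    channels: dict[str, ChannelTrace] = {}
    for name in SAMPLED_CHANNELS:
        f = root / f"{name}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"missing channel file {f}")
        hdr, n_header = _read_header(f)
        if "fs" not in hdr:
            raise ValueError(f"header of {f} lacks the fs= line")
        arr = np.loadtxt(f, skiprows=n_header, ndmin=2)
        channels[name] = ChannelTrace(name, float(hdr["fs"]), arr[:, 1],
                                      hdr.get("units", ""))
    profile = None
    pf = root / "profile.json"
    if pf.exists():
        profile = SubjectProfile.from_dict(json.loads(pf.read_text()))
    return Recording(subject_id=meta.get("subject_id", root.name), nn=nn,
                     channels=channels, epochs=epochs,
                     seed=int(meta.get("seed", 0)), profile=profile)


def write_cohort(recordings, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / rec.subject_id)
    return out


def read_cohort(path: str | Path) -> list[Recording]:
    root = Path(path)
    subdirs = sorted(p for p in root.iterdir()
                     if p.is_dir() and (p / "epochs.json").exists())
    if not subdirs:
        raise FileNotFoundError(f"no recording directories found in {root}")
    return [read_recording(p) for p in subdirs]


# ---------------------------------------------------------------------------
# Index tables and batteries
# ---------------------------------------------------------------------------

def write_index_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_index_table(table)
    table.to_csv(path, index=False)


def read_index_table(path: str | Path) -> pd.DataFrame:
    return validate_index_table(pd.read_csv(path))


def write_batteries(batteries: dict[str, RmBattery], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {m: b.to_dict() for m, b in batteries.items()}, indent=2))


def read_batteries(path: str | Path) -> dict[str, RmBattery]:
    raw = json.loads(Path(path).read_text())
    return {m: RmBattery.from_dict(d) for m, d in raw.items()}


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 output_dir: str | Path):
    """extract -> analyze -> decide over a cohort directory.

    Writes ``index_table.csv``, ``batteries.json``, ``report.json`` and
    ``report.txt`` into ``output_dir`` and returns the
    :class:`~felicity.decision.HappinessReport`.
    """
    from .features import extract_index_table
    from .stats import run_battery
    from .decision import classify, format_report

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "extract"
    try:
        recordings = read_cohort(input_dir)
        if len(recordings) < 3:
            raise ValueError(f"need >= 3 subjects, found {len(recordings)}")
        log.info("extract: %d subjects from %s", len(recordings), input_dir)
        table = extract_index_table(recordings)
        write_index_table(table, out / "index_table.csv")

        stage = "analyze"
        log.info("analyze: alpha=%g over %d measures", config.alpha,
                 len(MEASURES))
        batteries = run_battery(table, MEASURES, alpha=config.alpha)
        write_batteries(batteries, out / "batteries.json")

        stage = "decide"
        report = classify(batteries, alpha=config.alpha, quorum=config.quorum)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "report.txt").write_text(format_report(report, batteries))
        log.info("decide: classification=%s", report.classification)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
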