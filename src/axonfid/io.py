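"""File formats: spike-train text, session/behaviour/morphometry CSV, manifests.

Spike times are serialised in seconds at 6 decimal places (microsecond
precision, well below the sub-millisecond delays of interest).  All CSV is
UTF-8 with LF line endings and a header row; every output directory written
by the CLI carries exactly one JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorRecord
from .exceptions import InvalidInputError
from .morphometry import TimelapseRecord
from .spike_metrics import PairedRecording, SpikeTrain

__all__ = [
    "write_paired_recording",
    "read_paired_recording",
    "behavior_records_to_frame",
    "frame_to_behavior_records",
    "write_behavior_csv",
    "read_behavior_csv",
    "timelapse_records_to_frame",
    "frame_to_timelapse_records",
    "write_timelapse_csv",
    "read_timelapse_csv",
    "write_manifest",
    "config_hash",
]

_TIME_FMT = "%.6f"


def _header_lines(meta: dict) -> List[str]:
    return [f"# {k}: {v}" for k, v in meta.items()]


def write_paired_recording(path, rec: PairedRecording) -> None:
    """Write a paired recording as commented-header tabular text.

    Header block carries cell id, duration, swelling flag and distance;
    rows are (compartment, time_s) at 6 decimal places.  Ground truth, if
    present, goes to a ``.json`` sidecar next to the file.
    """
    path = Path(path)
    meta = {
        "cell_id": rec.soma.cell_id,
        "duration_s": rec.soma.duration_s,
        "has_swelling": rec.has_swelling,
        "axon_distance_um": rec.axon_distance_um,
    }
    lines = _header_lines(meta)
    lines.append("compartment,time_s")
    for train in (rec.soma, rec.axon):
        for t in train.times_s:
            lines.append(f"{train.compartment},{_TIME_FMT % t}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if rec.ground_truth is not None:
        gt = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in rec.ground_truth.items()
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(gt, indent=1), encoding="utf-8"
        )


def read_paired_recording(path) -> PairedRecording:
    """Read a paired recording written by :func:`write_paired_recording`."""
    path = Path(path)
    meta = {}
    rows = []
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].partition(":")
            meta[k.strip()] = v.strip()
        elif not header_seen:
            if line.strip() != "compartment,time_s":
                raise InvalidInputError(f"unexpected column header {line!r} in {path}")
            header_seen = True
        elif line.strip():
            comp, _, t = line.partition(",")
            rows.append((comp, float(t)))
    if "cell_id" not in meta or "duration_s" not in meta:
        raise InvalidInputError(f"missing header metadata in {path}")
    duration = float(meta["duration_s"])
    cell_id = meta["cell_id"]
    trains = {}
    for comp in ("soma", "axon"):
        times = np.array([t for c, t in rows if c == comp])
        trains[comp] = SpikeTrain(
            cell_id=cell_id, compartment=comp, times_s=times, duration_s=duration
        )
    gt_path = path.with_suffix(path.suffix + ".json")
    ground_truth = None
    if gt_path.exists():
        ground_truth = json.loads(gt_path.read_text(encoding="utf-8"))
        if "deletion_mask" in ground_truth:
            ground_truth["deletion_mask"] = np.asarray(ground_truth["deletion_mask"], dtype=bool)
    return PairedRecording(
        soma=trains["soma"],
        axon=trains["axon"],
        has_swelling=str(meta.get("has_swelling", "False")) == "True",
        axon_distance_um=float(meta.get("axon_distance_um", 100.0)),
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# behaviour tables (long format)


def behavior_records_to_frame(records: Sequence[BehaviorRecord]) -> pd.DataFrame:
    """Long-format table: one row per (animal, day, trial)."""
    rows = []
    for rec in records:
        m = rec.per_day_scores
        for d in range(m.shape[0]):
            for tr in range(m.shape[1]):
                rows.append(
                    {
                        "animal_id": rec.animal_id,
                        "task": rec.task,
                        "day": d + 1,
                        "trial": tr + 1,
                        "value": m[d, tr],
                        "swelling_density_pct": rec.swelling_density_pct,
                        "region": rec.region,
                    }
                )
    return pd.DataFrame(rows)


def frame_to_behavior_records(df: pd.DataFrame) -> List[BehaviorRecord]:
    records = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        task = sub["task"].iloc[0]
        days = sorted(sub["day"].unique())
        trials = sorted(sub["trial"].unique())
        m = np.full((len(days), len(trials)), np.nan)
        for _, row in sub.iterrows():
            m[days.index(row["day"]), trials.index(row["trial"])] = row["value"]
        records.append(
            BehaviorRecord(
                animal_id=str(animal_id),
                task=task,
                per_day_scores=m,
                swelling_density_pct=float(sub["swelling_density_pct"].iloc[0]),
                region=str(sub["region"].iloc[0]),
            )
        )
    return records


def write_behavior_csv(path, records: Sequence[BehaviorRecord]) -> None:
    behavior_records_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def read_behavior_csv(path) -> List[BehaviorRecord]:
    return frame_to_behavior_records(pd.read_csv(path))


# ---------------------------------------------------------------------------
# time-lapse tables (long format)


def timelapse_records_to_frame(records: Sequence[TimelapseRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for t, c in zip(rec.timepoints_h, rec.new_swellings):
            rows.append(
                {
                    "condition": rec.condition,
                    "field_id": rec.field_id,
                    "timepoint_h": t,
                    "new_swellings": int(c),
                    "n_cells": rec.n_cells,
                }
            )
    return pd.DataFrame(rows)


def frame_to_timelapse_records(df: pd.DataFrame) -> List[TimelapseRecord]:
    records = []
    for (cond, field_id), sub in df.groupby(["condition", "field_id"], sort=True):
        sub = sub.sort_values("timepoint_h")
        records.append(
            TimelapseRecord(
                condition=str(cond),
                field_id=str(field_id),
                timepoints_h=sub["timepoint_h"].to_numpy(dtype=float),
                new_swellings=sub["new_swellings"].to_numpy(dtype=int),
                n_cells=int(sub["n_cells"].iloc[0]),
            )
        )
    return records


def write_timelapse_csv(path, records: Sequence[TimelapseRecord]) -> None:
    timelapse_records_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def read_timelapse_csv(path) -> List[TimelapseRecord]:
    return frame_to_timelapse_records(pd.read_csv(path))


# ---------------------------------------------------------------------------
# manifests


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_manifest(
    out_dir,
    stage: str,
    seed: int,
    config: dict,
    extra: Optional[dict] = None,
) -> Path:
    """Write the run manifest for one output directory.

    Records the package version, master seed, configuration echo and hash,
    and the gap-filling decisions in force (matching window, split rule,
    g-ratio convention) so a rerun with the same manifest reproduces the
    stochastic outputs bit-for-bit.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "axonfid",
        "version": __version__,
        "stage": stage,
        "master_seed": int(seed),
        "config": config,
        "config_hash": config_hash(config),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str), encoding="utf-8")
    return path
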