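"""CSV/JSON readers and writers for every pipeline table.

All tables are plain CSV with explicit headers and SI-stated units in
the column names; sidecar metadata (configs, truth records, fit
summaries) is JSON with sorted keys so fixture directories are
byte-stable under a fixed seed. Readers are tolerant: malformed rows
are skipped, logged, and counted, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .afm import ComplexMeasurement
from .biochem import BindingIsotherm, ExcisionTimeCourse
from .survival import DwellRecord
from .trajectory import Trajectory

logger = logging.getLogger("smber")

TRAJECTORY_COLUMNS = ["particle_id", "channel", "frame", "time_s", "position_um", "censored"]
DWELL_COLUMNS = ["particle_id", "duration_s", "observed"]
COMPLEX_COLUMNS = ["particle_id", "v_complex_nm3", "v_dna1_nm3", "v_dna2_nm3"]
CALIBRATION_COLUMNS = ["label", "mw_kda", "volume_nm3"]
ESTIMATE_COLUMNS = ["particle_id", "D_um2_per_s", "alpha", "r2", "fraction_used",
                    "valid", "motility"]


class ReadResult(NamedTuple):
    data: list
    n_skipped: int


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    frames = []
    for t in trajectories:
        frames.append(pd.DataFrame({
            "particle_id": t.particle_id,
            "channel": t.channel,
            "frame": np.arange(t.n_frames),
            "time_s": t.times,
            "position_um": t.positions,
            "censored": t.censored,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=TRAJECTORY_COLUMNS))
    df.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> ReadResult:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {sorted(missing)}")
    n_before = len(df)
    for col in ("particle_id", "frame", "time_s", "position_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["particle_id", "frame", "time_s", "position_um"])
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    trajectories = []
    for pid, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            n_skipped += len(g)
            logger.warning("%s: particle %s has <2 usable frames, dropped", path, pid)
            continue
        trajectories.append(Trajectory(
            particle_id=int(pid),
            channel=str(g["channel"].iloc[0]),
            times=g["time_s"].to_numpy(dtype=float),
            positions=g["position_um"].to_numpy(dtype=float),
            censored=bool(_as_bool(g["censored"].iloc[0])),
        ))
    return ReadResult(trajectories, n_skipped)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


# ---------------------------------------------------------------------------
# dwell records
# ---------------------------------------------------------------------------

def write_dwell_records(records: list[DwellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.particle_id, r.duration, r.observed) for r in records],
        columns=DWELL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_dwell_records(path: str | Path) -> ReadResult:
    df = pd.read_csv(path)
    missing = set(DWELL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing dwell columns {sorted(missing)}")
    n_before = len(df)
    df["duration_s"] = pd.to_numeric(df["duration_s"], errors="coerce")
    df = df.dropna(subset=["duration_s"])
    df = df[df["duration_s"] > 0]
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    records = [
        DwellRecord(int(r.particle_id), float(r.duration_s), _as_bool(r.observed))
        for r in df.itertuples()
    ]
    return ReadResult(records, n_skipped)


# ---------------------------------------------------------------------------
# AFM tables
# ---------------------------------------------------------------------------

def write_complexes(measurements: list[ComplexMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        [(i, m.v_complex, m.v_dna1, m.v_dna2) for i, m in enumerate(measurements)],
        columns=COMPLEX_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_complexes(path: str | Path) -> ReadResult:
    df = pd.read_csv(path)
    missing = set(COMPLEX_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing complex columns {sorted(missing)}")
    n_before = len(df)
    for col in COMPLEX_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=COMPLEX_COLUMNS[1:])
    n_skipped = n_before - len(df)
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    out = [
        ComplexMeasurement(float(r.v_complex_nm3), float(r.v_dna1_nm3), float(r.v_dna2_nm3))
        for r in df.itertuples()
    ]
    return ReadResult(out, n_skipped)


def write_calibration(points: list[tuple[str, float, float]], path: str | Path) -> None:
    pd.DataFrame(points, columns=CALIBRATION_COLUMNS).to_csv(path, index=False)


def read_calibration(path: str | Path) -> ReadResult:
    df = pd.read_csv(path)
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing calibration columns {sorted(missing)}")
    n_before = len(df)
    for col in ("mw_kda", "volume_nm3"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["mw_kda", "volume_nm3"])
    n_skipped = n_before - len(df)
    points = [(str(r.label), float(r.mw_kda), float(r.volume_nm3)) for r in df.itertuples()]
    return ReadResult(points, n_skipped)


# ---------------------------------------------------------------------------
# bulk biochemistry tables
# ---------------------------------------------------------------------------

def write_timecourse(tc: ExcisionTimeCourse, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": tc.times,
        "product_percent": tc.product_percent,
        "enzyme_total_nm": tc.enzyme_total,
        "substrate_total_nm": tc.substrate_total,
    }).to_csv(path, index=False)


def read_timecourse(path: str | Path) -> ExcisionTimeCourse:
    df = pd.read_csv(path)
    required = {"time_s", "product_percent", "enzyme_total_nm", "substrate_total_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing time-course columns {sorted(missing)}")
    df = df.dropna(subset=["time_s", "product_percent"])
    return ExcisionTimeCourse(
        times=df["time_s"].to_numpy(dtype=float),
        product_percent=df["product_percent"].to_numpy(dtype=float),
        enzyme_total=float(df["enzyme_total_nm"].iloc[0]),
        substrate_total=float(df["substrate_total_nm"].iloc[0]),
    )


def write_isotherm(iso: BindingIsotherm, path: str | Path) -> None:
    pd.DataFrame({
        "titrant_nm": iso.titrant,
        "fraction_bound": iso.fraction_bound,
        "dna_total_nm": iso.dna_total,
    }).to_csv(path, index=False)


def read_isotherm(path: str | Path) -> BindingIsotherm:
    df = pd.read_csv(path)
    required = {"titrant_nm", "fraction_bound", "dna_total_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing isotherm columns {sorted(missing)}")
    df = df.dropna(subset=["titrant_nm", "fraction_bound"])
    return BindingIsotherm(
        titrant=df["titrant_nm"].to_numpy(dtype=float),
        fraction_bound=df["fraction_bound"].to_numpy(dtype=float),
        dna_total=float(df["dna_total_nm"].iloc[0]),
    )
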