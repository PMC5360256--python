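"""Plain-text I/O for recordings, ground truth, events and image stacks.

Numeric traces travel as tab-separated tables with ``#`` header comments
carrying the column units; recording metadata lives in a JSON sidecar next
to the TSV; image stacks are multi-page TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .afm_calibration import Recording
from .synthgen import GroundTruthEvent, GroundTruthLog

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_events",
    "read_events",
    "write_segments",
    "write_stack",
    "read_stack",
]

_REC_COLUMNS = ("time_s", "v_defl_V", "z_servo_nm", "fnum")


def write_recording(rec: Recording, tsv_path) -> Path:
    """Write a recording as TSV plus a JSON metadata sidecar."""
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(
        {
            "time_s": rec.times,
            "v_defl_V": rec.v_defl,
            "z_servo_nm": rec.z_servo,
            "fnum": rec.fnum,
        }
    )
    with open(tsv_path, "w") as fh:
        fh.write("# columns: time_s [s]\tv_defl_V [V]\tz_servo_nm [nm]\tfnum [V-encoded]\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
    sidecar = tsv_path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(rec.meta, fh, indent=2, default=_jsonable)
    return tsv_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_recording(tsv_path) -> Recording:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    sidecar = tsv_path.with_suffix(".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sched = meta.get("schedule")
        if sched:  # JSON round-trips tuples as lists
            sched["approach"] = tuple(sched["approach"])
            sched["push"] = tuple(sched["push"])
            if "tail" in sched:
                sched["tail"] = tuple(sched["tail"])
    return Recording(
        times=df["time_s"].to_numpy(),
        v_defl=df["v_defl_V"].to_numpy(),
        z_servo=df["z_servo_nm"].to_numpy(),
        fnum=df["fnum"].to_numpy(),
        meta=meta,
    )


def write_ground_truth(log: GroundTruthLog, path) -> Path:
    path = Path(path)
    df = pd.DataFrame([asdict(e) for e in log.events])
    with open(path, "w") as fh:
        fh.write(
            f"# true_d_tirf_nm={log.true_d_tirf}\ttrue_drift_V_per_um={log.true_drift}\n"
        )
        if df.empty:
            fh.write(
                "segment_index\ttrue_time\ttrue_dz\ttrue_tau\tevent_type\tshape\n"
            )
        else:
            df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
    return path


def read_ground_truth(path) -> GroundTruthLog:
    path = Path(path)
    header = path.read_text().splitlines()[0]
    fields = dict(item.split("=") for item in header.lstrip("# ").split("\t"))
    df = pd.read_csv(path, sep="\t", comment="#")
    events = [
        GroundTruthEvent(
            segment_index=int(r.segment_index),
            true_time=float(r.true_time),
            true_dz=float(r.true_dz),
            true_tau=float(r.true_tau),
            event_type=str(r.event_type),
            shape=str(r.shape),
        )
        for r in df.itertuples()
    ]
    return GroundTruthLog(
        events=events,
        true_d_tirf=float(fields["true_d_tirf_nm"]),
        true_drift=float(fields["true_drift_V_per_um"]),
    )


def write_events(events_df: pd.DataFrame, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# events table; times [s], vmax [V], tau [s], dz [nm]\n")
        events_df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
    return path


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_segments(segments, path) -> Path:
    path = Path(path)
    rows = [
        {
            "index": s.index,
            "t_start_s": s.t_span[0],
            "t_end_s": s.t_span[1],
            "setpoint_v": s.setpoint_v,
            "F_pN": s.F,
            "sigmaF_pN": s.sigma_F,
            "reached_setpoint": s.reached_setpoint,
            "clamp_duration_s": s.clamp_duration,
            "is_U": s.is_U,
            "flags": ";".join(s.flags),
        }
        for s in segments
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# segments table; forces [pN], times [s]\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
    return path


def write_stack(stack: np.ndarray, path) -> Path:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
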