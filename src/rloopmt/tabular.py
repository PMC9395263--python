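"""Tabular text I/O: TSV traces/schedules/time courses and JSON manifests.

All tables are plain TSV with ``#``-prefixed header comments naming the
units (s, turns, nm, per-second, fraction), so every file is readable
without the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import CleavageTimecourse
from .trace import MagnetSchedule, TurnsTrace

__all__ = [
    "write_trace", "read_trace",
    "write_schedule", "read_schedule",
    "write_timecourses", "read_timecourses",
    "write_manifest", "read_manifest",
]

_UNITS = {"turns": "turns", "extension": "nm"}


def write_trace(path, trace: TurnsTrace) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# magnetic-tweezers trace; time_s [s], "
                 f"signal [{_UNITS[trace.channel]}]\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate!r} "
                 f"channel={trace.channel}\n")
        df = pd.DataFrame({"time_s": trace.time, "signal": trace.signal})
        if trace.truth_state is not None:
            df["truth_state"] = trace.truth_state
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_trace(path) -> TurnsTrace:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"empty trace file: {path}")
    truth = df["truth_state"].to_numpy() if "truth_state" in df else None
    rate = float(meta.get("sample_rate_hz", "nan"))
    if not np.isfinite(rate):
        dt = float(np.median(np.diff(df["time_s"])))
        rate = 1.0 / dt
    # rebuild the time axis exactly: TSV rounding must not break the
    # uniform-sampling invariant
    time = float(df["time_s"].iloc[0]) + np.arange(len(df)) / rate
    return TurnsTrace(time, df["signal"].to_numpy(),
                      rate, meta.get("channel", "turns"), truth)


def write_schedule(path, schedule: MagnetSchedule) -> None:
    with Path(path).open("w") as fh:
        fh.write("# magnet rotation schedule; t_start_s [s], "
                 "applied_turns [turns]\n")
        fh.write(f"# rotation_rate_tps={schedule.rotation_rate!r} "
                 f"force_pn={schedule.force!r}"
                 + (f" end_time_s={schedule.end_time!r}"
                    if schedule.end_time is not None else "") + "\n")
        pd.DataFrame({"t_start_s": schedule.breakpoints,
                      "applied_turns": schedule.applied_turns}
                     ).to_csv(fh, sep="\t", index=False)


def read_schedule(path) -> MagnetSchedule:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    return MagnetSchedule(
        df["t_start_s"].to_numpy(), df["applied_turns"].to_numpy(),
        rotation_rate=float(meta.get("rotation_rate_tps", 10.0)),
        force=float(meta.get("force_pn", 0.3)),
        end_time=float(meta["end_time_s"]) if "end_time_s" in meta else None)


def write_timecourses(path, timecourses) -> None:
    frames = []
    for tc in timecourses:
        frames.append(pd.DataFrame({
            "time_s": tc.times,
            "frac_sc": tc.fractions[:, 0],
            "frac_oc": tc.fractions[:, 1],
            "frac_lin": tc.fractions[:, 2],
            "repeat_id": tc.repeat_id,
        }))
    with Path(path).open("w") as fh:
        fh.write("# cleavage time courses; time_s [s], fractions "
                 "[dimensionless, sum to 1 per row]\n")
        pd.concat(frames, ignore_index=True).to_csv(
            fh, sep="\t", index=False, float_format="%.6g")


def read_timecourses(path) -> list[CleavageTimecourse]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_s", "frac_sc", "frac_oc", "frac_lin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-course file missing columns: {sorted(missing)}")
    if "repeat_id" not in df:
        df["repeat_id"] = 0
    out = []
    for rid, grp in df.groupby("repeat_id"):
        out.append(CleavageTimecourse(
            grp["time_s"].to_numpy(),
            grp[["frac_sc", "frac_oc", "frac_lin"]].to_numpy(),
            repeat_id=int(rid)))
    return out


def write_manifest(path, manifest: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=default) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
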