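"""Text I/O: trace and event TSV dialects, mutant-cycle CSV, results JSON.

Traces are tab-separated ``time_s, current_pA`` tables preceded by
``# key: value`` header lines carrying fs, t0, i_unit, f_acq, t_atp_off and
seed; event tables are ``level, start_s, duration_s`` with dead time and
analysis bandwidth in the header.  Both dialects round-trip losslessly and
tolerate CRLF line endings.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .idealize import EventTable
from .synth import CurrentTrace
from .thermo import CornerEstimate, MutantCycle

__all__ = [
    "write_trace", "read_trace", "write_events", "read_events",
    "read_cycle_csv", "write_results_json",
]

_TRACE_MAGIC = "cftrgate trace v1"
_EVENTS_MAGIC = "cftrgate events v1"


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_header(fh, magic: str, fields: dict) -> None:
    fh.write(f"# {magic}\n")
    for k, v in fields.items():
        if v is not None:
            fh.write(f"# {k}: {_fmt(v)}\n")


def _read_header(path: Path, magic: str) -> tuple[dict, int, list[str]]:
    meta: dict = {}
    body_start = 0
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != f"# {magic}":
        raise ValueError(f"{path}: line 1: expected header '# {magic}'")
    for i, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            body_start = i - 1
            break
        try:
            key, val = line[1:].split(":", 1)
        except ValueError as err:
            raise ValueError(f"{path}: line {i}: malformed header line "
                             f"{line!r}") from err
        key = key.strip()
        val = val.strip()
        try:
            meta[key] = int(val)
        except ValueError:
            try:
                meta[key] = float(val)
            except ValueError:
                meta[key] = val
    else:
        raise ValueError(f"{path}: no data rows found")
    return meta, body_start, lines


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """Write a trace in the TSV dialect (deterministic formatting)."""
    path = Path(path)
    fields = {
        "fs": trace.fs,
        "t0": trace.t0,
        "i_unit": trace.meta.get("i_unit"),
        "f_acq": trace.meta.get("f_acq"),
        "noise_sd": trace.meta.get("noise_sd"),
        "seed": trace.meta.get("seed"),
        "n_channels": trace.meta.get("n_channels"),
        "t_atp_off": trace.markers.get("t_atp_off"),
    }
    buf = _io.StringIO()
    _write_header(buf, _TRACE_MAGIC, fields)
    buf.write("time_s\tcurrent_pA\n")
    t = trace.times
    for ti, xi in zip(t, trace.samples):
        buf.write(f"{ti:.6f}\t{xi:.6f}\n")
    path.write_text(buf.getvalue())


def read_trace(path: str | Path) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    meta, body_start, lines = _read_header(path, _TRACE_MAGIC)
    if "fs" not in meta:
        raise ValueError(f"{path}: missing required '# fs' header")
    body = "\n".join(lines[body_start:])
    frame = pd.read_csv(_io.StringIO(body), sep="\t")
    if list(frame.columns) != ["time_s", "current_pA"]:
        raise ValueError(f"{path}: line {body_start + 1}: expected columns "
                         f"time_s, current_pA, got {list(frame.columns)}")
    markers = {}
    if "t_atp_off" in meta:
        markers["t_atp_off"] = float(meta.pop("t_atp_off"))
    fs = float(meta.pop("fs"))
    t0 = float(meta.pop("t0", 0.0))
    return CurrentTrace(t0, fs, frame["current_pA"].to_numpy(),
                        markers=markers, meta=meta)


def write_events(events: EventTable, path: str | Path) -> None:
    path = Path(path)
    buf = _io.StringIO()
    _write_header(buf, _EVENTS_MAGIC, {
        "dead_time_s": events.dead_time_s,
        "fc": events.fc,
        "source": events.source or None,
    })
    buf.write("level\tstart_s\tduration_s\n")
    for row in events.events.itertuples(index=False):
        buf.write(f"{row.level}\t{row.start_s:.6f}\t{row.duration_s:.6f}\n")
    path.write_text(buf.getvalue())


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    meta, body_start, lines = _read_header(path, _EVENTS_MAGIC)
    for key in ("dead_time_s", "fc"):
        if key not in meta:
            raise ValueError(f"{path}: missing required '# {key}' header")
    body = "\n".join(lines[body_start:])
    frame = pd.read_csv(_io.StringIO(body), sep="\t")
    if list(frame.columns) != ["level", "start_s", "duration_s"]:
        raise ValueError(f"{path}: line {body_start + 1}: expected columns "
                         f"level, start_s, duration_s")
    return EventTable(frame, dead_time_s=float(meta["dead_time_s"]),
                      fc=float(meta["fc"]), source=str(meta.get("source", "")))


def read_cycle_csv(path: str | Path) -> MutantCycle:
    """Mutant-cycle input: CSV with columns construct, role, kind, mean, sem, n.

    ``role`` is one of background, singleA, singleB, double.
    """
    frame = pd.read_csv(path)
    required = {"construct", "role", "kind", "mean", "sem", "n"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: cycle CSV needs columns {sorted(required)}")
    by_role = {}
    for row in frame.itertuples(index=False):
        by_role[row.role] = CornerEstimate(
            label=row.construct, kind=row.kind, mean=float(row.mean),
            sem=float(row.sem), n=int(row.n))
    missing = {"background", "singleA", "singleB", "double"} - set(by_role)
    if missing:
        raise ValueError(f"{path}: cycle CSV missing roles {sorted(missing)}")
    return MutantCycle(background=by_role["background"],
                       single_A=by_role["singleA"],
                       single_B=by_role["singleB"],
                       double=by_role["double"])


def write_results_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
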