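"""Dwell-event recovery from single-channel current traces.

The analysis chain mirrors standard single-channel practice: the trace is
Gaussian-filtered at an analysis bandwidth (100 Hz for intraburst work),
idealized by half-amplitude threshold crossing, and events shorter than the
filter's dead time ``T_d = 0.179 / fc`` are merged into the flanking level.
Intraburst statistics (tau_open, tau_flicker, K_eq|B, P_o|B) are computed as
simple arithmetic dwell-time averages over "last-channel" segments — windows
after ATP removal during which exactly one channel is still bursting, so that
every closure inside the window is a flicker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .synth import GAUSSIAN_SIGMA_COEF, CurrentTrace

__all__ = [
    "DEAD_TIME_COEF",
    "EventTable",
    "IntraburstStats",
    "gaussian_filter",
    "estimate_baseline",
    "half_amplitude_idealize",
    "last_channel_segment",
    "intraburst_stats",
]

#: T_d * fc — the Gaussian-filter resolution limit: an event of exactly this
#: duration is attenuated to half amplitude and is the shortest detectable.
DEAD_TIME_COEF = 0.179


@dataclass
class EventTable:
    """Idealized dwell events tiling one analyzed segment.

    ``events`` has columns ``level`` ('open'/'closed'), ``start_s``,
    ``duration_s``; levels alternate and durations are >= ``dead_time_s``.
    """

    events: pd.DataFrame
    dead_time_s: float
    fc: float
    source: str = ""

    def __post_init__(self) -> None:
        required = {"level", "start_s", "duration_s"}
        if not required <= set(self.events.columns):
            raise ValueError(f"events frame needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.events)

    def durations(self, level: str) -> np.ndarray:
        return self.events.loc[self.events["level"] == level, "duration_s"].to_numpy()


@dataclass(frozen=True)
class IntraburstStats:
    """Arithmetic dwell-time summaries of intraburst gating."""

    tau_open: float
    tau_flicker: float
    K_eqB: float      # tau_open / tau_flicker
    P_oB: float       # tau_open / (tau_open + tau_flicker)
    n_open: int
    n_flicker: int


def gaussian_filter(trace: CurrentTrace, fc: float) -> CurrentTrace:
    """Zero-phase Gaussian low-pass with -3 dB cutoff ``fc`` (DC gain 1).

    The kernel SD in time is ``0.1325 / fc``; output length equals input.
    """
    if fc >= trace.fs / 2:
        raise ValueError(f"fc = {fc} Hz must be below fs/2 = {trace.fs / 2} Hz")
    sigma = GAUSSIAN_SIGMA_COEF * trace.fs / fc
    out = gaussian_filter1d(trace.samples, sigma, mode="nearest")
    meta = dict(trace.meta)
    meta["fc_analysis"] = fc
    return CurrentTrace(trace.t0, trace.fs, out,
                        markers=dict(trace.markers), meta=meta)


def estimate_baseline(trace: CurrentTrace, window: float = 1.0) -> float:
    """Baseline as the median of the terminal ``window`` seconds.

    Intended for last-channel segments, which end with the channel closed.
    """
    n = max(1, int(window * trace.fs))
    return float(np.median(trace.samples[-n:]))


def _merge_subresolution(levels: list[int], durs: list[float],
                         dead_time: float) -> tuple[list[int], list[float]]:
    """Merge events shorter than the dead time into the flanking level.

    The globally shortest sub-dead-time event is removed first (ties go to
    the earlier event); removing an interior event fuses its two same-level
    neighbors into one.  Edge events merge into their single neighbor.
    """
    levels = list(levels)
    durs = list(durs)
    while len(durs) > 1:
        idx = -1
        best = dead_time
        for i, d in enumerate(durs):
            if d < best:
                best = d
                idx = i
        if idx < 0:
            break
        if 0 < idx < len(durs) - 1:
            durs[idx - 1] = durs[idx - 1] + durs[idx] + durs[idx + 1]
            del levels[idx:idx + 2]
            del durs[idx:idx + 2]
        elif idx == 0:
            durs[1] += durs[0]
            del levels[0]
            del durs[0]
        else:
            durs[-2] += durs[-1]
            del levels[-1]
            del durs[-1]
    return levels, durs


def half_amplitude_idealize(
    trace: CurrentTrace,
    baseline: float | None = None,
    i_unit: float | None = None,
    *,
    fc: float | None = None,
    source: str = "",
) -> EventTable:
    """Idealize a filtered single-channel trace by half-amplitude threshold.

    The threshold sits at ``baseline + i_unit / 2``; a sample is 'open' when
    it lies on the ``i_unit`` side of the threshold.  Crossings are located
    at sample resolution (the sampling rate far exceeds the analysis
    bandwidth, so sub-sample interpolation gains nothing).  Events shorter
    than the dead time ``0.179 / fc`` are merged into the flanking level.  A
    trace that never crosses the threshold yields a single-event table.

    ``baseline`` defaults to :func:`estimate_baseline`; ``i_unit`` and ``fc``
    default to the trace metadata.
    """
    if i_unit is None:
        i_unit = trace.meta.get("i_unit")
    if i_unit is None or i_unit == 0:
        raise ValueError("i_unit must be provided (nonzero)")
    if fc is None:
        fc = trace.meta.get("fc_analysis")
    if fc is None:
        raise ValueError("analysis bandwidth fc unknown: filter the trace "
                         "with gaussian_filter or pass fc explicitly")
    if baseline is None:
        baseline = estimate_baseline(trace)
    dead_time = DEAD_TIME_COEF / fc

    # normalized deviation: 1 at the open level regardless of sign convention
    d = (trace.samples - baseline) / i_unit
    is_open = d >= 0.5
    # run-length encode
    change = np.nonzero(np.diff(is_open))[0] + 1
    bounds = np.concatenate(([0], change, [len(d)]))
    levels = [int(is_open[b]) for b in bounds[:-1]]
    durs = [float((b1 - b0) / trace.fs) for b0, b1 in zip(bounds[:-1], bounds[1:])]
    levels, durs = _merge_subresolution(levels, durs, dead_time)

    starts = trace.t0 + np.concatenate(([0.0], np.cumsum(durs)[:-1]))
    frame = pd.DataFrame({
        "level": ["open" if l else "closed" for l in levels],
        "start_s": starts,
        "duration_s": durs,
    })
    return EventTable(frame, dead_time_s=dead_time, fc=fc, source=source)


def last_channel_segment(
    trace: CurrentTrace,
    t_atp_off: float | None = None,
    *,
    baseline: float = 0.0,
    i_unit: float | None = None,
    settle_s: float = 0.05,
) -> tuple[float, float]:
    """Bounds of the last-channel window in a multi-channel post-removal trace.

    Returns ``(t_start, t_stop)``: from the last moment the idealized open
    channel count reaches 2 (or from ``t_atp_off`` if it never does) until the
    terminal closure.  After ATP removal channels cannot reopen, so within
    the window every closure of the surviving channel is a flicker.  A
    ``settle_s`` guard is added after the penultimate channel's closure so
    its terminal transition is not counted as intraburst gating.
    """
    if t_atp_off is None:
        t_atp_off = trace.markers.get("t_atp_off")
    if t_atp_off is None:
        raise ValueError("trace carries no t_atp_off marker")
    if i_unit is None:
        i_unit = trace.meta.get("i_unit")
    if i_unit is None:
        raise ValueError("i_unit must be provided")
    t = trace.times
    post = t >= t_atp_off
    if not post.any():
        raise ValueError("trace ends before ATP removal")
    counts = np.rint((trace.samples - baseline) / i_unit).astype(int)
    counts = np.clip(counts, 0, None)
    idx_post = np.nonzero(post)[0]
    c = counts[idx_post]
    open_any = np.nonzero(c >= 1)[0]
    if len(open_any) == 0:
        raise ValueError("no open channel after ATP removal; nothing to analyze")
    t_close = t[idx_post[open_any[-1]]]
    multi = np.nonzero(c >= 2)[0]
    if len(multi) > 0:
        t_start = t[idx_post[multi[-1]]] + settle_s
    else:
        t_start = t_atp_off
    if t_start >= t_close:
        raise ValueError(
            "zero-length last-channel window (channels closed together or "
            "instantly); re-record with fewer channels")
    return float(t_start), float(t_close)


def intraburst_stats(events: EventTable,
                     *, exclude_terminal_closed: bool = True) -> IntraburstStats:
    """Intraburst dwell statistics from a last-channel event table.

    Mean open and flickery-closed durations are simple arithmetic averages;
    ``K_eq|B = tau_open / tau_flicker``.  The terminal closed event is an
    interburst (permanent) closure, not a flicker, and is excluded.
    """
    frame = events.events
    if exclude_terminal_closed and len(frame) and frame.iloc[-1]["level"] == "closed":
        frame = frame.iloc[:-1]
    opens = frame.loc[frame["level"] == "open", "duration_s"].to_numpy()
    closed = frame.loc[frame["level"] == "closed", "duration_s"].to_numpy()
    if len(opens) < 2 or len(closed) < 2:
        raise ValueError(
            f"insufficient events for intraburst statistics: "
            f"{len(opens)} open, {len(closed)} flickery closed (need >= 2 each)")
    tau_open = float(opens.mean())
    tau_flicker = float(closed.mean())
    return IntraburstStats(
        tau_open=tau_open,
        tau_flicker=tau_flicker,
        K_eqB=tau_open / tau_flicker,
        P_oB=tau_open / (tau_open + tau_flicker),
        n_open=len(opens),
        n_flicker=len(closed),
    )
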