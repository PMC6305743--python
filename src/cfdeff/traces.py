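"""Short-circuit-current traces and delta I_sc extraction.

An Ussing-chamber recording is a time series of area-normalised
short-circuit current with drug additions annotated in an event table
(amiloride, forskolin, genistein, CFTR inhibitor, ATP) plus repeating
resistance-check voltage pulses.  delta I_sc is the increase from the
steady-state baseline before forskolin to the maximum current after
genistein; pulse deflections are blanked out of both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, InsufficientDataError, ProtocolError, SchemaError

EVENT_NAMES = frozenset(
    {"amiloride", "forskolin", "genistein", "inhibitor", "atp", "pulse"}
)
_UNIQUE_EVENTS = ("forskolin", "genistein", "inhibitor")


@dataclass(frozen=True)
class IscTrace:
    """Area-normalised short-circuit current vs time (s, uA/cm^2)."""

    time: np.ndarray
    current: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.current, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ArgumentError("time and current must be 1-D arrays of equal length")
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ArgumentError("time must be strictly increasing with >= 2 samples")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", c)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass(frozen=True)
class EventTable:
    """Ordered (event_name, time_s) annotations for one recording."""

    events: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        evs = tuple((str(n), float(t)) for n, t in self.events)
        for name, _ in evs:
            if name not in EVENT_NAMES:
                raise ArgumentError(f"unknown event name {name!r}")
        for name in _UNIQUE_EVENTS:
            if sum(1 for n, _ in evs if n == name) > 1:
                raise ProtocolError(f"event {name!r} may appear at most once")
        object.__setattr__(self, "events", tuple(sorted(evs, key=lambda e: e[1])))

    def time_of(self, name: str) -> float | None:
        for n, t in self.events:
            if n == name:
                return t
        return None

    def times_of(self, name: str) -> list[float]:
        return [t for n, t in self.events if n == name]


def read_trace_csv(path) -> IscTrace:
    frame = pd.read_csv(path)
    for col in ("time_s", "isc_uA_cm2"):
        if col not in frame.columns:
            raise SchemaError(f"trace CSV is missing required column {col!r}")
    return IscTrace(
        time=frame["time_s"].to_numpy(float),
        current=frame["isc_uA_cm2"].to_numpy(float),
    )


def read_events_csv(path) -> EventTable:
    frame = pd.read_csv(path)
    for col in ("event", "time_s"):
        if col not in frame.columns:
            raise SchemaError(f"event CSV is missing required column {col!r}")
    return EventTable(tuple(zip(frame["event"].astype(str), frame["time_s"].astype(float))))


def write_trace_csv(trace: IscTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "isc_uA_cm2": trace.current}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_events_csv(events: EventTable, path) -> None:
    pd.DataFrame(events.events, columns=["event", "time_s"]).to_csv(path, index=False)


def _pulse_mask(trace: IscTrace, events: EventTable, pulse_blank: float) -> np.ndarray:
    """Boolean mask of samples NOT inside any blanked pulse window."""
    keep = np.ones_like(trace.time, dtype=bool)
    for tp in events.times_of("pulse"):
        keep &= ~((trace.time >= tp - pulse_blank) & (trace.time <= tp + pulse_blank))
    return keep


def extract_delta_isc(
    trace: IscTrace,
    events: EventTable,
    baseline_window: float = 60.0,
    pulse_blank: float = 3.0,
) -> float:
    """delta I_sc: post-genistein maximum minus pre-forskolin baseline mean.

    Parameters
    ----------
    baseline_window
        Length (s) of the averaging window ending at the forskolin addition.
    pulse_blank
        Half-width (s) of the window blanked around each resistance-check
        pulse so the bipolar deflections do not bias either statistic.

    The peak search runs from the genistein addition to the CFTR-inhibitor
    addition if annotated (the inhibitor abolishes the CFTR current, so
    later samples are not CFTR signal), otherwise to the end of the trace.
    """
    t_fsk = events.time_of("forskolin")
    t_gst = events.time_of("genistein")
    if t_fsk is None or t_gst is None:
        raise ProtocolError("both forskolin and genistein events are required")
    if t_gst <= t_fsk:
        raise ProtocolError("genistein must be added after forskolin")
    t0, t1 = trace.span
    for name, t in events.events:
        if not (t0 <= t <= t1):
            raise ProtocolError(f"event {name!r} at t={t} s lies outside the trace span")
    if t_fsk - baseline_window < t0:
        raise ArgumentError(
            f"baseline window of {baseline_window} s does not fit before the "
            f"forskolin addition at t={t_fsk} s"
        )
    t_end = events.time_of("inhibitor")
    unblanked = _pulse_mask(trace, events, pulse_blank)

    base_sel = unblanked & (trace.time >= t_fsk - baseline_window) & (trace.time < t_fsk)
    if not base_sel.any():
        raise InsufficientDataError("baseline window is empty after pulse blanking")
    peak_sel = unblanked & (trace.time >= t_gst)
    if t_end is not None:
        peak_sel &= trace.time < t_end
    if not peak_sel.any():
        raise InsufficientDataError("peak-search window is empty after pulse blanking")

    baseline = float(np.mean(trace.current[base_sel]))
    peak = float(np.max(trace.current[peak_sel]))
    return peak - baseline
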