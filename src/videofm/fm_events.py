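"""Spike-to-event merging (6-s rule) and the four clinical FM parameters.

Adjacent spikes closer than 6 s apart belong to the same fetal movement;
an event spans its first to its last constituent spike (a single-spike
event occupies one sample period).  From the merged events come:

* **number** — FM events per hour,
* **interval** — time from the end of one event to the start of the next,
* **duration** — span of each event,
* **percentage** — total event time as a share of the analyzed time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from videofm.spike_detect import SpikeTrain

__all__ = ["FMEvent", "FMParameters", "merge_spikes", "fm_parameters"]


@dataclass(frozen=True)
class FMEvent:
    """One fetal-movement event (merged spike group), in seconds."""

    start_s: float
    end_s: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("event end before start")
        if self.n_spikes < 1:
            raise ValueError("event must contain at least one spike")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FMParameters:
    """Clinical FM parameters over one analyzed recording."""

    number_per_hour: float
    intervals_s: list[float]
    durations_s: list[float]
    percentage: float
    analyzed_time_s: float
    n_events: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_events = len(self.durations_s)
        if not 0.0 <= self.percentage <= 100.0:
            raise ValueError("percentage out of [0, 100]")


def merge_spikes(spikes: SpikeTrain, gap_s: float = 6.0) -> list[FMEvent]:
    """Greedy left-to-right merging of spikes into FM events.

    A spike joins the current event iff its time minus the previous spike's
    time is strictly less than ``gap_s``; a gap of ``gap_s`` or more starts
    a new event.  A single-spike event gets duration of one sample period.
    """
    times = spikes.times_s
    if len(times) == 0:
        return []
    one_sample = 1.0 / spikes.fs
    events: list[FMEvent] = []
    start = prev = times[0]
    count = 1
    for t in times[1:]:
        if t - prev < gap_s:
            prev = t
            count += 1
        else:
            end = prev if count > 1 else start + one_sample
            events.append(FMEvent(float(start), float(end), count))
            start = prev = t
            count = 1
    end = prev if count > 1 else start + one_sample
    events.append(FMEvent(float(start), float(end), count))
    return events


def fm_parameters(
    events: list[FMEvent],
    analyzed_time_s: float,
    interval_mode: str = "end_to_start",
) -> FMParameters:
    """Compute the four FM parameters from merged events.

    ``interval_mode`` selects how the gap between adjacent events is
    measured: ``"end_to_start"`` (elapsed quiet time, default) or
    ``"onset_to_onset"``.
    """
    if analyzed_time_s <= 0:
        raise ValueError("analyzed_time_s must be > 0")
    if interval_mode not in ("end_to_start", "onset_to_onset"):
        raise ValueError("unknown interval_mode")
    events = sorted(events, key=lambda e: e.start_s)
    durations = [e.duration_s for e in events]
    if interval_mode == "end_to_start":
        intervals = [b.start_s - a.end_s for a, b in zip(events, events[1:])]
    else:
        intervals = [b.start_s - a.start_s for a, b in zip(events, events[1:])]
    total = float(np.sum(durations)) if durations else 0.0
    return FMParameters(
        number_per_hour=len(events) * 3600.0 / analyzed_time_s,
        intervals_s=[float(v) for v in intervals],
        durations_s=[float(v) for v in durations],
        percentage=min(100.0, total / analyzed_time_s * 100.0),
        analyzed_time_s=float(analyzed_time_s),
    )
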