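"""Event-level evaluation against gold-standard FM labels.

Detected events are matched to labeled intervals by temporal overlap: a
label counts as a true positive when at least one detection overlaps it;
a detection that overlaps no label is a false positive; an unmatched label
is a false negative.  From the counts come the detection metrics

    TDR = TP / TME * 100        PPV = TP / (TP + FP) * 100
    SEN = TP / (TP + FN) * 100  ACC = TP / (TP + FP + FN) * 100
    F1  = 2 * PPV * SEN / (PPV + SEN)

where TME is the number of manually labeled events.  TDR and SEN coincide
by construction (TP + FN = TME).  Event-level detection has no meaningful
true-negative count: ACC uses TP/(TP+FP+FN), the only reading consistent
with the other metrics (the per-recording report records this note).

Agreement of FM *parameters* between two raters/methods uses Bland–Altman
analysis: per-pair differences, their mean, and mean ± 1.96 SD limits.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from videofm.fm_events import FMEvent

__all__ = [
    "Annotation",
    "MatchCounts",
    "MetricsReport",
    "BlandAltmanResult",
    "load_annotation",
    "match_events",
    "metrics",
    "bland_altman",
    "f1_from_ppv_sen",
    "acc_from_ppv_sen",
]


@dataclass
class Annotation:
    """Gold-standard labeled FM intervals (seconds), ordered, non-overlapping."""

    labeled_events: list[tuple[float, float]]
    tme: int = field(init=False)

    def __post_init__(self) -> None:
        ev = sorted((float(a), float(b)) for a, b in self.labeled_events)
        for (a0, b0), (a1, _) in zip(ev, ev[1:]):
            if a1 < b0:
                raise ValueError("labeled intervals overlap")
        for a, b in ev:
            if b < a:
                raise ValueError("labeled interval end before start")
        self.labeled_events = ev
        self.tme = len(ev)


def load_annotation(path: str | os.PathLike, fps: float | None = None) -> Annotation:
    """Read labels from JSON (list of {start_s, end_s}) or CSV.

    CSV columns: ``start_s, end_s`` or ``start_frame, end_frame`` (the
    latter requires ``fps``).
    """
    path = os.fspath(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        events = data["events"] if isinstance(data, dict) else data
        return Annotation([(e["start_s"], e["end_s"]) for e in events])
    df = pd.read_csv(path)
    if {"start_s", "end_s"} <= set(df.columns):
        return Annotation(list(zip(df.start_s, df.end_s)))
    if {"start_frame", "end_frame"} <= set(df.columns):
        if fps is None:
            raise ValueError("frame-based annotation needs fps")
        return Annotation(list(zip(df.start_frame / fps, df.end_frame / fps)))
    raise ValueError("annotation file needs start_s/end_s or start_frame/end_frame")


@dataclass
class MatchCounts:
    """Event-level confusion counts; TN is undefined for event detection."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def tme(self) -> int:
        return self.tp + self.fn


def _overlaps(a: tuple[float, float], b: tuple[float, float], pad: float) -> bool:
    return a[0] <= b[1] + pad and b[0] <= a[1] + pad


def match_events(
    pred: list[FMEvent],
    labels: Annotation,
    pad_s: float = 0.0,
) -> MatchCounts:
    """Match detections to labels by (closed-interval) temporal overlap.

    Each label is judged independently: it is a TP if any detection
    overlaps it (one detection may validate several labels).  Detections
    overlapping no label are FPs.  ``pad_s`` widens the overlap test
    symmetrically (default 0: strict overlap).
    """
    pred_iv = [(e.start_s, e.end_s) for e in pred]
    tp = fn = 0
    used = [False] * len(pred_iv)
    for lab in labels.labeled_events:
        hit = False
        for i, p in enumerate(pred_iv):
            if _overlaps(lab, p, pad_s):
                hit = True
                used[i] = True
        if hit:
            tp += 1
        else:
            fn += 1
    fp = used.count(False)
    return MatchCounts(tp=tp, fp=fp, fn=fn)


@dataclass
class MetricsReport:
    """Detection metrics in percent; NaN marks an undefined (0/0) metric."""

    tdr: float
    ppv: float
    sen: float
    acc: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"TDR": self.tdr, "PPV": self.ppv, "SEN": self.sen,
                "ACC": self.acc, "F1": self.f1}


def metrics(counts: MatchCounts, tme: int | None = None) -> MetricsReport:
    """Compute TDR/PPV/SEN/ACC/F1 (percent) from match counts.

    ``tme`` defaults to ``tp + fn``; zero denominators yield NaN with the
    metric flagged missing rather than raising.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tme is None:
        tme = counts.tme
    nan = float("nan")
    tdr = tp / tme * 100.0 if tme > 0 else nan
    ppv = tp / (tp + fp) * 100.0 if tp + fp > 0 else nan
    sen = tp / (tp + fn) * 100.0 if tp + fn > 0 else nan
    acc = tp / (tp + fp + fn) * 100.0 if tp + fp + fn > 0 else nan
    if np.isnan(ppv) or np.isnan(sen) or ppv + sen == 0:
        f1 = nan
    else:
        f1 = 2.0 * ppv * sen / (ppv + sen)
    return MetricsReport(tdr=tdr, ppv=ppv, sen=sen, acc=acc, f1=f1)


def f1_from_ppv_sen(ppv: float, sen: float) -> float:
    """F1 (percent) as the harmonic mean of PPV and SEN percentages."""
    if ppv + sen == 0:
        return float("nan")
    return 2.0 * ppv * sen / (ppv + sen)


def acc_from_ppv_sen(ppv: float, sen: float) -> float:
    """ACC (percent) implied by PPV and SEN under ACC = TP/(TP+FP+FN).

    Dividing through by TP gives ``1/acc = 1/ppv + 1/sen - 1`` with the
    rates as fractions — ACC is fully determined by PPV and SEN.
    """
    p, s = ppv / 100.0, sen / 100.0
    if p == 0 or s == 0:
        return float("nan")
    return 100.0 / (1.0 / p + 1.0 / s - 1.0)


@dataclass
class BlandAltmanResult:
    """Bland–Altman agreement of one FM parameter across recordings."""

    means: np.ndarray       # per-pair (p1 + p2) / 2
    diffs: np.ndarray       # per-pair p1 - p2
    mean_diff: float
    loa_low: float          # mean_diff - 1.96 * SD(diffs)
    loa_high: float         # mean_diff + 1.96 * SD(diffs)

    def coverage(self) -> float:
        """Fraction of differences inside the limits of agreement."""
        inside = (self.diffs >= self.loa_low) & (self.diffs <= self.loa_high)
        return float(inside.mean())


def bland_altman(p1: np.ndarray, p2: np.ndarray) -> BlandAltmanResult:
    """Bland–Altman analysis of paired parameter values.

    Limits of agreement are ``mean(diff) ± 1.96 * SD(diff)`` with the
    sample standard deviation (n-1 denominator).
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape:
        raise ValueError("paired inputs must have equal length")
    if len(p1) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = p1 - p2
    means = (p1 + p2) / 2.0
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        means=means, diffs=diffs, mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd, loa_high=mean_diff + 1.96 * sd,
    )
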