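"""FM spike recognition by the first/second-order differential threshold method.

A fetal movement makes the FM signal change abruptly, so spikes are found
from the signal's first difference ``y1`` and second difference ``y2``:

* ``Th1`` — the mean of the local minima of ``y2``.  Samples with
  ``x(n) <= Th1`` are rejected outright.
* ``Th2 = a * max(y3)`` with ``y3(n) = max(y1)*y1(n) + max(y2)*y2(n)`` and
  coefficient ``a`` between 0.01 and 0.05.

A sample is an FM spike iff ``x(n) > Th1`` and ``x(n) > Th2``.  An
alternative mode compares ``y3(n)`` (instead of ``x(n)``) against ``Th2``;
the literal signal-amplitude comparison is the default.

Because ``Th2`` is quadratic in the signal scale while ``x`` is linear, the
inequalities only behave as intended for unit-order amplitudes; by default
the signal is therefore normalized to unit peak amplitude before
thresholding (the ``Th1`` comparison is scale-equivariant, so only the
``Th2`` condition is affected).  Detection then becomes invariant under
positive rescaling of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "first_diff",
    "second_diff",
    "threshold_th1",
    "threshold_th2",
    "detect_spikes",
]

A_RANGE = (0.01, 0.05)


@dataclass
class SpikeTrain:
    """Detected FM spike sample indices with the thresholds that produced them."""

    spike_indices: np.ndarray  # strictly increasing, in [0, len(x) - 3]
    fs: float
    th1: float
    th2: float
    a: float
    degenerate_th1: bool = False  # Th1 fell back to min(y2): no local minima
    low_crest: bool = False       # peak/background too small: no-FM guard fired

    def __post_init__(self) -> None:
        self.spike_indices = np.asarray(self.spike_indices, dtype=np.int64)
        if len(self.spike_indices) > 1 and np.any(np.diff(self.spike_indices) <= 0):
            raise ValueError("spike indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_indices)

    @property
    def times_s(self) -> np.ndarray:
        return self.spike_indices / self.fs


def first_diff(x: np.ndarray) -> np.ndarray:
    """y1(n) = x(n+1) - x(n); length len(x) - 1."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for the first difference")
    return np.diff(x)


def second_diff(x: np.ndarray) -> np.ndarray:
    """y2(n) = x(n+2) - 2 x(n+1) + x(n); length len(x) - 2."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for the second difference")
    return np.diff(x, n=2)


def threshold_th1(y2: np.ndarray) -> tuple[float, bool]:
    """Mean of the strict interior local minima of ``y2``.

    Returns ``(Th1, degenerate)``; with no local minima (monotone ``y2``)
    the fallback is ``min(y2)`` with the degenerate flag set.
    """
    y2 = np.asarray(y2, dtype=np.float64)
    if len(y2) < 1:
        raise ValueError("empty second difference")
    if len(y2) >= 3:
        interior = y2[1:-1]
        is_min = (interior < y2[:-2]) & (interior < y2[2:])
        minima = interior[is_min]
        if len(minima):
            return float(minima.mean()), False
    logger.warning("no local minima in y2; Th1 falls back to min(y2)")
    return float(y2.min()), True


def threshold_th2(
    y1: np.ndarray, y2: np.ndarray, a: float = 0.03
) -> tuple[np.ndarray, float]:
    """Weighted difference signal ``y3`` and the second threshold ``Th2``.

    ``y3(n) = max(y1) * y1(n) + max(y2) * y2(n)`` on the common index range
    (``y1`` truncated to ``len(y2)``); ``Th2 = a * max(y3)``.
    """
    if not (A_RANGE[0] <= a <= A_RANGE[1]):
        logger.warning("coefficient a=%s outside the standard range %s", a, A_RANGE)
    y1 = np.asarray(y1, dtype=np.float64)
    y2 = np.asarray(y2, dtype=np.float64)
    if len(y2) < 1:
        raise ValueError("empty second difference")
    y1max = float(y1.max())
    y2max = float(y2.max())
    y3 = y1max * y1[: len(y2)] + y2max * y2
    th2 = a * float(y3.max())
    return y3, th2


def detect_spikes(
    x: np.ndarray,
    a: float = 0.03,
    fs: float = 25.0,
    compare_on: str = "signal",
    normalize: bool = True,
    min_crest: float = 8.0,
) -> SpikeTrain:
    """Detect FM spikes in the FM signal ``x``.

    ``compare_on="signal"`` (default) tests the signal amplitude against
    both thresholds: spike at ``n`` iff ``x(n) > Th1 and x(n) > Th2``.
    ``compare_on="y3"`` tests ``y3(n) > Th2`` for the second condition
    instead.  Indices run over the common range ``[0, len(x) - 3]`` where
    both differences are defined.

    With ``normalize`` (default) the signal is divided by its peak absolute
    amplitude first, which puts ``Th2 = a * max(y3)`` on the scale the rule
    assumes; the recorded thresholds are then on the normalized scale.

    Both thresholds are relative to the signal's own maxima, so on a
    recording with no movement at all *something* would always exceed them.
    ``min_crest`` guards that degenerate case: if the peak amplitude is
    less than ``min_crest`` times the robust background level (1.4826 x
    median absolute deviation), the signal is treated as movement-free and
    no spikes are returned (``low_crest`` flag set).  Set ``min_crest=0``
    to disable.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to detect spikes")
    if compare_on not in ("signal", "y3"):
        raise ValueError("compare_on must be 'signal' or 'y3'")
    peak = np.abs(x).max()
    if min_crest > 0 and peak > 0:
        mad = np.median(np.abs(x - np.median(x)))
        if mad > 0 and peak / (1.4826 * mad) < min_crest:
            logger.info("crest factor below %.1f: treating signal as FM-free",
                        min_crest)
            return SpikeTrain(
                spike_indices=np.array([], dtype=np.int64), fs=fs,
                th1=float("nan"), th2=float("nan"), a=a, low_crest=True,
            )
    if normalize and peak > 0:
        x = x / peak
    y1 = first_diff(x)
    y2 = second_diff(x)
    th1, degenerate = threshold_th1(y2)
    y3, th2 = threshold_th2(y1, y2, a)
    n_common = len(y2)  # x(n), y1(n), y2(n) all defined for n < len(x) - 2
    xc = x[:n_common]
    if compare_on == "signal":
        hits = (xc > th1) & (xc > th2)
    else:
        hits = (xc > th1) & (y3 > th2)
    return SpikeTrain(
        spike_indices=np.flatnonzero(hits), fs=fs, th1=th1, th2=th2, a=a,
        degenerate_th1=degenerate,
    )
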