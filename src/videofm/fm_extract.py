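"""FM-signal extraction from the H/S motion series.

Three stages:

1.  **High-pass filtering** — a 7th-order Butterworth high-pass at 3 Hz
    removes respiration and other low-frequency background (fetal-movement
    energy lies in the 3–20 Hz band, clipped at Nyquist for 25-fps video).
    Applied forward–backward (zero phase) so spike timing is preserved.
2.  **EEMD** — ensemble empirical mode decomposition: each of ``n_ensemble``
    trials adds white noise with standard deviation ``noise_ratio x std(x)``
    to the signal, runs EMD sifting, and the intrinsic mode functions (IMFs)
    are averaged index-wise across trials.  The added noise populates the
    full timescale axis, which breaks the mode mixing that plagues plain
    EMD, and averages out of the final IMFs.
3.  **IMF selection** — each IMF is scored by its band-energy ratio
    ``E_f/E`` (fraction of spectral energy in the FM band) and its Spearman
    correlation ``eta`` with the filtered series.  IMFs with ``E_f/E >
    delta`` are candidates; the candidate maximizing ``E_f/E + eta`` becomes
    the FM signal.  If no IMF clears ``delta`` the global maximizer is used
    and flagged as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfilt, sosfiltfilt
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "IMFSet",
    "FMSignal",
    "highpass",
    "emd",
    "eemd",
    "band_energy_ratio",
    "spearman",
    "select_fm_imf",
    "extract_fm_signal",
]

FM_BAND_HZ = (3.0, 20.0)


# ---------------------------------------------------------------------------
# High-pass filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Butterworth high-pass specification."""

    fs: float
    order: int = 7
    cutoff_hz: float = 3.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValueError(
                f"cutoff must lie in (0, fs/2) = (0, {self.fs / 2}), got {self.cutoff_hz}"
            )


def highpass(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """High-pass filter a 1-D series (zero-phase by default)."""
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    min_len = 3 * spec.order + 1
    sos = butter(spec.order, spec.cutoff_hz, btype="highpass", fs=spec.fs, output="sos")
    if spec.zero_phase:
        # forward-backward filtering needs pad room on both ends
        padlen = 3 * (2 * sos.shape[0] + 1)
        min_len = max(min_len, padlen + 1)
        if len(x) < min_len:
            raise ValueError(f"series too short: need at least {min_len} samples")
        return sosfiltfilt(sos, x)
    if len(x) < min_len:
        raise ValueError(f"series too short: need at least {min_len} samples")
    return sosfilt(sos, x)


# ---------------------------------------------------------------------------
# EMD / EEMD
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D array."""
    d = np.diff(x)
    # collapse flat runs: treat zero diffs as continuing the previous trend
    d_sign = np.sign(d)
    for i in range(1, len(d_sign)):
        if d_sign[i] == 0:
            d_sign[i] = d_sign[i - 1]
    turn = np.diff(d_sign)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``.

    Extrema are mirror-extended past both signal ends (standard EMD boundary
    treatment) so the spline does not swing wildly at the edges.
    """
    n = len(x)
    t = idx.astype(np.float64)
    v = x[idx]
    n_ext = min(2, len(idx))
    left_t = 2 * 0.0 - t[:n_ext][::-1] - 1.0  # mirror about -0.5
    left_v = v[:n_ext][::-1]
    right_t = 2 * (n - 1.0) - t[-n_ext:][::-1] + 1.0
    right_v = v[-n_ext:][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    # guard against duplicate knots from mirroring a boundary extremum
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    if len(tt) < 2:
        return np.full(n, vv[0])
    if len(tt) < 4:
        return np.interp(np.arange(n), tt, vv)
    return CubicSpline(tt, vv)(np.arange(n))


def _sift_imf(x: np.ndarray, n_sifts: int) -> np.ndarray | None:
    """Extract one IMF by a fixed number of sifting iterations.

    Returns ``None`` when ``x`` is monotone (fewer than one maximum and one
    minimum), i.e. is a residual trend.
    """
    h = x
    for _ in range(n_sifts):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 1 or len(minima) < 1:
            return None if h is x else h
        upper = _mirrored_envelope(h, maxima)
        lower = _mirrored_envelope(h, minima)
        h = h - (upper + lower) / 2.0
    return h


def emd(
    series: np.ndarray, max_imfs: int | None = None, n_sifts: int = 10
) -> list[np.ndarray]:
    """Plain empirical mode decomposition with a fixed sifting count.

    Returns the list of IMFs, fastest first; the residual is
    ``series - sum(imfs)``.  ``max_imfs`` defaults to ``floor(log2 n) - 1``.
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if max_imfs is None:
        max_imfs = max(1, int(np.floor(np.log2(n))) - 1)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 3:
            break
        imf = _sift_imf(residual, n_sifts)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs


@dataclass
class IMFSet:
    """EEMD decomposition of a 1-D signal plus per-IMF diagnostics."""

    imfs: np.ndarray          # (m, n) ensemble-averaged IMFs, fastest first
    residual: np.ndarray      # input - sum of IMFs
    input_signal: np.ndarray
    fs: float
    noise_ratio: float = 0.1
    n_ensemble: int = 50
    seed: int = 42
    energy_ratios: np.ndarray = field(default=None)  # type: ignore[assignment]
    spearman_etas: np.ndarray = field(default=None)  # type: ignore[assignment]
    degenerate: bool = False  # constant input: no oscillatory content

    @property
    def m(self) -> int:
        return self.imfs.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def eemd(
    series: np.ndarray,
    fs: float,
    noise_ratio: float = 0.1,
    n_ensemble: int = 50,
    seed: int = 42,
    max_imfs: int | None = None,
    n_sifts: int = 10,
) -> IMFSet:
    """Ensemble empirical mode decomposition.

    Each trial adds white noise with ``std = noise_ratio * std(series)``,
    decomposes with :func:`emd`, and IMFs are averaged index-wise across
    the ensemble.  The residual is defined as ``series - sum(IMFs)`` so the
    decomposition is exactly complete by construction.
    """
    x = np.asarray(series, dtype=np.float64)
    n = len(x)
    if n < 64:
        raise ValueError(f"series too short for EEMD: {n} < 64 samples")
    sigma = float(np.std(x))
    if max_imfs is None:
        max_imfs = max(1, int(np.floor(np.log2(n))) - 1)
    if sigma == 0.0:
        logger.warning("constant input to EEMD: returning pure residual")
        return IMFSet(
            imfs=np.zeros((0, n)), residual=x.copy(), input_signal=x, fs=fs,
            noise_ratio=noise_ratio, n_ensemble=n_ensemble, seed=seed,
            degenerate=True,
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros((max_imfs, n))
    for _ in range(n_ensemble):
        noisy = x + rng.normal(0.0, noise_ratio * sigma, size=n)
        trial = emd(noisy, max_imfs=max_imfs, n_sifts=n_sifts)
        for j, imf in enumerate(trial):
            acc[j] += imf
    acc /= n_ensemble
    # drop trailing all-zero rows (IMF orders no trial reached)
    nonzero = np.flatnonzero(np.any(acc != 0.0, axis=1))
    m = int(nonzero[-1]) + 1 if len(nonzero) else 0
    imfs = acc[:m]
    residual = x - imfs.sum(axis=0)
    return IMFSet(
        imfs=imfs, residual=residual, input_signal=x, fs=fs,
        noise_ratio=noise_ratio, n_ensemble=n_ensemble, seed=seed,
    )


# ---------------------------------------------------------------------------
# IMF scoring and selection
# ---------------------------------------------------------------------------

def band_energy_ratio(
    imf: np.ndarray, fs: float, band: tuple[float, float] = FM_BAND_HZ
) -> float:
    """Fraction of spectral energy inside the FM band.

    ``E_f`` sums ``|X(f)|**2`` over ``band[0] <= f <= min(band[1], fs/2)``;
    ``E`` sums over all ``f > 0`` (DC excluded).  An all-zero signal yields
    0 by convention.
    """
    x = np.asarray(imf, dtype=np.float64)
    lo, hi = band
    if lo >= fs / 2:
        raise ValueError(f"band lower edge {lo} must be below Nyquist {fs / 2}")
    hi = min(hi, fs / 2)
    spectrum = np.abs(rfft(x)) ** 2
    freqs = rfftfreq(len(x), d=1.0 / fs)
    total = spectrum[freqs > 0].sum()
    if total == 0.0:
        logger.warning("all-zero signal in band_energy_ratio; ratio set to 0")
        return 0.0
    in_band = spectrum[(freqs >= lo) & (freqs <= hi)].sum()
    return float(in_band / total)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks on ties).

    Returns NaN for constant input — rank correlation is undefined there.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input to spearman: correlation undefined")
        return float("nan")
    rho = spearmanr(x, y).statistic
    return float(rho)


@dataclass
class FMSignal:
    """The IMF selected as the fetal-movement signal."""

    x: np.ndarray
    fs: float
    source_channel: str          # "H" or "S"
    selected_index: int          # 0-based index into the IMFSet
    energy_ratio: float
    spearman_eta: float
    fallback_flag: bool          # no IMF cleared the delta threshold


def select_fm_imf(
    imfs: IMFSet,
    reference: np.ndarray,
    delta: float = 0.6,
    source_channel: str = "S",
    band: tuple[float, float] = FM_BAND_HZ,
) -> FMSignal:
    """Select the FM signal from an EEMD decomposition.

    Every IMF gets a band-energy ratio ``r_j`` and a Spearman correlation
    ``eta_j`` against ``reference`` (the filtered series that was
    decomposed).  Candidates are ``{j : r_j > delta}``; the candidate with
    maximal ``r_j + eta_j`` wins.  With no candidates, the global maximizer
    of ``r_j + eta_j`` is returned with ``fallback_flag`` set.
    """
    if imfs.m == 0:
        raise ValueError("IMFSet is empty: nothing to select")
    reference = np.asarray(reference, dtype=np.float64)
    r = np.array([band_energy_ratio(imf, imfs.fs, band) for imf in imfs.imfs])
    eta = np.array([spearman(imf, reference) for imf in imfs.imfs])
    imfs.energy_ratios = r
    imfs.spearman_etas = eta
    score = r + eta  # NaN eta propagates and removes the IMF from argmax
    candidates = np.flatnonzero(r > delta)
    pool = candidates[~np.isnan(score[candidates])]
    fallback = len(pool) == 0
    if fallback:
        pool = np.flatnonzero(~np.isnan(score))
        if len(pool) == 0:
            raise ValueError("all IMF scores undefined (constant IMFs?)")
    j = int(pool[np.argmax(score[pool])])
    return FMSignal(
        x=imfs.imfs[j].copy(), fs=imfs.fs, source_channel=source_channel,
        selected_index=j, energy_ratio=float(r[j]), spearman_eta=float(eta[j]),
        fallback_flag=fallback,
    )


def extract_fm_signal(
    series: np.ndarray,
    fs: float,
    source_channel: str = "S",
    filter_order: int = 7,
    cutoff_hz: float = 3.0,
    zero_phase: bool = True,
    noise_ratio: float = 0.1,
    n_ensemble: int = 50,
    seed: int = 42,
    delta: float = 0.6,
    n_sifts: int = 10,
) -> tuple[FMSignal, IMFSet]:
    """Full extraction: high-pass → EEMD → IMF selection."""
    spec = FilterSpec(fs=fs, order=filter_order, cutoff_hz=cutoff_hz,
                      zero_phase=zero_phase)
    filtered = highpass(series, spec)
    imfset = eemd(filtered, fs, noise_ratio=noise_ratio,
                  n_ensemble=n_ensemble, seed=seed, n_sifts=n_sifts)
    fm = select_fm_imf(imfset, filtered, delta=delta,
                       source_channel=source_channel)
    return fm, imfset
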