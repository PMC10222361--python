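"""Seeded synthetic data with known fetal-movement ground truth.

Two generators:

* :func:`synth_signal` — the saturation/hue series the flow stage would
  produce: a baseline plus quasi-periodic respiration (0.2–0.5 Hz), sparse
  FM bursts (Gaussian temporal envelope carrying a 3–12.5 Hz oscillation)
  and white noise.
* :func:`synth_video` — an abdominal scene: a skin-toned, textured ellipse
  (wider than tall, so the aspect-ratio rule selects it) over a non-skin
  background; respiration warps the abdomen slowly and each FM event adds
  a localized oscillatory displacement bump.  Frames are written as a
  lossless PNG stack plus ground-truth JSON.

Both emulate a supine subject lying still: no maternal gross movement, no
lighting changes, no camera shake.  All randomness flows from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import map_coordinates

from videofm.abdomen_detect import SkinModel
from videofm.evaluation import Annotation
from videofm.flow_signal import HSTimeSeries

__all__ = ["SynthConfig", "GroundTruth", "synth_signal", "synth_video", "render_frames"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the recording setup the pipeline targets — 25 fps video
    of a still, supine subject — at a reduced frame size.  FM events carry
    oscillations inside the 3–12.5 Hz detection band; respiration sits well
    below the 3 Hz high-pass cutoff.
    """

    duration_s: float = 120.0
    fps: float = 25.0
    frame_size: tuple[int, int] = (180, 320)       # (height, width)

    n_events: int = 5
    event_times_s: list[float] | None = None       # fixed onsets; None = auto
    event_duration_range_s: tuple[float, float] = (1.0, 2.0)
    event_freq_range_hz: tuple[float, float] = (4.0, 8.0)
    event_amplitude_px: float = 1.6                # peak surface displacement
    event_sigma_px: float = 30.0                   # spatial extent of the bump
    well_separated: bool = True
    min_event_gap_s: float = 7.0                   # quiet time between events

    respiration_freq_hz: float = 0.3
    respiration_amplitude_px: float = 1.5

    pixel_noise_sigma: float = 2.0                 # gray levels, per frame
    signal_noise_sigma: float = 0.001              # saturation units

    # signal-mode amplitudes (saturation / hue-degree units); the baseline
    # keeps the series away from the [0, 1] clip under full swing
    s_baseline: float = 0.2
    s_respiration_amplitude: float = 0.03
    s_event_amplitude: float = 0.08
    h_baseline: float = 180.0
    h_respiration_amplitude: float = 10.0
    h_event_amplitude: float = 30.0
    h_noise_sigma: float = 1.0

    ellipse_axes_frac: tuple[float, float] = (0.42, 0.35)  # (a/W, b/H)
    skin_luma: float = 150.0
    texture_sigma: float = 12.0                    # luma texture contrast
    seed: int = 0

    def __post_init__(self) -> None:
        ny = self.fps / 2.0
        lo, hi = self.event_freq_range_hz
        if not (3.0 <= lo <= hi < ny):
            raise ValueError(
                f"event frequencies must lie in [3, fps/2) = [3, {ny}) Hz"
            )
        if not 0.0 < self.respiration_freq_hz < 3.0:
            raise ValueError("respiration frequency must sit below the 3 Hz cutoff")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if self.well_separated and self.n_events > 0 and self.event_times_s is None:
            worst = (self.n_events * self.event_duration_range_s[1]
                     + (self.n_events - 1) * self.min_event_gap_s)
            if worst > self.duration_s - 4.0:
                raise ValueError(
                    f"{self.n_events} well-separated events do not fit in "
                    f"{self.duration_s}s"
                )


@dataclass
class GroundTruth:
    """True event intervals plus the clean signal components."""

    events: list[tuple[float, float]]              # (start_s, end_s)
    clean_fm: np.ndarray | None = None
    clean_respiration: np.ndarray | None = None
    event_freqs_hz: list[float] = field(default_factory=list)

    def to_annotation(self) -> Annotation:
        return Annotation(list(self.events))

    def to_json(self) -> dict:
        return {
            "schema_version": 1,
            "events": [{"start_s": a, "end_s": b} for a, b in self.events],
        }


def _draw_events(cfg: SynthConfig, rng: np.random.Generator):
    """Event (center, duration, frequency) triples honoring separation."""
    durations = rng.uniform(*cfg.event_duration_range_s, size=cfg.n_events)
    freqs = rng.uniform(*cfg.event_freq_range_hz, size=cfg.n_events)
    if cfg.event_times_s is not None:
        centers = np.asarray(cfg.event_times_s, dtype=np.float64)
        if len(centers) != cfg.n_events:
            raise ValueError("event_times_s length must equal n_events")
        return centers, durations, freqs
    if cfg.n_events == 0:
        return np.array([]), durations, freqs
    # one slot per event; jitter within the slot, keeping the required gap
    margin = 2.0
    usable = cfg.duration_s - 2 * margin
    need = float(np.sum(durations)) + (cfg.n_events - 1) * cfg.min_event_gap_s
    if cfg.well_separated and need > usable:
        raise ValueError(
            f"{cfg.n_events} events with gap {cfg.min_event_gap_s}s do not fit "
            f"in {cfg.duration_s}s"
        )
    slot = usable / cfg.n_events
    centers = margin + slot * (np.arange(cfg.n_events) + 0.5)
    jitter_max = max(0.0, (slot - durations.max() - cfg.min_event_gap_s) / 2)
    centers = centers + rng.uniform(-jitter_max, jitter_max, size=cfg.n_events)
    return centers, durations, freqs


def _components(cfg: SynthConfig, rng: np.random.Generator):
    """Time axis, clean respiration (unit), clean FM (unit) and the truth."""
    n = int(round(cfg.duration_s * cfg.fps))
    t = np.arange(n) / cfg.fps
    resp = np.sin(2 * np.pi * cfg.respiration_freq_hz * t)
    centers, durations, freqs = _draw_events(cfg, rng)
    fm = np.zeros(n)
    events = []
    f_ref = float(np.mean(cfg.event_freq_range_hz))
    for c, d, f in zip(centers, durations, freqs):
        sigma = d / 4.0  # +-2 sigma spans the labeled interval
        envelope = np.exp(-0.5 * ((t - c) / sigma) ** 2)
        # saturation encodes surface *speed*, so a fixed displacement
        # produces a burst whose amplitude grows with carrier frequency
        fm += (f / f_ref) * envelope * np.sin(2 * np.pi * f * (t - c))
        events.append((float(c - d / 2), float(c + d / 2)))
    truth = GroundTruth(events=sorted(events), event_freqs_hz=[float(f) for f in freqs])
    return t, resp, fm, truth, (centers, durations, freqs)


def synth_signal(cfg: SynthConfig) -> tuple[HSTimeSeries, GroundTruth]:
    """Generate H and S motion series with known ground truth.

    ``S(t) = baseline + A_r sin(2 pi f_r t) + sum_i A_e g(t; t_i, s_i)
    sin(2 pi f_i t) + noise``; H analogous with independent noise.
    """
    rng = np.random.default_rng(cfg.seed)
    t, resp, fm, truth, _ = _components(cfg, rng)
    s = (
        cfg.s_baseline
        + cfg.s_respiration_amplitude * resp
        + cfg.s_event_amplitude * fm
        + rng.normal(0.0, cfg.signal_noise_sigma, size=len(t))
    )
    h = (
        cfg.h_baseline
        + cfg.h_respiration_amplitude * resp
        + cfg.h_event_amplitude * fm
        + rng.normal(0.0, cfg.h_noise_sigma, size=len(t))
    )
    truth.clean_fm = cfg.s_event_amplitude * fm
    truth.clean_respiration = cfg.s_respiration_amplitude * resp
    series = HSTimeSeries(H=h, S=np.clip(s, 0.0, 1.0), fs=cfg.fps)
    return series, truth


def _base_scene(cfg: SynthConfig, rng: np.random.Generator):
    """Static scene (float RGB) and the abdomen ellipse geometry."""
    h, w = cfg.frame_size
    skin = np.array(SkinModel().center_rgb(cfg.skin_luma), dtype=np.float64)
    background = np.array([60.0, 70.0, 110.0])  # bluish bedsheet, non-skin
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    a = cfg.ellipse_axes_frac[0] * w
    b = cfg.ellipse_axes_frac[1] * h
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    # luma-only texture keeps chroma inside the skin ellipse while giving
    # the flow solver gradients to lock onto
    texture = rng.normal(0.0, cfg.texture_sigma, size=(h, w))
    scene = np.where(inside[..., None], skin, background) + texture[..., None]
    return np.clip(scene, 0.0, 255.0), (cy, cx, a, b), inside


def render_frames(cfg: SynthConfig):
    """Yield synthetic RGB uint8 frames; returns the ground truth up front.

    Returns ``(frame_iterator, ground_truth)``.  Respiration shifts the
    whole abdomen vertically; each FM event displaces a Gaussian patch of
    the abdominal surface with an oscillatory time course.  Frames are made
    by inverse-warping the static scene and adding per-frame pixel noise.
    """
    rng = np.random.default_rng(cfg.seed)
    t, resp, _, truth, (centers, durations, freqs) = _components(cfg, rng)
    scene, (cy, cx, a, b), inside = _base_scene(cfg, np.random.default_rng(cfg.seed + 1))
    h, w = cfg.frame_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # spatial centers of the event bumps, inside the abdomen
    rng_ev = np.random.default_rng(cfg.seed + 2)
    ang = rng_ev.uniform(0, 2 * np.pi, size=len(centers))
    rad = rng_ev.uniform(0, 0.5, size=len(centers))
    ev_x = cx + rad * a * np.cos(ang)
    ev_y = cy + rad * b * np.sin(ang)
    spatial = [
        np.exp(-((xx - ex) ** 2 + (yy - ey) ** 2) / (2 * cfg.event_sigma_px**2))
        for ex, ey in zip(ev_x, ev_y)
    ]
    noise_rng = np.random.default_rng(cfg.seed + 3)

    def frames():
        for i, ti in enumerate(t):
            dy = np.full((h, w), cfg.respiration_amplitude_px * resp[i])
            dy = np.where(inside, dy, 0.0)
            dx = np.zeros((h, w))
            for (c, d, f, sp) in zip(centers, durations, freqs, spatial):
                sigma = d / 4.0
                env = np.exp(-0.5 * ((ti - c) / sigma) ** 2)
                if env < 1e-4:
                    continue
                disp = cfg.event_amplitude_px * env * np.sin(2 * np.pi * f * (ti - c))
                dy += sp * disp
            frame = np.empty((h, w, 3))
            coords = np.stack([yy - dy, xx - dx])
            for ch in range(3):
                frame[..., ch] = map_coordinates(
                    scene[..., ch], coords, order=1, mode="nearest"
                )
            frame += noise_rng.normal(0.0, cfg.pixel_noise_sigma, size=(h, w, 1))
            yield np.clip(frame, 0, 255).astype(np.uint8)

    return frames(), truth


def synth_video(cfg: SynthConfig, out_dir: str | Path) -> tuple[Path, GroundTruth]:
    """Render a synthetic abdominal video to a lossless PNG frame stack.

    Writes ``frame_00000.png ...``, ``meta.json`` (fps) and
    ``ground_truth.json`` (Annotation schema) under ``out_dir``; returns
    the directory path and the ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame_iter, truth = render_frames(cfg)
    for i, frame in enumerate(frame_iter):
        iio.imwrite(out_dir / f"frame_{i:05d}.png", frame)
    with open(out_dir / "meta.json", "w") as fh:
        json.dump({"schema_version": 1, "fps": cfg.fps}, fh)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return out_dir, truth
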