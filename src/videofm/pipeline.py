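"""End-to-end orchestration: video → FM events → parameters → evaluation.

Each contiguous segment is processed independently (abdomen masks → H/S
series → FM extraction → spikes); spike times are then placed on the
original video's absolute time axis and merged into events across the
whole recording.  The analyzed time used for the rate/percentage
denominators is the total duration of the segments actually processed —
manually excluded frames never count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from videofm import video_io
from videofm.abdomen_detect import SkinModel, detect_abdomen
from videofm.config import PipelineConfig
from videofm.evaluation import (
    Annotation,
    BlandAltmanResult,
    MetricsReport,
    bland_altman,
    match_events,
    metrics,
)
from videofm.flow_signal import FlowParams, HSTimeSeries, build_series
from videofm.fm_events import FMEvent, FMParameters, fm_parameters, merge_spikes
from videofm.fm_extract import FMSignal, extract_fm_signal
from videofm.spike_detect import SpikeTrain, detect_spikes
from videofm.video_io import FrameSequence, Segment

logger = logging.getLogger(__name__)

__all__ = ["ChannelResult", "RunReport", "run_detect", "run_signal", "run_eval"]


@dataclass
class ChannelResult:
    """Detection outcome for one motion channel (H or S)."""

    channel: str
    fm_signals: list[FMSignal]        # one per segment
    spikes: SpikeTrain                # absolute frame indices
    events: list[FMEvent]             # absolute seconds
    parameters: FMParameters


@dataclass
class RunReport:
    """Full result of a detection run (both channels)."""

    channels: dict[str, ChannelResult]
    series: list[HSTimeSeries]
    analyzed_time_s: float
    fps: float
    config_hash: str
    version: str = ""
    default_channel: str = "S"

    @property
    def result(self) -> ChannelResult:
        return self.channels[self.default_channel]

    def events_json(self, channel: str | None = None) -> dict:
        ch = self.channels[channel or self.default_channel]
        return {
            "schema_version": 1,
            "channel": ch.channel,
            "analyzed_time_s": self.analyzed_time_s,
            "events": [
                {"start_s": e.start_s, "end_s": e.end_s, "n_spikes": e.n_spikes}
                for e in ch.events
            ],
        }

    def parameters_json(self, channel: str | None = None) -> dict:
        p = self.channels[channel or self.default_channel].parameters
        return {
            "schema_version": 1,
            "number_per_hour": p.number_per_hour,
            "intervals_s": p.intervals_s,
            "durations_s": p.durations_s,
            "percentage": p.percentage,
            "analyzed_time_s": p.analyzed_time_s,
        }

    def write(self, out_dir: str | Path, config: PipelineConfig) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.channels:
            with open(out / f"events_{name}.json", "w") as fh:
                json.dump(self.events_json(name), fh, indent=1, sort_keys=True)
            with open(out / f"parameters_{name}.json", "w") as fh:
                json.dump(self.parameters_json(name), fh, indent=1, sort_keys=True)
        config.to_yaml(out / "resolved_config.yaml")


def _segment_masks(seq: FrameSequence, positions: np.ndarray, cfg: PipelineConfig):
    model = SkinModel(**cfg.abdomen.skin_model.model_dump())
    masks = []
    locked = None
    for pos in positions:
        if cfg.abdomen.lock_region and locked is not None:
            masks.append(locked)
            continue
        m = detect_abdomen(
            seq.frames[pos], model, opening_radius_px=cfg.abdomen.opening_radius_px
        )
        if cfg.abdomen.lock_region:
            locked = m
        masks.append(m)
    return masks


def _channel_pipeline(
    channel: str,
    series_list: list[HSTimeSeries],
    segments: list[Segment],
    analyzed_time_s: float,
    fps: float,
    cfg: PipelineConfig,
) -> ChannelResult:
    """FM extraction, spike detection and event merging for one channel."""
    fm_signals: list[FMSignal] = []
    global_spikes: list[int] = []
    th1 = th2 = float("nan")
    for series, segment in zip(series_list, segments):
        data = series.H if channel == "H" else series.S
        fm, _ = extract_fm_signal(
            data,
            fs=series.fs,
            source_channel=channel,
            filter_order=cfg.filter.order,
            cutoff_hz=cfg.filter.cutoff_hz,
            zero_phase=cfg.filter.zero_phase,
            noise_ratio=cfg.eemd.noise_ratio,
            n_ensemble=cfg.eemd.n_ensemble,
            seed=cfg.eemd.seed,
            delta=cfg.selection.delta,
            n_sifts=cfg.eemd.max_sift,
        )
        fm_signals.append(fm)
        train = detect_spikes(
            fm.x, a=cfg.spike.a, fs=series.fs,
            compare_on=cfg.spike.compare_on, normalize=cfg.spike.normalize,
            min_crest=cfg.spike.min_crest,
        )
        th1, th2 = train.th1, train.th2
        # sample n of the series maps to frame pair k_indices[n] within the
        # segment; absolute frame index anchors the spike on the video clock
        abs_idx = segment.start_index + series.k_indices[train.spike_indices]
        global_spikes.extend(int(i) for i in abs_idx)
    combined = SpikeTrain(
        spike_indices=np.asarray(sorted(global_spikes), dtype=np.int64),
        fs=fps, th1=th1, th2=th2, a=cfg.spike.a,
    )
    events = merge_spikes(combined, gap_s=cfg.events.gap_s)
    params = fm_parameters(
        events, analyzed_time_s, interval_mode=cfg.events.interval_mode
    )
    return ChannelResult(
        channel=channel, fm_signals=fm_signals, spikes=combined,
        events=events, parameters=params,
    )


def run_signal(
    series_list: list[HSTimeSeries] | HSTimeSeries,
    config: PipelineConfig | None = None,
    segments: list[Segment] | None = None,
    channels: tuple[str, ...] = ("H", "S"),
) -> RunReport:
    """Signal-only pipeline: precomputed H/S series → events and parameters.

    Accepts one series or a list (one per contiguous segment); without
    explicit ``segments`` each series is assumed to start at its own
    ``k_indices`` origin on a common clock.
    """
    cfg = config or PipelineConfig()
    if isinstance(series_list, HSTimeSeries):
        series_list = [series_list]
    if not series_list:
        raise ValueError("no series to process")
    fps = series_list[0].fs
    if segments is None:
        segments = []
        t0 = 0
        for s in series_list:
            n = int(s.k_indices[-1]) + 2  # pairs + closing frame
            segments.append(Segment(t0, t0 + n, fps))
            t0 += n
    analyzed = sum(seg.duration_s for seg in segments)
    channels_out = {
        ch: _channel_pipeline(ch, series_list, segments, analyzed, fps, cfg)
        for ch in channels
    }
    return RunReport(
        channels=channels_out, series=list(series_list),
        analyzed_time_s=analyzed, fps=fps, config_hash=cfg.hash(),
    )


def run_detect(
    video_path: str | Path,
    exclusions=None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    channels: tuple[str, ...] = ("H", "S"),
) -> RunReport:
    """Full pipeline on a video file or frame-stack directory."""
    cfg = config or PipelineConfig()
    if isinstance(exclusions, (str, Path)):
        exclusions = video_io.load_exclusions(exclusions)
    seq = video_io.load_video(video_path, exclusions, fps=cfg.video.fps)
    segments = video_io.contiguous_segments(seq, min_len_s=cfg.video.min_segment_s)
    if not segments:
        raise ValueError("no contiguous segment long enough to analyze")
    flow_params = FlowParams(
        radius=cfg.flow.radius, num_warp=cfg.flow.num_warp, m_norm=cfg.flow.m_norm
    )
    series_list, kept_segments = [], []
    for sid, segment in enumerate(segments):
        positions = video_io.segment_positions(seq, segment)
        masks = _segment_masks(seq, positions, cfg)
        frames = [seq.frames[p] for p in positions]
        series = build_series(
            frames, masks, seq.fps, flow_params, segment_id=sid,
            max_missing_frac=cfg.flow.max_missing_frac,
        )
        if series is None:
            logger.warning("segment %d rejected; skipping", sid)
            continue
        series_list.append(series)
        kept_segments.append(segment)
    if not series_list:
        raise ValueError("every segment was rejected")
    report = run_signal(series_list, cfg, segments=kept_segments, channels=channels)
    if out_dir is not None:
        report.write(out_dir, cfg)
    return report


def run_eval(
    events: list[FMEvent],
    annotation: Annotation,
    config: PipelineConfig | None = None,
) -> MetricsReport:
    """Event-level metrics of detections against a gold-standard annotation."""
    cfg = config or PipelineConfig()
    counts = match_events(events, annotation, pad_s=cfg.evaluation.overlap_pad_s)
    return metrics(counts, tme=annotation.tme)


def eval_parameters_agreement(
    detected: list[FMParameters], labeled: list[FMParameters]
) -> dict[str, BlandAltmanResult]:
    """Bland–Altman agreement of each FM parameter across recordings."""
    if len(detected) != len(labeled) or len(detected) < 2:
        raise ValueError("need the same (>= 2) number of recordings per method")

    def col(ps: list[FMParameters], attr: str) -> np.ndarray:
        if attr in ("intervals_s", "durations_s"):
            return np.array([float(np.mean(getattr(p, attr) or [0.0])) for p in ps])
        return np.array([getattr(p, attr) for p in ps])

    out = {}
    for name in ("number_per_hour", "intervals_s", "durations_s", "percentage"):
        out[name] = bland_altman(col(detected, name), col(labeled, name))
    return out
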