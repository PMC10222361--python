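"""Pipeline configuration: one validated schema for every stage.

Defaults are the method's published operating point: 7th-order 3 Hz
high-pass, EEMD noise ratio 0.1 with 50 ensemble trials, energy-ratio
threshold delta = 0.6, spike coefficient a = 0.03 (midpoint of the
0.01–0.05 range), 6-s event merging.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VideoConfig(_Strict):
    fps: float | None = None          # override container metadata
    min_segment_s: float = 10.0       # drop shorter contiguous runs


class SkinModelConfig(_Strict):
    cx: float = 109.38
    cy: float = 152.02
    a: float = 25.39
    b: float = 14.03
    theta: float = 2.53


class AbdomenConfig(_Strict):
    skin_model: SkinModelConfig = SkinModelConfig()
    opening_radius_px: int = 5        # at 1280-px reference width, scaled
    lock_region: bool = False         # detect once on the first frame


class FlowConfig(_Strict):
    radius: int = 7
    num_warp: int = 2
    m_norm: float = 5.0               # saturation normalization, px/frame
    max_missing_frac: float = 0.10


class FilterConfig(_Strict):
    order: int = 7
    cutoff_hz: float = 3.0
    zero_phase: bool = True


class EEMDConfig(_Strict):
    noise_ratio: float = 0.1
    n_ensemble: int = 50
    seed: int = 42
    max_sift: int = 10


class SelectionConfig(_Strict):
    delta: float = 0.6
    band_hz: tuple[float, float] = (3.0, 20.0)


class SpikeConfig(_Strict):
    a: float = Field(default=0.03)
    compare_on: str = "signal"        # "signal" (literal) or "y3"
    normalize: bool = True            # unit-peak scaling before thresholding
    min_crest: float = 8.0            # no-FM guard: peak / robust background


class EventsConfig(_Strict):
    gap_s: float = 6.0
    interval_mode: str = "end_to_start"


class EvalConfig(_Strict):
    overlap_pad_s: float = 0.0


class PipelineConfig(_Strict):
    """Resolved configuration of a full pipeline run."""

    schema_version: int = 1
    video: VideoConfig = VideoConfig()
    abdomen: AbdomenConfig = AbdomenConfig()
    flow: FlowConfig = FlowConfig()
    filter: FilterConfig = FilterConfig()
    eemd: EEMDConfig = EEMDConfig()
    selection: SelectionConfig = SelectionConfig()
    spike: SpikeConfig = SpikeConfig()
    events: EventsConfig = EventsConfig()
    evaluation: EvalConfig = EvalConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
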