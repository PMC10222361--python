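import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from videofm.synthetic import SynthConfig, render_frames, synth_signal

FS = 25.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random texture: a well-conditioned target for the flow solver."""
    rng = np.random.default_rng(0)
    base = gaussian_filter(rng.random((120, 160)) * 255.0, 2.0)
    return np.stack([base] * 3, axis=-1).astype(np.uint8)


@pytest.fixture(scope="session")
def small_signal():
    """60-s synthetic S/H series with 3 well-separated FM events."""
    cfg = SynthConfig(duration_s=60.0, n_events=3, seed=1)
    series, truth = synth_signal(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def small_clip():
    """16-s rendered clip (2 events) shared by the video-stage tests."""
    cfg = SynthConfig(duration_s=16.0, n_events=2, seed=2, min_event_gap_s=6.5)
    frames_iter, truth = render_frames(cfg)
    return cfg, list(frames_iter), truth
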