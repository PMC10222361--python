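"""Signal-only FM detection on a synthetic saturation/hue series.

Generates 90 s of motion series with five known fetal-movement events,
runs extraction (high-pass -> EEMD -> IMF selection), spike detection and
6-s event merging, then scores the result against the ground truth.
"""

import videofm

cfg = videofm.SynthConfig(duration_s=90.0, n_events=5, seed=42)
series, truth = videofm.synth_signal(cfg)
report = videofm.run_signal(series, channels=("S",))

res = report.result
print(f"analyzed time: {report.analyzed_time_s:.1f} s")
print(f"selected IMF index: {res.fm_signals[0].selected_index}, "
      f"band-energy ratio {res.fm_signals[0].energy_ratio:.3f}, "
      f"Spearman eta {res.fm_signals[0].spearman_eta:.3f}")
print("detected events (s):",
      [(round(e.start_s, 2), round(e.end_s, 2)) for e in res.events])
print("true events (s):    ",
      [(round(a, 2), round(b, 2)) for a, b in truth.events])

p = res.parameters
print(f"FM number: {p.number_per_hour:.1f}/h | mean duration "
      f"{sum(p.durations_s) / len(p.durations_s):.2f} s | "
      f"percentage {p.percentage:.2f}%")

metrics = videofm.run_eval(res.events, truth.to_annotation())
print("event-level metrics (%):",
      {k: round(v, 2) for k, v in metrics.as_dict().items()})
# TDR/SEN: share of true events found; PPV: share of detections that are
# real; F1: harmonic mean of PPV and SEN. 100 everywhere = exact recovery.
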