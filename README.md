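# videofm — non-contact fetal-movement monitoring from abdominal video

Fetal movement (FM) is a basic indicator of fetal health: both reduced and
excessive movement are risk factors for adverse outcomes, but maternal
counting is unreliable, ultrasound needs a clinician, and wearable sensors
require skin contact and careful strap tension.  `videofm` implements a
fully non-contact alternative: an ordinary camera films the maternal
abdomen, and transient surface deflections caused by fetal kicks and
stretches are detected, merged into movement events, and summarized as the
clinical FM parameters (number/hour, interval, duration, percentage).

The package is a library first (import `videofm`), with short narrative
scripts under `examples/` and a thin `videofm` command-line interface for
shell use.

## Method

For each video frame the maternal abdomen is located by elliptical
skin-chroma segmentation, morphological opening, and an aspect-ratio rule
over 8-connected components.  Dense optical flow between consecutive
frames is coded in HSL — hue H for motion direction, saturation
S = min(|v|/m_norm, 1) for magnitude — and averaged over the abdominal
region:

    R(k) = (1/N) Σᵢ θᵢ,

one H and one S sample per frame pair.  Each series is high-pass filtered
(7th-order Butterworth, 3 Hz cutoff; FM energy occupies 3–20 Hz, clipped at
the 12.5 Hz Nyquist limit of 25-fps video) and decomposed by ensemble
empirical mode decomposition (noise ratio 0.1, ensemble 50).  Each
intrinsic mode function IMFⱼ is scored by its FM-band energy ratio
E_f(j)/E(j) and Spearman correlation ηⱼ with the filtered series; among
IMFs with E_f/E > δ = 0.6, the maximizer of (E_f/E + η) is the FM signal
x(n).

FM spikes are recognized by the differential-threshold rule: with
y1(n) = x(n+1) − x(n) and y2(n) = x(n+2) − 2x(n+1) + x(n),

    Th1 = mean of the local minima of y2,
    y3(n) = y1_max·y1(n) + y2_max·y2(n),   Th2 = a·y3_max   (a = 0.03),

and a spike is declared where x(n) > Th1 and x(n) > Th2 (the signal is
normalized to unit peak first; see `docs/methods.md`).  Spikes closer than
6 s merge into one FM event, from which the four FM parameters follow.
Detections are scored against gold-standard labels by interval overlap —
TDR, PPV, SEN, ACC = TP/(TP+FP+FN), and F1 — and parameter agreement
between methods uses Bland–Altman limits (mean ± 1.96 SD of differences).

Because real abdominal recordings cannot be shipped, the package includes a
seeded synthetic generator (`videofm.synthetic`) that renders skin-toned
abdominal video with respiration warp and localized oscillatory FM
displacement events — plus a direct signal-level generator — with ground
truth in the annotation schema, so every stage is testable offline.

## Worked example

```
python examples/01_signal_pipeline.py
```

prints (90-s synthetic series, five FM events, seed 42):

```
analyzed time: 90.0 s
selected IMF index: 0, band-energy ratio 0.988, Spearman eta 0.937
detected events (s): [(8.8, 10.32), (30.84, 31.96), (45.4, 46.92), (64.28, 65.4), (78.6, 79.32)]
true events (s):     [(8.64, 10.41), (30.64, 32.08), (45.27, 47.13), (64.04, 65.74), (78.38, 79.48)]
FM number: 199.9/h | mean duration 1.20 s | percentage 6.66%
event-level metrics (%): {'TDR': 100.0, 'PPV': 100.0, 'SEN': 100.0, 'ACC': 100.0, 'F1': 100.0}
```

The first IMF of the decomposition carries 98.8 % of its energy in the FM
band and correlates strongly with the filtered series, so it is selected
as the FM signal; all five ground-truth events are recovered with onsets
within a fraction of a second, so every event-level metric is 100 %.  The
FM parameters read: ~200 movements/hour (five events in 90 s), mean event
duration 1.2 s, and movement occupying 6.7 % of the analyzed time.

Other examples: `02_video_pipeline.py` (full rendered-video chain),
`03_imf_selection.py` (EEMD diagnostics), `04_agreement_analysis.py`
(Bland–Altman across recordings).  From the shell:

```
videofm synth --out vid/ --n-events 3 --duration-s 40
videofm detect --video vid/ --out results/
videofm eval --events results/events_S.json --annotations vid/ground_truth.json
```

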