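# Methods

`videofm` implements a non-contact fetal-movement (FM) monitor: a camera
films the maternal abdomen, and transient surface deflections caused by
fetal kicks, stretches and general movements are detected and summarized as
clinical FM parameters.  This note documents the model, the tunable
parameters, the numerical choices, and what the synthetic test bed does and
does not establish.

## Pipeline model

**Abdomen detection.**  Skin pixels are classified in YCbCr chroma space by
an elliptical boundary model: a pixel is skin iff its (Cb, Cr) coordinates,
shifted to the ellipse center and rotated by the ellipse tilt, satisfy
`(x/a)² + (y/b)² ≤ 1`.  The default ellipse (center (109.38, 152.02),
semi-axes (25.39, 14.03), tilt 2.53 rad) follows the classical elliptical
skin-chroma boundary; skin chroma is lighting-dependent, so every parameter
is exposed in the config.  The binary mask is cleaned by a morphological
opening (disk, 5 px at a 1280-px frame width, scaled proportionally),
8-connected components are labeled, candidates with bounding-box
width/height > 1 are kept (a supine abdomen is wider than tall), and the
largest candidate by pixel area becomes the abdominal mask.  Detection is
per frame by default; a `lock_region` mode detects once and reuses the mask.

**Motion signal.**  Dense optical flow between consecutive frames is
estimated with the iterative Lucas–Kanade solver of scikit-image
(deterministic; window radius 7, two warp iterations).  Each motion vector
is coded in HSL: hue = direction angle (degrees, counterclockwise from +x
with y down, so downward motion maps to 270°), saturation =
`min(|v|/m_norm, 1)` with a *fixed* normalization `m_norm = 5 px/frame`
(per-frame normalization would erase amplitude information over time).
Averaging hue and saturation over the abdominal mask of the earlier frame
gives one H and one S sample per frame pair — two motion time series at the
video frame rate.  Hue is averaged arithmetically, not circularly, matching
the channel-averaging definition of the signals; a circular mean is
available behind a flag.

**FM extraction.**  FM energy lies in the 3–20 Hz band; at 25 fps the band
is clipped at the 12.5 Hz Nyquist limit.  Each series is high-pass filtered
(7th-order Butterworth, 3 Hz cutoff) to remove respiration (~0.2–0.5 Hz)
and other slow background.  Filtering is applied forward–backward (zero
phase) so that spike timing survives for event matching; this doubles the
stopband attenuation, which is documented behavior.  The filtered series is
decomposed by ensemble empirical mode decomposition (EEMD): 50 trials, each
adding white noise with standard deviation 0.1 × std(signal), plain EMD
sifting per trial, index-wise averaging of the intrinsic mode functions
(IMFs) across trials.  The residual is defined as `input − Σ IMFs`, so the
decomposition is complete by construction.  Each IMF j is scored by its
band-energy ratio `r_j = E_f(j)/E(j)` (fraction of FFT energy in
3–12.5 Hz, DC excluded) and its Spearman rank correlation `η_j` with the
filtered series.  IMFs with `r_j > δ = 0.6` are candidates; the candidate
maximizing `r_j + η_j` is the FM signal.  If no IMF clears δ the global
maximizer is used with a `fallback_flag`.

**Spike detection.**  From the FM signal x(n), first and second differences
`y1(n) = x(n+1) − x(n)` and `y2(n) = x(n+2) − 2x(n+1) + x(n)` are formed.
`Th1` is the mean of the strict local minima of y2; `Th2 = a·max(y3)` with
`y3(n) = max(y1)·y1(n) + max(y2)·y2(n)` and a = 0.03 (midpoint of the
admissible 0.01–0.05 range).  A sample is an FM spike iff `x(n) > Th1` and
`x(n) > Th2`.  Two implementation choices matter here:

* *Unit-peak normalization (default on).*  Th2 is quadratic in the signal
  scale while x is linear, so the inequalities only behave as intended for
  unit-order amplitudes; region-averaged saturation signals are two orders
  of magnitude smaller.  The signal is therefore divided by its peak
  absolute amplitude before thresholding.  The Th1 comparison is
  scale-equivariant, so this equals the literal rule evaluated at the
  amplitude scale the rule assumes, and makes detection invariant under
  positive rescaling.
* *Crest-factor guard (default 8).*  Both thresholds are relative to the
  signal's own maxima, so a recording containing no movement at all would
  still yield "spikes" at its noise maxima.  If the peak amplitude is below
  8 × the robust background level (1.4826 × median absolute deviation), the
  signal is declared movement-free.  Gaussian noise has a crest factor
  around 3.5–4.5 at these record lengths; real FM bursts sit far above it.
  Set `spike.min_crest: 0` to disable.

An alternative comparison mode (`spike.compare_on: y3`) tests `y3(n) > Th2`
instead of `x(n) > Th2`; the signal-amplitude comparison is the default.

**Events and parameters.**  Spikes closer than 6 s merge into one FM event
(strictly less than 6 s merges; exactly 6 s splits).  An event spans its
first to last spike; a single-spike event lasts one sample period (1/fps) —
a spike occupies at least one sample.  The four FM parameters are: number
of events per hour; interval (end of one event to start of the next, the
elapsed quiet time — an onset-to-onset mode is available); duration of each
event; and percentage (total event time over analyzed time).  The analyzed
time is the summed duration of the contiguous segments actually processed;
manually excluded frames never enter a denominator.  Segments are analyzed
independently — series are never concatenated across exclusion gaps, which
would fabricate motion spikes at the seams — but spike times are placed on
the original video clock before merging, so an FM interrupted by a short
exclusion is still one event.

**Evaluation.**  A labeled interval is a true positive when at least one
detected event overlaps it (closed intervals; each label judged
independently, so one detection may validate several labels); detections
overlapping no label are false positives.  Metrics, in percent: TDR =
TP/TME, PPV = TP/(TP+FP), SEN = TP/(TP+FN), ACC = TP/(TP+FP+FN), F1 =
harmonic mean of PPV and SEN.  TDR equals SEN by construction because
TP + FN = TME.  A true-negative count is undefined for event-level
detection; ACC therefore uses TP/(TP+FP+FN), the only reading consistent
with the other metrics (it reproduces, from PPV/SEN alone, the ACC values
this operating point implies via `1/acc = 1/ppv + 1/sen − 1`).  Agreement
of FM parameters between two raters or methods uses Bland–Altman analysis:
per-pair differences, their mean, and mean ± 1.96 × sample SD limits.

## Synthetic test bed

The study conditions are fixed by the generator defaults: 25 fps, 120 s
recordings, five (tests: two to six) FM events of 1–2 s duration carrying
4–8 Hz oscillations, separated by at least 7 s of quiet; respiration at
0.3 Hz; a skin-toned textured ellipse (wider than tall, chroma at the skin
ellipse center by construction) on a non-skin background at 320×180.

* **Video path** (`synth_video`): respiration is a slow vertical warp of
  the abdomen; each FM event displaces a Gaussian patch (σ = 30 px) of the
  surface with amplitude 1.6 px and an oscillatory time course, chosen so
  the peak optical-flow magnitude is ≈ 0.4 × m_norm — inside the linear
  range of the saturation coding.  Per-frame Gaussian pixel noise (σ = 2
  gray levels) is added, and frames are written as a lossless PNG stack
  with ground-truth JSON.
* **Signal path** (`synth_signal`): the saturation series is modeled
  directly as baseline 0.2 + 0.03·sin(2π·0.3t) + bursts + white noise
  (σ = 0.001 saturation units).  The burst amplitude (0.08) scales with
  carrier frequency, since saturation encodes surface *speed*; the noise
  default matches the in-band quiet-zone noise floor measured on the video
  path, where averaging over ~26 000 abdomen pixels crushes pixel noise.
  The baseline keeps the series clear of the [0, 1] clip under full swing.

What the generators deliberately omit: maternal gross movement (the method
assumes a still, supine subject; excluded frames are the user's
responsibility), lighting changes, camera shake, photorealistic skin, and
fetal biomechanics.  Passing tests therefore demonstrate the signal-chain
logic — detection, coding, decomposition, selection, thresholding, merging,
scoring — under the stated motion model, not clinical performance on real
recordings.

## Numerical choices

* EMD sifting uses cubic-spline envelopes through strict local extrema,
  mirror-extended past both signal ends; a fixed 10 sifting iterations per
  IMF (determinism over adaptive stop criteria); at most ⌊log₂ n⌋ − 1 IMFs.
  EEMD trials that produce fewer IMFs contribute zeros to the higher
  orders.  All ensemble noise flows from one seed (default 42).
* Fixed seeds make EEMD bit-for-bit reproducible; changing the seed moves
  IMFs by less than the ensemble noise floor (~0.1/√50 ≈ 0.014 × std,
  tested at ≤ 0.05 × std).
* Spearman correlation is undefined for constant inputs and reported as
  NaN; IMFs with undefined correlation drop out of the selection argmax.
* The flow solver registers the later frame onto the earlier one, so the
  returned field is forward motion; the mask of the earlier frame defines
  the averaging region for a frame pair.
* Pairs with an empty abdominal mask are dropped; a segment with more than
  10 % of its pairs missing is rejected with a warning.
* Frame indexing is 0-based, segments are half-open `[start, end)`
  intervals, and the exclusion list is taken as exact.
* `fps` from the config overrides container metadata, with a warning when
  they disagree.

## Problem sizes

The shipped tests and the acceptance script run the full video pipeline on
120 s of 320×180 @ 25 fps synthetic video (3 000 frames) with six FM
events, the signal-only pipeline on 60–120 s series, EEMD contracts on 30-s
series, and 1 000-trial randomized oracles for the selection rule — sizes
at which every stage's behavior is measurable in minutes on one CPU.

## Known limitations

* The differential-threshold detector keys on amplitude contrast: events
  whose peaks are within ~a × max(y3) of the background (roughly, noise
  tails above ~5 % of the strongest burst) cannot be separated, whatever
  the crest guard does.  Very weak FM is therefore missed before it is
  mis-segmented.
* Arithmetic averaging of hue is non-circular; motions whose directions
  straddle the 0°/360° wrap average incorrectly.  The saturation channel —
  the default reporting channel, and the stronger performer — is unaffected.
* MP4/AVI decoding depends on the codecs available to imageio at run time;
  the lossless image-stack directory format is the fully supported input
  and the one the synthetic generator emits.
* Automatic rejection of maternal motion is out of scope; the exclusion
  list is trusted as given.
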