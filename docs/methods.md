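# Methods

This note documents the models, estimators and numerical conventions
behind `confinequant`, the choices that were genuinely open, and what the
synthetic benchmarks do and do not demonstrate about real microscope data.

## The measurement problem

Cells migrating through confining channels or tissue clefts are imaged as
multichannel 2-D time lapses (typical calibration here: 0.65 µm/px,
108 s/frame). Three reporter readouts carry the biology:

1. an NLS-tagged fluorophore whose nuclear/cytoplasmic (N/C) mean-intensity
   ratio collapses abruptly when the nuclear envelope (NE) ruptures and
   recovers as import resumes after repair;
2. a tagged anillin whose distribution among nucleus, diffuse cytoplasm and
   plasma membrane shifts under confinement, forming anillin-rich cell
   edges (ACEs) at the poles;
3. optionally pMLC or actin stains quantified as pole-to-cytoplasm ratios.

All classifiers operate on background-subtracted intensities. Ratios are
offset-sensitive — adding a camera offset pulls every ratio toward 1 — so
`subtract_background` (median of a designated ROI, or the known camera
offset) must precede classification; the pipeline does this with the
configured offset.

## Event calling from N/C traces

A rupture is called at frame *f* when

* ratio(f) ≤ (1 − d) · baseline, with d the drop fraction (default 0.3)
  and the baseline a running median of the pre-event ratio (window
  5 frames), and
* the nuclear mean decreased and the cytoplasmic mean increased at *f*
  (the co-directionality requirement distinguishes rupture from
  photobleaching or focus loss, which move both channels together).

After a rupture the caller tracks the trough and declares repair once the
ratio recovers above baseline − r · (baseline − trough) (recovery fraction
r, default 0.5). The repair **event** is timestamped at the recovery onset
— the last frame at the trough — not at the detection frame: detection
necessarily lags the true repair by however long the recovery takes to
cross the confirmation threshold, whereas the onset frame coincides with
the true repair under noise-free kinetics. Consecutive events are at least
`min_separation_frames` (default 2) apart, and the state machine cannot
emit two ruptures without an intervening repair.

The magnitude of an "abrupt" N/C drop is not standardised anywhere; the
default d = 0.3 was chosen as a round value comfortably below the leak
fractions the generator renders (0.4–0.9) and is exposed, with the other
two knobs, in the analysis configuration. On simulated traces the default
caller reaches F1 = 1.0 with timing error ≤ 1 frame up to 5 % relative
noise per channel; at 10 % noise false positives appear (F1 ≈ 0.7) — at
that noise level a smaller d is counterproductive and pre-smoothing would
trade timing accuracy for robustness, so the degradation is reported
rather than hidden.

Traces whose segmented nucleus area collapses below 50 % of its median for
≥ 2 consecutive frames are QC-flagged (`qc_nucleus_occlusion`) as an
automated proxy for nuclei obstructed by debris, and excluded from event
calling.

## ACE detection

`detect_ace` scores a membrane linescan (positions in µm, intensities
averaged across a 4-px-wide perpendicular window by default) against a
cytoplasmic reference intensity. A maximal contiguous run of samples
qualifies when **every** sample is at or above `ratio_threshold` × reference
(default 2.0) and the run spans at least `min_length_um` (default 5.0).
Both thresholds are inclusive, exactly as printed in the criteria they
implement. Conventions fixed so the boundaries are unambiguous at any
sampling density:

* run length = last-qualifying − first-qualifying sample position + one
  sampling step (half-open convention), so a segment rendered on
  [a, a + L) measures exactly L at any step;
* no gap bridging: a single sub-threshold sample splits a run (strict
  reading of "contiguous membrane region", and it keeps the brute-force
  oracle trivially correct);
* whether the 2× criterion applies pointwise or to the segment mean is
  ambiguous in the field; pointwise is the default, a mean-based variant
  (`statistic="mean"`, union of all qualifying windows) is available but
  not used by the benchmarks.

The "surrounding cytoplasmic region" is taken as the cytoplasm within
3 µm of the membrane band (configurable radius), excluding band and
nucleus. Membrane positivity over time applies the same rule to the
time-averaged profile against the time-averaged reference. For z-stacks,
the plane with the strongest membrane-band anillin mean is selected
(`select_z_plane`). The movie-level pipeline uses a region variant of the
same rule (connected components of qualifying band pixels, length
estimated as component area / band thickness) because a contour linescan
adds an interpolation layer without changing the decision rule.

## Morphometry

Area is pixel count × pixel size²; axes come from the eigenvalues of the
second central moments with the ellipse convention (4·√λ), so a filled
ellipse recovers its own axes; circularity is 4πA/P². The perimeter
estimator is the deciding choice: pixel-edge counting and raw iso-contour
tracing both overestimate P on digitised discs (contour-length circularity
≈ 0.89 at r = 50 px), so the Crofton 4-direction estimator is used
instead — it converges to the true perimeter for smooth convex shapes
(circularity 0.992 at r = 50 px, monotone in radius) and is exactly
invariant under 90° rotations. Circularity values are therefore comparable
across tools only when the estimator is stated; this package states it.

Nuclear segmentation is deliberately classical: Gaussian smoothing
(σ = 1 px), multi-Otsu thresholding keeping the brightest of three classes
(falling back to plain Otsu for low-complexity images), hole filling and
removal of objects under 10 µm² — with every knob in
`SegmentationParams`. Border-touching objects are flagged, not dropped.
Maximum-intensity z-projection before morphometry is the expected
preprocessing for stacks; single-plane analysis works unchanged.

## The synthetic generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

**Geometry.** The cell is a stadium-shaped capsule (default 40 µm long,
15 µm wide clipped to the channel opening) translating at constant speed
(default 0.5 µm/min) along a straight channel (default 10 × 3 µm² cross
section); the nucleus is an ellipse (default 14 × 7 µm) whose short axis is
clamped to the channel opening minus the membrane band. The shape is
rasterised once and translated by whole pixels per frame: exact translation
keeps compartment pixel areas constant, so region means depend only on the
scheduled kinetics and never on discretisation jitter (with sub-pixel
re-rasterisation the "no events ⇒ constant ratio" identity would hold only
approximately).

**NLS kinetics.** Reporter "mass" (summed intensity) is conserved: at a
rupture a fraction `leak_fraction` (default 0.6) of the nuclear mass moves
instantaneously to the cytoplasm; after repair the nuclear mass relaxes
back exponentially with `recovery_halftime_s` (default 300 s, a plausible
re-import timescale for an NLS reporter). A step plus exponential is the
simplest two-parameter model consistent with an abrupt drop and a gradual
recovery; the true leak magnitude and kinetics are not known, so tests
sweep these parameters rather than fix them.

**Anillin.** Total anillin mass is partitioned nuclear/cytoplasmic/membrane
(default 0.7/0.2/0.1). A scheduled ACE sets the pole arc of the membrane
band to `enrichment_ratio` × the cytoplasmic mean, with the transferred
mass debited from the cytoplasm (solved self-consistently so total mass is
conserved). After the first rupture plus a configurable lag (default
300 s; delays up to tens of minutes occur in real cells), a fraction
(default 0.5) of nuclear anillin moves to the cytoplasm — the
`anillin_nuclear_exit` ground-truth event.

**Noise.** Per pixel: Poisson shot noise at `poisson_scale` (default 0.5
counts per intensity unit), additive Gaussian read noise (default σ = 2),
constant camera offset (default 100), clipped at zero. Random numbers are
drawn in a fixed documented order (one Poisson pass, one Gaussian pass)
from `numpy.random.default_rng(seed)`, so identical (config, seed) pairs
are bit-identical and the ground truth is seed-independent.

**Event quantisation.** Times are seconds internally; an event scheduled
at time t first affects the frame with index ⌈t/Δt⌉, and the ground-truth
event carries that frame. Entry events are mask-derived (first frame any /
all cell pixels are past the entrance plane), so an analysis running on the
same masks can match them exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nuclear mechanics and shape change under force
(the nucleus is rigid), photobleaching, focus drift, z-extent (rendering is
single-plane 2-D), membrane blebs and protrusion texture, cell-to-cell
contact, and segmentation-confounding clutter. Parameter-recovery results
bound algorithmic error under the stated noise model, not biological or
optical variability.

## Reporting conventions

Rates are per hour over an observation window spanning nucleus-at-entrance
to protrusion-at-exit (full trace span when those landmarks are absent);
entry times and delays are reported in minutes. Condition summaries follow
the per-experiment-averaging convention: per-experiment means first, then
mean ± s.d. (ddof = 1) across experiments; pooled per-cell medians are
emitted alongside, and the two coincide exactly when experiments have equal
n (a tested identity). Cells without an experiment assignment go to a
quarantine table rather than a default group. ACE-timing categories
(before / at / after the nearest rupture, with "at" = within ±1 frame by
default, plus "no_rupture") are reported as frequencies over classified
cells. Anillin N/C ratios strictly between 3 and 5 get the label
"intermediate"; that label is this package's, introduced so the classifier
is total. Pearson correlation (with the t-transform p-value) is the only
inferential statistic computed; anything further belongs in a stats
package reading the tidy CSVs.

## Benchmark problem sizes

The shipped benchmarks use sizes chosen to exercise each property while
keeping the whole suite fast on one CPU: decision-boundary sweeps of
30–150 synthetic inputs per threshold; 1,000 random profiles against the
brute-force ACE oracle; 100 traces × 200 frames for rupture-caller
recovery; 50 short movies (6 frames, 80 µm channel) for segmentation IoU;
a 100-cell cohort at a 1/h scheduled rupture rate for rate recovery; and a
60-frame movie for the exact zero-noise round trip.
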