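# Methods

## Scope and model

The pipeline quantifies single-worm planarian locomotion from the body-length
signal alone. Three gaits are modeled. Gliding is constant length. The two
oscillatory gaits are trains of trough → peak → trough cycles characterized by
four parameters: frequency `f` (cycles/s), maximum elongation
`A = (L_peak − L_trough)/L_peak`, relative speed `v = f·A` (body lengths/s,
an identity, not an independent measurement), and asymmetry `a`, the fraction
of each cycle spent elongating. Scrunching is fast, large-amplitude and
asymmetric (`a ≈ 0.57–0.62`); peristalsis is slower, smaller and symmetric
(`a ≈ 0.5`). Analysis windows are restricted to runs of at least
`min_cycles = 4` consecutive cycles that avoid strongly bent postures, since
the length proxy (ellipse major axis) under-reads a curled body.

## Synthetic recordings

The generator is the package's stand-in for raw video, which is not publicly
deposited for this assay. A recording is parameterized by
(`gait_kind, f, A, a, gliding_length, peak_factor, noise_sd, duration_s,
fps, seed`). The oscillation waveform is a piecewise cosine-eased ramp
between trough `P·(1−A)` and peak `P = peak_factor · gliding_length`: the
elongation phase occupies `a·T` of each period `T = 1/f` and the contraction
phase the rest, with smooth (differentiable) extrema as in real traces.
Defaults mirror the study conditions: 10 frames/s (the recording rate of the
original CCD setup), 30 s bouts, and the published per-condition parameter
regimes (packaged as `data/published_gait_parameters.csv`); the peristalsis
preset is `f=0.26, A=0.23, a=0.50` and the canonical scrunching preset
`f=0.72, A=0.52, a=0.59`. Additive i.i.d. Gaussian length noise (SD as a
fraction of gliding length, default regimes use 0.01–0.02) models tracking
jitter. An optional gliding prelude (constant length, then one contraction
ramp into the first trough) reproduces the gliding → escape transition and
gives the normalization stage a genuine gliding baseline. `peak_factor`
defaults to 1.2: published plots are normalized, so the absolute excursion
relative to gliding length is a free choice; 1.2 keeps the trough above half
the gliding length across all regimes.

Rendering draws the worm as an elliptical (tapered) silhouette, dark on a
light 8-bit background, optionally sheared by a sinusoidal bend that
preserves the end-to-end spine chord. The ellipse shape was chosen
deliberately over a constant-width capsule: the length measurement downstream
is the intensity-equivalent-ellipse major axis, which is exact for an
elliptical silhouette but overestimates a slim capsule's chord by ~10–15%
(a rectangle of length L has `4·sqrt(L²/12) ≈ 1.155 L`). With the tapered
body the extracted length is an unbiased estimate of the true spine length,
which is also the more realistic planarian outline. Rendered stacks carry
their exact per-frame masks and a clean background image as ground truth.

What the generator does **not** emulate: forward translation during
scrunching (the worm oscillates in place unless a drift is requested),
mucus trails, illumination drift, shadows, occlusions, desensitization
time-courses (latency onset/offset), or multi-animal scenes. Passing tests
therefore demonstrate correctness of the measurement chain under controlled
conditions, not robustness to arbitrary field recordings.

## Length extraction

Frames are background-subtracted (absolute difference), thresholded (Otsu by
default, fixed threshold available), reduced to the largest 8-connected
component (minimum area 50 px), and summarized by the equivalent-ellipse
major axis `4·sqrt(λ_max)` of the pixel-coordinate covariance — the same
convention as the "fit ellipse" measurement of common image software, with a
closed-form oracle. The `"auto"` background is the per-pixel temporal
median, which assumes the worm moves enough that each pixel is background in
most frames; for a stationary oscillating worm the median contains the worm
core, so synthetic stacks attach their known background and the extractor
prefers it (`background=None`). Frames that fail segmentation are flagged
and filled by linear interpolation (leading/trailing failures are dropped);
more than 20% failures is an error. Frames with minor/major axis ratio above
0.35 are flagged as bent and excluded from window selection. Traces are
normalized by the mean length over a gliding window — given explicitly, or
found automatically as the lowest-variance sliding window (default width
3 s, minimum 1 s of samples).

## Cycle detection and parameter estimation

Peak/trough candidates come from prominence-based peak finding on a lightly
smoothed copy (centered 0.3 s moving average; prominence ≥ 0.10 of the
median length; same-type spacing ≥ 0.5 s — defaults that separate the
published amplitude regimes from noise at 10 fps and are configurable).
Candidates are merged into a strictly alternating sequence (ties resolved by
keeping the more extreme), and boundary troughs that prominence-based
detection cannot see at the ends of a bout are recovered explicitly.

Each extremum is then refined to sub-sample precision by a least-squares
parabola on the **raw** samples within ±max(2, 0.1·T) frames. This matters
at 10 fps: smoothing drags the extremum of an asymmetric waveform toward its
flatter side (≈ 0.03 s for the fast regimes), and taking the raw argmax near
a detected peak selects positive noise (biasing amplitude up by ~2%); the
parabola fit is linear in the noise and avoids both effects. Per-cycle
amplitude uses the mean of the two bounding trough estimates rather than
their minimum — identical on clean periodic data, but the minimum of two
noisy estimates is biased low, which inflates `A` by ~0.007 in the
low-amplitude peristalsis regime.

Asymmetry is estimated from rise/fall transit times between the 25% and 75%
amplitude levels of each cycle (median of sub-sample linear-interpolated
crossings of the raw trace), with `a = Σ rise / Σ (rise + fall)`. Whenever
the elongation and contraction ramps share one time-scaled shape — exactly
true for the generator, approximately for real traces — this equals the
elongation fraction, while being insensitive to the frame-quantization and
flat-extremum timing errors that extremum-time differences suffer at 10 fps.
When crossings are unavailable (e.g. extremely short phases) the estimator
falls back to extremum times.

Window summary: `f = n_cycles / (t_last_trough − t_first_trough)` (less
outlier-sensitive than averaging reciprocal periods and identical on clean
data), `A` as the per-cycle mean, `a` time-weighted across the window,
`v = f·A` exactly. Population tables report mean ± SD (ddof = 1; a single
worm reports SD 0 with a flag), with population speed the mean of per-worm
speeds, not the product of population means. Reported values round
half-up to 2 decimals. Scrunch counting after an amputation-style initial
contraction discards any cycle whose peak precedes the end of the initial
monotone contraction from t = 0.

## Gait classification

The published analysis separated the gaits by comparing the four parameters
with per-species reference values; the package makes that decision rule
explicit and deterministic. Each summary is compared to the packaged
reference centroids (per-species amputation-induced scrunching; the single
published peristalsis reference, borrowed across species when needed) by the
standardized Euclidean distance over the four parameters, and labeled by the
nearest centroid. Guard rails: no qualifying oscillation window or
`A < 0.10` → gliding; distance ties (< 0.05) break on the asymmetry
hallmark (> 0.55 → scrunching). The floor and threshold are calibration
choices exposed as configuration. Welch (default) or pooled two-sample
t-tests from summary statistics, with Welch–Satterthwaite degrees of
freedom, accompany the label as a report; both variants are exposed because
published significance marks do not state which was used.

## Behavior scoring

Score tables hold one label per (condition, replicate, reviewer, worm,
15-s interval): `S` scrunched at least once, `R` other reaction, `N` no
reaction, six intervals covering 90 s. Aggregation averages per-interval
label counts across the two reviewers within each replicate, converts to
percent of worms, and reports mean ± SD (ddof = 1) across replicates;
`% reacting ≥ % scrunching` holds by construction. Window comparisons
(15–30 s → interval 2, also accepted as "16–30"; 31–45 s → interval 3)
count outcome-positive worms per reviewer, average the two reviewers, round
half-up (floor/ceil available — the rounding convention is not determined by
the published description, so exact published p-values are not reproduction
targets), sum over replicates, and apply a two-sided Fisher's exact test.
Degenerate margins return p = 1 with a flag; the odds ratio is `ad/bc` with
0/0 reported as undefined.

## qPCR

Technical replicates are averaged on the Ct scale (standard ΔΔCt practice);
per biological replicate, `ΔCt = Ct_target − Ct_housekeeping`,
`ΔΔCt = ΔCt_RNAi − ΔCt_control`, `relative expression = 2^(−ΔΔCt)`,
`knockdown% = (1 − relative expression)·100`. The reported knockdown is the
mean of per-bio-replicate relative expressions (ΔΔCt-scale averaging is
available via `average="ddct"`). ΔΔCt is invariant to per-plate constant Ct
offsets, which the synthetic Ct generator includes. Primer efficiency from
the standard-curve slope is a QC quantity only (the published range is
87–116%); no efficiency correction is applied to knockdown values.

## Numerical conventions and problem sizes

Pixel centers sit at integer coordinates; frame `i` is at `t = i/fps` with
the first retained frame at 0. All randomness flows from explicit integer
seeds through `numpy.random.default_rng`; identical inputs and seeds give
bit-identical traces, stacks and reports. The validation suite and the
acceptance script use 30 s recordings at 10 fps with 2% length noise
(10 worms per regime), three rendered noise-free stacks of 25 s plus a 5 s
gliding prelude for the image pipeline, an exhaustive Fisher sweep over all
2×2 tables with margins ≤ 12, 50 random masks for the ellipse oracle, and
200 simulated qPCR experiments per knockdown regime — sizes chosen so the
whole suite runs in well under a minute while keeping Monte-Carlo error far
below the tolerances tested.

## Known limitations

- The length proxy ignores the true midline of strongly bent worms; bent
  frames are excluded rather than skeletonized.
- One label per trace: gait switching within a recording is not segmented
  (the first qualifying window decides).
- The asymmetry estimator assumes elongation and contraction ramps share a
  shape; gaits with qualitatively different ramp shapes would need the
  extremum-time fallback.
- The classifier is a fixed-centroid rule, not a learned model; conditions
  far from all centroids are still assigned the nearest gait (flags, not
  rejection).
- Behavior-score and qPCR inputs are taken at face value; no inter-rater
  reliability or melt-curve QC is computed.
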