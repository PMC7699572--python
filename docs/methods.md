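# Methods

## Phantom model

Each synthetic cine sequence is a dark ellipse (the airway lumen) on a
brighter uniform background (soft tissue), rasterized at pixel centres
and observed through a Gaussian point-spread function plus additive
Gaussian noise. The semi-axes oscillate as

    a(t) = a0 · (1 + m · sin(2π · t · Δt / T)),   likewise b(t),

with frame interval Δt (default 350 ms, the midpoint of the 300–400 ms
cine temporal resolution this kind of acquisition delivers), respiratory
period T (default 3 s; tidal breathing in children spans roughly 2–5 s)
and modulation fraction m (default 0.2, i.e. ±20% size change over a
breath). Ground truth per frame is analytic: area π·a(t)·b(t), AP/TX
diameters 2a(t), 2b(t). An optional `amplitude_drift` perturbs m
per cycle (standard-normal multiplier) because real respiratory traces
are not strictly periodic; ground truth then uses the perturbed values,
so it stays exact.

Default contrast is lumen 20 / tissue 150 on an 8-bit scale with noise
SD 10 and 0.5 px blur; any well-separated pair behaves identically, the
defaults simply leave headroom for noise. Default pixel spacing is
0.5 mm/pixel — the scale at which 2 pixels equal 1 mm — with anisotropic
spacing supported throughout (AP uses row spacing, TX column spacing).
Typical pediatric upper-airway lumina motivate the default 5 × 4 mm
semi-axes; none of the geometric defaults is a claim about any
particular cohort, and all are config-exposed.

Cohorts mirror a within-subject sedation design: per (subject, plane)
the baseline semi-axes get an additive Normal(0, `between_subject_sd`)
offset (default 0.8 mm, clamped to ≥ 0.8 mm semi-axis); each condition
multiplies the semi-axes by its `condition_effects` entry (baseline
"00" fixed at 1.0); ages are uniform in `age_range`. All randomness
derives from named `default_rng` streams of the cohort seed, so any
record can be regenerated independently and lazily
(`iter_cohort` streams one sequence at a time; a full 22-subject,
2-plane, 4-condition cohort never needs to sit in memory).

What the phantoms deliberately do not model: MR physics (no k-space,
no Rician noise floor, no bias field), through-plane or bulk motion,
non-elliptical lumen shapes, and surrounding anatomy (a single tissue
intensity). Tests passing on phantoms therefore demonstrate the
pipeline's geometric and statistical correctness under its own
assumptions — not robustness to artifacts absent from the model.

## Segmentation

Per frame:

1. **Rectangular limits.** The 1-D intensity profiles through the seed
   along rows (AP) and columns (TX) are smoothed with a 3-px moving
   average. Boundary candidates are local maxima with prominence of at
   least 10% of the frame's intensity range *and* height above the
   midpoint of the profile's range — the flank must actually be bright
   tissue; a prominence criterion alone lets dark-side noise bumps
   truncate the airway. Profiles are padded with −∞ so tissue running
   into the image border still ends in a peak, and for plateau peaks
   the plateau edge nearest the seed is used. The nearest qualifying
   peak on each side of the seed (ties: lower index) bounds the airway;
   a side without one falls back to the image border. A seed at least
   as bright as the median of its profiles (or of the frame, when both
   profiles miss the lumen) is rejected as "not in lumen".
2. **Threshold.** Otsu's split of the in-bounds intensities; if the
   split is degenerate (one class under 2% of pixels — a unimodal
   histogram), the midpoint between the seed's 3×3 neighborhood mean
   and the mean intensity at the four bound edges is used instead. A
   contrast-free region raises an error.
3. **Growth.** The 4-connected sub-threshold component containing the
   seed (4-connectivity resists diagonal leakage through thin bright
   septa), then a union with every sub-threshold pixel inside that
   component's bounding box, so all low-intensity pixels within the
   detected airway extent are labeled. `fill_mode` selects the pure
   component (`"connected"`) or every sub-threshold pixel within the
   rectangular limits (`"any"`) instead; the hybrid is the default
   because the description "all low-intensity pixels within the
   limits" is ambiguous between the two extremes.

Across frames, the next seed is the rounded centroid of the previous
non-empty mask (falling back to the original user seed when the
previous mask was empty or the candidate pixel is not sub-threshold) —
the minimal mechanism that makes a single user seed serve a whole
sequence. Bounds and threshold are recomputed every frame for
robustness to intensity drift. An empty mask on frame 0 is fatal;
empty masks later are legitimate (transient airway closure) and
contribute zero area/diameters rather than being dropped, which would
bias minima upward. More than 50% empty frames logs a warning but
completes.

Diameters are mask bounding-box extents with the inclusive pixel-count
convention (a 1-px mask has diameter one pixel width); area is pixel
count × pixel area.

## Temporal summarization

A metric trace is summarized as t_min (mean over detected valleys),
t_mean (mean over all frames) and t_max (mean over detected peaks).
Extrema are `scipy.signal.find_peaks` local extrema with prominence
≥ 10% of the series range on the raw (unsmoothed) trace by default;
endpoints are excluded so truncated first/last breaths do not bias the
averages. If a side detects nothing (flat or monotone trace) the global
extremum stands in — this fallback is what guarantees
t_min ≤ t_mean ≤ t_max on degenerate inputs. (For adversarial
non-respiratory traces with broad secondary plateaus the valley mean
can in principle exceed the overall mean; the ordering is asserted in
tests on breathing-like traces, which is the intended domain.) A
constant series returns its value three times with extrema index 0.
Zero-valued frames (closed airway) are valid valley candidates.

## Statistics

* **Paired comparisons.** Within-pair differences are screened with
  Shapiro–Wilk at α = 0.05 (the "as appropriate" gate made explicit):
  normal → paired t with t-based 95% CI; else Wilcoxon signed-rank with
  a Hodges–Lehmann interval (Walsh averages, normal-approximation rank
  cutoff — adequate at the n ≈ 22 scale this targets). Cohen's *d* is
  mean(diff)/SD(diff) in both branches. Percent change averages the
  per-subject percent changes (respecting the pairing) rather than
  taking a ratio of means; zero-baseline subjects are excluded from it
  with a logged warning.
* **Mixed models.** `change ~ 0 + C(time) + age + baseline` with a
  random intercept per subject, REML, via statsmodels `MixedLM`.
  Least-squares mean change per time level is the prediction at sample
  means of age and baseline; its CI and p-value use the normal
  approximation to the fixed-effect distribution (statsmodels provides
  no Satterthwaite degrees of freedom; with ~60 observations the
  difference is small and the approximation is flagged in the result).
  A singular or non-convergent random-effects fit is refitted as OLS
  and flagged `random_effect_dropped` — this is expected, not an error,
  when the baseline covariate already absorbs the between-subject
  variance (e.g. null cohorts).
* **Multiplicity.** Bonferroni by default — the most transparent choice
  for a reported family — with Holm available; adjusted p-values are
  always ≥ raw ones.
* **Dunnett-type comparisons.** Paired t statistics of each time level
  against baseline are referred to the joint multivariate-t
  distribution (df = n−1) with correlation estimated from the
  within-subject difference vectors; adjusted p for level j is
  1 − P(max |T| ≤ |t_j|), evaluated by scipy's QMC multivariate-t CDF
  with a fixed `random_state` so results are reproducible. With one
  level this reduces exactly to the unadjusted paired t-test.
  (`scipy.stats.dunnett` assumes independent groups and is not
  applicable to this repeated-measures design.)
* **Power.** Exact noncentral-t: power = P(|T′| > t_{1−α/2,n−1}) with
  noncentrality d√n. α is the post-adjustment per-comparison level
  (0.05 split over two primary outcomes gives 0.025). `solve_n` binary
  searches the monotone power curve for the smallest sufficient n.

Calibration studies of the statistics stage (test size, sign recovery
of an injected −10% condition effect, CI coverage on null cohorts,
Dunnett family-wise error) run on analytic cohort tables perturbed by
4% multiplicative measurement noise (`simulate_cohort_measurements`) —
the same order as the phantom segmentation recovery error — rather than
on hundreds of rendered imaging cohorts; the imaging and statistics
stages are validated separately and joined by the end-to-end pipeline
test.

## Problem sizes and numerical choices

The validation suite segments 50 phantom sequences × 72 frames
(≈ 7 s on one CPU); statistical calibration uses 2000 replicates for
test-size/FWER checks and 200 simulated cohorts for mixed-model
recovery and coverage; the end-to-end determinism check runs the full
default cohort (22 subjects × 2 planes × 4 conditions × 72 frames at
128×128, ≈ 22 s per run) twice and compares file hashes. Ties among
equally prominent boundary peaks resolve to the lower index; all RNG
streams derive from explicit integer seed tuples; CSV floats are
written at 6 significant digits, which bounds round-trip error well
below measurement error.

## Known limitations

* The profile-bounds step assumes the lumen is the dark well *through
  the seed*; strongly non-convex lumina (e.g. crescents whose centroid
  falls outside the lumen) can defeat centroid seed propagation — the
  fallback to the original seed mitigates but does not eliminate this.
* Bounding-box diameters overestimate oblique lumen extents slightly
  (they measure the axis-aligned box, by design, matching the
  rectangular-limits convention of the measurement).
* The Wilcoxon CI uses a normal-approximation critical rank; for n < 10
  an exact enumeration would be preferable.
* LMM inference is asymptotic (normal approximation); at very small
  cohort sizes its CIs are mildly anticonservative, which the coverage
  test quantifies at n = 22.
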