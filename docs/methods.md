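# Methods

## Imaging model and contrast computation

The observable is a time-lapse series of 2-D frames of an embryonic heart,
acquired in at least two spectral channels with different hemoglobin
absorption (green strong, red weak for whole blood). High-bit-depth camera
data (e.g. 14-bit) is expected pre-converted to PNG or TIFF in an 8- or
16-bit container; intensities are used as-is, and `bit_depth` records the
container. No rescaling is applied because every downstream step — channel
subtraction, min–max normalization, Otsu thresholding — is invariant to
affine intensity maps.

The hemoglobin-contrast image is `C = (I_weak − I_strong)` normalized by
the min–max of the difference over the *whole series*, mapping it to
[0, 1]. Series-global (rather than per-frame) normalization is deliberate:
the same physical contrast maps to the same value at end-diastole and
end-systole, so blush differences between the two phases reflect blood
area, not frame-wise renormalization. The cost is sensitivity of the
nominal [0, 1] scale to extreme noise pixels; this is harmless here because
the Otsu threshold adapts to the realized histogram. An
`single_channel_inverted` mode serves grayscale data in which blood is
simply dark.

## Hb-blush classification

Pixels are classified hemoglobin-containing iff their contrast exceeds an
Otsu threshold. The implementation histograms the values into `otsu_bins`
(default 256) equal-width bins over the observed range and returns the
interior bin edge maximizing the between-class variance
ω₀ω₁(μ₀ − μ₁)², computed from cumulative histogram moments; class means
use bin centers, matching the classic discrete formulation. Ties are broken
toward the lowest qualifying edge, which is deterministic and counts
borderline pixels as blood. The classification rule is strict:
`value > threshold`.

Two numerical notes. First, candidate thresholds are bin *edges*, so the
threshold is well-defined for continuous data while reproducing classic
8-bit behavior when the data are integers. Second, the cumulative-moment
evaluation and a naive per-edge summation can differ by ~1 ulp, which
matters only when two edges tie analytically; validation therefore asserts
that the returned edge *attains* the exhaustive maximum of the criterion
rather than comparing edge indices.

By default the threshold for the final measurement pools the ROI pixels of
the selected ED and ES frames into one histogram ("pooled_over_
selected_frames"), so a single threshold applies to both phases and the
stroke area EDBA − ESBA cannot be an artifact of threshold drift;
`per_frame` thresholds are available for heavily drifting illumination.
Whether to compute Otsu over the whole frame or only within the ventricle
outline is an open choice in this kind of software; restricting to the ROI
is the default here because the surrounding yolk and agarose would
otherwise dominate the histogram.

## Phase selection

Automatic ED/ES selection needs a per-frame blood signal before the final
thresholds exist, so quantification runs in two passes: a provisional Otsu
threshold is computed on the union of all supplied ROI masks pooled across
*all* frames, giving a per-frame blush count trace; ED is the trace argmax
and ES the argmin (after an optional centered moving average with
truncated edges, window odd, default 1), ties broken to the earliest frame.
A constant trace raises a no-pulsatility error rather than returning an
arbitrary pair. One global ED/ES pair is selected per series; beat-by-beat
analysis is out of scope. Manual frame indices bypass the trace entirely.
Metric computation requires a ventricle outline on exactly the selected
frames and fails, naming the frame, if one is missing.

## Metrics

With (roi_area, blush) at ED and ES:
`SA = EDBA − ESBA`, `EF = 100·SA/EDBA`, `Δ%tA = 100·(tEDA − tESA)/tEDA`,
`MMI = tESA − ESBA`. These identities hold to machine precision by
construction and are asserted over the pipeline's outputs. Negative SA/EF
(paradoxical filling, e.g. regurgitation or segmentation error) are
reported and flagged, never clamped. Areas are in px²; an optional µm/px
scale converts areas (not ratios) at output time, since optical
calibration is rig-specific.

MMI assumes near-complete ejection at peak systole, so the non-blush
remainder of the end-systolic outline approximates the myocardial
cross-section; it is a rough index, not a wall-thickness model.

## ROI geometry

Outlines are simple polygons in 0-based pixel-center coordinates
(x right, y down), stored in a plain-text sidecar (`#hcsa-roi v1`). A pixel
belongs to the ROI iff its center is inside under the even–odd rule;
centers exactly on an edge are included. This convention is fixed so that
rasterization is testable: against an exhaustive point-in-polygon oracle
for exact agreement, and against the shoelace area (within 2% for convex
polygons above 500 px², where perimeter discretization error is small).
No partial-pixel weighting is used — blush is a whole-pixel count, so the
denominator must be too.

## Statistics

Groups are compared per metric with the two-sided Mann–Whitney U test,
U = Σ [aᵢ > bⱼ] + ½[aᵢ = bⱼ]. For tie-free samples with at most 8
observations per group the null distribution is enumerated exactly over all
C(n+m, n) arrangements and p = 2·P(U′ ≤ min(U, nm − U)), capped at 1
(≤ 12 870 arrangements, exact and fast); otherwise the normal approximation
with tie-corrected variance and 0.5 continuity correction is used. Group
location is summarized by the median with the distribution-free
order-statistic interval: the largest symmetric ranks (l, n+1−l) whose
binomial(n, ½) coverage is ≥ 95%. Below n = 6 no such interval exists and
the sample range is returned with a coverage warning. No multiple-testing
correction is applied — each metric is judged at the per-comparison α
(default 0.05) — and the comparison output records that policy.

## The phantom generator

The phantom is an elliptical blood pool centered in the frame whose
semi-axes follow `a(t) = a_es + (a_ed − a_es)(1 + cos 2πft)/2` (t = 0 at
end-diastole), surrounded by a myocardial annulus of fixed thickness. The
weak-absorption channel is uniformly bright at 85% of the 14-bit full
scale; the strong channel is attenuated by exp(−k) with k = 0.8 in blood
and 0.25 in the wall (mid-range values giving clearly bimodal but
overlapping contrast once noise is added). Additive Gaussian noise with sd
`noise_sd` × bright level (default 0.02, i.e. a clean modern sensor) is
applied to both channels, seeded, then the image is rounded into the
16-bit container. Ground truth is closed-form: every area is πab, so all
eight metrics and the per-frame blood-area waveform are exact.

Defaults: 256×256 px, 50 frames at 0.2 s, ED axes (60, 45) px, ES axes
scaled by √0.45 (true EF 55%, a healthy embryonic ventricle), wall 12 px.
The heart rate default is 1.25 Hz so that the 0.2 s sampling grid places
exactly 4 frames per cycle with samples landing exactly on end-diastole and
end-systole; the generator enforces ≥ 4 frames per cycle (and ≥ 1 full
cycle) as a resolvability floor, since a faster beat against this frame
interval aliases the extremes that the whole measurement depends on.
Ventricle outlines (64-gon approximations of the outer ellipse) are
emitted at *every* frame at an analytic extreme: with several identical
cycles in a series, sensor noise decides which cycle's peak becomes the
global argmax, and each candidate needs an outline. The cosine waveform is
a sampling model, not hemodynamics — real ventricles have asymmetric
filling/ejection phases; the pipeline only requires resolvable extremes.

Cohorts add per-embryo biological variability as lognormal (sd 5%)
factors: one size factor per blood-pool axis, shared between the ED and ES
values of that axis, plus one contractility factor on the ES axes. This
decomposition varies heart size, shape and ejection fraction realistically
while guaranteeing ES ≤ ED for any valid group parameters (fully
independent per-axis-per-phase factors would make the generator's own
validity invariant a positive-probability failure under emptying-impairment
effects). A treatment effect is a set of multiplicative changes to phantom
parameters; enlarging the ES axes ×1.15 models impaired emptying and drops
true EF from ≈55% to ≈40%. Embryo seeds derive deterministically from
(base_seed, group index, embryo index). Replicate studies use the analytic
ground-truth tables without rendering images, which keeps 500-replicate
calibration runs in seconds.

What the phantom does *not* emulate — and hence what passing tests do not
establish about real data: optical blur and scattering, trabeculation and
irregular chamber geometry, red-cell granularity and flow texture, motion
of the embryo, illumination drift, and manual-segmentation variability.
Recovery results on phantoms bound algorithmic error, not biological or
operator error.

## Validation problem sizes

The shipped validation uses 200 random histograms for the Otsu oracle
check, 100 sample pairs (n, m ≤ 7) for Mann–Whitney exactness, 1000 random
area quadruples for the metric identities, 50 convex + 20 small polygons
for rasterization, three phantoms (true EF 30/50/70%, noise sd 0.05) for
end-to-end recovery, and 20 effect + 500 null replicate cohorts (n = 30
per group) for discrimination and calibration — sizes at which each check
is statistically meaningful while the whole suite runs in well under a
minute on a laptop.

## Known limitations

- Single ED/ES pair per series; no heart-rate or beat-variability metrics.
- 2-D areas only; no volumetric extrapolation.
- Min–max normalization is outlier-sensitive in principle (mitigated by
  the adaptive threshold, but pathological hot pixels should be cleaned
  upstream).
- The ROI sidecar supports one simple polygon per frame — no holes or
  multi-part regions.
- Exact Mann–Whitney inference is limited to n ≤ 8 per group without ties;
  beyond that the normal approximation is used (accurate at the cohort
  sizes this tool targets).
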