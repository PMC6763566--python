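# hcsa — ventricular function metrics from hemoglobin-contrast videomicroscopy

`hcsa` quantifies embryonic heart function from ordinary color time-lapse
videomicroscopy, for labs that screen candidate cardiomyopathy genes or
teratogens in small, optically accessible animal models (e.g. *Xenopus*
tadpoles). Hemoglobin absorbs green light much more strongly than red, so
blood can be detected without injected dye: subtracting the strongly
absorbed channel from the weakly absorbed one yields an endogenous-contrast
image in which blood is bright (**hemoglobin contrast subtraction
angiography**, HCSA). The package turns a ~50-frame series plus per-frame
ventricle outlines into eight per-embryo metrics, and compares labeled
cohorts nonparametrically.

## The measurement

For a series of frames with a manually outlined ventricle, the pipeline

1. forms the contrast stack `C = normalize(I_weak − I_strong)` (min–max over
   the whole series, so values are comparable across frames);
2. classifies hemoglobin-containing pixels ("Hb blush") with Otsu's
   threshold — the value maximizing the between-class variance
   ω₀ω₁(μ₀−μ₁)² over a 256-bin histogram — implemented from first
   principles and checkable against exhaustive search;
3. selects end-diastole (ED) and end-systole (ES) as the extremes of the
   per-frame blush trace (or takes user-specified frames);
4. computes, from the ROI area and blush count at ED and ES:

   | metric | definition | meaning |
   |---|---|---|
   | tEDA, tESA | ROI pixel counts | total ventricular area at ED / ES |
   | Δ%tA | 100·(tEDA − tESA)/tEDA | fractional area shortening |
   | EDBA, ESBA | blush pixel counts | blood area at ED / ES |
   | SA | EDBA − ESBA | stroke area |
   | EF | 100·SA/EDBA | ejection fraction |
   | MMI | tESA − ESBA | myocardial mass index |

5. compares groups per metric with the two-sided Mann–Whitney U test
   (exact by full enumeration for n ≤ 8 per group without ties, otherwise
   the tie- and continuity-corrected normal approximation), summarizing each
   group by its median with a distribution-free order-statistic 95% CI.

A synthetic phantom generator (`hcsa.synth`) renders beating-heart series —
an elliptical blood pool contracting on a cosine waveform inside a
myocardial annulus, two spectral channels with Beer–Lambert attenuation,
Gaussian sensor noise — with closed-form ground truth for every metric, so
the whole pipeline is testable without microscope data.

## Worked example

Generate a phantom (50 frames, 0.2 s interval, true EF 55%), quantify it,
and inspect the result:

```bash
$ hcsa simulate phantom --seed 42
wrote phantom dataset to phantom (EF_true 55%)

$ hcsa quantify phantom/series.tiff phantom/rois.csv metrics.csv \
      --embryo-id tad01 --group control
contrast: mode=channel_difference raw range [-2108, 9521]
provisional threshold 0.583097 (pooled 12884 px x 50 frames)
phases: ED frame 24, ES frame 2
final thresholds: ED 0.591044, ES 0.591044 (pooled_over_selected_frames)
blush: ED 8476/12884 px, ES 3828/6912 px
metrics: EF 54.84%, SA 4648 px^2
wrote metrics.csv
```

The measured ejection fraction (54.84%) recovers the phantom's analytic
truth (55%) to 0.16 points; ED and ES were found at frames 24 and 2, both
exact analytic extremes of the blood-area waveform. `metrics.csv` holds the
full row:

```
embryo_id,group,tEDA,tESA,delta_pct_tA,EDBA,ESBA,SA,EF,MMI,ed_frame,es_frame
tad01,control,12884,6912,46.35206458,8476,3828,4648,54.83718735,3084,24,2
```

Comparing a simulated control cohort against one with impaired emptying
(end-systolic axes enlarged 15%, n = 30/30):

```bash
$ hcsa compare cohort.csv --pair control:treated --out comparison.csv
```

```
      metric   U            p        method     median_a     median_b  significant
        tEDA 483 6.308763e-01 normal_approx 13084.362440 12827.041170        False
        ESBA  31 6.121039e-10 normal_approx  4024.300896  5147.076816         True
          SA 865 8.890991e-10 normal_approx  4830.050546  3294.478716         True
          EF 895 4.975166e-11 normal_approx    55.379461    38.823686         True
         ...
```

The treated group fills normally (tEDA, EDBA not significant) but fails to
empty (ESBA up, EF and SA down) — the dose-style functional phenotype the
tool is designed to detect.

## Layout

- `hcsa.io_formats` — image series (PNG/TIFF), ROI sidecars, configs, tables
- `hcsa.geometry` — polygon rasterization (even–odd, pixel centers) + shoelace area
- `hcsa.hcsa_core` — contrast computation, Otsu threshold, blush measurement
- `hcsa.cardiac_metrics` — phase selection and the eight metrics
- `hcsa.group_stats` — Mann–Whitney, median CIs, cohort comparison
- `hcsa.synth` — phantom and cohort generators with analytic ground truth
- `hcsa.pipeline` / `hcsa.cli` — end-to-end quantification and the `hcsa` command

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
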