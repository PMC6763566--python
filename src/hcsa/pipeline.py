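"""End-to-end quantification: contrast -> phases -> Otsu -> blush -> metrics.

Automatic phase selection needs a per-frame blush trace before the final
per-phase thresholds exist, so the pipeline runs in two passes:

1. a *provisional* Otsu threshold is computed by pooling contrast values of
   every frame within the union of all supplied ROIs (the union covers the
   heart in all phases), giving a blush count per frame — the trace that
   locates end-diastole and end-systole;
2. the *final* threshold(s) are computed per the configured pooling policy
   on the selected ED/ES frames inside their own outlines, and blush is
   measured there.

The default pooling policy shares one threshold between the ED and ES
frames so the stroke area reflects blood, not threshold drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cardiac_metrics import (
    PhaseSelection,
    VentricleMetrics,
    compute_ventricle_metrics,
    select_phases,
)
from .errors import MissingRoiError
from .geometry import RoiMask, rasterize_polygon
from .hcsa_core import (
    ContrastStack,
    ThresholdResult,
    compute_hb_contrast,
    measure_blush,
    otsu_threshold,
)
from .io_formats import ImageSeries, RoiSet, RunConfig


@dataclass
class QuantifyResult:
    """Everything one series quantification produced, for auditing."""

    metrics: VentricleMetrics
    phases: PhaseSelection
    threshold_ed: ThresholdResult
    threshold_es: ThresholdResult
    provisional_threshold: ThresholdResult
    contrast: ContrastStack
    log: list[str] = field(default_factory=list)


def blush_trace(
    contrast: ContrastStack, union_mask: np.ndarray, threshold: ThresholdResult
) -> np.ndarray:
    """Per-frame count of Hb-classified pixels within a fixed mask."""
    t = threshold.threshold
    return np.array(
        [int(np.count_nonzero((f > t) & union_mask)) for f in contrast.frames]
    )


def quantify(
    series: ImageSeries,
    rois: RoiSet,
    config: RunConfig | None = None,
    embryo_id: str = "",
    group: str = "",
) -> QuantifyResult:
    """Quantify one embryo's ventricular function from a series + ROI set."""
    config = config or RunConfig()
    log: list[str] = []
    if not rois.entries:
        raise MissingRoiError("ROI set is empty")

    contrast = compute_hb_contrast(series, config)
    log.append(
        f"contrast: mode={config.contrast_mode} "
        f"raw range [{contrast.norm_min:.6g}, {contrast.norm_max:.6g}]"
    )

    masks: dict[int, RoiMask] = {
        fi: rasterize_polygon(rois[fi], rois.image_shape, frame_index=fi)
        for fi in rois.frames()
    }
    union = np.zeros(rois.image_shape, dtype=bool)
    for m in masks.values():
        union |= m.mask

    provisional = otsu_threshold(contrast.frames[:, union], config.otsu_bins)
    trace = blush_trace(contrast, union, provisional)
    log.append(
        f"provisional threshold {provisional.threshold:.6g} "
        f"(pooled {int(union.sum())} px x {series.n_frames} frames)"
    )

    phases = select_phases(trace, config)
    log.append(f"phases: ED frame {phases.ed_frame}, ES frame {phases.es_frame}")
    for name, fi in (("ED", phases.ed_frame), ("ES", phases.es_frame)):
        if fi not in masks:
            raise MissingRoiError(
                f"selected {name} frame {fi} has no ventricle outline"
            )
    ed_mask, es_mask = masks[phases.ed_frame], masks[phases.es_frame]

    ed_vals = contrast.frames[phases.ed_frame][ed_mask.mask]
    es_vals = contrast.frames[phases.es_frame][es_mask.mask]
    if config.otsu_pooling == "pooled_over_selected_frames":
        shared = otsu_threshold(np.concatenate([ed_vals, es_vals]), config.otsu_bins)
        thr_ed = thr_es = shared
    else:
        thr_ed = otsu_threshold(ed_vals, config.otsu_bins)
        thr_es = otsu_threshold(es_vals, config.otsu_bins)
    log.append(
        f"final thresholds: ED {thr_ed.threshold:.6g}, ES {thr_es.threshold:.6g} "
        f"({config.otsu_pooling})"
    )

    blush_ed = measure_blush(contrast.frames[phases.ed_frame], ed_mask, thr_ed)
    blush_es = measure_blush(contrast.frames[phases.es_frame], es_mask, thr_es)
    log.append(
        f"blush: ED {blush_ed.blush_px}/{blush_ed.roi_area_px} px, "
        f"ES {blush_es.blush_px}/{blush_es.roi_area_px} px"
    )

    metrics = compute_ventricle_metrics(
        (blush_ed.roi_area_px, blush_ed.blush_px),
        (blush_es.roi_area_px, blush_es.blush_px),
        phases,
        embryo_id=embryo_id,
        group=group,
    )
    log.append(f"metrics: EF {metrics.EF:.4g}%, SA {metrics.SA:.6g} px^2")
    return QuantifyResult(
        metrics=metrics,
        phases=phases,
        threshold_ed=thr_ed,
        threshold_es=thr_es,
        provisional_threshold=provisional,
        contrast=contrast,
        log=log,
    )
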