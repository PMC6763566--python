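"""Cardiac phase selection and the eight ventricular function metrics.

From the total segmented ventricle area and the Hb-blush (blood) area at
end-diastole (ED) and end-systole (ES):

    tEDA, tESA      total ventricular area at ED / ES           [px^2]
    delta_pct_tA    100 * (tEDA - tESA) / tEDA                  [%]
    EDBA, ESBA      blood (blush) area at ED / ES               [px^2]
    SA              stroke area = EDBA - ESBA                   [px^2]
    EF              ejection fraction = 100 * SA / EDBA         [%]
    MMI             myocardial mass index = tESA - ESBA         [px^2]

MMI rests on the assumption that at peak systole nearly all blood has been
ejected, so the non-blush remainder of the segmented area approximates the
myocardial tissue cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, NoPulsatilityError, UndefinedMetricError
from .io_formats import RunConfig


@dataclass
class PhaseSelection:
    """Selected end-diastolic and end-systolic frame indices."""

    ed_frame: int
    es_frame: int
    mode: str
    blush_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    smoothed_trace: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class VentricleMetrics:
    """Per-embryo ventricular function metrics (areas in px^2, EF/delta in %).

    ``paradoxical`` flags a negative stroke area (ES blood area exceeding
    the ED one); values are reported as-is, never clamped.
    """

    embryo_id: str
    group: str
    tEDA: float
    tESA: float
    delta_pct_tA: float
    EDBA: float
    ESBA: float
    SA: float
    EF: float
    MMI: float
    ed_frame: int
    es_frame: int
    paradoxical: bool = False

    def scaled(self, um_per_px: float) -> "VentricleMetrics":
        """Copy with areas converted to um^2; ratios (EF, delta) unchanged."""
        s = float(um_per_px) ** 2
        return VentricleMetrics(
            embryo_id=self.embryo_id,
            group=self.group,
            tEDA=self.tEDA * s,
            tESA=self.tESA * s,
            delta_pct_tA=self.delta_pct_tA,
            EDBA=self.EDBA * s,
            ESBA=self.ESBA * s,
            SA=self.SA * s,
            EF=self.EF,
            MMI=self.MMI * s,
            ed_frame=self.ed_frame,
            es_frame=self.es_frame,
            paradoxical=self.paradoxical,
        )


def smooth_trace(trace: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges (window odd, >= 1)."""
    trace = np.asarray(trace, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ConfigError("smoothing window must be an odd integer >= 1")
    if window == 1:
        return trace.copy()
    h = window // 2
    n = len(trace)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = trace[lo:hi].mean()
    return out


def select_phases(blush_trace, config: RunConfig | None = None) -> PhaseSelection:
    """Pick the ED (maximal blush) and ES (minimal blush) frames.

    In auto mode the trace is optionally smoothed, then ED = argmax and
    ES = argmin, ties broken toward the earliest frame.  Manual mode passes
    the configured indices through after validation.
    """
    config = config or RunConfig()
    trace = np.asarray(blush_trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 2:
        raise ConfigError("blush trace must be 1-D with >= 2 frames")
    if config.phase_selection == "manual":
        ed, es = int(config.ed_frame), int(config.es_frame)
        n = len(trace)
        if not (0 <= ed < n and 0 <= es < n):
            raise ConfigError(f"manual frames ({ed}, {es}) out of range [0, {n})")
        if ed == es:
            raise ConfigError("ed_frame and es_frame must differ")
        return PhaseSelection(ed, es, "manual", trace, trace)
    if config.smoothing_window > len(trace):
        raise ConfigError("smoothing_window exceeds trace length")
    sm = smooth_trace(trace, config.smoothing_window)
    if np.all(sm == sm[0]):
        raise NoPulsatilityError("blush trace is constant; no cardiac cycle found")
    ed = int(np.argmax(sm))
    es = int(np.argmin(sm))
    return PhaseSelection(ed, es, "auto", trace, sm)


def compute_ventricle_metrics(
    ed: tuple[float, float],
    es: tuple[float, float],
    phases: PhaseSelection,
    embryo_id: str = "",
    group: str = "",
) -> VentricleMetrics:
    """Compute the eight metrics from (roi_area_px, blush_px) at ED and ES.

    Negative SA/EF (paradoxical filling) are reported and flagged, not
    clamped.  EDBA = 0 leaves EF undefined and tEDA = 0 leaves delta_pct_tA
    undefined; both raise.
    """
    tEDA, EDBA = float(ed[0]), float(ed[1])
    tESA, ESBA = float(es[0]), float(es[1])
    for name, total, blush in (("ED", tEDA, EDBA), ("ES", tESA, ESBA)):
        if total < 0 or blush < 0:
            raise ValueError(f"{name} areas must be >= 0")
        if blush > total:
            raise ValueError(f"{name} blush area exceeds its ROI area")
    if tEDA == 0:
        raise UndefinedMetricError("tEDA = 0: delta_pct_tA is undefined")
    if EDBA == 0:
        raise UndefinedMetricError("EDBA = 0: ejection fraction is undefined")
    SA = EDBA - ESBA
    return VentricleMetrics(
        embryo_id=embryo_id,
        group=group,
        tEDA=tEDA,
        tESA=tESA,
        delta_pct_tA=100.0 * (tEDA - tESA) / tEDA,
        EDBA=EDBA,
        ESBA=ESBA,
        SA=SA,
        EF=100.0 * SA / EDBA,
        MMI=tESA - ESBA,
        ed_frame=phases.ed_frame,
        es_frame=phases.es_frame,
        paradoxical=SA < 0,
    )
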