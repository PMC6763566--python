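"""Synthetic beating-heart phantoms with analytic ground truth.

The phantom is an elliptical blood pool (semi-axes interpolating between
end-systolic and end-diastolic values along a cosine in time, end-diastole
at t = 0) surrounded by a myocardial annulus of fixed thickness, imaged in
two spectral channels.  The weak-absorption (red) channel is uniformly
bright; the strong-absorption (green) channel is attenuated by
Beer-Lambert-style factors exp(-k): k = ``hb_absorption`` inside blood,
``myocardium_absorption`` in the wall, 0 elsewhere.  Additive Gaussian
sensor noise (sd as a fraction of the bright level) is drawn from a
generator seeded by ``seed``, so a given parameter set is bit-reproducible.

Because every area is an ellipse area pi*a*b, all eight ventricular metrics
have closed forms; :class:`GroundTruth` carries them as recovery targets.
The cosine waveform is a sampling model, not hemodynamics: the pipeline
only needs resolvable extremes.

Cohorts emulate a control-vs-perturbed screening experiment: each embryo
gets lognormal (sd 5%) size factors on its blood-pool axes and a lognormal
contractility factor on the end-systolic axes, and a treatment is a set of
multiplicative effects on the phantom parameters (e.g. enlarging the
end-systolic axes models impaired emptying).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import ImageSeries, RoiSet

#: vertices used to approximate an ellipse outline
ELLIPSE_NGON = 64

#: lognormal sigma of per-embryo semi-axis variability
EMBRYO_JITTER_SD = 0.05

#: fraction of the 14-bit full scale used for the unattenuated background
BRIGHT_FRACTION = 0.85


@dataclass
class PhantomParams:
    """Parameters of one synthetic heart series.

    Defaults mimic a stage-45 tadpole ventricle filmed at 5 frames/s for
    50 frames: the 1.25 Hz beat puts exactly 4 samples in each cycle, so the
    0.2 s sampling grid hits end-diastole and end-systole exactly.  The
    default end-systolic axes give a healthy ejection fraction of 55%.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_frames: int = 50
    interframe_interval_s: float = 0.2
    heart_rate_hz: float = 1.25
    blood_semi_axes_ed: tuple[float, float] = (60.0, 45.0)
    blood_semi_axes_es: tuple[float, float] = (
        60.0 * 0.45**0.5,
        45.0 * 0.45**0.5,
    )
    wall_thickness_px: float = 12.0
    hb_absorption: float = 0.8
    myocardium_absorption: float = 0.25
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        a_ed, b_ed = self.blood_semi_axes_ed
        a_es, b_es = self.blood_semi_axes_es
        if a_es > a_ed or b_es > b_ed:
            raise ParameterError("end-systolic semi-axes must be <= end-diastolic")
        if min(a_es, b_es) <= 0:
            raise ParameterError("semi-axes must be positive")
        if not (0 <= self.myocardium_absorption < self.hb_absorption <= 1):
            raise ParameterError(
                "need 0 <= myocardium_absorption < hb_absorption <= 1"
            )
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.wall_thickness_px <= 0:
            raise ParameterError("wall_thickness_px must be > 0")
        if self.n_frames < 2:
            raise ParameterError("need >= 2 frames")
        frames_per_cycle = 1.0 / (self.heart_rate_hz * self.interframe_interval_s)
        if frames_per_cycle < 4:
            raise ParameterError(
                f"heart period under-resolved: {frames_per_cycle:.2f} frames/cycle "
                "(need >= 4)"
            )
        if self.n_frames * self.interframe_interval_s < 1.0 / self.heart_rate_hz:
            raise ParameterError("series must span at least one cardiac cycle")
        h, w = self.image_shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        if a_ed + self.wall_thickness_px > cx or b_ed + self.wall_thickness_px > cy:
            raise ParameterError("outer ellipse exceeds the image bounds")


@dataclass
class GroundTruth:
    """Analytic metric values of a phantom; the recovery target for tests."""

    blood_area_trace: np.ndarray
    phase: np.ndarray  # s(t) = (1 + cos 2*pi*f*t)/2; 1 at end-diastole
    tEDA_true: float
    tESA_true: float
    delta_pct_tA_true: float
    EDBA_true: float
    ESBA_true: float
    SA_true: float
    EF_true: float
    MMI_true: float
    ed_frame: int
    es_frame: int
    ed_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    es_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _ellipse_polygon(
    center: tuple[float, float], semi_axes: tuple[float, float], n: int = ELLIPSE_NGON
) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center[0] + semi_axes[0] * np.cos(theta), center[1] + semi_axes[1] * np.sin(theta)]
    )


def _metrics_from_axes(
    ed_axes: tuple[float, float],
    es_axes: tuple[float, float],
    wall: float,
) -> dict[str, float]:
    """Closed-form metric values for elliptical pool + annulus geometry."""
    edba = np.pi * ed_axes[0] * ed_axes[1]
    esba = np.pi * es_axes[0] * es_axes[1]
    teda = np.pi * (ed_axes[0] + wall) * (ed_axes[1] + wall)
    tesa = np.pi * (es_axes[0] + wall) * (es_axes[1] + wall)
    return {
        "tEDA": teda,
        "tESA": tesa,
        "delta_pct_tA": 100.0 * (teda - tesa) / teda,
        "EDBA": edba,
        "ESBA": esba,
        "SA": edba - esba,
        "EF": 100.0 * (edba - esba) / edba,
        "MMI": tesa - esba,
    }


def simulate_heart_series(
    params: PhantomParams,
) -> tuple[ImageSeries, RoiSet, GroundTruth]:
    """Render one phantom series with its ROI sidecar and ground truth.

    The ROI set holds 64-gon outlines of the outer (wall) ellipse at every
    frame where the analytic blood area attains its maximum or minimum, so
    whichever cycle the pipeline's phase selection lands on has an outline.
    """
    params.validate()
    h, w = params.image_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a_ed, b_ed = params.blood_semi_axes_ed
    a_es, b_es = params.blood_semi_axes_es
    wall = params.wall_thickness_px

    t = np.arange(params.n_frames) * params.interframe_interval_s
    s = (1.0 + np.cos(2.0 * np.pi * params.heart_rate_hz * t)) / 2.0
    a_t = a_es + (a_ed - a_es) * s
    b_t = b_es + (b_ed - b_es) * s
    area = np.pi * a_t * b_t

    tol = 1e-9 * max(1.0, float(area.max()))
    ed_frames = np.flatnonzero(area >= area.max() - tol)
    es_frames = np.flatnonzero(area <= area.min() + tol)

    full = 2**14 - 1  # 14-bit camera data in a 16-bit container
    bright = BRIGHT_FRACTION * full
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(params.seed)
    frames = np.empty((params.n_frames, h, w, 2), dtype=np.uint16)
    for i in range(params.n_frames):
        blood = ((xx - cx) / a_t[i]) ** 2 + ((yy - cy) / b_t[i]) ** 2 <= 1.0
        outer = ((xx - cx) / (a_t[i] + wall)) ** 2 + (
            (yy - cy) / (b_t[i] + wall)
        ) ** 2 <= 1.0
        k = np.zeros((h, w))
        k[outer] = params.myocardium_absorption
        k[blood] = params.hb_absorption
        weak = np.full((h, w), bright)
        strong = bright * np.exp(-k)
        img = np.stack([weak, strong], axis=-1)
        img = img + rng.normal(0.0, params.noise_sd * bright, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 2**16 - 1).astype(np.uint16)

    series = ImageSeries(
        frames=frames,
        bit_depth=16,
        interframe_interval_s=params.interframe_interval_s,
        channel_names=("red", "green"),
        source_id=f"phantom(seed={params.seed})",
    )

    entries = {}
    for fi in np.concatenate([ed_frames, es_frames]):
        entries[int(fi)] = _ellipse_polygon(
            (cx, cy), (a_t[fi] + wall, b_t[fi] + wall)
        )
    rois = RoiSet(entries=entries, image_shape=(h, w))

    m = _metrics_from_axes((a_ed, b_ed), (a_es, b_es), wall)
    truth = GroundTruth(
        blood_area_trace=area,
        phase=s,
        tEDA_true=m["tEDA"],
        tESA_true=m["tESA"],
        delta_pct_tA_true=m["delta_pct_tA"],
        EDBA_true=m["EDBA"],
        ESBA_true=m["ESBA"],
        SA_true=m["SA"],
        EF_true=m["EF"],
        MMI_true=m["MMI"],
        ed_frame=int(ed_frames[0]),
        es_frame=int(es_frames[0]),
        ed_frames=ed_frames,
        es_frames=es_frames,
    )
    return series, rois, truth


#: PhantomParams fields a cohort effect may scale
_SCALABLE = {
    "blood_semi_axes_ed",
    "blood_semi_axes_es",
    "wall_thickness_px",
    "hb_absorption",
    "myocardium_absorption",
    "noise_sd",
    "heart_rate_hz",
}


def _apply_effect(params: PhantomParams, effect: dict[str, float]) -> PhantomParams:
    changes: dict = {}
    for key, mult in effect.items():
        if key not in _SCALABLE:
            raise ParameterError(f"effect on unknown/unscalable parameter {key!r}")
        value = getattr(params, key)
        if isinstance(value, tuple):
            changes[key] = tuple(v * mult for v in value)
        else:
            changes[key] = value * mult
    return dataclasses.replace(params, **changes)


@dataclass
class CohortResult:
    """Ground-truth metrics table and (optionally) the rendered embryos."""

    truth_table: pd.DataFrame
    embryos: dict[str, tuple[ImageSeries, RoiSet, GroundTruth]] | None = None


def simulate_cohort(
    control: PhantomParams,
    effects: dict[str, dict[str, float]],
    n_per_group: int,
    base_seed: int = 0,
    render_images: bool = False,
) -> CohortResult:
    """Simulate a labeled cohort: a control group plus one group per effect.

    ``effects`` maps group name -> {parameter: multiplier}; the control group
    is always present with no effect.  Per-embryo biological variability is
    lognormal with sd 5%: one size factor per blood-pool axis (shared by the
    ED and ES values of that axis, so hearts vary in size and shape) and one
    contractility factor on the ES axes (so ejection fraction varies).
    Factors come from a stream seeded deterministically by (base_seed, group
    index, embryo index), so cohorts are reproducible and embryos
    independent.  With
    ``render_images=False`` only the analytic ground-truth table is built,
    which keeps large replicate studies cheap.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    groups = {"control": {}, **effects}
    rows = []
    embryos: dict[str, tuple[ImageSeries, RoiSet, GroundTruth]] = {}
    for gi, (gname, effect) in enumerate(groups.items()):
        group_params = _apply_effect(control, effect)
        for ei in range(n_per_group):
            embryo_id = f"{gname}_{ei:03d}"
            ss = np.random.SeedSequence([int(base_seed), gi, ei])
            rng = np.random.default_rng(ss)
            # anatomical size factors (per axis, shared by ED and ES) plus a
            # contractility factor on the ES axes; all lognormal, sd 5%
            size_a, size_b, contract = np.exp(
                rng.normal(0.0, EMBRYO_JITTER_SD, size=3)
            )
            a_ed, b_ed = group_params.blood_semi_axes_ed
            a_es, b_es = group_params.blood_semi_axes_es
            embryo_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31))
            p = dataclasses.replace(
                group_params,
                blood_semi_axes_ed=(a_ed * size_a, b_ed * size_b),
                blood_semi_axes_es=(
                    a_es * size_a * contract,
                    b_es * size_b * contract,
                ),
                seed=embryo_seed,
            )
            try:
                p.validate()
            except ParameterError as exc:
                raise ParameterError(f"embryo {embryo_id}: {exc}") from exc
            m = _metrics_from_axes(
                p.blood_semi_axes_ed, p.blood_semi_axes_es, p.wall_thickness_px
            )
            t = np.arange(p.n_frames) * p.interframe_interval_s
            area = np.pi * (
                p.blood_semi_axes_es[0]
                + (p.blood_semi_axes_ed[0] - p.blood_semi_axes_es[0])
                * (1 + np.cos(2 * np.pi * p.heart_rate_hz * t)) / 2
            ) * (
                p.blood_semi_axes_es[1]
                + (p.blood_semi_axes_ed[1] - p.blood_semi_axes_es[1])
                * (1 + np.cos(2 * np.pi * p.heart_rate_hz * t)) / 2
            )
            rows.append(
                {
                    "embryo_id": embryo_id,
                    "group": gname,
                    **m,
                    "ed_frame": int(np.argmax(area)),
                    "es_frame": int(np.argmin(area)),
                    "seed": embryo_seed,
                }
            )
            if render_images:
                embryos[embryo_id] = simulate_heart_series(p)
    table = pd.DataFrame(rows)
    return CohortResult(truth_table=table, embryos=embryos if render_images else None)
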