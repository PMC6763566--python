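"""Reading and writing image series, ROI sidecars, configs and result tables.

Supported image containers are numbered single-frame PNG/TIFF files (ordered
by their numeric suffix) and single multi-page TIFF stacks, 8- or 16-bit,
one or three channels (the synthetic phantoms use two).  14-bit camera data
is expected pre-converted into a 16-bit container; intensities are never
rescaled on read, and ``bit_depth`` records the container depth.

Ventricle outlines travel in a plain-text sidecar, one vertex per line::

    #hcsa-roi v1 shape=<height>x<width>
    frame_index,vertex_index,x,y

Coordinates are 0-based, x rightward, y downward, at pixel centers; a
frame's vertices are consecutive and ordered, and the polygon is implicitly
closed.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BoundsError,
    ConfigError,
    DegeneratePolygonError,
    EmptyResultsError,
    InsufficientFramesError,
    InvalidPolygonError,
    ShapeMismatchError,
)

ROI_HEADER_PREFIX = "#hcsa-roi v1"

#: canonical column order of a per-embryo metrics table
METRICS_COLUMNS = [
    "embryo_id",
    "group",
    "tEDA",
    "tESA",
    "delta_pct_tA",
    "EDBA",
    "ESBA",
    "SA",
    "EF",
    "MMI",
    "ed_frame",
    "es_frame",
]


@dataclass
class ImageSeries:
    """An ordered stack of equally shaped frames.

    frames has shape (n_frames, height, width) or
    (n_frames, height, width, n_channels).
    """

    frames: np.ndarray
    bit_depth: int
    interframe_interval_s: float = 0.2
    channel_names: tuple[str, ...] = ()
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ShapeMismatchError(
                f"frames must be (T, H, W[, C]); got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise InsufficientFramesError(
                f"an image series needs >= 2 frames; got {self.n_frames}"
            )
        if not 8 <= self.bit_depth <= 16:
            raise ConfigError(f"bit_depth must be in [8, 16]; got {self.bit_depth}")
        if self.interframe_interval_s <= 0:
            raise ConfigError("interframe_interval_s must be > 0")
        if np.issubdtype(self.frames.dtype, np.integer):
            hi = 2**self.bit_depth - 1
            if self.frames.min() < 0 or self.frames.max() > hi:
                raise ConfigError(
                    f"intensities outside [0, {hi}] for bit_depth {self.bit_depth}"
                )
        if self.n_channels > 1 and len(self.channel_names) != self.n_channels:
            raise ConfigError(
                f"{self.n_channels} channels need {self.n_channels} channel_names; "
                f"got {self.channel_names!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return one channel as a (T, H, W) array."""
        if self.frames.ndim == 3:
            return self.frames
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise ConfigError(
                    f"unknown channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.frames[..., idx]


def _validate_polygon(vertices: np.ndarray, image_shape: tuple[int, int]) -> None:
    import shapely.geometry as sg

    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise DegeneratePolygonError(
            f"polygon needs >= 3 (x, y) vertices; got shape {vertices.shape}"
        )
    h, w = image_shape
    if (
        vertices[:, 0].min() < 0
        or vertices[:, 0].max() > w - 1
        or vertices[:, 1].min() < 0
        or vertices[:, 1].max() > h - 1
    ):
        raise BoundsError(
            f"vertex outside image bounds {h}x{w}: "
            f"x in [{vertices[:, 0].min()}, {vertices[:, 0].max()}], "
            f"y in [{vertices[:, 1].min()}, {vertices[:, 1].max()}]"
        )
    if not sg.Polygon(vertices).is_valid:
        raise InvalidPolygonError("polygon is self-intersecting or degenerate")


@dataclass
class RoiSet:
    """Per-frame ventricle boundary polygons drawn on one image shape."""

    entries: dict[int, np.ndarray]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.entries = {
            int(k): np.asarray(v, dtype=float) for k, v in self.entries.items()
        }
        self.image_shape = (int(self.image_shape[0]), int(self.image_shape[1]))
        for idx, verts in self.entries.items():
            if idx < 0:
                raise BoundsError(f"negative frame index {idx} in ROI set")
            _validate_polygon(verts, self.image_shape)

    def __contains__(self, frame_index: int) -> bool:
        return int(frame_index) in self.entries

    def __getitem__(self, frame_index: int) -> np.ndarray:
        return self.entries[int(frame_index)]

    def frames(self) -> list[int]:
        return sorted(self.entries)


@dataclass
class RunConfig:
    """Pipeline configuration with the defaults used throughout.

    channel_roles maps the spectral roles to channel names: the strong
    channel is the one hemoglobin attenuates most (green for whole-blood
    imaging), the weak channel the least (red).
    """

    channel_roles: dict[str, str] = field(
        default_factory=lambda: {"strong": "green", "weak": "red"}
    )
    contrast_mode: str = "channel_difference"
    otsu_bins: int = 256
    otsu_pooling: str = "pooled_over_selected_frames"
    phase_selection: str = "auto"
    ed_frame: int | None = None
    es_frame: int | None = None
    smoothing_window: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.contrast_mode not in ("channel_difference", "single_channel_inverted"):
            raise ConfigError(f"unknown contrast_mode {self.contrast_mode!r}")
        if self.otsu_pooling not in ("pooled_over_selected_frames", "per_frame"):
            raise ConfigError(f"unknown otsu_pooling {self.otsu_pooling!r}")
        if self.phase_selection not in ("auto", "manual"):
            raise ConfigError(f"unknown phase_selection {self.phase_selection!r}")
        if self.otsu_bins < 2:
            raise ConfigError("otsu_bins must be >= 2")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError("smoothing_window must be an odd integer >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.phase_selection == "manual" and (
            self.ed_frame is None or self.es_frame is None
        ):
            raise ConfigError("manual phase_selection needs ed_frame and es_frame")


_CONFIG_KEYS = {
    "strong_channel",
    "weak_channel",
    "contrast_mode",
    "otsu_bins",
    "otsu_pooling",
    "phase_selection",
    "ed_frame",
    "es_frame",
    "smoothing_window",
    "alpha",
}


def read_config(path: str | os.PathLike) -> RunConfig:
    """Parse a flat key=value config file; unknown keys are an error."""
    kwargs: dict = {}
    roles = {"strong": "green", "weak": "red"}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in _CONFIG_KEYS:
                raise ConfigError(f"{path}:{ln}: unknown config key {key!r}")
            if key in ("strong_channel", "weak_channel"):
                roles[key.split("_")[0]] = value
            elif key in ("otsu_bins", "smoothing_window", "ed_frame", "es_frame"):
                kwargs[key] = int(value)
            elif key == "alpha":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return RunConfig(channel_roles=roles, **kwargs)


def write_config(config: RunConfig, path: str | os.PathLike) -> None:
    lines = [
        f"strong_channel={config.channel_roles['strong']}",
        f"weak_channel={config.channel_roles['weak']}",
        f"contrast_mode={config.contrast_mode}",
        f"otsu_bins={config.otsu_bins}",
        f"otsu_pooling={config.otsu_pooling}",
        f"phase_selection={config.phase_selection}",
        f"smoothing_window={config.smoothing_window}",
        f"alpha={config.alpha}",
    ]
    if config.ed_frame is not None:
        lines.append(f"ed_frame={config.ed_frame}")
    if config.es_frame is not None:
        lines.append(f"es_frame={config.es_frame}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_NUM_SUFFIX = re.compile(r"(\d+)(?=\.[A-Za-z]+$)")


def _numeric_key(name: str) -> tuple:
    m = _NUM_SUFFIX.search(os.path.basename(name))
    return (int(m.group(1)), name) if m else (float("inf"), name)


def _infer_bit_depth(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ConfigError(f"unsupported image dtype {dtype}; expected uint8 or uint16")


def read_image_series(
    path_spec: str | os.PathLike,
    config: RunConfig | None = None,
    interframe_interval_s: float | None = None,
) -> ImageSeries:
    """Load an image series from numbered PNG/TIFF files or one multi-page TIFF.

    ``path_spec`` may be a directory, a glob pattern, or a single stack file.
    Frames are ordered by their filename's numeric suffix (or page order) and
    intensities are taken as-is.
    """
    path_spec = os.fspath(path_spec)
    if os.path.isfile(path_spec):
        return _read_stack_file(path_spec, interframe_interval_s)
    if os.path.isdir(path_spec):
        names = [
            os.path.join(path_spec, n)
            for n in os.listdir(path_spec)
            if n.lower().endswith((".png", ".tif", ".tiff"))
        ]
    else:
        names = glob.glob(path_spec)
    if not names:
        raise IOError(f"no image files match {path_spec!r}")
    names.sort(key=_numeric_key)
    if len(names) < 2:
        raise InsufficientFramesError(
            f"found {len(names)} frame(s) at {path_spec!r}; need >= 2"
        )
    frames = []
    for name in names:
        try:
            arr = iio.imread(name)
        except Exception as exc:  # pragma: no cover - propagated with path
            raise IOError(f"cannot read frame {name!r}: {exc}") from exc
        if frames and arr.shape != frames[0].shape:
            raise ShapeMismatchError(
                f"frame {name!r} has shape {arr.shape}, expected {frames[0].shape}"
            )
        frames.append(arr)
    stack = np.stack(frames)
    names_c = _default_channel_names(stack)
    return ImageSeries(
        frames=stack,
        bit_depth=_infer_bit_depth(stack.dtype),
        interframe_interval_s=interframe_interval_s or 0.2,
        channel_names=names_c,
        source_id=path_spec,
    )


def _default_channel_names(stack: np.ndarray) -> tuple[str, ...]:
    if stack.ndim == 3:
        return ()
    n = stack.shape[3]
    if n == 3:
        return ("red", "green", "blue")
    if n == 2:
        return ("red", "green")
    return tuple(f"ch{i}" for i in range(n))


def _read_stack_file(path: str, interframe_interval_s: float | None) -> ImageSeries:
    if not path.lower().endswith((".tif", ".tiff")):
        raise IOError(f"stack files must be TIFF; got {path!r}")
    try:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description or ""
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    meta: dict = {}
    if desc.strip().startswith("{"):
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if stack.ndim == 2:
        raise InsufficientFramesError(f"{path!r} holds a single frame; need >= 2")
    channel_names = tuple(meta.get("channel_names", ())) or _default_channel_names(
        stack
    )
    return ImageSeries(
        frames=stack,
        bit_depth=int(meta.get("bit_depth", _infer_bit_depth(stack.dtype))),
        interframe_interval_s=(
            interframe_interval_s
            or float(meta.get("interframe_interval_s", 0.2))
        ),
        channel_names=channel_names,
        source_id=str(meta.get("source_id", path)),
    )


def write_image_series(series: ImageSeries, path: str | os.PathLike) -> None:
    """Write a series as a multi-page TIFF (``.tif``/``.tiff``) or a directory
    of numbered 16-bit PNG frames (single-channel data only)."""
    path = os.fspath(path)
    meta = {
        "bit_depth": series.bit_depth,
        "interframe_interval_s": series.interframe_interval_s,
        "channel_names": list(series.channel_names),
        "source_id": series.source_id,
    }
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(
            path,
            series.frames,
            photometric="minisblack",
            planarconfig="contig" if series.frames.ndim == 4 else None,
            description=json.dumps(meta),
        )
        return
    if series.frames.ndim == 4 and series.frames.shape[3] not in (3, 4):
        raise ConfigError("PNG export supports 1- or 3-channel frames; use TIFF")
    os.makedirs(path, exist_ok=True)
    width = max(3, len(str(series.n_frames - 1)))
    for i in range(series.n_frames):
        iio.imwrite(os.path.join(path, f"frame_{i:0{width}d}.png"), series.frames[i])
    with open(os.path.join(path, "series_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_roi(path: str | os.PathLike) -> RoiSet:
    """Parse a v1 ROI sidecar file into a validated :class:`RoiSet`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(ROI_HEADER_PREFIX):
            raise IOError(
                f"{path}: missing {ROI_HEADER_PREFIX!r} header (got {header!r})"
            )
        m = re.search(r"shape=(\d+)x(\d+)", header)
        if not m:
            raise IOError(f"{path}: header lacks shape=HxW")
        image_shape = (int(m.group(1)), int(m.group(2)))
        rows: dict[int, list[tuple[int, float, float]]] = {}
        for ln, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise IOError(f"{path}:{ln}: expected frame,vertex,x,y")
            fi, vi = int(parts[0]), int(parts[1])
            rows.setdefault(fi, []).append((vi, float(parts[2]), float(parts[3])))
    entries = {}
    for fi, verts in rows.items():
        verts.sort(key=lambda t: t[0])
        entries[fi] = np.array([(x, y) for _, x, y in verts], dtype=float)
    return RoiSet(entries=entries, image_shape=image_shape)


def write_roi(rois: RoiSet, path: str | os.PathLike) -> None:
    h, w = rois.image_shape
    lines = [f"{ROI_HEADER_PREFIX} shape={h}x{w}"]
    for fi in rois.frames():
        for vi, (x, y) in enumerate(rois[fi]):
            lines.append(f"{fi},{vi},{x:.10g},{y:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def metrics_to_frame(results: Sequence) -> pd.DataFrame:
    """Assemble VentricleMetrics-like records into the canonical table."""
    if not results:
        raise EmptyResultsError("no embryo metrics to tabulate")
    rows = []
    for r in results:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        rows.append({c: d[c] for c in METRICS_COLUMNS})
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_table(results: Sequence, path: str | os.PathLike) -> None:
    """One row per embryo; numeric fields keep >= 6 significant digits."""
    df = results if isinstance(results, pd.DataFrame) else metrics_to_frame(results)
    if df.empty:
        raise EmptyResultsError("no embryo metrics to write")
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise IOError(f"{path}: metrics table lacks columns {missing}")
    return df
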