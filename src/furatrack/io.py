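"""Readers and writers for the pipeline's standard artifacts.

Channels are stored as plain multi-page grayscale TIFF (one file per
excitation wavelength) with a JSON sidecar for acquisition metadata;
event tables are RFC-4180 CSV with a mandatory header (session metadata
in leading ``#`` comment lines); renders are lossless PNG.

Conventions: frame indexing is 0-based; times in seconds are
``t0_s + frame * dt_s``; centroids are (row, col), 0-based pixel units;
float CSV fields are serialized with 6 significant digits.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ShapeError, ValidationError
from .events import EventTable, TransientEvent
from .stacks import ImagePairStack

PathLike = Union[str, Path]

#: fixed CSV column order for event tables
EVENT_COLUMNS = [
    "id",
    "onset_frame",
    "offset_frame",
    "duration_s",
    "centroid_row",
    "centroid_col",
    "area_px",
    "peak_delta_ratio",
    "label",
]

_SIDECAR_NAME = "stack_meta.json"


def _read_tiff_stack(path: PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted exception types
        raise FormatError(f"could not read {path} as TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.size == 0:
        raise FormatError(f"{path} is not a grayscale multi-page stack (shape {arr.shape})")
    return arr


def read_pair_stack(
    path_340: PathLike,
    path_380: PathLike,
    dt_s: float,
    reference_path: Optional[PathLike] = None,
    t0_s: float = 0.0,
    meta: Optional[dict] = None,
) -> ImagePairStack:
    """Read paired 340/380-nm multi-page TIFF stacks.

    Integer TIFF values are preserved bit-exactly.  Raises
    :class:`ShapeError` when the two stacks disagree in frame count or
    spatial dimensions, :class:`FormatError` for unreadable files and
    :class:`ValidationError` for a non-positive ``dt_s``.
    """
    if not (dt_s > 0):
        raise ValidationError(f"dt_s must be > 0; got {dt_s}")
    f340 = _read_tiff_stack(path_340)
    f380 = _read_tiff_stack(path_380)
    if f340.shape != f380.shape:
        raise ShapeError(
            f"stack shapes differ: {path_340} has {f340.shape}, "
            f"{path_380} has {f380.shape}"
        )
    reference = None
    if reference_path is not None:
        ref = _read_tiff_stack(reference_path)
        if ref.shape[0] != 1:
            raise ShapeError(f"reference {reference_path} must be a single image")
        reference = ref[0]
    return ImagePairStack(
        f340=f340, f380=f380, dt_s=dt_s, t0_s=t0_s,
        reference_540=reference, meta=dict(meta or {}),
    )


def write_pair_stack(
    stack: ImagePairStack,
    directory: PathLike,
    quantize_scale: Optional[float] = None,
) -> dict[str, Path]:
    """Write a stack as ``f340.tif`` + ``f380.tif`` + JSON sidecar.

    Integer stacks round-trip exactly through :func:`read_pair_dir`.
    With ``quantize_scale`` set, float channels are stored as 16-bit
    ``round(value / scale)`` — the round-trip error is at most
    ``scale / 2`` per pixel; the scale is recorded in the sidecar and
    undone on read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    sidecar: dict = {
        "dt_s": stack.dt_s,
        "t0_s": stack.t0_s,
        "meta": dict(stack.meta),
        "quantize_scale": quantize_scale,
    }

    def _prepare(arr: np.ndarray) -> np.ndarray:
        if quantize_scale is not None:
            if not (quantize_scale > 0):
                raise ValidationError("quantize_scale must be > 0")
            q = np.round(np.asarray(arr, dtype=np.float64) / quantize_scale)
            if q.max() > np.iinfo(np.uint16).max:
                raise ValidationError(
                    "quantize_scale too small: values exceed 16-bit range"
                )
            return q.astype(np.uint16)
        return np.asarray(arr)

    for name, arr in (("f340", stack.f340), ("f380", stack.f380)):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, _prepare(arr), photometric="minisblack")
        paths[name] = p
    if stack.reference_540 is not None:
        p = directory / "reference_540.tif"
        tifffile.imwrite(p, np.asarray(stack.reference_540), photometric="minisblack")
        paths["reference_540"] = p
        sidecar["reference"] = p.name
    sidecar_path = directory / _SIDECAR_NAME
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sidecar_path
    return paths


def read_pair_dir(directory: PathLike) -> ImagePairStack:
    """Read back a directory produced by :func:`write_pair_stack`."""
    directory = Path(directory)
    sidecar_path = directory / _SIDECAR_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt sidecar {sidecar_path}: {exc}") from exc
    ref_path = directory / sidecar["reference"] if "reference" in sidecar else None
    stack = read_pair_stack(
        directory / "f340.tif",
        directory / "f380.tif",
        dt_s=float(sidecar["dt_s"]),
        reference_path=ref_path,
        t0_s=float(sidecar.get("t0_s", 0.0)),
        meta=sidecar.get("meta", {}),
    )
    scale = sidecar.get("quantize_scale")
    if scale is not None:
        stack.f340 = stack.f340.astype(np.float64) * scale
        stack.f380 = stack.f380.astype(np.float64) * scale
    return stack


def write_event_table(table: EventTable, path: PathLike) -> Path:
    """Write an event table as CSV (header always present).

    Session metadata travels in leading ``# key=value`` comment lines so
    the file alone suffices to recompute every downstream statistic.
    Float fields use 6 significant digits.
    """
    path = Path(path)
    rows = [
        {
            "id": e.id,
            "onset_frame": e.onset_frame,
            "offset_frame": e.offset_frame,
            "duration_s": e.duration_s,
            "centroid_row": e.centroid[0],
            "centroid_col": e.centroid[1],
            "area_px": e.area_px,
            "peak_delta_ratio": e.peak_delta_ratio,
            "label": e.label,
        }
        for e in table.events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    header_lines = [
        f"# dt_s={table.dt_s!r}",
        f"# t0_s={table.t0_s!r}",
        f"# n_frames={table.n_frames}",
        f"# height={table.height}",
        f"# width={table.width}",
    ]
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(header_lines) + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path


def read_event_table(path: PathLike) -> EventTable:
    """Read back a CSV written by :func:`write_event_table`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    required = {"dt_s", "t0_s", "n_frames", "height", "width"}
    if not required.issubset(meta):
        raise FormatError(f"{path} lacks session metadata lines {sorted(required - set(meta))}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(f"{path} has unexpected columns {list(df.columns)}")
    events = [
        TransientEvent(
            id=int(r.id),
            onset_frame=int(r.onset_frame),
            offset_frame=int(r.offset_frame),
            duration_s=float(r.duration_s),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            area_px=int(r.area_px),
            peak_delta_ratio=float(r.peak_delta_ratio),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
    return EventTable(
        events=events,
        dt_s=float(meta["dt_s"]),
        t0_s=float(meta["t0_s"]),
        n_frames=int(meta["n_frames"]),
        height=int(meta["height"]),
        width=int(meta["width"]),
    )


def render_frame_png(rgb_frame: np.ndarray, path: PathLike) -> Path:
    """Write an 8-bit RGB frame as lossless PNG (read-back equals input)."""
    rgb_frame = np.asarray(rgb_frame)
    if rgb_frame.dtype != np.uint8:
        raise ValidationError(f"frame must be uint8; got dtype {rgb_frame.dtype}")
    if rgb_frame.ndim != 3 or rgb_frame.shape[2] != 3:
        raise ValidationError(f"frame must be (height, width, 3); got shape {rgb_frame.shape}")
    path = Path(path)
    iio.imwrite(path, rgb_frame, extension=".png")
    return path


def read_frame_png(path: PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return np.asarray(iio.imread(path))
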