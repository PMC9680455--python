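"""Readers/writers for images, stacks, tables and JSON summaries."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError
from .viability import ZStack

SCHEMA_VERSION = "1"

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_series_csv",
    "write_table",
    "write_json",
]


def read_image(path) -> np.ndarray:
    """Read a single TIFF/PNG image as a numpy array."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"could not read image {path}: {exc}") from exc


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_stack(
    path,
    n_planes: int = 6,
    n_channels: int = 2,
    channel_roles: dict | None = None,
    z_range_um: float = 100.0,
) -> ZStack:
    """Read a plane-major multi-page TIFF as a :class:`ZStack`.

    Pages are expected in plane-major order (plane 0 channel 0, plane 0
    channel 1, plane 1 channel 0, ...), or already shaped
    ``(planes, channels, H, W)``.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read stack {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[0] != n_planes * n_channels:
            raise FormatError(
                f"{path}: expected {n_planes * n_channels} pages "
                f"({n_planes} planes x {n_channels} channels), got {arr.shape[0]}"
            )
        arr = arr.reshape(n_planes, n_channels, *arr.shape[1:])
    elif arr.ndim == 4:
        if arr.shape[0] != n_planes or arr.shape[1] != n_channels:
            raise FormatError(
                f"{path}: expected shape ({n_planes}, {n_channels}, H, W), got {arr.shape}"
            )
    else:
        raise FormatError(f"{path}: unsupported stack dimensionality {arr.ndim}")
    roles = channel_roles or {"green": 0, "red": 1}
    return ZStack(intensities=arr, channel_roles=roles, z_range_um=z_range_um)


def write_stack(stack: ZStack, path) -> None:
    """Write a :class:`ZStack` as a plane-major multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    p, c, h, w = stack.intensities.shape
    tifffile.imwrite(path, stack.intensities.reshape(p * c, h, w))


def read_series_csv(path) -> pd.DataFrame:
    """Read a filament time series CSV.

    Required columns: ``t_s, theta1_deg, theta2_deg, diameter_mm``;
    optional: ``gap_mm, temperature_label``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read CSV {path}: {exc}") from exc
    required = {"t_s", "theta1_deg", "theta2_deg", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_table(records, path) -> None:
    """Write dataclasses/dicts as a UTF-8 comma-separated table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [_to_plain(r) for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(summary, path) -> None:
    """Write a JSON summary carrying a ``schema_version`` field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_to_plain(summary))
    path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n", encoding="utf-8")
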