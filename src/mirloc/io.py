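"""Readers and writers for stacks, localization tables, masks and configs."""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    DEFAULT_PIXEL_SIZE_NM,
    LOC_COLUMNS,
    ImageStack,
    LocalizationTable,
    RegionSet,
)


class FormatError(ValueError):
    """Raised for files that are readable but not in the expected layout."""


class ParseError(ValueError):
    """Raised for malformed localization tables; names the offending line."""


def read_stack(path: str | os.PathLike, pixel_size_nm: float | None = None,
               integration_time_ms: float = 50.0) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    ``pixel_size_nm`` overrides any value stored in the TIFF metadata; if
    neither is available the package default (100 nm) is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise FormatError(f"{path}: expected grayscale pages, got "
                              f"{page.samplesperpixel} samples per pixel")
        try:
            arr = tf.asarray()
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: could not assemble stack: {exc}") from exc
        meta = tf.shaped_metadata
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if pixel_size_nm is None:
        pixel_size_nm = DEFAULT_PIXEL_SIZE_NM
        if meta:
            for m in meta:
                if isinstance(m, dict) and "pixel_size_nm" in m:
                    pixel_size_nm = float(m["pixel_size_nm"])
    return ImageStack(arr, pixel_size_nm=pixel_size_nm,
                      integration_time_ms=integration_time_ms)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack to multi-page TIFF; pixel size goes into shaped metadata."""
    frames = stack.frames
    if frames.dtype.kind == "f":
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack",
                     metadata={"pixel_size_nm": stack.pixel_size_nm})


def write_localizations(table: LocalizationTable, path: str | os.PathLike) -> None:
    """Write a localization table to CSV (one row per event, nm units)."""
    df = table.data.copy()
    df["frame"] = df["frame"].astype(int)
    df.to_csv(path, index=False, float_format="%.6f")


def read_localizations(path: str | os.PathLike) -> LocalizationTable:
    """Read a localization CSV written by :func:`write_localizations`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    out = {}
    for col in LOC_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based line numbers
            raise ParseError(f"{path}: non-numeric value in column "
                             f"'{col}' at line {bad[0] + 2}")
        out[col] = values.astype(float)
    return LocalizationTable(pd.DataFrame(out))


def read_mask(path: str | os.PathLike, pixel_size_nm: float,
              origin_nm: tuple[float, float] = (0.0, 0.0)) -> RegionSet:
    """Read a label image (TIFF or PNG) as a :class:`RegionSet`."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label mask must be single-channel 2-D")
    return RegionSet(arr.astype(int), pixel_size_nm=pixel_size_nm, origin_nm=origin_nm)


def write_mask(regions: RegionSet, path: str | os.PathLike) -> None:
    path = Path(path)
    arr = regions.labels.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single-frame grayscale image (wide-field reference channel)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D image")
    return np.asarray(arr, dtype=float)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
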