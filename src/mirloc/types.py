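"""Core domain types and the coordinate convention used throughout.

Coordinate convention
---------------------
Images are indexed ``(i, j)`` with ``i`` the row (y) and ``j`` the column
(x); the origin is the top-left corner of the image.  Pixel ``(i, j)``
covers the square ``[j*a, (j+1)*a) x [i*a, (i+1)*a)`` in nanometres, where
``a`` is the pixel pitch in the object plane, so the pixel *center* sits at
``((j + 0.5)*a, (i + 0.5)*a)``.  All localization coordinates are 0-based
nanometres in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: column order of the on-disk localization table
LOC_COLUMNS = (
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "psf_sigma_nm",
    "background",
    "precision_nm",
)

#: default object-plane pixel pitch (nm) when no metadata is available
DEFAULT_PIXEL_SIZE_NM = 100.0


@dataclass(frozen=True)
class CameraModel:
    """EMCCD counts <-> photons mapping.

    ``counts_per_photon`` lumps the electron-multiplying gain and the
    analog-digital conversion into a single factor; ``offset_counts`` is the
    camera baseline and ``read_noise_counts`` the Gaussian readout noise
    standard deviation, both in raw counts.
    """

    offset_counts: float = 100.0
    counts_per_photon: float = 10.0
    read_noise_counts: float = 10.0

    def __post_init__(self) -> None:
        if self.counts_per_photon <= 0:
            raise ValueError("counts_per_photon must be > 0")
        if self.offset_counts < 0:
            raise ValueError("offset_counts must be >= 0")
        if self.read_noise_counts < 0:
            raise ValueError("read_noise_counts must be >= 0")


@dataclass
class ImageStack:
    """A T x H x W stack of non-negative camera counts.

    ``pixel_size_nm`` is the object-plane pixel pitch; ``integration_time_ms``
    the per-frame exposure.
    """

    frames: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    integration_time_ms: float = 50.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("camera counts must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass(frozen=True)
class Localization:
    """One fitted single-molecule event."""

    x_nm: float
    y_nm: float
    photons: float
    psf_sigma_nm: float
    background_photons_per_px: float
    precision_nm: float
    frame_index: int
    cell_id: int | None = None

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be > 0")
        if self.precision_nm <= 0:
            raise ValueError("precision_nm must be > 0")


class LocalizationTable:
    """Ordered collection of localizations with a bounding region (nm).

    Backed by a :class:`pandas.DataFrame` with the columns of
    :data:`LOC_COLUMNS`.  ``bounds`` is ``(xmin, ymin, xmax, ymax)`` in nm and
    always contains every position; ``meta`` records provenance (source
    stack, parameters).
    """

    def __init__(
        self,
        data: pd.DataFrame | None = None,
        bounds: tuple[float, float, float, float] | None = None,
        meta: dict | None = None,
    ) -> None:
        if data is None:
            data = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
        missing = [c for c in LOC_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        self.data = data.loc[:, list(LOC_COLUMNS)].reset_index(drop=True)
        if bounds is None:
            bounds = self._extent()
        self.bounds = bounds
        self.meta = dict(meta or {})
        if len(self) and bounds is not None:
            x, y = self.data["x_nm"].to_numpy(), self.data["y_nm"].to_numpy()
            xmin, ymin, xmax, ymax = bounds
            if (x < xmin).any() or (x > xmax).any() or (y < ymin).any() or (y > ymax).any():
                raise ValueError("localizations fall outside the bounding region")

    def _extent(self) -> tuple[float, float, float, float] | None:
        if not len(self.data):
            return None
        x = self.data["x_nm"].to_numpy()
        y = self.data["y_nm"].to_numpy()
        return (float(x.min()), float(y.min()), float(x.max()), float(y.max()))

    @classmethod
    def from_localizations(
        cls,
        locs: Sequence[Localization],
        bounds: tuple[float, float, float, float] | None = None,
        meta: dict | None = None,
    ) -> "LocalizationTable":
        rows = [
            (l.frame_index, l.x_nm, l.y_nm, l.photons, l.psf_sigma_nm,
             l.background_photons_per_px, l.precision_nm)
            for l in locs
        ]
        df = pd.DataFrame(rows, columns=list(LOC_COLUMNS), dtype=float)
        return cls(df, bounds=bounds, meta=meta)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x_nm, y_nm)."""
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[Localization]:
        for row in self.data.itertuples(index=False):
            yield Localization(
                x_nm=row.x_nm,
                y_nm=row.y_nm,
                photons=row.photons,
                psf_sigma_nm=row.psf_sigma_nm,
                background_photons_per_px=row.background,
                precision_nm=row.precision_nm,
                frame_index=int(row.frame),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocalizationTable):
            return NotImplemented
        return len(self) == len(other) and bool(
            np.allclose(self.data.to_numpy(float), other.data.to_numpy(float))
        )


# compartment labels of the segmentation mask
LABEL_EXTRACELLULAR = 0
LABEL_NUCLEUS = 1
LABEL_CYTOPLASM = 2


@dataclass
class RegionSet:
    """Compartment label mask with a wide-field -> nm georeference.

    ``labels`` is an integer image with 0 = extracellular, 1 = nucleus,
    2 = cytoplasm + membrane.  ``origin_nm`` is the nm position of the
    top-left corner of mask pixel (0, 0); any nm point outside the mask
    footprint maps to label 0.
    """

    labels: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"mask labels must be in {{0,1,2}}, found {sorted(bad)}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")

    def label_at(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Vectorised point-in-mask lookup; outside the footprint -> 0."""
        x = np.atleast_1d(np.asarray(x_nm, dtype=float))
        y = np.atleast_1d(np.asarray(y_nm, dtype=float))
        j = np.floor((x - self.origin_nm[0]) / self.pixel_size_nm).astype(int)
        i = np.floor((y - self.origin_nm[1]) / self.pixel_size_nm).astype(int)
        h, w = self.labels.shape
        inside = (i >= 0) & (i < h) & (j >= 0) & (j < w)
        out = np.zeros(x.shape, dtype=int)
        out[inside] = self.labels[i[inside], j[inside]]
        return out

    def area_um2(self, labels: Sequence[int] = (LABEL_NUCLEUS, LABEL_CYTOPLASM)) -> float:
        """Total area of the given labels in square micrometres."""
        n_px = int(np.isin(self.labels, list(labels)).sum())
        return n_px * (self.pixel_size_nm ** 2) / 1e6


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in nm: the field of view / simulation region."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError("region must have positive area")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area_um2(self) -> float:
        return self.width * self.height / 1e6

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)
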