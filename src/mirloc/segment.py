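"""Compartment assignment and exosome co-localization.

Compartments (nucleus / cytoplasm+membrane / extracellular) arrive as label
masks drawn on a wide-field image; localizations are counted per
compartment through the mask's nm georeference.  Exosomes are detected as
bright blobs in a GFP reference channel and miRNA localizations are matched
to them by distance, with per-exosome normalization of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .localize import robust_sigma
from .types import (
    LABEL_CYTOPLASM,
    LABEL_EXTRACELLULAR,
    LABEL_NUCLEUS,
    LocalizationTable,
    RegionSet,
)


@dataclass
class CompartmentCounts:
    n_nucleus: int
    n_cytoplasm: int
    n_extracellular: int

    @property
    def total(self) -> int:
        return self.n_nucleus + self.n_cytoplasm + self.n_extracellular

    @property
    def fractions(self) -> dict:
        t = self.total
        if t == 0:
            return {"nucleus": 0.0, "cytoplasm": 0.0, "extracellular": 0.0}
        return {
            "nucleus": self.n_nucleus / t,
            "cytoplasm": self.n_cytoplasm / t,
            "extracellular": self.n_extracellular / t,
        }


@dataclass
class ExosomeSpots:
    """Detected GFP-exosome objects: centers and equivalent-circle radii (nm)."""

    centers_nm: np.ndarray  # (m, 2)
    radii_nm: np.ndarray  # (m,)
    source: str | None = None

    def __post_init__(self) -> None:
        self.centers_nm = np.asarray(self.centers_nm, dtype=float).reshape(-1, 2)
        self.radii_nm = np.asarray(self.radii_nm, dtype=float).reshape(-1)
        if (self.radii_nm <= 0).any():
            raise ValueError("spot radii must be > 0")

    def __len__(self) -> int:
        return len(self.radii_nm)


def upscale_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Upscale a label mask by bilinear interpolation of label indicators.

    Each label's indicator image is interpolated on the pixel-center grid
    (edge-clamped); every output pixel takes the label whose interpolated
    indicator is largest, ties going to the lower label.  ``factor=1``
    returns the mask unchanged.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    mask = np.asarray(mask)
    if factor == 1:
        return mask.copy()
    h, w = mask.shape
    ii = (np.arange(h * factor) + 0.5) / factor - 0.5
    jj = (np.arange(w * factor) + 0.5) / factor - 0.5
    grid_j, grid_i = np.meshgrid(jj, ii)
    labels = np.unique(mask)
    scores = np.stack([
        map_coordinates((mask == lab).astype(float), [grid_i, grid_j],
                        order=1, mode="nearest")
        for lab in labels
    ])
    # argmax returns the first (lowest-label) maximum on ties
    return labels[np.argmax(scores, axis=0)]


def assign_compartments(
    table: LocalizationTable, regions: RegionSet
) -> tuple[CompartmentCounts, np.ndarray]:
    """Label each localization by its containing mask pixel.

    Points outside the mask footprint count as extracellular.  The three
    compartment counts always sum to the table size.
    """
    pos = table.positions
    if len(pos) == 0:
        return CompartmentCounts(0, 0, 0), np.empty(0, dtype=int)
    labels = regions.label_at(pos[:, 0], pos[:, 1])
    counts = CompartmentCounts(
        n_nucleus=int((labels == LABEL_NUCLEUS).sum()),
        n_cytoplasm=int((labels == LABEL_CYTOPLASM).sum()),
        n_extracellular=int((labels == LABEL_EXTRACELLULAR).sum()),
    )
    return counts, labels


def detect_exosome_spots(
    gfp_image: np.ndarray,
    pixel_size_nm: float,
    threshold_sigmas: float = 5.0,
    min_area_px: int = 4,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    source: str | None = None,
) -> ExosomeSpots:
    """Segment bright blobs in a wide-field GFP channel.

    Pixels above ``median + threshold_sigmas * robust sigma`` are grouped by
    8-connectivity; components of at least ``min_area_px`` pixels become
    spots with intensity-weighted centroid and equivalent-circle radius.
    """
    img = np.asarray(gfp_image, dtype=float)
    med = float(np.median(img))
    sig = robust_sigma(img)
    fg = img > med + threshold_sigmas * max(sig, 1e-12)
    lab = cc_label(fg, connectivity=2)
    centers, radii = [], []
    for prop in regionprops(lab, intensity_image=img - med):
        if prop.area < min_area_px:
            continue
        ci, cj = prop.centroid_weighted
        centers.append((
            origin_nm[0] + (cj + 0.5) * pixel_size_nm,
            origin_nm[1] + (ci + 0.5) * pixel_size_nm,
        ))
        radii.append(np.sqrt(prop.area / np.pi) * pixel_size_nm)
    return ExosomeSpots(np.asarray(centers).reshape(-1, 2),
                        np.asarray(radii), source=source)


@dataclass
class ColocResult:
    per_spot_counts: np.ndarray
    coloc_fraction: float
    mean_per_exosome: float | None

    @property
    def n_colocalized(self) -> int:
        return int(self.per_spot_counts.sum())


def coloc_counts(
    table: LocalizationTable,
    spots: ExosomeSpots,
    match_radius_nm: float = 50.0,
) -> ColocResult:
    """Count miRNA localizations inside exosome spots.

    A localization co-localizes with a spot when it lies within the spot
    radius plus ``match_radius_nm`` of the spot center; each localization is
    assigned to the nearest qualifying spot.  ``mean_per_exosome`` is the
    total co-localized count divided by the number of spots (None when no
    spots were detected).
    """
    if match_radius_nm <= 0:
        raise ValueError("match_radius_nm must be > 0")
    m = len(spots)
    if m == 0:
        return ColocResult(np.zeros(0, dtype=int), 0.0, None)
    pos = table.positions
    per_spot = np.zeros(m, dtype=int)
    if len(pos):
        tree = cKDTree(spots.centers_nm)
        max_reach = float(spots.radii_nm.max() + match_radius_nm)
        neighbors = tree.query_ball_point(pos, max_reach)
        for p, cands in enumerate(neighbors):
            best, best_d = -1, np.inf
            for s in cands:
                d = np.hypot(*(pos[p] - spots.centers_nm[s]))
                if d <= spots.radii_nm[s] + match_radius_nm and d < best_d:
                    best, best_d = s, d
            if best >= 0:
                per_spot[best] += 1
    n_coloc = int(per_spot.sum())
    frac = n_coloc / len(pos) if len(pos) else 0.0
    return ColocResult(per_spot, float(frac), n_coloc / m)
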