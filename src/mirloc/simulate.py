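"""Synthetic acquisition: ground-truth scenes, blinking, and camera frames.

This module is the stand-in for the microscope.  Every generator is seeded
and keeps its ground truth (emitter positions, cluster memberships, blink
schedule) so each downstream stage of the pipeline can be tested against an
oracle.

The emission model is deliberately simple: each emitter switches on in each
frame independently with a fixed probability (no explicit on/off dwell
kinetics), and each on-event draws its photon yield from an exponential
distribution truncated from below.  This is the minimal model that
exercises a differential-stack detector; the blink kinetics are a
replaceable component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .types import (
    LABEL_CYTOPLASM,
    LABEL_NUCLEUS,
    CameraModel,
    ImageStack,
    Rect,
    RegionSet,
)


@dataclass
class SyntheticScene:
    """Ground truth for one simulated acquisition.

    ``positions`` are emitter coordinates in nm; ``labels`` are cluster
    memberships (-1 = background / unclustered).  The blink schedule is
    stored as three parallel arrays (emitter index, frame, photons), one
    entry per on-event.
    """

    positions: np.ndarray  # (n, 2) nm
    labels: np.ndarray  # (n,) int, -1 for background
    region: Rect
    event_emitter: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    event_frame: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    event_photons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))
    regions: RegionSet | None = None
    exosome_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.positions) != len(self.labels):
            raise ValueError("positions and labels must have equal length")
        if len(self.positions) and not self.region.contains(
            self.positions[:, 0], self.positions[:, 1]
        ).all():
            raise ValueError("all emitters must lie inside the region")
        if len(self.event_photons) and (np.asarray(self.event_photons) <= 0).any():
            raise ValueError("event photons must be > 0")

    @property
    def n_emitters(self) -> int:
        return len(self.positions)

    @property
    def n_events(self) -> int:
        return len(self.event_frame)

    @property
    def event_positions(self) -> np.ndarray:
        """(n_events, 2) nm position of the emitter behind each on-event."""
        return self.positions[self.event_emitter]


def sample_csr(n: int, region: Rect, seed: int) -> SyntheticScene:
    """Complete spatial randomness: ``n`` independent uniform points."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(region.xmin, region.xmax, size=n)
    y = rng.uniform(region.ymin, region.ymax, size=n)
    return SyntheticScene(np.column_stack([x, y]), np.full(n, -1), region)


def sample_thomas(
    n_parents: int,
    mean_offspring: float,
    cluster_sigma_nm: float,
    background_n: int,
    region: Rect,
    seed: int,
) -> SyntheticScene:
    """Thomas cluster process: Poisson offspring scattered around parents.

    Parents are uniform in the region; each spawns ``Poisson(mean_offspring)``
    children displaced by an isotropic Gaussian of width ``cluster_sigma_nm``.
    ``background_n`` CSR points are appended with label -1; offspring carry
    their parent index as cluster label.  Offspring falling outside the
    region are clipped to its boundary so the scene invariant holds.
    """
    if n_parents < 0 or background_n < 0:
        raise ValueError("counts must be >= 0")
    if n_parents > 0 and (mean_offspring <= 0 or cluster_sigma_nm <= 0):
        raise ValueError("mean_offspring and cluster_sigma_nm must be > 0")
    rng = np.random.default_rng(seed)
    px = rng.uniform(region.xmin, region.xmax, size=n_parents)
    py = rng.uniform(region.ymin, region.ymax, size=n_parents)
    pts, labels = [], []
    for p in range(n_parents):
        n_off = rng.poisson(mean_offspring)
        off = rng.normal(0.0, cluster_sigma_nm, size=(n_off, 2))
        pts.append(np.column_stack([px[p] + off[:, 0], py[p] + off[:, 1]]))
        labels.append(np.full(n_off, p))
    bx = rng.uniform(region.xmin, region.xmax, size=background_n)
    by = rng.uniform(region.ymin, region.ymax, size=background_n)
    pts.append(np.column_stack([bx, by]))
    labels.append(np.full(background_n, -1))
    positions = np.concatenate(pts) if pts else np.empty((0, 2))
    positions[:, 0] = np.clip(positions[:, 0], region.xmin, region.xmax)
    positions[:, 1] = np.clip(positions[:, 1], region.ymin, region.ymax)
    return SyntheticScene(positions, np.concatenate(labels), region)


def make_nanoruler(
    n_pairs: int, separation_nm: float, region: Rect, seed: int,
    max_tries: int | None = None,
) -> SyntheticScene:
    """Fluorophore pairs at a fixed design separation (calibration standard).

    Anchor points are placed uniformly with a minimum mutual distance of
    5x the separation (dart throwing); each pair straddles its anchor at
    ``+-separation/2`` along a uniformly random orientation.  Cluster labels
    carry the pair index.
    """
    if separation_nm <= 0:
        raise ValueError("separation_nm must be > 0")
    rng = np.random.default_rng(seed)
    margin = separation_nm  # keep both fluorophores inside the region
    if region.width <= 2 * margin or region.height <= 2 * margin:
        raise ValueError("region too small for the requested separation")
    min_dist = 5.0 * separation_nm
    if max_tries is None:
        max_tries = max(10000, 100 * n_pairs)
    anchors = np.empty((n_pairs, 2))
    n_placed = 0
    tries = 0
    while n_placed < n_pairs:
        if tries >= max_tries:
            raise ValueError(
                f"region too small to place {n_pairs} pairs at spacing {min_dist} nm"
            )
        tries += 1
        cand = np.array([
            rng.uniform(region.xmin + margin, region.xmax - margin),
            rng.uniform(region.ymin + margin, region.ymax - margin),
        ])
        d = anchors[:n_placed] - cand
        if n_placed == 0 or (d[:, 0] ** 2 + d[:, 1] ** 2).min() >= min_dist ** 2:
            anchors[n_placed] = cand
            n_placed += 1
    theta = rng.uniform(0.0, np.pi, size=n_pairs)
    half = 0.5 * separation_nm * np.column_stack([np.cos(theta), np.sin(theta)])
    a = anchors
    positions = np.concatenate([a + half, a - half])
    labels = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)])
    return SyntheticScene(positions, labels, region)


def make_blink_schedule(
    scene: SyntheticScene,
    n_frames: int,
    p_on_per_frame: float,
    mean_photons: float,
    seed: int,
    min_photons: float = 10.0,
) -> SyntheticScene:
    """Memoryless per-frame blinking with truncated-exponential photon yield.

    Each emitter emits in each frame independently with probability
    ``p_on_per_frame`` (at most one event per emitter per frame).  Event
    photons follow an exponential of mean ``mean_photons`` conditioned on
    exceeding ``min_photons`` — by memorylessness this is
    ``min_photons + Exponential(mean_photons)``.
    """
    if not 0 <= p_on_per_frame < 1:
        raise ValueError("p_on_per_frame must be in [0, 1)")
    if mean_photons <= 0:
        raise ValueError("mean_photons must be > 0")
    rng = np.random.default_rng(seed)
    on = rng.random((scene.n_emitters, n_frames)) < p_on_per_frame
    emitter, frame = np.nonzero(on)
    photons = min_photons + rng.exponential(mean_photons, size=len(emitter))
    return replace(
        scene,
        event_emitter=emitter,
        event_frame=frame,
        event_photons=photons,
    )


def _pixel_masses_1d(center_px: float, sigma_px: float, lo: int, hi: int) -> np.ndarray:
    """Integrated Gaussian mass over unit pixels ``lo..hi-1`` along one axis."""
    edges = np.arange(lo, hi + 1, dtype=float)
    cdf = 0.5 * (1.0 + erf((edges - center_px) / (sigma_px * np.sqrt(2.0))))
    return np.diff(cdf)


def render_frames(
    scene: SyntheticScene,
    camera: CameraModel,
    psf_sigma_nm: float,
    stack_shape: tuple[int, int, int],
    seed: int,
    pixel_size_nm: float = 100.0,
    background_photons_per_px: float = 2.0,
    integration_time_ms: float = 50.0,
    shot_noise: bool = True,
) -> ImageStack:
    """Render the blink schedule into noisy EMCCD frames.

    Each on-event deposits a pixel-integrated isotropic 2D Gaussian with
    total mass equal to its photon yield.  Per pixel,
    ``counts = offset + g * Poisson(photons) + N(0, read_noise)`` with
    ``g = counts_per_photon``, clipped at zero.  ``shot_noise=False``
    renders the noiseless expectation (no Poisson, no readout noise).
    Events centred outside the frame are dropped with a warning.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be > 0")
    T, H, W = stack_shape
    a = pixel_size_nm
    sigma_px = psf_sigma_nm / a
    expected = np.full((T, H, W), float(background_photons_per_px))
    reach = int(np.ceil(4.0 * sigma_px)) + 1
    n_dropped = 0
    for e, t, n_ph in zip(scene.event_emitter, scene.event_frame,
                          scene.event_photons):
        if t < 0 or t >= T:
            n_dropped += 1
            continue
        x_px = scene.positions[e, 0] / a
        y_px = scene.positions[e, 1] / a
        if not (0 <= x_px < W and 0 <= y_px < H):
            n_dropped += 1
            continue
        j0, j1 = max(0, int(x_px) - reach), min(W, int(x_px) + reach + 1)
        i0, i1 = max(0, int(y_px) - reach), min(H, int(y_px) + reach + 1)
        mx = _pixel_masses_1d(x_px, sigma_px, j0, j1)
        my = _pixel_masses_1d(y_px, sigma_px, i0, i1)
        expected[t, i0:i1, j0:j1] += n_ph * np.outer(my, mx)
    if n_dropped:
        warnings.warn(f"render_frames: dropped {n_dropped} out-of-bounds events",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    if shot_noise:
        photons = rng.poisson(expected).astype(float)
        counts = (camera.offset_counts + camera.counts_per_photon * photons
                  + rng.normal(0.0, camera.read_noise_counts, size=expected.shape))
    else:
        counts = camera.offset_counts + camera.counts_per_photon * expected
    counts = np.clip(counts, 0.0, None)
    return ImageStack(counts, pixel_size_nm=a, integration_time_ms=integration_time_ms)


def make_compartment_masks(
    region: Rect,
    nucleus_ellipse: tuple[float, float, float, float],
    cell_ellipse: tuple[float, float, float, float],
    mask_pixel_nm: float = 100.0,
) -> RegionSet:
    """Elliptical nucleus/cell compartment mask over the region.

    Ellipses are ``(cx_nm, cy_nm, rx_nm, ry_nm)``.  Label 1 inside the
    nucleus, 2 inside the cell but outside the nucleus, 0 elsewhere.  The
    nucleus must lie entirely inside the cell ellipse.
    """
    ncx, ncy, nrx, nry = nucleus_ellipse
    ccx, ccy, crx, cry = cell_ellipse
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    bx = ncx + nrx * np.cos(theta)
    by = ncy + nry * np.sin(theta)
    if (((bx - ccx) / crx) ** 2 + ((by - ccy) / cry) ** 2 > 1.0).any():
        raise ValueError("nucleus ellipse must lie inside the cell ellipse")
    w = int(np.ceil(region.width / mask_pixel_nm))
    h = int(np.ceil(region.height / mask_pixel_nm))
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = region.xmin + (jj + 0.5) * mask_pixel_nm
    y = region.ymin + (ii + 0.5) * mask_pixel_nm
    in_nuc = ((x - ncx) / nrx) ** 2 + ((y - ncy) / nry) ** 2 <= 1.0
    in_cell = ((x - ccx) / crx) ** 2 + ((y - ccy) / cry) ** 2 <= 1.0
    labels = np.zeros((h, w), dtype=int)
    labels[in_cell] = LABEL_CYTOPLASM
    labels[in_nuc] = LABEL_NUCLEUS
    return RegionSet(labels, pixel_size_nm=mask_pixel_nm,
                     origin_nm=(region.xmin, region.ymin))


def render_spots_image(
    centers_nm: np.ndarray,
    amplitudes: np.ndarray | float,
    sigma_nm: float,
    shape: tuple[int, int],
    pixel_size_nm: float = 100.0,
    background: float = 10.0,
    read_noise: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render a wide-field reference image of diffraction-limited blobs.

    Used for the GFP-exosome channel: each center contributes an integrated
    Gaussian blob of the given peak-mass amplitude on a constant background,
    optionally with Gaussian noise.
    """
    H, W = shape
    centers = np.asarray(centers_nm, dtype=float).reshape(-1, 2)
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(centers),))
    sigma_px = sigma_nm / pixel_size_nm
    img = np.full((H, W), float(background))
    reach = int(np.ceil(4.0 * sigma_px)) + 1
    for (x, y), amp in zip(centers, amps):
        x_px, y_px = x / pixel_size_nm, y / pixel_size_nm
        j0, j1 = max(0, int(x_px) - reach), min(W, int(x_px) + reach + 1)
        i0, i1 = max(0, int(y_px) - reach), min(H, int(y_px) + reach + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        mx = _pixel_masses_1d(x_px, sigma_px, j0, j1)
        my = _pixel_masses_1d(y_px, sigma_px, i0, i1)
        img[i0:i1, j0:j1] += amp * np.outer(my, mx)
    if read_noise > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, read_noise, size=img.shape), 0.0, None)
    return img
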