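"""Pipeline configuration: YAML mapping -> validated parameter objects."""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster import ClusterParams
from .localize import DetectionParams
from .render import RenderParams
from .types import CameraModel


class ConfigError(ValueError):
    """Invalid or missing configuration value; the message names the key."""


#: simulator defaults: a 500-frame acquisition of a clustered scene on a
#: 64 x 64 px field, sparse blinking, bright events
SIM_DEFAULTS = {
    "layout": "thomas",
    "n_frames": 500,
    "width_px": 64,
    "height_px": 64,
    "pixel_size_nm": 100.0,
    "psf_sigma_nm": 130.0,
    "p_on_per_frame": 0.01,
    "mean_photons": 2000.0,
    "min_event_photons": 500.0,
    "background_photons_per_px": 2.0,
    # thomas layout
    "n_parents": 10,
    "mean_offspring": 20.0,
    "cluster_sigma_nm": 60.0,
    "background_n": 100,
    # csr layout
    "n": 500,
    # nanoruler layout
    "n_pairs": 50,
    "separation_nm": 35.0,
    # optional compartment geometry: [cx, cy, rx, ry] in nm
    "nucleus_ellipse": None,
    "cell_ellipse": None,
}


@dataclass
class PipelineConfig:
    camera: CameraModel
    detection: DetectionParams = field(default_factory=DetectionParams)
    cluster: ClusterParams = field(default_factory=lambda: ClusterParams.from_preset("results"))
    render: RenderParams = field(default_factory=RenderParams)
    simulation: dict = field(default_factory=lambda: dict(SIM_DEFAULTS))
    seed: int = 0
    outdir: str = "mirloc_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        cam_raw = raw.get("camera")
        if cam_raw is None:
            raise ConfigError("missing required section 'camera'")
        for key in ("counts_per_photon",):
            if key not in cam_raw:
                raise ConfigError(f"missing required key 'camera.{key}'")
        camera = _build("camera", CameraModel, cam_raw)
        detection = _build("detection", DetectionParams, raw.get("detection", {}))
        cluster_raw = dict(raw.get("cluster", {}))
        preset = cluster_raw.pop("preset", None)
        if preset is not None and not cluster_raw:
            try:
                cluster = ClusterParams.from_preset(preset)
            except KeyError as exc:
                raise ConfigError(f"cluster.preset: {exc.args[0]}") from exc
        else:
            cluster = _build("cluster", ClusterParams, cluster_raw or
                             {"radius_nm": 120.0, "min_neighbors": 5})
        render = _build("render", RenderParams, raw.get("render", {}))
        sim = dict(SIM_DEFAULTS)
        for key, val in dict(raw.get("simulation", {})).items():
            if key not in SIM_DEFAULTS:
                raise ConfigError(f"unknown key 'simulation.{key}'")
            sim[key] = val
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("'seed' must be an integer")
        return cls(camera=camera, detection=detection, cluster=cluster,
                   render=render, simulation=sim, seed=seed,
                   outdir=str(raw.get("outdir", "mirloc_out")))


def _build(section: str, cls, raw: dict):
    if not isinstance(raw, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigError(f"{section}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{section}: {exc}") from exc
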