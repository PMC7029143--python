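"""Configuration objects for imaging, motion models, scenarios and tracking.

All lengths are in micrometres, times in seconds, rates in 1/s.  Image
pixel values are in photon counts (camera offset/gain are not modelled).

The three built-in scenario presets encode experimental conditions for
membrane-tethered RNase Y foci in *Bacillus subtilis* imaged by TIRF:

``wt``
    exponentially growing wild-type cells: focus density ~0.3/um^2, about
    60 % of foci constrained, D = 0.02 um^2/s, v = 0.4 um/s.
``rif``
    30 min after transcription arrest with rifampin: density ~0.8/um^2,
    constrained fraction down to ~40 %, D = 0.03 um^2/s, v = 0.48 um/s,
    focus intensity x1.22.
``mutant``
    Y-complex deletion mutants: wild-type kinetics with density x4 and
    focus intensity x1.75.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

MOTION_MODELS = ("directed", "random", "confined", "blended")

#: labels produced by the MSD classifier (generator "confined" maps to
#: classifier "constrained"; "blended" tracks should mostly land in
#: "unclassified")
MOTION_CLASSES = ("directed", "random", "constrained", "unclassified")


@dataclass
class ImagingConfig:
    """Optical and camera parameters of the simulated/analysed acquisition.

    Defaults follow a TIRF acquisition with 64-nm pixels, 100-ms frames
    and a diffraction-limited PSF for green fluorescent protein.
    """

    pixel_size_um: float = 0.064
    frame_interval_s: float = 0.1
    frames: int = 200
    image_shape: tuple[int, int] = (512, 512)
    psf_sigma_um: float = 0.13
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    bleach_rate_per_s: float = 0.02

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.frames < 2:
            raise ValueError("need at least 2 frames")
        if self.psf_sigma_um <= 0 or self.background_level < 0:
            raise ValueError("psf sigma must be positive, background non-negative")
        if self.read_noise_sd < 0 or self.bleach_rate_per_s < 0:
            raise ValueError("noise and bleach rates must be non-negative")
        if self.psf_sigma_um >= 30 * self.pixel_size_um:
            raise ValueError("psf sigma implausibly large for this pixel size")
        self.image_shape = tuple(self.image_shape)  # type: ignore[assignment]
        if len(self.image_shape) != 2 or min(self.image_shape) < 8:
            raise ValueError("image_shape must be (rows, cols) with >= 8 pixels")

    @property
    def duration_s(self) -> float:
        return self.frames * self.frame_interval_s

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical field size (height, width) in micrometres."""
        return (self.image_shape[0] * self.pixel_size_um,
                self.image_shape[1] * self.pixel_size_um)


@dataclass
class MotionModelParams:
    """Parameters of one motion model.

    ``model`` is one of ``directed`` (straight path at speed ``v``),
    ``random`` (2D Brownian motion with diffusion coefficient ``D``),
    ``confined`` (Brownian motion reflected inside a disc of radius
    ``domain_radius_um`` for a gamma-distributed dwell time, then free),
    or ``blended`` (two-state switching between random and directed
    segments at ``switch_rate_per_s``).
    """

    model: str
    D: float = 0.0
    v: float = 0.0
    dwell_shape: float = 2.0
    dwell_scale_s: float = 0.8
    domain_radius_um: float = 0.15
    switch_rate_per_s: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MOTION_MODELS:
            raise ValueError(f"unknown motion model {self.model!r}")
        if self.D < 0 or self.v < 0:
            raise ValueError("D and v must be non-negative")
        if self.model == "confined":
            if self.domain_radius_um <= 0:
                raise ValueError("confined motion needs a positive domain radius")
            if self.dwell_shape <= 0 or self.dwell_scale_s <= 0:
                raise ValueError("gamma dwell parameters must be positive")
        if self.model == "blended" and self.switch_rate_per_s <= 0:
            raise ValueError("blended motion needs a positive switch rate")


@dataclass
class ScenarioConfig:
    """A generator preset: how many foci, how they move, how bright they are."""

    name: str = "wt"
    focus_density_per_um2: float = 0.3
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {"confined": 0.60, "random": 0.12,
                                 "directed": 0.13, "blended": 0.15})
    params_per_class: dict[str, MotionModelParams] = field(default_factory=dict)
    amplitude_photons: float = 1000.0
    intensity_multiplier: float = 1.0
    cell_length_um: float = 4.0
    cell_width_um: float = 0.9
    n_cells: int = 12
    focus_lifetime_mean_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focus_density_per_um2 < 0:
            raise ValueError("focus density must be non-negative")
        if self.cell_length_um <= 0 or self.cell_width_um <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.cell_width_um > self.cell_length_um:
            raise ValueError("cell width must not exceed cell length")
        if self.focus_lifetime_mean_s <= 0 or self.amplitude_photons <= 0:
            raise ValueError("lifetime and amplitude must be positive")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture sums to {total}, expected 1")
        unknown = set(self.class_mixture) - set(MOTION_MODELS)
        if unknown:
            raise ValueError(f"unknown mixture classes {sorted(unknown)}")
        for model in self.class_mixture:
            self.params_per_class.setdefault(
                model, _default_params(model))
        for model, p in self.params_per_class.items():
            if p.model != model:
                raise ValueError(f"params_per_class[{model!r}] has model {p.model!r}")


def _default_params(model: str, D: float = 0.02, v: float = 0.4) -> MotionModelParams:
    if model == "directed":
        return MotionModelParams(model="directed", D=0.0, v=v)
    if model == "random":
        return MotionModelParams(model="random", D=D)
    if model == "confined":
        return MotionModelParams(model="confined", D=D, domain_radius_um=0.15,
                                 dwell_shape=2.0, dwell_scale_s=0.8)
    return MotionModelParams(model="blended", D=D, v=v, switch_rate_per_s=1.0)


def wt_scenario(**overrides) -> ScenarioConfig:
    """Wild-type preset: density 0.3/um^2, 60/12/13/15 mixture, D=0.02, v=0.4."""
    cfg = dict(name="wt", focus_density_per_um2=0.3,
               class_mixture={"confined": 0.60, "random": 0.12,
                              "directed": 0.13, "blended": 0.15},
               params_per_class={m: _default_params(m, D=0.02, v=0.4)
                                 for m in MOTION_MODELS},
               amplitude_photons=1000.0, intensity_multiplier=1.0)
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def rifampin_scenario(**overrides) -> ScenarioConfig:
    """Transcription-arrest preset: density 0.8/um^2, 40 % constrained,
    D=0.03, v=0.48, intensity x1.22."""
    cfg = dict(name="rif", focus_density_per_um2=0.8,
               class_mixture={"confined": 0.40, "random": 0.17,
                              "directed": 0.13, "blended": 0.30},
               params_per_class={m: _default_params(m, D=0.03, v=0.48)
                                 for m in MOTION_MODELS},
               amplitude_photons=1000.0, intensity_multiplier=1.22)
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


def mutant_scenario(**overrides) -> ScenarioConfig:
    """Y-complex mutant preset: wild-type kinetics, density x4, intensity x1.75."""
    cfg = dict(name="mutant", focus_density_per_um2=1.2,
               class_mixture={"confined": 0.60, "random": 0.12,
                              "directed": 0.13, "blended": 0.15},
               params_per_class={m: _default_params(m, D=0.02, v=0.4)
                                 for m in MOTION_MODELS},
               amplitude_photons=1000.0, intensity_multiplier=1.75)
    cfg.update(overrides)
    return ScenarioConfig(**cfg)


SCENARIO_PRESETS = {"wt": wt_scenario, "rif": rifampin_scenario,
                    "mutant": mutant_scenario}


@dataclass
class TrackingConfig:
    """Detection, linking and filtering settings.

    ``quality_threshold`` is in scale-normalised LoG response units; when
    ``None`` it is calibrated per movie as ``mean + threshold_k * SD`` of
    the response (absolute camera-count thresholds do not transfer between
    detectors).  ``min_track_frames`` is inclusive: a 10-frame track at
    100-ms frames is the 1-s minimum duration.
    """

    blob_diameter_um: float = 0.3
    quality_threshold: Optional[float] = None
    threshold_k: float = 5.0
    link_max_dist_um: float = 0.3
    min_track_frames: int = 10
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.blob_diameter_um <= 0 or self.link_max_dist_um <= 0:
            raise ValueError("blob diameter and link distance must be positive")
        if self.min_track_frames < 2:
            raise ValueError("min_track_frames must be >= 2")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")

    def log_sigma_um(self) -> float:
        """LoG scale matched to the blob: sigma = diameter / (2*sqrt(2))."""
        return self.blob_diameter_um / (2.0 * 2.0 ** 0.5)


# ---------------------------------------------------------------------------
# serialisation helpers (YAML/JSON round-trip for CLI configs)

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(obj, path: str | Path) -> None:
    """Write any config dataclass as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    payload = _to_plain(obj)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_scenario(path: str | Path) -> ScenarioConfig:
    data = _load_mapping(path)
    params = data.pop("params_per_class", {})
    data["params_per_class"] = {m: MotionModelParams(**p) for m, p in params.items()}
    return ScenarioConfig(**data)


def load_imaging(path: str | Path) -> ImagingConfig:
    return ImagingConfig(**_load_mapping(path))


def load_tracking(path: str | Path) -> TrackingConfig:
    return TrackingConfig(**_load_mapping(path))
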