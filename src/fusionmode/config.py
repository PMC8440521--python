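"""Run configuration: YAML file + CLI overrides -> validated Config.

The config has five sections (``simulate``, ``detect``, ``quantify``,
``classify``, ``membrane``). Keys inside each section are flat and mirror
the field names of the underlying parameter dataclasses; unknown keys are
rejected by name, before any computation. The fully resolved config is
echoed to the log and written beside outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import ImagingParams, KineticParams, ParameterError, RoiGeometry

log = logging.getLogger("fusionmode")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    """Automated fusion-onset detection thresholds.

    Onset is the first frame where the spot's local intensity exceeds its
    rolling pre-frame baseline mean by ``k_sd`` standard deviations at a
    spatial local maximum, confirmed on the following frame against the
    same baseline (suppresses single-frame shot-noise excursions).
    """

    k_sd: float = 5.0
    baseline_window_s: float = 10.0
    merge_radius_um: float = 2.4
    smooth_sigma_um: float = 0.2
    min_consecutive: int = 2
    refractory_s: float = 10.0

    def __post_init__(self) -> None:
        if self.k_sd <= 0 or self.baseline_window_s <= 0 or self.merge_radius_um <= 0:
            raise ParameterError("detection thresholds must be > 0")
        if self.min_consecutive not in (1, 2):
            raise ParameterError("min_consecutive must be 1 or 2")


@dataclass(frozen=True)
class QuantifyParams:
    """Trace extraction, normalization and ensemble-averaging settings."""

    circle_diameter: float = 1.3
    annulus_inner: float = 1.3
    annulus_outer: float = 2.4
    square_side: float = 4.0
    baseline_window_s: float = 10.0   # pre-fusion baseline (last 10 s)
    peak_window_s: float = 10.0       # post-onset window defining "during fusion"
    exclude_start_frames: int = 50
    exclude_end_frames: int = 100
    level: str = "per-cell"           # or "pooled"
    tether_integral_window_s: float = 50.0

    def __post_init__(self) -> None:
        if self.level not in ("per-cell", "pooled"):
            raise ParameterError("level must be 'per-cell' or 'pooled'")
        self.geometry  # validates the circle/annulus ordering

    @property
    def geometry(self) -> RoiGeometry:
        return RoiGeometry(self.circle_diameter, self.annulus_inner,
                           self.annulus_outer, self.square_side)


@dataclass(frozen=True)
class ClassifyParams:
    """Fusion-mode decision thresholds (config-exposed, see docs)."""

    plateau_min: float = 0.3
    fast_max_s: float = 2.0
    slope_min: float = 0.0
    slope_se_factor: float = 3.0
    plateau_window_s: tuple[float, float] = (30.0, 60.0)
    min_plateau_coverage_s: float = 10.0
    fit_window_s: float = 5.0
    hepes_condition: str = "high"
    use_tether_for_ks: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.plateau_window_s
        if not (0 < lo < hi):
            raise ParameterError("plateau_window_s must be an increasing positive pair")
        if self.hepes_condition not in ("low", "high"):
            raise ParameterError("hepes_condition must be 'low' or 'high'")


@dataclass(frozen=True)
class MembraneParams:
    """Footprint segmentation and expansion morphometry settings."""

    policy: str = "otsu"              # per-frame Otsu, or "manual"
    manual_threshold: float | None = None
    n_bins: int = 256
    connectivity: int = 8
    fill_holes: bool = False
    area_bounds: tuple[float, float] = (0.01, 0.95)  # sanity check, frame fraction
    baseline_window_s: tuple[float, float] = (5.0, 10.0)
    final_window_s: float = 10.0

    def __post_init__(self) -> None:
        if self.policy not in ("otsu", "manual"):
            raise ParameterError("policy must be 'otsu' or 'manual'")
        if self.policy == "manual" and self.manual_threshold is None:
            raise ParameterError("manual policy requires manual_threshold")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")


@dataclass(frozen=True)
class SimulateParams:
    """Dataset-level simulation settings (kinetics/imaging ride alongside)."""

    n_cells: int = 5
    events_per_cell: int = 20
    hepes_condition: str = "high"
    reporter_kind: str = "pH_sensitive"
    residual_fraction: float = 0.0
    tether_channel: bool = False
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.events_per_cell < 1:
            raise ParameterError("n_cells and events_per_cell must be >= 1")
        if self.hepes_condition not in ("low", "high"):
            raise ParameterError("hepes_condition must be 'low' or 'high'")


@dataclass(frozen=True)
class Config:
    simulate: SimulateParams
    kinetics: KineticParams
    imaging: ImagingParams
    detect: DetectionParams
    quantify: QuantifyParams
    classify: ClassifyParams
    membrane: MembraneParams


# the simulate section is flat: its keys are partitioned across these three
_SIMULATE_PARTS = (SimulateParams, KineticParams, ImagingParams)
_SECTIONS = {
    "simulate": None,  # special-cased
    "detect": DetectionParams,
    "quantify": QuantifyParams,
    "classify": ClassifyParams,
    "membrane": MembraneParams,
}

_TUPLE_FIELDS = {"mode_probabilities", "dwell_mean_per_mode", "field_size",
                 "plateau_window_s", "area_bounds", "baseline_window_s"}


def _coerce(name: str, value):
    if name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _build(cls, section: str, values: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}")
    try:
        return cls(**{k: _coerce(k, v) for k, v in values.items()})
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid value in [{section}]: {exc}") from exc


def _build_simulate(values: dict):
    claimed: dict[type, dict] = {cls: {} for cls in _SIMULATE_PARTS}
    all_names = {}
    for cls in _SIMULATE_PARTS:
        for f in dataclasses.fields(cls):
            all_names[f.name] = cls
    for key, val in values.items():
        # MembraneParams reuses 'baseline_window_s' as a pair; in simulate it
        # is not a tuple field, so coercion stays name-driven and safe here.
        cls = all_names.get(key)
        if cls is None:
            raise ConfigError(f"unknown key in [simulate]: ['{key}']")
        claimed[cls][key] = _coerce(key, val)
    try:
        return tuple(cls(**claimed[cls]) for cls in _SIMULATE_PARTS)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid value in [simulate]: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load and validate a run config.

    ``path`` may be None (all defaults). ``overrides`` maps dotted keys
    (``"simulate.frame_interval"``, ``"classify.plateau_min"``) to values;
    overrides win over file values.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    unknown_sections = set(raw) - set(_SECTIONS)
    if unknown_sections:
        raise ConfigError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, content in raw.items():
        if content is not None and not isinstance(content, dict):
            raise ConfigError(f"section [{section}] must be a mapping")

    merged = {s: dict(raw.get(s) or {}) for s in _SECTIONS}
    for dotted, value in (overrides or {}).items():
        if "." not in dotted:
            raise ConfigError(f"override key must be 'section.key', got {dotted!r}")
        section, key = dotted.split(".", 1)
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section in override: {section!r}")
        merged[section][key] = value

    sim, kin, img = _build_simulate(merged["simulate"])
    cfg = Config(
        simulate=sim, kinetics=kin, imaging=img,
        detect=_build(DetectionParams, "detect", merged["detect"]),
        quantify=_build(QuantifyParams, "quantify", merged["quantify"]),
        classify=_build(ClassifyParams, "classify", merged["classify"]),
        membrane=_build(MembraneParams, "membrane", merged["membrane"]),
    )
    log.info("resolved config: %s", config_to_dict(cfg))
    return cfg


def config_to_dict(cfg: Config) -> dict:
    out = {}
    sim = {}
    for part in (cfg.simulate, cfg.kinetics, cfg.imaging):
        sim.update(dataclasses.asdict(part))
    out["simulate"] = sim
    for name in ("detect", "quantify", "classify", "membrane"):
        out[name] = dataclasses.asdict(getattr(cfg, name))
    return out


def dump_config(cfg: Config, path) -> None:
    """Write the fully resolved config next to run outputs (provenance)."""
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj
    Path(path).write_text(yaml.safe_dump(_plain(config_to_dict(cfg)), sort_keys=True))
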