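"""Parameter containers for the synthetic TIRF movie generator.

The simulator is a phenomenological forward model of single-vesicle
exocytosis as seen by TIRF microscopy with a pH-sensitive lumenal reporter:

* a vesicle arrives at the plasma membrane, tethers for a stochastic dwell,
  then opens a fusion pore at ``fusion_time``;
* on pore opening the lumen equilibrates with the extracellular medium
  (pH 7.4) and the reporter dequenches;
* in **full fusion (FF)** the pore dilates, the vesicle membrane merges and
  cargo spreads laterally by 2D diffusion (sigma^2 = 2 D t);
* in **kiss-and-run (KR)** the pore reseals after ``pore_open_duration``,
  the lumen reacidifies with first-order rate ``reacidification_rate`` and
  the vesicle departs axially through the evanescent field ("runs");
* in **kiss-and-stay (KS)** the pore reseals but the vesicle remains
  tethered at the membrane indefinitely ("stuck").

High extracellular HEPES that entered through the open pore buffers the
lumen and slows reacidification by ``buffer_factor``.

All parameters are plain dataclasses validated on construction; every field
is configurable from the run config (see :mod:`fusionmode.config`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

MODES = ("FF", "KR", "KS")

EXTERNAL_PH_DEFAULT = 7.4


class ParameterError(ValueError):
    """Raised when a simulator parameter violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Vesicle arrival / tethering / fusion kinetics.

    Parameters
    ----------
    mode_probabilities
        Probabilities of (FF, KR, KS); must sum to 1.
    dwell_mean_per_mode
        Mean tethering dwell in seconds per mode (FF, KR, KS). Kissing
        vesicles tether longer than fully fusing ones by default.
    dwell_distribution
        ``"exponential"`` (memoryless tethering, default) or ``"gamma"``
        with shape ``dwell_gamma_shape``.
    pore_open_duration
        Seconds the fusion pore stays open for KR/KS before resealing.
    reacidification_rate
        First-order rate k_acid (1/s) at which lumen pH relaxes back to
        ``lumen_pH_rest`` after pore closure (low-HEPES condition).
    buffer_factor
        Multiplicative slowdown of reacidification under high (100 mM)
        extracellular HEPES; >= 1. Effective rate is k_acid / buffer_factor.
    membrane_diffusion_coeff
        D (um^2/s) of lateral cargo spread after full fusion.
    departure_speed
        Axial speed (um/s) of a KR vesicle running away after pore closure.
    arrival_rate
        Vesicle appearances per cell per second (used when events are drawn
        as a Poisson process rather than at a fixed count).
    dilution_rate
        Extra first-order decay (1/s) applied to the *receptor* (pH-reporter)
        channel after full fusion, modelling mixing/dilution of the receptor
        into the plasma membrane on top of lateral diffusion.
    drift_coeff
        Optional lateral Brownian drift coefficient (um^2/s) of the tethered
        vesicle; 0 disables drift (default).
    """

    mode_probabilities: tuple[float, float, float] = (0.6, 0.3, 0.1)
    dwell_mean_per_mode: tuple[float, float, float] = (8.0, 15.0, 20.0)
    dwell_distribution: str = "exponential"
    dwell_gamma_shape: float = 2.0
    pore_open_duration: float = 2.0
    reacidification_rate: float = 0.15
    buffer_factor: float = 20.0
    lumen_pH_rest: float = 5.5
    external_pH: float = EXTERNAL_PH_DEFAULT
    membrane_diffusion_coeff: float = 0.05
    departure_speed: float = 0.02
    arrival_rate: float = 0.1
    dilution_rate: float = 0.5
    drift_coeff: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.mode_probabilities, dtype=float)
        _require(p.shape == (3,), "mode_probabilities must have three entries (FF, KR, KS)")
        _require(np.all((p >= 0) & (p <= 1)), "mode_probabilities must lie in [0, 1]")
        _require(abs(float(p.sum()) - 1.0) <= 1e-9, "mode_probabilities must sum to 1")
        d = np.asarray(self.dwell_mean_per_mode, dtype=float)
        _require(d.shape == (3,) and np.all(d > 0), "dwell_mean_per_mode must be three positive values")
        _require(self.dwell_distribution in ("exponential", "gamma"),
                 f"unknown dwell_distribution {self.dwell_distribution!r}")
        _require(self.dwell_gamma_shape > 0, "dwell_gamma_shape must be > 0")
        _require(self.pore_open_duration > 0, "pore_open_duration must be > 0")
        _require(self.reacidification_rate > 0, "reacidification_rate must be > 0")
        _require(self.buffer_factor >= 1, "buffer_factor must be >= 1")
        _require(self.membrane_diffusion_coeff > 0, "membrane_diffusion_coeff must be > 0")
        _require(self.departure_speed > 0, "departure_speed must be > 0")
        _require(self.arrival_rate > 0, "arrival_rate must be > 0")
        _require(self.dilution_rate >= 0, "dilution_rate must be >= 0")
        _require(self.drift_coeff >= 0, "drift_coeff must be >= 0")

    def dwell_mean(self, mode: str) -> float:
        return float(self.dwell_mean_per_mode[MODES.index(mode)])

    def with_hepes(self, condition: str) -> "KineticParams":
        """Resolve the HEPES condition: ``"low"`` sets buffer_factor to 1."""
        if condition not in ("low", "high"):
            raise ParameterError(f"hepes_condition must be 'low' or 'high', got {condition!r}")
        if condition == "low":
            return replace(self, buffer_factor=1.0)
        return self


@dataclass(frozen=True)
class ReporterModel:
    """Brightness-vs-pH model of one fluorescence channel.

    ``kind`` is one of ``pH_sensitive`` (pHluorin-like, fully quenched at
    lumenal pH), ``partially_quenched`` (pHTomato-like, residual brightness
    allows pre-fusion detection) or ``pH_insensitive`` (ligand channel,
    brightness identically 1).

    Brightness follows a single-site titration sigmoid normalised to 1 at
    extracellular pH 7.4::

        b(pH) = r + (1 - r) * f(pH) / f(7.4),   f(pH) = 1 / (1 + 10**(pKa - pH))

    with residual fraction ``r`` the brightness floor at acidic pH.
    """

    kind: str = "pH_sensitive"
    pKa: float = 7.1
    residual_fraction: float = 0.0
    reference_pH: float = EXTERNAL_PH_DEFAULT

    def __post_init__(self) -> None:
        _require(self.kind in ("pH_sensitive", "pH_insensitive", "partially_quenched"),
                 f"unknown reporter kind {self.kind!r}")
        _require(0.0 <= self.residual_fraction < 1.0, "residual_fraction must be in [0, 1)")
        if self.kind == "pH_sensitive":
            _require(self.residual_fraction == 0.0,
                     "pH_sensitive reporter has residual_fraction 0; use partially_quenched")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition geometry, optics and camera noise.

    Defaults follow a back-illuminated EMCCD TIRF setup: 512 x 512 field,
    0.18 um pixels, 16-bit counts, 2 Hz frame rate. The evanescent field
    attenuates excitation as exp(-z / penetration_depth). Shot noise is
    Poisson on photons, followed by linear gain and additive Gaussian read
    noise; counts are clipped to the bit depth.
    """

    pixel_size: float = 0.18          # um / px
    frame_interval: float = 0.5       # s (2 Hz); 5.0 for the 0.2 Hz protocol
    exposure: float = 0.1             # s
    n_frames: int = 480
    field_size: tuple[int, int] = (512, 512)
    psf_sigma: float = 0.2            # um
    penetration_depth: float = 0.15   # um
    photons_per_vesicle: float = 2000.0
    background_photons: float = 50.0  # per pixel per frame
    camera_gain: float = 1.0          # counts / photon
    read_noise_sd: float = 2.0        # counts
    bit_depth: int = 16
    bleaching_rate: float = 0.0       # 1/s photobleaching of vesicle signal; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "exposure", "psf_sigma",
                     "penetration_depth", "photons_per_vesicle", "camera_gain"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.background_photons >= 0, "background_photons must be >= 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd must be >= 0")
        _require(self.bleaching_rate >= 0, "bleaching_rate must be >= 0")
        _require(self.n_frames >= 1, "n_frames must be >= 1")
        fs = tuple(int(v) for v in self.field_size)
        _require(len(fs) == 2 and fs[0] > 0 and fs[1] > 0, "field_size must be two positive ints")
        _require(self.bit_depth in (8, 16), "bit_depth must be 8 or 16")

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    def frame_times(self) -> np.ndarray:
        """Time stamp of frame k is k * frame_interval (start of exposure)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiGeometry:
    """Circle / annulus / crop geometry of the single-vesicle measurement.

    A vesicle's fluorescence is the spatially averaged intensity difference
    between a circle centred on the vesicle and a concentric background
    annulus; the event is excised as a square ministack around the brightest
    pixel. All values are diameters/sides in micrometres.
    """

    circle_diameter: float = 1.3
    annulus_inner: float = 1.3
    annulus_outer: float = 2.4
    square_side: float = 4.0

    def __post_init__(self) -> None:
        _require(0 < self.circle_diameter <= self.annulus_inner < self.annulus_outer,
                 "require 0 < circle_diameter <= annulus_inner < annulus_outer")
        _require(self.annulus_outer <= self.square_side * np.sqrt(2.0),
                 "annulus_outer must fit inside the square crop (<= side * sqrt(2))")

    def square_side_px(self, pixel_size: float) -> int:
        """Crop side in pixels: round(side / pixel_size), forced odd."""
        n = int(round(self.square_side / pixel_size))
        if n % 2 == 0:
            n += 1
        return n


def params_to_dict(p) -> dict:
    """Flatten a parameter dataclass to a plain dict (for config echo)."""
    return {f.name: getattr(p, f.name) for f in fields(p)}
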