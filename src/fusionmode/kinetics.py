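"""Ground-truth vesicle kinetics and reporter photophysics.

A simulated event is a continuous-time trajectory of one vesicle sampled on
the acquisition frame grid: lateral position, lumen pH, axial distance from
the membrane, lateral cargo spread and tether occupancy. Rendering
(:mod:`fusionmode.render`) turns these into photon fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MODES, KineticParams, ParameterError, ReporterModel


def reporter_brightness(pH, model: ReporterModel):
    """Relative brightness of a reporter at the given pH.

    Normalised so that brightness at the extracellular reference pH (7.4)
    is exactly 1. pH-insensitive reporters return 1 everywhere. Accepts a
    scalar or array; pH must lie in [3, 10].

    Raises
    ------
    ValueError
        If any pH value falls outside [3, 10].
    """
    arr = np.asarray(pH, dtype=float)
    if np.any(arr < 3.0) or np.any(arr > 10.0):
        raise ValueError("pH outside the supported range [3, 10]")
    if model.kind == "pH_insensitive":
        out = np.ones_like(arr)
        return float(out) if np.isscalar(pH) else out
    f = 1.0 / (1.0 + 10.0 ** (model.pKa - arr))
    f_ref = 1.0 / (1.0 + 10.0 ** (model.pKa - model.reference_pH))
    r = model.residual_fraction
    out = r + (1.0 - r) * f / f_ref
    return float(out) if np.isscalar(pH) else out


@dataclass
class EventKinetics:
    """Sampled ground-truth trajectory of one vesicle.

    All trajectory arrays share the frame-time grid ``times`` (s). ``z`` is
    the axial distance from the membrane in um (0 = at the membrane),
    ``spread_sigma`` the lateral cargo spread sigma(t) in um (0 before full
    fusion), ``tethered`` the tether-marker occupancy (step function).
    ``present`` marks frames where the vesicle contributes any photons.
    """

    mode: str
    arrival_time: float
    fusion_time: float
    pore_close_time: float | None
    xy_um: tuple[float, float]
    times: np.ndarray
    lumen_pH: np.ndarray
    z: np.ndarray
    spread_sigma: np.ndarray
    tethered: np.ndarray
    present: np.ndarray
    departed: bool
    xy_track_um: np.ndarray | None = None  # (T, 2) if lateral drift enabled

    @property
    def dwell(self) -> float:
        return self.fusion_time - self.arrival_time

    def onset_frame(self, frame_interval: float) -> int:
        return int(np.floor(self.fusion_time / frame_interval))


def _draw_dwell(params: KineticParams, mode: str, rng: np.random.Generator) -> float:
    mean = params.dwell_mean(mode)
    if params.dwell_distribution == "exponential":
        return float(rng.exponential(mean))
    shape = params.dwell_gamma_shape
    return float(rng.gamma(shape, mean / shape))


def simulate_event_kinetics(
    params: KineticParams,
    mode: str,
    duration: float,
    rng: np.random.Generator,
    *,
    frame_interval: float = 0.5,
    fusion_time: float | None = None,
    xy_um: tuple[float, float] = (0.0, 0.0),
    field_depth_um: float = 2.0,
) -> EventKinetics:
    """Simulate one vesicle's ground-truth trajectory.

    The tether marker is a step function over [arrival, fusion] (extended
    indefinitely for KS, whose vesicle stays stuck). After pore closure the
    lumen pH relaxes first-order toward its resting value at rate
    ``k_acid / buffer_factor``; a KR vesicle additionally departs axially at
    constant ``departure_speed``. Full fusion never closes its pore and the
    cargo spread follows sigma^2(t) = 2 D (t - fusion_time).

    Parameters
    ----------
    fusion_time
        Optional fixed fusion time (s); when None the dwell is drawn from
        the configured distribution and arrival is placed at
        ``fusion_time - dwell`` (arrival may precede frame 0, in which case
        the tether is simply on from the first frame).
    """
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    if duration <= 0 or frame_interval <= 0:
        raise ParameterError("duration and frame_interval must be > 0")

    dwell = _draw_dwell(params, mode, rng)
    if fusion_time is None:
        fusion_time = dwell + float(rng.uniform(0.0, frame_interval))
    arrival_time = fusion_time - dwell
    if fusion_time > duration:
        raise ParameterError("duration does not cover the dwell plus a post-fusion window")

    times = np.arange(int(np.ceil(duration / frame_interval))) * frame_interval
    t = times

    pore_close = None if mode == "FF" else fusion_time + params.pore_open_duration

    # lumen pH: resting before fusion, external while the pore is open,
    # first-order relaxation back to rest after closure
    pH = np.full_like(t, params.lumen_pH_rest, dtype=float)
    open_mask = t >= fusion_time
    pH[open_mask] = params.external_pH
    if pore_close is not None:
        k_eff = params.reacidification_rate / params.buffer_factor
        after = t >= pore_close
        dt = t[after] - pore_close
        pH[after] = params.lumen_pH_rest + (
            params.external_pH - params.lumen_pH_rest
        ) * np.exp(-k_eff * dt)

    z = np.zeros_like(t)
    departed = False
    if mode == "KR":
        after = t >= pore_close
        z[after] = params.departure_speed * (t[after] - pore_close)
        departed = bool(np.any(z >= field_depth_um))

    spread = np.zeros_like(t)
    if mode == "FF":
        after = t >= fusion_time
        spread[after] = np.sqrt(
            2.0 * params.membrane_diffusion_coeff * (t[after] - fusion_time)
        )

    tethered = (t >= arrival_time) & (t < fusion_time)
    if mode == "KS":
        tethered = t >= arrival_time

    present = t >= arrival_time
    if mode == "KR":
        present &= z < field_depth_um

    track = None
    if params.drift_coeff > 0:
        # Brownian drift of the tethered vesicle; frozen at the fusion site
        # from pore opening onward (cargo position, not vesicle centre).
        steps = rng.normal(0.0, np.sqrt(2 * params.drift_coeff * frame_interval), size=(len(t), 2))
        track = np.cumsum(steps, axis=0)
        freeze = min(int(np.searchsorted(t, fusion_time)), len(t) - 1)
        track[t >= fusion_time] = track[freeze]
        track += np.asarray(xy_um)

    return EventKinetics(
        mode=mode,
        arrival_time=float(arrival_time),
        fusion_time=float(fusion_time),
        pore_close_time=pore_close,
        xy_um=tuple(map(float, xy_um)),
        times=times,
        lumen_pH=pH,
        z=z,
        spread_sigma=spread,
        tethered=tethered,
        present=present,
        departed=departed,
        xy_track_um=track,
    )


def event_brightness(event: EventKinetics, reporter: ReporterModel,
                     dilution_rate: float = 0.0,
                     penetration_depth: float | None = None) -> np.ndarray:
    """Per-frame relative brightness of one event in one channel.

    Combines the reporter's pH response, evanescent-field attenuation
    exp(-z/d) and, for the receptor channel after full fusion, an extra
    first-order dilution decay. The tether-marker channel should instead be
    rendered from ``event.tethered`` directly.
    """
    b = reporter_brightness(event.lumen_pH, reporter)
    b = np.where(event.present, b, 0.0)
    if penetration_depth is not None:
        b = b * np.exp(-event.z / penetration_depth)
    if dilution_rate > 0 and event.mode == "FF":
        post = event.times >= event.fusion_time
        decay = np.ones_like(b)
        decay[post] = np.exp(-dilution_rate * (event.times[post] - event.fusion_time))
        b = b * decay
    return b
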