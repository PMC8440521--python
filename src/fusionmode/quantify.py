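"""Fusion-event quantification.

Implements the single-vesicle measurement chain: automated fusion-onset
detection (a quantified surrogate for by-eye event calling), ministack
excision around the brightest pixel, circle-annulus background-corrected
intensity traces, reporter/marker normalisation, fusion-aligned ensemble
averaging with early/late exclusion rules, and tethering-duration metrics.

The measurement ROI stays fixed at the fusion site for the whole trace, so
a vesicle that drifts laterally during tethering under-reports long dwells
— a known property of the fixed-ROI protocol, reproduced deliberately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import DetectionParams, QuantifyParams
from .movie import MovieStack
from .params import RoiGeometry

log = logging.getLogger("fusionmode")


class GeometryError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class EnsembleError(ValueError):
    pass


@dataclass
class Trace:
    """Background-corrected intensity vs time relative to fusion onset."""

    values: np.ndarray
    time: np.ndarray          # s; 0 at onset, negative = pre-fusion
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape != self.time.shape:
            raise ValueError("trace values and time must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time axis must be strictly increasing")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else np.nan


@dataclass
class FusionEvent:
    """One detected (or curated) fusion event."""

    event_id: int
    cell_id: int
    center_px: tuple[int, int]        # (row, col) of the brightest pixel
    onset_frame: int
    site_id: int = -1                 # shared by repeated kisses at one site
    traces: dict[str, Trace] = field(default_factory=dict)
    qc: set[str] = field(default_factory=set)
    mode: str = "unclassified"


@dataclass
class EnsembleTrace:
    """Fusion-aligned mean +/- SEM trace."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    n_cells: int
    level: str


# --- detection ------------------------------------------------------------

def detect_fusion_events(reporter: MovieStack,
                         params: DetectionParams | None = None) -> list[FusionEvent]:
    """Detect fusion onsets in the pH-reporter channel.

    Onset is the first frame whose lightly smoothed intensity exceeds the
    rolling baseline mean (previous ``baseline_window_s``) by ``k_sd``
    standard deviations at a spatial local maximum, confirmed on the next
    frame against the same baseline. Detections closer than
    ``merge_radius_um`` are merged (brightest wins); a detected site is
    refractory for ``refractory_s`` while its own signal contaminates the
    rolling baseline. Later re-activations of a site share its ``site_id``
    (repeated kissing).
    """
    from scipy.ndimage import maximum_filter

    params = params or DetectionParams()
    dt = reporter.frame_interval
    W = int(round(params.baseline_window_s / dt))
    T, ny, nx = reporter.shape
    if T <= W + 1:
        raise ValueError(
            f"movie of {T} frames is shorter than the {W}-frame baseline window")

    sigma_px = params.smooth_sigma_um / reporter.pixel_size
    sm = np.empty(reporter.shape, dtype=np.float64)
    raw = reporter.astype_float()
    for t in range(T):
        sm[t] = gaussian_filter(raw[t], sigma_px, mode="nearest")
    del raw

    # shot-noise floor for the rolling SD: the variance of the smoothed
    # image under Poisson counting is (local mean) x (sum of squared kernel
    # weights). Without it, noise-free or low-noise movies make any
    # arbitrarily small step (e.g. a dim vesicle arriving) look infinitely
    # significant, and locally underestimated rolling SDs fire false onsets.
    impulse = np.zeros((int(8 * sigma_px) + 9,) * 2)
    impulse[impulse.shape[0] // 2, impulse.shape[1] // 2] = 1.0
    kernel_ss = float((gaussian_filter(impulse, sigma_px) ** 2).sum())

    cs = np.concatenate([np.zeros((1, ny, nx)), np.cumsum(sm, axis=0)])
    cs2 = np.concatenate([np.zeros((1, ny, nx)), np.cumsum(sm**2, axis=0)])

    merge_px = params.merge_radius_um / reporter.pixel_size
    m = int(np.ceil(merge_px))
    yy, xx = np.mgrid[-m:m + 1, -m:m + 1]
    footprint = yy**2 + xx**2 <= merge_px**2
    refractory = int(round(params.refractory_s / dt))

    accepted: list[FusionEvent] = []
    sites: list[tuple[int, int]] = []     # site centres for repeated-kiss linking
    eps = 1e-12
    for t in range(W, T - 1 if params.min_consecutive == 2 else T):
        mean = (cs[t] - cs[t - W]) / W
        var = np.maximum((cs2[t] - cs2[t - W]) / W - mean**2, 0.0)
        sd = np.sqrt(var)
        shot_sd = np.sqrt(np.maximum(mean, 0.0) * kernel_ss)
        sd = np.maximum(np.maximum(sd, np.median(sd)), shot_sd)
        z = (sm[t] - mean) / np.maximum(sd, eps)
        cand = z > params.k_sd
        if params.min_consecutive == 2:
            z_next = (sm[t + 1] - mean) / np.maximum(sd, eps)
            cand &= z_next > params.k_sd
        if not cand.any():
            continue
        is_peak = sm[t] >= maximum_filter(sm[t], footprint=footprint, mode="nearest")
        cand &= is_peak
        if not cand.any():
            continue
        rows, cols = np.nonzero(cand)
        order = np.argsort(-z[rows, cols])
        for idx in order:
            r, c = int(rows[idx]), int(cols[idx])
            clash = False
            for ev in accepted:
                if t - ev.onset_frame <= refractory:
                    er, ec = ev.center_px
                    if (r - er) ** 2 + (c - ec) ** 2 <= merge_px**2:
                        clash = True
                        break
            if clash:
                continue
            # centre = brightest pixel once the event has fully developed
            tc = min(t + 1, T - 1)
            r0, r1 = max(r - 3, 0), min(r + 4, ny)
            c0, c1 = max(c - 3, 0), min(c + 4, nx)
            local = sm[tc, r0:r1, c0:c1]
            pr, pc = np.unravel_index(np.argmax(local), local.shape)
            center = (r0 + int(pr), c0 + int(pc))
            site_id = len(sites)
            for sid, (sr, sc) in enumerate(sites):
                if (center[0] - sr) ** 2 + (center[1] - sc) ** 2 <= merge_px**2:
                    site_id = sid
                    break
            if site_id == len(sites):
                sites.append(center)
            accepted.append(FusionEvent(
                event_id=len(accepted), cell_id=0, center_px=center,
                onset_frame=t, site_id=site_id))
    return accepted


# --- circle / annulus measurement ----------------------------------------

def roi_masks(shape: tuple[int, int], center: tuple[float, float],
              geometry: RoiGeometry, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean circle and annulus masks on a pixel grid.

    ``center`` is in pixel-index coordinates (may be fractional); a pixel
    belongs to a region iff its centre lies inside it: circle d <= r_c,
    annulus r_in < d <= r_out.
    """
    r_c = geometry.circle_diameter / 2.0
    r_in = geometry.annulus_inner / 2.0
    r_out = geometry.annulus_outer / 2.0
    rows = (np.arange(shape[0])[:, None] - center[0]) * pixel_size
    cols = (np.arange(shape[1])[None, :] - center[1]) * pixel_size
    d = np.sqrt(rows**2 + cols**2)
    circle = d <= r_c
    annulus = (d > r_in) & (d <= r_out)
    if not circle.any() or not annulus.any():
        raise GeometryError(
            f"pixel size {pixel_size} um too coarse: empty circle or annulus mask")
    return circle, annulus


def circle_annulus_intensity(frame: np.ndarray, center: tuple[float, float],
                             geometry: RoiGeometry, pixel_size: float) -> float:
    """mean(circle) - mean(annulus): background-corrected spot intensity."""
    frame = np.asarray(frame, dtype=float)
    circle, annulus = roi_masks(frame.shape, center, geometry, pixel_size)
    return float(frame[circle].mean() - frame[annulus].mean())


def excise_ministack(movie: MovieStack, event: FusionEvent,
                     geometry: RoiGeometry) -> MovieStack | None:
    """Square crop around the event's brightest pixel, all frames kept.

    The crop side is round(square_side / pixel_size) forced odd so the
    event pixel is exactly central; the same coordinates apply to every
    channel. Edge-proximal events are flagged ``edge`` and skipped.
    """
    n = geometry.square_side_px(movie.pixel_size)
    half = n // 2
    r, c = event.center_px
    T, ny, nx = movie.shape
    if r - half < 0 or c - half < 0 or r + half >= ny or c + half >= nx:
        event.qc.add("edge")
        log.warning("event %d at (%d, %d) too close to the field edge; skipped",
                    event.event_id, r, c)
        return None
    return MovieStack(
        data=movie.data[:, r - half:r + half + 1, c - half:c + half + 1],
        pixel_size=movie.pixel_size, frame_interval=movie.frame_interval,
        channel_label=movie.channel_label)


def extract_trace(ministack: MovieStack, onset_frame: int,
                  geometry: RoiGeometry) -> Trace:
    """Per-frame circle-annulus intensity of a ministack, fusion-aligned."""
    T = ministack.n_frames
    center = ((ministack.shape[1] - 1) / 2.0, (ministack.shape[2] - 1) / 2.0)
    circle, annulus = roi_masks(ministack.shape[1:], center, geometry,
                                ministack.pixel_size)
    data = ministack.astype_float()
    vals = data[:, circle].mean(axis=1) - data[:, annulus].mean(axis=1)
    time = (np.arange(T) - onset_frame) * ministack.frame_interval
    return Trace(values=vals, time=time, channel_label=ministack.channel_label)


# --- normalisation --------------------------------------------------------

def normalize_reporter_trace(trace: Trace, *, baseline_window_s: float = 10.0,
                             peak_window_s: float = 10.0) -> Trace:
    """Baseline-subtract and peak-normalise a pH-reporter trace.

    The mean over the last ``baseline_window_s`` before fusion maps to 0
    and the maximum over [0, peak_window_s] after onset maps to 1.
    """
    base_mask = (trace.time >= -baseline_window_s) & (trace.time < 0)
    if trace.time[0] > -baseline_window_s or not base_mask.any():
        raise NormalizationError(
            f"trace lacks {baseline_window_s} s of pre-fusion baseline")
    peak_mask = (trace.time >= 0) & (trace.time <= peak_window_s)
    if not peak_mask.any():
        raise NormalizationError("trace has no post-onset fusion window")
    baseline = float(trace.values[base_mask].mean())
    peak = float(trace.values[peak_mask].max())
    span = peak - baseline
    if span <= 0:
        raise NormalizationError("non-positive dynamic range; event unusable")
    return Trace(values=(trace.values - baseline) / span, time=trace.time,
                 channel_label=trace.channel_label)


def normalize_marker_trace(trace: Trace) -> Trace:
    """Normalise a vesicle-marker trace to its pre-fusion maximum."""
    pre = trace.time < 0
    if not pre.any():
        raise NormalizationError("marker trace has no pre-fusion frames")
    peak = float(trace.values[pre].max())
    if peak <= 0:
        raise NormalizationError("marker trace has no positive pre-fusion signal")
    return Trace(values=trace.values / peak, time=trace.time,
                 channel_label=trace.channel_label)


# --- ensemble averaging ---------------------------------------------------

def apply_exclusion_rules(events: list[FusionEvent], n_frames: int,
                          params: QuantifyParams | None = None) -> list[FusionEvent]:
    """Drop events too close to the recording's start or end.

    Events within the first ``exclude_start_frames`` or the last
    ``exclude_end_frames`` of the recording are excluded from averages
    (their pre-fusion baseline or post-fusion course is truncated); they
    are flagged, not deleted.
    """
    params = params or QuantifyParams()
    kept = []
    for ev in events:
        if ev.onset_frame < params.exclude_start_frames:
            ev.qc.add("excluded_early")
        elif ev.onset_frame > n_frames - params.exclude_end_frames:
            ev.qc.add("excluded_late")
        else:
            kept.append(ev)
    return kept


def _aligned_matrix(traces: list[Trace]) -> tuple[np.ndarray, np.ndarray]:
    """Stack fusion-aligned traces on a common time grid, NaN-padded."""
    dt = traces[0].frame_interval
    offsets = [int(round(tr.time[0] / dt)) for tr in traces]
    lo = min(offsets)
    hi = max(o + len(tr.time) for o, tr in zip(offsets, traces))
    grid = np.arange(lo, hi) * dt
    mat = np.full((len(traces), hi - lo), np.nan)
    for i, (o, tr) in enumerate(zip(offsets, traces)):
        mat[i, o - lo:o - lo + len(tr.values)] = tr.values
    return grid, mat


def ensemble_average(events: list[FusionEvent], channel: str, n_frames: int,
                     params: QuantifyParams | None = None,
                     level: str | None = None) -> EnsembleTrace:
    """Fusion-aligned ensemble mean +/- SEM.

    Default level ``per-cell``: individual traces are first averaged within
    each cell, then cell averages are averaged with SEM across cells.
    ``pooled`` averages individual traces directly. Time bins with fewer
    than two contributing units are masked NaN.
    """
    params = params or QuantifyParams()
    level = level or params.level
    kept = apply_exclusion_rules(events, n_frames, params)
    kept = [ev for ev in kept if channel in ev.traces]
    if not kept:
        raise EnsembleError("no events survive the exclusion rules")

    if level == "per-cell":
        units = []
        for cell_id in sorted({ev.cell_id for ev in kept}):
            cell_traces = [ev.traces[channel] for ev in kept if ev.cell_id == cell_id]
            grid, mat = _aligned_matrix(cell_traces)
            with np.errstate(invalid="ignore"):
                vals = np.nanmean(mat, axis=0)
            units.append(Trace(values=vals, time=grid, channel_label=channel))
        n_cells = len(units)
    else:
        units = [ev.traces[channel] for ev in kept]
        n_cells = len({ev.cell_id for ev in kept})

    grid, mat = _aligned_matrix(units)
    n_per_bin = np.sum(np.isfinite(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(n_per_bin, 1))
    thin = n_per_bin < 2
    mean[thin] = np.nan
    sem[thin] = np.nan
    return EnsembleTrace(time=grid, mean=mean, sem=sem,
                         n_events=len(kept), n_cells=n_cells, level=level)


# --- tethering metrics ----------------------------------------------------

def tethering_metrics(trace_or_ensemble, *, window_s: float = 50.0) -> dict:
    """Tethering-duration metrics of a normalised marker trace.

    ``integral`` is the Riemann sum of the normalised intensity times the
    frame interval over [-window_s, 0) before fusion onset (units: s, since
    intensity is normalised); ``half_rise_time`` is the interpolated time
    before fusion at which the trace first exceeds 0.5 (earliest crossing),
    reported as positive seconds.
    """
    if isinstance(trace_or_ensemble, EnsembleTrace):
        time, values = trace_or_ensemble.time, trace_or_ensemble.mean
    else:
        time, values = trace_or_ensemble.time, trace_or_ensemble.values
    dt = float(time[1] - time[0])
    mask = (time >= -window_s) & (time < 0)
    expected = int(round(window_s / dt))
    if mask.sum() < expected:
        raise ValueError(
            f"trace covers only {mask.sum()} of the {expected} frames in "
            f"[-{window_s}, 0) s")
    vals = values[mask]
    if np.any(~np.isfinite(vals)):
        raise ValueError("non-finite values inside the tethering window")
    integral = float(np.sum(vals) * dt)

    t_win = time[mask]
    half_rise = np.nan
    above = vals >= 0.5
    if above.any():
        i = int(np.argmax(above))      # earliest crossing
        if i == 0:
            t_cross = t_win[0]
        else:
            v0, v1 = vals[i - 1], vals[i]
            t_cross = t_win[i - 1] + (0.5 - v0) / (v1 - v0) * dt
        half_rise = float(-t_cross)
    return {"integral": integral, "half_rise_time": half_rise}
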