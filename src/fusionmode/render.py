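"""Forward model: render ground-truth kinetics into TIRF movies.

Each vesicle contributes a 2D Gaussian spot whose total photon flux is

    photons_per_vesicle * brightness(pH) * exp(-z / penetration_depth)

and whose width is sqrt(psf_sigma^2 + spread_sigma(t)^2). Spots are
integrated over pixel areas with the error function, so photon totals are
exact to machine precision on an unbounded grid. The camera applies Poisson
shot noise on photons, linear gain, additive Gaussian read noise and clips
to the bit depth; with noise disabled the expectation is returned as float.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .kinetics import EventKinetics, event_brightness, simulate_event_kinetics
from .movie import EVENT_COLUMNS, MovieStack
from .params import MODES, ImagingParams, KineticParams, ParameterError, ReporterModel


@dataclass(frozen=True)
class ChannelSpec:
    """One rendered acquisition channel.

    ``role`` selects the source of brightness: ``reporter`` follows the
    lumen pH (with post-FF receptor dilution), ``ligand`` is the
    pH-insensitive cargo channel, ``tether`` renders the tether-marker
    step function.
    """

    label: str
    reporter: ReporterModel
    role: str = "reporter"

    def __post_init__(self) -> None:
        if self.role not in ("reporter", "ligand", "tether"):
            raise ParameterError(f"unknown channel role {self.role!r}")


def default_channels(*, tether: bool = False,
                     reporter_kind: str = "pH_sensitive",
                     residual_fraction: float = 0.0) -> list[ChannelSpec]:
    """Reporter + ligand (+ optional tether marker) channel set."""
    channels = [
        ChannelSpec("reporter", ReporterModel(kind=reporter_kind,
                                              residual_fraction=residual_fraction),
                    role="reporter"),
        ChannelSpec("ligand", ReporterModel(kind="pH_insensitive"), role="ligand"),
    ]
    if tether:
        channels.append(ChannelSpec("tether", ReporterModel(kind="pH_insensitive"),
                                    role="tether"))
    return channels


def _pixel_gaussian_patch(shape, center_px, sigma_px, photons):
    """Photon expectation of a spot integrated over pixel areas.

    ``center_px`` is in pixel-index coordinates where pixel (i, j) spans
    [i, i+1) x [j, j+1) and its centre sits at (i+0.5, j+0.5). Returns
    (row_slice, col_slice, patch).
    """
    cy, cx = center_px
    half = int(np.ceil(5.0 * sigma_px + 3.0))
    r0 = max(int(np.floor(cy)) - half, 0)
    r1 = min(int(np.floor(cy)) + half + 1, shape[0])
    c0 = max(int(np.floor(cx)) - half, 0)
    c1 = min(int(np.floor(cx)) + half + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1 + 1, dtype=float)
    cols = np.arange(c0, c1 + 1, dtype=float)
    fy = ndtr((rows - (cy + 0.5)) / sigma_px)
    fx = ndtr((cols - (cx + 0.5)) / sigma_px)
    patch = photons * np.outer(np.diff(fy), np.diff(fx))
    return slice(r0, r1), slice(c0, c1), patch


def _channel_brightness(event: EventKinetics, spec: ChannelSpec,
                        kinetics: KineticParams, imaging: ImagingParams) -> np.ndarray:
    if spec.role == "tether":
        b = event.tethered.astype(float)
    else:
        dilution = kinetics.dilution_rate if spec.role == "reporter" else 0.0
        b = event_brightness(event, spec.reporter, dilution_rate=dilution,
                             penetration_depth=imaging.penetration_depth)
    if imaging.bleaching_rate > 0:
        b = b * np.exp(-imaging.bleaching_rate * event.times)
    return b


def render_movie(
    events: list[EventKinetics],
    channels: list[ChannelSpec],
    imaging: ImagingParams,
    kinetics: KineticParams | None = None,
    *,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    cell_id: int = 0,
) -> tuple[dict[str, MovieStack], pd.DataFrame]:
    """Render events into per-channel movies plus their ground-truth table.

    An empty event list yields a valid background-only movie. With
    ``noise=False`` the Poisson draw is replaced by its expectation and read
    noise is disabled; stacks are then float64 (unclipped expectation times
    gain) so analytic checks are exact.
    """
    kinetics = kinetics or KineticParams()
    if rng is None:
        rng = np.random.default_rng(imaging.seed)
    ny, nx = imaging.field_size
    n_frames = imaging.n_frames

    expect = np.full((n_frames, ny, nx), float(imaging.background_photons))
    records = []
    for eid, ev in enumerate(events):
        x_um, y_um = ev.xy_um
        col = x_um / imaging.pixel_size - 0.5
        row = y_um / imaging.pixel_size - 0.5
        if not (0 <= row < ny and 0 <= col < nx):
            raise ParameterError(f"event {eid} at ({x_um}, {y_um}) um lies outside the field")
        brightness = [
            _channel_brightness(ev, spec, kinetics, imaging) for spec in channels
        ]
        sigma_px = np.sqrt(imaging.psf_sigma**2 + ev.spread_sigma**2) / imaging.pixel_size
        records.append({
            "event_id": eid,
            "cell_id": cell_id,
            "mode": ev.mode,
            "onset_frame": ev.onset_frame(imaging.frame_interval),
            "x_px": int(round(col)),
            "y_px": int(round(row)),
            "dwell_s": ev.dwell,
        })
        ev._render_cache = (row, col, sigma_px, brightness)  # type: ignore[attr-defined]

    stacks: dict[str, MovieStack] = {}
    for ci, spec in enumerate(channels):
        chan = expect.copy()
        for ev in events:
            row, col, sigma_px, brightness = ev._render_cache  # type: ignore[attr-defined]
            b = brightness[ci]
            for t in range(n_frames):
                if b[t] <= 0:
                    continue
                drawn = _pixel_gaussian_patch(
                    (ny, nx), (row, col), float(sigma_px[t]),
                    imaging.photons_per_vesicle * b[t])
                if drawn is not None:
                    rs, cs, patch = drawn
                    chan[t, rs, cs] += patch
        if noise:
            counts = rng.poisson(chan).astype(float) * imaging.camera_gain
            if imaging.read_noise_sd > 0:
                counts += rng.normal(0.0, imaging.read_noise_sd, size=counts.shape)
            counts = np.clip(np.rint(counts), 0, imaging.max_count)
            data = counts.astype(np.uint16 if imaging.bit_depth == 16 else np.uint8)
        else:
            data = chan * imaging.camera_gain
        stacks[spec.label] = MovieStack(
            data=data, pixel_size=imaging.pixel_size,
            frame_interval=imaging.frame_interval, channel_label=spec.label)

    for ev in events:
        if hasattr(ev, "_render_cache"):
            del ev._render_cache

    truth = pd.DataFrame(records, columns=EVENT_COLUMNS)
    return stacks, truth


# --- dataset generation ---------------------------------------------------

@dataclass
class CellDataset:
    """Rendered movies plus ground truth for one simulated cell."""

    cell_id: int
    movies: dict[str, MovieStack]
    ground_truth: pd.DataFrame
    events: list[EventKinetics] = field(default_factory=list)


def _event_sites(imaging: ImagingParams, n_events: int, geometry_side_um: float,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Jittered grid of event pixels, spaced so ministack crops stay clean."""
    ny, nx = imaging.field_size
    side_px = int(round(geometry_side_um / imaging.pixel_size)) | 1
    margin = side_px // 2 + 1
    spacing = side_px + 1
    rows = np.arange(margin, ny - margin, spacing)
    cols = np.arange(margin, nx - margin, spacing)
    sites = [(int(r), int(c)) for r in rows for c in cols]
    if len(sites) < n_events:
        raise ParameterError(
            f"field {imaging.field_size} too small for {n_events} events with "
            f"{geometry_side_um} um crops ({len(sites)} sites available)")
    idx = rng.choice(len(sites), size=n_events, replace=False)
    return [sites[i] for i in idx]


def generate_dataset(
    n_cells: int,
    events_per_cell: int,
    params: KineticParams,
    channels: list[ChannelSpec],
    imaging: ImagingParams,
    hepes_condition: str = "high",
    *,
    master_seed: int | None = None,
    noise: bool = True,
    crop_side_um: float = 4.0,
    fusion_frame_range: tuple[int, int] | None = None,
) -> list[CellDataset]:
    """Simulate and render a multi-cell experiment.

    Per-cell RNG streams are spawned deterministically from ``master_seed``
    (default: ``imaging.seed``), so a fixed seed reproduces the dataset
    bit-identically. Fusion times are drawn uniformly inside
    ``fusion_frame_range`` (default: frames 60 to n_frames - 130), which
    keeps every event clear of the ensemble-averaging exclusion windows and
    leaves a full post-fusion observation window.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    params = params.with_hepes(hepes_condition)
    if master_seed is None:
        master_seed = imaging.seed
    if fusion_frame_range is None:
        lo = min(60, max(1, imaging.n_frames // 4))
        hi = max(lo + 1, imaging.n_frames - 130)
        fusion_frame_range = (lo, hi)
    lo_f, hi_f = fusion_frame_range
    duration = imaging.n_frames * imaging.frame_interval

    cells = []
    for cell_id, seq in enumerate(np.random.SeedSequence(master_seed).spawn(n_cells)):
        rng = np.random.default_rng(seq)
        sites = _event_sites(imaging, events_per_cell, crop_side_um, rng)
        events = []
        for row, col in sites:
            mode = MODES[rng.choice(3, p=np.asarray(params.mode_probabilities))]
            fusion_time = float(rng.uniform(lo_f, hi_f)) * imaging.frame_interval
            xy = ((col + 0.5) * imaging.pixel_size, (row + 0.5) * imaging.pixel_size)
            events.append(simulate_event_kinetics(
                params, mode, duration, rng,
                frame_interval=imaging.frame_interval,
                fusion_time=fusion_time, xy_um=xy))
        movies, truth = render_movie(events, channels, imaging, params,
                                     rng=rng, noise=noise, cell_id=cell_id)
        cells.append(CellDataset(cell_id=cell_id, movies=movies,
                                 ground_truth=truth, events=events))
    return cells


# --- membrane scenes ------------------------------------------------------

def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Rasterized disk: pixels whose centres lie within ``radius``."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy + 0.5 - center[0]) ** 2 + (xx + 0.5 - center[1]) ** 2 <= radius**2


def generate_membrane_scene(
    initial_mask: np.ndarray,
    growth_script,
    imaging: ImagingParams,
    *,
    contrast: float = 4.0,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> tuple[MovieStack, np.ndarray]:
    """Render a whole-cell footprint movie plus its ground-truth masks.

    ``growth_script(frame_index, initial_mask) -> mask`` supplies the
    footprint of each frame (``None`` means a static scene). In-cell pixels
    receive ``contrast`` times the background photon flux on top of
    background, giving the segmentation stage a configurable but distinct
    foreground. A footprint touching the field border raises, since growth
    would be clipped.
    """
    if rng is None:
        rng = np.random.default_rng(imaging.seed)
    initial_mask = np.asarray(initial_mask, dtype=bool)
    ny, nx = imaging.field_size
    if initial_mask.shape != (ny, nx):
        raise ParameterError("initial footprint shape must match imaging.field_size")
    masks = np.empty((imaging.n_frames, ny, nx), dtype=bool)
    for t in range(imaging.n_frames):
        m = initial_mask if growth_script is None else np.asarray(
            growth_script(t, initial_mask), dtype=bool)
        if m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any():
            raise ParameterError(f"footprint reaches the field border at frame {t}")
        masks[t] = m

    expect = imaging.background_photons * (1.0 + contrast * masks.astype(float))
    if noise:
        counts = rng.poisson(expect).astype(float) * imaging.camera_gain
        if imaging.read_noise_sd > 0:
            counts += rng.normal(0.0, imaging.read_noise_sd, size=counts.shape)
        counts = np.clip(np.rint(counts), 0, imaging.max_count)
        data = counts.astype(np.uint16 if imaging.bit_depth == 16 else np.uint8)
    else:
        data = expect * imaging.camera_gain
    stack = MovieStack(data=data, pixel_size=imaging.pixel_size,
                       frame_interval=imaging.frame_interval,
                       channel_label="membrane")
    return stack, masks
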