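"""End-to-end stage chaining: detect -> quantify -> classify.

These helpers connect the per-stage functions into the per-cell workflow
the CLI exposes, and provide ground-truth matching used to validate the
pipeline on simulator output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import (ModeFeatures, classify_event, line_profile_width_series,
                       post_fusion_decay)
from .config import ClassifyParams, Config, DetectionParams, QuantifyParams
from .movie import MovieStack
from .quantify import (FusionEvent, NormalizationError, detect_fusion_events,
                       excise_ministack, extract_trace, normalize_marker_trace,
                       normalize_reporter_trace)

log = logging.getLogger("fusionmode")

CALL_COLUMNS = ["event_id", "cell_id", "mode", "half_decay_s", "plateau",
                "width_slope_um2_per_s", "dwell_s", "rule_fired",
                "onset_frame", "x_px", "y_px"]


def quantify_cell(movies: dict[str, MovieStack], events: list[FusionEvent],
                  params: QuantifyParams | None = None) -> list[FusionEvent]:
    """Attach per-channel circle-annulus traces to each detected event.

    The crop found on the reporter channel is transferred to the same
    coordinates in every other channel. Edge-proximal events keep their
    ``edge`` flag and receive no traces.
    """
    params = params or QuantifyParams()
    geometry = params.geometry
    for ev in events:
        for label, movie in movies.items():
            mini = excise_ministack(movie, ev, geometry)
            if mini is None:
                break
            ev.traces[label] = extract_trace(mini, ev.onset_frame, geometry)
    return events


def event_features(movies: dict[str, MovieStack], event: FusionEvent,
                   qparams: QuantifyParams, cparams: ClassifyParams) -> ModeFeatures:
    """Compute decay, plateau, spread and tether features for one event."""
    half_decay = plateau = None
    if "reporter" in event.traces:
        try:
            norm = normalize_reporter_trace(
                event.traces["reporter"],
                baseline_window_s=qparams.baseline_window_s,
                peak_window_s=qparams.peak_window_s)
            half_decay, plateau = post_fusion_decay(
                norm, peak_window_s=qparams.peak_window_s,
                plateau_window_s=cparams.plateau_window_s,
                min_plateau_coverage_s=cparams.min_plateau_coverage_s)
        except NormalizationError as exc:
            event.qc.add("unusable_reporter")
            log.warning("event %d reporter unusable: %s", event.event_id, exc)

    slope = slope_se = None
    if "ligand" in movies:
        mini = excise_ministack(movies["ligand"], event, qparams.geometry)
        if mini is not None:
            _, _, slope, slope_se = line_profile_width_series(
                mini, event.onset_frame, fit_window_s=cparams.fit_window_s)

    tether_persistent = None
    dwell = None
    if "tether" in event.traces:
        try:
            tether = normalize_marker_trace(event.traces["tether"])
            lo, hi = cparams.plateau_window_s
            late = (tether.time >= lo) & (tether.time <= hi)
            if late.any():
                tether_persistent = bool(tether.values[late].mean() > 0.5)
            pre = tether.values[tether.time < 0]
            t_pre = tether.time[tether.time < 0]
            on = pre >= 0.5
            if on.any():
                dwell = float(-t_pre[np.argmax(on)])
        except NormalizationError:
            pass

    return ModeFeatures(half_decay_time=half_decay, plateau=plateau,
                        width_slope=slope, width_slope_se=slope_se,
                        dwell=dwell, hepes_condition=cparams.hepes_condition,
                        tether_persistent=tether_persistent)


def classify_cell(movies: dict[str, MovieStack], events: list[FusionEvent],
                  qparams: QuantifyParams | None = None,
                  cparams: ClassifyParams | None = None) -> pd.DataFrame:
    """Feature extraction + mode call for every quantified event."""
    qparams = qparams or QuantifyParams()
    cparams = cparams or ClassifyParams()
    rows = []
    for ev in events:
        if "edge" in ev.qc or not ev.traces:
            continue
        feats = event_features(movies, ev, qparams, cparams)
        call = classify_event(feats, cparams)
        ev.mode = call.mode
        rows.append({
            "event_id": ev.event_id, "cell_id": ev.cell_id, "mode": call.mode,
            "half_decay_s": feats.half_decay_time, "plateau": feats.plateau,
            "width_slope_um2_per_s": feats.width_slope, "dwell_s": feats.dwell,
            "rule_fired": call.rule_fired, "onset_frame": ev.onset_frame,
            "x_px": ev.center_px[1], "y_px": ev.center_px[0],
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def analyze_cell(movies: dict[str, MovieStack], cfg: Config,
                 cell_id: int = 0) -> tuple[list[FusionEvent], pd.DataFrame]:
    """Full per-cell chain on rendered movies: detect, quantify, classify."""
    events = detect_fusion_events(movies["reporter"], cfg.detect)
    for ev in events:
        ev.cell_id = cell_id
    quantify_cell(movies, events, cfg.quantify)
    calls = classify_cell(movies, events, cfg.quantify, cfg.classify)
    return events, calls


def match_events(truth: pd.DataFrame, events: list[FusionEvent],
                 tol_px: int = 1, tol_frames: int = 1) -> pd.DataFrame:
    """Greedy one-to-one match of ground-truth events to detections.

    A match requires per-axis pixel distance <= ``tol_px`` and onset-frame
    difference <= ``tol_frames``. Returns the truth table with columns
    ``det_event_id`` (or -1), ``onset_err`` and ``loc_err`` added.
    """
    used: set[int] = set()
    out = truth.copy()
    out["det_event_id"] = -1
    out["onset_err"] = np.nan
    out["loc_err"] = np.nan
    for i, row in truth.iterrows():
        best, best_cost = None, None
        for ev in events:
            if ev.event_id in used:
                continue
            d_frame = abs(ev.onset_frame - int(row["onset_frame"]))
            d_px = max(abs(ev.center_px[0] - int(row["y_px"])),
                       abs(ev.center_px[1] - int(row["x_px"])))
            if d_frame <= tol_frames and d_px <= tol_px:
                cost = (d_px, d_frame)
                if best_cost is None or cost < best_cost:
                    best, best_cost = ev, cost
        if best is not None:
            used.add(best.event_id)
            out.loc[i, "det_event_id"] = best.event_id
            out.loc[i, "onset_err"] = abs(best.onset_frame - int(row["onset_frame"]))
            out.loc[i, "loc_err"] = best_cost[0]
    return out
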