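"""Fusion-mode features and FF / KR / KS classification.

Three diagnostics distinguish the modes:

* **post-fusion decay** of the normalised pH-reporter trace — fast for full
  fusion (receptor dilutes into the plasma membrane), slow for kiss-and-run
  under high extracellular HEPES (reacidification is buffered and the decay
  reflects the vesicle's departure through the evanescent field);
* **plateau** — a kiss-and-stay vesicle neither departs nor (under high
  HEPES) reacidifies, so its reporter signal stays elevated long after
  fusion;
* **lateral spread** — only full fusion releases cargo into the membrane,
  so Gaussian line-profile widths grow as sigma^2(t) = sigma_psf^2 + 2 D t.

Under high HEPES the FF/KR contrast is read from the reporter decay; under
low HEPES reacidification confounds the reporter decay and the ligand
spread criterion takes priority.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ClassifyParams
from .movie import MovieStack
from .quantify import Trace

log = logging.getLogger("fusionmode")


class FeatureError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass
class ModeFeatures:
    """Per-event diagnostics feeding the mode decision."""

    half_decay_time: float | None     # s; None = censored (never falls to 0.5)
    plateau: float | None             # mean normalised reporter, late window
    width_slope: float | None         # d(sigma^2)/dt, um^2/s; None = censored
    width_slope_se: float | None
    dwell: float | None = None
    hepes_condition: str = "high"
    tether_persistent: bool | None = None


@dataclass
class ModeCall:
    mode: str                         # FF | KR | KS | unclassified
    features: ModeFeatures
    rule_fired: str


# --- decay / plateau features --------------------------------------------

def post_fusion_decay(trace: Trace, *, peak_window_s: float = 10.0,
                      plateau_window_s: tuple[float, float] = (30.0, 60.0),
                      min_plateau_coverage_s: float = 10.0) -> tuple[float | None, float | None]:
    """(half_decay_time, plateau) of a peak-normalised reporter trace.

    ``half_decay_time`` is the first linearly interpolated crossing of 0.5
    after the post-onset peak, in seconds after onset; None when the trace
    never falls below 0.5 (censored, the kiss-and-stay signature).
    ``plateau`` is the mean over the late window; None when the trace
    covers less than ``min_plateau_coverage_s`` of it.
    """
    post = trace.time >= 0
    if not post.any():
        raise FeatureError("trace ends before fusion onset")
    t = trace.time[post]
    v = trace.values[post]

    peak_mask = t <= peak_window_s
    i_peak = int(np.argmax(v[peak_mask]))
    half_decay: float | None = None
    below = v[i_peak:] <= 0.5
    if below.any():
        j = i_peak + int(np.argmax(below))
        if j == 0:
            half_decay = float(t[0])
        else:
            v0, v1 = v[j - 1], v[j]
            frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.0
            half_decay = float(t[j - 1] + frac * (t[j] - t[j - 1]))

    lo, hi = plateau_window_s
    pm = (t >= lo) & (t <= hi)
    dt = trace.frame_interval
    plateau = float(v[pm].mean()) if pm.sum() * dt >= min_plateau_coverage_s else None
    return half_decay, plateau


# --- line-profile spread --------------------------------------------------

def _gauss1d(x, offset, amp, mu, sigma):
    return offset + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_profile_sigma(profile: np.ndarray, sigma0: float) -> tuple[float, float] | None:
    """Fit offset + amp * Gaussian; return (sigma, sigma_err) in px or None."""
    x = np.arange(len(profile), dtype=float)
    offset0 = float(profile.min())
    amp0 = float(profile.max() - offset0)
    if amp0 <= 0:
        return None
    mu0 = float(np.argmax(profile))
    sigma_max = len(profile) / 2.0
    try:
        popt, pcov = optimize.curve_fit(
            _gauss1d, x, profile, p0=(offset0, amp0, mu0, min(sigma0, sigma_max)),
            bounds=([-np.inf, 0.0, 0.0, 0.2], [np.inf, np.inf, len(profile), sigma_max]),
            maxfev=2000)
    except (RuntimeError, ValueError):
        return None
    sigma = float(popt[3])
    err = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else np.inf
    if sigma >= 0.98 * sigma_max or not np.isfinite(err) or err > sigma:
        return None       # width unconstrained by this profile
    return sigma, err


def line_profile_width_series(
    ligand_ministack: MovieStack, onset_frame: int, *,
    fit_window_s: float = 5.0, psf_sigma_um: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, float | None, float | None]:
    """Gaussian line-profile widths through the event centre and their trend.

    For each frame in [onset, onset + fit_window] a horizontal and a
    vertical line profile through the centre (averaged over the three
    central rows/columns to tame shot noise) are each fitted with
    offset + amplitude * Gaussian. Returns ``(times_s, sigma_um, slope,
    slope_se)`` where ``slope`` is the error-weighted least-squares slope
    of sigma^2(t) vs t (um^2/s); fit-precision weighting keeps the late,
    dim frames of a spreading spot from drowning the trend. The slope is
    censored (None) when fewer than half the frames yield a usable fit or
    fewer than three points remain.
    """
    dt = ligand_ministack.frame_interval
    px = ligand_ministack.pixel_size
    T, ny, nx = ligand_ministack.shape
    cr, cc = ny // 2, nx // 2
    n_fit = int(round(fit_window_s / dt)) + 1
    frames = range(onset_frame, min(onset_frame + n_fit, T))
    sigma0 = max(psf_sigma_um / px, 0.5)

    data = ligand_ministack.astype_float()
    t_pts, s2_pts, var_pts = [], [], []
    frame_sigma: dict[float, list[float]] = {}
    n_attempted = 0
    for f in frames:
        n_attempted += 1
        row = data[f, max(cr - 1, 0):cr + 2, :].mean(axis=0)
        col = data[f, :, max(cc - 1, 0):cc + 2].mean(axis=1)
        got_any = False
        for profile in (row, col):
            fit = _fit_profile_sigma(profile, sigma0)
            if fit is None:
                continue
            s, err = fit
            t_rel = (f - onset_frame) * dt
            t_pts.append(t_rel)
            s2_pts.append((s * px) ** 2)
            var_pts.append((2.0 * s * err * px**2) ** 2)  # var of sigma^2
            frame_sigma.setdefault(t_rel, []).append(s * px)
            got_any = True
        if not got_any:
            continue
    times = np.asarray(sorted(frame_sigma))
    sigmas = np.asarray([np.mean(frame_sigma[t]) for t in times])

    if n_attempted == 0 or len(times) < max(3, (n_attempted + 1) // 2):
        return times, sigmas, None, None

    t_arr = np.asarray(t_pts)
    y = np.asarray(s2_pts)
    w = 1.0 / np.maximum(np.asarray(var_pts), 1e-12)
    sw = w.sum()
    tb = (w * t_arr).sum() / sw
    yb = (w * y).sum() / sw
    stt = (w * (t_arr - tb) ** 2).sum()
    if stt <= 0:
        return times, sigmas, None, None
    slope = float((w * (t_arr - tb) * (y - yb)).sum() / stt)
    resid = y - (yb + slope * (t_arr - tb))
    dof = max(len(y) - 2, 1)
    chi2 = float((w * resid**2).sum() / dof)   # scale SE by observed scatter
    slope_se = float(np.sqrt(max(chi2, 1.0) / stt))
    return times, sigmas, slope, slope_se


# --- classification -------------------------------------------------------

def classify_event(features: ModeFeatures, params: ClassifyParams | None = None) -> ModeCall:
    """Assign FF / KR / KS from per-event features.

    Rule order: (1) a sustained late plateau (or a persistent tether-marker
    signal when that channel exists) means the vesicle is stuck after a
    transient fusion -> KS; (2) the condition-appropriate FF criterion
    (fast reporter decay under high HEPES, significant ligand spread under
    low HEPES, the other as fallback when censored) -> FF; (3) otherwise
    KR. Events whose features are all censored are left unclassified.
    """
    p = params or ClassifyParams()
    f = features

    if p.use_tether_for_ks and f.tether_persistent:
        return ModeCall("KS", f, "tether-persistent")
    if f.plateau is not None and f.plateau > p.plateau_min:
        return ModeCall("KS", f, "plateau")

    slope_sig = (
        f.width_slope is not None and f.width_slope_se is not None
        and f.width_slope > p.slope_min
        and f.width_slope > p.slope_se_factor * f.width_slope_se
    )
    fast_decay = f.half_decay_time is not None and f.half_decay_time < p.fast_max_s

    if f.hepes_condition == "high":
        if f.half_decay_time is not None:
            if fast_decay:
                return ModeCall("FF", f, "fast-decay")
        elif slope_sig:
            return ModeCall("FF", f, "spread-fallback")
        elif f.width_slope is None and f.plateau is None:
            return ModeCall("unclassified", f, "all-censored")
    else:
        if f.width_slope is not None:
            if slope_sig:
                return ModeCall("FF", f, "spread")
        elif f.half_decay_time is not None:
            if fast_decay:
                return ModeCall("FF", f, "fast-decay-fallback")
        elif f.plateau is None:
            return ModeCall("unclassified", f, "all-censored")
    return ModeCall("KR", f, "default")


def mode_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-mode frequencies (%) as mean +/- SEM across cells.

    ``calls`` needs columns ``cell_id`` and ``mode``. Percentages are
    computed per cell over classified events only (each cell sums to 100);
    cells with no classified event are dropped with a warning.
    """
    modes = ["FF", "KR", "KS"]
    rows = []
    for cell_id, grp in calls.groupby("cell_id"):
        classified = grp[grp["mode"].isin(modes)]
        if classified.empty:
            log.warning("cell %s has no classified events; excluded", cell_id)
            continue
        counts = classified["mode"].value_counts()
        n = len(classified)
        rows.append({"cell_id": cell_id, "n_events": n,
                     **{m: 100.0 * counts.get(m, 0) / n for m in modes}})
    if not rows:
        raise DegenerateInputError("no cell has classified events")
    per_cell = pd.DataFrame(rows)
    out = []
    for m in modes:
        vals = per_cell[m].to_numpy()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out.append({"mode": m, "mean_pct": float(vals.mean()),
                    "sem_pct": float(sem), "n_cells": len(vals)})
    summary = pd.DataFrame(out)
    summary.attrs["per_cell"] = per_cell
    return summary


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test (pooled variance).

    Returns (t, p) with n_a + n_b - 2 degrees of freedom. Two identical
    constant groups give (0, 1); constant groups with unequal means have no
    valid t statistic and raise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateInputError(
            "zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
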