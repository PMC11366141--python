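"""Movement-biomarker extraction from raw tri-axial accelerometry.

Processing chain (mirroring established ICU activity-recognition practice):

1. linear-interpolation downsampling to 10 Hz,
2. zero-phase 4th-order Butterworth high-pass at 0.2 Hz (removes gravity and
   slow postural drift),
3. masking of documented passive-movement episodes,
4. non-overlapping 5-s windows with per-window signal magnitude area
   SMA = mean(|ax| + |ay| + |az|), in g,
5. activity bouts = maximal runs of consecutive non-excluded windows with
   SMA >= 0.135 g,
6. feature summary: %active, overall intensity, bouts/hour, and log-normal
   ML location/scale of bout intensity and duration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .types import (
    AccelRecording,
    ActivityBout,
    ExclusionEpisode,
    MovementFeatureSet,
    WindowSeries,
    merge_episodes,
)

DEFAULT_TARGET_HZ = 10.0
DEFAULT_CUTOFF_HZ = 0.2
DEFAULT_FILTER_ORDER = 4
DEFAULT_WINDOW_S = 5.0
DEFAULT_THRESHOLD_G = 0.135


def resample_to_10hz(rec: AccelRecording, target_hz: float = DEFAULT_TARGET_HZ) -> AccelRecording:
    """Resample a recording onto a uniform ``target_hz`` grid.

    Values are obtained by linear interpolation of each axis; an output
    sample is flagged excluded if either neighbouring input sample was
    excluded (conservative).  A recording already on the target grid is
    returned unchanged (copy).
    """
    rec.check_uniform_grid()
    if rec.sample_rate_hz < target_hz - 1e-9:
        raise ValueError(
            f"cannot upsample: input rate {rec.sample_rate_hz} Hz below target {target_hz} Hz"
        )
    if abs(rec.sample_rate_hz - target_hz) < 1e-9:
        return rec.copy()
    span = rec.t[-1] - rec.t[0]
    n_out = int(math.floor(span * target_hz + 1e-9)) + 1
    t_out = rec.t[0] + np.arange(n_out) / target_hz
    xyz_out = np.empty((n_out, 3))
    for k in range(3):
        xyz_out[:, k] = np.interp(t_out, rec.t, rec.xyz[:, k])
    excl_out = np.interp(t_out, rec.t, rec.excluded.astype(float)) > 0.0
    return AccelRecording(
        t=t_out,
        xyz=xyz_out,
        sample_rate_hz=target_hz,
        leg_id=rec.leg_id,
        patient_id=rec.patient_id,
        excluded=excl_out,
    )


def highpass_filter(
    rec: AccelRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> AccelRecording:
    """Zero-phase Butterworth high-pass of each axis (forward-backward).

    The forward-backward application cancels phase shifts, so bout
    boundaries are not displaced; the stopband attenuation of the filter is
    applied twice.
    """
    if not 0 < cutoff_hz < rec.sample_rate_hz / 2:
        raise ValueError("cutoff must lie in (0, sample_rate/2)")
    settle_s = 3.0 / cutoff_hz  # ~3x the filter settling length
    if rec.duration_s < settle_s:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s too short for a {cutoff_hz} Hz "
            f"high-pass (needs >= {settle_s:.0f} s)"
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.sample_rate_hz, output="sos")
    out = rec.copy()
    for k in range(3):
        out.xyz[:, k] = sps.sosfiltfilt(sos, rec.xyz[:, k])
    return out


def mask_exclusions(rec: AccelRecording, episodes: list[ExclusionEpisode]) -> AccelRecording:
    """Flag samples falling inside any exclusion episode.

    Episodes are merged if overlapping and clipped to the recording span;
    flagged samples contribute to no window statistics downstream.
    """
    out = rec.copy()
    for ep in merge_episodes(episodes):
        out.excluded |= (rec.t >= ep.start_s) & (rec.t < ep.end_s)
    return out


def compute_sma(rec: AccelRecording, window_s: float = DEFAULT_WINDOW_S) -> WindowSeries:
    """Per-window signal magnitude area on non-overlapping windows.

    SMA is the mean over the window's samples of |ax| + |ay| + |az|, i.e. the
    time-normalised integral of the rectified three-axis sum, in units of g.
    A window containing any excluded sample is wholly excluded; a trailing
    partial window is dropped.
    """
    rec.check_uniform_grid()
    nw = window_s * rec.sample_rate_hz
    if abs(nw - round(nw)) > 1e-6:
        raise ValueError("window length must be an integer number of samples")
    nw = int(round(nw))
    n_win = rec.t.shape[0] // nw
    if n_win < 1:
        raise ValueError("recording shorter than one window")
    n_used = n_win * nw
    rect = np.abs(rec.xyz[:n_used]).sum(axis=1)
    sma = rect.reshape(n_win, nw).mean(axis=1)
    excluded = rec.excluded[:n_used].reshape(n_win, nw).any(axis=1)
    starts = rec.t[0] + np.arange(n_win) * window_s
    return WindowSeries(window_start_s=starts, sma_g=sma, excluded=excluded, window_s=window_s)


def detect_bouts(ws: WindowSeries, threshold_g: float = DEFAULT_THRESHOLD_G) -> list[ActivityBout]:
    """Activity bouts: maximal runs of non-excluded windows with SMA >= threshold.

    Excluded windows break runs; a single sub-threshold window ends a bout
    (no gap tolerance).  Bout intensity is the mean SMA of its windows.
    """
    active = (ws.sma_g >= threshold_g) & ~ws.excluded
    bouts: list[ActivityBout] = []
    i = 0
    n = ws.n_windows
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            run = slice(i, j + 1)
            bouts.append(
                ActivityBout(
                    start_s=float(ws.window_start_s[i]),
                    duration_s=(j - i + 1) * ws.window_s,
                    intensity_g=float(ws.sma_g[run].mean()),
                )
            )
            i = j + 1
        else:
            i += 1
    return bouts


def lognormal_mle(values) -> tuple[float, float]:
    """Closed-form maximum-likelihood fit of a log-normal law.

    Returns ``(logmean, logsd)``: the mean and the population (divide-by-n)
    standard deviation of the natural logs.  An empty input yields
    ``(nan, nan)``; non-positive values raise.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return (math.nan, math.nan)
    if np.any(v <= 0):
        raise ValueError("log-normal MLE requires strictly positive values")
    logs = np.log(v)
    return (float(logs.mean()), float(logs.std(ddof=0)))


def extract_features(ws: WindowSeries, bouts: list[ActivityBout]) -> MovementFeatureSet:
    """Summarise a window series and its bouts into the seven biomarkers."""
    non_excl = ~ws.excluded
    n_non_excl = int(non_excl.sum())
    if n_non_excl == 0:
        raise ValueError("no non-excluded windows: nothing to analyze")
    active_windows = sum(int(round(b.duration_s / ws.window_s)) for b in bouts)
    analyzed_hours = n_non_excl * ws.window_s / 3600.0
    int_lm, int_lsd = lognormal_mle([b.intensity_g for b in bouts])
    dur_lm, dur_lsd = lognormal_mle([b.duration_s for b in bouts])
    return MovementFeatureSet(
        pct_active=100.0 * active_windows / n_non_excl,
        overall_intensity_g=float(ws.sma_g[non_excl].mean()),
        ab_per_hour=len(bouts) / analyzed_hours,
        ab_intensity_logmean=int_lm,
        ab_intensity_logsd=int_lsd,
        ab_duration_logmean=dur_lm,
        ab_duration_logsd=dur_lsd,
        n_bouts=len(bouts),
        analyzed_hours=analyzed_hours,
    )


def extract_movement_features(
    rec: AccelRecording,
    episodes: list[ExclusionEpisode] | None = None,
    *,
    target_hz: float = DEFAULT_TARGET_HZ,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    window_s: float = DEFAULT_WINDOW_S,
    threshold_g: float = DEFAULT_THRESHOLD_G,
) -> MovementFeatureSet:
    """Run the full chain: resample, filter, mask, window, detect, summarise."""
    rec10 = resample_to_10hz(rec, target_hz)
    filt = highpass_filter(rec10, cutoff_hz=cutoff_hz, order=order)
    if episodes:
        filt = mask_exclusions(filt, episodes)
    ws = compute_sma(filt, window_s=window_s)
    bouts = detect_bouts(ws, threshold_g=threshold_g)
    return extract_features(ws, bouts)
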