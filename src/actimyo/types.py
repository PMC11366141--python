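"""Domain containers for accelerometer recordings and movement features.

The pipeline represents one leg's monitoring episode as an
:class:`AccelRecording` (tri-axial acceleration in g on a uniform grid),
reduces it to a :class:`WindowSeries` of per-window signal magnitude area
(SMA), detects :class:`ActivityBout` runs above the activity threshold, and
summarises everything into a :class:`MovementFeatureSet` of seven movement
biomarkers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: Dynamic range of the sensors, in g.
SENSOR_RANGE_G = 16.0

#: Tolerance on the uniformity of the sample grid, in seconds.
GRID_TOL_S = 1e-6


@dataclass
class AccelRecording:
    """Tri-axial acceleration time series for one leg.

    Parameters
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds on a uniform grid.
    xyz : ndarray, shape (n, 3)
        Acceleration of the x/y/z axes in units of g, |value| <= 16 g.
    sample_rate_hz : float
        Nominal sampling rate; must match the grid spacing.
    leg_id, patient_id : str
        Identifiers carried through the pipeline.
    excluded : ndarray of bool, shape (n,), optional
        Per-sample exclusion mask (passive-mobilisation episodes etc.).
    """

    t: np.ndarray
    xyz: np.ndarray
    sample_rate_hz: float
    leg_id: str = ""
    patient_id: str = ""
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise ValueError("t and xyz must have the same length")
        if self.t.shape[0] == 0:
            raise ValueError("recording is empty")
        if np.nanmax(np.abs(self.xyz)) > SENSOR_RANGE_G + 1e-9:
            raise ValueError(f"acceleration exceeds sensor range +/-{SENSOR_RANGE_G} g")
        if self.excluded is None:
            self.excluded = np.zeros(self.t.shape[0], dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape[0] != self.t.shape[0]:
                raise ValueError("excluded mask must match the number of samples")

    def check_uniform_grid(self) -> None:
        """Raise ``ValueError`` naming the first irregular gap, if any."""
        if self.t.shape[0] < 2:
            return
        dt = np.diff(self.t)
        expected = 1.0 / self.sample_rate_hz
        bad = np.flatnonzero(np.abs(dt - expected) > GRID_TOL_S)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-uniform sample grid: gap of {dt[i]:.6g} s between samples "
                f"{i} and {i + 1} (t={self.t[i]:.6g} s), expected {expected:.6g} s"
            )

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) + 1.0 / self.sample_rate_hz

    def copy(self) -> "AccelRecording":
        return replace(
            self,
            t=self.t.copy(),
            xyz=self.xyz.copy(),
            excluded=None if self.excluded is None else self.excluded.copy(),
        )


@dataclass(frozen=True)
class ExclusionEpisode:
    """Interval [start_s, end_s) of passive movement to drop from analysis."""

    start_s: float
    end_s: float
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("exclusion episode must have start_s < end_s")


def merge_episodes(episodes: list[ExclusionEpisode]) -> list[ExclusionEpisode]:
    """Merge overlapping/touching episodes into disjoint intervals."""
    if not episodes:
        return []
    eps = sorted(episodes, key=lambda e: (e.start_s, e.end_s))
    merged = [eps[0]]
    for e in eps[1:]:
        last = merged[-1]
        if e.start_s <= last.end_s:
            if e.end_s > last.end_s:
                reason = last.reason if last.reason == e.reason else "merged"
                merged[-1] = ExclusionEpisode(last.start_s, e.end_s, reason)
        else:
            merged.append(e)
    return merged


@dataclass
class WindowSeries:
    """Per-window signal magnitude area on contiguous, non-overlapping windows."""

    window_start_s: np.ndarray
    sma_g: np.ndarray
    excluded: np.ndarray
    window_s: float = 5.0

    def __post_init__(self) -> None:
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.sma_g = np.asarray(self.sma_g, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = self.window_start_s.shape[0]
        if self.sma_g.shape[0] != n or self.excluded.shape[0] != n:
            raise ValueError("window arrays must share one length")
        if n and np.nanmin(self.sma_g) < -1e-12:
            raise ValueError("SMA must be non-negative")

    @property
    def n_windows(self) -> int:
        return int(self.window_start_s.shape[0])


@dataclass(frozen=True)
class ActivityBout:
    """Maximal run of consecutive active windows (SMA >= threshold)."""

    start_s: float
    duration_s: float
    intensity_g: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class MovementFeatureSet:
    """The seven movement biomarkers for one recording.

    ``pct_active`` is the percentage of non-excluded monitored time spent in
    activity bouts; ``overall_intensity_g`` the mean SMA over non-excluded
    windows; ``ab_per_hour`` the bout rate; the four log features are the
    log-normal maximum-likelihood location/scale of bout intensity and
    duration (natural log).  With zero bouts the log features are NaN.
    """

    pct_active: float
    overall_intensity_g: float
    ab_per_hour: float
    ab_intensity_logmean: float
    ab_intensity_logsd: float
    ab_duration_logmean: float
    ab_duration_logsd: float
    n_bouts: int
    analyzed_hours: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_active <= 100.0 + 1e-9):
            raise ValueError("pct_active must lie in [0, 100]")
        if self.n_bouts == 0:
            for name in (
                "ab_intensity_logmean",
                "ab_intensity_logsd",
                "ab_duration_logmean",
                "ab_duration_logsd",
            ):
                if not math.isnan(getattr(self, name)):
                    raise ValueError(f"{name} must be NaN when n_bouts == 0")

    def to_dict(self) -> dict[str, float]:
        return {
            "pct_active": self.pct_active,
            "overall_intensity_g": self.overall_intensity_g,
            "ab_per_hour": self.ab_per_hour,
            "ab_intensity_logmean": self.ab_intensity_logmean,
            "ab_intensity_logsd": self.ab_intensity_logsd,
            "ab_duration_logmean": self.ab_duration_logmean,
            "ab_duration_logsd": self.ab_duration_logsd,
            "n_bouts": float(self.n_bouts),
            "analyzed_hours": self.analyzed_hours,
        }


#: Names of the movement-feature columns that enter the prediction model.
MOVEMENT_FEATURE_COLUMNS = [
    "overall_intensity_g",
    "pct_active",
    "ab_intensity_logmean",
    "ab_duration_logmean",
    "ab_intensity_logsd",
    "ab_duration_logsd",
]

#: The full 12-variable standardized predictor set.
PREDICTOR_COLUMNS = [
    "age",
    "sex",
    "baseline_rfm_mm",
    "msofa",
    "calorie_deficit",
    "protein_deficit",
] + MOVEMENT_FEATURE_COLUMNS
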