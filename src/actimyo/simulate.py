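"""Synthetic accelerometer recordings and cohorts with known ground truth.

The generator emulates a neurocritical-care monitoring study: per-leg
tri-axial recordings (static gravity + sensor noise + planted oscillatory
activity bouts, clipped to the +/-16 g sensor range), prospectively
documented passive-movement exclusion episodes, and a cohort whose day-10
relative rectus femoris (RFM) atrophy follows a linear model with patient
random intercepts and standardized effects of baseline RFM thickness and
%active.

Randomness is organised in named, seeded substreams so that any part can be
regenerated independently:

* per-leg recordings draw from ``SeedSequence([seed, crc32(leg_id), k])``
  with ``k`` = 0 (exclusion episodes), 1 (bout laws/placement), 2 (noise);
* the cohort draws sequentially from ``SeedSequence([seed, crc32("cohort")])``
  in three documented passes: (1) per-patient clinical variables in patient
  order, (2) per-leg feature laws in leg order, (3) outcome noise in
  observation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from .types import AccelRecording, ActivityBout, ExclusionEpisode

BOUT_CARRIER_HZ = 2.0  # fixed bout carrier frequency; SMA is analytically checkable
BOUT_BUFFER_S = 10.0  # minimum spacing between planted bouts / exclusions
OUTCOME_DAYS = (3, 7, 10)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the target cohort: ~53 patients with ~91 leg datasets,
    baseline RFM thickness 10.3 (SD 2.6) mm, %active 0.84 (SD 1.08) %,
    day-10 RFM atrophy -19.5 (SD 12.0) % with standardized effects -5.1
    (baseline RFM) and +1.6 (%active), and day-10 temporalis atrophy
    -15.3 (SD 11.1) %.
    """

    seed: int = 0
    n_patients: int = 53
    legs_per_patient: int = 2
    #: probability that a patient's second leg dataset is unavailable;
    #: 15/53 makes the expected number of leg datasets 91 for 53 patients.
    leg_missing_rate: float = 15.0 / 53.0

    # --- recording physics ---
    recording_hours: float = 6.0
    sample_rate_hz: float = 12.5
    bout_rate_per_hour: float = 1.4
    bout_duration_logmean: float = math.log(18.0)  # log-seconds
    bout_duration_logsd: float = 0.6
    bout_intensity_logmean: float = math.log(0.30)  # log-g
    bout_intensity_logsd: float = 0.4
    noise_sd_g: float = 0.01
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    exclusion_episodes_per_day: float = 6.0
    exclusion_duration_logmean: float = math.log(900.0)  # log-seconds (~15 min)
    exclusion_duration_logsd: float = 0.5
    require_detectable_bouts: bool = False

    # --- cohort / outcome model (percent-change scale) ---
    true_beta_baseline_rfm: float = -5.1  # pp per SD of baseline RFM
    true_beta_pct_active: float = 1.6  # pp per SD of %active
    outcome_intercept: float = -19.5  # mean day-10 RFM change, %
    random_intercept_sd: float = 7.0
    residual_sd: float = 8.2
    baseline_rfm_mean_mm: float = 10.3
    baseline_rfm_sd_mm: float = 2.6
    pct_active_mean: float = 0.84
    pct_active_sd: float = 1.08
    day_fractions: dict[int, float] = field(default_factory=lambda: {3: 0.4, 7: 0.8, 10: 1.0})
    day_scaling_noise_sd: float = 2.5
    ultrasound_repeat_sd_mm: float = 0.10
    tm_atrophy_mean: float = -15.3
    tm_atrophy_sd: float = 11.1
    tm_baseline_mean_mm: float = 6.0
    tm_baseline_sd_mm: float = 1.2
    confound_nulls: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.legs_per_patient < 1:
            raise ValueError("legs_per_patient must be positive")
        if not 0 <= self.leg_missing_rate < 1:
            raise ValueError("leg_missing_rate must lie in [0, 1)")
        if self.sample_rate_hz <= 0.4:
            raise ValueError("sample_rate_hz must exceed 0.4 Hz (filter cutoff below Nyquist)")
        for name in (
            "bout_rate_per_hour",
            "noise_sd_g",
            "exclusion_episodes_per_day",
            "random_intercept_sd",
            "residual_sd",
            "day_scaling_noise_sd",
            "ultrasound_repeat_sd_mm",
            "bout_duration_logsd",
            "bout_intensity_logsd",
            "exclusion_duration_logsd",
            "pct_active_sd",
            "tm_atrophy_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("baseline_rfm_mean_mm", "baseline_rfm_sd_mm", "pct_active_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        g = np.asarray(self.gravity_orientation, dtype=float)
        if g.shape != (3,) or abs(np.linalg.norm(g) - 1.0) > 1e-9:
            raise ValueError("gravity_orientation must be a unit 3-vector")

    @classmethod
    def healthy_preset(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Positive-control conditions: ambulatory adults, %active ~13.3 (SD 0.8).

        The bout structure of healthy controls is unreported; this preset
        keeps the ICU bout laws but raises the bout rate so that the planted
        fraction of active time matches the healthy mean.
        """
        kw = dict(
            seed=seed,
            n_patients=3,
            legs_per_patient=1,
            leg_missing_rate=0.0,
            pct_active_mean=13.3,
            pct_active_sd=0.8,
            bout_rate_per_hour=13.3 / 100.0 * 3600.0 / (18.0 * math.exp(0.6**2 / 2)),
            # a full day of wear: with ~500 bouts the realized activity
            # fraction settles to within a few percent of its target
            recording_hours=24.0,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def mean_bout_duration_s(self) -> float:
        return math.exp(self.bout_duration_logmean + self.bout_duration_logsd**2 / 2)


@dataclass
class RecordingTruth:
    """Planted ground truth for one synthetic recording."""

    bouts: list[ActivityBout]
    episodes: list[ExclusionEpisode]
    true_pct_active: float  # % of non-excluded time inside planted bouts


@dataclass
class CohortTruth:
    """Planted ground truth for a synthetic cohort."""

    beta_baseline_rfm: float
    beta_pct_active: float
    random_intercepts: dict[str, float]  # patient_id -> intercept (pp)
    true_pct_active: dict[str, float]  # leg_id -> %active used in the outcome model
    noiseless_outcome: pd.DataFrame  # leg_id, day, outcome_pct_change (no residual noise)


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    ultrasound: pd.DataFrame
    features: pd.DataFrame
    truth: CohortTruth


def _leg_rng(config: SimConfig, leg_id: str, stream: int) -> np.random.Generator:
    key = zlib.crc32(leg_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key, stream]))


def _cohort_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, zlib.crc32(b"cohort")]))


def _draw_exclusions(config: SimConfig, duration_s: float, rng: np.random.Generator) -> list[ExclusionEpisode]:
    days = duration_s / 86400.0
    n = rng.poisson(config.exclusion_episodes_per_day * days)
    episodes: list[ExclusionEpisode] = []
    reasons = ["physiotherapy", "transport", "repositioning"]
    for _ in range(n):
        dur = float(
            rng.lognormal(config.exclusion_duration_logmean, config.exclusion_duration_logsd)
        )
        dur = min(dur, duration_s / 2)
        start = float(rng.uniform(0.0, max(duration_s - dur, 1e-9)))
        reason = reasons[int(rng.integers(0, len(reasons)))]
        cand = ExclusionEpisode(start, start + dur, reason)
        if all(cand.end_s <= e.start_s or cand.start_s >= e.end_s for e in episodes):
            episodes.append(cand)
    episodes.sort(key=lambda e: e.start_s)
    return episodes


def generate_exclusion_log(config: SimConfig, recording: AccelRecording) -> list[ExclusionEpisode]:
    """Passive-movement episodes for a recording (non-overlapping, in-span).

    Regenerates exactly the episodes that :func:`generate_accel_recording`
    reserved when planting bouts for this leg (same seeded substream), so
    the planted bouts of the default generator lie in non-excluded time.
    """
    return _draw_exclusions(
        config, recording.duration_s, _leg_rng(config, recording.leg_id, 0)
    )


def generate_accel_recording(
    config: SimConfig,
    leg_id: str,
    patient_id: str = "",
    pct_active_target: float | None = None,
) -> tuple[AccelRecording, RecordingTruth]:
    """Simulate one leg's tri-axial recording with planted activity bouts.

    The series is static gravity (1 g along ``gravity_orientation``) plus
    zero-mean Gaussian sensor noise plus planted bout segments: per-axis
    2 Hz sinusoids with random phases whose amplitudes sum so the rectified
    three-axis mean equals the planted intensity.  Bout log-durations and
    log-intensities follow the configured log-normal laws; bouts are placed
    non-overlapping, separated by >= 10 s, outside exclusion episodes.

    ``pct_active_target`` (percent) overrides the bout rate so the expected
    planted active fraction matches the target.
    """
    if config.recording_hours <= 0:
        raise ValueError("recording_hours must be positive")
    duration_s = config.recording_hours * 3600.0
    fs = config.sample_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    episodes = _draw_exclusions(config, duration_s, _leg_rng(config, leg_id, 0))

    rng_b = _leg_rng(config, leg_id, 1)
    if pct_active_target is None:
        rate = config.bout_rate_per_hour
    else:
        rate = pct_active_target / 100.0 * 3600.0 / config.mean_bout_duration_s
    # the bout rate (like %active and AB/hour) refers to analyzed,
    # i.e. non-excluded, time
    non_excl_hours = (duration_s - sum(e.end_s - e.start_s for e in episodes)) / 3600.0
    n_bouts = int(rng_b.poisson(rate * max(non_excl_hours, 0.0)))
    durations = rng_b.lognormal(config.bout_duration_logmean, config.bout_duration_logsd, n_bouts)
    intensities = rng_b.lognormal(
        config.bout_intensity_logmean, config.bout_intensity_logsd, n_bouts
    )
    if config.require_detectable_bouts and np.any(intensities < feat.DEFAULT_THRESHOLD_G):
        raise ValueError("planted bout intensity below the detection threshold")

    xyz = np.tile(np.asarray(config.gravity_orientation, dtype=float), (n, 1))
    placed: list[ActivityBout] = []
    occupied = [(e.start_s - BOUT_BUFFER_S, e.end_s + BOUT_BUFFER_S) for e in episodes]
    for dur, inten in zip(durations, intensities):
        dur = min(float(dur), duration_s / 4)
        for _ in range(100):
            start = float(rng_b.uniform(0.0, duration_s - dur))
            lo, hi = start - BOUT_BUFFER_S, start + dur + BOUT_BUFFER_S
            if all(hi <= a or lo >= b for a, b in occupied):
                occupied.append((lo, hi))
                placed.append(ActivityBout(start_s=start, duration_s=dur, intensity_g=float(inten)))
                break
    placed.sort(key=lambda b: b.start_s)
    for b in placed:
        i0 = int(math.ceil(b.start_s * fs))
        i1 = min(int(math.floor(b.end_s * fs)) + 1, n)
        seg_t = t[i0:i1]
        # per-axis amplitude: equal thirds; mean(|A sin|) = 2A/pi per axis,
        # so sum of the three rectified means equals the planted intensity
        amp = b.intensity_g * math.pi / 6.0
        for k in range(3):
            phase = rng_b.uniform(0.0, 2 * math.pi)
            xyz[i0:i1, k] += amp * np.sin(2 * math.pi * BOUT_CARRIER_HZ * seg_t + phase)

    rng_n = _leg_rng(config, leg_id, 2)
    if config.noise_sd_g > 0:
        xyz += rng_n.normal(0.0, config.noise_sd_g, size=(n, 3))
    np.clip(xyz, -16.0, 16.0, out=xyz)

    rec = AccelRecording(
        t=t, xyz=xyz, sample_rate_hz=fs, leg_id=leg_id, patient_id=patient_id
    )
    excl_time = sum(e.end_s - e.start_s for e in episodes)
    non_excl = max(duration_s - excl_time, 1e-9)
    true_pct = 100.0 * sum(b.duration_s for b in placed) / non_excl
    return rec, RecordingTruth(bouts=placed, episodes=episodes, true_pct_active=true_pct)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def draw_clinical(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pass 1: per-patient clinical/nutritional variables and random intercepts.

    Draw order per patient: age, sex, mSOFA, weight, calorie adequacy,
    protein adequacy, baseline RFM (truncated positive), random intercept.
    """
    rows = []
    intercepts: dict[str, float] = {}
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        age = float(np.clip(rng.normal(59.2, 15.9), 18.0, 95.0))
        sex = int(rng.random() < 0.585)  # 1 = male
        msofa = float(np.clip(rng.normal(4.5, 2.1), 0.0, 20.0))
        weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 130.0))
        cal_adeq = float(np.clip(rng.normal(62.6, 18.4), 5.0, 130.0))
        prot_adeq = float(np.clip(rng.normal(57.9, 21.6), 5.0, 130.0))
        base = float(rng.normal(config.baseline_rfm_mean_mm, config.baseline_rfm_sd_mm))
        while base <= 0.5:
            base = float(rng.normal(config.baseline_rfm_mean_mm, config.baseline_rfm_sd_mm))
        b_i = float(rng.normal(0.0, config.random_intercept_sd))
        presc_cal = 25.0 * weight * 10.0  # kcal over days 1..10
        presc_prot = 1.3 * weight * 10.0  # g over days 1..10
        rows.append(
            {
                "patient_id": pid,
                "age": age,
                "sex": sex,
                "msofa": msofa,
                "weight_kg": weight,
                "calorie_adequacy_pct": cal_adeq,
                "protein_adequacy_pct": prot_adeq,
                "calorie_deficit": presc_cal * (1.0 - cal_adeq / 100.0),
                "protein_deficit": presc_prot * (1.0 - prot_adeq / 100.0),
                "baseline_rfm_true_mm": base,
            }
        )
        intercepts[pid] = b_i
    return pd.DataFrame(rows), intercepts


def draw_leg_features(
    config: SimConfig, clinical: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Pass 2: leg availability and movement-feature laws, in leg order.

    Draw order per patient: availability of each leg beyond the first, then
    per available leg: %active (log-normal matched to the configured
    mean/SD), bout-law features, overall intensity, TM day-10 atrophy.
    """
    s2 = math.log(1.0 + (config.pct_active_sd / config.pct_active_mean) ** 2)
    mu = math.log(config.pct_active_mean) - s2 / 2.0
    rows = []
    sides = ["L", "R", "3", "4"]
    for pid in clinical["patient_id"]:
        present = [True] + [
            bool(rng.random() >= config.leg_missing_rate)
            for _ in range(config.legs_per_patient - 1)
        ]
        for side, ok in zip(sides, present):
            if not ok:
                continue
            pa = float(rng.lognormal(mu, math.sqrt(s2)))
            int_lm = float(rng.normal(config.bout_intensity_logmean, 0.25))
            int_lsd = float(abs(rng.normal(config.bout_intensity_logsd, 0.10)))
            dur_lm = float(rng.normal(config.bout_duration_logmean, 0.30))
            dur_lsd = float(abs(rng.normal(config.bout_duration_logsd, 0.15)))
            if config.confound_nulls:
                # couple overall intensity to activity (realistic collinearity)
                ovi = float(0.02 + pa / 100.0 * math.exp(int_lm) + rng.normal(0.0, 0.003))
            else:
                ovi = float(rng.lognormal(math.log(0.025), 0.4))
            ab_per_hour = float(pa / 100.0 * 3600.0 / math.exp(dur_lm) + rng.normal(0.0, 0.1))
            tm10 = float(rng.normal(config.tm_atrophy_mean, config.tm_atrophy_sd))
            rows.append(
                {
                    "leg_id": f"{pid}_{side}",
                    "patient_id": pid,
                    "side": side,
                    "pct_active": pa,
                    "overall_intensity_g": max(ovi, 1e-4),
                    "ab_per_hour": max(ab_per_hour, 0.0),
                    "ab_intensity_logmean": int_lm,
                    "ab_intensity_logsd": int_lsd,
                    "ab_duration_logmean": dur_lm,
                    "ab_duration_logsd": dur_lsd,
                    "tm_day10_atrophy_pct": tm10,
                }
            )
    return pd.DataFrame(rows)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd < 1e-12:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def attach_outcomes(
    config: SimConfig,
    clinical: pd.DataFrame,
    features: pd.DataFrame,
    intercepts: dict[str, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Pass 3: outcomes and ultrasound tables from clinical + feature values.

    day-10 change (%) = intercept + b1*z(baseline RFM) + b2*z(%active)
    + patient random intercept + residual noise; day-3/7 changes are fixed
    fractions of the day-10 change plus noise.  Standardization uses the
    sample mean/SD of the generated legs, so the planted coefficients are on
    the same scale a modelling z-score produces.

    Returns the ultrasound long table (three repeats per site/day) and the
    cohort ground truth.
    """
    legs = features.merge(
        clinical[["patient_id", "baseline_rfm_true_mm"]], on="patient_id", how="left"
    )
    z_rfm = _zscore(legs["baseline_rfm_true_mm"].to_numpy(float))
    z_pa = _zscore(legs["pct_active"].to_numpy(float))
    b = np.array([intercepts[p] for p in legs["patient_id"]])
    mean10 = (
        config.outcome_intercept
        + config.true_beta_baseline_rfm * z_rfm
        + config.true_beta_pct_active * z_pa
        + b
    )
    eps10 = rng.normal(0.0, config.residual_sd, len(legs)) if config.residual_sd > 0 else 0.0
    delta10 = mean10 + eps10

    us_rows = []
    truth_rows = []
    for i, leg in legs.iterrows():
        pid, side = leg["patient_id"], leg["side"]
        base = leg["baseline_rfm_true_mm"]
        deltas = {}
        for day in OUTCOME_DAYS:
            frac = config.day_fractions.get(day, 1.0)
            if day == 10:
                d = delta10[i]
            else:
                noise = (
                    rng.normal(0.0, config.day_scaling_noise_sd)
                    if config.day_scaling_noise_sd > 0
                    else 0.0
                )
                d = frac * delta10[i] + noise
            deltas[day] = d
            truth_rows.append(
                {
                    "leg_id": leg["leg_id"],
                    "day": day,
                    "outcome_pct_change": frac * mean10[i] if day != 10 else mean10[i],
                }
            )
        for day in (0,) + OUTCOME_DAYS:
            thick = base if day == 0 else base * (1.0 + deltas[day] / 100.0)
            reps = thick + rng.normal(0.0, config.ultrasound_repeat_sd_mm, 3)
            reps = np.maximum(reps, 0.1)
            us_rows.append(
                {
                    "patient_id": pid,
                    "side": side,
                    "muscle": "RFM",
                    "day": day,
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "rep3": reps[2],
                }
            )
        # temporalis: day 0 and day 10 only
        tm_base = float(
            np.clip(rng.normal(config.tm_baseline_mean_mm, config.tm_baseline_sd_mm), 1.0, None)
        )
        for day, thick in ((0, tm_base), (10, tm_base * (1.0 + leg["tm_day10_atrophy_pct"] / 100.0))):
            reps = np.maximum(thick + rng.normal(0.0, config.ultrasound_repeat_sd_mm, 3), 0.1)
            us_rows.append(
                {
                    "patient_id": pid,
                    "side": side,
                    "muscle": "TM",
                    "day": day,
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "rep3": reps[2],
                }
            )
    truth = CohortTruth(
        beta_baseline_rfm=config.true_beta_baseline_rfm,
        beta_pct_active=config.true_beta_pct_active,
        random_intercepts=dict(intercepts),
        true_pct_active=dict(zip(legs["leg_id"], legs["pct_active"])),
        noiseless_outcome=pd.DataFrame(truth_rows),
    )
    return pd.DataFrame(us_rows), truth


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with feature values drawn from laws.

    Movement features are drawn directly from their distributional laws
    (fast path); use the pipeline's study simulation to derive them from
    planted recordings instead.
    """
    if config.n_patients < 2:
        raise ValueError("cohort generation requires n_patients >= 2")
    rng = _cohort_rng(config)
    clinical, intercepts = draw_clinical(config, rng)
    features = draw_leg_features(config, clinical, rng)
    ultrasound, truth = attach_outcomes(config, clinical, features, intercepts, rng)
    return SyntheticCohort(
        clinical=clinical, ultrasound=ultrasound, features=features, truth=truth
    )
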