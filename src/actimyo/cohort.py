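"""Analysis-table assembly: ultrasound outcomes joined with predictors.

The modelled outcome is the relative change of rectus femoris muscle (RFM)
thickness versus day 0, in percent (atrophy negative), evaluated at days 3,
7 and 10; each leg contributes its own observations and movement features
are computed once per leg over the whole monitored span.  No value is ever
imputed: rows missing the outcome or any predictor are dropped and counted
in an audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PREDICTOR_COLUMNS

OUTCOME_COLUMN = "outcome_pct_change"
ULTRASOUND_KEY = ["patient_id", "side", "muscle", "day"]
REPEAT_COLUMNS = ["rep1", "rep2", "rep3"]


def average_repeats(repeats) -> float:
    """Mean of the three repeated ultrasound thickness measurements (mm)."""
    r = np.asarray(repeats, dtype=float)
    if r.shape != (3,) or np.any(~np.isfinite(r)):
        raise ValueError("exactly three finite repeated measurements are required")
    if np.any(r <= 0):
        raise ValueError("thickness measurements must be positive")
    return float(r.mean())


def relative_change(thickness_day_mm: float, thickness_day0_mm: float) -> float:
    """Signed percent change versus baseline: 100 * (day - day0) / day0."""
    if thickness_day0_mm <= 0:
        raise ValueError("baseline thickness must be positive")
    return 100.0 * (thickness_day_mm - thickness_day0_mm) / thickness_day0_mm


def cumulative_deficit(prescribed_daily, administered_daily, up_to_day: int | None = None):
    """Cumulative nutrition deficit and percent adequacy over days 1..up_to_day.

    Returns ``(deficit, adequacy_pct)`` where deficit = sum(prescribed -
    administered) and adequacy = 100 * sum(administered) / sum(prescribed).
    """
    p = np.asarray(prescribed_daily, dtype=float)
    a = np.asarray(administered_daily, dtype=float)
    if p.shape != a.shape:
        raise ValueError("prescribed and administered series must have equal length")
    if np.any(a < 0):
        raise ValueError("administered amounts cannot be negative")
    if up_to_day is not None:
        p, a = p[:up_to_day], a[:up_to_day]
    total_p = p.sum()
    adequacy = 100.0 * a.sum() / total_p if total_p > 0 else np.nan
    return float((p - a).sum()), float(adequacy)


@dataclass
class TableAudit:
    """Accounting of rows dropped while building the analysis table."""

    n_candidate_rows: int
    n_rows: int
    n_dropped_no_baseline: int
    n_dropped_missing_predictor: int
    dropped_legs_no_baseline: list[str]

    def to_dict(self) -> dict:
        return {
            "n_candidate_rows": self.n_candidate_rows,
            "n_rows": self.n_rows,
            "n_dropped_no_baseline": self.n_dropped_no_baseline,
            "n_dropped_missing_predictor": self.n_dropped_missing_predictor,
            "dropped_legs_no_baseline": sorted(self.dropped_legs_no_baseline),
        }


def ultrasound_wide(ultrasound: pd.DataFrame, muscle: str = "RFM") -> pd.DataFrame:
    """Per (patient, side, day) mean thickness for one muscle site."""
    us = ultrasound.loc[ultrasound["muscle"] == muscle].copy()
    if us.duplicated(subset=ULTRASOUND_KEY).any():
        dup = us[us.duplicated(subset=ULTRASOUND_KEY, keep=False)]
        raise ValueError(
            "duplicate ultrasound measurements for "
            + ", ".join(map(str, dup[ULTRASOUND_KEY].drop_duplicates().to_records(index=False)))
        )
    us["thickness_mm"] = [
        average_repeats(row) for row in us[REPEAT_COLUMNS].to_numpy(float)
    ]
    return us[["patient_id", "side", "day", "thickness_mm"]]


def build_analysis_table(
    ultrasound: pd.DataFrame,
    clinical: pd.DataFrame,
    features: pd.DataFrame,
    *,
    days: tuple[int, ...] = (3, 7, 10),
    day10_only: bool = False,
) -> tuple[pd.DataFrame, TableAudit]:
    """Join outcomes, clinical covariates and movement features per leg-day.

    One row per (leg, follow-up day) with the day-0 RFM baseline attached.
    Legs without a day-0 scan are dropped (logged), as are rows missing the
    outcome or any of the 12 predictors.  The result is sorted by
    (patient_id, leg_id, day) so assembly is input-order independent.
    """
    if day10_only:
        days = (10,)
    thick = ultrasound_wide(ultrasound, "RFM")
    base = thick[thick["day"] == 0].rename(columns={"thickness_mm": "baseline_rfm_mm"})
    follow = thick[thick["day"].isin(days)]

    merged = follow.merge(
        base[["patient_id", "side", "baseline_rfm_mm"]], on=["patient_id", "side"], how="left"
    )
    no_base = merged["baseline_rfm_mm"].isna()
    dropped_legs = sorted(
        (merged.loc[no_base, "patient_id"] + "_" + merged.loc[no_base, "side"]).unique()
    )
    merged = merged[~no_base].copy()
    merged[OUTCOME_COLUMN] = [
        relative_change(t, b)
        for t, b in zip(merged["thickness_mm"], merged["baseline_rfm_mm"])
    ]
    merged["leg_id"] = merged["patient_id"] + "_" + merged["side"]

    table = merged.merge(clinical, on="patient_id", how="left", suffixes=("", "_clin"))
    table = table.merge(features, on=["leg_id", "patient_id"], how="left", suffixes=("", "_feat"))
    n_candidate = len(follow)

    needed = PREDICTOR_COLUMNS + [OUTCOME_COLUMN]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"input tables lack required columns: {missing_cols}")
    complete = table[needed].notna().all(axis=1)
    n_missing = int((~complete).sum())
    out = (
        table.loc[complete, ["patient_id", "leg_id", "side", "day", OUTCOME_COLUMN, "baseline_rfm_mm"]
                  + [c for c in PREDICTOR_COLUMNS if c != "baseline_rfm_mm"]]
        .sort_values(["patient_id", "leg_id", "day"], kind="stable")
        .reset_index(drop=True)
    )
    audit = TableAudit(
        n_candidate_rows=n_candidate,
        n_rows=len(out),
        n_dropped_no_baseline=int(no_base.sum()),
        n_dropped_missing_predictor=n_missing,
        dropped_legs_no_baseline=list(dropped_legs),
    )
    return out, audit


def tm_day10_table(
    ultrasound: pd.DataFrame, clinical: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Day-10 temporalis (TM) atrophy with covariates, for the linear model."""
    thick = ultrasound_wide(ultrasound, "TM")
    base = thick[thick["day"] == 0].rename(columns={"thickness_mm": "tm_baseline_mm"})
    d10 = thick[thick["day"] == 10].rename(columns={"thickness_mm": "tm_day10_mm"})
    merged = d10.merge(base[["patient_id", "side", "tm_baseline_mm"]], on=["patient_id", "side"])
    merged["tm_atrophy_pct"] = [
        relative_change(t, b) for t, b in zip(merged["tm_day10_mm"], merged["tm_baseline_mm"])
    ]
    merged["leg_id"] = merged["patient_id"] + "_" + merged["side"]
    out = merged.merge(clinical, on="patient_id", how="left")
    out = out.merge(
        features[["leg_id", "patient_id", "pct_active"]], on=["leg_id", "patient_id"], how="left"
    )
    return out.dropna(subset=["tm_atrophy_pct", "pct_active"]).reset_index(drop=True)
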