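"""Study filtering, valid-day, compliance and daily aggregation rules.

The rules mirror the protocol exactly: free-living walking bouts shorter
than 10 s or longer than 3000 s are excluded, as are bouts with fewer than
four detected gait cycles; a lumbar day is valid with at least 10 h of
wear, a wrist day with at least 18 h; daily gait values are the mean over
bouts of per-bout stride medians; the 95th-percentile gait speed is taken
across walking bouts within the day; subjects need four or more valid
compliant days for inclusion, with no missing-data imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GaitBout, strides_to_frame

GAIT_METRICS = ("cadence_spm", "stride_time_s", "stride_length_m", "speed_mps")


@dataclass(frozen=True)
class ValidityRules:
    lumbar_min_wear_h: float = 10.0
    wrist_min_wear_h: float = 18.0
    bout_min_s: float = 10.0
    bout_max_s: float = 3000.0
    min_gait_cycles: int = 4
    min_valid_days: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.bout_min_s < self.bout_max_s):
            raise ValueError("bout duration bounds must satisfy 0 < min < max")
        if min(self.lumbar_min_wear_h, self.wrist_min_wear_h, self.min_gait_cycles,
               self.min_valid_days) <= 0:
            raise ValueError("thresholds must be positive")


def filter_bouts(bouts: list[GaitBout], rules: ValidityRules = ValidityRules()) -> list[GaitBout]:
    """Keep bouts with min_s <= duration <= max_s and enough gait cycles.

    Boundary values are retained (only strictly shorter/longer bouts are
    excluded). Idempotent.
    """
    return [
        b for b in bouts
        if rules.bout_min_s <= b.duration_s <= rules.bout_max_s
        and b.n_gait_cycles >= rules.min_gait_cycles
    ]


def flag_valid_days(wear_h_by_day: pd.Series, site: str,
                    rules: ValidityRules = ValidityRules()) -> pd.Series:
    """Boolean validity per day; exactly the threshold counts as valid."""
    if site == "lumbar":
        thr = rules.lumbar_min_wear_h
    elif site == "wrist":
        thr = rules.wrist_min_wear_h
    else:
        raise ValueError(f"unknown site {site!r}")
    return wear_h_by_day >= thr


def daily_gait_summary(
    bouts: list[GaitBout],
    percentile_basis: str = "bout_medians",
) -> dict | None:
    """Daily gait aggregates from the retained bouts of one valid day.

    Per metric: median within each bout, then the mean across bouts. The
    95th-percentile gait speed uses linear interpolation over per-bout
    median speeds by default; ``percentile_basis='pooled_strides'`` pools
    all strides instead. Returns None when no bout is retained (gait fields
    absent for the day).
    """
    if percentile_basis not in ("bout_medians", "pooled_strides"):
        raise ValueError("percentile_basis must be 'bout_medians' or 'pooled_strides'")
    frames = [strides_to_frame(b.strides) for b in bouts if b.strides]
    if not frames:
        return None
    medians = pd.DataFrame([f[list(GAIT_METRICS)].median() for f in frames])
    out = {m: float(medians[m].mean()) for m in GAIT_METRICS}
    if percentile_basis == "bout_medians":
        basis = medians["speed_mps"].to_numpy()
    else:
        basis = np.concatenate([f["speed_mps"].to_numpy() for f in frames])
    basis = basis[~np.isnan(basis)]
    out["gait_speed_p95"] = float(np.percentile(basis, 95, method="linear")) if basis.size else np.nan
    out["n_bouts"] = len(frames)
    return out


def compliance_summary(valid_by_day: pd.Series,
                       rules: ValidityRules = ValidityRules()) -> dict:
    """Percent compliant days and the subject-inclusion flag.

    percent = 100 * compliant / observed days; a subject is included when
    at least ``min_valid_days`` days are compliant. Days never observed are
    not imputed.
    """
    total = int(valid_by_day.size)
    if total == 0:
        raise ValueError("no observed days")
    compliant = int(valid_by_day.sum())
    return {
        "n_days": total,
        "n_compliant": compliant,
        "percent_compliant": 100.0 * compliant / total,
        "included": compliant >= rules.min_valid_days,
    }
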