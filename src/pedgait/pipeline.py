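"""End-to-end study pipelines: in-clinic validation and at-home summaries.

Both entry points are driven by a plain-dict config (YAML at the file
boundary); a run's effective config is echoed into its output directory so
re-running with the same config and seed reproduces every output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import ValidityRules, compliance_summary, daily_gait_summary, filter_bouts, flag_valid_days
from .bouts import detect_gait_bouts
from .gait import GaitParams, analyze_pass
from .records import SPEED_CLASSES, SubjectProfile, strides_to_frame
from .stats import age_group_anova, icc_2_1, pearson_r, setting_contrast_mmrm
from .synth import SimConfig, simulate_free_living_days, simulate_reference_walkway, simulate_walk_pass
from .wear_activity import classify_intensity, daily_activity_summary, detect_wear, epoch_counts

PASS_METRICS = {
    "cadence_spm": "cadence_spm",
    "gait_speed_mps": "speed_mps",
    "stride_time_s": "stride_time_s",
    "stride_length_m": "stride_length_m",
}


def default_cohort(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """An age-balanced cohort spanning the study's 3-17-year range."""
    rng = np.random.default_rng(seed)
    ranges = {"3-5": (3.0, 5.9), "6-11": (6.0, 11.9), "12-17": (12.0, 17.0)}
    heights = {"3-5": (0.95, 1.18), "6-11": (1.15, 1.52), "12-17": (1.50, 1.80)}
    out = []
    groups = list(ranges)
    for i in range(n_subjects):
        g = groups[i % 3]
        out.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                age_years=float(rng.uniform(*ranges[g])),
                height_m=float(rng.uniform(*heights[g])),
                sex="F" if rng.random() < 0.5 else "M",
            )
        )
    return out


def device_pass_estimates(recording, height_m: float, params: GaitParams = GaitParams()) -> dict | None:
    """Pass-level mean gait metrics from the device pipeline."""
    strides = analyze_pass(recording, height_m, params)
    if not strides:
        return None
    df = strides_to_frame(strides)
    return {
        "cadence_spm": float(df["cadence_spm"].mean()),
        "gait_speed_mps": float(df["speed_mps"].mean()),
        "stride_time_s": float(df["stride_time_s"].mean()),
        "stride_length_m": float(df["stride_length_m"].mean()),
    }


def run_clinic_validation(config: dict, out_dir=None) -> pd.DataFrame:
    """Simulate the staged walkway protocol and report device-vs-reference
    agreement (ICC(2,1) with CI and category, Pearson r) per metric and
    speed class.

    Config keys (all optional): n_subjects, n_repeats, pass_duration_s,
    noise_sd_g, reference_noise_sd, seed.
    """
    n_subjects = int(config.get("n_subjects", 20))
    n_repeats = int(config.get("n_repeats", 3))
    duration = float(config.get("pass_duration_s", 20.0))
    noise = float(config.get("noise_sd_g", 0.05))
    ref_noise = float(config.get("reference_noise_sd", 0.02))
    seed = int(config.get("seed", 0))
    params = GaitParams()

    cohort = default_cohort(n_subjects, seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for subj in cohort:
        for speed in SPEED_CLASSES:
            for rep in range(n_repeats):
                pass_seed = int(rng.integers(0, 2**31 - 1))
                cfg = SimConfig(noise_sd_g=noise, seed=pass_seed)
                rec, truth = simulate_walk_pass(subj, speed, duration, cfg)
                est = device_pass_estimates(rec, subj.height_m, params)
                if est is None:
                    continue
                ref = simulate_reference_walkway(
                    truth, noise_sd=ref_noise, seed=pass_seed + 1, subject_id=subj.subject_id
                )
                for metric in PASS_METRICS:
                    rows.append(
                        dict(subject=subj.subject_id, speed_class=speed, repeat=rep,
                             metric=metric, device=est[metric], reference=getattr(ref, metric))
                    )
    long = pd.DataFrame(rows)

    report = []
    for (metric, speed), g in long.groupby(["metric", "speed_class"]):
        per_subj = g.groupby("subject")[["device", "reference"]].mean()
        icc = icc_2_1(per_subj.to_numpy())
        r, p = pearson_r(per_subj["device"], per_subj["reference"])
        report.append(
            dict(metric=metric, speed_class=speed, n=len(per_subj),
                 icc=icc.estimate, icc_low=icc.ci_low, icc_high=icc.ci_high,
                 category=icc.category, pearson_r=r, pearson_p=p)
        )
    out = pd.DataFrame(report).sort_values(["metric", "speed_class"]).reset_index(drop=True)
    if out_dir is not None:
        _write_outputs(out_dir, config, {"clinic_agreement.csv": out, "clinic_passes.csv": long})
    return out


def run_home_summary(config: dict, out_dir=None, clinic_values: pd.DataFrame | None = None) -> dict:
    """Simulate at-home wear for a cohort and apply the full study rules.

    Produces daily summaries, per-subject compliance and inclusion flags,
    the age-group ANOVA on daily-mean gait speed, and (when clinic data is
    supplied) the in-clinic vs at-home mixed-model contrast.

    Config keys: n_subjects, n_days, seed, plus optional generator fields.
    """
    n_subjects = int(config.get("n_subjects", 6))
    n_days = int(config.get("n_days", 7))
    seed = int(config.get("seed", 0))
    rules = ValidityRules()
    params = GaitParams()

    sim_kwargs = dict(config.get("sim", {}))
    cohort = default_cohort(n_subjects, seed)
    daily_rows, subj_rows = [], []
    for si, subj in enumerate(cohort):
        cfg = SimConfig(seed=seed + 1000 + si, **sim_kwargs)
        lum_rec, lum_truth = simulate_free_living_days(subj, n_days, cfg, site="lumbar")
        wr_cfg = SimConfig(seed=seed + 5000 + si, **sim_kwargs)
        wr_rec, _ = simulate_free_living_days(subj, n_days, wr_cfg, site="wrist")

        lum_ep = classify_intensity(detect_wear(epoch_counts(lum_rec)))
        wr_ep = classify_intensity(detect_wear(epoch_counts(wr_rec)))
        lum_daily = daily_activity_summary(lum_ep)
        wr_daily = daily_activity_summary(wr_ep)

        lum_valid = flag_valid_days(lum_daily["wear_h"], "lumbar", rules)
        wr_valid = flag_valid_days(wr_daily["wear_h"], "wrist", rules)

        bouts = detect_gait_bouts(lum_rec, model=None, height_m=subj.height_m)
        kept = filter_bouts(bouts, rules)

        for day in range(n_days):
            day_bouts = [b for b in kept if day * 86400 <= b.start_s < (day + 1) * 86400]
            row = dict(subject=subj.subject_id, age_group=subj.age_group, day=day,
                       lumbar_wear_h=float(lum_daily["wear_h"].get(day, 0.0)),
                       wrist_wear_h=float(wr_daily["wear_h"].get(day, 0.0)),
                       lumbar_valid=bool(lum_valid.get(day, False)),
                       wrist_valid=bool(wr_valid.get(day, False)))
            if row["lumbar_valid"]:
                gait = daily_gait_summary(day_bouts)
                if gait:
                    row.update({(k if k.startswith("gait") else f"gait_{k}"): v
                                for k, v in gait.items()})
            if row["wrist_valid"]:
                for k in ("mvpa_min", "sedentary_min", "total_vm"):
                    row[k] = float(wr_daily[k].get(day, np.nan))
            daily_rows.append(row)

        subj_rows.append(
            dict(subject=subj.subject_id, age_group=subj.age_group,
                 lumbar=compliance_summary(lum_valid, rules),
                 wrist=compliance_summary(wr_valid, rules))
        )

    daily = pd.DataFrame(daily_rows)
    compliance = pd.DataFrame(
        [
            dict(subject=r["subject"], age_group=r["age_group"],
                 lumbar_percent=r["lumbar"]["percent_compliant"],
                 wrist_percent=r["wrist"]["percent_compliant"],
                 included=r["lumbar"]["included"] and r["wrist"]["included"])
            for r in subj_rows
        ]
    )

    result: dict = {"daily": daily, "compliance": compliance}

    included = set(compliance.loc[compliance["included"], "subject"])
    gait_col = "gait_speed_mps"
    means = (
        daily[daily["subject"].isin(included) & daily.get(gait_col, pd.Series(dtype=float)).notna()]
        .groupby(["subject", "age_group"])[gait_col].mean().reset_index()
        .rename(columns={gait_col: "value"})
        if gait_col in daily else pd.DataFrame()
    )
    if not means.empty and means.groupby("age_group").size().min() >= 2 and means["age_group"].nunique() >= 2:
        result["age_anova"] = age_group_anova(means)

    if clinic_values is not None and not means.empty:
        home = means.rename(columns={"value": "value"}).assign(setting="at_home")
        clinic = clinic_values.assign(setting="in_clinic")
        both = pd.concat([home, clinic], ignore_index=True)
        try:
            result["setting_contrast"] = setting_contrast_mmrm(both)
        except ValueError:
            pass

    if daily.empty or not (daily.get("lumbar_valid", pd.Series(dtype=bool)).any()
                           or daily.get("wrist_valid", pd.Series(dtype=bool)).any()):
        raise ValueError("no valid days in any recording")

    if out_dir is not None:
        _write_outputs(out_dir, config, {"daily_summary.csv": daily, "compliance.csv": compliance})
    return result


def _write_outputs(out_dir, config: dict, tables: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    manifest = {"config": config, "version": __version__, "seed": config.get("seed", 0)}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
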