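"""End-to-end analysis pipeline tying the stages together.

Stage order per trial: window-truncate and crop at turn-back, build the
random null, classify; then across trials: extract first/start-end
angles, fit the circular model family on each angle sample, run the
group-level tests against model expectations, and fit the strategy-
choice covariate model.  Failing trials are isolated and reported; the
run manifest records every seed and parameter needed to reproduce the
outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import arena, circular, classify, cohort
from .arena import ArenaConfig, RANDOM_LABEL, STRATEGIES
from .errors import FishnavError, NoAnalysableTrialsError
from .trajectory import Trajectory, arc_length, crop_at_turnback, read_trajectories

logger = logging.getLogger(__name__)


def _tool_version() -> str:
    try:
        return _pkg_version("fishnav")
    except PackageNotFoundError:
        return "unknown"


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    classification: pd.DataFrame
    angles: pd.DataFrame
    group_stats: pd.DataFrame
    distance_groups: pd.DataFrame | None
    distance_posthoc: pd.DataFrame | None
    circfit: pd.DataFrame
    strategy_model: pd.DataFrame | None
    failures: pd.DataFrame
    manifest: dict


def classify_cohort(
    trajectories: list[Trajectory],
    metadata: pd.DataFrame,
    config: ArenaConfig,
    rule: str = "sd_uniform",
    n_null: int = 10_000,
    seed: int = 0,
    cone_deg: float = 30.0,
    persistence: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, list[Trajectory]]:
    """Crop and classify every trial; failures are flagged, not fatal.

    Returns (classification table, failure table, cropped trajectories).
    Each trial's null uses a child seed spawned deterministically from
    ``seed`` and the trial's position, so a run is reproducible while
    trials stay independent.
    """
    meta = metadata.set_index("trial_id")
    rows, failures, cropped_all = [], [], []
    for i, traj in enumerate(trajectories):
        try:
            displacement = str(meta.loc[traj.trial_id, "displacement"])
            door = arena.displaced_chamber_position(config, displacement)
            models = arena.model_trajectories(config, displacement)
            cropped = crop_at_turnback(
                traj,
                door,
                cone_deg=cone_deg,
                persistence=persistence,
                analysis_window=config.analysis_window,
            )
            trial_seed = (seed * 100_003 + i) % (2**31 - 1)
            null = classify.build_null(cropped, models["PI"], n=n_null, seed=trial_seed)
            res = classify.classify_trial(cropped, models, null, rule=rule)
        except (FishnavError, KeyError) as exc:
            logger.warning("trial %s skipped: %s", traj.trial_id, exc)
            failures.append({"trial_id": traj.trial_id, "stage": "classify", "error": str(exc)})
            continue
        cropped_all.append(cropped)
        rows.append(
            {
                "trial_id": traj.trial_id,
                "fish_id": traj.fish_id,
                "displacement": displacement,
                "crop_index": cropped.crop_index if cropped.crop_index is not None else -1,
                "cropped_length_cm": arc_length(cropped.xy),
                "full_length_cm": arc_length(traj.xy),
                **{f"dist_{s}_cm": res.mean_distance_to[s] for s in STRATEGIES},
                "best_strategy": res.best_strategy,
                "best_distance_cm": res.best_distance,
                "null_mu_cm": res.null_mu,
                "null_a_cm": res.null_a,
                "null_b_cm": res.null_b,
                "null_sd_uniform_cm": res.null_sd_uniform,
                "null_sd_normal_cm": res.null_sd_normal,
                "null_q20_cm": res.null_q20,
                "rule": rule,
                "threshold_cm": res.threshold,
                "label": res.label,
                "null_seed": trial_seed,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(failures), cropped_all


def extract_angles(
    trajectories: list[Trajectory],
    config: ArenaConfig,
    metadata: pd.DataFrame,
    cone_deg: float = 30.0,
    persistence: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial first and start-end angles (full and axial) plus lengths."""
    meta = metadata.set_index("trial_id")
    rows, failures = [], []
    for traj in trajectories:
        try:
            displacement = str(meta.loc[traj.trial_id, "displacement"])
            door = arena.displaced_chamber_position(config, displacement)
            cropped = crop_at_turnback(
                traj,
                door,
                cone_deg=cone_deg,
                persistence=persistence,
                analysis_window=config.analysis_window,
            )
            first = circular.first_straight_angle(cropped)
            se = circular.angle_start_end(cropped)
        except (FishnavError, KeyError) as exc:
            logger.warning("trial %s skipped in angle extraction: %s", traj.trial_id, exc)
            failures.append({"trial_id": traj.trial_id, "stage": "angles", "error": str(exc)})
            continue
        rows.append(
            {
                "trial_id": traj.trial_id,
                "fish_id": traj.fish_id,
                "displacement": displacement,
                "first_angle_deg": first.theta_deg,
                "first_angle_axial_deg": first.axial_deg,
                "start_end_angle_deg": se.theta_deg,
                "start_end_axial_deg": se.axial_deg,
                "crop_index": cropped.crop_index if cropped.crop_index is not None else -1,
                "path_length_cm": arc_length(cropped.xy),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(failures)


def _strategy_groups(cls_df: pd.DataFrame) -> pd.Series:
    """Five-level grouping: PI, APC split by displacement, RR, RANDOM."""
    def name(row):
        if row["label"] == "APC":
            return f"APC_{row['displacement']}"
        return row["label"]

    return cls_df.apply(name, axis=1)


def group_expectation_table(
    cls_df: pd.DataFrame, angles_df: pd.DataFrame, seed: int = 0, reps: int = 9999
) -> pd.DataFrame:
    """Table of group metrics tested against model expectations.

    For each strategy group (APC split by displacement) tests first
    angle, start-end angle (axial degrees) and full path length against
    the published expectations, using the normality-gated chooser.
    Groups with fewer than 3 trials report raw values only.
    """
    df = cls_df.merge(angles_df.drop(columns=["fish_id", "displacement", "crop_index"]), on="trial_id")
    rows = []
    group_specs = [
        ("PI", df["label"] == "PI", ("PI", "lateral")),
        ("APC_lateral", (df["label"] == "APC") & (df["displacement"] == "lateral"), ("APC", "lateral")),
        ("APC_diagonal", (df["label"] == "APC") & (df["displacement"] == "diagonal"), ("APC", "diagonal")),
        ("RR", df["label"] == "RR", ("RR", "lateral")),
    ]
    rng = np.random.default_rng(seed)
    for gname, mask, key in group_specs:
        sub = df[mask]
        exp = arena.EXPECTATIONS[key]
        metrics = [
            ("first_straight_angle_deg", sub["first_angle_axial_deg"], circular.fold_axial(exp.expected_first_angle_deg)),
            ("start_end_angle_deg", sub["start_end_axial_deg"], circular.fold_axial(exp.expected_start_end_angle_deg)),
            ("distance_traveled_cm", sub["full_length_cm"], exp.expected_length_cm),
        ]
        for metric, values, expectation in metrics:
            vals = values.to_numpy(float)
            base = {"group": gname, "metric": metric, "n": len(vals), "expectation": expectation}
            if len(vals) < 3:
                rows.append({**base, "test": "raw", "raw_values": ";".join(f"{v:.2f}" for v in vals)})
                continue
            try:
                res, shap = cohort.compare_to_expectation(
                    vals, expectation, reps=reps, seed=rng
                )
            except FishnavError as exc:
                rows.append({**base, "test": "failed", "raw_values": str(exc)})
                continue
            rows.append(
                {
                    **base,
                    "test": "bootstrap_t" if res.statistic_name == "t" else "wilcoxon",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "mean": res.mean,
                    "ci_lo": res.ci95[0] if res.ci95 else None,
                    "ci_hi": res.ci95[1] if res.ci95 else None,
                    "shapiro_W": shap.statistic,
                    "shapiro_p": shap.p,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    trajectories_csv: str | Path,
    metadata_csv: str | Path,
    config: ArenaConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    rule: str = "sd_uniform",
    n_null: int = 10_000,
    cone_deg: float = 30.0,
    persistence: int = 2,
    reps: int = 9999,
) -> PipelineResult:
    """Run the full analysis on a trajectory CSV + metadata CSV.

    Writes (when ``out_dir`` is given) classification.csv, angles.csv,
    group_stats.csv, distance_groups.csv, circfit.csv,
    strategy_model.csv, failures.csv and manifest.json.
    """
    config = config or ArenaConfig()
    trajectories = read_trajectories(trajectories_csv, tank_side=config.tank_side)
    metadata = pd.read_csv(metadata_csv)
    cls_df, fail1, _ = classify_cohort(
        trajectories, metadata, config, rule=rule, n_null=n_null, seed=seed,
        cone_deg=cone_deg, persistence=persistence,
    )
    if cls_df.empty:
        raise NoAnalysableTrialsError("no trial survived cropping and classification")
    angles_df, fail2 = extract_angles(
        trajectories, config, metadata, cone_deg=cone_deg, persistence=persistence
    )
    failures = pd.concat([fail1, fail2], ignore_index=True) if len(fail1) + len(fail2) else pd.DataFrame(
        columns=["trial_id", "stage", "error"]
    )

    # circular model family on both angle samples
    circ_rows = []
    for colname, sample_name in (
        ("first_angle_axial_deg", "first_angle"),
        ("start_end_axial_deg", "start_end_angle"),
    ):
        vals = angles_df[colname].dropna().to_numpy(float)
        if vals.size >= 5:
            fam = circular.fit_circular_model_family(vals, seed=seed)
            frame = fam.to_frame()
            frame.insert(0, "sample", sample_name)
            frame["lr_vs_uniform"] = fam.lr_stat
            frame["lr_p"] = fam.lr_p
            circ_rows.append(frame)
    circfit = pd.concat(circ_rows, ignore_index=True) if circ_rows else pd.DataFrame()

    group_stats = group_expectation_table(cls_df, angles_df, seed=seed, reps=reps)

    merged = cls_df.merge(
        angles_df[["trial_id", "path_length_cm"]], on="trial_id", how="inner"
    )
    dist_groups = dist_posthoc = None
    groups = _strategy_groups(merged)
    if groups.nunique() >= 2:
        try:
            res, posthoc = cohort.distance_across_groups(merged["full_length_cm"], groups)
            dist_groups = pd.DataFrame(
                [{"statistic": "H", "value": res.statistic, "df": res.df, "p": res.p}]
            )
            dist_posthoc = posthoc
        except FishnavError as exc:
            logger.warning("across-group distance test skipped: %s", exc)

    strat_model = None
    records = cls_df.merge(
        metadata[["trial_id", "age_days", "swim_speed_cm_s", "trial_number"]], on="trial_id"
    )
    try:
        scm = cohort.strategy_choice_model(records)
        strat_model = scm.table
    except FishnavError as exc:
        logger.warning("strategy-choice model skipped: %s", exc)

    manifest = {
        "tool_version": _tool_version(),
        "seed": seed,
        "inputs": {
            "trajectories_csv": {"path": str(trajectories_csv), "sha256": _digest(trajectories_csv)},
            "metadata_csv": {"path": str(metadata_csv), "sha256": _digest(metadata_csv)},
        },
        "config": config.to_dict(),
        "parameters": {
            "rule": rule,
            "n_null": n_null,
            "cone_deg": cone_deg,
            "persistence": persistence,
            "bootstrap_reps": reps,
        },
        "n_trials_in": len(trajectories),
        "n_trials_classified": int(len(cls_df)),
        "n_failures": int(len(failures)),
        "label_counts": cls_df["label"].value_counts().to_dict(),
    }

    result = PipelineResult(
        cls_df, angles_df, group_stats, dist_groups, dist_posthoc, circfit, strat_model,
        failures, manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cls_df.to_csv(out / "classification.csv", index=False)
        angles_df.to_csv(out / "angles.csv", index=False)
        group_stats.to_csv(out / "group_stats.csv", index=False)
        circfit.to_csv(out / "circfit.csv", index=False)
        failures.to_csv(out / "failures.csv", index=False)
        if dist_groups is not None:
            dist_groups.to_csv(out / "distance_groups.csv", index=False)
            dist_posthoc.to_csv(out / "distance_posthoc.csv", index=False)
        if strat_model is not None:
            strat_model.to_csv(out / "strategy_model.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
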