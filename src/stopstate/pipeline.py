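"""End-to-end orchestration: simulate (or ingest) -> behavior -> MEP
preprocessing -> state-space distances -> mixed-model inference, with a
manifest recording seed, configuration hash and exclusion accounting."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import rde_table, summarize_behavior
from .inference import ModelSpec, fit_mixed, posthoc_rise_onset
from .mep import assign_cue_bins, assign_response_bins, preprocess
from .simulate import TRIAL_COLUMNS, ParticipantDistribution, simulate_dataset
from .statespace import (
    assemble_comparison_table,
    bootstrap_simulated_trajectories,
    real_distance_table,
    task_bin_counts,
)
from .task import GO_ONLY_SPEC, SST_SPEC, TaskSpec


@dataclass
class RunConfig:
    """Pipeline configuration (YAML/JSON-loadable)."""

    seed: int = 0
    n_participants: int = 16
    out_dir: str = "results/run"
    n_boot: int = 1000
    bootstrap_mode: str = "split"
    replicate_summary: str = "single"  # "single" | "mean" | "full"
    omission_cutoff_ms: float = 1000.0
    motor_time_ms: float = 50.0
    skew_threshold: float = 1.0
    make_plots: bool = False
    task_overrides: dict = field(default_factory=dict)  # TaskSpec field overrides per task
    distribution_overrides: dict = field(default_factory=dict)  # ParticipantDistribution fields
    trials_csv: str | None = None  # ingest instead of simulating

    def validate(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.omission_cutoff_ms <= 0 or self.motor_time_ms < 0:
            raise ValueError("invalid thresholds")
        if self.trials_csv is not None and not Path(self.trials_csv).exists():
            raise ValueError(f"trials_csv not found: {self.trials_csv}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def specs(self) -> tuple[TaskSpec, ...]:
        out = []
        for base in (SST_SPEC, GO_ONLY_SPEC):
            ov = self.task_overrides.get(base.task_label, {})
            out.append(dataclasses.replace(base, **ov) if ov else base)
        return tuple(out)

    def distribution(self) -> ParticipantDistribution:
        return ParticipantDistribution(**self.distribution_overrides)


def validate_trial_schema(trials: pd.DataFrame) -> None:
    """Check the interchange schema, naming the offending column/row."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad_type = ~trials["trial_type"].isin(["go", "stop", "catch", "baseline"])
    if bad_type.any():
        row = int(trials.index[bad_type][0])
        raise ValueError(f"invalid trial_type at row {row} (column 'trial_type')")
    resp = trials["responded"].astype(bool)
    mismatch = resp != trials["rt_ms"].notna()
    if mismatch.any():
        row = int(trials.index[mismatch][0])
        raise ValueError(f"rt_ms must be present iff responded (row {row}, column 'rt_ms')")
    is_stop = trials["trial_type"] == "stop"
    if (trials.loc[is_stop, "ssd_ms"].isna()).any() or (trials.loc[~is_stop, "ssd_ms"].notna()).any():
        raise ValueError("ssd_ms must be present iff trial_type == 'stop' (column 'ssd_ms')")


def _config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant configuration (paths excluded)."""
    payload = dataclasses.asdict(config)
    for key in ("out_dir", "trials_csv"):
        payload.pop(key, None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _result_json(model_result) -> dict:
    return {
        "terms": model_result.terms.reset_index()
        .rename(columns={"index": "term"})
        .to_dict("records"),
        "converged": model_result.converged,
        "transform": model_result.transform_applied,
        "group_var": model_result.group_var,
        "n_obs": model_result.n_obs,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write tidy CSV/JSON outputs plus a manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config_hash": _config_hash(config)}

    if config.trials_csv:
        trials = pd.read_csv(config.trials_csv)
    else:
        trials = simulate_dataset(
            n_participants=config.n_participants,
            specs=config.specs(),
            distribution=config.distribution(),
            seed=config.seed,
        )
    validate_trial_schema(trials)
    trials.to_csv(out_dir / "trials.csv", index=False)
    log["n_trials"] = len(trials)

    summary = summarize_behavior(trials)
    summary.to_csv(out_dir / "behavior_summary.csv", index=False)
    rde = rde_table(summary)
    rde.to_csv(out_dir / "rde.csv", index=False)

    cue, resp, norm, report = preprocess(
        trials, motor_time_ms=config.motor_time_ms, omission_cutoff_ms=config.omission_cutoff_ms
    )
    cue.to_csv(out_dir / "binned_cue_locked.csv", index=False)
    resp.to_csv(out_dir / "binned_response_locked.csv", index=False)
    log["exclusions"] = report

    models: dict = {}
    cue_ms = ModelSpec(
        response="mean_normalized_mep",
        fixed_factors=("coil", "task", "bin_label"),
        random_intercept="participant_id",
        skew_threshold=config.skew_threshold,
    )
    models["cue_locked"] = _result_json(fit_mixed(cue.astype({"bin_label": str}), cue_ms))
    models["response_locked"] = _result_json(fit_mixed(resp.astype({"bin_label": str}), cue_ms))
    onsets = posthoc_rise_onset(cue)
    models["rise_onset"] = {task: v["onset"] for task, v in onsets.items()}

    distance_tables = {}
    rng_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    for alignment, assign in (("cue_locked", assign_cue_bins), ("response_locked", assign_response_bins)):
        trial_bins = assign(norm)
        if "out_of_range" in trial_bins:
            trial_bins = trial_bins[~trial_bins["out_of_range"]]
        binned = cue if alignment == "cue_locked" else resp
        real = real_distance_table(binned, alignment)
        sim = bootstrap_simulated_trajectories(
            trial_bins,
            alignment,
            n_boot=config.n_boot,
            seed=rng_seed,
            mode=config.bootstrap_mode,
            summarize=config.replicate_summary,
            match_counts=task_bin_counts(trial_bins),
        )
        comp = assemble_comparison_table(real, sim)
        comp.to_csv(out_dir / f"distances_{alignment}.csv", index=False)
        distance_tables[alignment] = comp
        for metric in ("euclidean", "cosine"):
            sub = comp[comp["metric"] == metric]
            spec = ModelSpec(
                response="distance_value",
                fixed_factors=("TIME", "ANALYSIS_TYPE"),
                random_intercept="participant",
                transform="log" if (sub["distance_value"] > 0).all() else "auto",
                skew_threshold=config.skew_threshold,
            )
            models[f"distance_{alignment}_{metric}"] = _result_json(fit_mixed(sub, spec))

    with open(out_dir / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, default=str)

    if config.make_plots:
        from .plots import plot_excitability_timecourses, plot_state_space

        plot_excitability_timecourses(cue, resp).savefig(out_dir / "timecourses.svg")
        for alignment in ("cue_locked", "response_locked"):
            binned = cue if alignment == "cue_locked" else resp
            plot_state_space(binned, alignment).savefig(out_dir / f"state_space_{alignment}.svg")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": log["config_hash"],
        "n_trials": log["n_trials"],
        "exclusions": report,
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "trials": trials,
        "behavior": summary,
        "rde": rde,
        "cue_binned": cue,
        "response_binned": resp,
        "models": models,
        "distances": distance_tables,
        "manifest": manifest,
        "out_dir": out_dir,
    }
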