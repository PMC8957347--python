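"""Task engine: trial scheduling and the dynamic SSD tracking staircase.

The stop-signal task (SST) interleaves go, stop and catch trials. Stop trials
carry a stop signal at a variable stop-signal delay (SSD) after the go cue;
the SSD is adapted trial-by-trial by a +/-50 ms staircase so that stopping
succeeds on roughly half of stop trials. The Go-only task is the same block
without stop trials. Catch trials show only the fixation cross and carry the
baseline TMS pulse (1,000 ms after fixation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical cue-locked TMS timepoints (ms after the go cue).
DEFAULT_TIMEPOINTS_MS = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0)


@dataclass(frozen=True)
class TaskSpec:
    """Block layout for one task.

    Defaults reproduce the experimental protocol: 105 go trials, 35 stop
    trials (SST only), 15 catch/baseline trials, seven cue-locked TMS
    timepoints with 15 MEPs each, baseline TMS 1,000 ms after fixation,
    go cue 500 ms after fixation, 1,750 ms intertrial interval.
    """

    task_label: str  # "SST" or "GoOnly"
    n_go: int = 105
    n_stop: int = 35
    n_catch: int = 15
    tms_timepoints_ms: tuple[float, ...] = DEFAULT_TIMEPOINTS_MS
    meps_per_timepoint: int = 15
    baseline_tms_offset_ms: float = 1000.0
    fixation_to_cue_ms: float = 500.0
    intertrial_interval_ms: float = 1750.0

    def __post_init__(self) -> None:
        if self.task_label not in ("SST", "GoOnly"):
            raise ValueError(f"unknown task_label {self.task_label!r}")
        if min(self.n_go, self.n_stop, self.n_catch) < 0:
            raise ValueError("trial counts must be non-negative")
        tps = self.tms_timepoints_ms
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("tms_timepoints_ms must be strictly increasing")
        if self.meps_per_timepoint <= 0:
            raise ValueError("meps_per_timepoint must be positive")
        if self.task_label == "GoOnly" and self.n_stop != 0:
            raise ValueError("GoOnly blocks cannot contain stop trials")

    @property
    def n_trials(self) -> int:
        return self.n_go + self.n_stop + self.n_catch


SST_SPEC = TaskSpec(task_label="SST")
GO_ONLY_SPEC = TaskSpec(task_label="GoOnly", n_stop=0)


@dataclass(frozen=True)
class StaircaseState:
    """Dynamic tracking state for the stop-signal delay.

    The SSD starts at 150 ms and moves in 50 ms steps within [100, 250] ms:
    +50 after a successful stop (stopping gets harder), -50 after a failed
    stop. Updates at a bound clip (the tracker stays well-defined).
    """

    current_ssd_ms: float = 150.0
    step_ms: float = 50.0
    lower_ms: float = 100.0
    upper_ms: float = 250.0
    history: tuple[tuple[float, bool], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.lower_ms <= self.current_ssd_ms <= self.upper_ms:
            raise ValueError("current SSD outside [lower, upper]")
        if (self.current_ssd_ms - self.lower_ms) % self.step_ms != 0:
            raise ValueError("current SSD is not on the staircase grid")


def staircase_update(state: StaircaseState, stop_success: bool) -> StaircaseState:
    """Advance the staircase after one stop trial.

    Success moves the next SSD 50 ms later, failure 50 ms earlier; both are
    clipped to the [100, 250] ms range.
    """
    delta = state.step_ms if stop_success else -state.step_ms
    new_ssd = float(np.clip(state.current_ssd_ms + delta, state.lower_ms, state.upper_ms))
    return replace(
        state,
        current_ssd_ms=new_ssd,
        history=state.history + ((state.current_ssd_ms, bool(stop_success)),),
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def schedule_block(spec: TaskSpec, seed) -> pd.DataFrame:
    """Lay out one block: trial order, trial types and TMS timing.

    Go trials receive each cue-locked timepoint exactly
    ``meps_per_timepoint`` times, in randomized order. In the SST the
    responding trials (go + stop) are arranged so that each successive group
    of four contains exactly one stop trial ("one in every four trials
    contained a stop signal"); the stop position within each group is random.
    Catch trials are inserted at random positions and carry the baseline TMS
    pulse, timed from fixation. Stop trials are given a random cue-locked TMS
    timepoint (TMS is delivered on all trials) but their MEPs are never
    analyzed.

    Returns a skeleton table (no reaction times or MEP amplitudes yet); fully
    reproducible from ``seed`` (an int or a numpy Generator).
    """
    rng = _as_rng(seed)
    n_tp = len(spec.tms_timepoints_ms)
    if spec.n_go != spec.meps_per_timepoint * n_tp:
        raise ValueError(
            "unbalanced schedule: n_go=%d is not meps_per_timepoint (%d) x "
            "number of timepoints (%d)" % (spec.n_go, spec.meps_per_timepoint, n_tp)
        )
    if spec.n_stop > 0:
        n_resp = spec.n_go + spec.n_stop
        if n_resp % 4 != 0 or spec.n_stop != n_resp // 4:
            raise ValueError(
                "stop trials must be one in every four responding trials "
                f"(got {spec.n_stop} stop / {n_resp} responding)"
            )

    go_tps = np.repeat(np.asarray(spec.tms_timepoints_ms, dtype=float), spec.meps_per_timepoint)
    rng.shuffle(go_tps)

    # Responding-trial sequence: tumbling groups of 4 with one stop each.
    resp_type: list[str] = []
    if spec.n_stop > 0:
        for _ in range(spec.n_stop):
            group = ["go", "go", "go", "stop"]
            rng.shuffle(group)
            resp_type.extend(group)
    else:
        resp_type = ["go"] * spec.n_go

    # Insert catch trials at random positions in the full sequence.
    n_total = spec.n_trials
    catch_pos = set(rng.choice(n_total, size=spec.n_catch, replace=False).tolist())
    rows = []
    resp_iter = iter(resp_type)
    go_tp_iter = iter(go_tps)
    stop_tps = rng.choice(spec.tms_timepoints_ms, size=spec.n_stop)
    stop_i = 0
    for idx in range(n_total):
        if idx in catch_pos:
            rows.append(
                dict(
                    trial_index=idx,
                    trial_type="catch",
                    tms_timepoint_ms=np.nan,
                    tms_from_fixation_ms=spec.baseline_tms_offset_ms,
                )
            )
            continue
        ttype = next(resp_iter)
        if ttype == "go":
            tp = float(next(go_tp_iter))
        else:
            tp = float(stop_tps[stop_i])
            stop_i += 1
        rows.append(
            dict(
                trial_index=idx,
                trial_type=ttype,
                tms_timepoint_ms=tp,
                tms_from_fixation_ms=spec.fixation_to_cue_ms + tp,
            )
        )
    df = pd.DataFrame(rows)
    df["task"] = spec.task_label
    return df
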