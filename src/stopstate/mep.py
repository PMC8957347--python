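"""MEP preprocessing: peak-to-peak extraction, exclusions, normalization,
cue-locked and response-locked binning.

Only go-trial MEPs are analyzed. Trials where TMS arrived during or after
the EMG burst are excluded; amplitudes are normalized to each participant x
coil baseline (catch-trial MEPs, TMS 1,000 ms after fixation). Cue-locked
analysis groups MEPs by their scheduled timepoint (Cue, 50 ... 300 ms after
the go cue); response-locked analysis groups them by the lead time between
TMS and the response into 50 ms bins (300-350 down to 50-100 ms before
movement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CUE_BIN_LABELS = ("Cue", "50", "100", "150", "200", "250", "300")
#: Response-locked bins ordered from far-from-movement to near-movement,
#: half-open [lower, upper) on the lead time rt - tms.
RESPONSE_BIN_EDGES = ((300, 350), (250, 300), (200, 250), (150, 200), (100, 150), (50, 100))
RESPONSE_BIN_LABELS = tuple(f"{lo}-{hi}" for lo, hi in RESPONSE_BIN_EDGES)
LEAD_BOUNDS_MS = (50.0, 350.0)
DEFAULT_MOTOR_TIME_MS = 50.0  # EMG burst onset precedes the registered keypress by this much

_KEY = ["participant_id", "task", "coil"]


@dataclass(frozen=True)
class EmgTrace:
    """A raw EMG sweep in mV with event times in trace coordinates (ms)."""

    samples_mv: np.ndarray
    sampling_rate_hz: float
    tms_time_ms: float | None = None
    response_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        span = len(self.samples_mv) / self.sampling_rate_hz * 1000.0
        for ev in (self.tms_time_ms, self.response_time_ms):
            if ev is not None and not 0 <= ev <= span:
                raise ValueError("event time outside trace span")

    def window(self, start_ms: float, end_ms: float) -> np.ndarray:
        i0 = int(np.ceil(start_ms / 1000.0 * self.sampling_rate_hz))
        i1 = int(np.ceil(end_ms / 1000.0 * self.sampling_rate_hz))
        return self.samples_mv[max(i0, 0) : i1]


def peak_to_peak(trace: EmgTrace, window_start_ms: float, window_end_ms: float) -> float:
    """Peak-to-peak amplitude (max - min, mV) within [start, end)."""
    if window_end_ms <= window_start_ms:
        raise ValueError("window_end_ms must exceed window_start_ms")
    seg = trace.window(window_start_ms, window_end_ms)
    if seg.size == 0:
        raise ValueError("empty window")
    return float(seg.max() - seg.min())


def detect_burst_onset(
    trace: EmgTrace,
    k: float = 3.0,
    min_duration_ms: float = 5.0,
    baseline_end_ms: float | None = None,
) -> float | None:
    """Threshold EMG-burst detector: rectified signal above k x baseline SD
    sustained for at least ``min_duration_ms``. Returns onset in ms, or None.

    Stand-in for visual inspection; the criterion is a package choice.
    """
    fs = trace.sampling_rate_hz
    if baseline_end_ms is None:
        baseline_end_ms = trace.tms_time_ms if trace.tms_time_ms else len(trace.samples_mv) / fs * 100.0
    base = trace.window(0.0, baseline_end_ms)
    if base.size < 10:
        raise ValueError("baseline segment too short for burst detection")
    thresh = k * float(base.std())
    above = np.abs(trace.samples_mv) > thresh
    need = max(int(min_duration_ms / 1000.0 * fs), 1)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return (i - need + 1) / fs * 1000.0
    return None


def exclude_tms_in_burst(tms_time_ms: float, burst_onset_ms: float | None) -> bool:
    """True iff TMS arrived during or after the EMG burst.

    Trials without a burst (no response) are never excluded by this rule.
    """
    if burst_onset_ms is None:
        return False
    return tms_time_ms >= burst_onset_ms


def normalize_to_baseline(amplitude_mv, baseline_mean_mv: float):
    """Express an MEP amplitude as a ratio of the baseline mean."""
    if not np.isfinite(baseline_mean_mv) or baseline_mean_mv <= 0:
        raise ValueError("baseline mean must be positive and finite")
    return np.asarray(amplitude_mv) / baseline_mean_mv if np.ndim(amplitude_mv) else float(amplitude_mv) / baseline_mean_mv


def apply_burst_exclusion(trials: pd.DataFrame, motor_time_ms: float = DEFAULT_MOTOR_TIME_MS) -> pd.DataFrame:
    """Flag go trials where TMS fell during/after the EMG burst.

    For tabular (trace-free) data the burst onset is taken as
    rt - ``motor_time_ms``; responding go trials with
    tms_timepoint >= rt - motor_time are excluded as ``tms_in_burst``.
    Already-excluded trials keep their original reason. Idempotent.
    """
    out = trials.copy()
    out["exclusion_reason"] = out["exclusion_reason"].astype("string")
    cand = (
        (out["trial_type"] == "go")
        & out["responded"].astype(bool)
        & ~out["excluded"].astype(bool)
        & (out["tms_timepoint_ms"] >= out["rt_ms"] - motor_time_ms)
    )
    out.loc[cand, "excluded"] = True
    out.loc[cand, "exclusion_reason"] = "tms_in_burst"
    return out


def baseline_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean baseline MEP per participant x coil from catch/baseline trials."""
    base = trials[trials["trial_type"].isin(["catch", "baseline"])]
    return (
        base.groupby(["participant_id", "coil"], observed=True)["mep_amplitude_mv"]
        .mean()
        .rename("baseline_mean_mv")
        .reset_index()
    )


def normalize_table(trials: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Attach baseline-normalized amplitudes; drop coils without a baseline.

    Returns the table with a ``norm_mep`` column and the list of
    (participant, coil) pairs dropped because no positive baseline mean was
    available (participants without elicitable baseline MEPs for that coil).
    """
    bases = baseline_means(trials)
    merged = trials.merge(bases, on=["participant_id", "coil"], how="left")
    bad = ~np.isfinite(merged["baseline_mean_mv"]) | (merged["baseline_mean_mv"] <= 0)
    dropped = sorted(
        set(map(tuple, merged.loc[bad, ["participant_id", "coil"]].drop_duplicates().to_numpy()))
    )
    merged = merged[~bad].copy()
    merged["norm_mep"] = merged["mep_amplitude_mv"] / merged["baseline_mean_mv"]
    return merged, dropped


def _analyzable_go(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[(trials["trial_type"] == "go") & ~trials["excluded"].astype(bool)]


def assign_cue_bins(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level cue-locked bin labels for analyzable go trials."""
    go = _analyzable_go(trials).copy()
    go["bin_label"] = go["tms_timepoint_ms"].map(
        lambda tp: "Cue" if tp == 0 else f"{int(tp)}"
    )
    go["alignment"] = "cue_locked"
    return go


def assign_response_bins(trials: pd.DataFrame) -> pd.DataFrame:
    """Trial-level response-locked bin labels for analyzable, responded go trials.

    Lead time = rt - tms_timepoint, binned half-open [lower, upper). Leads
    outside [50, 350) ms are flagged ``out_of_range`` (lead < 50 ms implies
    TMS at or inside the EMG burst given electromechanical delay) and carry
    bin_label = NA.
    """
    go = _analyzable_go(trials)
    go = go[go["responded"].astype(bool)].copy()
    lead = go["rt_ms"] - go["tms_timepoint_ms"]
    go["lead_ms"] = lead
    lo, hi = LEAD_BOUNDS_MS
    in_range = (lead >= lo) & (lead < hi)
    labels = pd.array([pd.NA] * len(go), dtype="string")
    for (blo, bhi), lab in zip(RESPONSE_BIN_EDGES, RESPONSE_BIN_LABELS):
        sel = ((lead >= blo) & (lead < bhi)).to_numpy()
        labels[sel] = lab
    go["bin_label"] = labels
    go["out_of_range"] = ~in_range
    go["alignment"] = "response_locked"
    return go


def _aggregate(binned: pd.DataFrame, labels: tuple[str, ...], alignment: str) -> pd.DataFrame:
    agg = (
        binned.groupby(_KEY + ["bin_label"], observed=True)["norm_mep"]
        .agg(mean_normalized_mep="mean", n_trials="size")
        .reset_index()
    )
    agg["bin_label"] = pd.Categorical(agg["bin_label"], categories=labels, ordered=True)
    agg["alignment"] = alignment
    return agg.sort_values(_KEY + ["bin_label"]).reset_index(drop=True)


def bin_cue_locked(trials_norm: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized MEP per participant x task x coil x cue-locked bin."""
    return _aggregate(assign_cue_bins(trials_norm), CUE_BIN_LABELS, "cue_locked")


def bin_response_locked(trials_norm: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized MEP per participant x task x coil x response-locked bin."""
    rb = assign_response_bins(trials_norm)
    rb = rb[~rb["out_of_range"]]
    return _aggregate(rb, RESPONSE_BIN_LABELS, "response_locked")


def preprocess(
    trials: pd.DataFrame,
    motor_time_ms: float = DEFAULT_MOTOR_TIME_MS,
    omission_cutoff_ms: float = 1000.0,
):
    """Full MEP preprocessing from a raw trial table.

    Applies omission flagging, the TMS-in-burst exclusion and baseline
    normalization, then bins cue-locked and response-locked. Returns
    (cue_binned, response_binned, trials_norm, report) where ``report``
    carries exclusion accounting and dropped participant x coil pairs.
    """
    from .behavior import flag_omissions

    flagged = apply_burst_exclusion(flag_omissions(trials, omission_cutoff_ms), motor_time_ms)
    norm, dropped = normalize_table(flagged)
    cue = bin_cue_locked(norm)
    resp_trials = assign_response_bins(norm)
    resp = bin_response_locked(norm)
    n_go = int((flagged["trial_type"] == "go").sum())
    report = {
        "n_go_trials": n_go,
        "n_omission": int((flagged["exclusion_reason"] == "omission").sum()),
        "n_tms_in_burst": int((flagged["exclusion_reason"] == "tms_in_burst").sum()),
        "n_out_of_range_response_locked": int(resp_trials["out_of_range"].sum()),
        "dropped_participant_coils": dropped,
    }
    return cue, resp, norm, report
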