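"""Synthetic experiment generator.

Behavioral model: go finishing times are ex-Gaussian; the stop-signal task
(SST) context adds a proactive-slowing shift (the response delay effect,
RDE) to the Gaussian mean. Stop trials follow the independent horse-race
rule: a response escapes inhibition iff the go process finishes before
SSD + SSRT. Corticospinal excitability is modeled as a baseline MEP
amplitude multiplied by a movement-locked gain ramp g(t_rel) that rises from
1 toward a plateau as TMS approaches the response, plus multiplicative
lognormal noise with unit median. Because the ramp is locked to the
response, the proactive RT shift alone delays the cue-locked rise in the
SST while leaving response-locked profiles identical across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import GO_ONLY_SPEC, SST_SPEC, StaircaseState, TaskSpec, _as_rng, schedule_block, staircase_update

COILS = ("PA120", "AP30")


@dataclass(frozen=True)
class ParticipantParams:
    """One participant's generative parameters.

    Times in ms, MEP amplitudes in mV. ``rise_gain`` is the plateau of the
    excitability ramp per coil (relative weighting of the PA vs AP rise);
    ``rise_gain_sst`` optionally overrides it in the SST context to plant a
    task-dependent weighting. ``rise_onset_before_rt_ms`` is the lead time
    (before the response) at which the ramp leaves baseline, per task.
    """

    participant_id: str = "P00"
    go_mu_ms: float = 230.0
    go_sigma_ms: float = 30.0
    go_tau_ms: float = 55.0
    rde_shift_ms: float = 100.0
    ssrt_true_ms: float = 220.0
    ssrt_sd_ms: float = 0.0
    coil_rt_penalty_ms: dict = field(default_factory=lambda: {"PA120": 0.0, "AP30": 20.0})
    baseline_mep_mv: dict = field(default_factory=lambda: {"PA120": 0.5, "AP30": 0.5})
    rise_onset_before_rt_ms: dict = field(default_factory=lambda: {"SST": 150.0, "GoOnly": 150.0})
    rise_gain: dict = field(default_factory=lambda: {"PA120": 3.0, "AP30": 2.4})
    rise_gain_sst: dict | None = None
    ramp_shape: str = "linear"  # or "sigmoid"
    mep_noise_cv: float = 0.5
    omission_rate: float = 0.004

    def __post_init__(self) -> None:
        if min(self.go_sigma_ms, self.go_tau_ms) < 0:
            raise ValueError("sigma and tau must be non-negative")
        if self.ssrt_true_ms <= 0:
            raise ValueError("ssrt_true_ms must be positive")
        if self.mep_noise_cv < 0:
            raise ValueError("mep_noise_cv must be non-negative")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must be in [0, 1)")
        if any(v <= 0 for v in self.baseline_mep_mv.values()):
            raise ValueError("baseline MEP amplitudes must be positive")
        if self.ramp_shape not in ("linear", "sigmoid"):
            raise ValueError("ramp_shape must be 'linear' or 'sigmoid'")

    def gain_for(self, task_label: str, coil: str) -> float:
        if task_label == "SST" and self.rise_gain_sst is not None:
            return self.rise_gain_sst[coil]
        return self.rise_gain[coil]


@dataclass(frozen=True)
class ParticipantDistribution:
    """Between-participant distribution the generator samples from.

    Group-level means are anchored to the experiment's behavioral table:
    Go-only mean RT ~285 ms (mu + tau), proactive slowing ~100 ms, SSRT
    ~220 ms, AP coil RT penalty ~20 ms, ~0.4% omissions.
    """

    go_mu_mean: float = 230.0
    go_mu_sd: float = 30.0
    go_sigma_mean: float = 30.0
    go_sigma_sd: float = 5.0
    go_tau_mean: float = 55.0
    go_tau_sd: float = 10.0
    rde_mean: float = 100.0
    rde_sd: float = 25.0
    ssrt_mean: float = 220.0
    ssrt_sd: float = 20.0
    ap_penalty_mean: float = 20.0
    ap_penalty_sd: float = 8.0
    baseline_mep_mean_mv: float = 0.5
    baseline_mep_cv: float = 0.3
    rise_onset_mean: float = 150.0
    rise_onset_sd: float = 15.0
    rise_gain_pa_mean: float = 3.0
    rise_gain_ap_mean: float = 2.4
    rise_gain_sd: float = 0.3
    sst_gain_scale: dict | None = None  # e.g. {"PA120": 1.0, "AP30": 0.7} plants a weighting shift
    mep_noise_cv: float = 0.5
    omission_rate: float = 0.004

    def sample(self, rng: np.random.Generator, participant_id: str) -> ParticipantParams:
        def pos(x, lo=1e-3):
            return float(max(x, lo))

        gains = {
            "PA120": pos(rng.normal(self.rise_gain_pa_mean, self.rise_gain_sd), 1.0),
            "AP30": pos(rng.normal(self.rise_gain_ap_mean, self.rise_gain_sd), 1.0),
        }
        gains_sst = None
        if self.sst_gain_scale is not None:
            gains_sst = {c: pos(gains[c] * self.sst_gain_scale.get(c, 1.0), 1.0) for c in gains}
        # lognormal with unit median around the mean baseline amplitude
        s = np.sqrt(np.log1p(self.baseline_mep_cv**2))
        base = {c: float(self.baseline_mep_mean_mv * rng.lognormal(0.0, s)) for c in COILS}
        onset = pos(rng.normal(self.rise_onset_mean, self.rise_onset_sd), 50.0)
        return ParticipantParams(
            participant_id=participant_id,
            go_mu_ms=pos(rng.normal(self.go_mu_mean, self.go_mu_sd), 80.0),
            go_sigma_ms=pos(rng.normal(self.go_sigma_mean, self.go_sigma_sd), 5.0),
            go_tau_ms=pos(rng.normal(self.go_tau_mean, self.go_tau_sd), 10.0),
            rde_shift_ms=float(rng.normal(self.rde_mean, self.rde_sd)),
            ssrt_true_ms=pos(rng.normal(self.ssrt_mean, self.ssrt_sd), 80.0),
            coil_rt_penalty_ms={"PA120": 0.0, "AP30": float(rng.normal(self.ap_penalty_mean, self.ap_penalty_sd))},
            baseline_mep_mv=base,
            rise_onset_before_rt_ms={"SST": onset, "GoOnly": onset},
            rise_gain=gains,
            rise_gain_sst=gains_sst,
            mep_noise_cv=self.mep_noise_cv,
            omission_rate=self.omission_rate,
        )


def sample_go_rt(params: ParticipantParams, task_label: str, coil: str, rng, size=None):
    """Draw ex-Gaussian go finishing times (ms) for a task/coil context.

    RT = Normal(mu + rde_shift*[task==SST] + coil_penalty, sigma) + Exp(tau).
    Non-positive draws (possible only with extreme parameters) are redrawn.
    """
    rng = _as_rng(rng)
    mu = params.go_mu_ms + params.coil_rt_penalty_ms.get(coil, 0.0)
    if task_label == "SST":
        mu += params.rde_shift_ms
    scalar = size is None
    n = 1 if scalar else int(size)
    rt = rng.normal(mu, params.go_sigma_ms, n) + (
        rng.exponential(params.go_tau_ms, n) if params.go_tau_ms > 0 else 0.0
    )
    bad = rt <= 0
    while bad.any():
        k = int(bad.sum())
        rt[bad] = rng.normal(mu, params.go_sigma_ms, k) + (
            rng.exponential(params.go_tau_ms, k) if params.go_tau_ms > 0 else 0.0
        )
        bad = rt <= 0
    return float(rt[0]) if scalar else rt


def race_stop_trial(go_rt_ms, ssd_ms, ssrt_ms):
    """Independent horse race: respond iff the go process wins.

    The response escapes inhibition iff the go process finishes no later
    than ssd + ssrt; a tie counts as a response (ties have measure zero
    under continuous RTs; fixed for determinism). Returns
    (responded, stop_success); accepts arrays.
    """
    responded = np.asarray(go_rt_ms) <= np.asarray(ssd_ms) + np.asarray(ssrt_ms)
    if responded.ndim == 0:
        r = bool(responded)
        return r, not r
    return responded, ~responded


def mep_gain(t_rel_ms, onset_ms: float, plateau: float, shape: str = "linear"):
    """Excitability gain as a function of lead time before the response.

    t_rel >= onset: baseline (gain 1). t_rel <= 0: full plateau. In between
    the gain rises monotonically toward the plateau as the response
    approaches — linearly by default, or along a logistic ramp.
    """
    t = np.asarray(t_rel_ms, dtype=float)
    if shape == "linear":
        frac = np.clip(1.0 - t / onset_ms, 0.0, 1.0)
    elif shape == "sigmoid":
        # logistic centered mid-ramp, pinned to ~[0, 1] at the ends
        z = (onset_ms / 2.0 - t) / (onset_ms / 8.0)
        frac = np.clip(1.0 / (1.0 + np.exp(-z)), 0.0, 1.0)
        frac = np.where(t >= onset_ms, 0.0, np.where(t <= 0.0, 1.0, frac))
    else:
        raise ValueError(f"unknown ramp shape {shape!r}")
    g = 1.0 + (plateau - 1.0) * frac
    return float(g) if g.ndim == 0 else g


def _lognormal_noise(rng, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(0.0, s, size)  # unit median


def generate_mep(trial, params: ParticipantParams, rng) -> float:
    """Draw one MEP amplitude (mV) for a trial record (mapping-like).

    Baseline (catch) trials use gain 1 exactly. Responding trials use the
    response-locked ramp at t_rel = rt - tms_timepoint. Non-responding
    go/stop trials (successful stops, lapses) have no movement and use
    gain 1. A responding trial without an RT is a contract violation.
    """
    rng = _as_rng(rng)
    coil = trial["coil"]
    base = params.baseline_mep_mv[coil]
    ttype = trial["trial_type"]
    if ttype in ("catch", "baseline"):
        g = 1.0
    elif trial.get("responded", False):
        rt = trial.get("rt_ms")
        if rt is None or (isinstance(rt, float) and np.isnan(rt)):
            raise ValueError("responding trial without rt_ms: cannot compute response-locked gain")
        t_rel = rt - trial["tms_timepoint_ms"]
        task = trial.get("task", "GoOnly")
        g = mep_gain(
            t_rel,
            params.rise_onset_before_rt_ms[task],
            params.gain_for(task, coil),
            params.ramp_shape,
        )
    else:
        g = 1.0
    return float(base * g * _lognormal_noise(rng, params.mep_noise_cv))


def simulate_block(spec: TaskSpec, params: ParticipantParams, coil: str, rng) -> pd.DataFrame:
    """Simulate one participant x coil x task block."""
    rng = _as_rng(rng)
    df = schedule_block(spec, rng)
    n = len(df)
    df["participant_id"] = params.participant_id
    df["coil"] = coil
    df["ssd_ms"] = np.nan
    df["responded"] = False
    df["rt_ms"] = np.nan
    df["stop_success"] = pd.array([pd.NA] * n, dtype="boolean")

    is_go = (df["trial_type"] == "go").to_numpy()
    is_stop = (df["trial_type"] == "stop").to_numpy()

    go_idx = np.flatnonzero(is_go)
    go_rt = sample_go_rt(params, spec.task_label, coil, rng, size=go_idx.size)
    lapse = rng.random(go_idx.size) < params.omission_rate
    df.loc[df.index[go_idx[~lapse]], "rt_ms"] = go_rt[~lapse]
    df.loc[df.index[go_idx[~lapse]], "responded"] = True

    if is_stop.any():
        state = StaircaseState()
        for i in np.flatnonzero(is_stop):
            ssd = state.current_ssd_ms
            grt = sample_go_rt(params, spec.task_label, coil, rng)
            ssrt = params.ssrt_true_ms + (
                rng.normal(0.0, params.ssrt_sd_ms) if params.ssrt_sd_ms > 0 else 0.0
            )
            responded, success = race_stop_trial(grt, ssd, ssrt)
            df.iloc[i, df.columns.get_loc("ssd_ms")] = ssd
            df.iloc[i, df.columns.get_loc("responded")] = responded
            if responded:
                df.iloc[i, df.columns.get_loc("rt_ms")] = grt
            df.iloc[i, df.columns.get_loc("stop_success")] = success
            state = staircase_update(state, success)

    meps = np.empty(n)
    for i, row in enumerate(df.to_dict("records")):
        meps[i] = generate_mep(row, params, rng)
    df["mep_amplitude_mv"] = meps
    df["excluded"] = False
    df["exclusion_reason"] = pd.array([pd.NA] * n, dtype="string")
    return df


#: Column order of the tidy trial table (the interchange schema).
TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "coil",
    "trial_index",
    "trial_type",
    "tms_timepoint_ms",
    "tms_from_fixation_ms",
    "ssd_ms",
    "responded",
    "rt_ms",
    "stop_success",
    "mep_amplitude_mv",
    "excluded",
    "exclusion_reason",
]


def simulate_dataset(
    n_participants: int = 16,
    specs: tuple[TaskSpec, ...] = (SST_SPEC, GO_ONLY_SPEC),
    distribution: ParticipantDistribution | None = None,
    seed: int = 0,
    coils: tuple[str, ...] = COILS,
) -> pd.DataFrame:
    """Simulate a complete experiment (participants x coils x tasks).

    Child RNG streams are spawned per participant so the table is bit-for-bit
    reproducible from ``seed`` regardless of block order.
    """
    dist = distribution or ParticipantDistribution()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    blocks = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = dist.sample(rng, f"P{p + 1:02d}")
        for coil in coils:
            for spec in specs:
                blocks.append(simulate_block(spec, params, coil, rng))
    out = pd.concat(blocks, ignore_index=True)
    return out[TRIAL_COLUMNS]


def simulate_stop_trials(
    params: ParticipantParams, n_stop: int, coil: str, rng, burn_in: int = 0
) -> pd.DataFrame:
    """Run the staircase against the race model for ``n_stop`` stop trials.

    Lightweight driver (no scheduling or MEPs) for long-run convergence and
    estimator-recovery studies of the tracking algorithm. ``burn_in`` extra
    stop trials are run first and discarded, so the returned trials sample
    the staircase at convergence rather than the 150 ms starting transient.
    Returns one row per retained stop trial with the presented SSD and the
    outcome.
    """
    rng = _as_rng(rng)
    state = StaircaseState()
    total = burn_in + n_stop
    ssds = np.empty(total)
    successes = np.empty(total, dtype=bool)
    go_rts = sample_go_rt(params, "SST", coil, rng, size=total)
    for i in range(total):
        ssds[i] = state.current_ssd_ms
        _, success = race_stop_trial(go_rts[i], state.current_ssd_ms, params.ssrt_true_ms)
        successes[i] = success
        state = staircase_update(state, success)
    return pd.DataFrame({"ssd_ms": ssds[burn_in:], "stop_success": successes[burn_in:]})


def synthesize_emg_trace(
    mep_amplitude_mv: float,
    tms_time_ms: float,
    response_time_ms: float | None,
    duration_ms: float = 1500.0,
    sampling_rate_hz: float = 5000.0,
    noise_sd_mv: float = 0.01,
    motor_time_ms: float = 50.0,
    rng=None,
):
    """Synthesize a raw EMG trace: biphasic MEP + voluntary burst + noise.

    The MEP is a one-cycle sine starting ~20 ms after TMS whose peak-to-peak
    span equals ``mep_amplitude_mv``. If the trial has a response, a
    high-frequency EMG burst starts ``motor_time_ms`` before the response.
    Returns an :class:`stopstate.mep.EmgTrace`.
    """
    from .mep import EmgTrace

    rng = _as_rng(rng)
    n = int(duration_ms / 1000.0 * sampling_rate_hz)
    t = np.arange(n) / sampling_rate_hz * 1000.0  # ms
    x = rng.normal(0.0, noise_sd_mv, n)
    mep_start = tms_time_ms + 20.0
    mep_dur = 10.0
    in_mep = (t >= mep_start) & (t < mep_start + mep_dur)
    x[in_mep] += (mep_amplitude_mv / 2.0) * np.sin(2 * np.pi * (t[in_mep] - mep_start) / mep_dur)
    burst_onset = None
    if response_time_ms is not None:
        burst_onset = response_time_ms - motor_time_ms
        in_burst = (t >= burst_onset) & (t < burst_onset + 150.0)
        x[in_burst] += rng.normal(0.0, 0.3, int(in_burst.sum()))
    return EmgTrace(
        samples_mv=x,
        sampling_rate_hz=sampling_rate_hz,
        tms_time_ms=tms_time_ms,
        response_time_ms=response_time_ms,
    )
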