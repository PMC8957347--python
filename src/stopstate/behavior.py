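"""Behavioral measures: go RT, omissions, p(inhibit), SSD, SSRT, RDE.

All summaries are computed per participant x coil x task from the tidy trial
table. SSRT uses the mean method (mean go RT minus mean SSD); the RDE
(response delay effect, the behavioral signature of proactive inhibition) is
the go-RT difference between the SST and Go-only contexts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

OMISSION_CUTOFF_MS = 1000.0

_GROUP = ["participant_id", "coil", "task"]


def flag_omissions(trials: pd.DataFrame, cutoff_ms: float = OMISSION_CUTOFF_MS) -> pd.DataFrame:
    """Flag omission errors on go trials.

    Go trials with RT strictly greater than the cutoff (default 1,000 ms) or
    with no response at all are excluded as omissions (lapses in
    concentration). Idempotent; returns a copy. Raises if any participant x
    coil x task block is left with no analyzable go trial.
    """
    out = trials.copy()
    out["exclusion_reason"] = out["exclusion_reason"].astype("string")
    is_go = out["trial_type"] == "go"
    omit = is_go & (~out["responded"].astype(bool) | (out["rt_ms"] > cutoff_ms))
    out.loc[omit, "excluded"] = True
    out.loc[omit, "exclusion_reason"] = "omission"
    ok = is_go & ~omit
    counts = out[is_go].groupby(_GROUP, observed=True).size()
    kept = out[ok].groupby(_GROUP, observed=True).size().reindex(counts.index, fill_value=0)
    empty = kept[kept == 0]
    if len(empty):
        raise ValueError(f"no analyzable go trials for blocks: {list(empty.index)}")
    return out


def ssrt_mean_method(mean_go_rt_ms: float, mean_ssd_ms: float) -> float:
    """Stop-signal reaction time by the mean method: mean go RT - mean SSD."""
    if not (np.isfinite(mean_go_rt_ms) and np.isfinite(mean_ssd_ms)):
        raise ValueError("mean go RT and mean SSD must be finite")
    return float(mean_go_rt_ms) - float(mean_ssd_ms)


def compute_rde(mean_go_rt_sst_ms: float, mean_go_rt_goonly_ms: float) -> float:
    """Response delay effect: SST minus Go-only go RT (positive = slowing)."""
    return float(mean_go_rt_sst_ms) - float(mean_go_rt_goonly_ms)


def compute_p_inhibit(stop_trials: pd.DataFrame) -> float:
    """Percentage of stop trials with a successfully withheld response."""
    st = stop_trials[stop_trials["trial_type"] == "stop"] if "trial_type" in stop_trials else stop_trials
    if len(st) == 0:
        raise ValueError("p(inhibit) undefined: no stop trials")
    return 100.0 * float(st["stop_success"].astype(bool).mean())


def summarize_behavior(trials: pd.DataFrame, ssd_scope: str = "all") -> pd.DataFrame:
    """Per participant x coil x task behavioral summary.

    Columns mirror the behavioral table of the experiment: mean go RT,
    omission %, and on SST rows p(inhibit), stop-respond RT (failed stop
    trials only), mean SSD and mean-method SSRT. ``ssd_scope`` selects which
    stop trials enter the mean SSD: "all" presented stop trials (the
    mean-method convention of the tracking literature; default) or
    "successful" stops only.
    """
    if ssd_scope not in ("all", "successful"):
        raise ValueError("ssd_scope must be 'all' or 'successful'")
    t = flag_omissions(trials)
    rows = []
    for (pid, coil, task), grp in t.groupby(_GROUP, observed=True, sort=True):
        go = grp[(grp["trial_type"] == "go") & ~grp["excluded"]]
        n_go_all = int((grp["trial_type"] == "go").sum())
        rec = dict(
            participant_id=pid,
            coil=coil,
            task=task,
            mean_go_rt_ms=float(go["rt_ms"].mean()),
            omission_pct=100.0 * (n_go_all - len(go)) / n_go_all if n_go_all else np.nan,
            p_inhibit_pct=np.nan,
            stop_respond_rt_ms=np.nan,
            mean_ssd_ms=np.nan,
            ssrt_ms=np.nan,
        )
        stops = grp[grp["trial_type"] == "stop"]
        if len(stops):
            rec["p_inhibit_pct"] = compute_p_inhibit(stops)
            failed = stops[stops["responded"].astype(bool)]
            rec["stop_respond_rt_ms"] = float(failed["rt_ms"].mean()) if len(failed) else np.nan
            pool = stops if ssd_scope == "all" else stops[stops["stop_success"].astype(bool)]
            if len(pool) == 0:
                raise ValueError(f"no SSD records in scope for {(pid, coil, task)}")
            rec["mean_ssd_ms"] = float(pool["ssd_ms"].mean())
            rec["ssrt_ms"] = ssrt_mean_method(rec["mean_go_rt_ms"], rec["mean_ssd_ms"])
        rows.append(rec)
    return pd.DataFrame(rows)


def rde_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per participant x coil RDE from a :func:`summarize_behavior` table."""
    wide = summary.pivot_table(
        index=["participant_id", "coil"], columns="task", values="mean_go_rt_ms"
    )
    for col in ("SST", "GoOnly"):
        if col not in wide:
            raise ValueError(f"RDE needs both tasks; missing {col}")
    out = wide.reset_index()
    out["rde_ms"] = out["SST"] - out["GoOnly"]
    return out[["participant_id", "coil", "rde_ms"]]
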