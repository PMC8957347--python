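"""State-space trajectories over PA x AP excitability and their distances.

Normalized PA120 excitability is the x axis and normalized AP30 excitability
the y axis of a 2-D state space; the ordered bin means trace a trajectory
through movement preparation (cue-locked) or execution (response-locked).
Two trajectories are compared per matched bin by Euclidean distance (vector
magnitude difference) and cosine distance (difference in the relative
PA/AP weighting, insensitive to magnitude). A bootstrap over Go-only trials
yields the null distribution of distances expected between two trajectories
drawn from the same underlying law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mep import CUE_BIN_LABELS, RESPONSE_BIN_LABELS
from .task import _as_rng

CANONICAL_BINS = {"cue_locked": CUE_BIN_LABELS, "response_locked": RESPONSE_BIN_LABELS}


@dataclass(frozen=True)
class StatePoint:
    """One point of M1 population activity: (PA120, AP30) normalized MEPs."""

    pa: float
    ap: float
    bin_label: str | None = None
    alignment: str | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.pa, self.ap], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Ordered state points over the canonical bin sequence.

    ``points`` is a DataFrame indexed by bin_label with columns pa, ap.
    ``scope`` is "participant" or "group".
    """

    points: pd.DataFrame
    alignment: str
    task_label: str
    scope: str = "participant"
    participant_id: str | None = None

    @property
    def bins(self) -> list[str]:
        return list(self.points.index)


def _coords(p) -> np.ndarray:
    if isinstance(p, StatePoint):
        return p.as_array()
    return np.asarray(p, dtype=float)


def euclidean_distance(p, q) -> float:
    """Straight-line distance between two state points."""
    a, b = _coords(p), _coords(q)
    return float(np.sqrt(((a - b) ** 2).sum()))


def cosine_distance(p, q) -> float:
    """1 - cosine similarity of the two points as vectors from the origin.

    Lies in [0, 2]; 0 for collinear vectors (any positive rescaling), 2 for
    antiparallel ones. Undefined at the origin.
    """
    a, b = _coords(p), _coords(q)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for the zero vector")
    c = float(np.dot(a, b) / (na * nb))
    return 1.0 - min(max(c, -1.0), 1.0)


def cosine_angle_rad(p, q) -> float:
    """The angle (radians) between the two vectors; auxiliary to cosine distance."""
    return float(np.arccos(1.0 - cosine_distance(p, q)))


def build_trajectory(
    binned_pa: pd.DataFrame,
    binned_ap: pd.DataFrame,
    alignment: str,
    scope: str = "participant",
    align_bins: str = "strict",
) -> Trajectory:
    """Pair PA and AP bin means into a trajectory.

    Inputs are rows of a binned-excitability table for a single task (and a
    single participant when scope="participant") restricted to one coil
    each. With ``align_bins="strict"`` a mismatch in bin coverage raises an
    error listing the missing bins; ``"intersect"`` keeps the common bins.
    Group scope averages participant bin means per bin before pairing.
    """
    canonical = CANONICAL_BINS[alignment]

    def collapse(df: pd.DataFrame) -> pd.Series:
        s = df.groupby("bin_label", observed=True)["mean_normalized_mep"].mean()
        return s.reindex([b for b in canonical if b in s.index])

    pa, ap = collapse(binned_pa), collapse(binned_ap)
    common = [b for b in canonical if b in pa.index and b in ap.index]
    missing = sorted(set(canonical) - set(common), key=canonical.index)
    if align_bins == "strict" and missing:
        raise ValueError(f"bin coverage mismatch; missing bins: {missing}")
    if not common:
        raise ValueError("no common bins between PA and AP inputs")
    pts = pd.DataFrame({"pa": pa.loc[common], "ap": ap.loc[common]})
    pts.index.name = "bin_label"
    tasks = set(binned_pa["task"]) | set(binned_ap["task"])
    pids = set(binned_pa["participant_id"]) | set(binned_ap["participant_id"])
    return Trajectory(
        points=pts,
        alignment=alignment,
        task_label=tasks.pop() if len(tasks) == 1 else "mixed",
        scope=scope,
        participant_id=pids.pop() if (scope == "participant" and len(pids) == 1) else None,
    )


def distance_series(traj_a: Trajectory, traj_b: Trajectory) -> pd.DataFrame:
    """Per-bin Euclidean and cosine distances between two trajectories."""
    if traj_a.alignment != traj_b.alignment:
        raise ValueError("trajectories have different alignments")
    if traj_a.bins != traj_b.bins:
        raise ValueError("trajectories have different bin coverage")
    rows = []
    for b in traj_a.bins:
        p = traj_a.points.loc[b].to_numpy()
        q = traj_b.points.loc[b].to_numpy()
        rows.append(
            dict(
                bin_label=b,
                euclidean_d=euclidean_distance(p, q),
                cosine_d=cosine_distance(p, q),
                theta_rad=cosine_angle_rad(p, q),
            )
        )
    return pd.DataFrame(rows)


#: Bins with fewer trials than this are dropped from trajectories and
#: bootstrap pools: a single trial defines no state estimate and no
#: within-bin variability for the null construction to draw on.
MIN_TRIALS_PER_BIN = 2


def participant_trajectories(
    binned: pd.DataFrame,
    alignment: str,
    align_bins: str = "intersect",
    min_trials: int = MIN_TRIALS_PER_BIN,
) -> dict[tuple[str, str], Trajectory]:
    """All (participant, task) trajectories available in a binned table.

    Only participants with both coils present are used; bins are intersected
    across coils (late bins can be thinned by the burst-exclusion rule) and
    bins with fewer than ``min_trials`` trials are dropped.
    """
    if "n_trials" in binned.columns and min_trials > 1:
        binned = binned[binned["n_trials"] >= min_trials]
    out: dict[tuple[str, str], Trajectory] = {}
    for (pid, task), grp in binned.groupby(["participant_id", "task"], observed=True):
        pa = grp[grp["coil"] == "PA120"]
        ap = grp[grp["coil"] == "AP30"]
        if pa.empty or ap.empty:
            continue
        try:
            out[(pid, task)] = build_trajectory(pa, ap, alignment, "participant", align_bins)
        except ValueError:
            continue
    return out


def real_distance_table(binned: pd.DataFrame, alignment: str) -> pd.DataFrame:
    """Per-participant SST-vs-Go-only distances (analysis_type="real")."""
    trajs = participant_trajectories(binned, alignment)
    rows = []
    for pid in sorted({p for p, _ in trajs}):
        a, b = trajs.get((pid, "SST")), trajs.get((pid, "GoOnly"))
        if a is None or b is None:
            continue
        common = [x for x in a.bins if x in b.bins]
        if not common:
            continue
        a2 = Trajectory(a.points.loc[common], alignment, a.task_label, "participant", pid)
        b2 = Trajectory(b.points.loc[common], alignment, b.task_label, "participant", pid)
        d = distance_series(a2, b2)
        d["participant_id"] = pid
        rows.append(d)
    if not rows:
        raise ValueError("no participant with both-task trajectories")
    out = pd.concat(rows, ignore_index=True)
    out["analysis_type"] = "real"
    return out


def task_bin_counts(trials_binned: pd.DataFrame, task: str = "SST") -> pd.DataFrame:
    """Per participant x coil x bin trial counts for one task's analyzable
    go trials (feed as ``match_counts`` to the bootstrap)."""
    t = trials_binned[(trials_binned["task"] == task) & trials_binned["bin_label"].notna()]
    return (
        t.groupby(["participant_id", "coil", "bin_label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )


def _bin_pools(trials_binned: pd.DataFrame) -> dict[str, dict[tuple[str, str], np.ndarray]]:
    """participant -> (coil, bin) -> array of normalized trial MEPs."""
    pools: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for (pid, coil, b), grp in trials_binned.groupby(
        ["participant_id", "coil", "bin_label"], observed=True
    ):
        pools.setdefault(pid, {})[(coil, str(b))] = grp["norm_mep"].to_numpy()
    return pools


def bootstrap_simulated_trajectories(
    goonly_trials_binned: pd.DataFrame,
    alignment: str,
    n_boot: int = 1000,
    seed=0,
    mode: str = "split",
    variance_correction: bool = True,
    summarize: str | bool = "single",
    min_trials: int = MIN_TRIALS_PER_BIN,
    match_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bootstrap null distances from Go-only trials (analysis_type="simulated").

    Input is a trial-level Go-only table carrying ``norm_mep`` and
    ``bin_label`` (see :func:`stopstate.mep.assign_cue_bins` /
    ``assign_response_bins``). For each participant and replicate, a
    simulated pair of trajectory points is drawn from the participant's own
    Go-only trials within each coil x bin pool, and the distances between
    the pair estimate what the real two-trajectory distance would be if both
    tasks shared one underlying law.

    Modes:

    - ``"split"`` (default): trajectories are drawn from the Go-only task
      only; each replicate randomly partitions the Go-only pool into two
      disjoint halves — marginally, means of two independent samples from
      the bin's true law, with no plug-in scale estimate — and the half-mean
      difference is rescaled by the known factor
      sqrt((1/n_a + 1/n_b)/(1/n_1 + 1/n_2)) so its sampling variance equals
      the real pair's (``match_counts`` supplies the comparison arm's
      per-bin counts n_a). Exact variance; the halved group size leaves a
      small shape mismatch at heavy-tailed bins.
    - ``"permute"``: each replicate randomly re-partitions the cell's POOLED
      trials (both tasks together) into two groups of the original per-task
      sizes and takes the two group means. When the two tasks share one law
      the trials are exchangeable, so the simulated pair is distributed
      exactly like the real pair of per-task bin means — all moments. The
      exactness costs power: under a true task difference the pooled cells
      absorb the effect into the null. Requires both tasks' trials in the
      input table.
    - ``"resample"``: two independent with-replacement resamples per
      replicate; with ``variance_correction`` the centered resample means
      are scaled by sqrt(n/(n-1)) (unbiased variance, though the resampled
      dispersion remains slightly light-tailed at small n).
    - ``"vs_original"``: one resample measured against the participant's
      original Go-only trajectory; its distances are ~sqrt(2) smaller than
      the real comparison's even under the null (kept for comparison with
      the literal construction).

    ``summarize`` controls how replicates enter the output: "single"
    (default) keeps one replicate per participant x bin, so the simulated
    arm carries the same sampling dispersion as the real arm — the
    comparison stays calibrated under any monotone transform the normality
    rule may later apply; "mean" averages over replicates (a smooth estimate
    of the expected null distance, for plots and summaries — averaging
    removes the simulated arm's dispersion, so a concave transform shifts
    the two arms apart even under the null); "full" (or False) keeps every
    replicate as a row.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("permute", "split", "resample", "vs_original"):
        raise ValueError("mode must be 'permute', 'split', 'resample' or 'vs_original'")
    if summarize is True:
        summarize = "mean"
    elif summarize is False:
        summarize = "full"
    if summarize not in ("single", "mean", "full"):
        raise ValueError("summarize must be 'single', 'mean' or 'full'")
    rng = _as_rng(seed)
    canonical = CANONICAL_BINS[alignment]
    g = goonly_trials_binned[goonly_trials_binned["task"] == "GoOnly"]
    g = g[g["bin_label"].notna()]
    pools = _bin_pools(g)
    sst_pools: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    if mode == "permute":
        sst = goonly_trials_binned[goonly_trials_binned["task"] == "SST"]
        sst = sst[sst["bin_label"].notna()]
        if sst.empty:
            raise ValueError("mode='permute' needs the SST trials in the input table")
        sst_pools = _bin_pools(sst)
    counts: dict[tuple[str, str, str], int] = {}
    if match_counts is not None:
        counts = {
            (r.participant_id, r.coil, str(r.bin_label)): int(r.n)
            for r in match_counts.itertuples()
        }
    rows = []
    for pid in sorted(pools):
        pp = pools[pid]
        pp = {k: v for k, v in pp.items() if v.size >= min_trials}
        if mode == "permute":
            sp = sst_pools.get(pid, {})
            pp = {k: v for k, v in pp.items() if sp.get(k, np.empty(0)).size >= min_trials}
        bins = [b for b in canonical if ("PA120", b) in pp and ("AP30", b) in pp]
        sim = {}  # (coil, bin) -> (2, n_boot) simulated point coordinates
        for coil in ("PA120", "AP30"):
            for b in bins:
                pool = pp[(coil, b)]
                n = pool.size
                if n == 0:
                    raise ValueError(f"empty trial pool for bin {b!r} ({pid}, {coil})")
                center = pool.mean()
                n_other = counts.get((pid, coil, b), n)
                if mode == "permute":
                    other = sst_pools[pid][(coil, b)]
                    combined = np.concatenate([other, pool])
                    perms = rng.permuted(np.tile(combined, (n_boot, 1)), axis=1)
                    m1 = perms[:, : other.size].mean(axis=1)
                    m2 = perms[:, other.size :].mean(axis=1)
                    sim[(coil, b)] = np.stack([m1, m2])
                elif mode == "split":
                    n1 = n // 2
                    perms = rng.permuted(np.tile(pool, (n_boot, 1)), axis=1)
                    m1 = perms[:, :n1].mean(axis=1)
                    m2 = perms[:, n1:].mean(axis=1)
                    lam = np.sqrt((1.0 / n_other + 1.0 / n) / (1.0 / n1 + 1.0 / (n - n1)))
                    sim[(coil, b)] = np.stack(
                        [center + lam * (m1 - center), center + lam * (m2 - center)]
                    )
                else:
                    draws = 2 if mode == "resample" else 1
                    sizes = (n, max(n_other, 2))[:draws]
                    means = np.stack(
                        [pool[rng.integers(0, n, size=(n_boot, m))].mean(axis=1) for m in sizes]
                    )
                    if variance_correction and n > 1:
                        means = center + (means - center) * np.sqrt(n / (n - 1))
                    sim[(coil, b)] = means
        for b in bins:
            if mode != "vs_original":
                pa_a, pa_b = sim[("PA120", b)]
                ap_a, ap_b = sim[("AP30", b)]
            else:
                pa_a, ap_a = sim[("PA120", b)][0], sim[("AP30", b)][0]
                pa_b = np.full(n_boot, pp[("PA120", b)].mean())
                ap_b = np.full(n_boot, pp[("AP30", b)].mean())
            eu = np.sqrt((pa_a - pa_b) ** 2 + (ap_a - ap_b) ** 2)
            na = np.sqrt(pa_a**2 + ap_a**2)
            nb = np.sqrt(pa_b**2 + ap_b**2)
            cos = 1.0 - np.clip((pa_a * pa_b + ap_a * ap_b) / (na * nb), -1.0, 1.0)
            rows.append(
                pd.DataFrame(
                    dict(
                        participant_id=pid,
                        bin_label=b,
                        replicate_id=np.arange(n_boot),
                        euclidean_d=eu,
                        cosine_d=cos,
                    )
                )
            )
    if not rows:
        raise ValueError("no participant had both-coil Go-only trial pools")
    out = pd.concat(rows, ignore_index=True)
    out["analysis_type"] = "simulated"
    if summarize == "mean":
        out = (
            out.groupby(["participant_id", "bin_label"], observed=True)[["euclidean_d", "cosine_d"]]
            .mean()
            .reset_index()
        )
        out["analysis_type"] = "simulated"
    elif summarize == "single":
        out = out[out["replicate_id"] == 0].drop(columns="replicate_id").reset_index(drop=True)
    return out


def assemble_comparison_table(
    real: pd.DataFrame, simulated: pd.DataFrame, align: bool = True
) -> pd.DataFrame:
    """Long table for the real-vs-simulated mixed model.

    One row per participant x bin x analysis_type x metric with columns
    distance_value, metric, TIME, ANALYSIS_TYPE, participant (and
    replicate_id where present). With ``align`` (default) only participant x
    bin cells present in BOTH arms are kept, so the two analysis arms are
    paired and every TIME level is identifiable in the interaction model.
    """
    if simulated is None or len(simulated) == 0:
        raise ValueError("simulated distance table is empty")
    if real is None or len(real) == 0:
        raise ValueError("real distance table is empty")
    if align:
        key = ["participant_id", "bin_label"]
        cells = pd.merge(
            real[key].drop_duplicates(), simulated[key].drop_duplicates(), on=key
        )
        real = real.merge(cells, on=key)
        simulated = simulated.merge(cells, on=key)
        if real.empty:
            raise ValueError("no participant x bin cells shared by both arms")
    frames = []
    for df in (real, simulated):
        id_vars = ["participant_id", "bin_label", "analysis_type"]
        if "replicate_id" in df.columns:
            id_vars.append("replicate_id")
        m = df.melt(
            id_vars=id_vars,
            value_vars=["euclidean_d", "cosine_d"],
            var_name="metric",
            value_name="distance_value",
        )
        frames.append(m)
    out = pd.concat(frames, ignore_index=True)
    out["metric"] = out["metric"].str.replace("_d", "", regex=False)
    out = out.rename(
        columns={"bin_label": "TIME", "analysis_type": "ANALYSIS_TYPE", "participant_id": "participant"}
    )
    out["TIME"] = out["TIME"].astype(str)
    return out
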