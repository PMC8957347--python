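"""Corticospinal excitability time courses: preprocessing, binning, models.

Normalizes go-trial MEPs to each participant's baseline, bins them
cue-locked (Cue .. 300 ms) and response-locked (300-350 .. 50-100 ms before
movement), fits the factorial mixed models (coil x task x time, participant
random intercept) and locates the rise onset (earliest timepoint whose
excitability exceeds the cue level, Tukey-corrected). The proactive-slowing
generator should show a later cue-locked rise in the stop-signal task and no
task effect response-locked.
"""

import json
from pathlib import Path

import pandas as pd

from stopstate.inference import ModelSpec, fit_mixed, posthoc_rise_onset
from stopstate.mep import preprocess

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = pd.read_csv(RESULTS / "trials.csv")
    cue, resp, norm, report = preprocess(trials)
    cue.to_csv(RESULTS / "binned_cue_locked.csv", index=False)
    resp.to_csv(RESULTS / "binned_response_locked.csv", index=False)
    print("exclusion accounting:", report)

    spec = ModelSpec(
        response="mean_normalized_mep",
        fixed_factors=("coil", "task", "bin_label"),
        random_intercept="participant_id",
    )
    out = {}
    for name, table in (("cue_locked", cue), ("response_locked", resp)):
        res = fit_mixed(table.astype({"bin_label": str}), spec)
        out[name] = res.terms.reset_index().rename(columns={"index": "term"}).to_dict("records")
        print(f"\n{name} mixed model (transform={res.transform_applied}):")
        print(res.terms.round(4))

    onsets = posthoc_rise_onset(cue)
    out["rise_onset"] = {task: v["onset"] for task, v in onsets.items()}
    print("\ncue-locked rise onset (first timepoint significantly above cue):")
    print(out["rise_onset"])

    with open(RESULTS / "excitability_models.json", "w") as fh:
        json.dump(out, fh, indent=2, default=str)


if __name__ == "__main__":
    main()
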