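"""Real-vs-simulated distance comparison: the proactive-inhibition test.

Fits the linear mixed model distance ~ TIME * ANALYSIS_TYPE (participant
random intercept, log-transformed distances) for each metric and alignment.
A significant ANALYSIS_TYPE effect means the stop-signal trajectories
diverge from Go-only trajectories beyond same-law sampling noise.
"""

import json
from pathlib import Path

import pandas as pd

from stopstate.inference import ModelSpec, fit_mixed

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}
    for alignment in ("cue_locked", "response_locked"):
        comp = pd.read_csv(RESULTS / f"distances_{alignment}.csv")
        for metric in ("euclidean", "cosine"):
            sub = comp[comp["metric"] == metric]
            spec = ModelSpec(
                response="distance_value",
                fixed_factors=("TIME", "ANALYSIS_TYPE"),
                random_intercept="participant",
                transform="log" if (sub["distance_value"] > 0).all() else "auto",
            )
            res = fit_mixed(sub, spec)
            key = f"{alignment}_{metric}"
            out[key] = {
                "p_analysis_type": res.pvalue("ANALYSIS_TYPE"),
                "terms": res.terms.reset_index().rename(columns={"index": "term"}).to_dict("records"),
            }
            print(f"{key}: ANALYSIS_TYPE p = {out[key]['p_analysis_type']:.4f}")

    with open(RESULTS / "distance_models.json", "w") as fh:
        json.dump(out, fh, indent=2, default=str)


if __name__ == "__main__":
    main()
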