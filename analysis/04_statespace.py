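"""State-space trajectories and distances against the bootstrap null.

Builds per-participant PA120 x AP30 trajectories for both alignments,
computes real SST-vs-Go-only Euclidean/cosine distances per time bin,
draws the same-law null distances from Go-only trials (half-sampling
bootstrap) and exports the comparison tables plus Fig.-style plots.
"""

from pathlib import Path

import pandas as pd

from stopstate.mep import assign_cue_bins, assign_response_bins, preprocess
from stopstate.plots import plot_excitability_timecourses, plot_state_space
from stopstate.statespace import (
    assemble_comparison_table,
    bootstrap_simulated_trajectories,
    real_distance_table,
    task_bin_counts,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    trials = pd.read_csv(RESULTS / "trials.csv")
    cue, resp, norm, _ = preprocess(trials)

    for alignment, binned, assign in (
        ("cue_locked", cue, assign_cue_bins),
        ("response_locked", resp, assign_response_bins),
    ):
        tb = assign(norm)
        if "out_of_range" in tb:
            tb = tb[~tb["out_of_range"]]
        real = real_distance_table(binned, alignment)
        sim = bootstrap_simulated_trajectories(
            tb, alignment, n_boot=1000, seed=SEED, summarize="single",
            match_counts=task_bin_counts(tb),
        )
        comp = assemble_comparison_table(real, sim)
        comp.to_csv(RESULTS / f"distances_{alignment}.csv", index=False)
        means = comp.groupby(["metric", "ANALYSIS_TYPE"])["distance_value"].mean().round(4)
        print(f"{alignment}: mean distances by metric x arm")
        print(means, "\n")

    plot_excitability_timecourses(cue, resp).savefig(RESULTS / "timecourses.svg")
    for alignment, binned in (("cue_locked", cue), ("response_locked", resp)):
        plot_state_space(binned, alignment).savefig(RESULTS / f"state_space_{alignment}.svg")
    print("wrote distance tables and SVG figures to", RESULTS)


if __name__ == "__main__":
    main()
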