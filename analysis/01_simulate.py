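"""Simulate the full synthetic experiment.

Generates 16 participants x 2 coil orientations (PA120, AP30) x 2 tasks
(stop-signal task, Go-only), with staircase-tracked SSDs, horse-race stop
trials and response-locked excitability ramps, and writes the tidy trial
table that every later stage consumes.
"""

from pathlib import Path

from stopstate.simulate import simulate_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    trials = simulate_dataset(n_participants=16, seed=SEED)
    path = OUT / "trials.csv"
    trials.to_csv(path, index=False)
    n_stop = int((trials["trial_type"] == "stop").sum())
    print(f"wrote {len(trials)} trials ({n_stop} stop trials) to {path}")
    print(trials.groupby(["task", "trial_type"], observed=True).size())


if __name__ == "__main__":
    main()
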