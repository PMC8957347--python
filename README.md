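# stopstate

Simulation and analysis of **proactive inhibition** experiments that combine a
stop-signal task (SST) with transcranial magnetic stimulation (TMS) probes of
corticospinal excitability.

When people know they may have to cancel a movement, they respond with
restraint: go reaction times slow by ~100 ms (the *response delay effect*,
RDE) and the rise of motor-cortex excitability after the go cue is delayed.
This package implements the full analysis chain used to study that
phenomenon, plus a synthetic generator so every stage can be exercised
without human recordings:

- **Task engine** — SST and Go-only block scheduling (105 go / 35 stop / 15
  catch trials, one stop in every four responding trials, seven cue-locked
  TMS timepoints with 15 MEPs each) and the dynamic stop-signal-delay (SSD)
  staircase: start 150 ms, ±50 ms per stop outcome, clipped to [100, 250] ms,
  which holds successful inhibition near 50%.
- **Behavior** — omission filtering (RT > 1,000 ms), go RT, p(inhibit),
  stop-respond RT, mean SSD, and SSRT by the *mean method*,
  `SSRT = mean go RT − mean SSD`; the RDE is
  `mean go RT(SST) − mean go RT(Go-only)`.
- **MEP preprocessing** — peak-to-peak extraction from EMG sweeps, exclusion
  of trials where TMS falls in or after the EMG burst, baseline
  normalization (catch-trial MEPs, TMS 1,000 ms after fixation), and binning
  of go-trial MEPs cue-locked (Cue, 50 … 300 ms) and response-locked (50-ms
  lead-time bins, 300–350 … 50–100 ms before movement).
- **State space** — normalized PA₁₂₀ excitability (x) against AP₃₀
  excitability (y); per-bin trajectory comparison by Euclidean distance *d*
  (magnitude) and cosine distance 1 − cos θ (relative PA/AP weighting), with
  a same-law bootstrap null drawn from Go-only trials.
- **Inference** — linear mixed models with a participant random intercept and
  fully crossed factors (COIL × TASK × TIME; TIME × ANALYSIS_TYPE for the
  distance comparison), automatic log transforms under a residual-skewness
  rule, and Tukey-corrected paired contrasts including the *rise onset*
  (earliest timepoint whose excitability exceeds the cue level).
- **Generator** — ex-Gaussian go finishing times with an additive
  proactive-slowing shift in the SST, an independent horse race against a
  constant-latency stop process (respond iff `go RT ≤ SSD + SSRT`), and MEP
  amplitudes `baseline × g(t_rel) × lognormal noise`, where the gain ramp
  `g` rises from 1 to a coil-specific plateau over the last ~150 ms before
  the response. Because the ramp is response-locked, proactive slowing alone
  delays the cue-locked rise while leaving response-locked profiles
  identical — the signature the analysis is built to detect.

## Worked example

```python
from stopstate import simulate_dataset, summarize_behavior
from stopstate.behavior import rde_table

trials = simulate_dataset(n_participants=16, seed=7)
summary = summarize_behavior(trials)
print(summary.groupby(["task", "coil"])[["mean_go_rt_ms", "p_inhibit_pct", "ssrt_ms"]].mean().round(2))
print(rde_table(summary)["rde_ms"].mean().round(2))
```

prints

```
              mean_go_rt_ms  p_inhibit_pct  ssrt_ms
task   coil
GoOnly AP30          302.24            NaN      NaN
       PA120         282.52            NaN      NaN
SST    AP30          403.17          49.46   236.92
       PA120         384.88          44.64   233.90
101.65
```

— go responses are ~100 ms slower in the stop-signal context (the RDE), the
staircase holds stopping success near 50%, and the mean-method SSRT sits
near the generator's planted ~220 ms stop latency (the small overestimate is
the staircase's 150-ms starting transient at 35 stop trials; see
`docs/methods.md`). The numbered scripts under `analysis/` continue the
chain: `03_excitability.py` fits the excitability mixed models and finds the
cue-locked rise at 150 ms in the Go-only task but 200–250 ms in the SST with
no response-locked task difference; `04_statespace.py`/`05_inference.py`
compare the two tasks' PA×AP trajectories against the bootstrap null;
`06_validation.py` re-checks the pipeline's type-I error and signature
recovery by Monte Carlo. Each script reads and writes `results/`.

The command line mirrors the same stages:

```bash
stopstate simulate --seed 7 --out trials.csv
stopstate behavior trials.csv --out behavior.csv
stopstate run-all --seed 7 --out results/run --n-boot 1000
```

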