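"""MEP preprocessing: peak-to-peak, exclusions, normalization, binning."""

import numpy as np
import pandas as pd
import pytest

from stopstate.behavior import flag_omissions
from stopstate.mep import (
    CUE_BIN_LABELS,
    RESPONSE_BIN_LABELS,
    EmgTrace,
    apply_burst_exclusion,
    assign_response_bins,
    bin_cue_locked,
    bin_response_locked,
    detect_burst_onset,
    exclude_tms_in_burst,
    normalize_table,
    normalize_to_baseline,
    peak_to_peak,
    preprocess,
)
from stopstate.simulate import ParticipantDistribution, simulate_dataset, synthesize_emg_trace


class TestPeakToPeak:
    def test_max_minus_min(self):
        samples = np.zeros(1000)
        samples[100] = 0.3
        samples[200] = -0.2
        trace = EmgTrace(samples_mv=samples, sampling_rate_hz=5000.0)
        assert peak_to_peak(trace, 0.0, 100.0) == pytest.approx(0.5)

    def test_flat_trace_is_zero(self):
        trace = EmgTrace(samples_mv=np.ones(100), sampling_rate_hz=5000.0)
        assert peak_to_peak(trace, 0.0, 10.0) == 0.0

    def test_empty_window_is_error(self):
        trace = EmgTrace(samples_mv=np.ones(100), sampling_rate_hz=5000.0)
        with pytest.raises(ValueError):
            peak_to_peak(trace, 5.0, 5.0)


class TestBurstExclusion:
    def test_tms_after_onset_excluded(self):
        assert exclude_tms_in_burst(tms_time_ms=280.0, burst_onset_ms=270.0)

    def test_tms_before_onset_kept(self):
        assert not exclude_tms_in_burst(tms_time_ms=230.0, burst_onset_ms=270.0)

    def test_no_burst_never_excluded(self):
        assert not exclude_tms_in_burst(tms_time_ms=280.0, burst_onset_ms=None)

    def test_table_rule_uses_motor_time(self):
        rows = [
            dict(participant_id="P01", task="SST", coil="PA120", trial_type="go",
                 responded=True, rt_ms=320.0, tms_timepoint_ms=300.0,
                 excluded=False, exclusion_reason=pd.NA),  # burst at 270 -> excluded
            dict(participant_id="P01", task="SST", coil="PA120", trial_type="go",
                 responded=True, rt_ms=320.0, tms_timepoint_ms=100.0,
                 excluded=False, exclusion_reason=pd.NA),
            dict(participant_id="P01", task="SST", coil="PA120", trial_type="catch",
                 responded=False, rt_ms=np.nan, tms_timepoint_ms=np.nan,
                 excluded=False, exclusion_reason=pd.NA),
        ]
        out = apply_burst_exclusion(pd.DataFrame(rows), motor_time_ms=50.0)
        assert out["excluded"].tolist() == [True, False, False]
        assert out.loc[0, "exclusion_reason"] == "tms_in_burst"

    def test_detector_finds_synthetic_burst(self, rng):
        trace = synthesize_emg_trace(
            mep_amplitude_mv=0.0, tms_time_ms=400.0, response_time_ms=900.0,
            noise_sd_mv=0.01, rng=rng,
        )
        onset = detect_burst_onset(trace)
        assert onset == pytest.approx(850.0, abs=25.0)


class TestNormalization:
    def test_ratio(self):
        assert normalize_to_baseline(1.0, 0.5) == 2.0

    def test_nonpositive_baseline_is_error(self):
        with pytest.raises(ValueError):
            normalize_to_baseline(1.0, 0.0)

    def test_baseline_trials_self_normalize_to_one(self, small_dataset):
        norm, _ = normalize_table(flag_omissions(small_dataset))
        base = norm[norm["trial_type"] == "catch"]
        means = base.groupby(["participant_id", "coil"])["norm_mep"].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0, rtol=1e-12)

    def test_participants_without_baseline_dropped_per_coil(self, small_dataset):
        trials = small_dataset[
            ~((small_dataset["participant_id"] == "P01")
              & (small_dataset["coil"] == "AP30")
              & (small_dataset["trial_type"] == "catch"))
        ]
        norm, dropped = normalize_table(flag_omissions(trials))
        assert ("P01", "AP30") in dropped
        assert not ((norm["participant_id"] == "P01") & (norm["coil"] == "AP30")).any()
        # the other coil is retained
        assert ((norm["participant_id"] == "P01") & (norm["coil"] == "PA120")).any()


class TestCueBinning:
    def test_timepoint_label_passthrough(self, full_preprocessed):
        cue = full_preprocessed["cue"]
        assert set(cue["bin_label"].astype(str)) <= set(CUE_BIN_LABELS)

    def test_seven_bins_when_all_survive(self, full_preprocessed):
        cue = full_preprocessed["cue"]
        counts = cue.groupby(["participant_id", "task", "coil"], observed=True)["bin_label"].nunique()
        assert counts.max() == 7

    def test_excluded_trials_enter_no_bin(self, small_dataset):
        cue, _, _, report = preprocess(small_dataset)
        n_go = int((small_dataset["trial_type"] == "go").sum())
        assert cue["n_trials"].sum() == n_go - report["n_omission"] - report["n_tms_in_burst"]


class TestResponseBinning:
    def _one_trial(self, rt, tms):
        return pd.DataFrame([
            dict(participant_id="P01", task="SST", coil="PA120", trial_type="go",
                 responded=True, rt_ms=rt, tms_timepoint_ms=tms,
                 excluded=False, exclusion_reason=pd.NA, norm_mep=1.0)
        ])

    @pytest.mark.parametrize(
        "rt,tms,label",
        [
            (320.0, 200.0, "100-150"),  # lead 120
            (350.0, 200.0, "150-200"),  # lead 150: lower-inclusive
            (380.0, 100.0, "250-300"),  # lead 280
            (400.0, 100.0, "300-350"),  # lead 300: lower-inclusive
        ],
    )
    def test_lead_time_bins(self, rt, tms, label):
        out = assign_response_bins(self._one_trial(rt, tms))
        assert out["bin_label"].iloc[0] == label
        assert not out["out_of_range"].iloc[0]

    @pytest.mark.parametrize("rt,tms", [(500.0, 100.0), (240.0, 200.0)])  # leads 400, 40
    def test_leads_outside_window_are_out_of_range(self, rt, tms):
        out = assign_response_bins(self._one_trial(rt, tms))
        assert out["out_of_range"].iloc[0]
        assert pd.isna(out["bin_label"].iloc[0])

    def test_partition_property(self, full_preprocessed):
        """Every analyzable responding go trial lands in exactly one
        response-locked bin or is flagged out of range."""
        norm = full_preprocessed["norm"]
        rb = assign_response_bins(norm)
        n_analyzable = len(norm[(norm["trial_type"] == "go")
                                & ~norm["excluded"] & norm["responded"]])
        assert len(rb) == n_analyzable
        in_bin = rb["bin_label"].notna()
        assert (in_bin ^ rb["out_of_range"]).all()
        binned = bin_response_locked(norm)
        assert binned["n_trials"].sum() == int(in_bin.sum())
        assert set(binned["bin_label"].astype(str)) <= set(RESPONSE_BIN_LABELS)


class TestGeneratorRoundTrips:
    def test_flat_excitability_normalizes_to_one(self):
        """With unit gains everywhere the normalized means carry no time
        structure: a pooled t-test against 1 stays null at alpha = .01."""
        from scipy import stats

        flat = ParticipantDistribution(
            rise_gain_pa_mean=1.0, rise_gain_ap_mean=1.0, rise_gain_sd=0.0
        )
        trials = simulate_dataset(8, distribution=flat, seed=21)
        cue, resp, _, _ = preprocess(trials)
        for binned in (cue, resp):
            t = stats.ttest_1samp(binned["mean_normalized_mep"], 1.0)
            assert t.pvalue > 0.01

    def test_response_locked_rise_recovered_monotone(self, full_preprocessed):
        resp = full_preprocessed["resp"]
        means = (
            resp.groupby("bin_label", observed=True)["mean_normalized_mep"]
            .mean()
            .reindex(RESPONSE_BIN_LABELS)
        )
        # pre-rise bins hover at baseline; the final bins climb steeply
        assert (np.diff(means.to_numpy()) > -0.1).all()
        assert (np.diff(means.to_numpy()[-3:]) > 0).all()
        assert means.iloc[-1] > means.iloc[0] + 0.3
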