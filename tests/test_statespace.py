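"""State-space trajectories, distance metrics, bootstrap null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopstate.mep import assign_cue_bins, preprocess
from stopstate.statespace import (
    StatePoint,
    Trajectory,
    assemble_comparison_table,
    bootstrap_simulated_trajectories,
    build_trajectory,
    cosine_distance,
    distance_series,
    euclidean_distance,
    participant_trajectories,
    real_distance_table,
    task_bin_counts,
)

coords = st.floats(min_value=-100.0, max_value=100.0, allow_nan=False)
points = st.tuples(coords, coords)
pos_coords = st.floats(min_value=0.01, max_value=100.0)
pos_points = st.tuples(pos_coords, pos_coords)


class TestEuclidean:
    def test_three_four_five(self):
        assert euclidean_distance((0.0, 0.0), (3.0, 4.0)) == 5.0

    def test_statepoint_inputs(self):
        assert euclidean_distance(StatePoint(1.0, 1.0), StatePoint(1.0, 1.0)) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=points, q=points, r=points)
    def test_metric_axioms(self, p, q, r):
        dpq = euclidean_distance(p, q)
        assert dpq >= 0
        assert euclidean_distance(p, p) == 0
        assert dpq == euclidean_distance(q, p)
        assert dpq <= euclidean_distance(p, r) + euclidean_distance(r, q) + 1e-9


class TestCosine:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            ((1.0, 0.0), (0.0, 1.0), 1.0),  # orthogonal
            ((2.0, 2.0), (5.0, 5.0), 0.0),  # collinear
            ((1.0, 1.0), (-1.0, -1.0), 2.0),  # antiparallel
        ],
    )
    def test_reference_angles(self, p, q, expected):
        assert cosine_distance(p, q) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance((0.0, 0.0), (1.0, 1.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(p=pos_points, q=pos_points,
           a=st.floats(min_value=0.01, max_value=50.0),
           b=st.floats(min_value=0.01, max_value=50.0))
    def test_positive_scale_invariance(self, p, q, a, b):
        base = cosine_distance(p, q)
        scaled = cosine_distance((a * p[0], a * p[1]), (b * q[0], b * q[1]))
        assert scaled == pytest.approx(base, abs=1e-9)
        assert 0.0 <= base <= 2.0


def _binned_rows(pid, task, coil, values):
    return pd.DataFrame(
        dict(
            participant_id=pid, task=task, coil=coil,
            bin_label=list(values), mean_normalized_mep=list(values.values()),
            n_trials=10, alignment="cue_locked",
        )
    )


class TestTrajectories:
    def test_unit_point_at_cue(self):
        pa = _binned_rows("P01", "GoOnly", "PA120", {"Cue": 1.0})
        ap = _binned_rows("P01", "GoOnly", "AP30", {"Cue": 1.0})
        traj = build_trajectory(pa, ap, "cue_locked", align_bins="intersect")
        assert traj.points.loc["Cue"].tolist() == [1.0, 1.0]

    def test_strict_mode_reports_missing_bins(self):
        pa = _binned_rows("P01", "GoOnly", "PA120", {"Cue": 1.0, "50": 1.1})
        ap = _binned_rows("P01", "GoOnly", "AP30", {"Cue": 1.0})
        with pytest.raises(ValueError, match="missing bins"):
            build_trajectory(pa, ap, "cue_locked", align_bins="strict")

    def test_group_of_identical_participants_equals_each(self):
        vals = {"Cue": 1.0, "50": 1.2, "100": 1.5}
        pa = pd.concat([_binned_rows(p, "GoOnly", "PA120", vals) for p in ("P01", "P02")])
        ap = pd.concat([_binned_rows(p, "GoOnly", "AP30", vals) for p in ("P01", "P02")])
        group = build_trajectory(pa, ap, "cue_locked", scope="group", align_bins="intersect")
        single = build_trajectory(
            pa[pa.participant_id == "P01"], ap[ap.participant_id == "P01"],
            "cue_locked", align_bins="intersect",
        )
        pd.testing.assert_frame_equal(group.points, single.points)

    def test_distance_series_identity_and_scaling(self):
        vals = {"Cue": 1.0, "50": 1.2, "100": 1.5}
        pa = _binned_rows("P01", "GoOnly", "PA120", vals)
        ap = _binned_rows("P01", "GoOnly", "AP30", vals)
        t1 = build_trajectory(pa, ap, "cue_locked", align_bins="intersect")
        d_same = distance_series(t1, t1)
        assert (d_same["euclidean_d"] == 0).all()
        np.testing.assert_allclose(d_same["cosine_d"], 0.0, atol=1e-12)
        t2 = Trajectory(t1.points * 2.0, "cue_locked", "SST")
        d_scaled = distance_series(t1, t2)
        assert (d_scaled["euclidean_d"] > 0).all()
        np.testing.assert_allclose(d_scaled["cosine_d"], 0.0, atol=1e-12)

    def test_three_bin_hand_oracle(self):
        """Distances match hand arithmetic on a 3-bin toy table:
        A (1,1) vs (2,2); B (1,2) vs (2,1); C (3,4) vs (4,3)."""
        pa_a = _binned_rows("P01", "SST", "PA120", {"Cue": 1.0, "50": 1.0, "100": 3.0})
        ap_a = _binned_rows("P01", "SST", "AP30", {"Cue": 1.0, "50": 2.0, "100": 4.0})
        pa_b = _binned_rows("P01", "GoOnly", "PA120", {"Cue": 2.0, "50": 2.0, "100": 4.0})
        ap_b = _binned_rows("P01", "GoOnly", "AP30", {"Cue": 2.0, "50": 1.0, "100": 3.0})
        ta = build_trajectory(pa_a, ap_a, "cue_locked", align_bins="intersect")
        tb = build_trajectory(pa_b, ap_b, "cue_locked", align_bins="intersect")
        d = distance_series(ta, tb).set_index("bin_label")
        np.testing.assert_allclose(d["euclidean_d"], [np.sqrt(2)] * 3)
        np.testing.assert_allclose(
            d["cosine_d"], [0.0, 1 - 4 / 5, 1 - 24 / 25], atol=1e-12
        )


class TestBootstrapNull:
    def _trial_bins(self, values_by_bin, pid="P01", task="GoOnly"):
        rows = []
        for b, vals in values_by_bin.items():
            for coil in ("PA120", "AP30"):
                for v in vals:
                    rows.append(dict(participant_id=pid, task=task, coil=coil,
                                     bin_label=b, norm_mep=v))
        return pd.DataFrame(rows)

    def test_constant_pool_gives_zero_distances(self):
        tb = self._trial_bins({"Cue": [1.3] * 8})
        for mode in ("split", "resample", "vs_original"):
            sim = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=20,
                                                   seed=1, mode=mode, summarize="full")
            np.testing.assert_allclose(sim["euclidean_d"], 0.0, atol=1e-12)
            np.testing.assert_allclose(sim["cosine_d"], 0.0, atol=1e-12)

    def test_same_seed_identical_replicates(self, rng):
        tb = self._trial_bins({"Cue": list(rng.lognormal(0, 0.4, 10)),
                               "50": list(rng.lognormal(0, 0.4, 10))})
        a = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=50, seed=9, summarize="full")
        b = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=50, seed=9, summarize="full")
        pd.testing.assert_frame_equal(a, b)

    def test_argument_validation(self):
        tb = self._trial_bins({"Cue": [1.0, 1.1, 1.2]})
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=0)
        with pytest.raises(ValueError, match="mode"):
            bootstrap_simulated_trajectories(tb, "cue_locked", mode="bogus")
        with pytest.raises(ValueError, match="SST trials"):
            bootstrap_simulated_trajectories(tb, "cue_locked", mode="permute")

    def test_summarize_modes_shapes(self, rng):
        tb = self._trial_bins({"Cue": list(rng.lognormal(0, 0.4, 10))})
        full = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=30, seed=2, summarize="full")
        single = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=30, seed=2, summarize="single")
        mean = bootstrap_simulated_trajectories(tb, "cue_locked", n_boot=30, seed=2, summarize="mean")
        assert len(full) == 30 and len(single) == 1 and len(mean) == 1


class TestComparisonAssembly:
    def test_row_counts_and_alignment(self, full_preprocessed):
        cue, norm = full_preprocessed["cue"], full_preprocessed["norm"]
        tb = assign_cue_bins(norm)
        real = real_distance_table(cue, "cue_locked")
        sim = bootstrap_simulated_trajectories(
            tb, "cue_locked", n_boot=1, seed=3, match_counts=task_bin_counts(tb)
        )
        comp = assemble_comparison_table(real, sim)
        cells = comp[["participant", "TIME"]].drop_duplicates()
        # one row per cell x arm x metric
        assert len(comp) == len(cells) * 2 * 2
        assert set(comp["ANALYSIS_TYPE"]) == {"real", "simulated"}
        assert set(comp["metric"]) == {"euclidean", "cosine"}

    def test_empty_simulated_is_error(self, full_preprocessed):
        real = real_distance_table(full_preprocessed["cue"], "cue_locked")
        with pytest.raises(ValueError, match="simulated"):
            assemble_comparison_table(real, real.iloc[0:0])

    def test_group_trajectories_available_for_plots(self, full_preprocessed):
        trajs = participant_trajectories(full_preprocessed["cue"], "cue_locked")
        tasks = {t for _, t in trajs}
        assert tasks == {"SST", "GoOnly"}


class TestPlantedWeightingSensitivity:
    def test_real_cosine_exceeds_null_under_planted_weighting(self):
        """Removing the SST's AP excitability rise shifts its trajectory
        direction: real cosine distances sit above the same-law bootstrap
        null on average (directional sensitivity of the comparison)."""
        from scipy import stats

        from stopstate.studies import planted_weighting_sensitivity

        ratios = planted_weighting_sensitivity(n_reps=6, seed=3, ap_gain_scale=0.0)
        t = stats.ttest_1samp(ratios, 0.0, alternative="greater")
        assert t.pvalue < 0.05
        assert (ratios > 0).sum() >= 4
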