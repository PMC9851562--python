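"""Reading, exclusion rules, alignment and the two normalizations."""

import numpy as np
import pandas as pd
import pytest

from stroop_trace.errors import AlignmentError, DataError, FormatError
from stroop_trace.io import read_trials, trials_to_frames, write_trials
from stroop_trace.preprocess import (
    AlignedTrajectory,
    filter_trials,
    remap_and_align,
    space_normalize,
    time_normalize,
)
from stroop_trace.simulate import simulate_dataset
from stroop_trace.trial import RawTrial, TrajectorySamples

from conftest import small_config


def make_trial(
    xy,
    times=None,
    status="correct",
    correct_box="green",
    rt=None,
    pid="P1",
    idx=0,
    condition="neutral",
):
    xy = np.asarray(xy, dtype=float)
    times = np.arange(len(xy)) * 10.0 if times is None else np.asarray(times, float)
    chosen = None if status == "timeout" else (correct_box if status == "correct" else "red")
    return RawTrial(
        participant_id=pid,
        trial_index=idx,
        condition=condition,
        word="pont",
        ink=correct_box,
        correct_box=correct_box,
        chosen_box=chosen,
        status=status,
        rt_ms=float(times[-1]) if rt is None and status != "timeout" else rt,
        it_ms=0.0,
        samples=TrajectorySamples(time_ms=times, x_px=xy[:, 0], y_px=xy[:, 1]),
    )


# ---------------------------------------------------------------- I/O


def test_read_trials_single_trial_fixture(tmp_path):
    meta = tmp_path / "meta.csv"
    samp = tmp_path / "samples.csv"
    trial = make_trial([(960, 935), (1000, 800), (1650, 135)])
    write_trials([trial], meta, samp)
    out = read_trials(meta, samp)
    assert len(out) == 1
    assert len(out[0].samples) == 3
    assert out[0].condition == "neutral"


def test_round_trip_is_exact(tmp_path):
    trials = simulate_dataset(small_config(seed=2, n_participants=2))
    write_trials(trials, tmp_path / "m.csv", tmp_path / "s.csv")
    back = read_trials(tmp_path / "m.csv", tmp_path / "s.csv")
    ma, sa = trials_to_frames(trials)
    mb, sb = trials_to_frames(back)
    pd.testing.assert_frame_equal(ma, mb)
    pd.testing.assert_frame_equal(sa, sb)


def test_orphan_sample_ids_rejected(tmp_path):
    trial = make_trial([(960, 935), (1650, 135)])
    write_trials([trial], tmp_path / "m.csv", tmp_path / "s.csv")
    s = pd.read_csv(tmp_path / "s.csv")
    s.loc[0, "trial_index"] = 99
    s.to_csv(tmp_path / "s.csv", index=False)
    with pytest.raises(DataError, match="99"):
        read_trials(tmp_path / "m.csv", tmp_path / "s.csv")


def test_missing_column_rejected(tmp_path):
    trial = make_trial([(960, 935), (1650, 135)])
    write_trials([trial], tmp_path / "m.csv", tmp_path / "s.csv")
    m = pd.read_csv(tmp_path / "m.csv").drop(columns=["status"])
    m.to_csv(tmp_path / "m.csv", index=False)
    with pytest.raises(FormatError, match="status"):
        read_trials(tmp_path / "m.csv", tmp_path / "s.csv")


def test_non_monotone_time_rejected(tmp_path):
    trial = make_trial([(960, 935), (1100, 700), (1650, 135)])
    write_trials([trial], tmp_path / "m.csv", tmp_path / "s.csv")
    s = pd.read_csv(tmp_path / "s.csv")
    s.loc[1, "time_ms"] = 50.0
    s.loc[2, "time_ms"] = 20.0
    s.to_csv(tmp_path / "s.csv", index=False)
    with pytest.raises(DataError, match="non-monotone"):
        read_trials(tmp_path / "m.csv", tmp_path / "s.csv")


# ---------------------------------------------------------------- filtering


def _rt_cell(rts, pid="P1", condition="neutral"):
    return [
        make_trial(
            [(960, 935), (1650, 135)], times=[0.0, rt], pid=pid, idx=i, condition=condition
        )
        for i, rt in enumerate(rts)
    ]


def test_rt_outlier_removed_in_study_sized_cell():
    """In a 32-trial cell, an RT 5 SDs above the rest is excluded."""
    rng = np.random.default_rng(0)
    rts = list(1000 + 50 * rng.standard_normal(31))
    outlier = float(np.mean(rts) + 5 * np.std(rts, ddof=1))
    trials = _rt_cell(rts + [outlier])
    kept, report = filter_trials(trials)
    assert report.n_rt_outlier == 1
    assert all(t.rt_ms != pytest.approx(outlier) for t in kept)
    # brute-force oracle: same rule computed independently
    all_rts = np.array(rts + [outlier])
    z = np.abs(all_rts - all_rts.mean()) / all_rts.std(ddof=1)
    assert (z > 3).sum() == 1


def test_all_timeouts_yield_empty_kept_set():
    trials = [
        make_trial([(960, 935), (961, 934)], status="timeout", rt=None, idx=i)
        for i in range(5)
    ]
    kept, report = filter_trials(trials)
    assert kept == []
    assert report.n_omission == 5
    assert report.percentages()["omission"] == 100.0


def test_identical_rts_degenerate_sd_removes_nothing():
    kept, report = filter_trials(_rt_cell([800.0] * 10))
    assert len(kept) == 10
    assert report.n_rt_outlier == 0


def test_small_cell_skipped_and_logged():
    kept, report = filter_trials(_rt_cell([800.0]))
    assert len(kept) == 1
    assert ("P1", "neutral") in report.skipped_cells


def test_errors_removed_before_outlier_stats():
    """A wild RT on an error trial cannot shift the cell's outlier threshold."""
    good = _rt_cell(list(np.linspace(900, 1100, 12)))
    bad = make_trial([(960, 935), (1650, 135)], times=[0, 30000.0], status="error", idx=50)
    kept, report = filter_trials(good + [bad])
    assert report.n_error == 1
    assert report.n_rt_outlier == 0
    assert len(kept) == 12


def test_filtering_is_idempotent_on_simulated_data():
    trials = simulate_dataset(small_config(seed=11))
    kept, _ = filter_trials(trials)
    kept2, report2 = filter_trials(kept)
    assert len(kept2) == len(kept)
    assert report2.n_rt_outlier == 0


# ---------------------------------------------------------------- alignment


def test_alignment_anchors_endpoints_exactly(layout, kept_small):
    for t in kept_small[:200]:
        a = remap_and_align(t, layout)
        assert (a.x[0], a.y[0]) == (0.0, 0.0)
        assert a.x[-1] == pytest.approx(1.0, abs=1e-12)
        assert a.y[-1] == pytest.approx(1.5, abs=1e-12)


def test_affine_image_of_known_point(layout):
    """Hand-computed affine image of an intermediate sample."""
    t = make_trial([(960, 935), (1100, 700), (1650, 135)], correct_box="green")
    a = remap_and_align(t, layout)
    assert not a.remap_applied
    assert a.x[1] == pytest.approx((1100 - 960) / (1650 - 960))
    assert a.y[1] == pytest.approx((700 - 935) * 1.5 / (135 - 935))
    assert a.y[1] > 0  # pixel y decreases upward; alignment flips it


def test_mirror_symmetry_of_left_and_right_trials(layout):
    """A leftward path and its exact mirror align identically."""
    right = [(960, 935), (1050, 800), (1200, 400), (1650, 135)]
    left = [(2 * 960 - x, y) for x, y in right]
    a_right = remap_and_align(make_trial(right, correct_box="green"), layout)
    a_left = remap_and_align(make_trial(left, correct_box="red"), layout)
    assert a_left.remap_applied and not a_right.remap_applied
    np.testing.assert_allclose(a_left.x, a_right.x, atol=1e-12)
    np.testing.assert_allclose(a_left.y, a_right.y, atol=1e-12)


def test_degenerate_path_raises(layout):
    t = make_trial([(960, 935), (960, 935)], correct_box="green")
    with pytest.raises(AlignmentError):
        remap_and_align(t, layout)


def test_only_correct_trials_aligned(layout):
    t = make_trial([(960, 935), (270, 135)], status="error", correct_box="green")
    with pytest.raises(DataError):
        remap_and_align(t, layout)


# ---------------------------------------------------------------- normalization


def _straight_aligned(n=5):
    s = np.linspace(0.0, 1.0, n)
    return AlignedTrajectory(x=s, y=1.5 * s, time_ms=1000.0 * s, remap_applied=False)


def test_time_normalize_identity_when_already_uniform():
    traj = _straight_aligned(101)
    tn = time_normalize(traj)
    np.testing.assert_allclose(tn.x, traj.x, atol=1e-12)
    np.testing.assert_allclose(tn.y, traj.y, atol=1e-12)
    assert tn.total_duration_ms == pytest.approx(1000.0)


def test_time_normalize_two_sample_straight_path():
    tn = time_normalize(_straight_aligned(2))
    assert len(tn) == 101
    np.testing.assert_allclose(tn.y, 1.5 * tn.x, atol=1e-12)
    np.testing.assert_allclose(np.diff(tn.x), np.full(100, 0.01), atol=1e-12)


def test_time_normalize_kinked_path_matches_hand_interpolation():
    traj = AlignedTrajectory(
        x=np.array([0.0, 0.2, 1.0]),
        y=np.array([0.0, 1.0, 1.5]),
        time_ms=np.array([0.0, 400.0, 1000.0]),
        remap_applied=False,
    )
    tn = time_normalize(traj)
    # steps 26, 51, 76 sit at 250, 500, 750 ms
    assert tn.x[25] == pytest.approx(0.2 * 250 / 400)
    assert tn.y[25] == pytest.approx(1.0 * 250 / 400)
    assert tn.x[50] == pytest.approx(0.2 + 0.8 * 100 / 600)
    assert tn.y[75] == pytest.approx(1.0 + 0.5 * 350 / 600)


def test_time_normalize_step_to_percent_mapping():
    """Step 11 sits at ~10% of the total response duration."""
    traj = _straight_aligned(11)
    tn = time_normalize(traj)
    step11_time = 1000.0 * (11 - 1) / 100
    assert tn.x[10] == pytest.approx(np.interp(step11_time, traj.time_ms, traj.x))
    assert step11_time / tn.total_duration_ms == pytest.approx(0.10)


def test_time_normalize_zero_duration_raises():
    traj = AlignedTrajectory(
        x=np.array([0.0, 1.0]), y=np.array([0.0, 1.5]),
        time_ms=np.array([0.0, 0.0]), remap_applied=False,
    )
    with pytest.raises(DataError):
        time_normalize(traj)


def test_space_normalize_straight_segment_equal_spacing():
    sn = space_normalize(_straight_aligned(2))
    assert len(sn) == 100
    gaps = np.hypot(np.diff(sn.x), np.diff(sn.y))
    np.testing.assert_allclose(gaps, gaps[0], rtol=1e-6)
    assert (sn.x[0], sn.y[0]) == (0.0, 0.0)
    assert (sn.x[-1], sn.y[-1]) == (1.0, 1.5)


def test_space_normalize_l_shaped_path_arc_positions():
    traj = AlignedTrajectory(
        x=np.array([0.0, 3.0, 3.0]),
        y=np.array([0.0, 0.0, 4.0]),
        time_ms=np.array([0.0, 1.0, 2.0]),
        remap_applied=False,
    )
    sn = space_normalize(traj)
    # oracle: point k sits at arc position k*7/99 along the original polyline
    expected_arcs = np.arange(100) * 7.0 / 99.0
    exp_x = np.where(expected_arcs <= 3.0, expected_arcs, 3.0)
    exp_y = np.where(expected_arcs <= 3.0, 0.0, expected_arcs - 3.0)
    np.testing.assert_allclose(sn.x, exp_x, atol=1e-9)
    np.testing.assert_allclose(sn.y, exp_y, atol=1e-9)


def test_space_normalize_ignores_dwell_samples():
    base = AlignedTrajectory(
        x=np.array([0.0, 0.5, 1.0]), y=np.array([0.0, 1.2, 1.5]),
        time_ms=np.array([0.0, 1.0, 2.0]), remap_applied=False,
    )
    dup = AlignedTrajectory(
        x=np.array([0.0, 0.0, 0.5, 0.5, 0.5, 1.0]),
        y=np.array([0.0, 0.0, 1.2, 1.2, 1.2, 1.5]),
        time_ms=np.arange(6.0), remap_applied=False,
    )
    a, b = space_normalize(base), space_normalize(dup)
    np.testing.assert_allclose(a.x, b.x, atol=1e-12)
    np.testing.assert_allclose(a.y, b.y, atol=1e-12)


def test_space_normalize_zero_arc_raises():
    traj = AlignedTrajectory(
        x=np.zeros(3), y=np.zeros(3), time_ms=np.arange(3.0), remap_applied=False
    )
    with pytest.raises(DataError):
        space_normalize(traj)


def test_normalizations_commute_with_mirroring(layout):
    """Mirroring raw x then normalizing equals normalizing then mirroring."""
    right = [(960, 935), (1020, 850), (1250, 500), (1100, 300), (1650, 135)]
    left = [(2 * 960 - x, y) for x, y in right]
    tr = make_trial(right, correct_box="green")
    tl = make_trial(left, correct_box="red")
    for norm in (time_normalize, space_normalize):
        nr = norm(remap_and_align(tr, layout))
        nl = norm(remap_and_align(tl, layout))
        np.testing.assert_allclose(nr.x, nl.x, atol=1e-12)
        np.testing.assert_allclose(nr.y, nl.y, atol=1e-12)
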