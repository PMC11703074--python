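"""Windowing, circularity time courses, cluster inference, behavior splits."""

import numpy as np
import pandas as pd
import pytest

from geomstate import (
    DesignSpec,
    PlantedGeometry,
    generate_behavior,
    generate_design,
    generate_epochs,
    goal_labels,
    goal_square_coords,
)
from geomstate.errors import (
    InvalidParameterError,
    MissingConditionError,
    SplitCoverageError,
)
from geomstate.timecourse import (
    behavior_correlation,
    chi2_independence,
    cluster_test,
    combined_error,
    incorrect_goal_relabel,
    motor_relabel,
    permutation_null,
    timecourse_circularity,
    trial_split_difference,
    window_partition,
)


@pytest.mark.parametrize(
    "start, end, window, expected",
    [(-500, 4300, 80, 60), (0, 400, 80, 5), (0, 79, 80, 0)],
)
def test_window_partition_counts(start, end, window, expected):
    w = window_partition(start, end, window)
    assert len(w) == expected
    if expected:
        assert w[0, 0] == start and np.allclose(w[:, 1] - w[:, 0], window)


def test_window_partition_rejects_bad_window():
    with pytest.raises(InvalidParameterError):
        window_partition(0, 100, -5)


def test_noisefree_square_recovers_pi_over_4(noisefree_epochs, small_labels):
    tc = timecourse_circularity(noisefree_epochs, small_labels, "goal_square",
                                n_resamples=1, seed=0)
    assert tc.n_windows == 60
    w = tc.window_centers
    overlap = (w + 40 > 400) & (w - 40 < 1700)  # windows touching Delay 1
    assert np.allclose(tc.values[overlap], np.pi / 4, atol=1e-9)
    assert np.allclose(tc.values[~overlap], 0.0, atol=1e-12)  # degenerate floor


def test_resampling_is_noop_on_noisefree_data(noisefree_epochs, small_labels):
    a = timecourse_circularity(noisefree_epochs, small_labels, n_resamples=1, seed=0)
    b = timecourse_circularity(noisefree_epochs, small_labels, n_resamples=10, seed=1)
    assert np.allclose(a.values, b.values, atol=1e-12)


def test_timecourse_missing_condition(noisefree_epochs, small_labels):
    labs = [("bigger", "redder")] * len(small_labels)
    with pytest.raises(MissingConditionError):
        timecourse_circularity(noisefree_epochs, labs)


def test_resample_mean_stabilizes_noisy_estimates(small_design, goal_geometry,
                                                  small_labels):
    """Across-seed variance of the curve shrinks when averaging 10 stratified
    resamples instead of 1."""
    ep = generate_epochs(small_design, goal_geometry, n_channels=16,
                         noise_sd=2.0, seed=33, t_start=-500, t_end=1700)
    var = {}
    for n_res in (1, 10):
        curves = [timecourse_circularity(ep, small_labels, n_resamples=n_res,
                                         seed=s).values for s in range(12)]
        var[n_res] = np.var(np.stack(curves), axis=0).mean()
    assert var[10] < var[1]


def test_permutation_null_determinism_and_shape(noisefree_epochs, small_labels):
    with pytest.warns(UserWarning):
        a = permutation_null(noisefree_epochs, small_labels, n_perm=2,
                             n_resamples=1, seed=4)
    with pytest.warns(UserWarning):
        b = permutation_null(noisefree_epochs, small_labels, n_perm=2,
                             n_resamples=1, seed=4)
    assert a.shape == (2, 60)
    assert np.array_equal(a, b)


def test_cluster_test_empty_when_flat():
    rng = np.random.default_rng(0)
    null = rng.standard_normal((500, 30))
    true = np.zeros(30) - 10.0
    cs = cluster_test(true, null)
    assert cs.clusters == []


def test_cluster_test_finds_planted_run():
    rng = np.random.default_rng(1)
    null = rng.standard_normal((500, 30))
    true = np.zeros(30)
    true[10:18] = 10.0
    cs = cluster_test(true, null)
    sig = cs.significant_clusters
    assert len(sig) == 1 and (sig[0].start, sig[0].end) == (10, 17)
    assert sig[0].p_value <= 0.05


def test_cluster_test_pooled_threshold_variant():
    rng = np.random.default_rng(2)
    null = rng.standard_normal((300, 20))
    true = np.full(20, 5.0)
    cs = cluster_test(true, null, pointwise="pooled")
    assert len(cs.significant_clusters) == 1
    assert np.allclose(cs.pointwise_threshold, cs.pointwise_threshold[0])


def test_planted_delay1_cluster_recovered(small_design, goal_geometry, small_labels):
    ep = generate_epochs(small_design, goal_geometry, n_channels=16,
                         noise_sd=1.0, seed=55)
    tc = timecourse_circularity(ep, small_labels, n_resamples=5, seed=0)
    null = permutation_null(ep, small_labels, n_perm=200, n_resamples=5, seed=1)
    cs = cluster_test(tc, null)
    sig = cs.significant_clusters
    assert len(sig) >= 1
    w = tc.window_centers
    for c in sig:  # every significant cluster overlaps the active Delay-1 span
        assert w[c.end] > 400 and w[c.start] < 1700


# ---------------------------------------------------------------------------
# combined error and splits
# ---------------------------------------------------------------------------

def test_combined_error_matches_hand_computation():
    t = pd.DataFrame({"size_error": [0.1, -0.2, 0.3, 0.0],
                      "color_error": [-2.0, 1.0, 0.0, 3.0]})
    s = np.abs(t["size_error"].to_numpy())
    c = np.abs(t["color_error"].to_numpy())
    expected = (s - s.mean()) / s.std() + (c - c.mean()) / c.std()
    assert np.allclose(combined_error(t), expected)


def test_combined_error_sign_irrelevant():
    t1 = pd.DataFrame({"size_error": [0.1, 0.2, 0.3], "color_error": [1.0, 2.0, 0.5]})
    t2 = t1 * -1
    assert np.allclose(combined_error(t1), combined_error(t2))


def test_combined_error_zero_variance_guard():
    t = pd.DataFrame({"size_error": [0.5, 0.5, 0.5],
                      "color_error": [1.0, 2.0, 4.0]})
    with pytest.warns(UserWarning):
        got = combined_error(t)
    c = np.abs(t["color_error"].to_numpy())
    assert np.allclose(got, (c - c.mean()) / c.std())


def _coupled_session(coupling, seed, reps=6, noise_sd=1.0):
    # strength spans down to 0 so the weak-gain trials sit at the noise
    # floor and the good/bad split has headroom to differ
    trials = generate_design(DesignSpec(reps_per_cell=reps), seed=seed)
    rng = np.random.default_rng(seed + 1)
    strength = rng.uniform(0.0, 1.5, len(trials))
    trials = generate_behavior(trials, strength, coupling=coupling, noise_sd=1.0,
                               seed=seed + 2)
    geom = PlantedGeometry(coords=goal_square_coords(2.0),
                           activation={"delay1": 1.0}, label="goal")
    ep = generate_epochs(trials, geom, n_channels=16, noise_sd=noise_sd,
                         seed=seed + 3, trial_gain=strength,
                         t_start=-500, t_end=1700)
    return trials, ep


def test_trial_split_recovers_positive_difference():
    """Strong behavior-geometry coupling: good trials carry more planted
    gain, so the good-minus-bad circularity difference is positive and
    significant inside the active window."""
    trials, ep = _coupled_session(coupling=3.0, seed=70, reps=9, noise_sd=1.0)
    err = combined_error(trials)
    res = trial_split_difference(ep, goal_labels(trials), err, n_perm=200,
                                 n_resamples=3, seed=0)
    w = res.window_centers
    active = (w > 400) & (w < 1700)
    assert res.diff_timecourse[active].mean() > 0
    sig = res.significant_windows
    assert sig and all(w[i] > 400 - 80 for i in sig)


def test_trial_split_symmetry():
    """Negating the error ranking swaps good and bad and exactly negates the
    difference curve (group-keyed resampling)."""
    trials, ep = _coupled_session(coupling=1.0, seed=80)
    err = combined_error(trials)
    a = trial_split_difference(ep, goal_labels(trials), err, n_perm=2,
                               n_resamples=3, seed=5)
    b = trial_split_difference(ep, goal_labels(trials), -err, n_perm=2,
                               n_resamples=3, seed=5)
    assert np.allclose(a.diff_timecourse, -b.diff_timecourse, atol=1e-12)


def test_trial_split_coverage_error():
    trials = generate_design(DesignSpec(reps_per_cell=1), seed=9)  # 36 trials
    # all 9 lowest-error trials share one goal, so the good quartile cannot
    # cover the remaining three polygon vertices
    br = ((trials["goal_size"] == "bigger") & (trials["goal_color"] == "redder")).to_numpy()
    trials["size_error"] = np.where(br, 0.1, 1.0) + np.arange(36) * 1e-3
    trials["color_error"] = np.where(br, 0.1, 1.0) + np.arange(36) * 1e-3
    geom = PlantedGeometry(coords=goal_square_coords(2.0), label="goal")
    ep = generate_epochs(trials, geom, n_channels=8, noise_sd=1.0, seed=1,
                         t_start=0, t_end=400)
    err = combined_error(trials)
    with pytest.raises(SplitCoverageError, match="median"):
        trial_split_difference(ep, goal_labels(trials), err, rule="quartile",
                               n_perm=2, n_resamples=1, seed=0)


def test_behavior_correlation_monotone_and_fdr():
    circ = pd.DataFrame({
        "delay1_frontal": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
        "flat": [1.0] * 6,
    })
    err = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
    out = behavior_correlation(circ, err)
    row = out.set_index("cell").loc["delay1_frontal"]
    assert row["r"] == pytest.approx(-1.0)
    assert row["p_fdr"] == pytest.approx(row["p"])  # single-test family
    assert bool(out.set_index("cell").loc["flat", "excluded"])


def test_bh_adjustment_matches_hand_stepup():
    """BH on (0.01, 0.02, 0.04, 0.8) at q=0.05: the largest i with
    p_(i) <= i*q/4 is i=2, so exactly the two smallest are rejected."""
    from statsmodels.stats.multitest import multipletests

    rej, adj, _, _ = multipletests([0.01, 0.02, 0.04, 0.8], alpha=0.05,
                                   method="fdr_bh")
    assert list(rej) == [True, True, False, False]
    assert np.allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8])


# ---------------------------------------------------------------------------
# relabeling controls
# ---------------------------------------------------------------------------

def test_motor_relabel_sign_rule():
    t = pd.DataFrame({
        "initial_size": [10.0, 10.0, 50.0],
        "final_size": [14.0, 10.0, 40.0],
        "initial_color": [50.0, 20.0, 20.0],
        "final_color": [44.0, 30.0, 35.0],
    })
    labels, keep = motor_relabel(t)
    assert list(keep) == [True, False, True]  # zero size delta excluded
    assert labels == [("bigger", "redder"), ("smaller", "greener")]


def test_motor_relabel_no_clusters_on_pure_noise():
    trials = generate_design(DesignSpec(reps_per_cell=3), seed=14)
    geom = PlantedGeometry(coords=goal_square_coords(2.0), activation={},
                           label="goal")  # activation empty: no signal at all
    ep = generate_epochs(trials, geom, n_channels=8, noise_sd=1.0, seed=15,
                         t_start=0, t_end=1600)
    labels, keep = motor_relabel(trials)
    ep = ep.select_trials(np.flatnonzero(keep))
    tc = timecourse_circularity(ep, labels, "motor_square", n_resamples=3, seed=0)
    null = permutation_null(ep, labels, "motor_square", n_perm=200,
                            n_resamples=3, seed=1)
    assert cluster_test(tc, null).significant_clusters == []


def test_chi2_helper_matches_textbook_formula():
    a = ["x"] * 30 + ["y"] * 30
    b = (["p"] * 20 + ["q"] * 10) + (["p"] * 10 + ["q"] * 20)
    chi2, p, dof, table = chi2_independence(a, b)
    obs = table.to_numpy().astype(float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum())
    assert dof == 1


def test_incorrect_goal_relabel_rules():
    base = dict(size_bin=1, color_bin=1)
    t = pd.DataFrame([
        dict(goal_size="bigger", goal_color="redder",
             response_dir_size="bigger", response_dir_color="redder", **base),
        dict(goal_size="bigger", goal_color="redder",
             response_dir_size="smaller", response_dir_color="redder", **base),
        dict(goal_size="smaller", goal_color="greener",
             response_dir_size="smaller", response_dir_color="greener", **base),
        dict(goal_size="smaller", goal_color="greener",
             response_dir_size="smaller", response_dir_color="redder", **base),
        dict(goal_size="bigger", goal_color="greener",
             response_dir_size="bigger", response_dir_color="greener", **base),
        dict(goal_size="smaller", goal_color="redder",
             response_dir_size="smaller", response_dir_color="redder", **base),
    ])
    out = incorrect_goal_relabel(t)
    assert list(out.index) == [1, 3]
    assert out.loc[1, "goal_size"] == "smaller"
    assert out.loc[3, "goal_color"] == "redder"

    all_correct = t.iloc[[0, 2, 4, 5]]
    with pytest.warns(UserWarning):
        empty = incorrect_goal_relabel(all_correct)
    assert empty.empty


def test_incorrect_goal_pipeline_smoke():
    """Relabeled incorrect trials run end-to-end through the circularity
    pipeline (coverage permitting)."""
    trials = generate_design(DesignSpec(reps_per_cell=6), seed=16)
    trials = generate_behavior(trials, np.ones(len(trials)), 0.0, 1.0, seed=17,
                               lapse_rate=0.4)
    sub = incorrect_goal_relabel(trials)
    geom = PlantedGeometry(coords=goal_square_coords(2.0),
                           activation={"delay1": 1.0}, label="goal")
    ep = generate_epochs(trials, geom, n_channels=8, noise_sd=1.0, seed=18,
                         t_start=0, t_end=800)
    ep_sub = ep.select_trials(sub.index.to_numpy())
    tc = timecourse_circularity(ep_sub, goal_labels(sub), n_resamples=2, seed=0)
    assert tc.n_windows == 10 and np.isfinite(tc.values).all()
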