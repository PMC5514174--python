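"""Synthetic observers: subjects, trials, design contracts, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from photoforge import observer as obs
from photoforge.gridchance import score_trials


def make_trials(stimset, tables, params, design="exp1", n_subjects=200, seed=0):
    table, sets = tables
    profiles = obs.simulate_subjects(n_subjects, rng=np.random.default_rng(seed))
    trials = obs.simulate_trials(
        stimset, profiles, params, design=design,
        rng=np.random.default_rng(seed + 1), stim_table=table, region_sets=sets,
    )
    return score_trials(trials, sets, stimset.grid)


# ---------------------------------------------------------------- subjects


def test_subject_sample_size_and_mix():
    profiles = obs.simulate_subjects(707, rng=np.random.default_rng(0))
    assert len(profiles) == 707
    for cov, levels in obs.COVARIATE_LEVELS.items():
        p_ref = obs.DEFAULT_MIX[cov][levels[0]]
        count = sum(getattr(s, cov) == levels[0] for s in profiles)
        sigma = np.sqrt(707 * p_ref * (1 - p_ref))
        assert abs(count - 707 * p_ref) < 3 * sigma


def test_degenerate_mix_and_determinism():
    mix = {"gender": {"male": 1.0, "female": 0.0}}
    a = obs.simulate_subjects(50, mix=mix, rng=np.random.default_rng(3))
    b = obs.simulate_subjects(50, mix=mix, rng=np.random.default_rng(3))
    assert all(s.gender == "male" for s in a)
    assert a == b


def test_invalid_mix_rejected():
    with pytest.raises(ValueError):
        obs.simulate_subjects(5, mix={"gender": {"male": 0.7, "female": 0.4}})
    with pytest.raises(ValueError):
        obs.simulate_subjects(5, mix={"mood": {"good": 1.0}})


# ---------------------------------------------------------------- collapse


def test_collapse_detection_is_total_and_correct():
    assert obs.collapse_detection("yes_can_locate") is True
    assert obs.collapse_detection("yes_cannot_locate") is True
    assert obs.collapse_detection("no") is False
    with pytest.raises(ValueError):
        obs.collapse_detection("maybe")


# ---------------------------------------------------------------- trials


def test_design_contracts(exp1_set10, exp1_tables):
    params = obs.ObserverParams()
    exp1 = make_trials(exp1_set10, exp1_tables, params, "exp1", n_subjects=40)
    has_loc = exp1["locate_region"].notna()
    assert (has_loc == exp1["detect_yes"]).all()

    import photoforge.scenegen as sg

    exp2_set = sg.build_stimulus_set(10, "exp2", rng=np.random.default_rng(9))
    tables2 = obs.prepare_stimulus_table(exp2_set)
    exp2 = make_trials(exp2_set, tables2, params, "exp2", n_subjects=40)
    assert exp2["locate_region"].notna().all()
    assert (exp2["rt_detect"] > 0).all() and (exp2["rt_locate"] > 0).all()

    with pytest.raises(ValueError):
        obs.simulate_trials(exp1_set10, [], params, design="exp3")


def test_trial_balance_and_type_coverage(exp1_set10, exp1_tables):
    trials = make_trials(exp1_set10, exp1_tables, obs.ObserverParams(), n_subjects=30)
    per_subject = trials.groupby("subject_id")
    assert (per_subject.size() == 10).all()
    assert (per_subject["is_manipulated"].sum() == 5).all()
    # each subject sees every scene at most once and all five types
    assert (per_subject["image_id"].nunique() == 10).all()
    types = trials[trials["is_manipulated"]].groupby("subject_id")["truth"].nunique()
    assert (types == 5).all()


def test_same_seed_reproduces_trials(exp1_set10, exp1_tables):
    a = make_trials(exp1_set10, exp1_tables, obs.ObserverParams(), n_subjects=15, seed=4)
    b = make_trials(exp1_set10, exp1_tables, obs.ObserverParams(), n_subjects=15, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_flat_observer_detects_all_types_equally(exp1_set10, exp1_tables):
    """With zero signal sensitivity the detection rate cannot depend on type."""
    params = obs.ObserverParams(
        gamma0=0.0, gamma1=0.0, covariate_effects={}, attentiveness_weight=0.0
    )
    trials = make_trials(exp1_set10, exp1_tables, params, n_subjects=400)
    manip = trials[trials["is_manipulated"]]
    pooled = manip["detect_yes"].mean()
    for _, sub in manip.groupby("truth"):
        se = np.sqrt(pooled * (1 - pooled) / len(sub))
        assert abs(sub["detect_yes"].mean() - pooled) < 3 * se
    # and overall accuracy on the balanced set sits at the 50% chance level
    acc = trials["detect_correct"].mean()
    assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / len(trials))


def test_full_lapse_localizes_at_weight_driven_chance(exp1_set10, exp1_tables):
    """lapse=1 observers place responses from the popularity weights only."""
    table, sets = exp1_tables
    grid = exp1_set10.grid
    weights = obs.default_region_weights(grid)
    params = obs.ObserverParams(lapse=1.0, gamma0=5.0)  # always "yes" -> always locate
    trials = make_trials(exp1_set10, exp1_tables, params, n_subjects=400)
    manip = trials[trials["is_manipulated"]]
    expected = np.mean(
        [sum(weights[r] for r in sets[(row.scene_id, row.mtype)].acceptable)
         for row in table.itertuples()]
    )
    acc = manip["locate_correct"].mean()
    se = np.sqrt(expected * (1 - expected) / len(manip))
    assert abs(acc - expected) < 3.5 * se


def test_parameter_recovery(exp1_set10, exp1_tables):
    """A maximum-likelihood refit of the generative logistic recovers the
    signal slope (+-0.15) and a covariate effect (+-0.1) at 600 subjects."""
    true_g1, true_belief = 1.2, 0.405
    params = obs.ObserverParams(
        gamma1=true_g1, covariate_effects={"belief_high": true_belief}
    )
    trials = make_trials(exp1_set10, exp1_tables, params, n_subjects=600, seed=17)
    x = np.where(
        trials["is_manipulated"],
        trials["log_delta_e"].fillna(0.0) - params.log_de_center,
        0.0,
    )
    X = pd.DataFrame(
        {
            "const": 1.0,
            "signal": x,
            "belief_high": (trials["belief"] == "high").astype(float),
        }
    )
    fit = sm.Logit(trials["detect_yes"].astype(float), X).fit(disp=False)
    assert fit.params["signal"] == pytest.approx(true_g1, abs=0.15)
    assert fit.params["belief_high"] == pytest.approx(true_belief, abs=0.1)
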