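"""RT octiles and the repeated-measures GEE layer."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from photoforge import models, observer
from photoforge.gridchance import score_trials


def test_octiles_equal_groups_and_direction():
    rts = np.arange(16, dtype=float)
    lv = models.rt_octiles(rts)
    counts = np.bincount(lv.levels, minlength=9)[1:]
    assert (counts == 2).all()
    assert lv.levels[np.argmax(rts)] == 1  # slowest -> level 1
    assert lv.levels[np.argmin(rts)] == 8  # fastest -> level 8
    assert len(lv.boundaries) == 7


def test_octiles_match_sort_and_slice_oracle():
    rng = np.random.default_rng(0)
    rts = rng.exponential(10.0, size=103)
    lv = models.rt_octiles(rts)
    order = np.argsort(-rts, kind="stable")
    expect = np.empty(len(rts), dtype=int)
    for level, chunk in enumerate(np.array_split(order, 8), start=1):
        expect[chunk] = level
    assert np.array_equal(lv.levels, expect)
    sizes = np.bincount(lv.levels)[1:]
    assert sizes.max() - sizes.min() <= 1


def test_octiles_need_eight_observations():
    with pytest.raises(ValueError):
        models.rt_octiles([1.0] * 7)


def simulate(n_subjects, seed, effects=None, design="exp1", stimset=None, tables=None):
    params = observer.ObserverParams(covariate_effects=effects or {})
    table, sets = tables
    profiles = observer.simulate_subjects(n_subjects, rng=np.random.default_rng(seed))
    trials = observer.simulate_trials(
        stimset, profiles, params, design=design,
        rng=np.random.default_rng(seed + 1), stim_table=table, region_sets=sets,
    )
    return score_trials(trials, sets, stimset.grid)


def test_independence_on_singleton_clusters_matches_plain_logistic():
    rng = np.random.default_rng(1)
    n = 400
    df = pd.DataFrame(
        {
            "subject_id": np.arange(n),  # one observation per cluster
            "x": rng.normal(size=n),
        }
    )
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * df["x"])))).astype(float)
    gee = models.RepeatedMeasuresGEE(
        df, "y", ("x",), family="binomial", working_correlation="independence"
    ).fit()
    logit = sm.Logit(df["y"], sm.add_constant(df[["x"]])).fit(disp=False)
    assert gee.coefficients.loc["x", "B"] == pytest.approx(logit.params["x"], abs=1e-6)
    assert gee.coefficients.loc["const", "B"] == pytest.approx(logit.params["const"], abs=1e-6)


def test_or_equals_exp_b_and_summary(exp1_set10, exp1_tables):
    trials = simulate(120, 3, stimset=exp1_set10, tables=exp1_tables)
    res = models.fit_repeated_binary(trials, "detect_accuracy")
    assert np.allclose(res.coefficients["OR"], np.exp(res.coefficients["B"]), atol=1e-9)
    text = res.summary()
    assert "exchangeable" in text and "detect_correct" in text


def test_reference_level_flip_negates_coefficient(exp1_set10, exp1_tables):
    trials = simulate(120, 5, stimset=exp1_set10, tables=exp1_tables)
    a = models.fit_repeated_binary(trials, "detect_accuracy", predictors=("belief",))
    b = models.fit_repeated_binary(
        trials, "detect_accuracy", predictors=("belief",),
        reference_overrides={"belief": "high"},
    )
    assert a.coefficients.loc["belief_high", "B"] == pytest.approx(
        -b.coefficients.loc["belief_low", "B"], abs=1e-6
    )


def test_intercept_only_linear_returns_mean():
    df = pd.DataFrame(
        {"subject_id": np.arange(40), "d_prime": np.random.default_rng(2).normal(0.8, 0.3, 40)}
    )
    for col, val in zip(
        ("belief", "gender", "interest", "frequency"),
        ("low", "male", "interested", "daily_weekly"),
    ):
        df[col] = val
    res = models.fit_repeated_linear(df, "d_prime", predictors=())
    assert res.coefficients.loc["const", "B"] == pytest.approx(df["d_prime"].mean(), abs=1e-9)


def test_working_correlations_agree_on_exchangeable_data(exp1_set10, exp1_tables):
    trials = simulate(600, 9, stimset=exp1_set10, tables=exp1_tables)
    ex = models.fit_repeated_binary(trials, "detect_accuracy", working_correlation="exchangeable")
    ind = models.fit_repeated_binary(trials, "detect_accuracy", working_correlation="independence")
    joint_se = np.sqrt(ex.coefficients["se"] ** 2 + ind.coefficients["se"] ** 2)
    assert (np.abs(ex.coefficients["B"] - ind.coefficients["B"]) < 2 * joint_se).all()


def test_locate_model_replicates_missing_rt_exclusion(exp1_set10, exp1_tables):
    """In the detect-first design only 'yes' trials carry a location; the
    location model must run on exactly those trials."""
    trials = simulate(150, 11, stimset=exp1_set10, tables=exp1_tables)
    res = models.fit_repeated_binary(
        trials, "locate_accuracy", predictors=("belief", "gender", "interest", "frequency")
    )
    manip = trials[trials["is_manipulated"]]
    assert res.n_obs == int(manip["locate_correct"].notna().sum())
    assert res.n_obs < len(manip)


def test_null_covariates_covered_smoke(exp1_set10, exp1_tables):
    """Light null check: with no true effects, factor CIs usually cover 0."""
    hits = {p: 0 for p in ("belief_high", "gender_female")}
    runs = 8
    for k in range(runs):
        trials = simulate(250, 100 + 3 * k, stimset=exp1_set10, tables=exp1_tables)
        res = models.fit_repeated_binary(trials, "detect_accuracy")
        for p in hits:
            lo, hi = res.coefficients.loc[p, ["ci_lo", "ci_hi"]]
            hits[p] += int(lo <= 0.0 <= hi)
    for p, n_cover in hits.items():
        assert n_cover >= runs - 2, f"{p} covered 0 in only {n_cover}/{runs} runs"
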