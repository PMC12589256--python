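"""Likelihoods, multi-start MLE, shared fits, and model-comparison bookkeeping."""

import math

import numpy as np
import pytest

from tempgen import (
    BSUParams,
    CGParams,
    DDMParams,
    TrialData,
    aic,
    compare_aic,
    fit_mle,
    fit_shared,
    initial_starts,
    likelihood_ratio_log10,
    log_likelihood,
    make_design,
    p_same,
    simulate_trials,
    summed_likelihood_ratio_log10,
    winner_table,
)
from tempgen.fitting import FitResult

S = 0.4


def _naive_log_likelihood(model_id, params, trials, standard):
    total = 0.0
    for t, r in zip(trials.durations, trials.responses):
        p = float(np.clip(p_same(model_id, params, t, standard), 1e-12, 1 - 1e-12))
        total += math.log(p) if r == 1 else math.log(1 - p)
    return total


def test_single_trial_at_half_probability():
    # t exactly at the lower boundary with a distant upper boundary: p = 0.5
    trials = TrialData(durations=[0.3], responses=[1])
    ll = log_likelihood("bsu", BSUParams(0.3, 50.0, 0.5), trials, S)
    assert ll == pytest.approx(math.log(0.5), abs=1e-9)


def test_perfect_zero_noise_prediction_scores_zero():
    design = make_design("exp1")
    params = DDMParams(0.31, 0.49, 1e-9)
    trials = simulate_trials("ddm", params, design, seed=0)
    ll = log_likelihood("ddm", params, trials, S)
    assert abs(ll) < 1e-9


def test_five_trial_hand_dataset_oracle():
    trials = TrialData(durations=[0.1, 0.3, 0.4, 0.5, 0.8], responses=[0, 1, 1, 0, 0])
    params = DDMParams(0.3, 0.5, 0.2)
    assert log_likelihood("ddm", params, trials, S) == pytest.approx(
        _naive_log_likelihood("ddm", params, trials, S), abs=1e-10
    )


@pytest.mark.parametrize("model_id", ["ddm", "bsu", "mcg", "cg"])
def test_aggregated_likelihood_equals_per_trial_loop(model_id, ddm_trials):
    if model_id in ("ddm", "bsu"):
        params = (DDMParams if model_id == "ddm" else BSUParams)(0.28, 0.52, 0.25)
    else:
        params = CGParams(B=0.3, sigma_B=0.1, k=0.2)
    ll = log_likelihood(model_id, params, ddm_trials, S)
    assert ll == pytest.approx(
        _naive_log_likelihood(model_id, params, ddm_trials, S), abs=1e-10
    )


def test_empty_data_is_an_error():
    empty = TrialData(durations=[], responses=[])
    with pytest.raises(ValueError):
        log_likelihood("ddm", DDMParams(0.3, 0.5, 0.2), empty, S)
    with pytest.raises(ValueError):
        fit_mle("ddm", empty, S)


@pytest.mark.parametrize("model_id", ["ddm", "bsu", "mcg", "cg"])
def test_initial_starts_are_the_eight_grid_points(model_id, exp1_design):
    starts = initial_starts(model_id, exp1_design)
    assert len(starts) == 8
    if model_id in ("cg", "mcg"):
        triples = {p.as_tuple() for p in starts}
        assert (0.1, 0.05, 0.05) in triples  # (B, sigma_B, k)
        assert {t[0] for t in triples} == {0.1, 0.5}
    else:
        mean_d = 3.0 / 7.0  # unweighted mean of the seven probe durations
        b_l_values = {round(p.b_l, 10) for p in starts}
        assert b_l_values == {0.125, round(mean_d, 10)}
        assert 0.6 in {round(p.b_u, 10) for p in starts}
        noise = {round(p.as_tuple()[2], 10) for p in starts}
        assert noise == ({0.05, 0.5} if model_id == "ddm" else {0.1, 0.5})


def test_large_sample_consistency_ddm():
    """With 10,000+ trials the MLE lands within 5% of the generating values."""
    design = make_design("exp1")
    big = type(design)(
        durations=design.durations,
        standard=design.standard,
        counts=tuple(45 * c for c in design.counts),  # 10,125 trials
    )
    truth = DDMParams(0.3, 0.5, 0.2)
    trials = simulate_trials("ddm", truth, big, seed=21)
    fit = fit_mle("ddm", trials, S)
    for name in ("b_l", "b_u", "c"):
        est, true = getattr(fit.params, name), getattr(truth, name)
        assert abs(est - true) / true < 0.05
    assert fit.log_lik >= log_likelihood("ddm", truth, trials, S) - 1e-6


def test_fitted_likelihood_beats_parameter_grid(ddm_trials):
    fit = fit_mle("ddm", ddm_trials, S)
    grid = np.linspace(0.05, 0.6, 20)
    noises = np.linspace(0.05, 0.5, 20)
    best = -np.inf
    for b_l in grid:
        for b_u in grid:
            if b_u <= b_l:
                continue
            for c in noises:
                ll = log_likelihood("ddm", DDMParams(b_l, b_u, c), ddm_trials, S)
                best = max(best, ll)
    assert fit.log_lik >= best - 1e-6


def test_refit_from_fitted_params_is_idempotent(ddm_trials):
    fit = fit_mle("ddm", ddm_trials, S)
    refit = fit_mle("ddm", ddm_trials, S, starts=[fit.params])
    for name in ("b_l", "b_u", "c"):
        assert getattr(refit.params, name) == pytest.approx(
            getattr(fit.params, name), abs=1e-4
        )
    assert refit.log_lik == pytest.approx(fit.log_lik, abs=1e-6)


def test_fit_is_invariant_to_trial_order(ddm_trials):
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(ddm_trials))
    shuffled = TrialData(
        durations=ddm_trials.durations[perm], responses=ddm_trials.responses[perm]
    )
    fit_a = fit_mle("ddm", ddm_trials, S)
    fit_b = fit_mle("ddm", shuffled, S)
    assert fit_a.log_lik == pytest.approx(fit_b.log_lik, abs=1e-12)
    assert fit_a.params == fit_b.params


def test_multistart_never_below_best_start(ddm_trials, exp1_design):
    for model_id in ("ddm", "bsu", "mcg", "cg"):
        starts = initial_starts(model_id, exp1_design)
        start_lls = [log_likelihood(model_id, s, ddm_trials, S) for s in starts]
        fit = fit_mle(model_id, ddm_trials, S)
        assert fit.log_lik >= max(start_lls) - 1e-9


@pytest.mark.parametrize("model_id", ["bsu", "mcg"])
def test_mle_recovers_other_models_loosely(model_id):
    """Sanity: each model roughly recovers its own generating parameters."""
    design = make_design("exp1_x3")
    if model_id == "bsu":
        truth = BSUParams(0.3, 0.55, 0.35)
        names = ("b_l", "b_u", "k")
    else:
        truth = CGParams(B=0.4, sigma_B=0.05, k=0.25)
        names = ("B",)  # noise parameters trade off; only B is asserted
    trials = simulate_trials(model_id, truth, design, seed=5)
    fit = fit_mle(model_id, trials, S)
    for name in names:
        est, true = getattr(fit.params, name), getattr(truth, name)
        assert abs(est - true) / true < 0.25


# --- shared-parameter fits -------------------------------------------------


def test_shared_fit_on_identical_conditions_doubles_likelihood(ddm_trials):
    single = fit_mle("ddm", ddm_trials, S)
    shared = fit_shared("ddm", {"a": ddm_trials, "b": ddm_trials}, S, "c")
    assert shared.log_lik == pytest.approx(2 * single.log_lik, abs=0.05)
    assert shared.n_free_params == 5
    c_values = {p.c for p in shared.params_by_condition.values()}
    assert len(c_values) == 1  # bit-identical shared parameter


def test_shared_fit_respects_nesting():
    design = make_design("exp1")
    t1 = simulate_trials("ddm", DDMParams(0.3, 0.5, 0.15), design, seed=31)
    t2 = simulate_trials("ddm", DDMParams(0.25, 0.6, 0.3), design, seed=32)
    free = fit_mle("ddm", t1, S).log_lik + fit_mle("ddm", t2, S).log_lik
    for shared_param in ("b_l", "b_u", "c"):
        shared = fit_shared("ddm", {"a": t1, "b": t2}, S, shared_param)
        assert shared.log_lik <= free + 1e-6
        assert shared.aic == pytest.approx(aic(shared.log_lik, 5))


def test_shared_fit_errors():
    trials = TrialData(durations=[0.4], responses=[1])
    with pytest.raises(ValueError):
        fit_shared("ddm", {"a": trials, "b": trials}, S, "nope")
    with pytest.raises(ValueError):
        fit_shared("ddm", {"a": trials}, S, "c")


def test_n_free_params_for_three_conditions(ddm_trials):
    shared = fit_shared(
        "ddm", {"a": ddm_trials, "b": ddm_trials, "c": ddm_trials}, S, "b_u"
    )
    assert shared.n_free_params == 7


# --- bookkeeping -----------------------------------------------------------


def _fake_fit(model_id, log_lik, n_trials=225):
    return FitResult(
        model_id=model_id,
        params=None,
        log_lik=log_lik,
        n_starts=8,
        best_start_index=0,
        converged=True,
        n_trials=n_trials,
    )


def test_aic_arithmetic():
    assert aic(-100.0, 3) == 206.0
    with pytest.raises(ValueError):
        aic(-100.0, 0)
    deltas = compare_aic({"full": 210.0, "constrained": 206.0})
    assert deltas["constrained"] == 0.0
    assert deltas["full"] == 4.0


def test_log10_likelihood_ratio():
    a, b = _fake_fit("ddm", -100.0), _fake_fit("bsu", -110.0)
    assert likelihood_ratio_log10(a, a) == 0.0
    assert likelihood_ratio_log10(a, b) == pytest.approx(10 / math.log(10), abs=1e-12)
    assert summed_likelihood_ratio_log10([a, a], [b, b]) == pytest.approx(
        2 * likelihood_ratio_log10(a, b)
    )
    with pytest.raises(ValueError):
        likelihood_ratio_log10(a, _fake_fit("bsu", -110.0, n_trials=10))


def test_winner_table_counts_and_ties():
    fits = {
        "p1": {m: _fake_fit(m, ll) for m, ll in
               [("ddm", -100), ("bsu", -105), ("mcg", -110), ("cg", -110)]},
        "p2": {m: _fake_fit(m, -100) for m in ("ddm", "bsu", "mcg", "cg")},
    }
    table = winner_table(fits)
    assert sum(table["counts"].values()) == table["n_participants"] == 2
    assert table["counts"]["ddm"] == 2  # p2 tie breaks to the fixed order
    with pytest.raises(ValueError):
        winner_table({"p": {"ddm": _fake_fit("ddm", -1)}})


def test_winner_table_simulated_ddm_cohort():
    design = make_design("exp1")
    fits = {}
    for i in range(4):
        trials = simulate_trials("ddm", DDMParams(0.3, 0.5, 0.12), design, seed=100 + i)
        fits[f"p{i}"] = {m: fit_mle(m, trials, S) for m in ("ddm", "bsu", "mcg", "cg")}
    table = winner_table(fits)
    assert table["counts"]["ddm"] >= 1  # at least chance level (25%)
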