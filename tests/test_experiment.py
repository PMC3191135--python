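"""Tests of design generation, trial simulation, coding, trimming, summaries."""

import numpy as np
import pandas as pd
import pytest

import primevoice as pv
from primevoice.experiment import (
    EXP1,
    EXP2_CONTROL,
    EXP2_EXPERIMENTAL,
    FORCED_PASSIVE,
    FREE_TRANSITIVE,
    TRAINING_VERBS,
    TrialResult,
    TrialSpec,
)
from primevoice.model import ACTIVE, PASSIVE


def _counts(trials):
    out = {}
    for t in trials:
        out[t.condition] = out.get(t.condition, 0) + 1
    return out


# -- design generation -------------------------------------------------


@pytest.mark.parametrize("seed", range(50))
def test_exp1_design_counts_exact_for_every_seed(seed):
    d = pv.generate_design(EXP1, 1, seed)
    trials = d.per_participant[0]
    c = _counts(trials)
    assert c["baseline"] == 72
    for cond in ("active_none", "active_full", "passive_none", "passive_full"):
        assert c[cond] == 24
    assert c["filler"] == 96
    assert sum(1 for t in trials if t.target_elicitation == FREE_TRANSITIVE) == 168


@pytest.mark.parametrize("seed", range(50))
def test_exp2_design_counts_exact_for_every_seed(seed):
    d = pv.generate_design(EXP2_EXPERIMENTAL, 1, seed)
    trials = d.per_participant[0]
    training = [t for t in trials if t.phase == "training"]
    assert len(training) == 100
    assert sum(t.prime_elicitation == FORCED_PASSIVE for t in training) == 90
    assert {t.prime_verb for t in training} == set(TRAINING_VERBS)
    c = _counts(t for t in trials if t.phase == "main")
    assert c["baseline"] == 48
    for cond in ("active_none", "active_verb", "passive_none", "passive_verb"):
        assert c[cond] == 24
    assert d.pictures_per_list("main") == 480


def test_exp2_control_training_mix():
    d = pv.generate_design(EXP2_CONTROL, 2, 7)
    for trials in d.per_participant:
        training = [t for t in trials if t.phase == "training"]
        assert sum(t.prime_elicitation == FORCED_PASSIVE for t in training) == 10


def test_half_of_pictures_elicit_transitives():
    for exp in (EXP1, EXP2_CONTROL):
        d = pv.generate_design(exp, 1, 3)
        main = [t for t in d.per_participant[0] if t.phase == "main"]
        n_pictures = sum(t.n_pictures for t in main)
        n_transitive = sum(
            (t.prime_verb is not None) + (t.target_verb is not None) for t in main
        )
        assert n_transitive * 2 == n_pictures


def test_training_verbs_disjoint_from_main_targets():
    d = pv.generate_design(EXP2_EXPERIMENTAL, 1, 0)
    main_verbs = {
        t.target_verb for t in d.per_participant[0] if t.target_verb is not None
    }
    assert len(main_verbs) == 31
    assert main_verbs.isdisjoint(TRAINING_VERBS)


def test_repetition_conditions_share_the_verb():
    d = pv.generate_design(EXP1, 1, 11)
    for t in d.per_participant[0]:
        if t.trial_type == "priming" and t.word_repetition != "none":
            assert t.prime_verb == t.target_verb
        elif t.trial_type == "priming":
            assert t.prime_verb != t.target_verb


def test_counterbalancing_rotates_prime_category_across_lists():
    d = pv.generate_design(EXP1, 3, 5)
    # same seed, three lists: per-verb condition assignments differ by list
    def verb_conditions(p):
        return {
            (t.target_verb, t.condition)
            for t in d.per_participant[p]
            if t.target_elicitation == FREE_TRANSITIVE
        }

    assert verb_conditions(0) != verb_conditions(1) != verb_conditions(2)


def test_unknown_experiment_rejected():
    with pytest.raises(ValueError):
        pv.generate_design("exp3", 1, 0)


# -- trial simulation --------------------------------------------------


def _spec(**kw):
    base = dict(
        trial_index=0, phase="main", trial_type="baseline",
        prime_elicitation="filler_intransitive",
        target_elicitation=FREE_TRANSITIVE,
        prime_verb=None, target_verb="a", word_repetition="none",
    )
    base.update(kw)
    return TrialSpec(**base)


def test_latency_is_exact_additive_sum(params, rng):
    lex = pv.build_lexicon(["a", "b"], params)
    res = pv.simulate_trial(
        _spec(trial_type="priming", prime_elicitation="forced_passive",
              prime_verb="b"),
        lex, params, rng,
    )
    assert res.latency_ms == pytest.approx(
        params.latency_intercept_ms
        + params.ms_per_cycle * res.selection_cycles
        + res.planning_ms
    )


def test_zero_noise_baseline_target_is_active(quiet_params, rng):
    lex = pv.build_lexicon(["a"], quiet_params)
    res = pv.simulate_trial(_spec(), lex, quiet_params, rng)
    assert res.response == ACTIVE
    assert res.syntactic_repetition is None
    assert res.condition == "baseline"


def test_baseline_trial_equals_target_after_settle_only(quiet_params, rng):
    """A filler prime leaves no transitive residual on the target race."""
    lex1 = pv.build_lexicon(["a"], quiet_params)
    r1 = pv.simulate_trial(_spec(), lex1, quiet_params, rng)
    lex2 = pv.build_lexicon(["a"], quiet_params)
    lex2.settle_all(quiet_params.settle_cycles, quiet_params, None)
    a, p = lex2.pair("a")
    out = pv.run_selection(
        a, p, (quiet_params.input_drive,) * 2, quiet_params,
        np.random.default_rng(0),
    )
    assert r1.selection_cycles == out.n_cycles
    assert r1.response == out.winner


def test_forced_prime_learns_and_spreads(params, rng):
    lex = pv.build_lexicon(["a", "b"], params)
    rest0 = lex.rest[1]
    res = pv.simulate_trial(
        _spec(trial_type="priming", prime_elicitation="forced_passive",
              prime_verb="b"),
        lex, params, rng,
    )
    assert res.prime_structure == PASSIVE
    assert lex.rest[1] == pytest.approx(rest0 + params.learn_increment)


def test_filler_trial_returns_no_result(params, rng):
    lex = pv.build_lexicon(["a"], params)
    res = pv.simulate_trial(
        _spec(trial_type="filler", target_elicitation="none", target_verb=None),
        lex, params, rng,
    )
    assert res is None


def test_run_virtual_experiment_deterministic(params):
    d = pv.generate_design(EXP1, 2, 9)
    r1 = pv.run_virtual_experiment(d, params, 42)
    r2 = pv.run_virtual_experiment(d, params, 42)
    assert r1 == r2
    r3 = pv.run_virtual_experiment(d, params, 43)
    assert r1 != r3


def test_training_raises_passive_rest_more_in_experimental_group(params):
    """A 90%-passive block shifts the passive resting level more than 10%."""
    fin = {}
    for exp in (EXP2_CONTROL, EXP2_EXPERIMENTAL):
        d = pv.generate_design(exp, 1, 1)
        training = [t for t in d.per_participant[0] if t.phase == "training"]
        lex = pv.build_lexicon(d.verbs, params)
        rng = np.random.default_rng(0)
        for t in training:
            pv.simulate_trial(t, lex, params, rng)
        fin[exp] = lex.rest[1]
    assert fin[EXP2_EXPERIMENTAL] > fin[EXP2_CONTROL]
    assert fin[EXP2_EXPERIMENTAL] == pytest.approx(
        min(params.rest_passive + 90 * params.learn_increment, params.rest_ceiling)
    )


# -- coding, trimming, summarizing -------------------------------------


@pytest.mark.parametrize(
    "prime,resp,expected",
    [(PASSIVE, PASSIVE, True), (PASSIVE, ACTIVE, False), (ACTIVE, ACTIVE, True)],
)
def test_code_syntactic_repetition(prime, resp, expected):
    assert pv.code_syntactic_repetition(prime, resp) is expected


def test_code_syntactic_repetition_rejects_baseline():
    with pytest.raises(ValueError, match="priming trials"):
        pv.code_syntactic_repetition(None, ACTIVE)


def _result(participant, condition, latency, response=ACTIVE, **kw):
    base = dict(
        participant=participant, trial_index=0, phase="main",
        condition=condition, prime_structure=None, response=response,
        word_repetition="none", syntactic_repetition=None,
        selection_cycles=10, planning_ms=0.0, latency_ms=latency,
        timed_out=False,
    )
    base.update(kw)
    return TrialResult(**base)


def test_trim_matches_direct_mean_sd_computation():
    """Exclusion agrees with an independent mean +/- 2 SD computation.

    With five values the sample SD is inflated by any outlier so much that
    no value can sit two SDs out (max standardized deviation (n-1)/sqrt(n)
    < 2 for n = 5): nothing is excluded.  A ten-value cell with one gross
    outlier does exclude it.
    """
    five = [500.0, 510.0, 520.0, 530.0, 2000.0]
    ten = [490.0 + 10 * i for i in range(9)] + [2000.0]
    for lats in (five, ten):
        results = [_result(0, "baseline", x) for x in lats]
        pv.trim_outliers(results)
        arr = np.array(lats)
        lo = arr.mean() - 2 * arr.std(ddof=1)
        hi = arr.mean() + 2 * arr.std(ddof=1)
        expected = [(x < lo) or (x > hi) for x in lats]
        assert [r.excluded for r in results] == expected
    # the five-value cell keeps everything, the ten-value cell drops the outlier
    assert sum(_trim_flags(five)) == 0
    assert _trim_flags(ten) == [False] * 9 + [True]


def _trim_flags(lats):
    results = [_result(0, "c", x) for x in lats]
    pv.trim_outliers(results)
    return [r.excluded for r in results]


def test_trim_degenerate_cells():
    assert _trim_flags([700.0] * 6) == [False] * 6  # identical values kept
    assert _trim_flags([700.0]) == [False]  # singleton cell untouched


def test_trim_is_per_participant_and_condition():
    results = [_result(0, "baseline", 500.0) for _ in range(10)]
    results += [_result(0, "baseline", 900.0)]
    results += [_result(1, "baseline", 900.0)]  # other subject: own cell
    pv.trim_outliers(results)
    assert results[10].excluded  # outlier within participant 0's cell
    assert not results[11].excluded


def test_summarize_proportions_and_missing_cells():
    results = [_result(0, "baseline", 800.0) for _ in range(9)]
    results += [_result(0, "baseline", 800.0, response=PASSIVE)]
    s = pv.summarize(results, EXP1)
    assert s.baseline_passive_rate() == pytest.approx(0.10)
    assert len(s.tendencies) == 5  # baseline + 4 priming cells reported
    assert np.isnan(s.passive_rate("passive_full"))  # missing, not zero
    assert s.tendencies.set_index("condition").loc["passive_full", "n"] == 0


def test_summarize_excluded_trials_do_not_count():
    results = [_result(0, "baseline", 800.0) for _ in range(4)]
    results += [_result(0, "baseline", 800.0, response=PASSIVE, excluded=True)]
    s = pv.summarize(results, EXP1)
    assert s.baseline_passive_rate() == 0.0


def test_tendencies_invariant_to_trial_order():
    rng = np.random.default_rng(3)
    results = [
        _result(0, "baseline", 700 + i, response=PASSIVE if i % 4 == 0 else ACTIVE)
        for i in range(20)
    ]
    s1 = pv.summarize(results, EXP1)
    perm = [results[i] for i in rng.permutation(20)]
    s2 = pv.summarize(perm, EXP1)
    pd.testing.assert_frame_equal(s1.tendencies, s2.tendencies)


def test_summarize_latency_cells_and_se():
    results = [
        _result(0, "active_none", lat, response=ACTIVE,
                prime_structure=ACTIVE, syntactic_repetition=True)
        for lat in (900.0, 1000.0, 1100.0)
    ]
    s = pv.summarize(results, EXP1)
    assert s.latency(ACTIVE, True) == pytest.approx(1000.0)
    row = s.latencies[
        (s.latencies.target_structure == ACTIVE) & s.latencies.syntactic_repetition
    ]
    assert row["se_ms"].iloc[0] == pytest.approx(100.0 / np.sqrt(3))


def test_check_patterns_equal_latencies_fail_strict_facilitation():
    results = []
    for cond, prime in [("active_none", ACTIVE), ("passive_none", PASSIVE)]:
        for resp in (ACTIVE, PASSIVE):
            for _ in range(5):
                results.append(
                    _result(0, cond, 1000.0, response=resp, prime_structure=prime,
                            syntactic_repetition=(prime == resp))
                )
    results += [_result(0, "baseline", 1000.0, response=PASSIVE)]
    results += [_result(0, "baseline", 1000.0) for _ in range(9)]
    rep = pv.check_patterns(pv.summarize(results, EXP1), EXP1)
    assert rep.checks["p3"] is False  # ties are not facilitation
    assert rep.checks["p4"] is True  # exp1 reads >= as replication


def test_check_patterns_missing_cells_indeterminate():
    results = [_result(0, "baseline", 1000.0)]
    rep = pv.check_patterns(pv.summarize([*results], EXP1), EXP1)
    assert rep.checks["p1"] is None and rep.checks["p3"] is None


def test_check_patterns_group_contrast_requires_control():
    results = [_result(0, "baseline", 1000.0) for _ in range(5)]
    s = pv.summarize(results, EXP2_EXPERIMENTAL)
    rep = pv.check_patterns(s, EXP2_EXPERIMENTAL)
    assert rep.checks["p5"] is None
    rep2 = pv.check_patterns(s, EXP2_EXPERIMENTAL, control_summary=s)
    assert rep2.checks["p5"] is False  # equal rates are not a boost
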