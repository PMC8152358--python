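import itertools

import numpy as np
import pytest
from scipy import stats

from cpforage import hmm
from cpforage.synthetic import FORAGE, REST, TRAVEL

from conftest import make_trip


def brute_force_loglik(params, steps, turns):
    """Path-enumeration oracle for the forward log-likelihood."""
    n = len(steps)
    # emission table computed once, straight from scipy densities
    logB = np.empty((n, 3))
    for i in range(n):
        for k in range(3):
            s = max(steps[i], hmm.MIN_STEP_KM)
            shape = (params.step_mean[k] / params.step_sd[k]) ** 2
            scale = params.step_sd[k] ** 2 / params.step_mean[k]
            v = stats.gamma.logpdf(s, shape, scale=scale)
            if not np.isnan(turns[i]):
                v += stats.vonmises.logpdf(turns[i], params.turn_kappa[k], loc=params.turn_mu[k])
            logB[i, k] = v

    total = -np.inf
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(3), repeat=n):
        lp = np.log(params.initial[path[0]]) + logB[0, path[0]]
        for i in range(1, n):
            lp += np.log(params.transition[path[i - 1], path[i]]) + logB[i, path[i]]
        total = np.logaddexp(total, lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return total, np.array(best_path)


@pytest.fixture(scope="module")
def generic_params():
    return hmm.HMMParams(
        step_mean=np.array([0.01, 0.1, 0.5]),
        step_sd=np.array([0.01, 0.06, 0.2]),
        turn_mu=np.array([0.0, np.pi, 0.0]),
        turn_kappa=np.array([0.5, 1.0, 8.0]),
        transition=np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]),
        initial=np.array([1 / 3, 1 / 3, 1 / 3]),
    )


# ---------------------------------------------------------------------------
# steps_and_turns
# ---------------------------------------------------------------------------


def test_square_path_geometry():
    # unit square, counterclockwise: all steps 1 km, all turns +pi/2... but
    # heading convention (from north) makes a left circuit -pi/2; use the
    # circuit whose turns are +pi/2
    x = [0, 0, 1, 1, 0, 0]
    y = [0, 1, 1, 0, 0, 1]
    trip = make_trip(x, y)
    steps, turns = hmm.steps_and_turns(trip)
    assert np.allclose(steps, 1.0)
    assert np.isnan(turns[0])
    assert np.allclose(turns[1:], np.pi / 2)


def test_straight_path_zero_turns():
    trip = make_trip(np.arange(10) * 0.3, np.arange(10) * 0.4)
    steps, turns = hmm.steps_and_turns(trip)
    assert np.allclose(steps, 0.5)
    assert np.allclose(turns[1:], 0.0, atol=1e-12)


def test_steps_turns_match_trig_oracle():
    rng = np.random.default_rng(2)
    x = np.cumsum(rng.normal(0, 1, 50))
    y = np.cumsum(rng.normal(0, 1, 50))
    steps, turns = hmm.steps_and_turns(make_trip(x, y))
    for i in range(len(x) - 1):
        assert abs(steps[i] - np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2)) < 1e-12
    for i in range(1, len(x) - 1):
        h1 = np.arctan2(x[i] - x[i - 1], y[i] - y[i - 1])
        h2 = np.arctan2(x[i + 1] - x[i], y[i + 1] - y[i])
        d = h2 - h1
        d = np.arctan2(np.sin(d), np.cos(d))
        if np.isclose(d, -np.pi):
            d = np.pi
        assert abs(turns[i] - d) < 1e-12


def test_too_few_fixes_error():
    with pytest.raises(ValueError):
        hmm.steps_and_turns(make_trip([0, 1], [0, 0]))


# ---------------------------------------------------------------------------
# hmm_loglik
# ---------------------------------------------------------------------------


def test_loglik_matches_enumeration(generic_params):
    for seed in range(3):
        steps, turns, _ = hmm.simulate(generic_params, 8, seed=seed)
        ll = hmm.hmm_loglik(generic_params, [(steps, turns)])
        oracle, _ = brute_force_loglik(generic_params, steps, turns)
        assert abs(ll - oracle) < 1e-8


def test_loglik_multiple_sequences_sum(generic_params):
    s1 = hmm.simulate(generic_params, 5, seed=1)[:2]
    s2 = hmm.simulate(generic_params, 6, seed=2)[:2]
    ll = hmm.hmm_loglik(generic_params, [s1, s2])
    assert np.isclose(ll, hmm.hmm_loglik(generic_params, [s1]) + hmm.hmm_loglik(generic_params, [s2]))


def test_single_state_collapse(generic_params):
    # initial mass and transitions pinned to state 1: iid density sum
    p = hmm.HMMParams(
        step_mean=generic_params.step_mean.copy(),
        step_sd=generic_params.step_sd.copy(),
        turn_mu=generic_params.turn_mu.copy(),
        turn_kappa=generic_params.turn_kappa.copy(),
        transition=np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=float),
        initial=np.array([0.0, 1.0, 0.0]),
    )
    steps, turns, _ = hmm.simulate(generic_params, 30, seed=3)
    ll = hmm.hmm_loglik(p, [(steps, turns)])
    shape = (p.step_mean[1] / p.step_sd[1]) ** 2
    scale = p.step_sd[1] ** 2 / p.step_mean[1]
    iid = stats.gamma.logpdf(np.maximum(steps, 0.001), shape, scale=scale).sum()
    iid += stats.vonmises.logpdf(turns[1:], p.turn_kappa[1], loc=p.turn_mu[1]).sum()
    assert abs(ll - iid) < 1e-8


def test_loglik_permutation_invariance(generic_params):
    steps, turns, _ = hmm.simulate(generic_params, 40, seed=4)
    ll = hmm.hmm_loglik(generic_params, [(steps, turns)])
    perm = [2, 0, 1]
    ll_p = hmm.hmm_loglik(generic_params.permuted(perm), [(steps, turns)])
    assert abs(ll - ll_p) < 1e-8


def test_invalid_params_error(generic_params):
    bad = generic_params.permuted([0, 1, 2])
    bad.step_mean = np.array([-1.0, 0.1, 0.5])
    with pytest.raises(ValueError):
        hmm.hmm_loglik(bad, [(np.ones(5), np.zeros(5))])


# ---------------------------------------------------------------------------
# decode_states
# ---------------------------------------------------------------------------


def test_viterbi_matches_enumeration(generic_params):
    for seed in range(3):
        steps, turns, _ = hmm.simulate(generic_params, 10, seed=10 + seed)
        seq = hmm.decode_states(generic_params, [(steps, turns)])
        _, oracle_path = brute_force_loglik(generic_params, steps, turns)
        assert np.array_equal(seq.labels, oracle_path)


def test_posteriors_sum_to_one(generic_params):
    steps, turns, _ = hmm.simulate(generic_params, 200, seed=6)
    seq = hmm.decode_states(generic_params, [(steps, turns)])
    assert np.allclose(seq.posteriors.sum(axis=1), 1.0, atol=1e-9)


def test_state_identifying_emissions_decode_exactly():
    p = hmm.HMMParams(
        step_mean=np.array([0.001, 1.0, 1000.0]),
        step_sd=np.array([0.0001, 0.01, 1.0]),
        turn_mu=np.zeros(3),
        turn_kappa=np.full(3, 1.0),
        transition=np.full((3, 3), 1 / 3),
        initial=np.full(3, 1 / 3),
    )
    steps, turns, states = hmm.simulate(p, 300, seed=7)
    seq = hmm.decode_states(p, [(steps, turns)])
    assert np.array_equal(seq.labels, states)


def test_decoding_accuracy_well_separated(hmm_truth):
    steps, turns, states = hmm.simulate(hmm_truth, 5000, seed=8)
    seq = hmm.decode_states(hmm_truth, [(steps, turns)])
    assert (seq.labels == states).mean() >= 0.90


# ---------------------------------------------------------------------------
# fit_hmm
# ---------------------------------------------------------------------------


def test_ascent_from_truth(hmm_truth):
    steps, turns, _ = hmm.simulate(hmm_truth, 3000, seed=9)
    data = [(steps, turns)]
    fit = hmm.fit_hmm(data, n_restarts=1, init=hmm_truth, seed=0)
    assert fit.loglik >= hmm.hmm_loglik(hmm_truth, data)


def test_canonical_ordering(hmm_truth):
    steps, turns, _ = hmm.simulate(hmm_truth, 2000, seed=12)
    fit = hmm.fit_hmm([(steps, turns)], n_restarts=3, seed=1)
    m = fit.params.step_mean
    assert m[0] <= m[1] <= m[2]


def test_parameter_recovery_scaled(hmm_truth):
    # scaled-down version of the acceptance recovery (n=20k, 8 restarts)
    steps, turns, _ = hmm.simulate(hmm_truth, 20_000, seed=13)
    fit = hmm.fit_hmm([(steps, turns)], n_restarts=8, seed=2)
    assert np.all(np.abs(fit.params.step_mean / hmm_truth.step_mean - 1) < 0.05)
    assert np.all(np.abs(fit.params.turn_kappa / hmm_truth.turn_kappa - 1) < 0.15)
    assert np.all(np.abs(fit.params.transition - hmm_truth.transition) < 0.05)


def test_viterbi_loglik_below_total(generic_params):
    steps, turns, _ = hmm.simulate(generic_params, 60, seed=14)
    total = hmm.hmm_loglik(generic_params, [(steps, turns)])
    logB = hmm._log_emissions(generic_params, steps, turns)
    _, best = hmm._viterbi(
        logB, np.log(generic_params.transition), np.log(generic_params.initial)
    )
    assert best <= total + 1e-9


# ---------------------------------------------------------------------------
# extract_foraging / validate_states
# ---------------------------------------------------------------------------


def _seq_from_labels(labels):
    labels = np.asarray(labels)
    post = np.zeros((labels.size, 3))
    post[np.arange(labels.size), labels] = 1.0
    return hmm.StateSequence(labels, post, np.array([0, labels.size]), ["t1"])


def test_extract_all_forage():
    trip = make_trip(np.arange(11) * 0.1, np.zeros(11))
    seq = _seq_from_labels([FORAGE] * 10)
    fixes, props = hmm.extract_foraging(seq, [trip])
    assert len(fixes) == 11
    assert props.loc[0, "prop_forage"] == 1.0


def test_extract_alternating():
    trip = make_trip(np.arange(11) * 0.1, np.zeros(11))
    seq = _seq_from_labels([FORAGE, TRAVEL] * 5)
    _, props = hmm.extract_foraging(seq, [trip])
    assert props.loc[0, "prop_forage"] == 0.5
    assert props.loc[0, "prop_travel"] == 0.5


def test_extract_random_counting_oracle():
    rng = np.random.default_rng(15)
    labels = rng.choice([REST, FORAGE, TRAVEL], size=60)
    trip = make_trip(np.arange(61) * 0.1, np.zeros(61))
    _, props = hmm.extract_foraging(_seq_from_labels(labels), [trip])
    assert np.isclose(props.loc[0, "prop_forage"], (labels == FORAGE).mean())
    assert np.isclose(
        props.loc[0, "prop_rest"] + props.loc[0, "prop_forage"] + props.loc[0, "prop_travel"],
        1.0,
    )


def test_validate_states_perfect_decode():
    fix_states = np.array([FORAGE] * 50 + [TRAVEL] * 50 + [REST] * 20)
    dive_counts = np.array([1] * 50 + [0] * 70)
    rep = hmm.validate_states(fix_states, dive_counts, None)
    assert rep.evaluable and rep.passed
    assert rep.dive_rate_per_h["travel"] == 0.0
    assert rep.dive_rate_per_h["rest"] == 0.0


def test_validate_states_confusion_attenuation():
    # 10% of forage fixes decoded travel and vice versa; closed-form mixing
    nf = nt = 1000
    true_states = np.array([FORAGE] * nf + [TRAVEL] * nt)
    dive_counts = (true_states == FORAGE).astype(float)  # 1 dive per forage fix
    decoded = true_states.copy()
    decoded[:100] = TRAVEL  # 10% of forage mislabelled
    decoded[nf : nf + 100] = FORAGE  # 10% of travel mislabelled
    rep = hmm.validate_states(decoded, dive_counts, None, dt_s=30.0)
    per_fix_hours = 30.0 / 3600.0
    expect_forage = (0.9 * nf) / ((0.9 * nf + 0.1 * nt) * per_fix_hours)
    expect_travel = (0.1 * nf) / ((0.1 * nf + 0.9 * nt) * per_fix_hours)
    assert np.isclose(rep.dive_rate_per_h["forage"], expect_forage)
    assert np.isclose(rep.dive_rate_per_h["travel"], expect_travel)
    assert rep.passed


def test_validate_states_no_dives_not_evaluable():
    rep = hmm.validate_states(np.array([FORAGE, TRAVEL]), np.zeros(2), None)
    assert not rep.evaluable and rep.passed is None
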