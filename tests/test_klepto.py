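from math import comb

import numpy as np
import pandas as pd
import pytest

from cpforage import klepto, synthetic
from cpforage.synthetic import FORAGE, TRAVEL

T0 = pd.Timestamp("2017-06-01 00:00:00", tz="UTC")


def intervals(pairs, bird="b1"):
    return pd.DataFrame(
        {
            "bird_id": bird,
            "start": [T0 + pd.Timedelta(seconds=s) for s, _ in pairs],
            "end": [T0 + pd.Timedelta(seconds=e) for _, e in pairs],
        }
    )


# ---------------------------------------------------------------------------
# discretize_events
# ---------------------------------------------------------------------------


def test_small_gap_merged():
    out = klepto.discretize_events(intervals([(0, 10), (25, 40)]))  # gap 15 s
    assert len(out) == 1
    assert out["total_duration_s"].iloc[0] == 25.0  # 10 + 15


def test_large_gap_separate():
    out = klepto.discretize_events(intervals([(0, 10), (55, 70)]))  # gap 45 s
    assert len(out) == 2


def test_gap_exactly_30s_separate():
    # merge rule is strictly-less-than the 30 s gap
    out = klepto.discretize_events(intervals([(0, 10), (40, 50)]))
    assert len(out) == 2


def test_overlap_merged_with_warning():
    with pytest.warns(UserWarning):
        out = klepto.discretize_events(intervals([(0, 20), (10, 30)]))
    assert len(out) == 1


def sweep_merge(pairs, gap_s=30.0):
    """Independent sweep-line merge oracle."""
    pairs = sorted(pairs)
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s - merged[-1][1] < gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def test_random_intervals_match_sweep_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        starts = np.sort(rng.integers(0, 2000, 25))
        ends = starts + rng.integers(1, 50, 25)
        pairs = list(zip(starts.tolist(), ends.tolist()))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = klepto.discretize_events(intervals(pairs))
        oracle = sweep_merge(pairs)
        assert len(out) == len(oracle)
        got = [
            ((r["start"] - T0).total_seconds(), (r["end"] - T0).total_seconds())
            for _, r in out.iterrows()
        ]
        assert got == [(float(s), float(e)) for s, e in oracle]


def test_merge_idempotent_and_order_independent():
    rng = np.random.default_rng(1)
    starts = np.sort(rng.integers(0, 1000, 15))
    ends = starts + rng.integers(1, 40, 15)
    pairs = list(zip(starts.tolist(), ends.tolist()))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        once = klepto.discretize_events(intervals(pairs))
        twice = klepto.discretize_events(once)
        shuffled = klepto.discretize_events(intervals(pairs[::-1]))
    assert len(once) == len(twice)
    assert list(once["start"]) == list(twice["start"])
    assert list(once["start"]) == list(shuffled["start"])


# ---------------------------------------------------------------------------
# fisher_exact
# ---------------------------------------------------------------------------


def test_fisher_reproduces_reported_p():
    # 5 of 9 females attacked vs 0 of 7 males
    res = klepto.fisher_exact([[5, 4], [0, 7]])
    assert round(res.p_value, 3) == 0.034


def test_fisher_balanced_unit_table():
    res = klepto.fisher_exact([[1, 0], [0, 1]])
    assert res.p_value == pytest.approx(1.0)


def enumeration_oracle(a, b, c, d):
    """Exact two-sided p by direct binomial-coefficient enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = comb(N, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = comb(r1, k) * comb(r2, c1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        t = rng.integers(0, 12, size=(2, 2))
        res = klepto.fisher_exact(t)
        assert abs(res.p_value - enumeration_oracle(*t.ravel())) < 1e-12


def test_fisher_matches_scipy():
    from scipy.stats import fisher_exact as scipy_fisher

    rng = np.random.default_rng(3)
    for _ in range(30):
        t = rng.integers(0, 15, size=(2, 2))
        assert klepto.fisher_exact(t).p_value == pytest.approx(
            scipy_fisher(t)[1], abs=1e-10
        )


def test_fisher_transpose_symmetry_and_range():
    rng = np.random.default_rng(4)
    for _ in range(20):
        t = rng.integers(0, 10, size=(2, 2))
        p = klepto.fisher_exact(t).p_value
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(klepto.fisher_exact(t.T).p_value, abs=1e-12)


def test_fisher_doubling_rule():
    res = klepto.fisher_exact([[5, 4], [0, 7]], method="doubling")
    assert 0.0 < res.p_value <= 1.0
    assert res.p_value >= klepto.fisher_exact([[5, 4], [0, 7]]).p_value - 1e-12


def test_fisher_negative_entries_rejected():
    with pytest.raises(ValueError):
        klepto.fisher_exact([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# event_context
# ---------------------------------------------------------------------------


def _context_setup():
    n = 40
    fix_times = T0 + pd.to_timedelta(np.arange(n) * 30, unit="s")
    states = np.array([TRAVEL] * 10 + [FORAGE] * 10 + [TRAVEL] * 20)
    return fix_times, states


def test_event_during_forage():
    fix_times, states = _context_setup()
    events = pd.DataFrame({"fix_index": [15]})
    out = klepto.event_context(events, fix_times, states)
    assert out["context"].iloc[0] == "during_forage"


def test_event_near_forage():
    fix_times, states = _context_setup()
    events = pd.DataFrame({"fix_index": [21]})  # 2 fixes (60 s) after forage
    out = klepto.event_context(events, fix_times, states)
    assert out["context"].iloc[0] == "near_forage"


def test_event_other_and_unmatched():
    fix_times, states = _context_setup()
    events = pd.DataFrame({"fix_index": [35, -1]})  # 7.5 min after forage
    out = klepto.event_context(events, fix_times, states)
    assert out["context"].iloc[0] == "other"
    assert out["context"].iloc[1] == "missing_context"


def test_context_matches_scan_oracle():
    rng = np.random.default_rng(5)
    n = 100
    fix_times = T0 + pd.to_timedelta(np.arange(n) * 30, unit="s")
    states = rng.choice([TRAVEL, FORAGE], size=n, p=[0.8, 0.2])
    idx = rng.integers(0, n, 40)
    events = pd.DataFrame({"fix_index": idx})
    out = klepto.event_context(events, fix_times, states)
    ft = np.arange(n) * 30.0
    forage_t = ft[states == FORAGE]
    for fi, got in zip(idx, out["context"]):
        if states[fi] == FORAGE:
            want = "during_forage"
        elif forage_t.size and np.min(np.abs(forage_t - ft[fi])) <= 2.4 * 60:
            want = "near_forage"
        else:
            want = "other"
        assert got == want


# ---------------------------------------------------------------------------
# sex_discriminant
# ---------------------------------------------------------------------------


def test_dfa_no_signal_near_chance(truth):
    rng = np.random.default_rng(6)
    n = 60
    X = rng.normal(0, 1, size=(2 * n, 3))
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["sex"] = ["female"] * n + ["male"] * n
    df["bird_id"] = [f"x{i}" for i in range(2 * n)]
    res = klepto.sex_discriminant(df, predictors=["a", "b", "c"])
    assert abs(res.loo_accuracy - 0.5) < 0.2


def test_dfa_separated_sexes(truth):
    table = synthetic.generate_morpho(truth, 60, seed=7)
    res = klepto.sex_discriminant(table, predictors=list(synthetic.MORPHO_COLUMNS))
    assert res.loo_accuracy >= 0.95


def test_dfa_direction_matches_closed_form(truth):
    table = synthetic.generate_morpho(truth, 50, seed=8)
    preds = list(synthetic.MORPHO_COLUMNS)
    res = klepto.sex_discriminant(table, predictors=preds)
    Xf = table.loc[table["sex"] == "female", preds].to_numpy()
    Xm = table.loc[table["sex"] == "male", preds].to_numpy()
    Sf = np.cov(Xf.T) * (len(Xf) - 1)
    Sm = np.cov(Xm.T) * (len(Xm) - 1)
    pooled = (Sf + Sm) / (len(Xf) + len(Xm) - 2)
    w_oracle = np.linalg.solve(pooled, Xf.mean(0) - Xm.mean(0))
    cos = res.coefficients @ w_oracle / (
        np.linalg.norm(res.coefficients) * np.linalg.norm(w_oracle)
    )
    assert cos > 1 - 1e-10


def test_dfa_predictions_and_ambiguity(truth):
    table = synthetic.generate_morpho(truth, 40, seed=9)
    unknown = synthetic.generate_morpho(truth, 10, seed=10).drop(columns=["sex"])
    res = klepto.sex_discriminant(table, unknown, predictors=list(synthetic.MORPHO_COLUMNS))
    assert len(res.predictions) == 20
    assert set(res.predictions["predicted_sex"]) <= {"female", "male"}
    # well-separated defaults: most predictions should be confident
    assert len(res.ambiguous_ids) < 10


def test_dfa_needs_five_per_sex():
    df = pd.DataFrame({"sex": ["female"] * 3 + ["male"] * 6, "a": np.arange(9.0)})
    with pytest.raises(ValueError):
        klepto.sex_discriminant(df, predictors=["a"])


# ---------------------------------------------------------------------------
# cohens_d / standardize
# ---------------------------------------------------------------------------


def test_cohens_d_zero_for_equal_means():
    assert klepto.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0


def test_cohens_d_arithmetic():
    # means 10 vs 8, both sample variances 4 -> pooled sd 2, d = 1
    assert klepto.cohens_d([8.0, 10.0, 12.0], [6.0, 8.0, 10.0]) == pytest.approx(1.0)


def test_cohens_d_population_limit():
    rng = np.random.default_rng(11)
    a = rng.normal(5.0, 2.0, 200_00)
    b = rng.normal(4.0, 2.0, 200_00)
    assert abs(klepto.cohens_d(a, b) - 0.5) < 0.03


def test_cohens_d_zero_sd_flag():
    assert np.isnan(klepto.cohens_d([1.0, 1.0], [1.0, 1.0]))


def test_standardize_moments():
    rng = np.random.default_rng(12)
    v = rng.normal(3, 7, 500)
    z = klepto.standardize(v)
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=1) - 1.0) < 1e-12
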