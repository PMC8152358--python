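"""Kleptoparasitism event analysis and morphometric discrimination.

Raw attack intervals are merged into discrete events (gap < 30 s), sex bias
is tested with an exact Fisher test by hypergeometric enumeration, events
are contextualized against decoded foraging activity, and morphometrics
feed a linear discriminant sexing function and Cohen's d effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GAP_S = 30.0
DEFAULT_CONTEXT_WINDOW_MIN = 2.4


# ---------------------------------------------------------------------------
# Event discretization
# ---------------------------------------------------------------------------


def discretize_events(intervals: pd.DataFrame, gap_s: float = DEFAULT_GAP_S) -> pd.DataFrame:
    """Merge per-bird raw intervals separated by a gap strictly below ``gap_s``.

    Input needs bird_id, start, end (and optionally attacker_class, carried
    from the first member of each merged event).  Raw durations are summed
    into ``total_duration_s``; overlapping raw intervals merge with a warning.
    """
    if len(intervals) == 0:
        return intervals.copy()
    rows = []
    for bird, sub in intervals.groupby("bird_id", sort=True):
        sub = sub.sort_values("start").reset_index(drop=True)
        cur = sub.iloc[0].to_dict()
        cur_dur = (cur["end"] - cur["start"]).total_seconds()
        for _, r in sub.iloc[1:].iterrows():
            gap = (r["start"] - cur["end"]).total_seconds()
            if gap < 0:
                warnings.warn(f"overlapping raw intervals for bird {bird}; merged")
            if gap < gap_s:
                cur["end"] = max(cur["end"], r["end"])
                cur_dur += (r["end"] - r["start"]).total_seconds()
            else:
                cur["total_duration_s"] = cur_dur
                rows.append(cur)
                cur = r.to_dict()
                cur_dur = (r["end"] - r["start"]).total_seconds()
        cur["total_duration_s"] = cur_dur
        rows.append(cur)
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fisher's exact test (hypergeometric enumeration)
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float
    table: np.ndarray


def fisher_exact(table, method: str = "minlike") -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table, margins fixed.

    ``method='minlike'`` (default) sums the probabilities of all tables whose
    hypergeometric probability is <= the observed table's (the convention of
    R's fisher.test); ``'doubling'`` doubles the smaller one-sided tail,
    capped at 1.  The reported odds ratio is the conditional maximum
    likelihood estimate.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[support == a][0]
    if method == "minlike":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif method == "doubling":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = min(2.0 * min(lower, upper), 1.0)
    else:
        raise ValueError("method must be 'minlike' or 'doubling'")
    p = min(p, 1.0)
    orr = stats.contingency.odds_ratio(np.round(t).astype(int), kind="conditional")
    return FisherResult(p_value=p, odds_ratio=float(orr.statistic), table=np.round(t).astype(int))


# ---------------------------------------------------------------------------
# Event context
# ---------------------------------------------------------------------------


def event_context(
    events: pd.DataFrame,
    fix_times: np.ndarray,
    fix_states: np.ndarray,
    forage_state: int = 1,
    window_min: float = DEFAULT_CONTEXT_WINDOW_MIN,
    coast_distance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Label each matched event against decoded foraging activity.

    Events carry ``fix_index`` (from track matching; -1 = unmatched).
    ``during_forage`` if the matched fix decoded forage; ``near_forage`` if
    any forage fix lies within ±``window_min`` minutes; else ``other``.
    Unmatched events get ``missing_context``.
    """
    fix_times = pd.to_datetime(pd.Series(fix_times)).astype("int64").to_numpy() / 1e9
    fix_states = np.asarray(fix_states)
    forage_times = fix_times[fix_states == forage_state]
    out = events.copy()
    contexts, coasts = [], []
    for _, r in out.iterrows():
        fi = int(r["fix_index"])
        if fi < 0:
            contexts.append("missing_context")
            coasts.append(np.nan)
            continue
        if fix_states[fi] == forage_state:
            contexts.append("during_forage")
        else:
            t = fix_times[fi]
            if forage_times.size and np.min(np.abs(forage_times - t)) <= window_min * 60.0 + 1e-9:
                contexts.append("near_forage")
            else:
                contexts.append("other")
        coasts.append(float(coast_distance[fi]) if coast_distance is not None else np.nan)
    out["context"] = contexts
    out["coast_distance_km"] = coasts
    return out


# ---------------------------------------------------------------------------
# Morphometric discrimination and effect sizes
# ---------------------------------------------------------------------------


@dataclass
class DiscriminantResult:
    coefficients: np.ndarray
    intercept: float
    predictors: list
    loo_accuracy: float
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    ambiguous_ids: list = field(default_factory=list)


def _lda_fit(Xf: np.ndarray, Xm: np.ndarray):
    nf, nm = len(Xf), len(Xm)
    mf, mm = Xf.mean(axis=0), Xm.mean(axis=0)
    Sf = (Xf - mf).T @ (Xf - mf)
    Sm = (Xm - mm).T @ (Xm - mm)
    pooled = (Sf + Sm) / (nf + nm - 2)
    try:
        w = np.linalg.solve(pooled, mf - mm)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; consider dropping a collinear predictor"
        ) from e
    # decision boundary at the pooled midpoint, adjusted by log prior odds
    b = -0.5 * w @ (mf + mm) + np.log(nf / nm)
    return w, b


def sex_discriminant(
    train: pd.DataFrame,
    predict: pd.DataFrame | None = None,
    predictors: list | None = None,
    ambiguous_band: tuple = (0.4, 0.6),
) -> DiscriminantResult:
    """Two-class linear discriminant sexing from morphometrics.

    Fits pooled-covariance LDA on known-sex birds ('female' vs 'male'),
    reports leave-one-out accuracy, and predicts unknowns with posterior
    probabilities; posteriors inside ``ambiguous_band`` are flagged.
    """
    if predictors is None:
        predictors = [c for c in train.columns if c not in ("bird_id", "sex")]
    for sx in ("female", "male"):
        if (train["sex"] == sx).sum() < 5:
            raise ValueError(f"need >= 5 known-sex birds of sex {sx!r}")
    if train[predictors].isna().any().any():
        raise ValueError("missing predictor values in training data")
    Xf = train.loc[train["sex"] == "female", predictors].to_numpy(dtype=float)
    Xm = train.loc[train["sex"] == "male", predictors].to_numpy(dtype=float)
    w, b = _lda_fit(Xf, Xm)

    # leave-one-out
    X = train[predictors].to_numpy(dtype=float)
    is_f = (train["sex"] == "female").to_numpy()
    correct = 0
    for i in range(len(train)):
        keep = np.ones(len(train), dtype=bool)
        keep[i] = False
        wi, bi = _lda_fit(X[keep & is_f], X[keep & ~is_f])
        pred_f = X[i] @ wi + bi > 0
        correct += int(pred_f == is_f[i])
    loo = correct / len(train)

    preds = pd.DataFrame()
    ambiguous = []
    if predict is not None and len(predict):
        Xp = predict[predictors].to_numpy(dtype=float)
        score = Xp @ w + b
        post_f = 1.0 / (1.0 + np.exp(-score))
        sexes = np.where(post_f >= 0.5, "female", "male")
        preds = predict[["bird_id"]].copy() if "bird_id" in predict else pd.DataFrame(index=predict.index)
        preds["predicted_sex"] = sexes
        preds["posterior_female"] = post_f
        lo, hi = ambiguous_band
        amb = (post_f > lo) & (post_f < hi)
        if "bird_id" in predict:
            ambiguous = list(predict.loc[amb, "bird_id"])
    return DiscriminantResult(
        coefficients=w,
        intercept=float(b),
        predictors=list(predictors),
        loo_accuracy=float(loo),
        predictions=preds,
        ambiguous_ids=ambiguous,
    )


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled-sd (n_a + n_b - 2) denominator; NaN if sd = 0."""
    a = np.asarray(group_a, dtype=float)
    bb = np.asarray(group_b, dtype=float)
    if a.size < 2 or bb.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (bb.size - 1) * bb.var(ddof=1))
        / (a.size + bb.size - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - bb.mean()) / pooled)


def standardize(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd transform used for radial morphometric plots."""
    v = np.asarray(values, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)
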