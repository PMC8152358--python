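"""Per-trip characteristics, trip-tactic mixture clustering, and the
random-intercept binomial test of sex differences in tactic probability.

Trip metrics: total distance, maximum distance from the colony, duration,
mean distance to the nearest coastline, median underlying bathymetry and
time-in-state proportions.  Tactic clustering is a Gaussian mixture on
(duration, mean coast distance, max distance), standardized, with the number
of components chosen by BIC.  The sex test is a likelihood-ratio test from a
random-intercept logistic model fitted by adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from sklearn.mixture import GaussianMixture

GMM_VARS = ("duration_h", "mean_coast_km", "max_distance_km")


# ---------------------------------------------------------------------------
# Trip metrics
# ---------------------------------------------------------------------------


def trip_metrics(trip, world, prop_row: dict | None = None) -> dict:
    """Five movement metrics (plus optional state proportions) for one trip.

    ``prop_row`` carries prop_rest/prop_forage/prop_travel from decoding;
    bathymetry cells missing under a fix are excluded from the median.
    """
    fixes = trip.fixes
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    steps = np.hypot(np.diff(x), np.diff(y))
    dist_colony = np.hypot(x, y)
    coast = world.coast_distance(x, y)
    bathy = world.bathymetry_at(x, y)
    row = {
        "trip_id": trip.trip_id,
        "bird_id": trip.bird_id,
        "total_distance_km": float(steps.sum()),
        "max_distance_km": float(dist_colony.max()),
        "duration_h": float(trip.duration_h),
        "mean_coast_km": float(np.mean(coast)),
        "median_bathymetry_m": float(np.nanmedian(bathy)) if np.isfinite(bathy).any() else np.nan,
    }
    if prop_row is not None:
        for k in ("prop_rest", "prop_forage", "prop_travel"):
            row[k] = prop_row[k]
    return row


def trip_metrics_table(trips, world, props: pd.DataFrame | None = None) -> pd.DataFrame:
    prop_by_id = {}
    if props is not None:
        prop_by_id = {r["trip_id"]: r.to_dict() for _, r in props.iterrows()}
    return pd.DataFrame([trip_metrics(t, world, prop_by_id.get(t.trip_id)) for t in trips])


# ---------------------------------------------------------------------------
# Gaussian mixture tactic clustering
# ---------------------------------------------------------------------------


@dataclass
class MixtureResult:
    K: int
    weights: np.ndarray
    means: np.ndarray  # on the original (unstandardized) scale
    covariances: np.ndarray
    bic: float
    bic_by_k: dict
    labels: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray


def fit_gmm(
    metrics: pd.DataFrame,
    vars: tuple = GMM_VARS,
    k_range=range(1, 6),
    n_init: int = 10,
    seed: int = 0,
) -> MixtureResult:
    """EM Gaussian mixture on z-scored trip metrics; K chosen by lowest BIC.

    Components are canonically ordered by ascending mean duration (first
    variable), so component 0 is the shorter/coastal tactic.
    """
    if len(metrics) < 10:
        raise ValueError("need at least 10 trips to cluster")
    X = metrics.loc[:, list(vars)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("a clustering variable has zero variance")
    Z = (X - mu) / sd

    bic_by_k, fits = {}, {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(Z)
        bic_by_k[k] = float(gm.bic(Z))
        fits[k] = gm
    best_k = min(bic_by_k, key=bic_by_k.get)
    gm = fits[best_k]

    order = np.argsort(gm.means_[:, 0], kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(best_k)
    labels = inv[gm.predict(Z)]
    means_z = gm.means_[order]
    covs_z = gm.covariances_[order]
    means = means_z * sd + mu
    covs = covs_z * np.outer(sd, sd)
    return MixtureResult(
        K=best_k,
        weights=gm.weights_[order],
        means=means,
        covariances=covs,
        bic=bic_by_k[best_k],
        bic_by_k=bic_by_k,
        labels=labels,
        scaler_mean=mu,
        scaler_sd=sd,
    )


# ---------------------------------------------------------------------------
# Random-intercept binomial GLMM (adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------


def _ghq_loglik(beta, log_sigma, X, y, group_idx, n_groups, nodes, weights):
    """Marginal log-likelihood via adaptive GH quadrature, vectorized over groups."""
    sigma = np.exp(log_sigma)
    eta0 = X @ beta

    def grad_hess(b):
        eta = eta0 + b[group_idx]
        p = expit(eta)
        g = np.bincount(group_idx, weights=y - p, minlength=n_groups) - b / sigma**2
        h = -np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups) - 1.0 / sigma**2
        return g, h

    # Newton to the per-group conditional mode
    b = np.zeros(n_groups)
    for _ in range(50):
        g, h = grad_hess(b)
        step = g / h
        b = b - step
        if np.max(np.abs(step)) < 1e-10:
            break
    _, h = grad_hess(b)
    tau = 1.0 / np.sqrt(-h)  # Laplace sd per group

    def joint_log(bvals):
        # log p(y_j | b) + log phi(b; 0, sigma) per group, at per-group bvals
        eta = eta0 + bvals[group_idx]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        ll = np.bincount(group_idx, weights=ll_obs, minlength=n_groups)
        ll += -0.5 * np.log(2 * np.pi) - log_sigma - 0.5 * (bvals / sigma) ** 2
        return ll

    # adaptive rule: integral = sqrt(2)*tau * sum_k w_k e^{t_k^2} f(bhat + sqrt2 tau t_k)
    acc = np.full(n_groups, -np.inf)
    for t_k, w_k in zip(nodes, weights):
        bvals = b + np.sqrt(2.0) * tau * t_k
        term = joint_log(bvals) + t_k**2 + np.log(w_k)
        acc = np.logaddexp(acc, term)
    return float(np.sum(acc + 0.5 * np.log(2.0) + np.log(tau)))


@dataclass
class GLMMResult:
    beta: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    separation_flag: bool = False


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 15,
    log_sigma_bounds: tuple = (-8.0, 3.0),
) -> GLMMResult:
    """ML fit of logit(p) = X beta + b_group, b ~ N(0, sigma^2).

    Pinning ``log_sigma_bounds`` to a large negative value fits the
    no-random-effect submodel (plain logistic regression).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes, _ = pd.factorize(groups)
    n_groups = codes.max() + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def negll(theta):
        with np.errstate(over="ignore"):
            return -_ghq_loglik(
                theta[:-1], theta[-1], X, y, codes, n_groups, nodes, weights
            )

    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.clip(np.log(0.5), *log_sigma_bounds)
    bounds = [(-30.0, 30.0)] * X.shape[1] + [tuple(log_sigma_bounds)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    beta = res.x[:-1]
    separation = bool(np.any(np.abs(beta) > 15.0))
    return GLMMResult(
        beta=beta,
        sigma=float(np.exp(res.x[-1])),
        loglik=float(-res.fun),
        converged=bool(res.success),
        separation_flag=separation,
    )


@dataclass
class TacticSexTest:
    lrt_statistic: float
    df: int
    p_value: float
    beta_sex: float
    sigma: float
    per_sex_proportions: dict = field(default_factory=dict)
    separation_flag: bool = False


def tactic_sex_test(
    labels: np.ndarray,
    bird_id: np.ndarray,
    sex: np.ndarray,
    n_nodes: int = 15,
) -> TacticSexTest:
    """LRT of a sex effect on a binary tactic with a per-bird random intercept.

    Compares logit(p) = b0 + b1*male + u_bird against the intercept-only
    model (same random effect); chi-squared reference with 1 df.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("tactic labels show no variation")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("tactic labels must be binary (0/1)")
    sex = np.asarray(sex)
    for s in np.unique(sex):
        if len(np.unique(bird_id[sex == s])) < 2:
            raise ValueError(f"need >= 2 birds of sex {s!r}")
    is_male = (sex == "male").astype(float)
    n = labels.size
    X_full = np.column_stack([np.ones(n), is_male])
    X_null = np.ones((n, 1))

    full = fit_logistic_glmm(labels, X_full, bird_id, n_nodes=n_nodes)
    null = fit_logistic_glmm(labels, X_null, bird_id, n_nodes=n_nodes)
    lrt = max(2.0 * (full.loglik - null.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    props = {
        str(s): float(labels[sex == s].mean()) for s in np.unique(sex)
    }
    return TacticSexTest(
        lrt_statistic=float(lrt),
        df=1,
        p_value=p,
        beta_sex=float(full.beta[1]),
        sigma=full.sigma,
        per_sex_proportions=props,
        separation_flag=full.separation_flag,
    )
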