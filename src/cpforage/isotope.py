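"""Isotopic niche estimation and diet statistics.

Standard ellipse areas (SEA, with the small-sample correction SEAc) in
δ13C-δ15N space, a pluggable lipid-normalization hook, trophic-enrichment
correction into prey isotope space, heteroscedastic (per-group variance)
linear models fitted by maximum likelihood, and prey-composition chi-squared
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TEFConfig:
    """Blood→prey trophic enrichment factors (‰): Δ15N 1.96 ± 0.79, Δ13C 0.32 ± 0.86."""

    dN_mean: float = 1.96
    dC_mean: float = 0.32
    dN_sd: float = 0.79
    dC_sd: float = 0.86

    def __post_init__(self):
        if self.dN_sd < 0 or self.dC_sd < 0:
            raise ValueError("TEF sds must be nonnegative")


# ---------------------------------------------------------------------------
# Lipid normalization
# ---------------------------------------------------------------------------


def lipid_normalize(d13C, cn_ratio=None, model=("identity",)):
    """Apply a configurable lipid-normalization correction to δ13C.

    ``model`` is ``("identity",)`` (no-op) or ``("linear", b0, b1)`` which
    adds b0 + b1 * C:N.  Vectorized over array inputs.
    """
    d13C = np.asarray(d13C, dtype=float)
    if model[0] == "identity":
        return d13C.copy()
    if model[0] == "linear":
        if cn_ratio is None:
            raise ValueError("cn_ratio required for the linear normalization model")
        cn = np.asarray(cn_ratio, dtype=float)
        if np.any(cn <= 0):
            raise ValueError("C:N ratios must be positive")
        _, b0, b1 = model
        return d13C + b0 + b1 * cn
    raise ValueError(f"unknown lipid-normalization model {model[0]!r}")


# ---------------------------------------------------------------------------
# TEF correction
# ---------------------------------------------------------------------------


def tef_correct(samples: pd.DataFrame, tef: TEFConfig = TEFConfig()) -> tuple[pd.DataFrame, dict]:
    """Shift consumer values into prey isotope space and build the sd box.

    Subtracts the TEF means from each sample; the uncertainty box spans the
    corrected group mean ± one TEF sd on each axis.
    """
    out = samples.copy()
    out["d13C_prey"] = out["d13C"] - tef.dC_mean
    out["d15N_prey"] = out["d15N"] - tef.dN_mean
    cx = float(out["d13C_prey"].mean())
    cy = float(out["d15N_prey"].mean())
    box = {
        "x_center": cx,
        "y_center": cy,
        "xmin": cx - tef.dC_sd,
        "xmax": cx + tef.dC_sd,
        "ymin": cy - tef.dN_sd,
        "ymax": cy + tef.dN_sd,
    }
    return out, box


# ---------------------------------------------------------------------------
# Standard ellipse area
# ---------------------------------------------------------------------------


@dataclass
class EllipseSummary:
    group: str
    n: int
    centroid: np.ndarray
    covariance: np.ndarray
    sea: float
    seac: float
    polygon: np.ndarray  # (m, 2) 1-sd ellipse vertices
    degenerate: bool = False


def sea_ellipse(
    d13C: np.ndarray,
    d15N: np.ndarray,
    group: str = "",
    ddof: int = 1,
    n_vertices: int = 100,
) -> EllipseSummary:
    """Standard ellipse of a bivariate isotope sample.

    SEA = π √(λ1 λ2) with λ the eigenvalues of the sample covariance
    (divisor n-1 by default, config-pinned via ``ddof``); SEAc applies the
    small-sample correction (n-1)/(n-2).  Collinear data give SEA = 0 and
    the degenerate flag.
    """
    x = np.asarray(d13C, dtype=float)
    y = np.asarray(d15N, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("standard ellipse needs n >= 3")
    cov = np.cov(np.vstack([x, y]), ddof=ddof)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    sea = float(np.pi * np.sqrt(evals[0] * evals[1]))
    seac = sea * (n - 1) / (n - 2)
    centroid = np.array([x.mean(), y.mean()])
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    circle = np.vstack([np.cos(theta), np.sin(theta)])
    poly = (evecs @ (np.sqrt(evals)[:, None] * circle)).T + centroid
    return EllipseSummary(
        group=group,
        n=n,
        centroid=centroid,
        covariance=cov,
        sea=sea,
        seac=seac,
        polygon=poly,
        degenerate=bool(np.min(evals) <= 1e-12),
    )


def drop_repeated_individuals(samples: pd.DataFrame, id_col: str = "bird_id") -> pd.DataFrame:
    """Keep only the first sample per individual (repeated-measure rule)."""
    return samples.drop_duplicates(subset=id_col, keep="first").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Heteroscedastic linear model (per-group residual variances, ML)
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, factors) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for f in factors:
        col = df[f]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=f, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(f)
    return np.column_stack(cols), names


@dataclass
class HetLMResult:
    coefficients: dict
    group_variances: dict
    loglik: float
    n_iter: int
    fitted: np.ndarray
    residuals: np.ndarray


def heteroscedastic_lm(
    df: pd.DataFrame,
    response: str,
    factors,
    variance_group: str,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> HetLMResult:
    """ML linear model with a separate residual variance per group.

    Alternates weighted least squares for the mean and per-group ML variance
    updates until the log-likelihood changes by less than ``tol``.
    """
    y = df[response].to_numpy(dtype=float)
    X, names = _design(df, factors)
    codes, levels = pd.factorize(df[variance_group])
    counts = np.bincount(codes)
    if np.any(counts < 2):
        bad = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"variance group(s) with < 2 observations: {bad}")

    sig2 = np.full(len(levels), np.var(y) if np.var(y) > 0 else 1.0)
    last_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = 1.0 / sig2[codes]
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ y)
        r = y - X @ beta
        sig2 = np.bincount(codes, weights=r**2) / counts
        sig2 = np.maximum(sig2, 1e-12)
        ll = -0.5 * np.sum(np.log(2 * np.pi * sig2[codes]) + r**2 / sig2[codes])
        if abs(ll - last_ll) < tol:
            last_ll = ll
            break
        last_ll = ll
    return HetLMResult(
        coefficients=dict(zip(names, beta)),
        group_variances={str(levels[i]): float(sig2[i]) for i in range(len(levels))},
        loglik=float(last_ll),
        n_iter=n_iter,
        fitted=X @ beta,
        residuals=r,
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


def heteroscedastic_lrt(
    df: pd.DataFrame,
    response: str,
    full_factors,
    reduced_factors,
    variance_group: str,
) -> LRTResult:
    """LRT between nested mean models under the same variance structure."""
    full = heteroscedastic_lm(df, response, full_factors, variance_group)
    red = heteroscedastic_lm(df, response, reduced_factors, variance_group)
    _, full_names = _design(df, full_factors)
    _, red_names = _design(df, reduced_factors)
    ddf = len(full_names) - len(red_names)
    if ddf <= 0:
        raise ValueError("full model must have more mean parameters than reduced")
    stat = max(2.0 * (full.loglik - red.loglik), 0.0)
    return LRTResult(
        statistic=float(stat),
        df=ddf,
        p_value=float(stats.chi2.sf(stat, ddf)),
        loglik_full=full.loglik,
        loglik_reduced=red.loglik,
    )


# ---------------------------------------------------------------------------
# Prey composition
# ---------------------------------------------------------------------------


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


def prey_composition_test(table) -> ChiSquareResult:
    """Pearson chi-squared test of homogeneity on a groups x prey-type table."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    stat, p, dof, expected = stats.chi2_contingency(t, correction=False)
    low = bool(np.any(expected < 5))
    if low:
        warnings.warn("expected counts < 5; chi-squared approximation may be poor")
    return ChiSquareResult(float(stat), int(dof), float(p), expected, low)
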