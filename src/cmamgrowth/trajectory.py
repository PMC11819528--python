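"""Group growth-trajectory smoothing with subject-level clustering.

Weekly mean curves per response category are fitted with a penalized
regression spline model of the additive-model family:

    y_ij = f_g(i)(w_ij) + beta_age * (age_i - mean age) + b_i + e_ij

where ``f_g`` is a cubic B-spline smooth of weeks since admission,
separate for each group ``g`` (group level and group-by-time
interaction in one block), ``b_i`` is a per-child random intercept
absorbed as a ridge-penalized effect, and ``e_ij`` is Gaussian noise.
Each group smooth carries a second-order difference penalty on its
B-spline coefficients, so straight-line group trends are unpenalized
(the penalty null space).  Smoothing parameters — one shared for the
group smooths, one for the subject intercepts — are chosen by
generalized cross-validation (default) or an approximate Gaussian
REML score, over a log-spaced grid.

Pointwise 95% intervals come from the Bayesian-style covariance of the
penalized coefficients, sigma^2 (X'X + S)^-1, the convention of the
established penalized-GAM literature.  Prediction outside the fitted
week range is an error: curves are only reported where data exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.interpolate import BSpline


@dataclass
class SmoothFit:
    """Fitted penalized-spline group-trajectory model."""

    outcome: str
    groups: list
    knots: np.ndarray
    degree: int
    coefs: dict                      # group -> basis coefficient vector
    age_coef: float | None
    mean_age: float | None
    lambda_smooth: float
    lambda_subject: float | None
    sigma2: float
    edf: float
    week_range: tuple
    cov_pop: np.ndarray              # covariance of population-level coefficients
    pop_slices: dict = field(repr=False, default=None)  # group/age -> column slice
    method: str = "gcv"
    subject_sd: float = 0.0


def _bspline_knots(weeks: np.ndarray, n_interior: int, degree: int) -> np.ndarray:
    lo, hi = float(weeks.min()), float(weeks.max())
    interior = np.quantile(np.unique(weeks), np.linspace(0, 1, n_interior + 2)[1:-1])
    interior = np.unique(interior[(interior > lo) & (interior < hi)])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _design(weeks, knots, degree):
    return BSpline.design_matrix(weeks, knots, degree, extrapolate=False).tocsr()


def _greville(knots: np.ndarray, degree: int) -> np.ndarray:
    p = len(knots) - degree - 1
    return np.array([knots[j + 1: j + degree + 1].mean() for j in range(p)])


def _second_diff_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    # second divided differences at the Greville abscissae: annihilates
    # coefficient sequences linear in x, i.e. straight-line trends are
    # exactly unpenalized even with non-uniform knots
    g = _greville(knots, degree)
    p = len(g)
    D = np.zeros((p - 2, p))
    for j in range(p - 2):
        h1, h2 = g[j + 1] - g[j], g[j + 2] - g[j + 1]
        D[j, j] = 1.0 / h1
        D[j, j + 1] = -(1.0 / h1 + 1.0 / h2)
        D[j, j + 2] = 1.0 / h2
    return D.T @ D


def fit_group_curves(
    data: pd.DataFrame,
    outcome: str,
    adjust_age: bool = False,
    n_interior_knots: int = 10,
    degree: int = 3,
    method: str = "gcv",
    subject_effects: bool = True,
    lambda_smooth: float | None = None,
    lambda_subject: float | None = None,
    smooth_grid=None,
    subject_grid=None,
) -> SmoothFit:
    """Fit penalized group smooths of ``outcome`` against weeks.

    Parameters
    ----------
    data : DataFrame
        Columns ``child_id, week, group`` plus the outcome column and,
        when ``adjust_age``, ``age_adm_months`` (admission age).
    outcome : str
        Name of the outcome column (e.g. ``muac_mm``).
    adjust_age : bool
        Add a linear admission-age adjustment (used for MUAC and
        weight curves).
    method : {"gcv", "reml"}
        Smoothing-parameter selection criterion.
    lambda_smooth, lambda_subject : float, optional
        Fix a smoothing parameter instead of selecting it.
    """
    cols = ["child_id", "week", "group", outcome] + (
        ["age_adm_months"] if adjust_age else []
    )
    d = data[cols].dropna().copy()
    groups = sorted(d["group"].unique())
    weeks = d["week"].to_numpy(dtype=float)
    y = d[outcome].to_numpy(dtype=float)
    n = len(d)

    # basis; shrink if some group has too few distinct weeks to support it
    min_distinct = min(d.groupby("group")["week"].nunique())
    p_b = n_interior_knots + degree + 1
    if min_distinct < p_b:
        n_interior_knots = max(min_distinct - degree - 1, 0)
        warnings.warn(
            f"reduced spline basis to {n_interior_knots} interior knots: "
            "a group has too few distinct weeks", stacklevel=2,
        )
    knots = _bspline_knots(weeks, n_interior_knots, degree)
    B = _design(weeks, knots, degree)
    p_b = B.shape[1]

    blocks, pop_slices = [], {}
    col = 0
    S_sm = _second_diff_penalty(knots, degree)
    for g in groups:
        ind = sp.diags((d["group"] == g).to_numpy(dtype=float))
        blocks.append(ind @ B)
        pop_slices[g] = slice(col, col + p_b)
        col += p_b
    mean_age = None
    if adjust_age:
        mean_age = float(d["age_adm_months"].mean())
        age = (d["age_adm_months"].to_numpy(dtype=float) - mean_age)[:, None]
        blocks.append(sp.csr_matrix(age))
        pop_slices["age"] = slice(col, col + 1)
        col += 1
    p_pop = col
    child_ids = None
    if subject_effects:
        child_ids, child_idx = np.unique(d["child_id"].to_numpy(), return_inverse=True)
        Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), child_idx)), shape=(n, len(child_ids))
        )
        blocks.append(Z)
    X = sp.hstack(blocks, format="csr")
    p = X.shape[1]

    XtX = np.asarray((X.T @ X).todense())
    Xty = np.asarray(X.T @ y).ravel()
    yty = float(y @ y)

    S_smooth = np.zeros((p, p))
    for g in groups:
        s = pop_slices[g]
        S_smooth[s, s] = S_sm
    S_subject = np.zeros((p, p))
    if subject_effects:
        S_subject[p_pop:, p_pop:] = np.eye(p - p_pop)
    rank_sm = len(groups) * max(p_b - 2, 0)
    rank_sub = p - p_pop

    def solve(lam_s, lam_u):
        A = XtX + lam_s * S_smooth + (lam_u * S_subject if subject_effects else 0.0)
        A[np.diag_indices_from(A)] += 1e-10 * (1.0 + np.abs(np.diag(XtX)))
        c, low = sla.cho_factor(A, check_finite=False)
        beta = sla.cho_solve((c, low), Xty, check_finite=False)
        AinvXtX = sla.cho_solve((c, low), XtX, check_finite=False)
        edf = float(np.trace(AinvXtX))
        rss = max(yty - 2 * beta @ Xty + beta @ (XtX @ beta), 1e-300)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
        return beta, edf, rss, logdet_A, (c, low)

    def score(lam_s, lam_u):
        _, edf, rss, logdet_A, _ = solve(lam_s, lam_u)
        if method == "gcv":
            denom = max(n - edf, 1e-8)
            return n * rss / denom**2
        # approximate Gaussian REML (up to lambda-independent constants)
        logdet_S = rank_sm * np.log(lam_s) + (
            rank_sub * np.log(lam_u) if subject_effects else 0.0
        )
        return (n - rank_sm) / 2.0 * np.log(rss) + 0.5 * logdet_A - 0.5 * logdet_S

    sgrid = np.logspace(-2, 6, 9) if smooth_grid is None else np.asarray(smooth_grid)
    ugrid = np.logspace(-1, 8, 7) if subject_grid is None else np.asarray(subject_grid)
    if lambda_smooth is not None:
        sgrid = np.array([lambda_smooth])
    if lambda_subject is not None or not subject_effects:
        ugrid = np.array([lambda_subject if lambda_subject is not None else 0.0])
    best, best_score = None, np.inf
    for ls in sgrid:
        for lu in ugrid:
            sc = score(ls, lu)
            if sc < best_score:
                best_score, best = sc, (float(ls), float(lu))
    lam_s, lam_u = best
    beta, edf, rss, _, chol = solve(lam_s, lam_u)
    sigma2 = rss / max(n - edf, 1e-8)

    # covariance of the population block only (Bayesian-style)
    E = np.zeros((p, p_pop))
    E[:p_pop, :] = np.eye(p_pop)
    cov_pop = sigma2 * sla.cho_solve(chol, E, check_finite=False)[:p_pop, :]

    coefs = {g: beta[pop_slices[g]].copy() for g in groups}
    subject_sd = float(np.std(beta[p_pop:])) if subject_effects else 0.0
    return SmoothFit(
        outcome=outcome,
        groups=groups,
        knots=knots,
        degree=degree,
        coefs=coefs,
        age_coef=float(beta[pop_slices["age"]][0]) if adjust_age else None,
        mean_age=mean_age,
        lambda_smooth=lam_s,
        lambda_subject=lam_u if subject_effects else None,
        sigma2=float(sigma2),
        edf=edf,
        week_range=(float(weeks.min()), float(weeks.max())),
        cov_pop=cov_pop,
        pop_slices=pop_slices,
        method=method,
        subject_sd=subject_sd,
    )


def predict_weekly_means(
    fit: SmoothFit, weeks, reference_age: float | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Population curves per group on a week grid, with pointwise CIs.

    Curves are evaluated for the average child (subject effect zero) at
    ``reference_age`` (default: the mean admission age of the fitting
    data) when the fit is age-adjusted.  Weeks outside the fitted range
    raise ``ValueError`` — no extrapolated curves.
    """
    weeks = np.asarray(weeks, dtype=float)
    lo, hi = fit.week_range
    if weeks.min() < lo or weeks.max() > hi:
        raise ValueError(
            f"requested weeks outside the fitted range [{lo:g}, {hi:g}]"
        )
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + level / 2.0)
    B = _design(weeks, fit.knots, fit.degree).toarray()
    p_pop = fit.cov_pop.shape[0]
    rows = []
    for g in fit.groups:
        Xg = np.zeros((len(weeks), p_pop))
        Xg[:, fit.pop_slices[g]] = B
        mean = B @ fit.coefs[g]
        if fit.age_coef is not None:
            ref = fit.mean_age if reference_age is None else float(reference_age)
            Xg[:, fit.pop_slices["age"]] = ref - fit.mean_age
            mean = mean + fit.age_coef * (ref - fit.mean_age)
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, fit.cov_pop, Xg), 0.0))
        for w, m, s in zip(weeks, mean, se):
            rows.append((g, w, m, m - zcrit * s, m + zcrit * s))
    return pd.DataFrame(rows, columns=["group", "week", "mean", "ci_low", "ci_high"])


def weekly_curve_table(
    data: pd.DataFrame, outcome: str, adjust_age: bool = False, **fit_kwargs
) -> pd.DataFrame:
    """Convenience: fit and evaluate on the integer weeks observed."""
    fit = fit_group_curves(data, outcome, adjust_age=adjust_age, **fit_kwargs)
    lo, hi = fit.week_range
    weeks = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    return predict_weekly_means(fit, weeks)
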