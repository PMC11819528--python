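"""Three-category multinomial logistic regression and its diagnostics.

The response has categories ``recovered`` (the reference),
``high_growth_nr`` and ``low_growth_nr``.  Odds ratios > 1 mean
increased odds of being in a non-responder group rather than recovered.

The maximum-likelihood fit is Newton-type on the multinomial
log-likelihood (via statsmodels' MNLogit), with standard errors from
the observed information.  For a single categorical predictor the MLE
odds ratios coincide exactly with the contingency-table cross-product
closed form implemented in :func:`contingency_or`, which therefore
serves as an independent oracle for the iterative fit.  Joint Wald
tests pool all coefficients of a variable across both non-reference
contrasts.  Multicollinearity is screened with variance inflation
factors (study rule: keep VIF < 1.5).  Classification quality is
summarised by in-sample accuracy and the Hand-Till multiclass AUC (the
average of pairwise one-vs-one AUCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

OUTCOME_LEVELS = ("recovered", "high_growth_nr", "low_growth_nr")
REFERENCE = "recovered"
VIF_LIMIT = 1.5


# ---------------------------------------------------------------- tables

@dataclass
class ContingencyTable:
    """Predictor-level by outcome-category count table.

    ``counts`` is a DataFrame indexed by predictor level with one
    column per outcome category; ``baseline`` names the reference
    predictor level.
    """

    counts: pd.DataFrame
    baseline: object

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.baseline not in self.counts.index:
            raise ValueError(f"baseline level {self.baseline!r} not in table")
        if REFERENCE not in self.counts.columns:
            raise ValueError(f"table must include the {REFERENCE!r} outcome")


def contingency_or(
    table: ContingencyTable, level, outcome, continuity: bool = False
):
    """Cross-product odds ratio with a 95% Woolf (log) interval.

    OR = (n[level, outcome] * n[baseline, recovered]) /
         (n[baseline, outcome] * n[level, recovered]).

    Identical to the univariate multinomial MLE for a categorical
    predictor.  A zero cell raises unless ``continuity`` adds the
    Haldane 0.5 correction.
    """
    c = table.counts
    cells = np.array(
        [
            c.loc[level, outcome], c.loc[table.baseline, REFERENCE],
            c.loc[table.baseline, outcome], c.loc[level, REFERENCE],
        ],
        dtype=float,
    )
    if (cells == 0).any():
        if not continuity:
            raise ZeroDivisionError(
                "zero cell in contingency table; pass continuity=True "
                "for the Haldane correction"
            )
        cells = cells + 0.5
    a, b, cc, dd = cells
    or_ = (a * b) / (cc * dd)
    se = np.sqrt((1.0 / cells).sum())
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), float(lo), float(hi)


def expand_table(table: ContingencyTable) -> pd.DataFrame:
    """Individual-level rows (columns ``level, outcome``) from counts."""
    rows = []
    for lev in table.counts.index:
        for out in table.counts.columns:
            rows.extend([(lev, out)] * int(table.counts.loc[lev, out]))
    return pd.DataFrame(rows, columns=["level", "outcome"])


# ---------------------------------------------------------------- model fit

@dataclass
class MultinomFit:
    """Multinomial logit fit with recovered as the reference category."""

    params: pd.DataFrame          # index: design columns, columns: non-ref outcomes
    bse: pd.DataFrame
    cov: np.ndarray               # covariance of vec(params), outcome-major
    llf: float
    converged: bool
    outcome_levels: list
    design_columns: list
    terms: dict                   # variable -> list of design columns
    n_obs: int
    _result: object = field(repr=False, default=None)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        rows = []
        with np.errstate(over="ignore"):
            for out in self.params.columns:
                for var in self.params.index:
                    if var == "const":
                        continue
                    b, se = self.params.loc[var, out], self.bse.loc[var, out]
                    rows.append(
                        (out, var, np.exp(b), np.exp(b - z * se), np.exp(b + z * se))
                    )
        return pd.DataFrame(rows, columns=["outcome", "term", "OR", "ci_low", "ci_high"])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        import statsmodels.api as sm

        Xd = sm.add_constant(X[[c for c in self.design_columns if c != "const"]],
                             has_constant="add")
        return self._result.predict(Xd.to_numpy(dtype=float))


def _encode_design(X: pd.DataFrame):
    """Dummy-encode object/categorical columns (first level is baseline)."""
    terms: dict[str, list[str]] = {}
    pieces = []
    for col in X.columns:
        s = X[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            terms[col] = list(dummies.columns)
            pieces.append(dummies)
        else:
            terms[col] = [col]
            pieces.append(s.astype(float))
    return pd.concat(pieces, axis=1), terms


def fit_multinomial(
    y,
    X: pd.DataFrame,
    ref: str = REFERENCE,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> MultinomFit:
    """Fit a multinomial logit of a 3-category outcome on ``X``.

    ``y`` holds category labels; ``ref`` is pinned as the reference
    (first) category.  Categorical/boolean columns of ``X`` are
    dummy-encoded with the first level as baseline.  Raises on a
    rank-deficient design, naming the collinear columns; separation
    surfaces as ``converged=False``.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(y, dtype=object), name="outcome")
    levels = [ref] + sorted(set(y) - {ref})
    codes = y.map({lev: i for i, lev in enumerate(levels)}).to_numpy(dtype=int)
    Xd, terms = _encode_design(pd.DataFrame(X))
    Xc = sm.add_constant(Xd, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy(dtype=float))
    if rank < Xc.shape[1]:
        # name the offending columns via QR pivoting on the design
        from scipy.linalg import qr

        _, r, piv = qr(Xc.to_numpy(dtype=float), pivoting=True)
        keep = np.abs(np.diag(r)) > 1e-8 * np.abs(r[0, 0])
        dropped = [Xc.columns[j] for j in piv[len(keep[keep]):]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dropped}")
    model = sm.MNLogit(codes, Xc.to_numpy(dtype=float))
    with warnings_catch():
        res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    out_names = levels[1:]
    params = pd.DataFrame(res.params, index=list(Xc.columns), columns=out_names)
    bse = pd.DataFrame(res.bse, index=list(Xc.columns), columns=out_names)
    return MultinomFit(
        params=params,
        bse=bse,
        cov=np.asarray(res.cov_params()),
        llf=float(res.llf),
        converged=converged,
        outcome_levels=levels,
        design_columns=list(Xc.columns),
        terms=terms,
        n_obs=len(y),
        _result=res,
    )


class warnings_catch:
    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def wald_test(fit: MultinomFit, variable: str):
    """Joint chi-square Wald test of all coefficients of ``variable``
    across both non-reference contrasts.

    Returns (statistic, df, p).  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    cols = fit.terms.get(variable)
    if not cols:
        raise KeyError(f"variable {variable!r} not in the fitted design")
    p = len(fit.design_columns)
    idx = []
    for j_out in range(len(fit.outcome_levels) - 1):
        for c in cols:
            idx.append(j_out * p + fit.design_columns.index(c))
    beta = np.concatenate(
        [fit.params[out].to_numpy() for out in fit.params.columns]
    )[idx]
    V = fit.cov[np.ix_(idx, idx)]
    stat = float(beta @ np.linalg.solve(V, beta))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------- screening

def vif_screen(X: pd.DataFrame, limit: float = VIF_LIMIT) -> pd.Series:
    """Variance inflation factor per dummy-encoded predictor column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the others
    (with intercept).  Constant columns are an error; perfect
    collinearity reports ``inf``.
    """
    Xd, _ = _encode_design(pd.DataFrame(X))
    A = Xd.to_numpy(dtype=float)
    if A.shape[1] < 2:
        raise ValueError("need at least 2 predictors for a VIF screen")
    if np.any(A.std(axis=0) == 0):
        const = [c for c, s in zip(Xd.columns, A.std(axis=0)) if s == 0]
        raise ValueError(f"constant column(s) have undefined VIF: {const}")
    out = {}
    n = A.shape[0]
    ones = np.ones((n, 1))
    for j, col in enumerate(Xd.columns):
        yj = A[:, j]
        others = np.hstack([ones, np.delete(A, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


# ---------------------------------------------------------------- metrics

@dataclass
class ModelMetrics:
    accuracy: float
    auc: float
    confusion: pd.DataFrame

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.auc <= 1.0):
            raise ValueError("accuracy and AUC must lie in [0, 1]")


def model_metrics(
    fit: MultinomFit, X: pd.DataFrame, y, multiclass: str = "ovo"
) -> ModelMetrics:
    """In-sample accuracy, Hand-Till AUC and confusion matrix.

    ``multiclass='ovo'`` (default) is the Hand-Till average of pairwise
    one-vs-one AUCs; ``'ovr'`` gives the macro one-vs-rest average.
    """
    from sklearn.metrics import confusion_matrix, roc_auc_score

    Xd, _ = _encode_design(pd.DataFrame(X))
    proba = fit.predict_proba(Xd)
    y = np.asarray(y, dtype=object)
    codes = pd.Series(y).map(
        {lev: i for i, lev in enumerate(fit.outcome_levels)}
    ).to_numpy(dtype=int)
    pred = proba.argmax(axis=1)
    accuracy = float((pred == codes).mean())
    if len(set(codes)) < 2:
        auc = 0.5
    elif np.allclose(proba, proba[0]):
        auc = 0.5  # uninformative scores
    else:
        auc = float(
            roc_auc_score(codes, proba, multi_class=multiclass, average="macro")
        )
    conf = pd.DataFrame(
        confusion_matrix(codes, pred, labels=range(len(fit.outcome_levels))),
        index=fit.outcome_levels,
        columns=fit.outcome_levels,
    )
    return ModelMetrics(accuracy=accuracy, auc=auc, confusion=conf)


def univariate_table_fit(table: ContingencyTable) -> MultinomFit:
    """Univariate multinomial fit from a count table (counts expanded to
    individual rows; predictor dummy-coded against the table baseline)."""
    rows = expand_table(table)
    levels = [table.baseline] + [l for l in table.counts.index if l != table.baseline]
    X = pd.DataFrame({"level": pd.Categorical(rows["level"], categories=levels)})
    return fit_multinomial(rows["outcome"], X)
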