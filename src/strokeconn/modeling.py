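"""Incremental linear regression of NIHSS with a predictor cap and K-fold CV.

Models are ordinary least squares with intercept.  Model quality is reported
as R-squared, adjusted R-squared, AIC and BIC; AIC/BIC use the full Gaussian
log-likelihood (constants included) with the error variance counted as a free
parameter, so a model with k slope coefficients carries k + 2 parameters.
Forward selection adds, at each step, the candidate giving the largest
increase in training R-squared whose inclusion keeps every variance inflation
factor below the limit (default 2), up to a cap of five predictors — a
10-15 observations-per-predictor rule of thumb at n = 44.  Generalization is
assessed by 5-fold cross-validation with a shared random partition so that
per-fold scores of different models can be compared pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._ols import design_matrix, ols_beta, ols_r2, vif_from_matrix

#: Default outcome column in cohort tables.
OUTCOME = "nihss"


@dataclass
class RegressionFit:
    """An OLS fit: coefficients, fit statistics and residuals."""

    predictor_names: tuple[str, ...]
    coefficients: pd.Series  # index: ["intercept", *predictor_names]
    r_squared: float
    adjusted_r_squared: float
    aic: float
    bic: float
    residuals: np.ndarray
    log_likelihood: float
    n: int
    k: int


def fit_linear_model(
    table: pd.DataFrame,
    predictors: list[str],
    outcome: str = OUTCOME,
) -> RegressionFit:
    """OLS with intercept; an empty predictor list fits the intercept-only
    model (R-squared 0)."""
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    y = table[outcome].to_numpy(dtype=float)
    n, k = len(y), len(predictors)
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors")
    X = design_matrix(table, list(predictors))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        vifs = vif_from_matrix(X[:, 1:]) if k >= 2 else np.array([])
        bad = [p for p, v in zip(predictors, vifs) if np.isinf(v)] or list(
            predictors
        )
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    llf = float(res.llf)
    n_params = k + 2  # intercept + slopes + error variance
    aic = -2.0 * llf + 2.0 * n_params
    bic = -2.0 * llf + np.log(n) * n_params
    coef = pd.Series(res.params, index=["intercept", *predictors])
    r2 = float(res.rsquared) if k > 0 else 0.0
    adj = float(res.rsquared_adj) if k > 0 else 0.0
    return RegressionFit(
        predictor_names=tuple(predictors),
        coefficients=coef,
        r_squared=r2,
        adjusted_r_squared=adj,
        aic=float(aic),
        bic=float(bic),
        residuals=np.asarray(res.resid),
        log_likelihood=llf,
        n=n,
        k=k,
    )


def compute_vif(table: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factor of each predictor given the others.

    Perfectly collinear predictors are reported as ``inf``.
    """
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = np.column_stack([table[p].to_numpy(dtype=float) for p in predictors])
    return pd.Series(vif_from_matrix(X), index=list(predictors))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResult:
    """Per-fold out-of-sample R-squared and MSE plus their means.

    Fold R-squared is 1 - SSE/SST with SST taken about the held-out fold's
    own mean; it may be negative for models that generalize poorly.
    """

    fold_assignments: np.ndarray  # subject -> fold index
    per_fold_r_squared: np.ndarray
    per_fold_mse: np.ndarray
    cv_r_squared: float
    cv_mse: float
    seed: int


def kfold_partition(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition into k folds with sizes differing by at most one."""
    if n < k:
        raise ValueError(f"cannot split n={n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, idx in enumerate(np.array_split(perm, k)):
        assignments[idx] = fold
    return assignments


def kfold_cv(
    table: pd.DataFrame,
    predictors: list[str],
    k: int = 5,
    seed: int = 0,
    outcome: str = OUTCOME,
) -> CrossValidationResult:
    """K-fold CV: fit on k-1 folds, score the held-out fold; average."""
    y = table[outcome].to_numpy(dtype=float)
    n = len(y)
    assignments = kfold_partition(n, k, seed)
    X = design_matrix(table, list(predictors))
    r2s, mses = np.empty(k), np.empty(k)
    for fold in range(k):
        test = assignments == fold
        beta = ols_beta(X[~test], y[~test])
        pred = X[test] @ beta
        err = y[test] - pred
        sst = float(((y[test] - y[test].mean()) ** 2).sum())
        if sst == 0:
            raise ValueError(
                f"fold {fold} has zero outcome variance; re-seed the partition"
            )
        r2s[fold] = 1.0 - float((err**2).sum()) / sst
        mses[fold] = float((err**2).mean())
    return CrossValidationResult(
        fold_assignments=assignments,
        per_fold_r_squared=r2s,
        per_fold_mse=mses,
        cv_r_squared=float(r2s.mean()),
        cv_mse=float(mses.mean()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# greedy forward selection


@dataclass
class SelectionStep:
    added: str
    fit: RegressionFit
    cv: CrossValidationResult | None


@dataclass
class SelectionPath:
    """Forward-selection trajectory: the seed model plus one step per added
    predictor.  Training R-squared is non-decreasing along the path."""

    seed_predictors: tuple[str, ...]
    cap: int
    seed_fit: RegressionFit
    seed_cv: CrossValidationResult | None
    steps: list[SelectionStep] = field(default_factory=list)

    @property
    def selected_predictors(self) -> tuple[str, ...]:
        return self.seed_predictors + tuple(s.added for s in self.steps)

    @property
    def final_fit(self) -> RegressionFit:
        return self.steps[-1].fit if self.steps else self.seed_fit

    @property
    def final_cv(self) -> CrossValidationResult | None:
        return self.steps[-1].cv if self.steps else self.seed_cv


def greedy_forward_selection(
    table: pd.DataFrame,
    candidates: list[str],
    cap: int = 5,
    seed_predictors: list[str] | tuple[str, ...] = (),
    vif_limit: float = 2.0,
    outcome: str = OUTCOME,
    cv_seed: int | None = None,
    n_folds: int = 5,
) -> SelectionPath:
    """Add the admissible candidate with the largest R-squared increase until
    the cap is reached or no candidate improves the fit.

    A candidate is admissible if, after inclusion, every VIF in the model
    stays below ``vif_limit``.  Ties in R-squared are broken by candidate
    (canonical feature) order.  ``cv_seed`` enables per-step K-fold CV.
    """
    seed_predictors = tuple(seed_predictors)
    if cap < len(seed_predictors):
        raise ValueError("cap smaller than the number of seed predictors")
    overlap = set(candidates) & set(seed_predictors)
    if overlap:
        raise ValueError(f"candidates overlap seed predictors: {sorted(overlap)}")
    y = table[outcome].to_numpy(dtype=float)
    current = list(seed_predictors)
    cols = {
        p: table[p].to_numpy(dtype=float)
        for p in list(candidates) + current
    }

    def _cv(preds):
        if cv_seed is None:
            return None
        return kfold_cv(table, preds, k=n_folds, seed=cv_seed, outcome=outcome)

    seed_fit = fit_linear_model(table, current, outcome=outcome)
    path = SelectionPath(
        seed_predictors=seed_predictors,
        cap=cap,
        seed_fit=seed_fit,
        seed_cv=_cv(current),
    )
    remaining = list(candidates)
    current_r2 = seed_fit.r_squared
    n = len(y)
    while len(current) < cap and remaining:
        base_cols = [np.ones(n)] + [cols[p] for p in current]
        scores = np.empty(len(remaining))
        for i, cand in enumerate(remaining):
            X = np.column_stack(base_cols + [cols[cand]])
            try:
                scores[i] = ols_r2(X, y)
            except ValueError:
                scores[i] = -np.inf
        # walk candidates from best score down, first-in-order wins ties
        order = sorted(range(len(remaining)), key=lambda i: (-scores[i], i))
        chosen = None
        for i in order:
            if scores[i] <= current_r2 + 1e-12:
                break  # no remaining candidate increases R2
            trial = current + [remaining[i]]
            if len(trial) >= 2:
                X_nc = np.column_stack([cols[p] for p in trial])
                if not np.all(vif_from_matrix(X_nc) < vif_limit):
                    continue
            chosen = i
            break
        if chosen is None:
            break
        cand = remaining.pop(chosen)
        current.append(cand)
        current_r2 = scores[chosen]
        fit = fit_linear_model(table, current, outcome=outcome)
        path.steps.append(SelectionStep(added=cand, fit=fit, cv=_cv(current)))
    return path


# ---------------------------------------------------------------------------
# residual diagnostics


@dataclass
class NormalityCheck:
    w_statistic: float
    p_value: float
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def residual_normality_check(fit: RegressionFit) -> NormalityCheck:
    """Shapiro-Wilk test of residual normality plus Q-Q plot coordinates."""
    resid = np.asarray(fit.residuals, dtype=float)
    if resid.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(resid) == 0:
        raise ValueError("constant residuals: normality test undefined")
    w, p = stats.shapiro(resid)
    (theoretical, ordered), _ = stats.probplot(resid, dist="norm")
    return NormalityCheck(
        w_statistic=float(w),
        p_value=float(p),
        qq_theoretical=theoretical,
        qq_sample=ordered,
    )
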