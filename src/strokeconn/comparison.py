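"""Model comparison: fold-paired t-tests, AIC differences and likelihood
ratio tests between nested OLS fits.

The paired t-test compares per-fold cross-validated R-squared of two models
evaluated on the *same* fold partition; with 5 folds it has 4 degrees of
freedom and the folds are correlated, so p-values should be read as
descriptive (a Nadeau-Bengio variance correction is available).  For nested
Gaussian OLS fits the likelihood-ratio statistic relates to the AIC
difference exactly: chi2 = (AIC_nested - AIC_full) + 2 * df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .modeling import CrossValidationResult, RegressionFit


@dataclass(frozen=True)
class PairedTTestResult:
    t_statistic: float
    p_value: float
    df: int


@dataclass(frozen=True)
class LikelihoodRatioResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class ModelComparisonReport:
    """Pairwise comparison of two models fit to the same cohort."""

    model_a: str
    model_b: str
    delta_aic: float  # AIC_a - AIC_b; positive favors model b
    paired_t: PairedTTestResult | None = None
    lrt: LikelihoodRatioResult | None = None


def paired_fold_ttest(
    cv_a: CrossValidationResult,
    cv_b: CrossValidationResult,
    nadeau_bengio: bool = False,
    test_fraction: float | None = None,
) -> PairedTTestResult:
    """Two-sided paired t-test on per-fold R-squared differences (a - b).

    Requires both CV results to share the fold partition (same seed); pairing
    is meaningless otherwise.  ``nadeau_bengio`` inflates the variance by
    (1/K + n_test/n_train) to account for fold overlap.
    """
    if not np.array_equal(cv_a.fold_assignments, cv_b.fold_assignments):
        raise ValueError(
            "fold partitions differ; run both cross-validations with the "
            "same seed so folds are paired"
        )
    d = cv_a.per_fold_r_squared - cv_b.per_fold_r_squared
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 folds")
    if np.all(d == 0):
        return PairedTTestResult(t_statistic=0.0, p_value=1.0, df=k - 1)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance, nonzero fold differences: t undefined")
    scale = 1.0 / k
    if nadeau_bengio:
        rho = test_fraction if test_fraction is not None else 1.0 / (k - 1)
        scale = 1.0 / k + rho
    t = float(d.mean() / (sd * np.sqrt(scale)))
    p = float(2.0 * stats.t.sf(abs(t), df=k - 1))
    return PairedTTestResult(t_statistic=t, p_value=p, df=k - 1)


def likelihood_ratio_test(
    fit_nested: RegressionFit, fit_full: RegressionFit
) -> LikelihoodRatioResult:
    """LRT of a nested model against the full model it is contained in.

    chi2 = 2 (logL_full - logL_nested), df = number of added predictors.
    For identical predictor sets chi2 = 0 and p = 1.
    """
    nested = set(fit_nested.predictor_names)
    full = set(fit_full.predictor_names)
    if not nested <= full:
        raise ValueError(
            "models are not nested: nested predictors must be a subset of "
            "the full model's"
        )
    if fit_nested.n != fit_full.n:
        raise ValueError("models were fit to different numbers of subjects")
    chi2 = 2.0 * (fit_full.log_likelihood - fit_nested.log_likelihood)
    if chi2 < -1e-8:
        raise ValueError(
            "full-model likelihood below nested-model likelihood: fits are "
            "inconsistent"
        )
    chi2 = max(chi2, 0.0)
    df = fit_full.k - fit_nested.k
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LikelihoodRatioResult(chi2=float(chi2), df=df, p_value=p)


def delta_aic(fit_a: RegressionFit, fit_b: RegressionFit) -> float:
    """AIC_a - AIC_b; positive values favor model b."""
    if fit_a.n != fit_b.n:
        raise ValueError("models were fit to different numbers of subjects")
    return float(fit_a.aic - fit_b.aic)
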