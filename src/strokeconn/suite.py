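"""The seven-model analysis suite and its pairwise comparisons.

Rows mirror the study's model overview: lesion size only; the best single
connectivity predictor; incremental selection without / with lesion size; and
hemisphere-restricted incremental models (left, right, both).  All rows share
one cross-validation partition so per-fold scores are pairwise comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._ols import design_matrix, ols_r2
from .comparison import (
    LikelihoodRatioResult,
    ModelComparisonReport,
    delta_aic,
    likelihood_ratio_test,
    paired_fold_ttest,
)
from .modeling import (
    OUTCOME,
    CrossValidationResult,
    RegressionFit,
    SelectionPath,
    fit_linear_model,
    greedy_forward_selection,
    kfold_cv,
)

_FEATURE_RE = re.compile(
    r"^(intra\|[^|:]+:(left|right|both)"
    r"|inter\|[^|:]+:(left|right|both)\|[^|:]+:(left|right|both))$"
)

#: Canonical row order of the suite report.
ROW_ORDER = (
    "lesion_only",
    "best_connectivity_only",
    "best_without_lesion",
    "best_with_lesion",
    "left_hemisphere",
    "right_hemisphere",
    "both_hemispheres",
)

_ROW_LABELS = {
    "lesion_only": "Lesion Size Only",
    "best_connectivity_only": "Best Connectivity Predictor Only",
    "best_without_lesion": "Best Predictors Without Lesion Size",
    "best_with_lesion": "Best Predictors Including Lesion Size",
    "left_hemisphere": "Best Predictors for Left Hemisphere Only",
    "right_hemisphere": "Best Predictors for Right Hemisphere Only",
    "both_hemispheres": "Best Predictors for Both Hemispheres",
}

METRIC_COLUMNS = (
    "R-Squared",
    "Adjusted R-Squared",
    "AIC",
    "BIC",
    "Cross-Validated R-Squared",
    "Cross-Validated MSE",
)


def _scopes_of(feature: str) -> tuple[str, ...]:
    if not _FEATURE_RE.match(feature):
        raise ValueError(f"unparseable connectivity feature name: {feature!r}")
    return tuple(part.rsplit(":", 1)[1] for part in feature.split("|")[1:])


def candidate_sets_by_hemisphere(
    features: list[str], strict_both: bool = False
) -> dict[str, list[str]]:
    """Partition feature names by hemisphere scope.

    ``left``/``right``: features whose every scope tag is that hemisphere.
    ``both``: all features by default (the bilateral model may draw on any
    scope); with ``strict_both`` only features whose scopes are all ``both``.
    """
    out: dict[str, list[str]] = {"left": [], "right": [], "both": []}
    for f in features:
        scopes = set(_scopes_of(f))
        if scopes == {"left"}:
            out["left"].append(f)
        elif scopes == {"right"}:
            out["right"].append(f)
        if strict_both:
            if scopes == {"both"}:
                out["both"].append(f)
        else:
            out["both"].append(f)
    return out


@dataclass
class SuiteConfig:
    """Knobs of the model suite (defaults follow the study design)."""

    cap: int = 5
    n_folds: int = 5
    vif_limit: float = 2.0
    cv_seed: int = 0
    outcome: str = OUTCOME
    #: baseline predictor of the nested "primary-motor-only" model extended
    #: with left-hemisphere predictors in the likelihood-ratio test
    motor_baseline: str = "intra|MotorI:both"
    strict_both_scope: bool = False


@dataclass
class SuiteRow:
    name: str
    predictors: tuple[str, ...]
    fit: RegressionFit
    cv: CrossValidationResult
    path: SelectionPath | None = None

    def metrics(self) -> dict[str, float]:
        return {
            "R-Squared": self.fit.r_squared,
            "Adjusted R-Squared": self.fit.adjusted_r_squared,
            "AIC": self.fit.aic,
            "BIC": self.fit.bic,
            "Cross-Validated R-Squared": self.cv.cv_r_squared,
            "Cross-Validated MSE": self.cv.cv_mse,
        }


@dataclass
class ModelSuiteReport:
    rows: dict[str, SuiteRow]
    comparisons: dict[str, ModelComparisonReport]
    motor_lrt: LikelihoodRatioResult | None
    cv_seed: int

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            _ROW_LABELS[name]: self.rows[name].metrics() for name in ROW_ORDER
        }
        df = pd.DataFrame(data).T
        df.index.name = "Model Description"
        return df[list(METRIC_COLUMNS)]

    def to_markdown(self) -> str:
        df = self.to_dataframe().round(2)
        lines = [
            "| Model Description | " + " | ".join(METRIC_COLUMNS) + " |",
            "|" + "---|" * (len(METRIC_COLUMNS) + 1),
        ]
        for label, row in df.iterrows():
            cells = " | ".join(f"{v:.2f}" for v in row)
            lines.append(f"| {label} | {cells} |")
        return "\n".join(lines)


def _best_single_predictor(table, candidates, outcome) -> str:
    y = table[outcome].to_numpy(dtype=float)
    best_name, best_r2 = None, -np.inf
    for name in candidates:  # canonical order breaks ties
        r2 = ols_r2(design_matrix(table, [name]), y)
        if r2 > best_r2 + 1e-12:
            best_name, best_r2 = name, r2
    return best_name


def run_model_suite(
    cohort: pd.DataFrame, config: SuiteConfig | None = None
) -> ModelSuiteReport:
    """Fit all seven models on one cohort table and compare them.

    The cohort table must contain ``lesion_volume``, the full canonical
    connectivity feature set and the outcome column.  The report is a pure
    function of (cohort, config): folds, tie-breaks and selection are all
    deterministic under the configured seed.
    """
    if config is None:
        config = SuiteConfig()
    if "lesion_volume" not in cohort.columns:
        raise ValueError("cohort table lacks the lesion_volume column")
    features = [
        c
        for c in cohort.columns
        if c.startswith("intra|") or c.startswith("inter|")
    ]
    if not features:
        raise ValueError(
            "cohort table lacks connectivity features; extraction must "
            "provide intra|... and inter|... columns"
        )
    sets = candidate_sets_by_hemisphere(
        features, strict_both=config.strict_both_scope
    )
    for scope in ("left", "right"):
        if not sets[scope]:
            raise ValueError(
                f"no pure {scope}-hemisphere features present; extraction "
                "must provide all hemisphere scopes"
            )

    def _cv(predictors) -> CrossValidationResult:
        return kfold_cv(
            cohort,
            list(predictors),
            k=config.n_folds,
            seed=config.cv_seed,
            outcome=config.outcome,
        )

    def _greedy(candidates, seeds=()) -> SelectionPath:
        return greedy_forward_selection(
            cohort,
            list(candidates),
            cap=config.cap,
            seed_predictors=tuple(seeds),
            vif_limit=config.vif_limit,
            outcome=config.outcome,
        )

    rows: dict[str, SuiteRow] = {}

    def _add(name, predictors, path=None):
        fit = path.final_fit if path is not None else fit_linear_model(
            cohort, list(predictors), outcome=config.outcome
        )
        rows[name] = SuiteRow(
            name=name,
            predictors=tuple(predictors),
            fit=fit,
            cv=_cv(predictors),
            path=path,
        )

    _add("lesion_only", ("lesion_volume",))
    best_single = _best_single_predictor(cohort, features, config.outcome)
    _add("best_connectivity_only", (best_single,))
    for name, candidates, seeds in (
        ("best_without_lesion", features, ()),
        ("best_with_lesion", features, ("lesion_volume",)),
        ("left_hemisphere", sets["left"], ()),
        ("right_hemisphere", sets["right"], ()),
        ("both_hemispheres", sets["both"], ()),
    ):
        path = _greedy(candidates, seeds)
        _add(name, path.selected_predictors, path)

    comparisons: dict[str, ModelComparisonReport] = {}
    for key, a, b in (
        ("left_vs_right", "left_hemisphere", "right_hemisphere"),
        ("left_vs_both", "left_hemisphere", "both_hemispheres"),
        ("lesion_vs_combined", "lesion_only", "best_with_lesion"),
    ):
        comparisons[key] = ModelComparisonReport(
            model_a=a,
            model_b=b,
            delta_aic=delta_aic(rows[a].fit, rows[b].fit),
            paired_t=paired_fold_ttest(rows[a].cv, rows[b].cv),
        )

    # nested LRT: primary-motor-only baseline extended with left-hemisphere
    # incremental predictors
    motor_lrt = None
    if config.motor_baseline in cohort.columns:
        nested_fit = fit_linear_model(
            cohort, [config.motor_baseline], outcome=config.outcome
        )
        extended = _greedy(sets["left"], seeds=(config.motor_baseline,))
        motor_lrt = likelihood_ratio_test(nested_fit, extended.final_fit)

    return ModelSuiteReport(
        rows=rows,
        comparisons=comparisons,
        motor_lrt=motor_lrt,
        cv_seed=config.cv_seed,
    )
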