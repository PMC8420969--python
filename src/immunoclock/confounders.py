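"""One-by-one clinical-confounder regressions on the cross-validated
predictions.

For each candidate confounder, gestational age is regressed by ordinary
least squares on an intercept, the blinded elastic-net prediction, and that
single covariate:

    ga ~ b0 + b1 * prediction + b2 * covariate

Rows with a missing covariate value are excluded listwise.  Each
coefficient's significance is the partial F-test p-value (identical to the
squared-t test for a single coefficient): the *prediction p* asks whether
the model's predictions remain associated with GA once the covariate is
controlled for; the *confounder p* asks whether the covariate itself is
associated with GA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, ValidationError

__all__ = ["confounder_regression", "run_all_confounders", "DEFAULT_COVARIATES"]

#: the nine candidate clinical confounders, by cohort-table column.
DEFAULT_COVARIATES = (
    "sex",
    "steroid_interval_h",
    "rom_duration_h",
    "labor_duration_h",
    "gdm",
    "hba1c_pct",
    "preeclampsia",
    "severe_preeclampsia",
    "gbs",
)

COLLINEARITY_R = 0.999


def confounder_regression(ga, predictions, covariate, name: str = "covariate") -> dict:
    """OLS of GA on intercept + prediction + one covariate.

    Returns a dict with the coefficient estimates (``beta0``, ``beta1`` on
    the prediction, ``beta2`` on the covariate), the two partial-F
    p-values, the number of complete cases used, and a collinearity flag
    (p-values suppressed when |r(prediction, covariate)| > 0.999).
    """
    ga = np.asarray(ga, float)
    pred = np.asarray(predictions, float)
    cov = np.asarray(covariate, float)
    if not (ga.size == pred.size == cov.size):
        raise ValidationError("ga, predictions and covariate are misaligned")
    keep = np.isfinite(ga) & np.isfinite(pred) & np.isfinite(cov)
    n_used = int(keep.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"covariate {name!r}: only {n_used} complete cases after listwise deletion"
        )
    ga, pred, cov = ga[keep], pred[keep], cov[keep]

    collinear = False
    if np.std(cov) == 0.0 or np.std(pred) == 0.0:
        collinear = np.std(cov) == 0.0 and np.std(pred) == 0.0
    elif abs(np.corrcoef(pred, cov)[0, 1]) > COLLINEARITY_R:
        collinear = True

    design = sm.add_constant(np.column_stack([pred, cov]), has_constant="add")
    fit = sm.OLS(ga, design).fit()
    b0, b1, b2 = fit.params
    # partial F for one coefficient == squared-t; statsmodels' t p-values
    # are therefore exactly the partial-F p-values.
    p_pred, p_cov = fit.pvalues[1], fit.pvalues[2]
    if collinear:
        p_pred = p_cov = np.nan
    return {
        "covariate": name,
        "n_used": n_used,
        "beta0": float(b0),
        "beta1": float(b1),
        "beta2": float(b2),
        "prediction_p": float(p_pred) if np.isfinite(p_pred) else np.nan,
        "confounder_p": float(p_cov) if np.isfinite(p_cov) else np.nan,
        "collinear": bool(collinear),
    }


def run_all_confounders(
    cohort: pd.DataFrame, en_result, covariates=None
) -> pd.DataFrame:
    """One confounder regression per configured covariate.

    ``en_result`` is an :class:`~immunoclock.model.ImmuneAgeResults` (or
    anything with a ``predictions`` Series aligned to ``cohort.sample_id``).
    Binary covariates must already be coded 0/1; unknown statuses are NaN
    and fall to listwise deletion.  Results are sorted by covariate name.
    """
    covariates = tuple(covariates) if covariates is not None else DEFAULT_COVARIATES
    unknown = [c for c in covariates if c not in cohort.columns]
    if unknown:
        raise ValidationError(f"unknown covariates requested: {unknown}")
    pred = en_result.predictions
    cohort = cohort.set_index("sample_id") if "sample_id" in cohort.columns else cohort
    pred = pred.reindex(cohort.index)
    if pred.isna().any():
        raise ValidationError("predictions do not cover every cohort sample")
    rows = []
    for name in sorted(covariates):
        rows.append(
            confounder_regression(
                cohort["ga_weeks"].to_numpy(),
                pred.to_numpy(),
                cohort[name].to_numpy(float),
                name=name,
            )
        )
    return pd.DataFrame(rows).set_index("covariate")
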