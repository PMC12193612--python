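"""Indirect need-standardization of healthcare utilization.

Horizontal equity asks whether participants with equal medical need receive
equal utilization regardless of income. The indirect method proceeds in
three steps for each outcome (outpatient visits, inpatient episodes):

1. Fit a linear model Y = a + b'X + g'Z + e, with need factors X (gender,
   age, self-rated health) and non-need factors Z (income, education,
   marital status, urban/rural, region).
2. Predict the need-expected utilization Yhat_i = a + b'X_i + g'Zbar: need
   factors at observed values, every non-need factor at its sample mean.
3. Standardize: Y_s = Y_i - Yhat_i + Ybar, with Ybar the overall actual
   mean. For least squares with an intercept the grand mean of Y_s equals
   the grand mean of Y exactly.

Per income quintile the actual, expected and standardized means are
tabulated with a coverage ratio 100 * actual / expected; a ratio below 100%
flags under-utilization relative to need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ParameterError
from .cardinalization import signed_log1p
from .cohort import REGION_LEVELS
from .inequality import QUINTILE_LABELS, quintile_assign

__all__ = [
    "NEED_FACTORS",
    "NONNEED_FACTORS",
    "OUTCOME_COLUMNS",
    "NeedModelFit",
    "fit_need_model",
    "expected_utilization",
    "standardize_utilization",
    "utilization_table",
]

NEED_FACTORS = ("gender", "age", "srh")
NONNEED_FACTORS = ("log_income", "education_years", "marital", "urban", "region")

OUTCOME_COLUMNS = {"outpatient": "outpatient_visits", "inpatient": "inpatient_episodes"}


@dataclass
class NeedModelFit:
    """Least-squares utilization model split into need / non-need factors."""

    outcome: str
    intercept: float
    need_coefficients: dict[str, float]
    nonneed_coefficients: dict[str, float]
    std_errors: dict[str, float]
    residual_sd: float
    r_squared: float
    n: int


def _design(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    need_cols = list(NEED_FACTORS)
    X = pd.DataFrame(
        {c: pd.to_numeric(cohort[c]).astype(float).to_numpy() for c in need_cols}
    )
    nonneed_cols: list[str] = []
    for col in NONNEED_FACTORS:
        if col == "log_income":
            X[col] = signed_log1p(cohort["income_initial"].to_numpy(dtype=float))
            nonneed_cols.append(col)
        elif col == "region":
            region = cohort["region"].to_numpy()
            for level in REGION_LEVELS[1:]:
                name = f"region_{level}"
                X[name] = (region == level).astype(float)
                nonneed_cols.append(name)
        else:
            X[col] = pd.to_numeric(cohort[col]).astype(float).to_numpy()
            nonneed_cols.append(col)
    return X, need_cols, nonneed_cols


def fit_need_model(cohort: pd.DataFrame, outcome: str) -> NeedModelFit:
    """Fit the linear utilization model for one outcome.

    ``outcome`` is ``"outpatient"`` or ``"inpatient"``. Income enters the
    non-need set as log(1 + income).

    Raises
    ------
    ParameterError
        On an unknown outcome or a rank-deficient design (listing the
        collinear columns).
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ParameterError(f"outcome must be one of {tuple(OUTCOME_COLUMNS)}, got {outcome!r}")
    y = cohort[OUTCOME_COLUMNS[outcome]].to_numpy(dtype=float)
    X, need_cols, nonneed_cols = _design(cohort)
    Xc = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify columns involved in the deficiency by leave-one-out rank
        collinear = [
            c for c in X.columns
            if np.linalg.matrix_rank(Xc.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ParameterError(f"rank-deficient utilization design; collinear columns: {collinear}")
    res = sm.OLS(y, Xc).fit()
    return NeedModelFit(
        outcome=outcome,
        intercept=float(res.params["const"]),
        need_coefficients={c: float(res.params[c]) for c in need_cols},
        nonneed_coefficients={c: float(res.params[c]) for c in nonneed_cols},
        std_errors={c: float(res.bse[c]) for c in Xc.columns},
        residual_sd=float(np.sqrt(res.mse_resid)),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
    )


def expected_utilization(fit: NeedModelFit, cohort: pd.DataFrame) -> np.ndarray:
    """Need-expected utilization: need factors observed, non-need at means.

    Two participants identical in need factors get identical expectations
    regardless of income; the mean expectation equals the actual mean (an
    exact least-squares identity).
    """
    X, need_cols, nonneed_cols = _design(cohort)
    yhat = np.full(len(X), fit.intercept)
    for c in need_cols:
        yhat = yhat + fit.need_coefficients[c] * X[c].to_numpy()
    for c in nonneed_cols:
        yhat = yhat + fit.nonneed_coefficients[c] * X[c].to_numpy().mean()
    return yhat


def standardize_utilization(actual: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Indirectly standardized utilization Y_s = Y - Yhat + Ybar."""
    actual = np.asarray(actual, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if actual.shape != expected.shape:
        raise ParameterError("actual and expected utilization differ in length")
    return actual - expected + actual.mean()


def utilization_table(
    cohort: pd.DataFrame, quintiles: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-quintile actual / need-expected / standardized utilization.

    One row per income quintile (of initial income); for each outcome the
    actual, expected and standardized group means plus the coverage ratio
    100 * actual_mean / expected_mean (NaN where the expected mean is not
    positive).
    """
    if quintiles is None:
        quintiles = quintile_assign(cohort["income_initial"].to_numpy(dtype=float))
    quintiles = np.asarray(quintiles, dtype=object)

    rows: dict[str, dict[str, float]] = {q: {} for q in QUINTILE_LABELS}
    for outcome, col in OUTCOME_COLUMNS.items():
        fit = fit_need_model(cohort, outcome)
        actual = cohort[col].to_numpy(dtype=float)
        expected = expected_utilization(fit, cohort)
        standardized = standardize_utilization(actual, expected)
        for q in QUINTILE_LABELS:
            mask = quintiles == q
            if not mask.any():
                for part in ("actual", "expected", "standardized", "coverage_ratio_pct"):
                    rows[q][f"{outcome}_{part}"] = np.nan
                continue
            a, e, s = actual[mask].mean(), expected[mask].mean(), standardized[mask].mean()
            rows[q][f"{outcome}_actual"] = a
            rows[q][f"{outcome}_expected"] = e
            rows[q][f"{outcome}_standardized"] = s
            rows[q][f"{outcome}_coverage_ratio_pct"] = 100.0 * a / e if e > 0 else np.nan
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "income_quintile"
    return table.loc[list(QUINTILE_LABELS)]
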