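"""Cardinalization of ordinal self-rated health (SRH).

The concentration index needs a cardinal health variable, but survey SRH is
ordinal. Following the interval-regression / latent-index tradition, we fit
an ordered probit

    H* = b1 * f(income) + b'X + e,   e ~ N(0, 1)

of SRH on the stage income (entering as log(1 + income), or a signed log for
stage incomes that can go negative) and the standard control set (gender,
age, education years, marital status, region), predict the linear latent
index Xb for every participant, and min-max rescale it to [0, 1]:

    SaH_i = (H_i - min H) / (max H - min H).

The predicted index is unbounded; rescaling uses the in-sample extrema, so
at least one participant attains 0 and one attains 1 and the ordering of
SaH equals the ordering of the latent index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .exceptions import (
    DegenerateInputError,
    DegenerateOutcomeError,
    NonConvergenceError,
    SchemaError,
)
from .cohort import REGION_LEVELS

__all__ = [
    "OrderedProbitFit",
    "CardinalHealth",
    "CONTROL_COLUMNS",
    "signed_log1p",
    "build_design",
    "fit_ordered_probit",
    "predict_latent",
    "rescale_unit",
    "cardinalize",
]

#: Control variables entering the ordered probit: gender, age, education
#: years, marital status and region (region expanded to dummies).
CONTROL_COLUMNS = ("gender", "age", "education_years", "marital", "region")

INCOME_COLUMN = "log_income"


def signed_log1p(x: np.ndarray) -> np.ndarray:
    """Signed log transform sign(x)*log(1+|x|).

    Equals log1p(x) for x >= 0 and extends it smoothly to the negative
    stage incomes that can arise after out-of-pocket spending.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


@dataclass
class OrderedProbitFit:
    """A fitted ordered probit of SRH on stage income and controls."""

    coefficients: dict[str, float]
    cutpoints: np.ndarray
    converged: bool
    loglik: float
    n_obs: int
    exog_columns: tuple[str, ...]
    bse: dict[str, float]

    def coef_table(self) -> pd.DataFrame:
        """Coefficient/SE table, exportable as delimited text."""
        return pd.DataFrame(
            {
                "coef": [self.coefficients[c] for c in self.exog_columns],
                "se": [self.bse[c] for c in self.exog_columns],
            },
            index=list(self.exog_columns),
        )


@dataclass
class CardinalHealth:
    """Latent health index and its [0, 1] min-max rescaling."""

    latent: np.ndarray
    sah: np.ndarray
    latent_min: float
    latent_max: float


def build_design(income_stage: np.ndarray, controls: pd.DataFrame) -> pd.DataFrame:
    """Design matrix: transformed stage income plus controls.

    Region is expanded to dummies with the first level as reference; any
    level outside the known coding raises :class:`SchemaError`.
    """
    X = pd.DataFrame({INCOME_COLUMN: signed_log1p(np.asarray(income_stage, dtype=float))})
    for col in controls.columns:
        if col == "region":
            region = controls["region"].to_numpy()
            unknown = ~np.isin(region, REGION_LEVELS)
            if unknown.any():
                bad = region[unknown][0]
                raise SchemaError(f"column 'region': unseen level {bad!r}")
            for level in REGION_LEVELS[1:]:
                X[f"region_{level}"] = (region == level).astype(float)
        else:
            X[col] = pd.to_numeric(controls[col]).astype(float).to_numpy()
    X.index = pd.RangeIndex(len(X))
    return X


def fit_ordered_probit(
    srh: np.ndarray,
    income_stage: np.ndarray,
    controls: pd.DataFrame,
    maxiter: int = 200,
    gtol: float = 1e-8,
) -> OrderedProbitFit:
    """Maximum-likelihood ordered probit of SRH on stage income + controls.

    With two observed SRH levels this reduces to a binary probit. A
    non-converged optimizer is reported via ``converged=False`` rather than
    silently returning a degraded fit.

    Raises
    ------
    DegenerateOutcomeError
        If fewer than two SRH levels are observed.
    """
    srh = np.asarray(srh)
    if len(np.unique(srh)) < 2:
        raise DegenerateOutcomeError(
            "ordered probit needs >= 2 observed SRH levels, got a constant outcome"
        )
    X = build_design(income_stage, controls)
    if X.isna().to_numpy().any():
        raise SchemaError("missing covariate values in ordered-probit design")

    model = OrderedModel(pd.Series(srh).astype(int).to_numpy(), X, distr="probit")
    try:
        res = model.fit(method="newton", maxiter=maxiter, tol=gtol, disp=False)
    except np.linalg.LinAlgError:
        # singular Hessian step: fall back to quasi-Newton
        res = model.fit(method="bfgs", maxiter=maxiter, gtol=gtol, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    k = X.shape[1]
    beta = np.asarray(res.params)[:k]
    bse = np.asarray(res.bse)[:k]
    cutpoints = np.asarray(model.transform_threshold_params(res.params))[1:-1]
    return OrderedProbitFit(
        coefficients=dict(zip(X.columns, beta)),
        cutpoints=cutpoints,
        converged=converged,
        loglik=float(res.llf),
        n_obs=len(srh),
        exog_columns=tuple(X.columns),
        bse=dict(zip(X.columns, bse)),
    )


def predict_latent(
    fit: OrderedProbitFit, income_stage: np.ndarray, controls: pd.DataFrame
) -> np.ndarray:
    """Linear latent index Xb per participant (cutpoints excluded).

    The index is unbounded; it is the input to :func:`rescale_unit`.

    Raises
    ------
    NonConvergenceError
        If the fit did not converge (downstream use would be unreliable).
    """
    if not fit.converged:
        raise NonConvergenceError(
            "refusing to predict from a non-converged ordered probit",
            diagnostics={"loglik": fit.loglik, "n_obs": fit.n_obs},
        )
    X = build_design(income_stage, controls)
    if tuple(X.columns) != fit.exog_columns:
        raise SchemaError(
            f"design columns {tuple(X.columns)} do not match fitted model {fit.exog_columns}"
        )
    beta = np.array([fit.coefficients[c] for c in fit.exog_columns])
    return X.to_numpy() @ beta


def rescale_unit(latent: np.ndarray) -> CardinalHealth:
    """Min-max rescale a latent vector to [0, 1] using its sample extrema.

    Invariant to positive affine transformations of the latent scale.

    Raises
    ------
    DegenerateInputError
        If the latent vector is constant (extrema coincide).
    """
    latent = np.asarray(latent, dtype=float)
    lo, hi = float(latent.min()), float(latent.max())
    if hi <= lo:
        raise DegenerateInputError("constant latent health cannot be min-max rescaled")
    return CardinalHealth(
        latent=latent, sah=(latent - lo) / (hi - lo), latent_min=lo, latent_max=hi
    )


def cardinalize(
    cohort: pd.DataFrame,
    income_stage: np.ndarray,
    fit: OrderedProbitFit | None = None,
) -> tuple[CardinalHealth, OrderedProbitFit]:
    """Fit (unless given), predict and rescale in one step.

    Convenience wrapper used by the stage pipeline: ``fit`` may be passed to
    hold the model fixed across stages while re-predicting with a different
    stage income.
    """
    controls = cohort.loc[:, list(CONTROL_COLUMNS)]
    if fit is None:
        fit = fit_ordered_probit(cohort["srh"].to_numpy(), income_stage, controls)
    latent = predict_latent(fit, income_stage, controls)
    return rescale_unit(latent), fit
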