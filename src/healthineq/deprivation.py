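"""Relative deprivation of health (Yitzhaki/Kakwani index).

For a health distribution x_1 <= ... <= x_n with mean u, participant i's
mean-normalized relative deprivation is

    RD(x_i) = (1 / (n u)) * sum_j max(x_j - x_i, 0)
            = (1 / u) * r+_i * (u+_i - x_i),

where r+_i is the share of participants strictly healthier than i and u+_i
their mean health. RD is 0 for anyone at the maximum, non-increasing in own
health, and its population mean equals the Gini coefficient of health
(Yitzhaki's identity).

The regression companion mirrors the common presentation: OLS of RD on
income-quintile dummies (lowest quintile as reference), with and without
the standard demographic controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ParameterError, UndefinedIndexError
from .cohort import REGION_LEVELS
from .inequality import QUINTILE_LABELS

__all__ = ["RDResult", "RDRegression", "relative_deprivation", "rd_regression"]

#: Controls for the with-controls RD specification.
RD_CONTROLS = ("gender", "age", "education_years", "marital", "region")


@dataclass
class RDResult:
    """Per-participant relative deprivation and its decomposition parts."""

    rd: np.ndarray            # mean-normalized deprivation, >= 0
    mean_health: float        # u
    count_above: np.ndarray   # n+_i: participants strictly healthier than i
    share_above: np.ndarray   # r+_i
    mean_above: np.ndarray    # u+_i (own health where no one is above, so the term vanishes)


@dataclass
class RDRegression:
    """OLS of relative deprivation on quintile dummies (+ controls)."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    intercept_se: float
    n: int
    with_controls: bool
    r_squared: float


def relative_deprivation(health: np.ndarray) -> RDResult:
    """Mean-normalized relative deprivation of each participant.

    Computed with the decomposed formula via sorting and suffix sums,
    O(n log n); identical (to machine precision) to the O(n^2) pairwise sum
    of positive shortfalls divided by n*u.

    Raises
    ------
    UndefinedIndexError
        If mean health is not strictly positive.
    """
    x = np.asarray(health, dtype=float)
    if x.size == 0:
        raise ParameterError("empty health vector")
    u = x.mean()
    if u <= 0:
        raise UndefinedIndexError(f"mean health must be > 0 for RD, got {u}")
    n = x.size
    xs = np.sort(x)
    suffix = np.concatenate([np.cumsum(xs[::-1])[::-1], [0.0]])  # suffix[k] = sum xs[k:]
    pos = np.searchsorted(xs, x, side="right")                    # count <= x_i
    count_above = n - pos
    sum_above = suffix[pos]
    share_above = count_above / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_above = np.where(count_above > 0, sum_above / np.maximum(count_above, 1), x)
    rd = (sum_above - count_above * x) / (n * u)
    rd = np.maximum(rd, 0.0)   # clip -0.0 / rounding dust at the top rank
    return RDResult(
        rd=rd,
        mean_health=float(u),
        count_above=count_above,
        share_above=share_above,
        mean_above=mean_above,
    )


def _quintile_dummies(quintiles: np.ndarray) -> pd.DataFrame:
    labels = np.asarray(quintiles, dtype=object)
    unknown = ~np.isin(labels, QUINTILE_LABELS)
    if unknown.any():
        raise ParameterError(f"unknown quintile label {labels[unknown][0]!r}")
    out = pd.DataFrame(
        {f"q_{q}": (labels == q).astype(float) for q in QUINTILE_LABELS[1:]}
    )
    return out


def rd_regression(
    rd: np.ndarray,
    quintiles: np.ndarray,
    controls: pd.DataFrame | None = None,
    with_controls: bool = False,
) -> RDRegression:
    """OLS of RD on income-quintile dummies, lowest quintile as reference.

    ``with_controls=True`` adds gender, age, education years, marital status
    and region dummies. Conventional (non-robust) standard errors.

    Raises
    ------
    ParameterError
        On collinear regressors (rank-deficient design).
    """
    y = np.asarray(rd, dtype=float)
    X = _quintile_dummies(quintiles)
    if with_controls:
        if controls is None:
            raise ParameterError("with_controls=True requires a controls table")
        for col in RD_CONTROLS:
            if col == "region":
                region = controls["region"].to_numpy()
                for level in REGION_LEVELS[1:]:
                    X[f"region_{level}"] = (region == level).astype(float)
            else:
                X[col] = pd.to_numeric(controls[col]).astype(float).to_numpy()
    X = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ParameterError(
            f"collinear regressors: design rank {rank} < {X.shape[1]} columns"
        )
    res = sm.OLS(y, X).fit()
    names = [c for c in X.columns if c != "const"]
    return RDRegression(
        coefficients={c: float(res.params[c]) for c in names},
        std_errors={c: float(res.bse[c]) for c in names},
        p_values={c: float(res.pvalues[c]) for c in names},
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        n=int(res.nobs),
        with_controls=with_controls,
        r_squared=float(res.rsquared),
    )
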