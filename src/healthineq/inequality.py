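"""Concentration and Erreygers indices over insurance-stage incomes.

The concentration index (CI) of a health variable h over fractional income
ranks R is

    CI = (2 / mean(h)) * cov(h, R),

with cov the population (1/n) covariance — equivalent, for untied ranks, to
the summation form (2/(n*mean(h))) * sum_i h_i R_i - 1. Positive CI means
health is concentrated among the rich ("pro-rich").

The Erreygers corrected index for a health variable bounded in
[h_min, h_max] is

    EI = (1/n) * sum_i [4 h_i / (h_max - h_min)] * (2 R_i - 1),

which for [0, 1]-bounded health and untied ranks equals 4 * mean(h) * CI.

An insurance scheme with a flat premium, out-of-pocket treatment spending
and partial reimbursement induces four income states per participant —
initial, post-contribution, post-treatment, post-reimbursement. Re-ranking
participants at each stage and recomputing the indices quantifies how each
segment moves income-related health inequality; the headline quantity is
delta_total = CI_initial - CI_reimbursement (negative = the scheme widened
inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ParameterError, UndefinedIndexError
from .cardinalization import CardinalHealth, OrderedProbitFit, cardinalize

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "QUINTILE_LABELS",
    "FractionalRanks",
    "StageIncomes",
    "CIResult",
    "DeltaResult",
    "BootstrapResult",
    "fractional_rank",
    "concentration_index",
    "erreygers_index",
    "build_stage_incomes",
    "quintile_assign",
    "bootstrap_se",
    "segment_pipeline",
    "subgroup_ci",
]

STAGES = ("initial", "contribution", "treatment", "reimbursement")

#: Income quintile labels, poorest to richest.
QUINTILE_LABELS = ("low", "lower_middle", "middle", "upper_middle", "high")


@dataclass
class FractionalRanks:
    """Fractional ranks (i - 0.5)/n with tie-averaging; mean exactly 0.5."""

    rank: np.ndarray
    n: int


@dataclass
class StageIncomes:
    """Per-participant income at the four insurance stages."""

    initial: np.ndarray
    contribution: np.ndarray
    treatment: np.ndarray
    reimbursement: np.ndarray

    def stage(self, name: str) -> np.ndarray:
        if name not in STAGES:
            raise ParameterError(f"unknown stage {name!r}; expected one of {STAGES}")
        return getattr(self, name)


@dataclass
class CIResult:
    """A concentration-type index value with its context."""

    index_value: float
    index_kind: str                 # "standard" | "erreygers"
    stage: str
    group: str
    mean_health: float
    n: int
    se_boot: float | None = None
    p_boot: float | None = None


@dataclass
class DeltaResult:
    """Stage-to-stage CI differences; positive delta = inequality narrowed."""

    delta_contribution: float       # CI_initial - CI_contribution
    delta_treatment: float          # CI_contribution - CI_treatment
    delta_reimbursement: float      # CI_treatment - CI_reimbursement
    delta_total: float              # CI_initial - CI_reimbursement


@dataclass
class BootstrapResult:
    se: float
    p_value: float
    B: int
    n_degenerate_redrawn: int = 0
    low_precision: bool = False
    estimates: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def fractional_rank(values: np.ndarray) -> FractionalRanks:
    """Ascending fractional ranks (i - 0.5)/n, tied values averaged."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot rank an empty vector")
    r = (rankdata(values, method="average") - 0.5) / values.size
    return FractionalRanks(rank=r, n=values.size)


def _as_rank(ranks: FractionalRanks | np.ndarray) -> np.ndarray:
    return ranks.rank if isinstance(ranks, FractionalRanks) else np.asarray(ranks, dtype=float)


def concentration_index(
    health: np.ndarray,
    ranks: FractionalRanks | np.ndarray,
    stage: str = "",
    group: str = "total",
) -> CIResult:
    """Standard concentration index 2*cov(h, R)/mean(h).

    Uses the population (1/n) covariance, matching the summation form.

    Raises
    ------
    UndefinedIndexError
        If mean health is not strictly positive.
    """
    h = np.asarray(health, dtype=float)
    r = _as_rank(ranks)
    if h.shape != r.shape:
        raise ParameterError(f"health ({h.shape}) and ranks ({r.shape}) differ in length")
    hbar = h.mean()
    if hbar <= 0:
        raise UndefinedIndexError(f"mean health must be > 0 for the CI, got {hbar}")
    cov = np.mean((h - hbar) * (r - r.mean()))
    return CIResult(
        index_value=2.0 * cov / hbar,
        index_kind="standard",
        stage=stage,
        group=group,
        mean_health=float(hbar),
        n=h.size,
    )


def erreygers_index(
    health: np.ndarray,
    ranks: FractionalRanks | np.ndarray,
    h_min: float = 0.0,
    h_max: float = 1.0,
    stage: str = "",
    group: str = "total",
) -> CIResult:
    """Erreygers corrected concentration index for bounded health.

    EI = (1/n) sum_i [4 h_i / (h_max - h_min)] (2 R_i - 1).
    """
    h = np.asarray(health, dtype=float)
    r = _as_rank(ranks)
    if h_min >= h_max:
        raise ParameterError(f"h_min ({h_min}) must be < h_max ({h_max})")
    tol = 1e-9 * max(1.0, abs(h_max - h_min))
    if (h < h_min - tol).any() or (h > h_max + tol).any():
        raise ParameterError(f"health values outside bounds [{h_min}, {h_max}]")
    ei = np.mean(4.0 * h / (h_max - h_min) * (2.0 * r - 1.0))
    return CIResult(
        index_value=float(ei),
        index_kind="erreygers",
        stage=stage,
        group=group,
        mean_health=float(h.mean()),
        n=h.size,
    )


def build_stage_incomes(cohort: pd.DataFrame) -> StageIncomes:
    """The four per-participant income vectors implied by the scheme.

    initial -> -premium -> -out-of-pocket spending -> +reimbursement.
    Negative post-treatment incomes are permitted (ranking stays defined).
    """
    initial = cohort["income_initial"].to_numpy(dtype=float)
    premium = cohort["premium"].to_numpy(dtype=float)
    oop = cohort["oop_spend"].to_numpy(dtype=float)
    reimb = cohort["reimbursement"].to_numpy(dtype=float)
    excess = reimb - oop
    if (excess > 1e-9 * np.maximum(1.0, oop)).any():
        i = int(np.flatnonzero(excess > 1e-9 * np.maximum(1.0, oop))[0])
        raise ParameterError(f"reimbursement exceeds oop_spend at row {i}")
    contribution = initial - premium
    treatment = contribution - oop
    reimbursement = treatment + reimb
    return StageIncomes(initial, contribution, treatment, reimbursement)


def quintile_assign(income: np.ndarray) -> np.ndarray:
    """Assign income quintile labels (:data:`QUINTILE_LABELS`).

    Cut at the 20/40/60/80th percentiles; values tied with a boundary go to
    the lower group. With an all-constant income everyone lands in the
    lowest group (a warning is logged).
    """
    income = np.asarray(income, dtype=float)
    if income.size < 5:
        raise ParameterError(f"need n >= 5 for quintiles, got {income.size}")
    boundaries = np.quantile(income, [0.2, 0.4, 0.6, 0.8])
    idx = np.searchsorted(boundaries, income, side="left")
    if np.unique(income).size == 1:
        logger.warning("constant income vector: all participants assigned to lowest quintile")
    return np.array(QUINTILE_LABELS, dtype=object)[idx]


def bootstrap_se(
    statistic: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    B: int = 200,
    seed: int | None = None,
    health_column: str | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap (resampling individuals) of a statistic.

    Returns the bootstrap SE and a two-sided percentile p-value against 0.
    Resamples in which the health column is constant (the index undefined)
    are redrawn and counted. ``B < 50`` is flagged ``low_precision``.
    """
    if B < 2:
        raise ParameterError(f"bootstrap needs B >= 2, got {B}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    estimates = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            sample = cohort.iloc[idx].reset_index(drop=True)
            if health_column is not None and sample[health_column].nunique() < 2:
                n_redrawn += 1
                continue
            try:
                estimates[b] = statistic(sample)
            except UndefinedIndexError:
                n_redrawn += 1
                continue
            break
        else:
            raise ParameterError("bootstrap: 100 consecutive degenerate resamples")
    if n_redrawn:
        logger.info("bootstrap: %d degenerate resamples redrawn", n_redrawn)
    se = float(estimates.std(ddof=1))
    p = 2.0 * min(np.mean(estimates <= 0.0), np.mean(estimates >= 0.0))
    return BootstrapResult(
        se=se,
        p_value=float(min(p, 1.0)),
        B=B,
        n_degenerate_redrawn=n_redrawn,
        low_precision=B < 50,
        estimates=estimates,
    )


def _ci_pair(
    sah: np.ndarray, stage_income: np.ndarray, stage: str, group: str
) -> tuple[CIResult, CIResult]:
    ranks = fractional_rank(stage_income)
    ci = concentration_index(sah, ranks, stage=stage, group=group)
    ei = erreygers_index(sah, ranks, 0.0, 1.0, stage=stage, group=group)
    return ci, ei


def segment_pipeline(
    cohort: pd.DataFrame,
    mode: str = "per_stage",
    bootstrap_B: int = 0,
    seed: int | None = None,
) -> tuple[list[CIResult], DeltaResult]:
    """Full four-stage inequality computation on one cohort.

    For each stage the cohort is cardinalized (``mode="per_stage"`` refits
    the ordered probit with that stage's income; ``mode="fixed"`` fits once
    on initial income and holds SaH constant so only the ranking changes),
    the stage income is ranked, and the standard CI and the Erreygers EI
    (bounds [0, 1]) are computed. Stage deltas are consecutive CI
    differences; ``delta_total = CI_initial - CI_reimbursement``, negative
    when the scheme widened inequality.

    With ``bootstrap_B > 0`` every CI/EI gets a seeded bootstrap SE and
    two-sided p-value (the cardinalization is held fixed within resamples).

    Returns
    -------
    (results, deltas)
        ``results`` holds a standard and an Erreygers :class:`CIResult` for
        each of the four stages, in stage order.
    """
    if mode not in ("per_stage", "fixed"):
        raise ParameterError(f"mode must be 'per_stage' or 'fixed', got {mode!r}")
    stage_incomes = build_stage_incomes(cohort)

    sah_by_stage: dict[str, np.ndarray] = {}
    fit: OrderedProbitFit | None = None
    for stage in STAGES:
        inc = stage_incomes.stage(stage)
        if mode == "fixed":
            if fit is None:
                card, fit = cardinalize(cohort, stage_incomes.initial)
                sah_fixed = card.sah
            sah_by_stage[stage] = sah_fixed
        else:
            card, _ = cardinalize(cohort, inc)
            sah_by_stage[stage] = card.sah

    results: list[CIResult] = []
    ci_by_stage: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for stage in STAGES:
        inc = stage_incomes.stage(stage)
        ci, ei = _ci_pair(sah_by_stage[stage], inc, stage, "total")
        ci_by_stage[stage] = ci.index_value
        if bootstrap_B > 0:
            frame = pd.DataFrame({"sah": sah_by_stage[stage], "income": inc})
            for res in (ci, ei):
                kind = res.index_kind

                def stat(df: pd.DataFrame, kind: str = kind) -> float:
                    r = fractional_rank(df["income"].to_numpy())
                    h = df["sah"].to_numpy()
                    if kind == "standard":
                        return concentration_index(h, r).index_value
                    return erreygers_index(h, r, 0.0, 1.0).index_value

                boot = bootstrap_se(
                    stat, frame, B=bootstrap_B, seed=int(rng.integers(2**31)),
                    health_column="sah",
                )
                res.se_boot, res.p_boot = boot.se, boot.p_value
        results.extend([ci, ei])

    deltas = DeltaResult(
        delta_contribution=ci_by_stage["initial"] - ci_by_stage["contribution"],
        delta_treatment=ci_by_stage["contribution"] - ci_by_stage["treatment"],
        delta_reimbursement=ci_by_stage["treatment"] - ci_by_stage["reimbursement"],
        delta_total=ci_by_stage["initial"] - ci_by_stage["reimbursement"],
    )
    return results, deltas


def subgroup_ci(
    cohort: pd.DataFrame,
    grouping: str,
    stage: str = "initial",
    health: np.ndarray | Sequence[float] | None = None,
    mode: str = "fixed",
    index_kind: str = "standard",
) -> list[CIResult]:
    """Per-subgroup concentration indices at one insurance stage.

    ``grouping`` is ``"income_quintile"`` (quintiles of initial income, held
    fixed across stages), ``"gender"`` or ``"education_group"``. Fractional
    ranks are recomputed *within* each subgroup on that stage's income.

    ``health`` may supply precomputed health values (e.g. SaH from a single
    cardinalization, or raw SRH scores); by default the cohort is
    cardinalized per ``mode`` (``fixed``: one fit on initial income;
    ``per_stage``: refit with the requested stage's income).

    Subgroups with fewer than 2 members are skipped with a warning.
    """
    stage_incomes = build_stage_incomes(cohort)
    inc = stage_incomes.stage(stage)
    if health is None:
        fit_income = stage_incomes.initial if mode == "fixed" else inc
        card, _ = cardinalize(cohort, fit_income)
        health = card.sah
    health = np.asarray(health, dtype=float)

    if grouping == "income_quintile":
        labels = quintile_assign(stage_incomes.initial)
    elif grouping == "gender":
        labels = np.where(cohort["gender"].to_numpy() == 1, "female", "male")
    elif grouping == "education_group":
        labels = cohort["education_group"].to_numpy()
    else:
        raise ParameterError(f"unknown grouping {grouping!r}")

    out: list[CIResult] = []
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() < 2:
            logger.warning("subgroup %r has < 2 members at stage %s; skipped", g, stage)
            continue
        ranks = fractional_rank(inc[mask])
        if index_kind == "standard":
            out.append(concentration_index(health[mask], ranks, stage=stage, group=str(g)))
        else:
            out.append(erreygers_index(health[mask], ranks, 0.0, 1.0, stage=stage, group=str(g)))
    return out
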