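"""Synthetic survey cohort generator and cohort file I/O.

Emulates the microdata structure of a household-finance-style survey of
urban–rural resident basic medical insurance (URRBMI) participants: an
ordinal 5-level self-rated health (SRH) outcome driven by an income-graded
latent process, per-capita household income, fixed insurance premiums with
subsidies for a low-income tail, income- and need-graded outpatient /
inpatient utilization, out-of-pocket medical spending, and partial
reimbursement of that spending.

The generator exists for two purposes: (i) exercising the full inequality
pipeline end to end, and (ii) parameter-recovery testing — every cohort is
returned together with a :class:`GroundTruth` record holding the realized
latent health and the generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "COLUMN_DICTIONARY",
    "REGION_LEVELS",
    "EDUCATION_GROUPS",
    "TARGET_SRH_MARGINAL",
]

SCHEMA_VERSION = "1"

REGION_LEVELS = ("east", "central", "west")

#: 4-level education grouping derived from completed years of schooling.
EDUCATION_GROUPS = (
    "below_middle_school",   # < 9 years
    "middle_school",         # 9 years
    "high_school",           # 10-12 years
    "above_high_school",     # > 12 years
)

#: Target marginal SRH distribution (very bad ... very good) used to
#: auto-calibrate cutpoints; a realistic class imbalance for survey SRH,
#: with "so so" the modal answer.
TARGET_SRH_MARGINAL = (0.0516, 0.1788, 0.4017, 0.2607, 0.1072)

#: Column dictionary for the cohort CSV (schema version 1).
#: name -> (dtype, description)
COLUMN_DICTIONARY: dict[str, tuple[str, str]] = {
    "srh": ("int", "self-rated health, ordinal 1 (very bad) .. 5 (very good)"),
    "income_initial": ("float", "per-capita household income, currency units/year, >= 0"),
    "premium": ("float", "insurance premium actually paid, currency units/year, >= 0"),
    "oop_spend": ("float", "out-of-pocket medical spending, currency units/year, >= 0"),
    "reimbursement": ("float", "insurance reimbursement received, <= oop_spend"),
    "outpatient_visits": ("int", "outpatient visits in the year, >= 0"),
    "inpatient_episodes": ("int", "inpatient episodes in the year, >= 0"),
    "gender": ("int", "1 = female, 0 = male"),
    "age": ("int", "age in years"),
    "education_years": ("int", "completed years of schooling"),
    "education_group": ("str", "one of " + "/".join(EDUCATION_GROUPS)),
    "marital": ("int", "1 = married, 0 = not married"),
    "urban": ("int", "1 = urban resident, 0 = rural"),
    "region": ("str", "one of " + "/".join(REGION_LEVELS)),
}

REQUIRED_COLUMNS = tuple(COLUMN_DICTIONARY)


def _default_covariate_effects() -> dict[str, float]:
    # Latent-health effects of the control variables. Age and education are
    # centered (age at 50 years, education at 9 years) so the defaults do not
    # shift the latent location.
    return {
        "female": -0.15,
        "age": -0.02,
        "education_years": 0.02,
        "married": 0.05,
        "urban": 0.05,
    }


def _default_oop_model() -> dict[str, float]:
    return {
        "outpatient_unit_cost": 150.0,   # currency per visit
        "inpatient_unit_cost": 4000.0,   # currency per episode
        "income_elasticity": 0.2,        # spend multiplier exp(e * z_log_income)
        "noise_shape": 5.0,              # gamma(shape, 1/shape) multiplicative noise
    }


def _default_utilization_model() -> dict[str, float]:
    # log-linear negative-binomial (gamma-Poisson) counts; means roughly
    # 4.5 outpatient visits and 0.7 inpatient episodes per year at defaults.
    return {
        "outpatient_base": math.log(4.5) - 0.06,
        "inpatient_base": math.log(0.7) - 0.06,
        "need_coef_outpatient": 0.30,
        "need_coef_inpatient": 0.40,
        "income_coef_outpatient": 0.15,
        "income_coef_inpatient": 0.20,
        "dispersion": 1.5,               # gamma shape; smaller = more overdispersed
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_individuals
        Cohort size (>= 2).
    seed
        Seed for the generator's random stream.
    income_log_mean, income_log_sd
        Log-scale parameters of the lognormal per-capita household income
        (currency units per year). Defaults give a right-skewed income with
        median ~18,000.
    health_income_slope
        Effect of log(1 + income) on latent health; positive values produce
        pro-rich health inequality.
    covariate_effects
        Latent-health effects of the controls (keys ``female``, ``age``,
        ``education_years``, ``married``, ``urban``); age and education are
        centered before being multiplied by their effect.
    female_income_slope_extra
        Additional log-income slope applied to women only, for gender
        heterogeneity experiments. Default 0 (no gender difference).
    srh_cutpoints
        Four strictly increasing thresholds partitioning the latent scale
        into the 5 SRH levels. ``None`` (default) calibrates them to the
        latent-sample quantiles implied by :data:`TARGET_SRH_MARGINAL`.
    premium_flat
        Flat annual premium (the URRBMI is a fixed-contribution scheme).
    subsidy_fraction_bottom
        Fraction of the poorest participants whose premium is waived.
    subsidy_rate
        Fraction of the premium waived for the subsidized tail (1 = full).
    oop_model, utilization_model
        Parameter dicts for spending and utilization; see the module
        defaults for keys.
    reimbursement_rate
        Fraction of out-of-pocket spending returned by the insurer.
    """

    n_individuals: int = 20_000
    seed: int = 0
    income_log_mean: float = 9.8
    income_log_sd: float = 0.8
    health_income_slope: float = 0.3
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    female_income_slope_extra: float = 0.0
    srh_cutpoints: tuple[float, float, float, float] | None = None
    premium_flat: float = 250.0
    subsidy_fraction_bottom: float = 0.05
    subsidy_rate: float = 1.0
    oop_model: dict[str, float] = field(default_factory=_default_oop_model)
    reimbursement_rate: float = 0.5
    utilization_model: dict[str, float] = field(default_factory=_default_utilization_model)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ParameterError(f"n_individuals must be >= 2, got {self.n_individuals}")
        if self.income_log_sd <= 0:
            raise ParameterError(f"income_log_sd must be > 0, got {self.income_log_sd}")
        if not (0.0 <= self.subsidy_rate <= 1.0):
            raise ParameterError(f"subsidy_rate must be in [0, 1], got {self.subsidy_rate}")
        if not (0.0 <= self.reimbursement_rate <= 1.0):
            raise ParameterError(
                f"reimbursement_rate must be in [0, 1], got {self.reimbursement_rate}"
            )
        if not (0.0 <= self.subsidy_fraction_bottom <= 1.0):
            raise ParameterError(
                f"subsidy_fraction_bottom must be in [0, 1], got {self.subsidy_fraction_bottom}"
            )
        if self.srh_cutpoints is not None:
            cp = tuple(float(c) for c in self.srh_cutpoints)
            if len(cp) != 4 or any(b <= a for a, b in zip(cp, cp[1:])):
                raise ParameterError(
                    f"srh_cutpoints must be 4 strictly increasing reals, got {self.srh_cutpoints}"
                )
            self.srh_cutpoints = cp


@dataclass
class GroundTruth:
    """Realized generator state stored alongside every generated cohort."""

    config: CohortConfig
    health_income_slope: float
    pro_rich: bool                      # true sign of income-related inequality
    srh_cutpoints: np.ndarray           # realized (possibly calibrated) cutpoints
    latent_health: np.ndarray           # true latent health per participant
    need_score: np.ndarray              # standardized medical need per participant

    def as_dict(self) -> dict:
        d = asdict(self)
        d["config"] = asdict(self.config)
        for k in ("srh_cutpoints", "latent_health", "need_score"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _education_group(years: np.ndarray) -> np.ndarray:
    out = np.full(years.shape, EDUCATION_GROUPS[0], dtype=object)
    out[years == 9] = EDUCATION_GROUPS[1]
    out[(years > 9) & (years <= 12)] = EDUCATION_GROUPS[2]
    out[years > 12] = EDUCATION_GROUPS[3]
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a synthetic cohort and its ground truth.

    Deterministic given ``config`` (including ``config.seed``): the same
    configuration always yields a byte-identical table.

    Returns
    -------
    (cohort, truth)
        ``cohort`` is a :class:`pandas.DataFrame` following
        :data:`COLUMN_DICTIONARY`; ``truth`` records the realized latent
        health, need scores and cutpoints for recovery tests.
    """
    cfg = config
    n = cfg.n_individuals
    rng = np.random.default_rng(cfg.seed)

    income = rng.lognormal(cfg.income_log_mean, cfg.income_log_sd, n)
    gender = rng.binomial(1, 0.5, n)                       # 1 = female
    age = np.clip(np.rint(rng.normal(50.0, 16.0, n)), 18, 90).astype(int)
    education_years = rng.choice(
        [0, 6, 9, 12, 16], size=n, p=[0.10, 0.25, 0.30, 0.20, 0.15]
    )
    marital = rng.binomial(1, 0.8, n)
    urban = rng.binomial(1, 0.5, n)
    region = rng.choice(np.array(REGION_LEVELS, dtype=object), size=n, p=[0.4, 0.3, 0.3])

    log_inc = np.log1p(income)
    eff = cfg.covariate_effects
    linear = (
        cfg.health_income_slope * log_inc
        + cfg.female_income_slope_extra * gender * log_inc
        + eff.get("female", 0.0) * gender
        + eff.get("age", 0.0) * (age - 50.0)
        + eff.get("education_years", 0.0) * (education_years - 9.0)
        + eff.get("married", 0.0) * marital
        + eff.get("urban", 0.0) * urban
    )
    latent = linear + rng.standard_normal(n)

    if cfg.srh_cutpoints is None:
        cum = np.cumsum(TARGET_SRH_MARGINAL)[:4]
        cutpoints = np.quantile(latent, cum)
        # quantile calibration can collapse only if latent is constant,
        # which the standard-normal noise rules out
    else:
        cutpoints = np.asarray(cfg.srh_cutpoints, dtype=float)
    srh = np.digitize(latent, cutpoints) + 1               # 1..5

    premium = np.full(n, float(cfg.premium_flat))
    if cfg.subsidy_fraction_bottom > 0 and cfg.subsidy_rate > 0:
        cutoff = np.quantile(income, cfg.subsidy_fraction_bottom)
        subsidized = income <= cutoff
        premium[subsidized] *= 1.0 - cfg.subsidy_rate

    # medical need: worse latent health -> higher need (gender/age channels
    # enter through the latent process itself)
    need = _zscore(-latent)
    z_inc = _zscore(log_inc)

    um = cfg.utilization_model
    k = um["dispersion"]
    mu_out = np.exp(
        um["outpatient_base"]
        + um["need_coef_outpatient"] * need
        + um["income_coef_outpatient"] * z_inc
    )
    mu_in = np.exp(
        um["inpatient_base"]
        + um["need_coef_inpatient"] * need
        + um["income_coef_inpatient"] * z_inc
    )
    outpatient = rng.poisson(rng.gamma(k, mu_out / k))
    inpatient = rng.poisson(rng.gamma(k, mu_in / k))

    om = cfg.oop_model
    noise = rng.gamma(om["noise_shape"], 1.0 / om["noise_shape"], n)
    oop = (
        om["outpatient_unit_cost"] * outpatient
        + om["inpatient_unit_cost"] * inpatient
    ) * np.exp(om["income_elasticity"] * z_inc) * noise
    reimbursement = cfg.reimbursement_rate * oop

    cohort = pd.DataFrame(
        {
            "srh": srh.astype(int),
            "income_initial": income,
            "premium": premium,
            "oop_spend": oop,
            "reimbursement": reimbursement,
            "outpatient_visits": outpatient.astype(int),
            "inpatient_episodes": inpatient.astype(int),
            "gender": gender.astype(int),
            "age": age,
            "education_years": education_years.astype(int),
            "education_group": _education_group(education_years),
            "marital": marital.astype(int),
            "urban": urban.astype(int),
            "region": region,
        }
    )
    truth = GroundTruth(
        config=cfg,
        health_income_slope=cfg.health_income_slope,
        pro_rich=cfg.health_income_slope > 0,
        srh_cutpoints=cutpoints,
        latent_health=latent,
        need_score=need,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# cohort file I/O (CSV, schema version 1)

def validate_cohort(df: pd.DataFrame) -> None:
    """Validate a cohort table against the column dictionary.

    Raises
    ------
    SchemaError
        Naming the offending column (and first offending row where
        applicable).
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")

    def _first_bad(mask: np.ndarray) -> int:
        return int(np.flatnonzero(mask)[0])

    srh = df["srh"].to_numpy()
    bad = ~np.isin(srh, [1, 2, 3, 4, 5])
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"column 'srh': value {srh[i]!r} at row {i} not an ordinal level 1..5")

    for col in ("income_initial", "premium", "oop_spend", "reimbursement",
                "outpatient_visits", "inpatient_episodes"):
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i = _first_bad(bad)
            raise SchemaError(f"column '{col}': negative or non-finite value at row {i}")

    excess = df["reimbursement"].to_numpy(dtype=float) - df["oop_spend"].to_numpy(dtype=float)
    bad = excess > 1e-9 * np.maximum(1.0, df["oop_spend"].to_numpy(dtype=float))
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"column 'reimbursement': exceeds oop_spend at row {i}")

    region = df["region"].to_numpy()
    bad = ~np.isin(region, REGION_LEVELS)
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"column 'region': unknown level {region[i]!r} at row {i}")

    edu = df["education_group"].to_numpy()
    bad = ~np.isin(edu, EDUCATION_GROUPS)
    if bad.any():
        i = _first_bad(bad)
        raise SchemaError(f"column 'education_group': unknown level {edu[i]!r} at row {i}")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to a UTF-8 CSV with header (schema version 1)."""
    validate_cohort(cohort)
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df
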