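"""End-to-end pipeline orchestration and table-shaped reporting.

Runs the whole analysis from a single configuration — simulate or load a
cohort, cardinalize self-rated health, compute the four-stage concentration
and Erreygers indices with subgroup breakdowns, the relative-deprivation
regression, and the need-standardized utilization table — and bundles the
six result tables with run metadata.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParameterError, UndefinedIndexError
from .cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .cardinalization import cardinalize, OrderedProbitFit
from .deprivation import relative_deprivation, rd_regression, RD_CONTROLS
from .inequality import (
    QUINTILE_LABELS,
    STAGES,
    bootstrap_se,
    build_stage_incomes,
    concentration_index,
    erreygers_index,
    fractional_rank,
    quintile_assign,
)
from .standardization import utilization_table

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "write_bundle",
    "delta_from_printed",
    "coverage_ratio",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) or ``simulate`` (a
    :class:`CohortConfig`) must be given.
    """

    input_path: str | None = None
    simulate: CohortConfig | None = None
    cardinalization_mode: str = "per_stage"     # or "fixed"
    rd_health: str = "srh"                      # "srh" (raw 1..5) or "sah"
    bootstrap_B: int = 200
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ParameterError("exactly one of input_path / simulate must be set")
        if self.cardinalization_mode not in ("per_stage", "fixed"):
            raise ParameterError(
                f"cardinalization_mode must be 'per_stage' or 'fixed', got "
                f"{self.cardinalization_mode!r}"
            )
        if self.rd_health not in ("srh", "sah"):
            raise ParameterError(f"rd_health must be 'srh' or 'sah', got {self.rd_health!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a nested-key/value YAML file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=CohortConfig(**sim) if sim is not None else None, **raw)
        return cfg


@dataclass
class ReportBundle:
    """The six result tables of a pipeline run plus run metadata."""

    table1_srh_distribution: pd.DataFrame
    table2_ci_stages: pd.DataFrame
    table3_ei_stages: pd.DataFrame
    table4_rd_regression: pd.DataFrame
    table5_subgroup_ci: pd.DataFrame
    table6_utilization: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "table1_srh_distribution": self.table1_srh_distribution,
            "table2_ci_stages": self.table2_ci_stages,
            "table3_ei_stages": self.table3_ei_stages,
            "table4_rd_regression": self.table4_rd_regression,
            "table5_subgroup_ci": self.table5_subgroup_ci,
            "table6_utilization": self.table6_utilization,
        }


# ---------------------------------------------------------------------------
# printed-value verification arithmetic

def delta_from_printed(ci_initial: float, ci_reimbursement: float) -> float:
    """Inequality change from two printed stage CIs: initial minus
    post-reimbursement (negative = the scheme widened inequality)."""
    if not (np.isfinite(ci_initial) and np.isfinite(ci_reimbursement)):
        raise ParameterError("printed CI values must be finite")
    return float(ci_initial) - float(ci_reimbursement)


def coverage_ratio(actual: float, expected: float) -> float:
    """Coverage ratio 100*actual/expected as a percentage, rounded
    half-up to two decimals for display."""
    if not expected > 0:
        raise UndefinedIndexError(f"coverage ratio undefined for expected={expected}")
    pct = Decimal(100 * float(actual) / float(expected))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# pipeline internals

def _stage_sah(cohort: pd.DataFrame, mode: str) -> dict[str, np.ndarray]:
    """Cardinal health per stage under the requested mode."""
    si = build_stage_incomes(cohort)
    sah: dict[str, np.ndarray] = {}
    fit: OrderedProbitFit | None = None
    for stage in STAGES:
        if mode == "fixed":
            if fit is None:
                card, fit = cardinalize(cohort, si.initial)
                fixed = card.sah
            sah[stage] = fixed
        else:
            card, _ = cardinalize(cohort, si.stage(stage))
            sah[stage] = card.sah
    return sah


def _boot_cell(
    sah: np.ndarray, income: np.ndarray, kind: str, B: int, seed: int
) -> tuple[float, float]:
    frame = pd.DataFrame({"sah": sah, "income": income})

    def stat(df: pd.DataFrame) -> float:
        r = fractional_rank(df["income"].to_numpy())
        h = df["sah"].to_numpy()
        if kind == "standard":
            return concentration_index(h, r).index_value
        return erreygers_index(h, r, 0.0, 1.0).index_value

    boot = bootstrap_se(stat, frame, B=B, seed=seed, health_column="sah")
    return boot.se, boot.p_value


def _index_table(
    sah_by_stage: dict[str, np.ndarray],
    stage_income: dict[str, np.ndarray],
    row_masks: dict[str, np.ndarray],
    kind: str,
    B: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Rows = groups, columns = stages (+ SE/p when bootstrapped) + delta_total.

    Ranks are recomputed within each row's subpopulation on each stage's
    income.
    """
    rows = {}
    for group, mask in row_masks.items():
        row: dict[str, float] = {}
        for stage in STAGES:
            h = sah_by_stage[stage][mask]
            ranks = fractional_rank(stage_income[stage][mask])
            if kind == "standard":
                value = concentration_index(h, ranks).index_value
            else:
                value = erreygers_index(h, ranks, 0.0, 1.0).index_value
            row[stage] = value
            if B > 0:
                se, p = _boot_cell(
                    h, stage_income[stage][mask], kind, B, int(rng.integers(2**31))
                )
                row[f"{stage}_se"] = se
                row[f"{stage}_p"] = p
        row["delta_total"] = row["initial"] - row["reimbursement"]
        rows[group] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "group"
    return table


def _srh_distribution_table(
    cohort: pd.DataFrame, sah_initial: np.ndarray, quintiles: np.ndarray
) -> pd.DataFrame:
    rows = {}
    srh = cohort["srh"].to_numpy()

    def row_for(mask: np.ndarray) -> dict[str, float]:
        d = {
            f"srh_{lvl}_pct": 100.0 * np.mean(srh[mask] == lvl) for lvl in range(1, 6)
        }
        d["sah_mean"] = float(sah_initial[mask].mean())
        d["n"] = int(mask.sum())
        return d

    rows["total"] = row_for(np.ones(len(cohort), dtype=bool))
    for q in QUINTILE_LABELS:
        rows[q] = row_for(quintiles == q)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "group"
    return table


def _rd_table(cohort: pd.DataFrame, quintiles: np.ndarray, rd_health: str,
              sah_initial: np.ndarray) -> pd.DataFrame:
    health = cohort["srh"].to_numpy(dtype=float) if rd_health == "srh" else sah_initial
    rd = relative_deprivation(health).rd
    controls = cohort.loc[:, list(RD_CONTROLS)]
    spec1 = rd_regression(rd, quintiles, with_controls=False)
    spec2 = rd_regression(rd, quintiles, controls=controls, with_controls=True)
    terms = [f"q_{q}" for q in QUINTILE_LABELS[1:]]
    rows = {}
    for t in terms + ["const"]:
        if t == "const":
            rows["constant"] = {
                "coef_no_controls": spec1.intercept,
                "se_no_controls": spec1.intercept_se,
                "coef_controls": spec2.intercept,
                "se_controls": spec2.intercept_se,
            }
        else:
            rows[t] = {
                "coef_no_controls": spec1.coefficients[t],
                "se_no_controls": spec1.std_errors[t],
                "p_no_controls": spec1.p_values[t],
                "coef_controls": spec2.coefficients[t],
                "se_controls": spec2.std_errors[t],
                "p_controls": spec2.p_values[t],
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "term"
    return table


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and return the six-table bundle.

    Fully reproducible given the config (and its seeds); every stage logs
    its wall time and parameter choices.
    """
    t0 = time.perf_counter()
    if config.simulate is not None:
        logger.info("simulating cohort: n=%d seed=%d",
                    config.simulate.n_individuals, config.simulate.seed)
        cohort, _truth = generate_cohort(config.simulate)
    else:
        logger.info("reading cohort from %s", config.input_path)
        cohort = read_cohort(config.input_path)

    rng = np.random.default_rng(config.seed)
    B = config.bootstrap_B

    try:
        si = build_stage_incomes(cohort)
        stage_income = {s: si.stage(s) for s in STAGES}
        quintiles = quintile_assign(si.initial)

        t = time.perf_counter()
        sah_by_stage = _stage_sah(cohort, config.cardinalization_mode)
        logger.info("cardinalization (%s mode): %.1fs",
                    config.cardinalization_mode, time.perf_counter() - t)

        table1 = _srh_distribution_table(cohort, sah_by_stage["initial"], quintiles)

        masks = {"total": np.ones(len(cohort), dtype=bool)}
        masks.update({q: quintiles == q for q in QUINTILE_LABELS})
        t = time.perf_counter()
        table2 = _index_table(sah_by_stage, stage_income, masks, "standard", B, rng)
        table3 = _index_table(sah_by_stage, stage_income, masks, "erreygers", B, rng)
        logger.info("stage/quintile indices (B=%d): %.1fs", B, time.perf_counter() - t)

        table4 = _rd_table(cohort, quintiles, config.rd_health, sah_by_stage["initial"])

        gender = np.where(cohort["gender"].to_numpy() == 1, "female", "male")
        edu = cohort["education_group"].to_numpy()
        sub_masks = {g: gender == g for g in ("male", "female")}
        sub_masks.update({g: edu == g for g in pd.unique(edu)})
        table5 = _index_table(sah_by_stage, stage_income, sub_masks, "standard", B, rng)

        t = time.perf_counter()
        table6 = utilization_table(cohort, quintiles)
        logger.info("need-standardization: %.1fs", time.perf_counter() - t)
    except Exception:
        logger.exception("pipeline aborted")
        raise

    metadata = {
        "package_version": __version__,
        "n_individuals": int(len(cohort)),
        "cardinalization_mode": config.cardinalization_mode,
        "rd_health": config.rd_health,
        "bootstrap_B": B,
        "seed": config.seed,
        "erreygers_bounds": [0.0, 1.0],
        "quintile_labels": list(QUINTILE_LABELS),
        "simulated": config.simulate is not None,
        "simulate_config": asdict(config.simulate) if config.simulate is not None else None,
        "significance_threshold": 0.01,
    }
    logger.info("pipeline complete: %.1fs", time.perf_counter() - t0)
    return ReportBundle(table1, table2, table3, table4, table5, table6, metadata)


def _stars(p: float | None) -> str:
    return "***" if p is not None and p < 0.01 else ""


def render_text(bundle: ReportBundle) -> str:
    """Human-readable rendering of the bundle (values to 4 decimals,
    *** at p < 0.01). Display only; stored tables keep full precision."""
    out = []
    for name, tab in bundle.tables().items():
        out.append(f"== {name} ==")
        disp = tab.copy()
        for col in list(disp.columns):
            if col.endswith("_p"):
                base = col[:-2]
                disp[base] = [
                    f"{v:.4f}{_stars(p)}" for v, p in zip(tab[base], tab[col])
                ]
        disp = disp[[c for c in disp.columns if not c.endswith("_p") and not c.endswith("_se")]]
        out.append(disp.to_string(float_format=lambda v: f"{v:.4f}"))
        out.append("")
    return "\n".join(out)


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the bundle as delimited text tables plus metadata and a
    rendered summary. Byte-identical across reruns of the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tab in bundle.tables().items():
        tab.to_csv(outdir / f"{name}.csv")
    with open(outdir / "metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.metadata, fh, sort_keys=True)
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(render_text(bundle))
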