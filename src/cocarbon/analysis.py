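"""Validation pipeline: predict mixed-substrate growth rates and score them.

Given a table of single-substrate growth rates and measured rates on
substrate pairs, this module applies the growth-rate composition formula to
every pair, quantifies the prediction error, and computes the summary
statistics used to judge the model: an OLS regression of measured on
predicted rates (slope, offset, R^2 with 95% CIs), per-group mean relative
deviations, and an exact Mann-Whitney U comparison of the deviation
distributions between the co-utilization group (A) and the group with known
extra uptake interactions (B: inducer exclusion by glucose, FBP feedback on
glycerol uptake).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

from .model import CompositionModel, compose_growth_rates, uptake_flux_ratio

__all__ = [
    "PairObservation",
    "GrowthTable",
    "PredictionRecord",
    "RegressionResult",
    "GroupComparison",
    "MannWhitneyResult",
    "PredictionReport",
    "predict_pairs",
    "regress_measured_on_predicted",
    "mann_whitney_exact",
    "group_deviation_summary",
    "run_full_analysis",
    "write_report",
]

logger = logging.getLogger(__name__)

#: Largest combined sample size for the exact Mann-Whitney permutation path.
EXACT_MW_LIMIT = 30

Denominator = Literal["predicted", "measured"]


@dataclass(frozen=True)
class PairObservation:
    """Measured steady-state growth rate on a pair of co-supplied substrates."""

    substrate_1: str
    substrate_2: str
    rate: float
    group: str  # "A" (co-utilized, null model expected) or "B" (known interactions)

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError(f"group must be 'A' or 'B', got {self.group!r}")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ValueError(
                f"pair {self.substrate_1}+{self.substrate_2}: rate must be a "
                f"finite positive growth rate, got {self.rate!r}"
            )
        if self.substrate_1 == self.substrate_2:
            raise ValueError(f"pair lists the same substrate twice: {self.substrate_1}")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.substrate_1, self.substrate_2))

    @property
    def label(self) -> str:
        return f"{self.substrate_1}+{self.substrate_2}"


@dataclass(frozen=True)
class GrowthTable:
    """The study's data model: single-substrate rates plus pair measurements.

    Invariants enforced at construction: every paired substrate has a
    declared single rate, all rates are positive, and each unordered pair
    appears at most once (deduplicate at ingest, see ``cocarbon.io``).
    """

    singles: dict[str, float]
    pairs: tuple[PairObservation, ...]

    def __post_init__(self) -> None:
        for name, rate in self.singles.items():
            if not (np.isfinite(rate) and rate > 0):
                raise ValueError(
                    f"substrate {name!r}: single rate must be finite and > 0, got {rate!r}"
                )
        object.__setattr__(self, "pairs", tuple(self.pairs))
        seen: set[frozenset[str]] = set()
        for p in self.pairs:
            for s in (p.substrate_1, p.substrate_2):
                if s not in self.singles:
                    raise ValueError(
                        f"pair {p.label} references substrate {s!r} with no declared single rate"
                    )
            if p.key in seen:
                raise ValueError(f"unordered pair {p.label} appears more than once")
            seen.add(p.key)

    def group(self, label: str) -> tuple[PairObservation, ...]:
        return tuple(p for p in self.pairs if p.group == label)


@dataclass(frozen=True)
class PredictionRecord:
    """One pair: measured vs composed prediction and the relative deviation."""

    substrate_1: str
    substrate_2: str
    group: str
    measured: float
    predicted: float
    relative_deviation: float

    @property
    def label(self) -> str:
        return f"{self.substrate_1}+{self.substrate_2}"


@dataclass(frozen=True)
class RegressionResult:
    """OLS of measured (response) on predicted (covariate) growth rates.

    CIs are 95% intervals from the t distribution with n-2 degrees of
    freedom.
    """

    slope: float
    offset: float
    r_squared: float
    slope_ci_95: tuple[float, float]
    offset_ci_95: tuple[float, float]
    n: int


class MannWhitneyResult(NamedTuple):
    u_statistic: float
    p_two_sided: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class GroupComparison:
    """Mean relative deviations per group and their rank-based comparison."""

    mean_dev_a: float
    mean_dev_b: float
    u_statistic: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class PredictionReport:
    """Everything the validation run produces, ready for serialization."""

    lambda_c: float
    denominator: Denominator
    records: tuple[PredictionRecord, ...]
    regression_group_a: RegressionResult
    group_comparison: GroupComparison
    property_checks: dict[str, bool] = field(default_factory=dict)
    #: deviation means recomputed at lambda_c +/- 0.05/h (the published
    #: uncertainty band of the strain constant), keyed by the shifted value
    lambda_c_sensitivity: dict[str, dict[str, float]] = field(default_factory=dict)


def predict_pairs(
    table: GrowthTable,
    model: CompositionModel | None = None,
    denominator: Denominator = "predicted",
) -> list[PredictionRecord]:
    """Apply the composition formula to every pair in the table.

    ``relative_deviation`` is ``|measured - predicted| / predicted`` by
    default; ``denominator="measured"`` switches the normalization.
    """
    model = CompositionModel() if model is None else model
    if denominator not in ("predicted", "measured"):
        raise ValueError(f"denominator must be 'predicted' or 'measured', got {denominator!r}")
    records = []
    for p in table.pairs:
        predicted = compose_growth_rates(
            [table.singles[p.substrate_1], table.singles[p.substrate_2]], model
        )
        denom = predicted if denominator == "predicted" else p.rate
        records.append(
            PredictionRecord(
                substrate_1=p.substrate_1,
                substrate_2=p.substrate_2,
                group=p.group,
                measured=p.rate,
                predicted=predicted,
                relative_deviation=abs(p.rate - predicted) / denom,
            )
        )
    return records


def regress_measured_on_predicted(
    records: Sequence[PredictionRecord],
    group_filter: str | None = None,
) -> RegressionResult:
    """OLS regression of measured growth rates on model predictions.

    A perfect model gives slope 1, offset 0; the scatter of group-A pairs
    around that line is the headline test of the composition formula.
    """
    if group_filter is not None:
        records = [r for r in records if r.group == group_filter]
    if len(records) < 3:
        raise ValueError(
            f"need at least 3 records for a regression, got {len(records)}"
        )
    x = np.array([r.predicted for r in records])
    y = np.array([r.measured for r in records])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        offset=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci_95=(float(ci[1, 0]), float(ci[1, 1])),
        offset_ci_95=(float(ci[0, 0]), float(ci[0, 1])),
        n=len(records),
    )


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of k-subsets of the pooled doubled midranks by their sum.

    Dynamic programme over items: ``counts[k, s]`` = number of size-``k``
    subsets of the pooled sample whose doubled-midrank sum is ``s``.  This
    is exactly the permutation distribution of the rank sum under random
    group assignment, ties included, without enumerating all C(n+m, n)
    subsets.  Counts stay below C(30, 15) < 2^63, so int64 is exact.
    """
    max_sum = int(doubled_ranks.sum())
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in doubled_ranks:
        counts[1:, r:] += counts[:-1, : max_sum + 1 - r]
    return counts[n_a]


def mann_whitney_exact(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test, exact for small samples.

    For combined sizes up to ``EXACT_MW_LIMIT`` the p-value is computed
    from the full permutation distribution of U over all C(n+m, n) group
    assignments of the observed (possibly tied) values, with midranks for
    ties; the two-sided p is twice the smaller tail probability, capped at
    1.  Larger samples fall back to the normal approximation with tie and
    continuity corrections, flagged by ``method="normal"``.

    Returns U for ``sample_a`` (in ``[0, n_a * n_b]``).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = sp_stats.rankdata(np.concatenate([a, b]))  # midranks
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b > EXACT_MW_LIMIT:
        res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "normal")

    doubled = np.rint(2 * ranks).astype(np.int64)
    dist = _rank_sum_distribution(doubled, n_a)
    total = dist.sum(dtype=float)
    s_obs = int(round(2 * r_a))
    p_le = dist[: s_obs + 1].sum(dtype=float) / total
    p_ge = dist[s_obs:].sum(dtype=float) / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return MannWhitneyResult(u_a, p, "exact")


def group_deviation_summary(records: Sequence[PredictionRecord]) -> GroupComparison:
    """Mean relative deviation per group and the exact rank test between them.

    Group A pairs are expected to sit at replicate-noise distance from the
    prediction; group B pairs, whose uptake systems interact outside the
    shared cAMP-Crp feedback, should deviate more.
    """
    dev_a = [r.relative_deviation for r in records if r.group == "A"]
    dev_b = [r.relative_deviation for r in records if r.group == "B"]
    if not dev_a or not dev_b:
        raise ValueError("both groups must be non-empty for a group comparison")
    mw = mann_whitney_exact(dev_a, dev_b)
    return GroupComparison(
        mean_dev_a=float(np.mean(dev_a)),
        mean_dev_b=float(np.mean(dev_b)),
        u_statistic=mw.u_statistic,
        p_two_sided=mw.p_two_sided,
        method=mw.method,
    )


def _property_checks(
    table: GrowthTable,
    records: Sequence[PredictionRecord],
    model: CompositionModel,
) -> dict[str, bool]:
    below_limit = all(r.predicted < model.lambda_c for r in records)
    subadditive = all(
        r.predicted < table.singles[r.substrate_1] + table.singles[r.substrate_2]
        for r in records
    )
    uptake_reduced = all(
        uptake_flux_ratio(table.singles[s], r.measured, model) < 1.0
        for r in records
        if r.group == "A"
        for s in (r.substrate_1, r.substrate_2)
    )
    return {
        "predictions_below_speed_limit": below_limit,
        "predictions_subadditive": subadditive,
        "group_a_uptake_reduced": uptake_reduced,
    }


def run_full_analysis(
    table: GrowthTable,
    model: CompositionModel | None = None,
    denominator: Denominator = "predicted",
) -> PredictionReport:
    """Predict every pair, regress group A, compare groups, check properties."""
    model = CompositionModel() if model is None else model
    records = predict_pairs(table, model, denominator)
    regression = regress_measured_on_predicted(records, group_filter="A")
    comparison = group_deviation_summary(records)
    checks = _property_checks(table, records, model)
    sensitivity: dict[str, dict[str, float]] = {}
    for shifted in (model.lambda_c - 0.05, model.lambda_c + 0.05):
        try:
            alt = group_deviation_summary(
                predict_pairs(table, CompositionModel(shifted), denominator)
            )
        except ValueError:  # shifted limit below a single rate, or the like
            continue
        sensitivity[f"{shifted:.6g}"] = {
            "mean_relative_deviation_a": alt.mean_dev_a,
            "mean_relative_deviation_b": alt.mean_dev_b,
        }
    logger.info(
        "analysis: lambda_c=%g/h, %d pairs (%d A, %d B), slope=%.3f, R2=%.3f, "
        "mean dev A=%.1f%% B=%.1f%%, MW p=%.3g",
        model.lambda_c,
        len(records),
        sum(r.group == "A" for r in records),
        sum(r.group == "B" for r in records),
        regression.slope,
        regression.r_squared,
        100 * comparison.mean_dev_a,
        100 * comparison.mean_dev_b,
        comparison.p_two_sided,
    )
    return PredictionReport(
        lambda_c=model.lambda_c,
        denominator=denominator,
        records=tuple(records),
        regression_group_a=regression,
        group_comparison=comparison,
        property_checks=checks,
        lambda_c_sensitivity=sensitivity,
    )


def report_to_frame(report: PredictionReport) -> pd.DataFrame:
    """Per-pair predictions as a DataFrame (the ``predictions.csv`` schema)."""
    return pd.DataFrame(
        {
            "substrate_1": [r.substrate_1 for r in report.records],
            "substrate_2": [r.substrate_2 for r in report.records],
            "group": [r.group for r in report.records],
            "measured_per_h": [r.measured for r in report.records],
            "predicted_per_h": [r.predicted for r in report.records],
            "relative_deviation": [r.relative_deviation for r in report.records],
        }
    )


def report_to_dict(report: PredictionReport) -> dict:
    """Summary statistics as a JSON-ready dict (the ``report.json`` schema)."""
    reg = report.regression_group_a
    cmp_ = report.group_comparison
    return {
        "lambda_c_per_h": report.lambda_c,
        "deviation_denominator": report.denominator,
        "n_pairs": len(report.records),
        "regression_group_a": {
            "slope": reg.slope,
            "offset_per_h": reg.offset,
            "r_squared": reg.r_squared,
            "slope_ci_95": list(reg.slope_ci_95),
            "offset_ci_95": list(reg.offset_ci_95),
            "n": reg.n,
        },
        "group_comparison": {
            "mean_relative_deviation_a": cmp_.mean_dev_a,
            "mean_relative_deviation_b": cmp_.mean_dev_b,
            "u_statistic": cmp_.u_statistic,
            "p_two_sided": cmp_.p_two_sided,
            "method": cmp_.method,
        },
        "property_checks": dict(report.property_checks),
        "lambda_c_sensitivity": dict(report.lambda_c_sensitivity),
    }


def write_report(report: PredictionReport, outdir: str | Path) -> tuple[Path, Path]:
    """Write ``predictions.csv`` and ``report.json`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "predictions.csv"
    json_path = outdir / "report.json"
    report_to_frame(report).to_csv(csv_path, index=False, float_format="%.15g")
    json_path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
    logger.info("wrote %s and %s", csv_path, json_path)
    return csv_path, json_path
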