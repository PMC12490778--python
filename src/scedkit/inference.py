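"""Randomization tests, p-value combination and Tau-U effect sizes.

The randomization test is exact by design: because the treatment start
point was randomized over a known set of admissible designs, the null
distribution of the test statistic is obtained by recomputing it under
*every* admissible design on the same observed series.  The test
statistic is the mean-difference MeanA − MeanBC: the baseline mean minus
the pooled treatment-plus-follow-up mean (phases B and C are pooled
because follow-up introduces no new intervention).  Large positive
values mean anxiety fell after treatment entry, so the default test is
one-sided in that direction; ties with the observed statistic count as
extreme (conservative), which guarantees p >= 1/n_scenarios.  With 20
admissible designs the attainable p values are exactly {k/20}, the
smallest being 0.05.

Per-participant p values are combined across the replicated cases with
the Edgington additive method: under the joint null the p values behave
like independent uniforms, so their sum S is referred to the Irwin–Hall
distribution,

    P(sum of n uniforms <= S) = (1/n!) * sum_{k=0}^{floor(S)}
                                (-1)^k C(n,k) (S-k)^n.

Tau-U is a Kendall-type nonoverlap effect size: the signed count of
baseline-versus-later pairs, optionally penalized by the baseline's own
internal trend pairs.  Negative values indicate the outcome fell from
baseline to the later phases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .daily import DailySeries
from .design import DesignSpace, PhaseDesign, enumerate_designs
from .simulate import SyntheticCohort

__all__ = [
    "RandomizationResult",
    "CombinedResult",
    "TauUResult",
    "mean_diff_stat",
    "randomization_test",
    "edgington_combine",
    "tau_u",
    "run_inference",
    "render_p",
]

log = logging.getLogger(__name__)

_TIE_TOL = 1e-12


def _split_observed(
    values: np.ndarray, baseline_days: int
) -> tuple[np.ndarray, np.ndarray]:
    a = values[:baseline_days]
    bc = values[baseline_days:]
    return a[~np.isnan(a)], bc[~np.isnan(bc)]


def mean_diff_stat(series: DailySeries, design: PhaseDesign | None = None) -> float:
    """MeanA − MeanBC under a (possibly counterfactual) design.

    Means are taken over observed values only.  Positive = the outcome is
    lower after treatment entry.  NaN when either side has no observed
    value (the caller decides whether to exclude such a scenario).
    """
    design = design or series.design
    a, bc = _split_observed(series.values, design.baseline_days)
    if len(a) == 0 or len(bc) == 0:
        return math.nan
    return float(np.mean(a) - np.mean(bc))


@dataclass(frozen=True)
class RandomizationResult:
    participant_id: str
    observed_stat: float
    null_stats: dict[int, float]  # keyed by baseline length
    n_scenarios: int
    p_value: float
    direction: str
    scenario_set: str
    excluded_baselines: tuple[int, ...] = ()


def randomization_test(
    series: DailySeries,
    space: DesignSpace,
    observed_design: PhaseDesign | None = None,
    direction: str = "greater",
    scenario_set: str = "all",
) -> RandomizationResult:
    """Exact randomization test over admissible treatment start points.

    Parameters
    ----------
    direction
        ``"greater"`` (one-sided, MeanA − MeanBC large = improvement,
        the default), ``"less"``, or ``"two_sided"``.
    scenario_set
        ``"all"`` enumerates every admissible design; ``"stratum"``
        restricts the null to the observed design's own baseline stratum
        (sensitivity analysis).

    A candidate scenario that leaves either side with no observed value
    is excluded from the null set with a warning.  The observed scenario
    is always a member of the null set, so p >= 1/n_scenarios.
    """
    if direction not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    observed_design = observed_design or series.design
    if len(series.values) != space.total_days:
        raise ValueError(
            f"series length {len(series.values)} != space total_days {space.total_days}"
        )
    candidates = enumerate_designs(space)
    if observed_design not in candidates:
        raise ValueError("observed design is not admissible under the design space")
    if scenario_set == "stratum":
        stratum = space.stratum_of(observed_design.baseline_days)
        lo, hi = space.strata[stratum]
        candidates = [d for d in candidates if lo <= d.baseline_days <= hi]
    elif scenario_set != "all":
        raise ValueError(f"unknown scenario_set {scenario_set!r}")

    null_stats: dict[int, float] = {}
    excluded = []
    for d in candidates:
        stat = mean_diff_stat(series, d)
        if math.isnan(stat):
            excluded.append(d.baseline_days)
            continue
        null_stats[d.baseline_days] = stat
    if excluded:
        log.warning(
            "participant %s: %d scenario(s) excluded for empty phases "
            "(baselines %s)", series.participant_id, len(excluded), excluded,
        )
    if observed_design.baseline_days not in null_stats:
        raise ValueError(
            f"participant {series.participant_id}: observed design has an "
            "empty phase; the test is undefined"
        )
    observed = null_stats[observed_design.baseline_days]
    stats = np.array(list(null_stats.values()))
    if direction == "greater":
        n_extreme = int(np.sum(stats >= observed - _TIE_TOL))
    elif direction == "less":
        n_extreme = int(np.sum(stats <= observed + _TIE_TOL))
    else:
        n_extreme = int(np.sum(np.abs(stats) >= abs(observed) - _TIE_TOL))
    n = len(stats)
    return RandomizationResult(
        participant_id=series.participant_id,
        observed_stat=observed,
        null_stats=null_stats,
        n_scenarios=n,
        p_value=n_extreme / n,
        direction=direction,
        scenario_set=scenario_set,
        excluded_baselines=tuple(excluded),
    )


@dataclass(frozen=True)
class CombinedResult:
    p_values: tuple[float, ...]
    sum_s: float
    combined_p: float

    @property
    def n_tests(self) -> int:
        return len(self.p_values)


def edgington_combine(p_values: list[float] | tuple[float, ...]) -> CombinedResult:
    """Additive combination of independent p values (Irwin–Hall CDF at their sum).

    The alternating closed form can exceed [0, 1] only through floating
    error near S = n; the result is clipped.
    """
    if len(p_values) == 0:
        raise ValueError("need at least one p value")
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p value {p} outside (0, 1]")
    n = len(p_values)
    s = float(sum(p_values))
    total = 0.0
    for k in range(math.floor(s) + 1):
        total += (-1) ** k * math.comb(n, k) * (s - k) ** n
    combined = min(max(total / math.factorial(n), 0.0), 1.0)
    return CombinedResult(tuple(p_values), s, combined)


@dataclass(frozen=True)
class TauUResult:
    participant_id: str
    s_cross: int
    s_trend_a: int
    n_a: int
    n_bc: int
    tau_u: float
    variant: str  # "trend_corrected" | "simple"

    @property
    def insufficient(self) -> bool:
        return math.isnan(self.tau_u)


def tau_u(
    series: DailySeries,
    design: PhaseDesign | None = None,
    correct_baseline_trend: bool = True,
) -> TauUResult:
    """Tau-U nonoverlap effect size of baseline versus pooled B∪C.

    ``s_cross`` sums sign(value_j − value_i) over all cross pairs
    (i in A, j in B∪C); with trend correction the within-baseline signed
    pairs ``s_trend_a`` are subtracted and the denominator is
    n_a·n_bc + n_a(n_a−1)/2, otherwise tau = s_cross / (n_a·n_bc).
    Observed values only; |tau_u| <= 1 in both variants.
    """
    design = design or series.design
    a, bc = _split_observed(series.values, design.baseline_days)
    n_a, n_bc = len(a), len(bc)
    variant = "trend_corrected" if correct_baseline_trend else "simple"
    min_a = 2 if correct_baseline_trend else 1
    if n_a < min_a or n_bc < 1:
        return TauUResult(series.participant_id, 0, 0, n_a, n_bc, math.nan, variant)
    s_cross = int(np.sum(np.sign(bc[None, :] - a[:, None])))
    s_trend_a = int(np.sum(np.sign(a[None, :] - a[:, None])[np.triu_indices(n_a, k=1)]))
    if correct_baseline_trend:
        denom = n_a * n_bc + n_a * (n_a - 1) / 2
        tau = (s_cross - s_trend_a) / denom
    else:
        denom = n_a * n_bc
        tau = s_cross / denom
    return TauUResult(series.participant_id, s_cross, s_trend_a, n_a, n_bc, float(tau), variant)


def render_p(p: float) -> str:
    """Two-decimal p rendering; values at or above .995 render as '≥.99'."""
    if math.isnan(p):
        return "NA"
    if p >= 0.995:
        return "≥.99"
    return f"{p:.2f}".lstrip("0")


def run_inference(
    cohort: SyntheticCohort | list[tuple[str, DailySeries, PhaseDesign]],
    space: DesignSpace | None = None,
    outcome: str = "anxiety",
    direction: str = "greater",
    scenario_set: str = "all",
    correct_baseline_trend: bool = True,
) -> tuple[pd.DataFrame, CombinedResult]:
    """Per-participant randomization tests and Tau-U, plus the combined p.

    Returns a table with one row per participant and an ``All combined``
    row, alongside the :class:`CombinedResult`.  p values are rendered to
    two decimals (``≥.99`` for near-total overlap) next to the exact
    values.
    """
    if isinstance(cohort, SyntheticCohort):
        space = space or cohort.space
        items = [
            (p.participant_id, p.series[outcome], p.design)
            for p in cohort.participants
        ]
    else:
        if space is None:
            raise ValueError("space is required when passing bare series")
        items = list(cohort)
    if not items:
        raise ValueError("need at least one participant")

    rows = []
    p_values = []
    for pid, series, design in items:
        rt = randomization_test(series, space, design, direction, scenario_set)
        tu = tau_u(series, design, correct_baseline_trend)
        p_values.append(rt.p_value)
        rows.append(
            {
                "participant_id": pid,
                "observed_stat": rt.observed_stat,
                "n_scenarios": rt.n_scenarios,
                "p_value": rt.p_value,
                "p_display": render_p(rt.p_value),
                "tau_u": round(tu.tau_u, 2) if not math.isnan(tu.tau_u) else math.nan,
                "tau_u_variant": tu.variant,
            }
        )
    combined = edgington_combine(p_values)
    rows.append(
        {
            "participant_id": "All combined",
            "observed_stat": math.nan,
            "n_scenarios": math.nan,
            "p_value": combined.combined_p,
            "p_display": render_p(combined.combined_p),
            "tau_u": math.nan,
            "tau_u_variant": "",
        }
    )
    return pd.DataFrame(rows), combined
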