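"""Deterministic cohort model for the estimated maximum intervention cost.

The question the model answers: how much can a health system pay, up front,
for an intervention that saves a life at age ``k`` while staying at or below
a cost-effectiveness threshold (CET, currency per health-adjusted life-year)?
The comparator is death — zero future costs, zero future health — so the
survivor's entire remaining stream is the increment.  The threshold condition

    ICER = (A + C(k)) / HALY(k) <= CET

solves for the maximum one-off price

    EMIC = A_max = CET * HALY(k) - C(k)

where, for a person aged ``k`` followed to a terminal model age,

    HALY(k) = sum_{i=k}^{max_age} S(i) * (1 - pYLD(i)) / (1 + r)^(i-k+1)
    C(k)    = sum_{i=k}^{max_age} S(i) * c(i)          / (1 + r)^(i-k+1)

``S(i)`` is the probability of being alive at the start of the year lived at
age ``i`` (the expectation of the survival indicator over the alive–dead
process), ``pYLD(i)`` the per-capita prevalent years lived with disability
(population background morbidity), ``c(i)`` the expected annual per-capita
health-system cost, and ``r`` the annual discount rate.  The first year is
discounted by one full period and every reward accrues at the start of a
cycle conditional on being alive; there is no half-cycle correction.

Mortality improves over calendar time: age-specific death probabilities are
reduced along the cohort's calendar diagonal by an annual proportional trend
(for the New Zealand 2011 baseline, 2 % per year through 2026 and 1 %
thereafter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDomainError, UnsupportedFeatureError

__all__ = [
    "LifeTable",
    "TrendSegment",
    "MortalityTrendSpec",
    "nz_default_trend",
    "MorbiditySchedule",
    "CostSchedule",
    "ScenarioSpec",
    "CohortResult",
    "DEFAULT_LYOL_MULTIPLIERS",
    "project_cohort_hazard",
    "survival_curve",
    "discounted_haly",
    "discounted_cost",
    "adjust_costs",
    "life_expectancy",
    "emic_ideal",
    "emic_general",
    "run_cohort",
]

#: Last-year-of-life cost multipliers by age band (closed start, inclusive
#: end, ``None`` meaning open-ended): residential-care spending missing from
#: routine costing data is concentrated in the year before death at old ages.
DEFAULT_LYOL_MULTIPLIERS: tuple[tuple[int, int | None, float], ...] = (
    (65, 74, 1.1),
    (75, 84, 1.2),
    (85, None, 1.3),
)

#: Global scale applied to all per-capita costs to correct for under-capture
#: in the source costing data.
DEFAULT_GLOBAL_COST_SCALE = 1.2


def _check_contiguous(index: pd.Index, what: str) -> None:
    ages = np.asarray(index)
    if len(ages) == 0:
        raise InputDomainError(f"{what}: empty age index")
    if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
        raise InputDomainError(f"{what}: ages must be contiguous integers")


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death q(i) by single year of age.

    Parameters
    ----------
    qx
        Series indexed by integer age, values in [0, 1]: the probability of
        dying within the year for a person alive at that age.
    base_year
        Calendar year the table describes; mortality-trend projection is
        anchored here.
    sex
        Optional stratum label; purely informational.
    """

    qx: pd.Series
    base_year: int
    sex: str | None = None

    def __post_init__(self) -> None:
        _check_contiguous(self.qx.index, "life table")
        q = self.qx.to_numpy(dtype=float)
        if np.any(q < 0) or np.any(q > 1) or np.any(~np.isfinite(q)):
            raise InputDomainError("life table: every q(i) must lie in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.qx.index[0])

    @property
    def max_age(self) -> int:
        return int(self.qx.index[-1])


@dataclass(frozen=True)
class TrendSegment:
    """One piece of a mortality-trend schedule: an annual proportional
    reduction applied through a calendar year (``None`` = open-ended)."""

    reduction: float
    through_year: int | None


@dataclass(frozen=True)
class MortalityTrendSpec:
    """Secular decline in age-specific death probabilities.

    Each calendar year after ``base_year`` multiplies q by
    ``1 - reduction(year)``, where the reduction comes from the first
    schedule segment whose ``through_year`` has not passed.  The final
    segment must be open-ended.
    """

    base_year: int
    schedule: tuple[TrendSegment, ...]

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ConfigurationError("trend schedule must have at least one segment")
        prev = None
        for seg in self.schedule:
            if not 0 <= seg.reduction < 1:
                raise InputDomainError(
                    f"trend reduction {seg.reduction} outside [0, 1)")
            if seg.through_year is not None:
                if prev is not None and seg.through_year <= prev:
                    raise ConfigurationError(
                        "trend segment years must be strictly increasing")
                prev = seg.through_year
        if self.schedule[-1].through_year is not None:
            raise ConfigurationError("final trend segment must be open-ended")

    def reduction_for_year(self, year: int) -> float:
        for seg in self.schedule:
            if seg.through_year is None or year <= seg.through_year:
                return seg.reduction
        raise AssertionError("unreachable: final segment is open-ended")

    def multiplier(self, elapsed_years: int) -> float:
        """Cumulative q-multiplier after ``elapsed_years`` calendar years.

        Reductions start the year after ``base_year``; the baseline year
        itself is untouched, so ``multiplier(0) == 1``.
        """
        if elapsed_years < 0:
            raise InputDomainError("elapsed years must be non-negative")
        m = 1.0
        for e in range(1, elapsed_years + 1):
            m *= 1.0 - self.reduction_for_year(self.base_year + e)
        return m


def nz_default_trend(base_year: int = 2011) -> MortalityTrendSpec:
    """Long-run New Zealand mortality trend: 2 % annual reduction through
    2026, 1 % per year thereafter."""
    return MortalityTrendSpec(
        base_year=base_year,
        schedule=(TrendSegment(0.02, 2026), TrendSegment(0.01, None)),
    )


@dataclass(frozen=True)
class MorbiditySchedule:
    """Per-capita prevalent years lived with disability pYLD(i) in [0, 1).

    The health reward for a year lived at age i is 1 - pYLD(i); a value of 1
    would mean a year of zero health, which is excluded.
    """

    pyld: pd.Series

    def __post_init__(self) -> None:
        _check_contiguous(self.pyld.index, "morbidity schedule")
        v = self.pyld.to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v >= 1) or np.any(~np.isfinite(v)):
            raise InputDomainError("morbidity schedule: pYLD(i) must lie in [0, 1)")


@dataclass(frozen=True)
class CostSchedule:
    """Annual per-capita health-system costs by age.

    ``background`` is the cost of an average survivor year; ``lyol`` the
    elevated cost of the last year of life (incurred by decedents).  After
    :func:`adjust_costs` has composed the expected per-capita cost c(i),
    ``adjusted`` is True and ``expected`` holds c(i) on the cohort's ages.
    """

    background: pd.Series
    lyol: pd.Series | None = None
    adjusted: bool = False
    expected: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_contiguous(self.background.index, "cost schedule")
        for name, series in (("background", self.background),
                             ("last-year-of-life", self.lyol),
                             ("expected", self.expected)):
            if series is None:
                continue
            v = series.to_numpy(dtype=float)
            if np.any(v < 0) or np.any(~np.isfinite(v)):
                raise InputDomainError(f"cost schedule: {name} costs must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything about a run that is not age-indexed data.

    Parameters
    ----------
    cet
        Cost-effectiveness threshold, currency per health-adjusted life-year
        (must share units with the cost schedule).
    r
        Annual discount rate applied to both health and costs.
    trend
        Mortality-trend projection, or None to hold rates fixed.
    p, e
        Baseline risk of death over the risk period and intervention
        effectiveness; the ideal life-saving scenario is p = e = 1.
    risk_duration
        Years the risk persists; only the one-year case is supported.
    max_age
        Terminal model age: the cohort is followed through the year lived at
        this age and truncated after it.
    """

    cet: float = 45_000.0
    r: float = 0.03
    trend: MortalityTrendSpec | None = None
    p: float = 1.0
    e: float = 1.0
    risk_duration: int = 1
    max_age: int = 105
    global_cost_scale: float = DEFAULT_GLOBAL_COST_SCALE
    lyol_multipliers: tuple[tuple[int, int | None, float], ...] = DEFAULT_LYOL_MULTIPLIERS

    def __post_init__(self) -> None:
        if self.cet < 0:
            raise InputDomainError("CET must be >= 0")
        if self.r < 0:
            raise InputDomainError("discount rate must be >= 0")
        if not 0 <= self.p <= 1:
            raise InputDomainError("risk of death p must lie in [0, 1]")
        if not 0 <= self.e <= 1:
            raise InputDomainError("effectiveness e must lie in [0, 1]")
        if self.risk_duration < 1:
            raise InputDomainError("risk duration must be >= 1 year")


@dataclass(frozen=True)
class CohortResult:
    """Per-starting-age outputs of a cohort run.

    ``survival`` maps age i to the probability of being alive at the start
    of the year lived at that age (starts at 1 and never increases).  A
    negative EMIC means the survivor's discounted future costs exceed the
    value of their discounted future health at the threshold: no positive
    up-front price is cost-effective.
    """

    start_age: int
    survival: pd.Series
    le: float
    haly: float
    cost: float
    emic: float

    @property
    def cost_ineffective(self) -> bool:
        return self.emic < 0


def project_cohort_hazard(
    lifetable: LifeTable,
    trend: MortalityTrendSpec | None,
    k: int,
    max_age: int | None = None,
) -> pd.Series:
    """Death probabilities along the cohort diagonal for a person aged ``k``.

    A person aged ``k`` in the table's base year reaches age ``i`` in
    calendar year ``base_year + (i - k)``; the period probability q(i) is
    reduced by the trend multiplier accumulated over those elapsed years:

        q~(i) = q(i) * prod_{y = base_year+1}^{base_year+(i-k)} (1 - reduction(y))

    Returns a Series on ages ``k .. max_age`` (default: the table's last
    age), clipped to [0, 1].
    """
    if k < lifetable.min_age or k > lifetable.max_age:
        raise InputDomainError(
            f"start age {k} outside table range "
            f"[{lifetable.min_age}, {lifetable.max_age}]")
    top = lifetable.max_age if max_age is None else min(max_age, lifetable.max_age)
    if top < k:
        raise InputDomainError(f"max_age {max_age} below start age {k}")
    if trend is not None and trend.base_year != lifetable.base_year:
        raise ConfigurationError(
            f"trend base year {trend.base_year} does not match "
            f"life-table base year {lifetable.base_year}")
    ages = np.arange(k, top + 1)
    q = lifetable.qx.loc[k:top].to_numpy(dtype=float)
    if trend is None:
        mult = np.ones_like(q)
    else:
        # cumulative product over elapsed years, elapsed = i - k
        factors = np.array(
            [1.0 - trend.reduction_for_year(trend.base_year + e)
             for e in range(1, len(ages))])
        mult = np.concatenate(([1.0], np.cumprod(factors)))
    return pd.Series(np.clip(q * mult, 0.0, 1.0), index=ages)


def survival_curve(hazard: pd.Series, k: int) -> pd.Series:
    """Probability of being alive at the start of each year's cycle.

    S(k) = 1 and S(i+1) = S(i) * (1 - q~(i)); defined on the hazard's ages.
    """
    if int(hazard.index[0]) != k:
        raise InputDomainError(
            f"hazard must start at age {k}, got {hazard.index[0]}")
    q = hazard.to_numpy(dtype=float)
    s = np.empty_like(q)
    s[0] = 1.0
    if len(q) > 1:
        s[1:] = np.cumprod(1.0 - q[:-1])
    return pd.Series(s, index=hazard.index)


def _discount_factors(ages: np.ndarray, r: float, k: int) -> np.ndarray:
    # reward for the year lived at age i is discounted by a full i-k+1 years
    return (1.0 + r) ** -(ages - k + 1)


def _aligned(series: pd.Series, ages: pd.Index, what: str) -> np.ndarray:
    out = series.reindex(ages)
    if out.isna().any():
        missing = out.index[out.isna()][0]
        raise InputDomainError(f"{what} does not cover age {missing}")
    return out.to_numpy(dtype=float)


def discounted_haly(
    survival: pd.Series, morbidity: MorbiditySchedule, r: float, k: int
) -> float:
    """Expected discounted future health-adjusted life-years HALY(k).

    Each year lived at age i contributes S(i) * (1 - pYLD(i)) discounted by
    (1+r)^(i-k+1).  Equals the discounted health-adjusted life expectancy.
    """
    if r < 0:
        raise InputDomainError("discount rate must be >= 0")
    ages = np.asarray(survival.index)
    pyld = _aligned(morbidity.pyld, survival.index, "morbidity schedule")
    if np.any(pyld >= 1):
        raise InputDomainError("pYLD(i) must be < 1")
    return float(np.sum(survival.to_numpy(dtype=float)
                        * (1.0 - pyld) * _discount_factors(ages, r, k)))


def discounted_cost(
    survival: pd.Series,
    costs: CostSchedule,
    r: float,
    k: int,
    *,
    allow_unadjusted: bool = False,
) -> float:
    """Expected discounted future health-system cost C(k).

    Uses the expected per-capita cost c(i) composed by :func:`adjust_costs`;
    pass ``allow_unadjusted=True`` to sum raw background costs instead.
    """
    if r < 0:
        raise InputDomainError("discount rate must be >= 0")
    if costs.adjusted and costs.expected is not None:
        c_series = costs.expected
    elif allow_unadjusted:
        c_series = costs.background
    else:
        raise ConfigurationError(
            "cost schedule has not been adjusted; call adjust_costs first "
            "or pass allow_unadjusted=True")
    ages = np.asarray(survival.index)
    c = _aligned(c_series, survival.index, "cost schedule")
    return float(np.sum(survival.to_numpy(dtype=float)
                        * c * _discount_factors(ages, r, k)))


def _band_multipliers(
    ages: np.ndarray,
    bands: tuple[tuple[int, int | None, float], ...],
) -> np.ndarray:
    m = np.ones(len(ages))
    for lo, hi, mult in bands:
        mask = ages >= lo if hi is None else (ages >= lo) & (ages <= hi)
        m[mask] = mult
    return m


def adjust_costs(
    raw: CostSchedule,
    hazard: pd.Series,
    global_scale: float = DEFAULT_GLOBAL_COST_SCALE,
    lyol_multipliers: tuple[tuple[int, int | None, float], ...] | None = None,
) -> CostSchedule:
    """Compose the expected per-capita annual cost c(i) from its parts.

    The decedent (last-year-of-life) cost is incurred with probability
    q~(i), scaled by the age-band multiplier m(i); the global scale then
    corrects the whole stream for cost under-capture:

        c(i) = global_scale * [ c_background(i) + m(i) * q~(i) * c_lyol(i) ]

    ``hazard`` must be the cohort's trend-adjusted death probabilities, so
    the adjusted schedule is specific to one starting age.
    """
    if global_scale < 0:
        raise InputDomainError("global cost scale must be >= 0")
    if raw.lyol is None:
        if lyol_multipliers is not None:
            raise ConfigurationError(
                "last-year-of-life multipliers given but the cost schedule "
                "has no decedent cost component")
        bands: tuple[tuple[int, int | None, float], ...] = ()
    else:
        bands = DEFAULT_LYOL_MULTIPLIERS if lyol_multipliers is None else lyol_multipliers
    ages = np.asarray(hazard.index)
    bg = _aligned(raw.background, hazard.index, "cost schedule")
    if raw.lyol is None:
        expected = global_scale * bg
    else:
        lyol = _aligned(raw.lyol, hazard.index, "decedent cost schedule")
        m = _band_multipliers(ages, bands)
        expected = global_scale * (bg + m * hazard.to_numpy(dtype=float) * lyol)
    return replace(raw, adjusted=True,
                   expected=pd.Series(expected, index=hazard.index))


def life_expectancy(survival: pd.Series) -> float:
    """Undiscounted remaining life expectancy: the sum of the survival curve
    (same start-of-cycle accrual convention as the discounted streams)."""
    return float(survival.to_numpy(dtype=float).sum())


def emic_ideal(haly: float, cost: float, cet: float) -> float:
    """Maximum one-off price for an ideal life-saving intervention.

    ``CET * HALY(k) - C(k)``: certain death without it, fully effective,
    survivor returned to average morbidity, mortality and cost trajectories.
    May be negative (reported as-is; see :attr:`CohortResult.cost_ineffective`).
    """
    if haly < 0 or cost < 0 or cet < 0:
        raise InputDomainError("haly, cost and cet must all be >= 0")
    return cet * haly - cost


def emic_general(
    haly: float,
    cost: float,
    cet: float,
    p: float,
    e: float,
    risk_duration: int = 1,
) -> float:
    """Maximum price when death is not certain and the intervention is not
    perfect.

    With a one-year risk of death ``p`` and effectiveness ``e``, the expected
    deaths averted per treated person is ``p * e``, which scales both the
    health gained and the future cost incurred:

        EMIC = p * e * (CET * HALY(k) - C(k))

    Reduces to :func:`emic_ideal` at p = e = 1.  Multi-year risk durations
    are an extension point, not implemented.
    """
    if not 0 <= p <= 1 or not 0 <= e <= 1:
        raise InputDomainError("p and e must lie in [0, 1]")
    if risk_duration != 1:
        raise UnsupportedFeatureError(
            "only a one-year risk duration is supported")
    return p * e * emic_ideal(haly, cost, cet)


def run_cohort(
    lifetable: LifeTable,
    morbidity: MorbiditySchedule,
    costs: CostSchedule,
    scenario: ScenarioSpec,
    k: int,
) -> CohortResult:
    """Full pipeline for one starting age: hazard projection, survival,
    cost adjustment, discounted streams and the maximum intervention cost."""
    hazard = project_cohort_hazard(lifetable, scenario.trend, k,
                                   max_age=scenario.max_age)
    s = survival_curve(hazard, k)
    adjusted = costs if costs.adjusted else adjust_costs(
        costs, hazard, scenario.global_cost_scale,
        scenario.lyol_multipliers if costs.lyol is not None else None)
    haly = discounted_haly(s, morbidity, scenario.r, k)
    c = discounted_cost(s, adjusted, scenario.r, k)
    emic = emic_general(haly, c, scenario.cet, scenario.p, scenario.e,
                        scenario.risk_duration)
    return CohortResult(start_age=k, survival=s, le=life_expectancy(s),
                        haly=haly, cost=c, emic=emic)
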