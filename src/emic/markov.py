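"""Explicit two-state alive–dead cohort Markov engine.

This is a deliberately literal annual-cycle state machine: the cohort
fraction in "Alive" transitions to the absorbing "Dead" state with the
year's death probability, and while alive collects a health reward
``1 - pYLD(i)`` and a cost reward ``c(i)``, each discounted by
``(1+r)^-(cycle index)`` with the first cycle indexed 1.  It exists as an
independent cross-check of the closed summations in :mod:`emic.model` —
same conventions, different code path — and is deterministic cohort-fraction
propagation, not Monte-Carlo sampling of individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _model
from .errors import ConfigurationError, InputDomainError

__all__ = ["MarkovModel", "MarkovResult", "CrossValidationReport",
           "run_markov", "cross_validate"]


@dataclass(frozen=True)
class MarkovModel:
    """Schedules for one cohort: trend-adjusted death probabilities, the
    morbidity decrement, the expected per-capita cost, and the discount
    rate.  All three series must share an identical contiguous age index."""

    hazard: pd.Series
    pyld: pd.Series
    cost: pd.Series
    r: float

    def __post_init__(self) -> None:
        idx = self.hazard.index
        if not (self.pyld.index.equals(idx) and self.cost.index.equals(idx)):
            raise ConfigurationError(
                "hazard, morbidity and cost schedules must cover the same ages")
        if self.r < 0:
            raise InputDomainError("discount rate must be >= 0")
        q = self.hazard.to_numpy(dtype=float)
        if np.any(q < 0) or np.any(q > 1):
            raise InputDomainError("transition probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class MarkovResult:
    haly: float
    cost: float
    survival: pd.Series  # Alive-state occupancy at the start of each cycle


def run_markov(mk: MarkovModel, k: int) -> MarkovResult:
    """Propagate the cohort year by year from age ``k`` and accumulate
    discounted rewards.

    Cycle ``n`` (1-based) is the year lived at age ``k + n - 1``; its reward
    is collected by the fraction alive at the start of the cycle and
    discounted by ``(1+r)^-n``, the same accrual convention as the direct
    sums.  The dead fraction collects nothing.
    """
    if int(mk.hazard.index[0]) != k:
        raise ConfigurationError(
            f"model schedules start at age {mk.hazard.index[0]}, not {k}")
    alive = 1.0
    haly = 0.0
    cost = 0.0
    trace = []
    for n, age in enumerate(mk.hazard.index, start=1):
        disc = (1.0 + mk.r) ** -n
        trace.append(alive)
        haly += alive * (1.0 - mk.pyld.loc[age]) * disc
        cost += alive * mk.cost.loc[age] * disc
        alive *= 1.0 - mk.hazard.loc[age]
    return MarkovResult(haly=haly, cost=cost,
                        survival=pd.Series(trace, index=mk.hazard.index))


@dataclass(frozen=True)
class CrossValidationReport:
    """Relative deviations between the Markov engine and the direct sums."""

    dev_haly: float
    dev_cost: float
    dev_survival: float
    tolerance: float

    @property
    def max_deviation(self) -> float:
        return max(self.dev_haly, self.dev_cost, self.dev_survival)

    @property
    def passed(self) -> bool:
        return self.max_deviation <= self.tolerance


def _rel(a: float, b: float) -> float:
    scale = max(abs(a), abs(b), 1.0)
    return abs(a - b) / scale


def cross_validate(mk: MarkovModel, k: int, tolerance: float = 1e-9) -> CrossValidationReport:
    """Run both evaluators on identical schedules and compare.

    Raises :class:`InputDomainError` for a non-positive tolerance and
    :class:`ConfigurationError` if any relative deviation exceeds it.
    """
    if tolerance <= 0:
        raise InputDomainError("tolerance must be positive")
    res = run_markov(mk, k)
    s = _model.survival_curve(mk.hazard, k)
    haly = _model.discounted_haly(
        s, _model.MorbiditySchedule(mk.pyld), mk.r, k)
    cost = _model.discounted_cost(
        s, _model.CostSchedule(mk.cost, adjusted=True, expected=mk.cost),
        mk.r, k)
    dev_s = float(np.max(np.abs(res.survival.to_numpy() - s.to_numpy())))
    report = CrossValidationReport(
        dev_haly=_rel(res.haly, haly),
        dev_cost=_rel(res.cost, cost),
        dev_survival=dev_s,
        tolerance=tolerance,
    )
    if not report.passed:
        raise ConfigurationError(
            f"Markov engine and direct sums disagree: max relative "
            f"deviation {report.max_deviation:.3e} > {tolerance:.1e}")
    return report
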