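"""Result surfaces: maximum intervention cost by age, by threshold, and by
discount rate.

All three builders accept either a :class:`ModelInputs` bundle of raw
age-indexed schedules (everything is then recomputed at five-year-group
midpoint ages through :mod:`emic.model`) or the reference fixture DataFrame
from :func:`emic.synthetic.nz2011_reference`, whose printed HALE and cost
columns stand in for the unavailable raw national data.  Internal arithmetic
is double precision throughout; rounding happens only in explicitly
requested display copies, half-up to the conventional printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InputDomainError
from .model import (
    CostSchedule,
    LifeTable,
    MorbiditySchedule,
    MortalityTrendSpec,
    ScenarioSpec,
    run_cohort,
)
from .synthetic import FIXTURE_RATES

__all__ = ["ModelInputs", "DEFAULT_AGE_GROUPS", "DEFAULT_CET_GRID",
           "round_half_up", "build_age_table", "build_cet_grid",
           "sensitivity_curves"]

#: Five-year age groups with midpoints 2, 7, ..., 92.
DEFAULT_AGE_GROUPS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 4) for lo in range(0, 95, 5))

#: Threshold grid for the willingness-to-pay sensitivity table.
DEFAULT_CET_GRID: tuple[int, ...] = tuple(range(20_000, 100_001, 10_000))


@dataclass(frozen=True)
class ModelInputs:
    """Raw age-indexed schedules plus the scenario they are run under.

    ``scenario.cet`` and ``scenario.r`` act as defaults; the table builders
    override them per column.
    """

    lifetable: LifeTable
    morbidity: MorbiditySchedule
    costs: CostSchedule
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always away from zero toward +inf for
    positives), matching how printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct_label(r: float) -> str:
    pct = 100.0 * r
    return f"{pct:g}"


def _fixture_hale_cost(fix: pd.DataFrame, r: float) -> tuple[pd.Series, pd.Series]:
    """HALE (years) and cost (currency units) columns of the fixture at a
    tabulated discount rate."""
    for rate, suffix in FIXTURE_RATES.items():
        if abs(r - rate) < 1e-12:
            return fix[f"hale_{suffix}"], fix[f"cost_{suffix}"] * 1_000.0
    raise InputDomainError(
        f"the reference fixture is tabulated only at discount rates "
        f"{sorted(FIXTURE_RATES)}, not {r}")


def _raw_hale_cost(
    inputs: ModelInputs, r: float, groups: tuple[tuple[int, int], ...]
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """HALE, cost and LE at group midpoints, recomputed from raw schedules."""
    from dataclasses import replace

    hale, cost, le = [], [], []
    scenario = replace(inputs.scenario, r=r)
    for lo, hi in groups:
        res = run_cohort(inputs.lifetable, inputs.morbidity, inputs.costs,
                         scenario, lo + 2)
        hale.append(res.haly)
        cost.append(res.cost)
        le.append(res.le)
    idx = pd.RangeIndex(len(groups))
    return pd.Series(hale, index=idx), pd.Series(cost, index=idx), pd.Series(le, index=idx)


def _group_labels(groups: tuple[tuple[int, int], ...]) -> list[str]:
    return [f"{lo}-{hi}" for lo, hi in groups]


def build_age_table(
    inputs: ModelInputs | pd.DataFrame,
    discount_rates: tuple[float, ...] = (0.0, 0.03, 0.06),
    cet: float = 45_000.0,
    *,
    round_display: bool = False,
    groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Life expectancy, HALE, future cost and maximum intervention cost by
    five-year age group, one column set per discount rate.

    Each row's EMIC cell is recomputed from that row's own (unrounded, in
    raw mode) HALE and cost: ``cet * HALE - C``.  HALE is reported in years,
    costs and EMIC in thousands of currency units.  With ``round_display``,
    HALE keeps one decimal and cost/EMIC round to whole thousands, half-up.
    """
    for r in discount_rates:
        if r < 0:
            raise InputDomainError("discount rate must be >= 0")
    fixture_mode = isinstance(inputs, pd.DataFrame)
    if fixture_mode:
        out = inputs[["age_group", "midpoint", "le"]].copy()
    else:
        out = pd.DataFrame({
            "age_group": _group_labels(groups),
            "midpoint": [lo + 2 for lo, _ in groups],
        })
    for r in discount_rates:
        lab = _pct_label(r)
        if fixture_mode:
            hale, cost = _fixture_hale_cost(inputs, r)
        else:
            hale, cost, le = _raw_hale_cost(inputs, r, groups)
            if "le" not in out.columns:
                out["le"] = le  # LE is discount-free; any rate gives it
        emic_k = (cet * hale - cost) / 1_000.0
        cost_k = cost / 1_000.0
        if round_display:
            hale = hale.map(lambda v: round_half_up(v, 1))
            cost_k = cost_k.map(round_half_up)
            emic_k = emic_k.map(round_half_up)
        out[f"hale_{lab}"] = hale.to_numpy()
        out[f"cost_{lab}"] = cost_k.to_numpy()
        out[f"emic_{lab}"] = emic_k.to_numpy()
    if round_display:
        out["le"] = out["le"].map(lambda v: round_half_up(v, 1))
    return out


def build_cet_grid(
    inputs: ModelInputs | pd.DataFrame,
    cets: tuple[float, ...] = DEFAULT_CET_GRID,
    r: float = 0.03,
    *,
    round_display: bool = False,
    groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Maximum intervention cost (millions of currency units) across a grid
    of cost-effectiveness thresholds, at one discount rate.

    Within a row the cells are exactly affine in the threshold (slope
    HALE / 1e6); the rounded display copies use two decimals, half-up.
    """
    if len(cets) == 0:
        raise InputDomainError("threshold grid must be non-empty")
    if any(b <= a for a, b in zip(cets, cets[1:])):
        raise InputDomainError("threshold grid must be strictly ascending")
    if isinstance(inputs, pd.DataFrame):
        hale, cost = _fixture_hale_cost(inputs, r)
        labels = inputs["age_group"].tolist()
    else:
        hale, cost, _ = _raw_hale_cost(inputs, r, groups)
        labels = _group_labels(groups)
    out = pd.DataFrame(index=pd.Index(labels, name="age_group"))
    for cet in cets:
        col = (cet * hale - cost).to_numpy() / 1e6
        if round_display:
            col = np.array([round_half_up(v, 2) for v in col])
        out[int(cet)] = col
    return out


def sensitivity_curves(
    inputs: ModelInputs | pd.DataFrame,
    discount_rates: tuple[float, ...] = (0.0, 0.03, 0.06),
    cet: float = 45_000.0,
    *,
    groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS,
) -> pd.DataFrame:
    """Maximum intervention cost (currency units) by midpoint age, one
    column per discount rate — the data behind a discount-rate sensitivity
    plot.  Values are unrounded."""
    if isinstance(inputs, pd.DataFrame):
        midpoints = inputs["midpoint"]
    else:
        midpoints = pd.Series([lo + 2 for lo, _ in groups])
    out = pd.DataFrame(index=pd.Index(midpoints.to_numpy(), name="age"))
    for r in discount_rates:
        if isinstance(inputs, pd.DataFrame):
            hale, cost = _fixture_hale_cost(inputs, r)
        else:
            hale, cost, _ = _raw_hale_cost(inputs, r, groups)
        out[_pct_label(r)] = (cet * hale - cost).to_numpy()
    return out
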