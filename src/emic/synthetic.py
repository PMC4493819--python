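"""Synthetic demographic, morbidity and cost inputs, plus the embedded
New Zealand 2011 reference table.

The generators produce internally consistent inputs with the qualitative
shape of real human data — a Gompertz–Makeham mortality hazard, a logistic
age-increasing morbidity curve bounded below 1, and a U-shaped per-capita
cost curve with an infant bump and a decedent-cost component — so every
stage of the pipeline is testable without any external download.  Default
parameters are order-of-magnitude humanlike only; they are deliberately not
calibrated to any country's demography.

:func:`nz2011_reference` embeds published New Zealand 2011 estimates of
remaining life expectancy, discounted health-adjusted life expectancy and
discounted future health-system costs by five-year age group, evaluated at
group midpoints and at 0 %, 3 % and 6 % discount rates.  These printed,
rounded values serve as fixture inputs for threshold analyses where the raw
national life-table, burden-of-disease and costing data are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputDomainError
from .model import CostSchedule, LifeTable, MorbiditySchedule

__all__ = ["SyntheticParams", "random_params", "gompertz_lifetable",
           "synthetic_pyld", "synthetic_costs", "nz2011_reference",
           "FIXTURE_RATES"]


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the three synthetic input curves.

    Mortality follows a Gompertz–Makeham hazard h(x) = c + a·e^{bx}
    converted to an annual death probability q(x) = 1 − e^{−h(x)}, which is
    a valid probability for any non-negative hazard.  Morbidity is a
    logistic pYLD(x) = L / (1 + e^{−s(x−m)}) with asymptote L < 1.
    Background cost is c0 + c1·e^{gx} plus an infant bump at ages 0–1;
    decedent (last-year-of-life) cost is a constant multiple of background.

    ``seed`` enables a lognormal per-age perturbation of the mortality
    hazard, for generating families of randomized but valid life tables.
    """

    gompertz_a: float = 3e-5
    gompertz_b: float = 0.09
    makeham_c: float = 2e-4
    pyld_max: float = 0.30
    pyld_midpoint: float = 75.0
    pyld_slope: float = 0.06
    cost_floor: float = 1500.0
    cost_scale: float = 30.0
    cost_growth: float = 0.055
    infant_bump: float = 2000.0
    lyol_ratio: float = 10.0
    hazard_noise_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gompertz_a < 0 or self.makeham_c < 0 or self.gompertz_b < 0:
            raise InputDomainError("hazard parameters must be >= 0")
        if not 0 <= self.pyld_max < 1:
            raise InputDomainError("morbidity asymptote must lie in [0, 1)")
        if min(self.cost_floor, self.cost_scale, self.infant_bump,
               self.lyol_ratio) < 0:
            raise InputDomainError("cost parameters must be >= 0")


def random_params(rng: np.random.Generator) -> SyntheticParams:
    """Draw a randomized but demographically plausible parameter set."""
    return SyntheticParams(
        gompertz_a=float(10 ** rng.uniform(-5, -4)),
        gompertz_b=float(rng.uniform(0.07, 0.11)),
        makeham_c=float(10 ** rng.uniform(-4.3, -3.0)),
        pyld_max=float(rng.uniform(0.1, 0.5)),
        pyld_midpoint=float(rng.uniform(60.0, 85.0)),
        pyld_slope=float(rng.uniform(0.03, 0.1)),
        cost_floor=float(rng.uniform(500.0, 3000.0)),
        cost_scale=float(rng.uniform(10.0, 60.0)),
        cost_growth=float(rng.uniform(0.04, 0.07)),
        infant_bump=float(rng.uniform(0.0, 4000.0)),
        lyol_ratio=float(rng.uniform(3.0, 15.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def gompertz_lifetable(
    params: SyntheticParams,
    max_age: int = 105,
    base_year: int = 2011,
    sex: str | None = None,
) -> LifeTable:
    """Life table from the Gompertz–Makeham hazard on ages 0..max_age.

    With ``params.seed`` set, each age's hazard is perturbed by an
    independent lognormal factor (median 1) before conversion to q(x);
    the result is still a valid probability at every age.
    """
    x = np.arange(0, max_age + 1, dtype=float)
    hazard = params.makeham_c + params.gompertz_a * np.exp(params.gompertz_b * x)
    if params.seed is not None and params.hazard_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        hazard = hazard * rng.lognormal(0.0, params.hazard_noise_sd, size=len(x))
    q = 1.0 - np.exp(-hazard)
    return LifeTable(pd.Series(q, index=x.astype(int)), base_year=base_year,
                     sex=sex)


def synthetic_pyld(params: SyntheticParams, max_age: int = 105) -> MorbiditySchedule:
    """Logistic per-capita morbidity curve, strictly inside [0, pyld_max)."""
    x = np.arange(0, max_age + 1, dtype=float)
    pyld = params.pyld_max / (
        1.0 + np.exp(-params.pyld_slope * (x - params.pyld_midpoint)))
    return MorbiditySchedule(pd.Series(pyld, index=x.astype(int)))


def synthetic_costs(params: SyntheticParams, max_age: int = 105) -> CostSchedule:
    """Exponentially rising background cost with an infant bump, plus a
    proportional decedent-cost schedule."""
    x = np.arange(0, max_age + 1, dtype=float)
    background = params.cost_floor + params.cost_scale * np.exp(
        params.cost_growth * x)
    background[:2] += params.infant_bump
    idx = x.astype(int)
    return CostSchedule(
        background=pd.Series(background, index=idx),
        lyol=pd.Series(params.lyol_ratio * background, index=idx),
    )


#: Discount rates at which the reference fixture is tabulated, mapped to the
#: column suffix used in its DataFrame.
FIXTURE_RATES: dict[float, str] = {0.0: "0", 0.03: "3", 0.06: "6"}

# Published New Zealand 2011 values by five-year age group, evaluated at the
# group midpoint (2, 7, ..., 92): remaining life expectancy (years,
# undiscounted), discounted HALE (years) and discounted future health-system
# cost (thousands of NZ$) at 0/3/6 % annual discount rates.  Values are as
# printed (rounded); downstream comparisons must carry matching tolerances.
_NZ2011_ROWS: tuple[tuple[str, float, float, float, float, float, float, float], ...] = (
    # group,   LE, HALE0, HALE3, HALE6, C0, C3, C6
    ("0-4",   88.2, 75.8, 28.8, 16.4, 209.0, 42.0, 17.0),
    ("5-9",   82.8, 70.7, 28.0, 16.2, 203.0, 43.0, 17.0),
    ("10-14", 77.4, 65.5, 27.2, 15.9, 198.0, 47.0, 19.0),
    ("15-19", 71.9, 60.4, 26.2, 15.5, 193.0, 51.0, 21.0),
    ("20-24", 66.6, 55.6, 25.4, 15.3, 187.0, 54.0, 23.0),
    ("25-29", 61.4, 50.9, 24.4, 15.0, 181.0, 57.0, 26.0),
    ("30-34", 56.2, 46.2, 23.3, 14.6, 174.0, 61.0, 28.0),
    ("35-39", 51.0, 41.5, 22.1, 14.2, 168.0, 64.0, 31.0),
    ("40-44", 45.8, 36.9, 20.8, 13.7, 161.0, 68.0, 35.0),
    ("45-49", 40.6, 32.4, 19.2, 13.1, 154.0, 73.0, 40.0),
    ("50-54", 35.7, 28.1, 17.6, 12.3, 147.0, 76.0, 45.0),
    ("55-59", 30.8, 23.8, 15.7, 11.4, 139.0, 79.0, 51.0),
    ("60-64", 26.1, 19.7, 13.7, 10.2, 129.0, 81.0, 55.0),
    ("65-69", 21.6, 15.9, 11.6, 9.0, 117.0, 80.0, 58.0),
    ("70-74", 17.2, 12.4, 9.5, 7.6, 101.0, 74.0, 57.0),
    ("75-79", 13.0, 9.1, 7.4, 6.1, 82.0, 65.0, 53.0),
    ("80-84", 9.3, 6.3, 5.4, 4.6, 64.0, 53.0, 46.0),
    ("85-89", 6.3, 4.2, 3.7, 3.3, 46.0, 40.0, 36.0),
    ("90-94", 4.1, 2.7, 2.5, 2.3, 31.0, 28.0, 26.0),
)


def nz2011_reference() -> pd.DataFrame:
    """The embedded New Zealand 2011 reference table.

    Returns a DataFrame with one row per five-year age group 0–4 … 90–94 and
    columns ``age_group``, ``midpoint``, ``le`` (undiscounted remaining life
    expectancy at the midpoint, years), ``hale_0``/``hale_3``/``hale_6``
    (discounted HALE in years at 0/3/6 %) and ``cost_0``/``cost_3``/``cost_6``
    (discounted future health-system cost in thousands of NZ$).  Maximum
    intervention costs are intentionally not embedded: they are recomputed
    from these inputs by the table builders.
    """
    df = pd.DataFrame(
        _NZ2011_ROWS,
        columns=["age_group", "le", "hale_0", "hale_3", "hale_6",
                 "cost_0", "cost_3", "cost_6"],
    )
    df.insert(1, "midpoint",
              [int(g.split("-")[0]) + 2 for g in df["age_group"]])
    return df
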