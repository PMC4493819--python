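"""Readers and writers for the delimited input formats and the scenario
configuration file.

Input schemas (CSV with header):

* life table — columns ``age``, optional ``sex``, ``qx``; one row per
  single year of age or per group written ``"0-4"`` (expanded to single
  ages as a step function)
* morbidity — columns ``age``, optional ``sex``, ``pyld_per_capita``
* costs — columns ``age``, optional ``sex``, ``cost_background``, optional
  ``cost_lyol``

The scenario configuration is a flat YAML mapping with keys ``cet``,
``discount_rate``, ``base_year``, ``trend`` (list of ``{reduction,
through_year}``, last segment with ``through_year: null``), ``p``, ``e``,
``risk_duration``, ``max_age``, ``global_cost_scale`` and
``lyol_multipliers`` (list of ``{from, to, multiplier}``).  Currency units
are documented in the config, never converted.

Validation failures raise :class:`~emic.errors.InputValidationError` naming
the file, column and 1-based data row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import InputValidationError
from .model import (
    CostSchedule,
    LifeTable,
    MorbiditySchedule,
    MortalityTrendSpec,
    ScenarioSpec,
    TrendSegment,
    nz_default_trend,
)

__all__ = ["read_lifetable", "read_morbidity", "read_costs", "read_inputs",
           "read_scenario", "write_table", "write_inputs"]


def _expand_ages(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Expand group rows like "0-4" into one row per single year of age."""
    rows = []
    for pos, rec in enumerate(df.to_dict("records"), start=1):
        raw = str(rec["age"]).strip()
        try:
            if "-" in raw:
                lo_s, hi_s = raw.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
                if hi < lo:
                    raise ValueError
                span = range(lo, hi + 1)
            else:
                span = range(int(raw), int(raw) + 1)
        except ValueError:
            raise InputValidationError(
                f"unparseable age {raw!r}", source=source, column="age",
                row=pos) from None
        for a in span:
            rows.append({**rec, "age": a, "_row": pos})
    out = pd.DataFrame(rows)
    dup = out["age"].duplicated()
    if dup.any():
        bad = out.loc[dup].iloc[0]
        raise InputValidationError(
            f"age {bad['age']} assigned more than once",
            source=source, column="age", row=int(bad["_row"]))
    out = out.sort_values("age").reset_index(drop=True)
    ages = out["age"].to_numpy()
    gaps = (ages[1:] - ages[:-1]) != 1
    if gaps.any():
        missing = int(ages[:-1][gaps][0]) + 1
        raise InputValidationError(
            f"ages are not contiguous: age {missing} missing",
            source=source, column="age")
    return out


def _load(path: str | Path, required: list[str], source: str,
          sex: str | None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputValidationError("file not found", source=source) from None
    for col in required:
        if col not in df.columns:
            raise InputValidationError(
                "missing required column", source=source, column=col)
    if "sex" in df.columns:
        strata = df["sex"].dropna().unique()
        if sex is not None:
            df = df[df["sex"] == sex]
            if df.empty:
                raise InputValidationError(
                    f"no rows for sex {sex!r}", source=source, column="sex")
        elif len(strata) > 1:
            raise InputValidationError(
                f"multiple sex strata {sorted(map(str, strata))} present; "
                "select one with sex=...", source=source, column="sex")
    return _expand_ages(df, source)


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float,
                 source: str, hi_open: bool = False) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals < lo) | ((vals >= hi) if hi_open else (vals > hi))
    if bad.any():
        i = bad.idxmax()
        bound = f"[{lo}, {hi})" if hi_open else f"[{lo}, {hi}]"
        raise InputValidationError(
            f"value {df[col].iloc[i]!r} at age {df['age'].iloc[i]} outside "
            f"{bound}", source=source, column=col, row=int(df["_row"].iloc[i]))


def read_lifetable(path: str | Path, base_year: int = 2011,
                   sex: str | None = None) -> LifeTable:
    source = str(path)
    df = _load(path, ["age", "qx"], source, sex)
    _check_range(df, "qx", 0.0, 1.0, source)
    return LifeTable(pd.Series(df["qx"].astype(float).to_numpy(),
                               index=df["age"].to_numpy()),
                     base_year=base_year, sex=sex)


def read_morbidity(path: str | Path, sex: str | None = None) -> MorbiditySchedule:
    source = str(path)
    df = _load(path, ["age", "pyld_per_capita"], source, sex)
    _check_range(df, "pyld_per_capita", 0.0, 1.0, source, hi_open=True)
    return MorbiditySchedule(pd.Series(
        df["pyld_per_capita"].astype(float).to_numpy(),
        index=df["age"].to_numpy()))


def read_costs(path: str | Path, sex: str | None = None) -> CostSchedule:
    source = str(path)
    df = _load(path, ["age", "cost_background"], source, sex)
    _check_range(df, "cost_background", 0.0, float("inf"), source)
    idx = df["age"].to_numpy()
    lyol = None
    if "cost_lyol" in df.columns and not df["cost_lyol"].isna().all():
        _check_range(df, "cost_lyol", 0.0, float("inf"), source)
        lyol = pd.Series(df["cost_lyol"].astype(float).to_numpy(), index=idx)
    return CostSchedule(
        background=pd.Series(df["cost_background"].astype(float).to_numpy(),
                             index=idx),
        lyol=lyol)


def read_inputs(
    lifetable_path: str | Path,
    morbidity_path: str | Path,
    costs_path: str | Path,
    base_year: int = 2011,
    sex: str | None = None,
) -> tuple[LifeTable, MorbiditySchedule, CostSchedule]:
    """Load and validate the three tabular inputs together."""
    return (read_lifetable(lifetable_path, base_year=base_year, sex=sex),
            read_morbidity(morbidity_path, sex=sex),
            read_costs(costs_path, sex=sex))


def _trend_from_config(cfg: dict[str, Any], base_year: int) -> MortalityTrendSpec | None:
    raw = cfg.get("trend", "default")
    if raw is None:
        return None
    if raw == "default":
        return nz_default_trend(base_year)
    segments = tuple(
        TrendSegment(float(seg["reduction"]),
                     None if seg.get("through_year") is None
                     else int(seg["through_year"]))
        for seg in raw)
    return MortalityTrendSpec(base_year=base_year, schedule=segments)


def read_scenario(path: str | Path) -> tuple[ScenarioSpec, int]:
    """Load a scenario configuration; returns the spec and the base year."""
    source = str(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise InputValidationError("file not found", source=source) from None
    if not isinstance(cfg, dict):
        raise InputValidationError("scenario file must be a flat mapping",
                                   source=source)
    base_year = int(cfg.get("base_year", 2011))
    kwargs: dict[str, Any] = {"trend": _trend_from_config(cfg, base_year)}
    for key, target in [("cet", "cet"), ("discount_rate", "r"), ("p", "p"),
                        ("e", "e"), ("risk_duration", "risk_duration"),
                        ("max_age", "max_age"),
                        ("global_cost_scale", "global_cost_scale")]:
        if key in cfg:
            kwargs[target] = cfg[key]
    if "lyol_multipliers" in cfg:
        kwargs["lyol_multipliers"] = tuple(
            (int(b["from"]),
             None if b.get("to") is None else int(b["to"]),
             float(b["multiplier"]))
            for b in cfg["lyol_multipliers"])
    return ScenarioSpec(**kwargs), base_year


def write_inputs(
    lifetable: LifeTable,
    morbidity: MorbiditySchedule,
    costs: CostSchedule,
    out_dir: str | Path,
    scenario: ScenarioSpec | None = None,
) -> dict[str, Path]:
    """Write the three input CSVs (single-year rows) and a matching scenario
    YAML into ``out_dir``; returns the paths keyed by kind."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lifetable": out / "lifetable.csv",
        "morbidity": out / "morbidity.csv",
        "costs": out / "costs.csv",
        "scenario": out / "scenario.yaml",
    }
    pd.DataFrame({"age": lifetable.qx.index, "qx": lifetable.qx.to_numpy()}
                 ).to_csv(paths["lifetable"], index=False)
    pd.DataFrame({"age": morbidity.pyld.index,
                  "pyld_per_capita": morbidity.pyld.to_numpy()}
                 ).to_csv(paths["morbidity"], index=False)
    cost_df = pd.DataFrame({"age": costs.background.index,
                            "cost_background": costs.background.to_numpy()})
    if costs.lyol is not None:
        cost_df["cost_lyol"] = costs.lyol.to_numpy()
    cost_df.to_csv(paths["costs"], index=False)
    scenario = scenario or ScenarioSpec()
    cfg: dict[str, Any] = {
        "cet": scenario.cet,
        "discount_rate": scenario.r,
        "base_year": lifetable.base_year,
        "p": scenario.p,
        "e": scenario.e,
        "risk_duration": scenario.risk_duration,
        "max_age": scenario.max_age,
        "global_cost_scale": scenario.global_cost_scale,
        "lyol_multipliers": [
            {"from": lo, "to": hi, "multiplier": m}
            for lo, hi, m in scenario.lyol_multipliers],
        "trend": None if scenario.trend is None else [
            {"reduction": seg.reduction, "through_year": seg.through_year}
            for seg in scenario.trend.schedule],
    }
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    """Write a result table as CSV or JSON (records orientation)."""
    out = df.reset_index() if df.index.name else df
    if fmt == "csv":
        out.to_csv(path, index=False)
    elif fmt == "json":
        out.to_json(path, orient="records", indent=2)
    else:
        raise InputValidationError(f"unknown output format {fmt!r}")
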