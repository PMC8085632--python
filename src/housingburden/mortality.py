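"""Attributable mortality and value-of-statistical-life costing.

Deaths are classified by their underlying cause of death (ICD-10-AM)
using the same registry as hospitalizations, aggregated to annual means
over the mortality span (2010-2014 by default, shorter than the
hospitalization span because of data availability), and multiplied by
each disorder's unrounded PAF.  Condition totals are sums of *unrounded*
disorder-level values, rounded only for display: summing pre-rounded
rows visibly distorts small totals.

The societal cost of attributable mortality is the total unrounded death
count times a willingness-to-pay value of a statistical life (VSL),
NZ$ 4.2 million (June 2017) by default.
"""

from __future__ import annotations

import logging

import pandas as pd

from .paf import attribute_interval
from .registry import Registry

logger = logging.getLogger("housingburden")

DEATH_COLUMNS = ["underlying_cause", "year", "age_years"]


def read_deaths(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"underlying_cause": str})
    missing = [c for c in DEATH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"death register {path} lacks columns: {missing}")
    return df


def classify_deaths(
    deaths: pd.DataFrame, registry: Registry, condition: str
) -> pd.Series:
    """Disorder id per death record under one condition (NaN when unmatched)."""
    if deaths.empty:
        return pd.Series(dtype=object)
    cache: dict[tuple[str, float], object] = {}
    out = []
    codes = deaths["underlying_cause"].to_numpy()
    ages = deaths["age_years"].to_numpy()
    for code, age in zip(codes, ages):
        key = (code, age)
        if key not in cache:
            cache[key] = (
                registry.classify_code(code, condition, age)
                if isinstance(code, str)
                else None
            )
        out.append(cache[key])
    unmatched = sum(1 for h in out if h is None)
    if unmatched:
        logger.info(
            "condition %s: %d of %d death records unclassified",
            condition,
            unmatched,
            len(out),
        )
    return pd.Series(out, index=deaths.index, dtype=object)


def annual_mean_deaths(
    deaths: pd.DataFrame, registry: Registry, condition: str
) -> pd.DataFrame:
    """Mean annual deaths per disorder over the configured mortality span."""
    years = registry.years("mortality")
    if deaths.empty:
        return pd.DataFrame(columns=["disorder", "deaths"])
    sub = deaths[deaths["year"].isin(years)].copy()
    sub["disorder"] = classify_deaths(sub, registry, condition)
    sub = sub[sub["disorder"].notna()]
    counts = sub.groupby("disorder", sort=True).size() / float(len(years))
    return counts.rename("deaths").reset_index()


def attribute_deaths(
    deaths: pd.DataFrame, registry: Registry, condition: str
) -> pd.DataFrame:
    """Attributable deaths per mortality category with uncertainty range.

    Disorders sharing a mortality category (e.g. acute and chronic
    rheumatic fever) are reported as one row; their attributable values
    add before any rounding.
    """
    means = annual_mean_deaths(deaths, registry, condition)
    by_disorder = means.set_index("disorder")["deaths"] if not means.empty else None
    rows = []
    for d in registry.condition_disorders(condition):
        pop = float(by_disorder.get(d.id, 0.0)) if by_disorder is not None else 0.0
        if pop == 0.0:
            continue
        res = registry.paf_for(d)
        point, lo, hi = attribute_interval(pop, res)
        rows.append(
            {
                "condition": condition,
                "category": d.mortality_label,
                "pop_deaths": pop,
                "paf": res.paf,
                "deaths": point,
                "deaths_lo": lo,
                "deaths_hi": hi,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "condition",
                "category",
                "pop_deaths",
                "paf",
                "deaths",
                "deaths_lo",
                "deaths_hi",
            ]
        )
    df = pd.DataFrame(rows)
    merged = (
        df.groupby(["condition", "category"], sort=False)
        .agg(
            pop_deaths=("pop_deaths", "sum"),
            paf=("paf", "first"),
            deaths=("deaths", "sum"),
            deaths_lo=("deaths_lo", "sum"),
            deaths_hi=("deaths_hi", "sum"),
        )
        .reset_index()
    )
    return merged


def cost_mortality(total_attributable_deaths: float, vsl: float) -> float:
    """Societal mortality cost: unrounded attributable deaths times the VSL."""
    if total_attributable_deaths < 0:
        raise ValueError(f"attributable deaths {total_attributable_deaths!r} < 0")
    if vsl < 0:
        raise ValueError(f"value of statistical life {vsl!r} < 0")
    return total_attributable_deaths * vsl
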