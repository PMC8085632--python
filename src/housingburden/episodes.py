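"""Hospital episode construction and attributable-burden aggregation.

An *episode* (case) is the analysis unit for hospitalization counts: one
or more admissions of the same patient merged whenever a re-admission
occurs within 7 days of the prior discharge (same-day transfers merge;
the chaining is transitive, so a long chain of close admissions forms one
episode).  Nights are counted as calendar days between admission and
discharge, so a same-day discharge contributes zero nights.

Each episode is assigned at most one disorder per housing condition by
walking the primary diagnoses of its first three admissions in order and
taking the first code that classifies (with the patient's age at first
admission applied against any age restriction).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .paf import attribute_interval
from .registry import HOSPITAL_METRICS, Registry

logger = logging.getLogger("housingburden")

ADMISSION_COLUMNS = [
    "patient_id",
    "admit_date",
    "discharge_date",
    "diag1",
    "diag2",
    "diag3",
    "age_years",
    "cost",
]

EPISODE_GAP_DAYS = 7


def read_admissions(path) -> pd.DataFrame:
    """Read an admissions register from headed delimited text (CSV).

    Dates are ISO-8601.  Exact duplicate rows are dropped; rows whose
    admission postdates the discharge are rejected with a logged reason.
    """
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "diag1": str, "diag2": str, "diag3": str},
        parse_dates=["admit_date", "discharge_date"],
    )
    missing = [c for c in ADMISSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"admissions register {path} lacks columns: {missing}")
    return clean_admissions(df)


def clean_admissions(df: pd.DataFrame) -> pd.DataFrame:
    n0 = len(df)
    df = df.drop_duplicates(subset=ADMISSION_COLUMNS)
    if len(df) < n0:
        logger.info("admissions: dropped %d exact duplicate rows", n0 - len(df))
    bad = df["admit_date"] > df["discharge_date"]
    if bad.any():
        logger.warning(
            "admissions: rejected %d records with admission after discharge",
            int(bad.sum()),
        )
        df = df[~bad]
    neg = df["cost"] < 0
    if neg.any():
        logger.warning("admissions: rejected %d records with negative cost", int(neg.sum()))
        df = df[~neg]
    return df.reset_index(drop=True)


def build_episodes(records: pd.DataFrame) -> pd.DataFrame:
    """Chain admissions into episodes with the 7-day transitive rule.

    Returns one row per episode: patient, year of first admission, age at
    first admission, summed nights and cost, admission count and the
    primary diagnoses of the first three admissions.
    """
    if records.empty:
        return pd.DataFrame(
            columns=[
                "patient_id",
                "episode_id",
                "year",
                "age_years",
                "n_admissions",
                "nights",
                "cost",
                "diag_1",
                "diag_2",
                "diag_3",
            ]
        )
    df = records.sort_values(
        ["patient_id", "admit_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)
    pid = df["patient_id"]
    # Latest discharge seen so far within the patient, *before* this row.
    # After an episode break the running maximum cannot reach back across
    # the break (a break requires every earlier discharge to be > 7 days
    # before the new admission), so the global within-patient cummax equals
    # the within-episode cummax wherever it matters.
    disch_cummax = df.groupby(pid, sort=False)["discharge_date"].cummax()
    prev_max = disch_cummax.groupby(pid, sort=False).shift()
    gap = (df["admit_date"] - prev_max).dt.days
    new_episode = prev_max.isna() | (gap > EPISODE_GAP_DAYS)
    df["episode_id"] = new_episode.cumsum()
    df["nights_rec"] = (df["discharge_date"] - df["admit_date"]).dt.days
    df["_seq"] = df.groupby("episode_id", sort=False).cumcount()

    first = df[df["_seq"] == 0].set_index("episode_id")
    agg = df.groupby("episode_id", sort=False).agg(
        n_admissions=("patient_id", "size"),
        nights=("nights_rec", "sum"),
        cost=("cost", "sum"),
    )
    episodes = agg.join(
        pd.DataFrame(
            {
                "patient_id": first["patient_id"],
                "year": first["admit_date"].dt.year,
                "age_years": first["age_years"],
            }
        )
    )
    for k in (0, 1, 2):
        dk = df[df["_seq"] == k].set_index("episode_id")["diag1"]
        episodes[f"diag_{k + 1}"] = dk
    return episodes.reset_index()


def assign_disorders(
    episodes: pd.DataFrame, registry: Registry, condition: str
) -> pd.Series:
    """Disorder id per episode under one housing condition (NaN if none).

    The primary diagnosis of the first admission is tried first, then the
    second and third admissions' primary diagnoses; age restrictions use
    the age at first admission.
    """
    if episodes.empty:
        return pd.Series(dtype=object)
    cache: dict[tuple[str, float], object] = {}

    def lookup(code, age) -> object:
        if not isinstance(code, str) or not code:
            return None
        key = (code, age)
        if key not in cache:
            cache[key] = registry.classify_code(code, condition, age)
        return cache[key]

    out = []
    cols = [episodes[f"diag_{k}"].to_numpy() for k in (1, 2, 3)]
    ages = episodes["age_years"].to_numpy()
    for i in range(len(episodes)):
        hit = None
        for col in cols:
            hit = lookup(col[i], ages[i])
            if hit is not None:
                break
        out.append(hit)
    n_unmatched = sum(1 for h in out if h is None)
    if n_unmatched:
        logger.info(
            "condition %s: %d of %d episodes matched no disorder",
            condition,
            n_unmatched,
            len(out),
        )
    return pd.Series(out, index=episodes.index, dtype=object)


def summarize_annual(
    episodes: pd.DataFrame, registry: Registry, condition: str
) -> pd.DataFrame:
    """Per (disorder, year) totals: distinct patients, episodes, cost, nights."""
    eps = episodes.copy()
    if "disorder" not in eps.columns:
        eps["disorder"] = assign_disorders(eps, registry, condition)
    eps = eps[eps["disorder"].notna()]
    if eps.empty:
        return pd.DataFrame(
            columns=["disorder", "year", "n_patients", "hospitalizations", "cost_nzd", "nights"]
        )
    grouped = (
        eps.groupby(["disorder", "year"], sort=True)
        .agg(
            n_patients=("patient_id", "nunique"),
            hospitalizations=("episode_id", "size"),
            cost_nzd=("cost", "sum"),
            nights=("nights", "sum"),
        )
        .reset_index()
    )
    return grouped


def annual_means(
    annual: pd.DataFrame, years: list[int]
) -> pd.DataFrame:
    """Mean per disorder over a fixed year span (absent years count as zero)."""
    if annual.empty:
        return pd.DataFrame(
            columns=["disorder", "patients", "hospitalizations", "cost_nzd", "nights"]
        )
    span = annual[annual["year"].isin(years)]
    sums = span.groupby("disorder", sort=True)[
        ["n_patients", "hospitalizations", "cost_nzd", "nights"]
    ].sum()
    means = sums / float(len(years))
    means = means.rename(columns={"n_patients": "patients"})
    return means.reset_index()


def attribute_hospital_burden(
    means: pd.DataFrame, registry: Registry, condition: str
) -> pd.DataFrame:
    """Apply each disorder's unrounded PAF to its population-level means.

    Returns one row per disorder with point/lo/hi columns for every metric
    plus the PAF itself (as a fraction); all values unrounded.
    """
    rows = []
    by_disorder = means.set_index("disorder") if not means.empty else means
    for d in registry.condition_disorders(condition):
        if not means.empty and d.id in by_disorder.index:
            pop = by_disorder.loc[d.id]
        else:
            continue
        res = registry.paf_for(d)
        row = {
            "condition": condition,
            "disorder": d.id,
            "label": d.label,
            "paf": res.paf,
            "paf_lo": res.paf_lo,
            "paf_hi": res.paf_hi,
        }
        for metric in HOSPITAL_METRICS:
            total = float(pop[metric if metric != "patients" else "patients"])
            point, lo, hi = attribute_interval(total, res)
            row[f"pop_{metric}"] = total
            row[metric] = point
            row[f"{metric}_lo"] = lo
            row[f"{metric}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def run_condition(
    admissions: pd.DataFrame, registry: Registry, condition: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-condition pipeline: episodes -> means -> attribution.

    Returns ``(annual_means, attributable)``.
    """
    episodes = build_episodes(admissions)
    if not episodes.empty:
        episodes["disorder"] = assign_disorders(episodes, registry, condition)
    annual = summarize_annual(episodes, registry, condition)
    means = annual_means(annual, registry.years("hospital"))
    return means, attribute_hospital_burden(means, registry, condition)
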