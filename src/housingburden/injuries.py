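"""Home-fall injury claims: filtering, severity aggregation, attribution.

New Zealand's no-fault accident compensation scheme records every
medically treated injury as a claim in one of six mutually exclusive
severity categories.  The analysis keeps claims where the injury scene
was the home, the claimant was a resident and the cause implies a fall,
then attributes annual mean counts and costs per severity with a single
falls PAF.  The default falls PAF is 0.2444, the ratio implied by the
published attributable claims table; the narrative figure of 26% is kept
in the registry as an alternative.
"""

from __future__ import annotations

import logging

import pandas as pd

from .registry import Registry

logger = logging.getLogger("housingburden")

SEVERITIES = (
    "fatal",
    "serious_injury",
    "hospitalization",
    "entitlement",
    "medical_fee_only",
    "other",
)

CLAIM_COLUMNS = ["scene", "cause_class", "resident", "severity", "cost", "year"]


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"scene": str, "cause_class": str, "severity": str})
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"claims register {path} lacks columns: {missing}")
    return df


def filter_claims(claims: pd.DataFrame, years: list[int] | None = None) -> pd.DataFrame:
    """Keep home-scene, resident, fall-cause claims with a known severity."""
    bad = ~claims["severity"].isin(SEVERITIES)
    if bad.any():
        logger.warning(
            "claims: rejected %d records with unknown severity labels %s",
            int(bad.sum()),
            sorted(claims.loc[bad, "severity"].unique().tolist()),
        )
        claims = claims[~bad]
    keep = (
        (claims["scene"] == "home")
        & (claims["cause_class"] == "fall")
        & claims["resident"].astype(bool)
    )
    if years is not None:
        keep &= claims["year"].isin(years)
    return claims[keep].reset_index(drop=True)


def summarize_claims(claims: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Annual mean claim count and cost per severity over a fixed span."""
    rows = []
    n_years = float(len(years))
    grouped = (
        claims.groupby("severity").agg(n=("severity", "size"), cost=("cost", "sum"))
        if not claims.empty
        else pd.DataFrame(columns=["n", "cost"])
    )
    for sev in SEVERITIES:
        if sev in grouped.index:
            n = float(grouped.loc[sev, "n"]) / n_years
            cost = float(grouped.loc[sev, "cost"]) / n_years
        else:
            n, cost = 0.0, 0.0
        rows.append({"severity": sev, "claims": n, "cost_nzd": cost})
    return pd.DataFrame(rows)


def attribute_claims(summary: pd.DataFrame, falls_paf: float) -> pd.DataFrame:
    """Attributable claim counts and costs per severity (unrounded).

    Severity categories partition claims, so attributable values sum to
    the attributable total exactly before rounding.
    """
    if not 0.0 <= falls_paf <= 1.0:
        raise ValueError(f"falls PAF {falls_paf!r} outside [0, 1]")
    out = summary.copy()
    out["attributable_claims"] = out["claims"] * falls_paf
    out["attributable_cost_nzd"] = out["cost_nzd"] * falls_paf
    return out


def run_claims(
    claims: pd.DataFrame,
    registry: Registry,
    falls_paf: float | None = None,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Filter -> annual means -> attribution, using the registry defaults."""
    years = years if years is not None else registry.years("claim")
    kept = filter_claims(claims, years)
    summary = summarize_claims(kept, years)
    return attribute_claims(summary, registry.falls_paf if falls_paf is None else falls_paf)


def fatal_attributable(attributed: pd.DataFrame) -> float:
    """Attributable fatal falls per year (feeds the mortality grand total)."""
    row = attributed[attributed["severity"] == "fatal"]
    return float(row["attributable_claims"].iloc[0]) if not row.empty else 0.0
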