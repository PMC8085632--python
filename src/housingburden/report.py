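"""Assemble attributable-burden tables and grand totals into a report bundle.

The bundle mirrors the analysis outputs: a PAF table, an attributable
hospitalization table, an attributable claims table, an attributable
mortality table, and grand totals (direct public-sector cost; total
attributable deaths including fatal falls; societal mortality cost at the
VSL).  All internal values are unrounded; display rounding (half-up, one
decimal for fractions and deaths, whole units for counts/costs/nights)
happens only when tables are written out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from ._util import round_half_up
from .episodes import clean_admissions, read_admissions, run_condition
from .injuries import fatal_attributable, read_claims, run_claims
from .mortality import attribute_deaths, cost_mortality, read_deaths
from .registry import Registry
from .synth import GeneratorConfig, calibrate_published, generate_register

logger = logging.getLogger("housingburden")

AdmissionsInput = Union[pd.DataFrame, str, Path, Mapping[str, Union[pd.DataFrame, str, Path]]]


@dataclass
class ReportBundle:
    """All result tables (unrounded) plus grand totals."""

    table_paf: pd.DataFrame
    table_hospital: pd.DataFrame
    table_claims: pd.DataFrame
    table_mortality: pd.DataFrame
    grand_totals: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "paf": _display_paf(self.table_paf),
            "hospitalizations": _display_hospital(self.table_hospital),
            "claims": _display_claims(self.table_claims),
            "mortality": _display_mortality(self.table_mortality),
        }
        for name, df in tables.items():
            p = out_dir / f"table_{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        bundle_path = out_dir / "bundle.json"
        with open(bundle_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "grand_totals": self.grand_totals,
                    "tables": {
                        "paf": self.table_paf.to_dict(orient="records"),
                        "hospitalizations": self.table_hospital.to_dict(orient="records"),
                        "claims": self.table_claims.to_dict(orient="records"),
                        "mortality": self.table_mortality.to_dict(orient="records"),
                    },
                },
                fh,
                indent=2,
                default=str,
            )
        paths["bundle"] = bundle_path
        return paths


def _count(x: float) -> float:
    """Counts print as whole numbers except sub-unit values (one decimal)."""
    return round_half_up(x, 1) if 0 < x < 1 else float(int(round_half_up(x)))


def _display_paf(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in ("paf_pct", "paf_pct_lo", "paf_pct_hi"):
        out[c] = out[c].map(lambda v: round_half_up(v, 1))
    return out


def _display_hospital(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if out.empty:
        return out
    out["paf_pct"] = (100 * out["paf"]).map(lambda v: round_half_up(v, 1))
    for m in ("patients", "hospitalizations", "nights"):
        for suffix in ("", "_lo", "_hi"):
            out[m + suffix] = out[m + suffix].map(_count)
    for suffix in ("", "_lo", "_hi"):
        out["cost_nzd" + suffix] = out["cost_nzd" + suffix].map(
            lambda v: int(round_half_up(v))
        )
    keep = ["condition", "label", "paf_pct"] + [
        m + s
        for m in ("patients", "hospitalizations", "cost_nzd", "nights")
        for s in ("", "_lo", "_hi")
    ]
    return out[keep]


def _display_claims(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if out.empty:
        return out
    for c in ("claims", "attributable_claims"):
        out[c] = out[c].map(_count)
    for c in ("cost_nzd", "attributable_cost_nzd"):
        out[c] = out[c].map(lambda v: int(round_half_up(v)))
    return out


def _display_mortality(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if out.empty:
        return out
    out["pop_deaths"] = out["pop_deaths"].map(_count)
    out["paf_pct"] = (100 * out["paf"]).map(lambda v: round_half_up(v, 1))
    for c in ("deaths", "deaths_lo", "deaths_hi"):
        out[c] = out[c].map(lambda v: round_half_up(v, 1))
    return out[
        ["condition", "category", "pop_deaths", "paf_pct", "deaths", "deaths_lo", "deaths_hi"]
    ]


def _as_admissions_frame(value) -> pd.DataFrame:
    if isinstance(value, pd.DataFrame):
        return clean_admissions(value)
    return read_admissions(value)


def run_pipeline(
    admissions: AdmissionsInput,
    deaths: Union[pd.DataFrame, str, Path, None],
    claims: Union[pd.DataFrame, str, Path, None],
    registry: Optional[Registry] = None,
    out_dir: str | Path | None = None,
    falls_paf: Optional[float] = None,
    vsl: Optional[float] = None,
    usd_per_nzd: Optional[float] = None,
    claim_years: Optional[list[int]] = None,
) -> ReportBundle:
    """Run every stage over record-level registers and assemble the bundle.

    ``admissions`` may be a single register applied to every housing
    condition, or a mapping from condition id to a per-condition register
    (useful when registers were generated per condition to avoid the
    cross-condition code overlap inflating tallies).
    """
    registry = registry or Registry.load()
    vsl = vsl if vsl is not None else registry.vsl_nzd
    fx = usd_per_nzd if usd_per_nzd is not None else registry.usd_per_nzd

    if isinstance(admissions, Mapping):
        adm_by_cond = {c: _as_admissions_frame(v) for c, v in admissions.items()}
    elif admissions is None:
        adm_by_cond = {}
    else:
        shared = _as_admissions_frame(admissions)
        adm_by_cond = {c: shared for c in registry.hospital_conditions}

    hosp_parts = []
    for cond in registry.hospital_conditions:
        if cond not in adm_by_cond:
            continue
        _, attributed = run_condition(adm_by_cond[cond], registry, cond)
        if not attributed.empty:
            hosp_parts.append(attributed)
    table_hospital = (
        pd.concat(hosp_parts, ignore_index=True)
        if hosp_parts
        else pd.DataFrame(
            columns=["condition", "disorder", "label", "paf", "paf_lo", "paf_hi"]
        )
    )

    if deaths is not None:
        deaths_df = deaths if isinstance(deaths, pd.DataFrame) else read_deaths(deaths)
        mort_parts = [
            attribute_deaths(deaths_df, registry, cond)
            for cond in registry.hospital_conditions
        ]
        table_mortality = pd.concat(
            [m for m in mort_parts if not m.empty], ignore_index=True
        ) if any(not m.empty for m in mort_parts) else pd.DataFrame(
            columns=["condition", "category", "pop_deaths", "paf", "deaths", "deaths_lo", "deaths_hi"]
        )
    else:
        table_mortality = pd.DataFrame(
            columns=["condition", "category", "pop_deaths", "paf", "deaths", "deaths_lo", "deaths_hi"]
        )

    if claims is not None:
        claims_df = claims if isinstance(claims, pd.DataFrame) else read_claims(claims)
        years = claim_years if claim_years is not None else registry.years("claim")
        table_claims = run_claims(claims_df, registry, falls_paf, years=years)
    else:
        table_claims = pd.DataFrame(
            columns=["severity", "claims", "cost_nzd", "attributable_claims", "attributable_cost_nzd"]
        )

    hospital_cost = float(table_hospital["cost_nzd"].sum()) if "cost_nzd" in table_hospital else 0.0
    claims_cost = float(table_claims["attributable_cost_nzd"].sum()) if len(table_claims) else 0.0
    condition_deaths = float(table_mortality["deaths"].sum()) if len(table_mortality) else 0.0
    fall_deaths = fatal_attributable(table_claims) if len(table_claims) else 0.0
    total_deaths = condition_deaths + fall_deaths
    mortality_cost = cost_mortality(total_deaths, vsl)
    direct_cost = hospital_cost + claims_cost

    grand_totals = {
        "hospital_cost_nzd": hospital_cost,
        "claims_cost_nzd": claims_cost,
        "direct_cost_nzd": direct_cost,
        "direct_cost_usd": direct_cost * fx,
        "condition_deaths": condition_deaths,
        "fall_deaths": fall_deaths,
        "total_deaths": total_deaths,
        "mortality_cost_nzd": mortality_cost,
        "mortality_cost_usd": mortality_cost * fx,
        "usd_per_nzd": fx,
        "vsl_nzd": vsl,
    }

    bundle = ReportBundle(
        table_paf=registry.paf_table(),
        table_hospital=table_hospital,
        table_claims=table_claims,
        table_mortality=table_mortality,
        grand_totals=grand_totals,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "events.log", mode="a")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        try:
            bundle.write(out_dir)
        finally:
            logger.removeHandler(handler)
            handler.close()
    return bundle


def reproduce_printed(
    registry: Optional[Registry] = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    conditions: Optional[list[str]] = None,
) -> ReportBundle:
    """End-to-end golden run on calibrated expectation-mode registers.

    One admissions register is generated per housing condition (the
    published per-condition tallies overlap in diagnosis codes, so a
    shared register would double-feed overlapping disorders); the death
    register uses the overlap-resolved allocation; the claims register is
    generated for a single year, which in expectation mode carries the
    exact annual means.
    """
    from .synth import calibrate_claim_rates, calibrate_death_allocation

    registry = registry or Registry.load()
    conds = conditions or registry.hospital_conditions
    admissions: dict[str, pd.DataFrame] = {}
    for cond in conds:
        cfg = calibrate_published(registry, condition=cond, mode="expectation", seed=seed)
        cfg.deaths, cfg.claims = [], []  # generated once below, not per condition
        admissions[cond] = generate_register(cfg)["admissions"]
    claim_years = [registry.years("claim")[0]]
    aux = GeneratorConfig(
        seed=seed,
        mode="expectation",
        hospital_years=registry.years("hospital"),
        mortality_years=registry.years("mortality"),
        claim_years=claim_years,
        deaths=calibrate_death_allocation(registry),
        claims=calibrate_claim_rates(registry),
    )
    tables = generate_register(aux)
    return run_pipeline(
        admissions=admissions,
        deaths=tables["deaths"],
        claims=tables["claims"],
        registry=registry,
        out_dir=out_dir,
        claim_years=claim_years,
    )
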