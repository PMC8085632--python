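"""Synthetic record-level registers: admissions, deaths, injury claims.

The real registers behind this analysis (national hospitalization and
mortality collections, no-fault accident claims) are confidential, so the
package ships a generator that emulates their structure at configurable
annual rates.  Two modes exist:

* ``expectation`` — deterministic: each (disorder, year) cell receives
  exactly the rounded expected number of admissions, with nights and costs
  distributed so that annual totals equal the configured expectations.
  This is what golden-table reproduction uses.
* ``stochastic`` — Poisson counts per cell, Poisson nights and exponential
  costs per admission, and optional within-7-day readmissions that the
  episode builder must re-merge.  Only aggregate annual means are
  specified by the study design, so any nonnegative cost law with the
  right mean satisfies calibration; the exponential is a modelling
  convenience.

Calibration back-derives population-level annual means from published
attributable values (population total = attributable / unrounded PAF) and
from the published population-level mortality and claims means.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._util import int_half_up
from .episodes import ADMISSION_COLUMNS
from .injuries import SEVERITIES
from .registry import Registry

DEATH_AGE = 70  # adult age outside every child-specific restriction


class CalibrationError(ValueError):
    """Raised when published targets cannot be back-derived (e.g. zero PAF)."""


@dataclass
class DisorderRates:
    """Annual population-level hospital rates for one (condition, disorder)."""

    condition: str
    disorder: str
    hospitalizations: float
    patients: float
    nights: float
    cost_nzd: float
    codes: list[str]
    age_lo: int = 0
    age_hi: int = 90
    readmission_prob: float = 0.0

    def validate(self) -> None:
        for name in ("hospitalizations", "patients", "nights", "cost_nzd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.condition}/{self.disorder}: {name} < 0")
        if self.patients > self.hospitalizations + 1e-9:
            raise ValueError(
                f"{self.condition}/{self.disorder}: patients exceed hospitalizations"
            )
        if not self.codes:
            raise ValueError(f"{self.condition}/{self.disorder}: empty code set")
        if not 0.0 <= self.readmission_prob <= 1.0:
            raise ValueError(f"{self.condition}/{self.disorder}: readmission_prob")


@dataclass
class DeathRates:
    code: str
    rate: float
    age: int = DEATH_AGE

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError(f"death rate for {self.code}: {self.rate} < 0")


@dataclass
class ClaimRates:
    severity: str
    rate: float
    mean_cost: float

    def validate(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown claim severity {self.severity!r}")
        if self.rate < 0 or self.mean_cost < 0:
            raise ValueError(f"claim rates for {self.severity}: negative value")


@dataclass
class GeneratorConfig:
    seed: int = 0
    mode: str = "expectation"  # or "stochastic"
    scale: float = 1.0
    hospital_years: list[int] = field(default_factory=lambda: list(range(2010, 2018)))
    mortality_years: list[int] = field(default_factory=lambda: list(range(2010, 2015)))
    claim_years: list[int] = field(default_factory=lambda: list(range(2010, 2018)))
    disorders: list[DisorderRates] = field(default_factory=list)
    deaths: list[DeathRates] = field(default_factory=list)
    claims: list[ClaimRates] = field(default_factory=list)
    noise_fraction: float = 0.02

    def validate(self) -> None:
        if self.mode not in {"expectation", "stochastic"}:
            raise ValueError(f"mode {self.mode!r} not expectation/stochastic")
        if not 0.0 <= self.scale <= 1.0:
            raise ValueError(f"scale {self.scale!r} outside [0, 1]")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError(f"noise_fraction {self.noise_fraction!r} outside [0, 1]")
        for entry in (*self.disorders, *self.deaths, *self.claims):
            entry.validate()

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["disorders"] = [DisorderRates(**d) for d in raw.get("disorders", [])]
        raw["deaths"] = [DeathRates(**d) for d in raw.get("deaths", [])]
        raw["claims"] = [ClaimRates(**d) for d in raw.get("claims", [])]
        return cls(**raw)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate_hospital_rates(
    registry: Registry, condition: Optional[str] = None
) -> list[DisorderRates]:
    """Back-derive per-disorder population rates from published attributables.

    population annual mean = published attributable value / unrounded PAF.
    """
    out = []
    for d in registry.disorders:
        if condition is not None and d.condition != condition:
            continue
        targets = d.hospital_annual_attributable
        if not targets:
            continue
        paf = registry.paf_for(d).paf
        if paf == 0.0 and any(v > 0 for v in targets.values()):
            raise CalibrationError(
                f"{d.condition}/{d.id}: nonzero attributable with zero PAF"
            )
        out.append(
            DisorderRates(
                condition=d.condition,
                disorder=d.id,
                hospitalizations=targets["hospitalizations"] / paf,
                patients=targets["patients"] / paf,
                nights=targets["nights"] / paf,
                cost_nzd=targets["cost_nzd"] / paf,
                codes=registry.codes_for(d.condition, d.id),
                age_lo=d.age_min if d.age_min is not None else 0,
                age_hi=min(d.age_max if d.age_max is not None else 90, 90),
            )
        )
    return out


def calibrate_death_allocation(registry: Registry) -> list[DeathRates]:
    """One death register consistent with every condition's mortality means.

    Conditions are tallied independently and their diagnosis patterns
    overlap (influenza codes count under crowding, cold and damp at once),
    so the published per-condition means constrain *sums* over disjoint
    code pools.  The allocation resolves the overlaps explicitly:

    * influenza codes carry the crowding-influenza mean and simultaneously
      feed the cold (winter colds/influenza) and damp (pneumonia/LRTI)
      categories;
    * the cold category's remainder goes to the common-cold code, which
      also feeds damp URTI;
    * the damp URTI and pneumonia remainders go to codes unique to damp.

    All death records are generated at an adult age so that child-specific
    crowding disorders are untouched.
    """
    entries: list[DeathRates] = []

    def deaths_of(condition: str, disorder: str) -> float:
        try:
            return registry.get(condition, disorder).deaths_annual_mean
        except KeyError:
            return 0.0

    flu_rate = deaths_of("crowding", "influenza")
    flu_codes = set(registry.codes_for("crowding", "influenza"))
    if flu_rate:
        entries.append(DeathRates(code=sorted(flu_codes)[0], rate=flu_rate))

    cold_extra = max(0.0, deaths_of("cold", "winter_colds_influenza") - flu_rate)
    cold_codes = [
        c for c in registry.codes_for("cold", "winter_colds_influenza")
        if c not in flu_codes
    ]
    if cold_extra and cold_codes:
        entries.append(DeathRates(code=cold_codes[0], rate=cold_extra))
    shared_with_cold = set(cold_codes[:1])

    damp_urti_extra = max(0.0, deaths_of("damp_mould", "urti") - cold_extra)
    urti_codes = [
        c
        for c in registry.codes_for("damp_mould", "urti")
        if c not in flu_codes and c not in shared_with_cold
    ]
    if damp_urti_extra and urti_codes:
        entries.append(DeathRates(code=urti_codes[0], rate=damp_urti_extra))

    damp_pneu_extra = max(0.0, deaths_of("damp_mould", "pneumonia_lrti") - flu_rate)
    pneu_codes = [
        c
        for c in registry.codes_for("damp_mould", "pneumonia_lrti")
        if c not in flu_codes and c not in shared_with_cold
    ]
    if damp_pneu_extra and pneu_codes:
        entries.append(DeathRates(code=pneu_codes[0], rate=damp_pneu_extra))

    handled = {
        ("crowding", "influenza"),
        ("cold", "winter_colds_influenza"),
        ("damp_mould", "urti"),
        ("damp_mould", "pneumonia_lrti"),
    }
    for d in registry.disorders:
        if (d.condition, d.id) in handled or d.deaths_annual_mean <= 0:
            continue
        codes = registry.codes_for(d.condition, d.id)
        if not codes:
            raise CalibrationError(f"{d.condition}/{d.id}: no codes for death records")
        entries.append(DeathRates(code=codes[0], rate=d.deaths_annual_mean))
    return entries


def calibrate_claim_rates(registry: Registry) -> list[ClaimRates]:
    out = []
    for sev in registry.claim_severities:
        n = float(sev["annual_claims"])
        cost = float(sev["annual_cost_nzd"])
        out.append(
            ClaimRates(severity=sev["id"], rate=n, mean_cost=cost / n if n else 0.0)
        )
    return out


def calibrate_published(
    registry: Registry,
    condition: Optional[str] = None,
    mode: str = "expectation",
    seed: int = 0,
    scale: float = 1.0,
    readmission_prob: float = 0.0,
) -> GeneratorConfig:
    """Generator configuration whose expected pipeline output reproduces the
    published attributable tables (for hospital conditions) and population
    means (deaths, claims)."""
    disorders = calibrate_hospital_rates(registry, condition)
    for entry in disorders:
        entry.readmission_prob = readmission_prob
    cfg = GeneratorConfig(
        seed=seed,
        mode=mode,
        scale=scale,
        hospital_years=registry.years("hospital"),
        mortality_years=registry.years("mortality"),
        claim_years=registry.years("claim"),
        disorders=disorders,
        deaths=calibrate_death_allocation(registry),
        claims=calibrate_claim_rates(registry),
    )
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _cell_counts(
    rate: float, scale: float, mode: str, rng: np.random.Generator
) -> int:
    lam = rate * scale
    if mode == "expectation":
        return int_half_up(lam)
    return int(rng.poisson(lam))


def generate_admissions(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Admission records for every (disorder, year) cell.

    Episodes of one patient are spaced more than 7 days apart so each
    generated episode survives episode construction as its own case; in
    stochastic mode a configurable fraction of episodes gains a second
    admission *within* the 7-day window, which the episode builder must
    merge back.
    """
    frames = []
    for entry in config.disorders:
        n_codes = len(entry.codes)
        mean_nights = (
            entry.nights / entry.hospitalizations if entry.hospitalizations else 0.0
        )
        mean_cost = (
            entry.cost_nzd / entry.hospitalizations if entry.hospitalizations else 0.0
        )
        for year in config.hospital_years:
            n = _cell_counts(entry.hospitalizations, config.scale, config.mode, rng)
            if n == 0:
                continue
            p_ratio = entry.patients / entry.hospitalizations
            n_pat = max(1, min(n, int_half_up(n * p_ratio)))
            idx = np.arange(n)
            pat_idx = idx % n_pat

            if config.mode == "expectation":
                nights_total = int_half_up(entry.nights * config.scale)
                base, rem = divmod(nights_total, n)
                nights = np.full(n, base, dtype=np.int64)
                nights[:rem] += 1
                costs = np.full(n, entry.cost_nzd * config.scale / n)
                ages = np.full(n, (entry.age_lo + entry.age_hi) // 2, dtype=np.int64)
                codes = np.asarray(entry.codes, dtype=object)[idx % n_codes]
            else:
                nights = rng.poisson(mean_nights, size=n)
                costs = rng.exponential(mean_cost, size=n) if mean_cost else np.zeros(n)
                ages = rng.integers(entry.age_lo, entry.age_hi + 1, size=n)
                codes = rng.choice(np.asarray(entry.codes, dtype=object), size=n)

            # schedule episodes per patient with > 7-day separation
            admit_off = np.empty(n, dtype=np.int64)
            offsets = np.zeros(n_pat, dtype=np.int64)
            k = 0
            while k * n_pat < n:
                sel = idx[(idx >= k * n_pat) & (idx < (k + 1) * n_pat)]
                admit_off[sel] = offsets[sel - k * n_pat]
                offsets[sel - k * n_pat] += nights[sel] + 8
                k += 1
            start = pd.Timestamp(year=year, month=1, day=15)
            admit = start + pd.to_timedelta(admit_off, unit="D")
            discharge = admit + pd.to_timedelta(nights, unit="D")

            frame = pd.DataFrame(
                {
                    "patient_id": [
                        f"{entry.condition}:{entry.disorder}:{year}:p{j}"
                        for j in pat_idx
                    ],
                    "admit_date": admit,
                    "discharge_date": discharge,
                    "diag1": codes,
                    "diag2": "",
                    "diag3": "",
                    "age_years": ages,
                    "cost": costs,
                }
            )
            if config.mode == "stochastic" and entry.readmission_prob > 0:
                split = rng.random(n) < entry.readmission_prob
                if split.any():
                    extra = frame[split].copy()
                    gap = rng.integers(0, 8, size=len(extra))
                    stay = rng.poisson(1.0, size=len(extra))
                    extra["admit_date"] = extra["discharge_date"] + pd.to_timedelta(
                        gap, unit="D"
                    )
                    extra["discharge_date"] = extra["admit_date"] + pd.to_timedelta(
                        stay, unit="D"
                    )
                    extra["cost"] = rng.exponential(mean_cost, size=len(extra))
                    frame = pd.concat([frame, extra], ignore_index=True)
            if config.mode == "stochastic" and config.noise_fraction > 0:
                n_noise = rng.poisson(config.noise_fraction * n)
                if n_noise:
                    nd = pd.Timestamp(year=year, month=6, day=1)
                    frames.append(
                        pd.DataFrame(
                            {
                                "patient_id": [
                                    f"noise:{entry.condition}:{year}:p{j}"
                                    for j in range(n_noise)
                                ],
                                "admit_date": nd,
                                "discharge_date": nd,
                                "diag1": "Z000",
                                "diag2": "",
                                "diag3": "",
                                "age_years": 40,
                                "cost": 0.0,
                            }
                        )
                    )
            frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=ADMISSION_COLUMNS)
    return pd.concat(frames, ignore_index=True)[ADMISSION_COLUMNS]


def generate_deaths(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = {"underlying_cause": [], "year": [], "age_years": []}
    for entry in config.deaths:
        for year in config.mortality_years:
            n = _cell_counts(entry.rate, config.scale, config.mode, rng)
            rows["underlying_cause"].extend([entry.code] * n)
            rows["year"].extend([year] * n)
            rows["age_years"].extend([entry.age] * n)
    return pd.DataFrame(rows)


def generate_claims(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for entry in config.claims:
        for year in config.claim_years:
            n = _cell_counts(entry.rate, config.scale, config.mode, rng)
            if n == 0:
                continue
            if config.mode == "expectation":
                costs = np.full(n, entry.mean_cost)
            else:
                costs = rng.exponential(entry.mean_cost, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "scene": "home",
                        "cause_class": "fall",
                        "resident": True,
                        "severity": entry.severity,
                        "cost": costs,
                        "year": year,
                    }
                )
            )
            # non-qualifying claims exercise the filter and are dropped by it
            n_noise = (
                int_half_up(config.noise_fraction * n)
                if config.mode == "expectation"
                else int(rng.poisson(config.noise_fraction * n))
            )
            if n_noise:
                frames.append(
                    pd.DataFrame(
                        {
                            "scene": ["road", "home"] * (n_noise // 2) + ["road"] * (n_noise % 2),
                            "cause_class": ["fall", "burn"] * (n_noise // 2)
                            + ["fall"] * (n_noise % 2),
                            "resident": True,
                            "severity": entry.severity,
                            "cost": entry.mean_cost,
                            "year": year,
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=["scene", "cause_class", "resident", "severity", "cost", "year"])
    return pd.concat(frames, ignore_index=True)


def generate_register(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame | Path]:
    """Generate the three registers; optionally write them as CSV files.

    Returns a dict with keys ``admissions``, ``deaths``, ``claims`` holding
    DataFrames (or file paths when ``out_dir`` is given).  Fixed seed and
    config give byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables = {
        "admissions": generate_admissions(config, rng),
        "deaths": generate_deaths(config, rng),
        "claims": generate_claims(config, rng),
    }
    if out_dir is None:
        return tables
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path
    return paths
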