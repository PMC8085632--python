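"""Condition/disorder registry: exposures, exposure-response measures,
diagnosis patterns and age restrictions, loaded from an editable YAML file.

The registry is the single source of truth for classification.  Within one
housing condition every diagnosis code resolves to at most one disorder:
patterns are ranked by specificity (longer exact prefixes first, exact
prefixes ahead of category ranges of equal length) with the listing order
in the configuration as the final tie-break.  Conditions are tallied
independently of each other, so the same code may, by design, contribute
to different disorders under different housing conditions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .icd import IcdPattern, expand_pattern, normalize_code, parse_icd_patterns
from .paf import PAFResult

HOSPITAL_METRICS = ("patients", "hospitalizations", "cost_nzd", "nights")


class RegistryError(ValueError):
    """Raised when the registry configuration fails validation."""


@dataclass(frozen=True)
class ExposureEstimate:
    """Proportion of the population exposed to a housing condition."""

    condition: str
    stratum: str
    p: float
    p_lo: float
    p_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_lo <= self.p <= self.p_hi <= 1.0:
            raise RegistryError(
                f"exposure for {self.condition}/{self.stratum}: bounds "
                f"({self.p_lo}, {self.p}, {self.p_hi}) must be ordered in [0, 1]"
            )


@dataclass(frozen=True)
class ExposureResponse:
    """Exposure-response measure (OR/RR/IRR treated alike) with 95% CI."""

    condition: str
    disorder: str
    rr: float
    rr_lo: float
    rr_hi: float
    measure_kind: str = "OR"

    def __post_init__(self) -> None:
        if not 0.0 < self.rr_lo <= self.rr <= self.rr_hi:
            raise RegistryError(
                f"measure for {self.condition}/{self.disorder}: bounds "
                f"({self.rr_lo}, {self.rr}, {self.rr_hi}) must be ordered and > 0"
            )
        if self.measure_kind not in {"OR", "RR", "IRR"}:
            raise RegistryError(
                f"measure kind {self.measure_kind!r} not one of OR/RR/IRR"
            )


@dataclass
class DisorderSpec:
    """One health disorder under one housing condition."""

    id: str
    condition: str
    label: str
    icd_text: str
    patterns: list[IcdPattern]
    exposure_stratum: str
    measure: ExposureResponse
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    paf_group: Optional[str] = None
    mortality_category: Optional[str] = None
    hospital_annual_attributable: Optional[dict[str, float]] = None
    deaths_annual_mean: float = 0.0
    order: int = 0

    def __post_init__(self) -> None:
        if not self.patterns:
            raise RegistryError(f"disorder {self.condition}/{self.id} has no ICD patterns")
        if (
            self.age_min is not None
            and self.age_max is not None
            and self.age_min > self.age_max
        ):
            raise RegistryError(f"disorder {self.condition}/{self.id}: age_min > age_max")

    @property
    def group(self) -> str:
        """Display group sharing one PAF row (defaults to the disorder label)."""
        return self.paf_group or self.label

    @property
    def mortality_label(self) -> str:
        return self.mortality_category or self.label

    def age_allows(self, age: Optional[float]) -> bool:
        if age is None:
            return True
        if self.age_min is not None and age < self.age_min:
            return False
        if self.age_max is not None and age > self.age_max:
            return False
        return True

    def representative_age(self) -> int:
        """An age guaranteed inside the restriction (for synthetic records)."""
        if self.age_min is None and self.age_max is None:
            return 45
        lo = self.age_min if self.age_min is not None else 0
        hi = self.age_max if self.age_max is not None else 90
        return (lo + hi) // 2


@dataclass
class HousingCondition:
    id: str
    label: str
    exposures: dict[str, ExposureEstimate] = field(default_factory=dict)


class Registry:
    """Validated registry of housing conditions and associated disorders."""

    def __init__(
        self,
        conditions: dict[str, HousingCondition],
        disorders: list[DisorderSpec],
        meta: dict,
        falls_paf: float = 0.2444,
        falls_paf_stated: float = 0.26,
        claim_severities: Optional[list[dict]] = None,
    ) -> None:
        self.conditions = conditions
        self.disorders = disorders
        self.meta = meta
        self.falls_paf = falls_paf
        self.falls_paf_stated = falls_paf_stated
        self.claim_severities = claim_severities or []
        self._match_order: dict[str, list[tuple[IcdPattern, DisorderSpec]]] = {}
        self._classify_cache: dict[tuple[str, str], tuple[str, ...]] = {}
        self.validate()

    # ------------------------------------------------------------------ load
    @classmethod
    def default_path(cls) -> Path:
        return Path(resources.files("housingburden").joinpath("data/registry.yaml"))

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Registry":
        path = Path(path) if path is not None else cls.default_path()
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "Registry":
        conditions: dict[str, HousingCondition] = {}
        falls_paf, falls_stated = 0.2444, 0.26
        for cid, craw in raw.get("conditions", {}).items():
            cond = HousingCondition(id=cid, label=craw.get("label", cid))
            for e in craw.get("exposures", []) or []:
                est = ExposureEstimate(
                    condition=cid,
                    stratum=e["stratum"],
                    p=float(e["p"]),
                    p_lo=float(e["p_lo"]),
                    p_hi=float(e["p_hi"]),
                )
                if est.stratum in cond.exposures:
                    raise RegistryError(
                        f"condition {cid}: duplicate exposure stratum {est.stratum!r}"
                    )
                cond.exposures[est.stratum] = est
            if "falls_paf" in craw:
                falls_paf = float(craw["falls_paf"])
                falls_stated = float(craw.get("falls_paf_stated", falls_stated))
            conditions[cid] = cond

        disorders: list[DisorderSpec] = []
        for i, d in enumerate(raw.get("disorders", [])):
            m = d["measure"]
            age = d.get("age_range")
            targets = d.get("hospital_annual_attributable")
            if targets is not None:
                targets = {k: float(v) for k, v in targets.items()}
            disorders.append(
                DisorderSpec(
                    id=d["id"],
                    condition=d["condition"],
                    label=d.get("label", d["id"]),
                    icd_text=d["icd"],
                    patterns=parse_icd_patterns(d["icd"]),
                    exposure_stratum=d.get("exposure_stratum", "all"),
                    measure=ExposureResponse(
                        condition=d["condition"],
                        disorder=d["id"],
                        rr=float(m["rr"]),
                        rr_lo=float(m["rr_lo"]),
                        rr_hi=float(m["rr_hi"]),
                        measure_kind=m.get("kind", "OR"),
                    ),
                    age_min=None if age is None or age[0] is None else int(age[0]),
                    age_max=None if age is None or age[1] is None else int(age[1]),
                    paf_group=d.get("paf_group"),
                    mortality_category=d.get("mortality_category"),
                    hospital_annual_attributable=targets,
                    deaths_annual_mean=float(d.get("deaths_annual_mean", 0.0)),
                    order=i,
                )
            )

        meta = dict(raw.get("meta", {}))
        claims = (raw.get("claims") or {}).get("severities")
        return cls(
            conditions=conditions,
            disorders=disorders,
            meta=meta,
            falls_paf=falls_paf,
            falls_paf_stated=falls_stated,
            claim_severities=claims,
        )

    # -------------------------------------------------------------- validate
    def validate(self) -> None:
        for d in self.disorders:
            if d.condition not in self.conditions:
                raise RegistryError(
                    f"disorder {d.id!r} references unknown condition {d.condition!r}"
                )
            cond = self.conditions[d.condition]
            if d.exposure_stratum not in cond.exposures:
                raise RegistryError(
                    f"disorder {d.condition}/{d.id} references missing exposure "
                    f"stratum {d.exposure_stratum!r}"
                )
        for cid in {d.condition for d in self.disorders}:
            seen: dict[tuple[str, str, str], str] = {}
            for d in self.condition_disorders(cid):
                for p in d.patterns:
                    key = (p.kind, p.lo, p.hi)
                    if key in seen and seen[key] != d.id:
                        raise RegistryError(
                            f"condition {cid}: identical pattern {p.lo}-{p.hi} in both "
                            f"{seen[key]!r} and {d.id!r} (ambiguous at equal priority)"
                        )
                    seen[key] = d.id

    # ---------------------------------------------------------------- access
    def condition_disorders(self, condition: str) -> list[DisorderSpec]:
        return [d for d in self.disorders if d.condition == condition]

    def get(self, condition: str, disorder: str) -> DisorderSpec:
        for d in self.disorders:
            if d.condition == condition and d.id == disorder:
                return d
        raise KeyError(f"no disorder {disorder!r} under condition {condition!r}")

    @property
    def hospital_conditions(self) -> list[str]:
        """Conditions attributed through the hospitalization/mortality path."""
        return [c for c in self.conditions if self.condition_disorders(c)]

    def years(self, which: str) -> list[int]:
        lo, hi = self.meta[f"{which}_years"]
        return list(range(int(lo), int(hi) + 1))

    @property
    def vsl_nzd(self) -> float:
        return float(self.meta.get("vsl_nzd", 4_200_000))

    @property
    def usd_per_nzd(self) -> float:
        return float(self.meta.get("usd_per_nzd", 0.7148))

    # ---------------------------------------------------------- classification
    def _ordered_patterns(self, condition: str) -> list[tuple[IcdPattern, DisorderSpec]]:
        if condition not in self._match_order:
            pairs = [
                (p, d) for d in self.condition_disorders(condition) for p in d.patterns
            ]
            pairs.sort(
                key=lambda pd: (
                    -pd[0].specificity,
                    0 if pd[0].kind == "prefix" else 1,
                    pd[1].order,
                )
            )
            self._match_order[condition] = pairs
        return self._match_order[condition]

    def _candidates(self, code: str, condition: str) -> tuple[str, ...]:
        """Disorder ids matching a normalized code, in priority order."""
        key = (condition, code)
        if key not in self._classify_cache:
            hits: list[str] = []
            for pattern, d in self._ordered_patterns(condition):
                if pattern.matches(code) and d.id not in hits:
                    hits.append(d.id)
            self._classify_cache[key] = tuple(hits)
        return self._classify_cache[key]

    def classify_code(
        self, code: str, condition: str, age: Optional[float] = None
    ) -> Optional[str]:
        """Map a diagnosis code to a disorder id under one housing condition.

        Returns ``None`` when no pattern matches or the age restriction of
        every matching disorder excludes the given age.
        """
        if condition not in self.conditions:
            raise KeyError(f"unknown housing condition {condition!r}")
        norm = normalize_code(code)
        if not norm:
            return None
        for did in self._candidates(norm, condition):
            if self.get(condition, did).age_allows(age):
                return did
        return None

    def codes_for(self, condition: str, disorder: str) -> list[str]:
        """Concrete codes that classify back to the disorder (round-trip safe).

        Expands the disorder's own patterns and keeps the codes that still
        resolve to it after priority ordering, at an age inside its
        restriction.  Used by the synthetic register generator.
        """
        d = self.get(condition, disorder)
        age = d.representative_age()
        out: list[str] = []
        for p in d.patterns:
            for code in expand_pattern(p):
                if code not in out and self.classify_code(code, condition, age) == disorder:
                    out.append(code)
        return out

    # ------------------------------------------------------------------- paf
    def exposure_for(self, disorder: DisorderSpec) -> ExposureEstimate:
        return self.conditions[disorder.condition].exposures[disorder.exposure_stratum]

    def paf_for(self, disorder: DisorderSpec | tuple[str, str]) -> PAFResult:
        if isinstance(disorder, tuple):
            disorder = self.get(*disorder)
        exp = self.exposure_for(disorder)
        m = disorder.measure
        return PAFResult.from_inputs(
            p=exp.p, rr=m.rr, p_lo=exp.p_lo, p_hi=exp.p_hi, rr_lo=m.rr_lo, rr_hi=m.rr_hi
        )

    def paf_table(self) -> pd.DataFrame:
        """One row per (condition, PAF group): inputs and unrounded PAF (%).

        Disorders sharing a ``paf_group`` (e.g. the damp chapter-J split)
        collapse to a single row, as in the published fraction table.
        """
        rows = []
        seen: set[tuple[str, str]] = set()
        for d in self.disorders:
            key = (d.condition, d.group)
            if key in seen:
                continue
            seen.add(key)
            exp = self.exposure_for(d)
            res = self.paf_for(d)
            pct, lo, hi = res.percent
            rows.append(
                {
                    "condition": d.condition,
                    "condition_label": self.conditions[d.condition].label,
                    "group": d.group,
                    "measure_kind": d.measure.measure_kind,
                    "p": exp.p,
                    "p_lo": exp.p_lo,
                    "p_hi": exp.p_hi,
                    "rr": d.measure.rr,
                    "rr_lo": d.measure.rr_lo,
                    "rr_hi": d.measure.rr_hi,
                    "paf_pct": pct,
                    "paf_pct_lo": lo,
                    "paf_pct_hi": hi,
                }
            )
        return pd.DataFrame(rows)

    # -------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        out: dict = {"meta": copy.deepcopy(self.meta), "conditions": {}, "disorders": []}
        for cid, cond in self.conditions.items():
            centry: dict = {"label": cond.label}
            if cond.exposures:
                centry["exposures"] = [
                    {
                        "stratum": e.stratum,
                        "p": e.p,
                        "p_lo": e.p_lo,
                        "p_hi": e.p_hi,
                    }
                    for e in cond.exposures.values()
                ]
            if cid == "injury_hazards":
                centry["falls_paf"] = self.falls_paf
                centry["falls_paf_stated"] = self.falls_paf_stated
            out["conditions"][cid] = centry
        for d in self.disorders:
            entry: dict = {
                "id": d.id,
                "condition": d.condition,
                "label": d.label,
                "icd": d.icd_text,
                "exposure_stratum": d.exposure_stratum,
                "measure": {
                    "kind": d.measure.measure_kind,
                    "rr": d.measure.rr,
                    "rr_lo": d.measure.rr_lo,
                    "rr_hi": d.measure.rr_hi,
                },
            }
            if d.age_min is not None or d.age_max is not None:
                entry["age_range"] = [d.age_min, d.age_max]
            if d.paf_group:
                entry["paf_group"] = d.paf_group
            if d.mortality_category:
                entry["mortality_category"] = d.mortality_category
            if d.hospital_annual_attributable:
                entry["hospital_annual_attributable"] = dict(
                    d.hospital_annual_attributable
                )
            if d.deaths_annual_mean:
                entry["deaths_annual_mean"] = d.deaths_annual_mean
            out["disorders"].append(entry)
        if self.claim_severities:
            out["claims"] = {"severities": copy.deepcopy(self.claim_severities)}
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def sweep_classification(self, condition: str, age: Optional[float] = None) -> dict[str, str]:
        """Classify every three-character category; used in consistency checks."""
        from .icd import all_categories

        out = {}
        for cat in all_categories():
            hit = self.classify_code(cat, condition, age)
            if hit is not None:
                out[cat] = hit
        return out
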