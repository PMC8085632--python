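"""Synthetic register generator: determinism, calibration, round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from housingburden.episodes import run_condition
from housingburden.synth import (
    CalibrationError,
    ClaimRates,
    DisorderRates,
    GeneratorConfig,
    calibrate_hospital_rates,
    calibrate_published,
    generate_register,
)


def small_config(registry, mode="stochastic", seed=0, readmit=0.0):
    return GeneratorConfig(
        seed=seed,
        mode=mode,
        hospital_years=[2012, 2013, 2014, 2015],
        mortality_years=[2012],
        claim_years=[2012],
        disorders=[
            DisorderRates(
                condition="cold",
                disorder="wheeze",
                hospitalizations=120.0,
                patients=100.0,
                nights=90.0,
                cost_nzd=24_000.0,
                codes=registry.codes_for("cold", "wheeze"),
                readmission_prob=readmit,
            ),
            DisorderRates(
                condition="cold",
                disorder="copd_symptoms",
                hospitalizations=60.0,
                patients=40.0,
                nights=480.0,
                cost_nzd=50_000.0,
                codes=registry.codes_for("cold", "copd_symptoms"),
            ),
        ],
        claims=[ClaimRates(severity="other", rate=30.0, mean_cost=100.0)],
    )


def test_same_seed_gives_identical_files(tmp_path, registry):
    cfg = small_config(registry, seed=7)
    d1 = generate_register(cfg, tmp_path / "a")
    d2 = generate_register(cfg, tmp_path / "b")
    for name in ("admissions", "deaths", "claims"):
        assert d1[name].read_bytes() == d2[name].read_bytes()


def test_different_seed_differs(registry):
    a = generate_register(small_config(registry, seed=1))["admissions"]
    b = generate_register(small_config(registry, seed=2))["admissions"]
    assert not a.equals(b)


def test_scale_zero_empty(registry):
    cfg = small_config(registry, mode="expectation")
    cfg.scale = 0.0
    tables = generate_register(cfg)
    assert all(df.empty for df in tables.values())


def test_invalid_config_rejected(registry):
    cfg = small_config(registry)
    cfg.scale = 1.5
    with pytest.raises(ValueError, match="scale"):
        cfg.validate()
    cfg = small_config(registry)
    cfg.disorders[0].hospitalizations = -1
    with pytest.raises(ValueError, match="hospitalizations"):
        cfg.validate()
    cfg = small_config(registry)
    cfg.claims[0].severity = "bogus"
    with pytest.raises(ValueError, match="severity"):
        cfg.validate()


def test_config_json_roundtrip(tmp_path, registry):
    cfg = small_config(registry)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    again = GeneratorConfig.from_json(path)
    assert again == cfg


def test_calibration_back_derivation(registry):
    """Population rate = published attributable / unrounded PAF."""
    rates = {r.disorder: r for r in calibrate_hospital_rates(registry, "damp_mould")}
    assert rates["pneumonia_lrti"].hospitalizations == pytest.approx(20_254, abs=2)
    cold = {r.disorder: r for r in calibrate_hospital_rates(registry, "cold")}
    assert cold["wheeze"].hospitalizations == pytest.approx(2_150, abs=2)


def test_calibration_rejects_zero_paf(registry):
    raw = registry.to_dict()
    for d in raw["disorders"]:
        if d["condition"] == "cold" and d["id"] == "wheeze":
            d["measure"] = {"kind": "OR", "rr": 1.0, "rr_lo": 1.0, "rr_hi": 1.0}
    from housingburden.registry import Registry

    broken = Registry.from_dict(raw)
    with pytest.raises(CalibrationError):
        calibrate_hospital_rates(broken, "cold")


def test_generated_codes_classify_back(registry):
    cfg = calibrate_published(registry, condition="crowding", mode="stochastic", seed=3, scale=0.02)
    adm = generate_register(cfg)["admissions"]
    assert len(adm) > 0
    by_disorder = {d.id: d for d in registry.condition_disorders("crowding")}
    for _, row in adm.iterrows():
        if row["diag1"].startswith("Z"):
            continue  # noise records are meant to classify to nothing
        hit = registry.classify_code(row["diag1"], "crowding", row["age_years"])
        assert hit in by_disorder


def test_expectation_mode_reproduces_configured_rates(registry):
    cfg = small_config(registry, mode="expectation")
    adm = generate_register(cfg)["admissions"]
    registry_years = cfg.hospital_years
    means, _ = run_condition(adm, registry, "cold")
    # run_condition averages over the registry's configured span; recompute
    # over the generator's span instead
    from housingburden.episodes import annual_means, build_episodes, summarize_annual

    eps = build_episodes(adm)
    annual = summarize_annual(eps, registry, "cold")
    means = annual_means(annual, registry_years).set_index("disorder")
    assert means.loc["wheeze", "hospitalizations"] == 120.0
    assert means.loc["wheeze", "patients"] == 100.0
    assert means.loc["wheeze", "nights"] == 90.0
    assert means.loc["wheeze", "cost_nzd"] == pytest.approx(24_000.0)
    assert means.loc["copd_symptoms", "nights"] == 480.0


def test_stochastic_means_match_configuration(registry):
    """Pipeline summaries on stochastic registers agree with configured
    expectations within three standard errors, averaged over seeds."""
    from housingburden.episodes import annual_means, build_episodes, summarize_annual

    n_seeds, years = 8, 4
    totals = []
    for seed in range(n_seeds):
        cfg = small_config(registry, seed=seed)
        adm = generate_register(cfg)["admissions"]
        eps = build_episodes(adm)
        annual = summarize_annual(eps, registry, "cold")
        means = annual_means(annual, cfg.hospital_years).set_index("disorder")
        totals.append(float(means.loc["wheeze", "hospitalizations"]))
    rate = 120.0
    se = math.sqrt(rate / (years * n_seeds))
    assert abs(np.mean(totals) - rate) < 3 * se


def test_readmissions_within_window_merge_back(registry):
    """Episodes split into close re-admissions must re-merge, keeping the
    episode count at its configured expectation."""
    from housingburden.episodes import build_episodes

    cfg = small_config(registry, seed=11, readmit=0.5)
    adm = generate_register(cfg)["admissions"]
    eps = build_episodes(adm)
    n_admissions = len(adm)
    n_episodes = len(eps)
    assert n_admissions > n_episodes  # splits actually happened
    lam = (120.0 + 60.0) * 4
    assert abs(n_episodes - lam) < 4 * math.sqrt(lam)
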