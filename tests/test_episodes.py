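"""Episode construction and hospitalization attribution.

The 7-day merge rule is cross-checked against an independent O(n^2)
union-find oracle: two admissions of one patient connect whenever the
later one starts no more than 7 days after the earlier one's discharge;
episodes are the connected components.
"""

from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from housingburden.episodes import (
    annual_means,
    assign_disorders,
    attribute_hospital_burden,
    build_episodes,
    clean_admissions,
    build_episodes as _build,
    summarize_annual,
)

D0 = date(2012, 1, 1)


def frame(rows):
    recs = []
    for i, (pid, admit, disch, diag, age, cost) in enumerate(rows):
        recs.append(
            {
                "patient_id": pid,
                "admit_date": pd.Timestamp(D0 + timedelta(days=admit)),
                "discharge_date": pd.Timestamp(D0 + timedelta(days=disch)),
                "diag1": diag,
                "diag2": "",
                "diag3": "",
                "age_years": age,
                "cost": float(cost),
            }
        )
    return pd.DataFrame(recs)


def oracle_components(rows):
    """Union-find transitive closure of the within-7-day linkage."""
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(rows):
        for j, b in enumerate(rows):
            if i == j or a[0] != b[0]:
                continue
            early, late = (a, b) if (a[1], a[2]) <= (b[1], b[2]) else (b, a)
            if late[1] - early[2] <= 7:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(len(rows)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def episode_signature(rows, components):
    sig = []
    for comp in components:
        members = [rows[i] for i in comp]
        nights = sum(m[2] - m[1] for m in members)
        cost = sum(m[5] for m in members)
        first = min(members, key=lambda m: (m[1], m[2]))
        sig.append((first[0], len(members), nights, round(cost, 6)))
    return sorted(sig)


@pytest.mark.parametrize(
    "gaps, expected_episodes",
    [
        ([(0, 1), (5, 6)], 1),    # re-admission 4 days after discharge merges
        ([(0, 1), (9, 10)], 2),   # 8-day gap starts a new episode
        ([(0, 1), (8, 9)], 1),    # exactly 7 days still merges
        ([(0, 0), (0, 0)], 1),    # same-day transfer (after dedup: one record)
    ],
)
def test_simple_merge_rules(gaps, expected_episodes):
    rows = [("p", a, d, "J10", 30, 100.0) for a, d in gaps]
    eps = build_episodes(clean_admissions(frame(rows)))
    assert len(eps) == expected_episodes


def test_transitive_chain_is_one_episode():
    # A discharges day d; B admits d+6, discharges d+10; C admits d+15:
    # C is within 7 days of B's discharge, so all three chain together.
    rows = [
        ("p", 0, 2, "J10", 30, 10.0),
        ("p", 8, 12, "J11", 30, 20.0),
        ("p", 17, 18, "J10", 30, 30.0),
    ]
    eps = build_episodes(frame(rows))
    assert len(eps) == 1
    assert int(eps["n_admissions"].iloc[0]) == 3
    assert int(eps["nights"].iloc[0]) == 2 + 4 + 1
    assert float(eps["cost"].iloc[0]) == 60.0


def test_rejects_inverted_dates_and_deduplicates(caplog):
    rows = [
        ("p", 5, 3, "J10", 30, 10.0),  # admit after discharge: rejected
        ("p", 0, 1, "J10", 30, 10.0),
        ("p", 0, 1, "J10", 30, 10.0),  # exact duplicate: dropped
    ]
    cleaned = clean_admissions(frame(rows))
    assert len(cleaned) == 1


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["a", "b", "c"]),
            st.integers(0, 40),
            st.integers(0, 12),
            st.floats(0, 500),
        ),
        min_size=1,
        max_size=50,
    )
)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_merge_matches_bruteforce_oracle(raw):
    rows = [
        (pid, admit, admit + stay, "J10", 30, round(cost, 3))
        for pid, admit, stay, cost in raw
    ]
    eps = build_episodes(frame(rows))
    got = sorted(
        zip(
            eps["patient_id"],
            eps["n_admissions"].astype(int),
            eps["nights"].astype(int),
            eps["cost"].round(6),
        )
    )
    assert got == episode_signature(rows, oracle_components(rows))


@given(
    st.lists(
        st.tuples(st.sampled_from(["a", "b"]), st.integers(0, 60), st.integers(0, 10), st.floats(1, 99)),
        min_size=1,
        max_size=40,
    )
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_episode_conservation(raw):
    """Nights and costs over episodes equal those over the accepted records."""
    rows = [(p, a, a + s, "J10", 30, round(c, 3)) for p, a, s, c in raw]
    df = frame(rows)
    eps = build_episodes(df)
    assert int(eps["nights"].sum()) == sum(r[2] - r[1] for r in rows)
    assert eps["cost"].sum() == pytest.approx(sum(r[5] for r in rows))


def test_disorder_assignment_walks_admissions(registry):
    # First admission's primary diagnosis is unmatched; the second one
    # (bronchiolitis) decides, per the first/second/third fallback rule.
    rows = [
        ("p", 0, 1, "Z38", 0, 10.0),
        ("p", 3, 5, "J21", 0, 20.0),
    ]
    eps = build_episodes(frame(rows))
    assert len(eps) == 1
    assigned = assign_disorders(eps, registry, "damp_mould")
    assert assigned.iloc[0] == "bronchiolitis"


def test_age_filter_uses_first_admission(registry):
    rows = [("p", 0, 2, "A09", 30, 10.0)]
    eps = build_episodes(frame(rows))
    assert assign_disorders(eps, registry, "crowding").iloc[0] is None


def test_summaries_count_patients_distinctly(registry):
    rows = [
        ("p1", 0, 1, "J45", 20, 100.0),
        ("p1", 30, 31, "J45", 20, 100.0),
        ("p1", 60, 61, "J45", 20, 100.0),
        ("p2", 0, 2, "J45", 25, 50.0),
    ]
    eps = build_episodes(frame(rows))
    eps["disorder"] = assign_disorders(eps, registry, "damp_mould")
    annual = summarize_annual(eps, registry, "damp_mould")
    row = annual[(annual["disorder"] == "asthma_current") & (annual["year"] == 2012)]
    assert int(row["n_patients"].iloc[0]) == 2
    assert int(row["hospitalizations"].iloc[0]) == 4


def test_annual_mean_over_fixed_span(registry):
    # identical activity in two years; span of two years -> mean = one year
    rows = []
    for year_shift in (0, 366):
        rows.append(("p", year_shift, year_shift + 1, "J45", 20, 100.0))
    eps = build_episodes(frame(rows))
    eps["disorder"] = assign_disorders(eps, registry, "damp_mould")
    annual = summarize_annual(eps, registry, "damp_mould")
    means = annual_means(annual, [2012, 2013])
    row = means[means["disorder"] == "asthma_current"].iloc[0]
    assert row["hospitalizations"] == 1.0
    assert row["cost_nzd"] == 100.0


def test_attribution_scales_linearly(registry):
    means = pd.DataFrame(
        [
            {
                "disorder": "asthma_current",
                "patients": 100.0,
                "hospitalizations": 120.0,
                "cost_nzd": 5000.0,
                "nights": 300.0,
            }
        ]
    )
    one = attribute_hospital_burden(means, registry, "damp_mould")
    doubled = attribute_hospital_burden(
        means.assign(**{c: means[c] * 2 for c in ["patients", "hospitalizations", "cost_nzd", "nights"]}),
        registry,
        "damp_mould",
    )
    for metric in ("patients", "hospitalizations", "cost_nzd", "nights"):
        assert doubled[metric].iloc[0] == pytest.approx(2 * one[metric].iloc[0])
        assert one[f"{metric}_lo"].iloc[0] <= one[metric].iloc[0] <= one[f"{metric}_hi"].iloc[0]
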