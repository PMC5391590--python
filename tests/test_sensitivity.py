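"""Post-hoc conservative exclusions and the negative-control machinery."""

import numpy as np
import pandas as pd
import pytest

from ppx.cases import find_pe_cases
from ppx.claims import parse_claims
from ppx.config import DesignConfig, SimulationConfig
from ppx.exposure import find_deliveries
from ppx.pipeline import analyze_claims
from ppx.sensitivity import (apply_posthoc_exclusions,
                             negative_control_analysis)
from ppx.simulate import simulate_population

from conftest import make_stay


def _case_with_delivery(build_claims, delivery_los=4, extra=()):
    stays = [
        make_stay("A", 30, "2011-01-01", delivery_los, "O80", ["Z37.0"],
                  [("JQGD010", 0)]),
        make_stay("A", 30, "2011-02-10", 5, "I26.0"),
        *extra,
    ]
    parsed = build_claims(stays)
    return parsed, find_pe_cases(parsed), find_deliveries(parsed)


def test_long_delivery_stay_excluded(build_claims):
    parsed, cases, deliveries = _case_with_delivery(build_claims,
                                                    delivery_los=10)
    report = apply_posthoc_exclusions(cases, deliveries, parsed)
    assert report.n_long_stay_excluded == 1
    assert report.n_retained == 0


def test_nine_day_delivery_stay_retained(build_claims):
    parsed, cases, deliveries = _case_with_delivery(build_claims,
                                                    delivery_los=9)
    report = apply_posthoc_exclusions(cases, deliveries, parsed)
    assert report.n_long_stay_excluded == 0
    assert report.n_retained == 1


def test_intercurrent_admission_excluded(build_claims):
    # delivery discharge 2011-01-05; unrelated stay strictly between
    intercurrent = make_stay("A", 30, "2011-01-20", 2, "K35.8")
    parsed, cases, deliveries = _case_with_delivery(
        build_claims, extra=[intercurrent])
    report = apply_posthoc_exclusions(cases, deliveries, parsed)
    assert report.n_intercurrent_excluded == 1
    assert report.n_retained == 0


@pytest.mark.parametrize("admission", ["2011-01-05", "2011-02-10"])
def test_boundary_admissions_are_not_intercurrent(build_claims, admission):
    """Strict inequalities: stays on the discharge or PE admission day
    do not trigger the exclusion."""
    boundary = make_stay("A", 30, admission, 1, "K35.8")
    parsed, cases, deliveries = _case_with_delivery(
        build_claims, extra=[boundary])
    report = apply_posthoc_exclusions(cases, deliveries, parsed)
    assert report.n_intercurrent_excluded == 0


def test_no_qualifying_cases_is_a_no_op(build_claims):
    parsed = build_claims([make_stay("A", 30, "2011-02-10", 5, "I26.0")])
    cases = find_pe_cases(parsed)
    report = apply_posthoc_exclusions(cases, find_deliveries(parsed), parsed)
    assert (report.n_long_stay_excluded, report.n_intercurrent_excluded) == (0, 0)
    assert report.n_retained == len(cases)


def test_exclusion_counts_partition_the_cases(sim_parsed):
    cases = find_pe_cases(sim_parsed)
    deliveries = find_deliveries(sim_parsed)
    report = apply_posthoc_exclusions(cases, deliveries, sim_parsed)
    assert (report.n_retained + report.n_long_stay_excluded
            + report.n_intercurrent_excluded) == len(cases)


def test_negative_control_produces_seven_windows(sim_parsed):
    table = negative_control_analysis(sim_parsed)
    assert len(table) == 7
    assert table["window"].iloc[0] == "0-29"
    assert table["window"].iloc[-1] == "180-209"


def test_zero_negative_control_stays_flagged_degenerate():
    cfg = SimulationConfig(n_women=2_000, negative_control_rate=0.0, seed=13)
    parsed = parse_claims(simulate_population(cfg), validate=False)
    table = negative_control_analysis(parsed)
    assert (table["flag"] != "").all()
    assert table["or_hat"].isna().all()


def test_posthoc_is_conservative_when_intercurrent_stays_target_cases(sim_parsed):
    """Injecting intercurrent admissions preferentially for postpartum
    cases must pull the post-hoc ORs down, never up."""
    cases = find_pe_cases(sim_parsed)
    deliveries = find_deliveries(sim_parsed)
    pairs = deliveries.merge(cases[["patient_id", "index_date",
                                    "stay_admission"]], on="patient_id")
    iv = (pd.to_datetime(pairs["index_date"])
          - pd.to_datetime(pairs["date"])).dt.days
    exposed = pairs[(iv >= 14) & (iv <= 139)]
    inject = []
    for row in exposed.itertuples(index=False):
        mid = pd.to_datetime(row.date) + (
            pd.to_datetime(row.stay_admission_y)
            - pd.to_datetime(row.date)) / 2
        if (mid - pd.to_datetime(row.stay_admission_x)).days > row.stay_los + 1:
            inject.append(make_stay(row.patient_id, 30,
                                    mid.strftime("%Y-%m-%d"), 1, "K35.8"))
    assert inject, "fixture should create at least one intercurrent stay"
    raw = sim_parsed[["patient_id", "age_years", "sex", "admission_date",
                      "length_of_stay", "primary_dx", "associated_dx",
                      "procedures"]]
    extra = pd.DataFrame([s.to_row() for s in inject])
    augmented = parse_claims(pd.concat([raw, extra], ignore_index=True))

    plain = analyze_claims(augmented)
    conservative = analyze_claims(augmented, posthoc=True)
    mask = plain["or_hat"].notna() & conservative["or_hat"].notna()
    assert (conservative.loc[mask, "n_case_events"]
            <= plain.loc[mask, "n_case_events"]).all()
    mid_windows = mask & (np.arange(len(plain)) >= 1) & (np.arange(len(plain)) <= 9)
    assert (conservative.loc[mid_windows, "or_hat"]
            <= plain.loc[mid_windows, "or_hat"] + 1e-9).all()
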