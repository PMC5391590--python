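"""Post-hoc conservative exclusions and the negative-control analysis.

The conservative re-analysis removes (in order) cases whose exposing
delivery stay lasted 10 days or more, then cases with an intercurrent
admission — any other inpatient stay strictly between the delivery-stay
discharge and the PE-stay admission.  Both rules are disjoint by
construction (the second is only applied to cases surviving the first) and
their counts are reported.

The negative control replays the whole crossover machinery with a
delivery-unrelated exposure (carpal-tunnel release) over seven 30-day
windows: odds ratios systematically near 1 indicate the design is not
manufacturing spurious associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortConfig, DesignConfig
from .exposure import find_deliveries, find_negative_control_exposures

logger = logging.getLogger(__name__)

__all__ = ["ExclusionReport", "apply_posthoc_exclusions",
           "negative_control_analysis"]

_LONG_STAY_DAYS = 10


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the post-hoc conservative exclusions."""

    n_long_stay_excluded: int
    n_intercurrent_excluded: int
    retained: pd.DataFrame  # same schema as the input cases table

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _exposing_delivery(cases: pd.DataFrame, deliveries: pd.DataFrame,
                       design: DesignConfig) -> pd.DataFrame:
    """Attach each case's exposing delivery (most recent within the case span).

    Returns the cases table with extra columns ``exp_stay_los``,
    ``exp_discharge`` (NaT when the case has no delivery in any case
    window).
    """
    out = cases.copy()
    out["exp_stay_los"] = np.nan
    out["exp_discharge"] = pd.NaT
    if not len(cases) or not len(deliveries):
        return out
    pairs = deliveries.merge(cases[["patient_id", "index_date"]],
                             on="patient_id", how="inner")
    if not len(pairs):
        return out
    iv = (pd.to_datetime(pairs["index_date"])
          - pd.to_datetime(pairs["date"])).dt.days
    inside = (iv >= 0) & (iv <= design.case_span_end)
    pairs = pairs[inside].assign(interval=iv[inside])
    if not len(pairs):
        return out
    best = pairs.sort_values(["patient_id", "interval"],
                             kind="mergesort").groupby("patient_id").head(1)
    best = best.set_index("patient_id")
    discharge = (pd.to_datetime(best["stay_admission"])
                 + pd.to_timedelta(best["stay_los"], unit="D"))
    out["exp_stay_los"] = out["patient_id"].map(best["stay_los"])
    out["exp_discharge"] = out["patient_id"].map(discharge)
    return out


def apply_posthoc_exclusions(cases: pd.DataFrame, deliveries: pd.DataFrame,
                             parsed_claims: pd.DataFrame,
                             design: DesignConfig | None = None) -> ExclusionReport:
    """Apply the two conservative exclusion rules, in order.

    ``cases`` and ``deliveries`` come from :func:`ppx.cases.find_pe_cases`
    and :func:`ppx.exposure.find_deliveries`; ``parsed_claims`` is the full
    parsed table (used to spot intercurrent admissions).
    """
    design = design or DesignConfig.two_week()
    attached = _exposing_delivery(cases, deliveries, design)

    long_stay = attached["exp_stay_los"].notna() & (
        attached["exp_stay_los"] >= _LONG_STAY_DAYS)
    after_rule1 = attached[~long_stay]

    # Intercurrent admission: any *other* stay strictly between the
    # delivery discharge and the PE admission of the same patient.
    intercurrent = pd.Series(False, index=after_rule1.index)
    exposed = after_rule1[after_rule1["exp_discharge"].notna()]
    if len(exposed):
        stays = parsed_claims[["patient_id", "admission"]].merge(
            exposed[["patient_id", "exp_discharge", "stay_admission",
                     "stay_idx"]].reset_index(names="case_row"),
            on="patient_id", how="inner")
        strictly_between = (
            (stays["admission"] > pd.to_datetime(stays["exp_discharge"]))
            & (stays["admission"] < pd.to_datetime(stays["stay_admission"])))
        hit_rows = stays.loc[strictly_between, "case_row"].unique()
        intercurrent.loc[hit_rows] = True

    retained = after_rule1[~intercurrent].drop(
        columns=["exp_stay_los", "exp_discharge"]).reset_index(drop=True)
    report = ExclusionReport(
        n_long_stay_excluded=int(long_stay.sum()),
        n_intercurrent_excluded=int(intercurrent.sum()),
        retained=retained)
    logger.info("post-hoc exclusions: %d long-stay, %d intercurrent, "
                "%d retained of %d",
                report.n_long_stay_excluded, report.n_intercurrent_excluded,
                report.n_retained, len(cases))
    return report


def negative_control_analysis(parsed_claims: pd.DataFrame,
                              cohort: CohortConfig | None = None,
                              design: DesignConfig | None = None) -> pd.DataFrame:
    """Crossover analysis with carpal-tunnel exposure and PE outcome.

    Runs the full pipeline over seven 30-day case windows (by default);
    windows with no usable information are flagged rather than estimated.
    Returns the per-window results table of
    :func:`ppx.pipeline.analyze_claims`.
    """
    from .pipeline import analyze_claims  # local import avoids a cycle

    cohort = cohort or CohortConfig()
    design = design or DesignConfig.negative_control()
    exposures = find_negative_control_exposures(parsed_claims)
    return analyze_claims(parsed_claims, design=design, cohort=cohort,
                          exposures=exposures,
                          denominator=max(len(exposures), 1))
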