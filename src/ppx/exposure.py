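"""Exposure extraction: eligible deliveries, negative-control stays, intervals.

A delivery exposure is a stay carrying the single-live-birth code Z37.0,
no fetal-anomaly / abnormal-screening code (O35.x, O28.x), and a mother
aged 15–45.  The delivery date is the dated delivery procedure when one is
recorded (admission day + offset); otherwise it falls back to the admission
date, which reproduces the legacy default-to-day-zero behaviour of older
records.

``interval_days`` implements the two-branch day count between a delivery
and a PE case: for a PE in a later hospitalization it is PE admission minus
delivery date; for a PE during the delivery stay the case's index date
already encodes admission + earliest diagnostic-procedure offset, so the
same subtraction applies (the delivery-compatible-primary check is made at
case identification).  Negative values mean the delivery followed the
reference date; they never count as exposure in any window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .config import CohortConfig

logger = logging.getLogger(__name__)

__all__ = ["DeliveryEvent", "find_deliveries",
           "find_negative_control_exposures", "interval_days"]


@dataclass(frozen=True)
class DeliveryEvent:
    """An eligible delivery: exposure of interest for the crossover design."""

    patient_id: str
    delivery_date: pd.Timestamp
    stay_idx: int
    mother_age_at_delivery: int


EXPOSURE_COLUMNS = ("patient_id", "date", "stay_idx", "stay_admission", "stay_los")


def find_deliveries(parsed: pd.DataFrame, cohort: CohortConfig | None = None) -> pd.DataFrame:
    """Extract eligible delivery exposures from a parsed claims table.

    Returns a DataFrame (``patient_id``, ``date``, ``stay_idx``,
    ``stay_admission``, ``stay_los``); stays failing the criteria are
    silently non-exposures (counts are logged).
    """
    cohort = cohort or CohortConfig()
    delivery_match = codes.code_matcher([codes.DELIVERY_DX])
    excl_match = codes.code_matcher(codes.DELIVERY_EXCLUSION_DX)
    proc_codes = set(codes.DELIVERY_PROCEDURES)

    primary = parsed["primary_dx"].to_numpy()
    assoc = parsed["assoc"].to_numpy(dtype=object)
    n = len(parsed)
    has_delivery = np.fromiter(
        (delivery_match(primary[i]) or any(delivery_match(c) for c in assoc[i])
         for i in range(n)), bool, n)
    excluded = np.fromiter(
        (excl_match(primary[i]) or any(excl_match(c) for c in assoc[i])
         for i in range(n)), bool, n)
    age_ok = ((parsed["age_years"] >= cohort.min_age)
              & (parsed["age_years"] <= cohort.max_age)).to_numpy()
    keep = has_delivery & ~excluded & age_ok
    logger.info("deliveries: %d stays with %s, %d excluded by O35/O28, "
                "%d excluded by age, %d retained",
                int(has_delivery.sum()), codes.DELIVERY_DX,
                int((has_delivery & excluded).sum()),
                int((has_delivery & ~excluded & ~age_ok).sum()), int(keep.sum()))

    idxs = np.flatnonzero(keep)
    offsets = np.zeros(len(idxs), dtype=np.int64)
    for j, i in enumerate(idxs):
        offs = [o for c, o in parsed["procs"].iloc[int(i)] if c in proc_codes]
        if offs:
            offsets[j] = min(offs)
    adm = parsed["admission"].iloc[idxs]
    out = pd.DataFrame({
        "patient_id": parsed["patient_id"].iloc[idxs].to_numpy(),
        "date": (adm + pd.to_timedelta(offsets, unit="D")).to_numpy(),
        "stay_idx": idxs,
        "stay_admission": adm.to_numpy(),
        "stay_los": parsed["length_of_stay"].iloc[idxs].to_numpy(),
    })
    return out.reset_index(drop=True)


def find_negative_control_exposures(parsed: pd.DataFrame) -> pd.DataFrame:
    """Carpal-tunnel stays: diagnosis G56.0 *and* the release procedure.

    Both codes are required on the same stay (the stricter conjunctive
    reading).  The exposure date is admission + procedure offset.
    """
    dx_match = codes.code_matcher([codes.NEGATIVE_CONTROL_DX])
    primary = parsed["primary_dx"].to_numpy()
    assoc = parsed["assoc"].to_numpy(dtype=object)
    n = len(parsed)
    has_dx = np.fromiter(
        (dx_match(primary[i]) or any(dx_match(c) for c in assoc[i])
         for i in range(n)), bool, n)
    rows, offsets = [], []
    for i in np.flatnonzero(has_dx):
        offs = [o for c, o in parsed["procs"].iloc[int(i)]
                if c == codes.NEGATIVE_CONTROL_PROCEDURE]
        if offs:
            rows.append(int(i))
            offsets.append(min(offs))
    if not rows:
        return pd.DataFrame(columns=list(EXPOSURE_COLUMNS))
    adm = parsed["admission"].iloc[rows]
    return pd.DataFrame({
        "patient_id": parsed["patient_id"].iloc[rows].to_numpy(),
        "date": (adm + pd.to_timedelta(offsets, unit="D")).to_numpy(),
        "stay_idx": np.asarray(rows),
        "stay_admission": adm.to_numpy(),
        "stay_los": parsed["length_of_stay"].iloc[rows].to_numpy(),
    }).reset_index(drop=True)


def interval_days(delivery_date, index_date) -> int:
    """Whole days from delivery to the case's index date (may be negative)."""
    delta = pd.Timestamp(index_date) - pd.Timestamp(delivery_date)
    return int(delta.days)
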