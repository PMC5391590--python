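"""Pulmonary-embolism case identification: first event per patient.

A *case* is a patient's chronologically first PE admission whose event date
falls inside the inclusion window.  Patients whose first-ever PE predates
the window are excluded entirely (their later events are recurrences, not
incident cases).  A PE coded on the delivery stay itself is dated by the
earliest PE-diagnostic procedure within that stay, provided the stay's
primary diagnosis is compatible with a delivery; when no dated diagnostic
procedure exists the interval is unresolvable and the case is dropped with
a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import codes
from .config import CohortConfig
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = ["CaseEvent", "find_pe_cases"]

CASE_COLUMNS = ("patient_id", "index_date", "during_delivery_stay",
                "stay_idx", "stay_admission", "stay_los")


@dataclass(frozen=True)
class CaseEvent:
    """A patient's first PE admission inside the inclusion window."""

    patient_id: str
    index_date: pd.Timestamp
    during_delivery_stay: bool
    stay_idx: int


def find_pe_cases(parsed: pd.DataFrame, cohort: CohortConfig | None = None) -> pd.DataFrame:
    """Identify PE cases in a parsed claims table.

    Parameters
    ----------
    parsed
        Output of :func:`ppx.claims.parse_claims`.
    cohort
        Code sets and inclusion window; defaults to :class:`CohortConfig()`.

    Returns
    -------
    DataFrame with one row per case: ``patient_id``, ``index_date``,
    ``during_delivery_stay``, ``stay_idx`` (row index of the source stay),
    ``stay_admission`` and ``stay_los``.
    """
    cohort = cohort or CohortConfig()
    if not cohort.pe_dx:
        raise ConfigError("pe_dx", "code set must be non-empty")
    pe_match = codes.code_matcher(cohort.pe_dx)
    delivery_match = codes.code_matcher([codes.DELIVERY_DX])
    compat_match = codes.code_matcher(codes.DELIVERY_COMPATIBLE_PRIMARY)
    pe_proc = set(cohort.pe_procedures)

    primary = parsed["primary_dx"].to_numpy()
    assoc = parsed["assoc"].to_numpy(dtype=object)
    primary_is_pe = np.fromiter((pe_match(c) for c in primary), bool, len(parsed))
    assoc_has_pe = np.fromiter((any(pe_match(c) for c in a) for a in assoc),
                               bool, len(parsed))
    candidate = primary_is_pe | assoc_has_pe
    idxs = np.flatnonzero(candidate)
    if len(idxs) == 0:
        return pd.DataFrame(columns=list(CASE_COLUMNS))

    adm = parsed["admission"]
    records = []  # (patient, event_date, during, resolvable, stay_idx)
    n_unresolvable = 0
    for i in idxs:
        i = int(i)
        is_delivery_stay = (delivery_match(primary[i])
                            or any(delivery_match(c) for c in assoc[i]))
        during = (not primary_is_pe[i]) and is_delivery_stay
        if during:
            offs = [o for c, o in parsed["procs"].iloc[i] if c in pe_proc]
            if not offs or not compat_match(primary[i]):
                # PE coded on the delivery stay but the postpartum interval
                # cannot be attributed: keeps its slot in first-event logic,
                # but cannot become an analyzable case.
                records.append((parsed["patient_id"].iloc[i], adm.iloc[i],
                                True, False, i))
                continue
            event_date = adm.iloc[i] + pd.Timedelta(days=min(offs))
        else:
            event_date = adm.iloc[i]
        records.append((parsed["patient_id"].iloc[i], event_date, during, True, i))

    rec = pd.DataFrame(records, columns=["patient_id", "event_date", "during",
                                         "resolvable", "stay_idx"])
    # first event per patient; ties broken by smaller row index
    rec = rec.sort_values(["patient_id", "event_date", "stay_idx"],
                          kind="mergesort")
    first = rec.groupby("patient_id", sort=False).head(1)

    start = pd.Timestamp(cohort.inclusion_start)
    end = pd.Timestamp(cohort.inclusion_end)
    pre_window = first["event_date"] < start
    in_window = (first["event_date"] >= start) & (first["event_date"] <= end)
    kept = first[in_window]
    n_unresolvable = int((~kept["resolvable"]).sum())
    if n_unresolvable:
        logger.info("dropped %d case(s) with unresolvable within-stay interval",
                    n_unresolvable)
    logger.info("PE case identification: %d candidate patients, %d excluded "
                "(first event before inclusion window), %d cases retained",
                first.shape[0], int(pre_window.sum()),
                int(kept["resolvable"].sum()))
    kept = kept[kept["resolvable"]]

    out = pd.DataFrame({
        "patient_id": kept["patient_id"].to_numpy(),
        "index_date": kept["event_date"].to_numpy(),
        "during_delivery_stay": kept["during"].to_numpy(),
        "stay_idx": kept["stay_idx"].to_numpy(),
    })
    out["stay_admission"] = adm.iloc[out["stay_idx"]].to_numpy()
    out["stay_los"] = parsed["length_of_stay"].iloc[out["stay_idx"]].to_numpy()
    return out.reset_index(drop=True)
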