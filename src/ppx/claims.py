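"""The inpatient-claims table: row model, CSV dialect, parsing, validation.

One row is one hospital stay.  The on-disk format is plain CSV with columns

    patient_id, age_years, sex, admission_date, length_of_stay,
    primary_dx, associated_dx, procedures

where ``admission_date`` is ISO-8601, ``associated_dx`` is a
semicolon-joined list of diagnosis codes and ``procedures`` is a
semicolon-joined list of ``CODE@OFFSET`` items, the offset being the
procedure date in days from admission.  Empty lists serialize as the empty
string.  The dialect round-trips exactly (tested), so a table written and
re-read compares equal byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClaimsValidationError

__all__ = [
    "CLAIMS_COLUMNS", "InpatientStay", "stays_to_frame", "frame_to_stays",
    "read_claims", "write_claims", "parse_claims",
]

CLAIMS_COLUMNS = (
    "patient_id", "age_years", "sex", "admission_date", "length_of_stay",
    "primary_dx", "associated_dx", "procedures",
)


@dataclass
class InpatientStay:
    """One hospital stay with dated diagnoses and procedures."""

    patient_id: str
    age_years: int
    sex: str
    admission_date: str  # ISO-8601
    length_of_stay: int
    primary_dx: str
    associated_dx: tuple[str, ...] = ()
    procedures: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "age_years": int(self.age_years),
            "sex": self.sex,
            "admission_date": str(self.admission_date),
            "length_of_stay": int(self.length_of_stay),
            "primary_dx": self.primary_dx,
            "associated_dx": ";".join(self.associated_dx),
            "procedures": ";".join(f"{c}@{o}" for c, o in self.procedures),
        }


def stays_to_frame(stays) -> pd.DataFrame:
    """Assemble a claims table from :class:`InpatientStay` records."""
    rows = [s.to_row() for s in stays]
    return pd.DataFrame(rows, columns=list(CLAIMS_COLUMNS))


def frame_to_stays(df: pd.DataFrame) -> list[InpatientStay]:
    out = []
    for row in df.itertuples(index=False):
        assoc = tuple(c for c in str(row.associated_dx).split(";") if c) \
            if row.associated_dx else ()
        procs = []
        if row.procedures:
            for item in str(row.procedures).split(";"):
                code, off = item.rsplit("@", 1)
                procs.append((code, int(off)))
        out.append(InpatientStay(
            patient_id=str(row.patient_id), age_years=int(row.age_years),
            sex=str(row.sex), admission_date=str(row.admission_date),
            length_of_stay=int(row.length_of_stay), primary_dx=str(row.primary_dx),
            associated_dx=assoc, procedures=tuple(procs)))
    return out


def write_claims(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsValidationError(-1, f"missing columns: {missing}")
    df["age_years"] = df["age_years"].astype(int)
    df["length_of_stay"] = df["length_of_stay"].astype(int)
    return df[list(CLAIMS_COLUMNS)]


def _parse_procs(text: str, row: int) -> tuple[tuple[str, int], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        try:
            code, off = item.rsplit("@", 1)
            out.append((code, int(off)))
        except ValueError as exc:
            raise ClaimsValidationError(row, f"bad procedure item {item!r}") from exc
    return tuple(out)


def parse_claims(df: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Parse serialized columns into typed ones and validate records.

    Returns a copy with additional columns:

    * ``admission`` — ``datetime64[ns]`` admission date,
    * ``assoc`` — tuple of associated diagnosis codes,
    * ``procs`` — tuple of ``(code, offset)`` pairs.

    Validation failures raise :class:`ClaimsValidationError` with the
    0-based row index of the offending record.
    """
    df = df.reset_index(drop=True).copy()
    adm = pd.to_datetime(df["admission_date"], format="%Y-%m-%d", errors="coerce")
    if adm.isna().any():
        bad = int(adm.isna().idxmax())
        raise ClaimsValidationError(bad, f"unparseable admission_date "
                                         f"{df['admission_date'].iloc[bad]!r}")
    df["admission"] = adm
    assoc_raw = df["associated_dx"].fillna("").astype(str)
    df["assoc"] = [tuple(c for c in s.split(";") if c) for s in assoc_raw]
    procs_raw = df["procedures"].fillna("").astype(str)
    df["procs"] = [_parse_procs(s, i) for i, s in enumerate(procs_raw)]
    if validate:
        los = df["length_of_stay"].to_numpy()
        if (los < 0).any():
            raise ClaimsValidationError(int(np.argmax(los < 0)),
                                        "negative length_of_stay")
        ages = df["age_years"].to_numpy()
        bad_age = (ages < 0) | (ages > 120)
        if bad_age.any():
            raise ClaimsValidationError(int(np.argmax(bad_age)),
                                        "age_years outside [0, 120]")
        for i, (procs, n) in enumerate(zip(df["procs"], los)):
            for code, off in procs:
                if not 0 <= off <= n:
                    raise ClaimsValidationError(
                        i, f"procedure {code} offset {off} outside stay [0, {n}]")
    return df
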