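"""Matched-set construction for the case-crossover design.

For each case the design compares exposure in one case window (``k``-th
interval of ``interval_width`` days before the index date) with exposure in
``M`` control windows roughly a year earlier.  Window membership is closed
on both ends and binary: several exposures inside one window count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DesignConfig
from .estimation import truncate1

__all__ = ["MatchedSet", "MatchedSets", "exposure_matrix",
           "build_matched_sets", "count_summary"]


@dataclass(frozen=True)
class MatchedSet:
    """One case's exposure indicators: case period + M control periods."""

    patient_id: str
    window_index: int
    case_exposed: int
    control_exposed: tuple[int, ...]


@dataclass(frozen=True)
class MatchedSets:
    """Matched sets for one case window, in array form.

    ``exposure`` has shape ``(n_cases, 1 + M)``; column 0 is the case
    period, columns 1..M the control periods.
    """

    window_index: int
    patient_ids: np.ndarray
    exposure: np.ndarray

    def __len__(self) -> int:
        return self.exposure.shape[0]

    def to_records(self) -> list[MatchedSet]:
        return [MatchedSet(str(p), self.window_index, int(row[0]),
                           tuple(int(v) for v in row[1:]))
                for p, row in zip(self.patient_ids, self.exposure)]

    def to_frame(self) -> pd.DataFrame:
        m = self.exposure.shape[1] - 1
        df = pd.DataFrame({"patient_id": self.patient_ids,
                           "k": self.window_index,
                           "case_exposed": self.exposure[:, 0]})
        for j in range(m):
            df[f"control_exposed_{j + 1}"] = self.exposure[:, j + 1]
        return df


def exposure_matrix(cases: pd.DataFrame, exposures: pd.DataFrame,
                    design: DesignConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exposure indicators for every case over all windows at once.

    Returns ``(patient_ids, matrix)`` where ``matrix`` has shape
    ``(n_cases, n_case_windows + M)``: case-window columns first, then the
    control windows in design order.
    """
    n_cases = len(cases)
    n_cols = design.n_case_windows + design.M
    mat = np.zeros((n_cases, n_cols), dtype=np.int8)
    ids = cases["patient_id"].to_numpy()
    if n_cases and len(exposures):
        pos = pd.Series(np.arange(n_cases), index=ids)
        pairs = exposures.merge(
            cases[["patient_id", "index_date"]], on="patient_id", how="inner")
        if len(pairs):
            iv = (pd.to_datetime(pairs["index_date"])
                  - pd.to_datetime(pairs["date"])).dt.days.to_numpy()
            rows = pos[pairs["patient_id"]].to_numpy()
            for k in range(design.n_case_windows):
                lo, hi = design.case_window(k)
                hit = (iv >= lo) & (iv <= hi)
                mat[rows[hit], k] = 1
            for j, (lo, hi) in enumerate(design.control_windows):
                hit = (iv >= lo) & (iv <= hi)
                mat[rows[hit], design.n_case_windows + j] = 1
    return ids, mat


def build_matched_sets(cases: pd.DataFrame, exposures: pd.DataFrame,
                       design: DesignConfig, k: int) -> MatchedSets:
    """Matched sets for case window ``k``: shape ``(n_cases, 1 + M)``.

    ``cases`` needs columns ``patient_id`` and ``index_date``; ``exposures``
    needs ``patient_id`` and ``date`` (see :mod:`ppx.exposure`).
    """
    design.case_window(k)  # validates k
    ids, mat = exposure_matrix(cases, exposures, design)
    cols = np.concatenate(([k], design.n_case_windows + np.arange(design.M)))
    return MatchedSets(window_index=k, patient_ids=ids,
                       exposure=mat[:, cols].copy())


def sets_for_all_windows(cases: pd.DataFrame, exposures: pd.DataFrame,
                         design: DesignConfig) -> list[MatchedSets]:
    """All windows' matched sets from a single exposure-matrix pass."""
    ids, mat = exposure_matrix(cases, exposures, design)
    ctrl = mat[:, design.n_case_windows:]
    out = []
    for k in range(design.n_case_windows):
        exp = np.column_stack([mat[:, k], ctrl])
        out.append(MatchedSets(window_index=k, patient_ids=ids, exposure=exp))
    return out


def count_summary(sets) -> tuple[int, int, float]:
    """Exposure counts of a matched-set collection.

    Returns ``(a, b, mean_control)`` where ``a`` is the number of
    case-exposed sets, ``b`` the total number of exposed control
    indicators, and ``mean_control = b / M`` truncated to one decimal (the
    reported "mean of the control periods").
    """
    exp = sets.exposure if isinstance(sets, MatchedSets) else np.asarray(
        [[s.case_exposed, *s.control_exposed] for s in sets])
    if exp.size == 0:
        return 0, 0, 0.0
    a = int(exp[:, 0].sum())
    b = int(exp[:, 1:].sum())
    m = exp.shape[1] - 1
    return a, b, truncate1(b / m)
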