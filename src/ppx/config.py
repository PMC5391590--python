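"""Configuration objects: simulation, cohort extraction, crossover design.

All three dataclasses validate on construction and raise
:class:`~ppx.errors.ConfigError` naming the offending field.  Each can be
round-tripped through a plain dict (``from_dict`` / ``to_dict``) so YAML
files and run manifests share one representation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .codes import (
    DEFAULT_PE_DX,
    DEFAULT_PE_PROCEDURES,
)
from .errors import ConfigError

__all__ = [
    "RiskProfile",
    "SimulationConfig",
    "CohortConfig",
    "DesignConfig",
    "load_yaml_section",
]


@dataclass(frozen=True)
class RiskProfile:
    """Postpartum hazard multiplier as a function of days since delivery.

    Two forms are supported:

    * parametric exponential decay ``1 + A * exp(-t / tau)``;
    * a piecewise-constant profile over consecutive intervals of
      ``interval_width`` days; beyond the last interval the multiplier is 1.

    The multiplier is dimensionless and multiplies the baseline pulmonary
    embolism hazard; a value of 1 means no postpartum excess.
    """

    kind: str  # "exponential" | "piecewise"
    amplitude: float = 0.0
    tau: float = 1.0
    values: tuple[float, ...] = ()
    interval_width: int = 14

    def __post_init__(self):
        if self.kind not in ("exponential", "piecewise"):
            raise ConfigError("rr_profile.kind", f"unknown kind {self.kind!r}")
        if self.kind == "exponential":
            if self.amplitude < 0:
                raise ConfigError("rr_profile.amplitude", "must be >= 0")
            if self.tau <= 0:
                raise ConfigError("rr_profile.tau", "must be > 0")
        else:
            if any(v < 0 for v in self.values):
                raise ConfigError("rr_profile.values", "multipliers must be >= 0")
            if self.interval_width <= 0:
                raise ConfigError("rr_profile.interval_width", "must be > 0")

    @classmethod
    def exponential(cls, amplitude: float, tau: float) -> "RiskProfile":
        return cls(kind="exponential", amplitude=float(amplitude), tau=float(tau))

    @classmethod
    def piecewise(cls, values: Sequence[float], interval_width: int = 14) -> "RiskProfile":
        return cls(kind="piecewise", values=tuple(float(v) for v in values),
                   interval_width=int(interval_width))

    @classmethod
    def flat(cls) -> "RiskProfile":
        """Multiplier identically 1 (no postpartum excess)."""
        return cls.piecewise(())

    @property
    def max_multiplier(self) -> float:
        if self.kind == "exponential":
            return 1.0 + self.amplitude
        return max(self.values, default=1.0) if max(self.values, default=0.0) > 1.0 else 1.0

    def __call__(self, t_days):
        """Vectorized multiplier; ``t_days`` must be >= 0 elementwise."""
        t = np.asarray(t_days, dtype=float)
        if np.any(t < 0):
            raise ValueError("t_days must be >= 0")
        if self.kind == "exponential":
            out = 1.0 + self.amplitude * np.exp(-t / self.tau)
        else:
            out = np.ones_like(t)
            if self.values:
                idx = (t // self.interval_width).astype(int)
                inside = idx < len(self.values)
                vals = np.asarray(self.values)
                out[inside] = vals[idx[inside]]
        if np.isscalar(t_days) or np.ndim(t_days) == 0:
            return float(out)
        return out

    def to_dict(self) -> dict:
        if self.kind == "exponential":
            return {"kind": "exponential", "amplitude": self.amplitude, "tau": self.tau}
        return {"kind": "piecewise", "values": list(self.values),
                "interval_width": self.interval_width}

    @classmethod
    def from_dict(cls, d: dict) -> "RiskProfile":
        kind = d.get("kind", "exponential")
        if kind == "exponential":
            return cls.exponential(d.get("amplitude", 0.0), d.get("tau", 1.0))
        return cls.piecewise(d.get("values", ()), d.get("interval_width", 14))


def _parse_date(value, fieldname: str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigError(fieldname, f"not an ISO date: {value!r}") from exc


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic claims generator.

    Rates are per woman-year; time is whole calendar days.  The defaults
    emulate the structure of a national inpatient database over 2007–2013,
    with event rates deliberately scaled so that a population of tens of
    thousands of women yields case counts comparable to the study tables
    (see docs/methods.md).
    """

    n_women: int = 50_000
    study_start: dt.date = dt.date(2007, 1, 1)
    study_end: dt.date = dt.date(2013, 12, 31)
    delivery_rate: float = 0.12
    baseline_pe_rate: float = 0.01
    rr_profile: RiskProfile = field(default_factory=lambda: RiskProfile.exponential(16.0, 25.0))
    negative_control_rate: float = 0.05
    background_admission_rate: float = 0.02
    legacy_date_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_women <= 0:
            raise ConfigError("n_women", "must be > 0")
        start = _parse_date(self.study_start, "study_start")
        end = _parse_date(self.study_end, "study_end")
        object.__setattr__(self, "study_start", start)
        object.__setattr__(self, "study_end", end)
        if not start < end:
            raise ConfigError("study_start", "must be before study_end")
        for name in ("delivery_rate", "baseline_pe_rate", "negative_control_rate",
                     "background_admission_rate"):
            if getattr(self, name) < 0 or not math.isfinite(getattr(self, name)):
                raise ConfigError(name, "must be a finite rate >= 0")
        if not 0.0 <= self.legacy_date_fraction <= 1.0:
            raise ConfigError("legacy_date_fraction", "must be in [0, 1]")
        if not isinstance(self.rr_profile, RiskProfile):
            object.__setattr__(self, "rr_profile", RiskProfile.from_dict(self.rr_profile))
        object.__setattr__(self, "seed", int(self.seed))

    @property
    def n_days(self) -> int:
        """Number of simulated days; admissions fall on days 0 .. n_days - 1."""
        return (self.study_end - self.study_start).days + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["rr_profile"] = self.rr_profile.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "rr_profile" in d and not isinstance(d["rr_profile"], RiskProfile):
            d["rr_profile"] = RiskProfile.from_dict(d["rr_profile"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown simulation field")
        return cls(**d)


@dataclass(frozen=True)
class CohortConfig:
    """Code sets, age bounds and inclusion window for cohort extraction.

    The inclusion window defaults to 18 months after the data window opens
    so that every control window (up to 399 days before an index event) is
    observable, and so patients with an earlier first event can be excluded.
    """

    pe_dx: tuple[str, ...] = DEFAULT_PE_DX
    pe_procedures: tuple[str, ...] = DEFAULT_PE_PROCEDURES
    inclusion_start: dt.date = dt.date(2008, 7, 1)
    inclusion_end: dt.date = dt.date(2013, 12, 31)
    min_age: int = 15
    max_age: int = 45

    def __post_init__(self):
        if not self.pe_dx:
            raise ConfigError("pe_dx", "code set must be non-empty")
        object.__setattr__(self, "pe_dx", tuple(self.pe_dx))
        object.__setattr__(self, "pe_procedures", tuple(self.pe_procedures))
        start = _parse_date(self.inclusion_start, "inclusion_start")
        end = _parse_date(self.inclusion_end, "inclusion_end")
        object.__setattr__(self, "inclusion_start", start)
        object.__setattr__(self, "inclusion_end", end)
        if start > end:
            raise ConfigError("inclusion_start", "must be <= inclusion_end")
        if not (0 <= self.min_age <= self.max_age <= 120):
            raise ConfigError("min_age", "need 0 <= min_age <= max_age <= 120")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pe_dx"] = list(self.pe_dx)
        d["pe_procedures"] = list(self.pe_procedures)
        d["inclusion_start"] = self.inclusion_start.isoformat()
        d["inclusion_end"] = self.inclusion_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown cohort field")
        return cls(**d)


_DEFAULT_CONTROLS_2W = ((330, 343), (344, 357), (358, 371), (372, 385), (386, 399))


@dataclass(frozen=True)
class DesignConfig:
    """Case-crossover window geometry.

    Case window ``k`` is the closed day interval
    ``[k*w, (k+1)*w - 1]`` before the index date (day 0 = index day);
    control windows are closed ``(start, end)`` day pairs before the index
    date, each of width ``interval_width``.  Closed-interval semantics make
    the enumerated boundaries (…343 / 344…) tile without gap or overlap.
    """

    interval_width: int = 14
    n_case_windows: int = 10
    control_windows: tuple[tuple[int, int], ...] = _DEFAULT_CONTROLS_2W

    def __post_init__(self):
        object.__setattr__(
            self, "control_windows",
            tuple((int(a), int(b)) for a, b in self.control_windows))
        if self.interval_width <= 0:
            raise ConfigError("interval_width", "must be > 0")
        if self.n_case_windows <= 0:
            raise ConfigError("n_case_windows", "must be > 0")
        if not self.control_windows:
            raise ConfigError("control_windows", "need at least one control window")
        spans = [(0, self.case_span_end)]
        for (a, b) in self.control_windows:
            if b - a + 1 != self.interval_width:
                raise ConfigError(
                    "control_windows",
                    f"window ({a}, {b}) does not have width {self.interval_width}")
            spans.append((a, b))
        spans_sorted = sorted(spans)
        for (a1, b1), (a2, b2) in zip(spans_sorted, spans_sorted[1:]):
            if a2 <= b1:
                raise ConfigError(
                    "control_windows",
                    f"windows ({a1}, {b1}) and ({a2}, {b2}) overlap")

    @property
    def M(self) -> int:
        """Number of control periods per matched set."""
        return len(self.control_windows)

    @property
    def case_span_end(self) -> int:
        """Last day covered by any case window (inclusive)."""
        return self.n_case_windows * self.interval_width - 1

    def case_window(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_case_windows:
            raise ConfigError("k", f"window index {k} outside [0, {self.n_case_windows})")
        w = self.interval_width
        return (k * w, (k + 1) * w - 1)

    def window_label(self, k: int) -> str:
        lo, hi = self.case_window(k)
        return f"{lo}-{hi}"

    @classmethod
    def two_week(cls) -> "DesignConfig":
        """Ten 2-week case windows, five 2-week controls at days 330–399."""
        return cls()

    @classmethod
    def six_week(cls) -> "DesignConfig":
        """Three 6-week case windows with three 6-week control windows."""
        return cls(interval_width=42, n_case_windows=3,
                   control_windows=((330, 371), (372, 413), (414, 455)))

    @classmethod
    def negative_control(cls) -> "DesignConfig":
        """Seven 30-day case windows; five 30-day controls starting day 330."""
        controls = tuple((330 + 30 * j, 330 + 30 * j + 29) for j in range(5))
        return cls(interval_width=30, n_case_windows=7, control_windows=controls)

    def to_dict(self) -> dict:
        return {"interval_width": self.interval_width,
                "n_case_windows": self.n_case_windows,
                "control_windows": [list(w) for w in self.control_windows]}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown design field")
        if "control_windows" in d:
            d["control_windows"] = tuple(tuple(w) for w in d["control_windows"])
        return cls(**d)


def load_yaml_section(path, section: str | None = None) -> dict:
    """Load a YAML mapping; optionally descend into one top-level section."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("file", f"{path} does not contain a mapping")
    if section is not None and section in data:
        data = data[section]
    return data
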