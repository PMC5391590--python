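"""Synthetic inpatient-claims generator with known postpartum risk structure.

The generator emulates, at configurable scale, an administrative inpatient
database covering women of childbearing age: delivery stays coded Z37.0
with a dated delivery procedure, pulmonary-embolism (PE) stays whose hazard
is ``baseline * multiplier(t since last delivery)``, carpal-tunnel stays
generated independently of deliveries (the negative-control exposure), and
unrelated background admissions.  Everything is drawn from a single seeded
``numpy`` generator, so identical configs produce byte-identical tables.

Mechanics worth knowing:

* Deliveries follow a per-woman renewal process with a 420-day minimum
  inter-delivery spacing (so no woman can be exposed in both a case window
  and a 330–399-day control window of the same index event) and stop at
  age 45.  The process starts 600 days before the study window so that the
  delivery intensity is stationary from day 0.
* PE events are drawn by thinning a homogeneous proposal process at the
  maximal hazard; a PE falling inside the woman's delivery stay is recorded
  *on* that stay (PE code among the associated diagnoses plus a dated
  diagnostic procedure) rather than as a separate admission.
* A configurable fraction of delivery stays carries a legacy-style
  procedure date: the recorded delivery offset defaults to day 0 of the
  stay even when the true delivery happened later in the stay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import codes
from .claims import CLAIMS_COLUMNS
from .config import SimulationConfig

__all__ = ["hazard_multiplier", "simulate_population"]

_BURN_IN_DAYS = 600
_MIN_SPACING_DAYS = 420
_ANTEPARTUM_LAG_PROB = 0.3
_CONTAMINATION_PROB = 0.02
_CESAREAN_PROB = 0.2


def hazard_multiplier(t_days, config: SimulationConfig):
    """Postpartum PE hazard multiplier at ``t_days`` since delivery.

    Scalar in, scalar out; arrays are broadcast.  Negative ``t_days``
    raise ``ValueError`` (the multiplier is defined postpartum only).
    """
    return config.rr_profile(t_days)


def _simulate_deliveries(rng, cfg: SimulationConfig):
    """Return (woman_index, day) arrays of delivery times, sorted.

    Days may be negative (burn-in deliveries); those never become stays but
    do drive the postpartum hazard.
    """
    n, last_day = cfg.n_women, cfg.n_days - 1
    ages = rng.integers(16, 41, size=n)
    if cfg.delivery_rate <= 0:
        return ages, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mean_gap = 365.0 / cfg.delivery_rate
    widx = np.arange(n)
    t = -_BURN_IN_DAYS + rng.exponential(mean_gap, size=n)
    out_w, out_t = [], []
    while True:
        in_time = t <= last_day
        if not in_time.any():
            break
        eligible = in_time & (ages + t / 365.25 < 45.0)
        out_w.append(widx[eligible])
        out_t.append(np.floor(t[eligible]).astype(np.int64))
        t = t + _MIN_SPACING_DAYS + rng.exponential(mean_gap, size=n)
    dw = np.concatenate(out_w) if out_w else np.empty(0, dtype=np.int64)
    dt_ = np.concatenate(out_t) if out_t else np.empty(0, dtype=np.int64)
    order = np.lexsort((dt_, dw))
    return ages, dw[order], dt_[order]


def _poisson_events(rng, rate_per_year: float, n_women: int, n_days: int):
    """Homogeneous per-woman events: (woman_index, day) flat arrays."""
    if rate_per_year <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lam = rate_per_year / 365.0 * n_days
    counts = rng.poisson(lam, size=n_women)
    total = int(counts.sum())
    w = np.repeat(np.arange(n_women), counts)
    t = rng.integers(0, n_days, size=total)
    return w, t


def _simulate_pe_events(rng, cfg: SimulationConfig, dw, dt_):
    """Thinning: propose at the max hazard, accept at multiplier/max.

    Returns (woman, day, delivery_pos) where ``delivery_pos`` indexes the
    sorted delivery arrays (most recent delivery at or before the event),
    or -1 when the woman has no prior delivery.
    """
    mmax = cfg.rr_profile.max_multiplier
    pw, pt = _poisson_events(rng, cfg.baseline_pe_rate * mmax, cfg.n_women, cfg.n_days)
    if len(pw) == 0:
        return pw, pt, np.empty(0, dtype=np.int64)
    key_span = cfg.n_days + _BURN_IN_DAYS + 1
    dkey = dw * key_span + (dt_ + _BURN_IN_DAYS)
    pkey = pw * key_span + (pt + _BURN_IN_DAYS)
    pos = np.searchsorted(dkey, pkey, side="right") - 1
    valid = pos >= 0
    if valid.any():
        valid[valid] &= dw[pos[valid]] == pw[valid]
    mult = np.ones(len(pw))
    if valid.any():
        tsd = pt[valid] - dt_[pos[valid]]
        mult[valid] = cfg.rr_profile(tsd)
    accept = rng.uniform(size=len(pw)) * mmax < mult
    pos = np.where(valid, pos, -1)
    return pw[accept], pt[accept], pos[accept]


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic claims table (one row per stay).

    Deterministic given ``config`` (including its seed).  Returns a
    DataFrame in the canonical CSV dialect of :mod:`ppx.claims`, sorted by
    patient, admission date and primary diagnosis.
    """
    rng = np.random.default_rng(config.seed)
    ages, dw, dt_ = _simulate_deliveries(rng, config)
    pe_w, pe_t, pe_pos = _simulate_pe_events(rng, config, dw, dt_)
    nc_w, nc_t = _poisson_events(rng, config.negative_control_rate,
                                 config.n_women, config.n_days)
    bg_w, bg_t = _poisson_events(rng, config.background_admission_rate,
                                 config.n_women, config.n_days)

    # --- delivery stays (only deliveries inside the study window) ---------
    emitted = dt_ >= 0
    nd = int(emitted.sum())
    ew, et = dw[emitted], dt_[emitted]
    lag = (rng.uniform(size=nd) < _ANTEPARTUM_LAG_PROB).astype(np.int64)
    lag = np.where(et - lag < 0, 0, lag)
    adm = et - lag
    los = rng.integers(3, 9, size=nd)
    cesarean = rng.uniform(size=nd) < _CESAREAN_PROB
    legacy = rng.uniform(size=nd) < config.legacy_date_fraction
    proc_off = np.where(legacy, 0, lag)
    contaminated = rng.uniform(size=nd) < _CONTAMINATION_PROB
    contaminant = rng.uniform(size=nd) < 0.5  # O35.1 vs O28.0

    # map sorted-delivery position -> emitted-stay slot (or -1)
    slot_of_pos = np.full(len(dw), -1, dtype=np.int64)
    slot_of_pos[emitted] = np.arange(nd)

    d_primary = np.where(cesarean, "O82", "O80")
    d_proc_code = np.where(cesarean, codes.DELIVERY_PROCEDURES[1],
                           codes.DELIVERY_PROCEDURES[0])
    d_assoc = [[codes.DELIVERY_DX] for _ in range(nd)]
    d_procs = [[(d_proc_code[i], int(proc_off[i]))] for i in range(nd)]
    for i in np.flatnonzero(contaminated):
        d_assoc[i].append("O35.1" if contaminant[i] else "O28.0")

    # --- PE events: attach to the delivery stay or emit a separate stay ---
    n_pe = len(pe_w)
    pe_code = rng.choice(np.array(codes.DEFAULT_PE_DX), size=n_pe,
                         p=[0.6, 0.25, 0.15]) if n_pe else np.empty(0, dtype=object)
    pe_sep_los = rng.integers(4, 11, size=n_pe)
    slot = np.where(pe_pos >= 0, slot_of_pos[pe_pos], -1)
    attached = np.zeros(n_pe, dtype=bool)
    if n_pe:
        has_slot = slot >= 0
        idx = np.flatnonzero(has_slot)
        within = pe_t[idx] <= adm[slot[idx]] + los[slot[idx]]
        attached[idx[within]] = True
    for j in np.flatnonzero(attached):
        s = slot[j]
        d_assoc[s].append(str(pe_code[j]))
        d_procs[s].append((codes.DEFAULT_PE_PROCEDURES[0], int(pe_t[j] - adm[s])))

    parts = []

    def _part(w, a, l, primary, assoc, procs):
        parts.append(pd.DataFrame({
            "widx": w, "adm_day": a, "length_of_stay": l,
            "primary_dx": primary, "associated_dx": assoc, "procedures": procs,
        }))

    _part(ew, adm, los, d_primary,
          [";".join(x) for x in d_assoc],
          [";".join(f"{c}@{o}" for c, o in x) for x in d_procs])

    sep = ~attached
    if sep.any():
        sl = pe_sep_los[sep]
        off = np.minimum(rng.integers(0, 2, size=int(sep.sum())), sl)
        _part(pe_w[sep], pe_t[sep], sl, pe_code[sep].astype(str),
              [""] * int(sep.sum()),
              [f"{codes.DEFAULT_PE_PROCEDURES[0]}@{int(o)}" for o in off])

    if len(nc_w):
        nc_los = rng.integers(0, 2, size=len(nc_w))
        _part(nc_w, nc_t, nc_los, codes.NEGATIVE_CONTROL_DX,
              [""] * len(nc_w),
              [f"{codes.NEGATIVE_CONTROL_PROCEDURE}@0"] * len(nc_w))

    if len(bg_w):
        bg_primary = rng.choice(np.array(["K35.8", "J18.9", "S52.5", "N10"]),
                                size=len(bg_w))
        bg_los = rng.integers(1, 6, size=len(bg_w))
        _part(bg_w, bg_t, bg_los, bg_primary.astype(str),
              [""] * len(bg_w), [""] * len(bg_w))

    stays = pd.concat(parts, ignore_index=True) if parts else None
    if stays is None or not len(stays):
        return pd.DataFrame(columns=list(CLAIMS_COLUMNS))

    widx = stays["widx"].to_numpy(dtype=np.int64)
    adm_day = stays["adm_day"].to_numpy(dtype=np.int64)
    start = np.datetime64(config.study_start.isoformat())
    out = pd.DataFrame({
        "patient_id": np.char.add("W", np.char.zfill(widx.astype(str), 7)),
        "age_years": (ages[widx] + adm_day / 365.25).astype(int),
        "sex": "F",
        "admission_date": pd.Series(start + adm_day.astype("timedelta64[D]"))
                            .dt.strftime("%Y-%m-%d"),
        "length_of_stay": stays["length_of_stay"].astype(int),
        "primary_dx": stays["primary_dx"].astype(str),
        "associated_dx": stays["associated_dx"].astype(str),
        "procedures": stays["procedures"].astype(str),
    })
    out = out.sort_values(
        ["patient_id", "admission_date", "primary_dx", "procedures"],
        kind="mergesort").reset_index(drop=True)
    return out[list(CLAIMS_COLUMNS)]
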