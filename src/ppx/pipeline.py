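"""End-to-end orchestration: claims in, per-window odds-ratio tables out.

:func:`analyze_claims` is the in-memory workhorse (cases -> exposures ->
matched sets -> conditional logit per window); :func:`run_pipeline` wraps
it with file I/O, a run manifest and structured logging, and aborts with
the failing stage named, removing partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cases import find_pe_cases
from .claims import parse_claims, read_claims
from .config import CohortConfig, DesignConfig
from .crossover import count_summary, sets_for_all_windows
from .errors import DegenerateEstimateError, EstimationError, PipelineError
from .estimation import (IntervalResult, event_rate, fit_conditional_logit,
                         truncate1, wald_ci)
from .exposure import find_deliveries
from .sensitivity import apply_posthoc_exclusions

logger = logging.getLogger(__name__)

__all__ = ["analyze_claims", "results_to_frame", "run_pipeline"]


def analyze_window(sets, denominator: int, label: str) -> IntervalResult:
    """Fit one window's matched sets into an :class:`IntervalResult`."""
    a, b, mean_control = count_summary(sets)
    rate = event_rate(a, denominator)
    try:
        fit = fit_conditional_logit(sets)
    except DegenerateEstimateError as exc:
        return IntervalResult(label=label, a=a, b=b, mean_control=mean_control,
                              rate_per_100k=rate,
                              flag=f"{exc.kind}-OR")
    except EstimationError:
        return IntervalResult(label=label, a=a, b=b, mean_control=mean_control,
                              rate_per_100k=rate, flag="no-discordant")
    lo, hi = wald_ci(fit.beta, fit.se)
    return IntervalResult(label=label, a=a, b=b, mean_control=mean_control,
                          rate_per_100k=rate, or_hat=fit.odds_ratio,
                          ci_low=lo, ci_high=hi,
                          beta_hat=fit.beta, se_beta=fit.se)


def analyze_claims(parsed: pd.DataFrame,
                   design: DesignConfig | None = None,
                   cohort: CohortConfig | None = None,
                   exposures: pd.DataFrame | None = None,
                   denominator: int | None = None,
                   posthoc: bool = False) -> pd.DataFrame:
    """Run the crossover analysis on a parsed claims table.

    Parameters
    ----------
    parsed
        Output of :func:`ppx.claims.parse_claims`.
    design, cohort
        Window geometry and extraction settings (defaults: the ten 2-week
        windows with five 330–399-day controls; default code sets).
    exposures
        Pre-extracted exposure table; defaults to eligible deliveries.
    denominator
        Denominator for the per-100,000 rate; defaults to the number of
        exposures dated inside the inclusion window.
    posthoc
        Apply the conservative exclusions before estimation.

    Returns the per-window results table (see :func:`results_to_frame`).
    """
    design = design or DesignConfig.two_week()
    cohort = cohort or CohortConfig()
    cases = find_pe_cases(parsed, cohort)
    if exposures is None:
        exposures = find_deliveries(parsed, cohort)
    if denominator is None:
        dates = pd.to_datetime(exposures["date"]) if len(exposures) else pd.Series(dtype="datetime64[ns]")
        in_window = ((dates >= pd.Timestamp(cohort.inclusion_start))
                     & (dates <= pd.Timestamp(cohort.inclusion_end)))
        denominator = max(int(in_window.sum()), 1)
    if posthoc:
        report = apply_posthoc_exclusions(cases, exposures, parsed, design)
        cases = report.retained
    results = []
    for sets in sets_for_all_windows(cases, exposures, design):
        label = design.window_label(sets.window_index)
        results.append(analyze_window(sets, denominator, label))
    return results_to_frame(results, design)


def results_to_frame(results, design: DesignConfig) -> pd.DataFrame:
    """Results table mirroring the published layout plus full precision.

    ``or_trunc`` / ``ci_low_trunc`` / ``ci_high_trunc`` are the one-decimal
    truncated reported values; ``or_hat`` etc. keep full precision.
    ``midpoint_day`` is the case-window midpoint used for the risk curve.
    """
    rows = []
    w = design.interval_width
    for k, r in enumerate(results):
        rows.append({
            "window": r.label,
            "midpoint_day": k * w + (w - 1) / 2.0,
            "n_case_events": r.a,
            "rate_per_100k": r.rate_per_100k,
            "mean_control_events": r.mean_control,
            "n_control_events": r.b,
            "or_trunc": truncate1(r.or_hat) if np.isfinite(r.or_hat) else np.nan,
            "ci_low_trunc": truncate1(r.ci_low) if np.isfinite(r.ci_low) else np.nan,
            "ci_high_trunc": truncate1(r.ci_high) if np.isfinite(r.ci_high) else np.nan,
            "or_hat": r.or_hat, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "beta_hat": r.beta_hat, "se_beta": r.se_beta, "flag": r.flag,
        })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(claims_path, out_dir,
                 design: DesignConfig | None = None,
                 cohort: CohortConfig | None = None,
                 posthoc: bool = False,
                 negative_control: bool = False) -> Path:
    """File-level pipeline: read claims, analyze, emit tables + manifest.

    Writes ``table2.csv`` (per-window results), ``risk_curve.csv``
    (midpoint day, OR, CI bounds), ``manifest.json`` and ``run.log`` into
    ``out_dir``.  On failure raises :class:`PipelineError` naming the
    stage and removes partial outputs.
    """
    design = design or (DesignConfig.negative_control() if negative_control
                        else DesignConfig.two_week())
    cohort = cohort or CohortConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "table2.csv", out_dir / "risk_curve.csv",
               out_dir / "manifest.json", out_dir / "run.log"]

    log_lines: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            for p in outputs:
                p.unlink(missing_ok=True)
            raise PipelineError(name, str(exc)) from exc
        log_lines.append(f"stage {name}: ok")
        return result

    claims_path = Path(claims_path)
    raw = stage("read_claims", read_claims, claims_path)
    parsed = stage("parse_claims", parse_claims, raw)
    if negative_control:
        from .sensitivity import negative_control_analysis
        table = stage("analyze", negative_control_analysis, parsed,
                      cohort, design)
    else:
        table = stage("analyze", analyze_claims, parsed, design, cohort,
                      None, None, posthoc)
    table.to_csv(out_dir / "table2.csv", index=False, lineterminator="\n")
    curve = table[["midpoint_day", "or_hat", "ci_low", "ci_high"]]
    curve.to_csv(out_dir / "risk_curve.csv", index=False, lineterminator="\n")
    manifest = {
        "version": __version__,
        "inputs": {claims_path.name: _sha256(claims_path)},
        "design": design.to_dict(),
        "cohort": cohort.to_dict(),
        "posthoc": posthoc,
        "negative_control": negative_control,
        "rows": {"claims": int(len(parsed)), "windows": int(len(table))},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir
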