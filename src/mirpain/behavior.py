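"""von Frey withdrawal-behaviour reductions.

Trial-level records (mouse, treatment group, post-implantation day,
filament force in grams, trials, withdrawals) are reduced to per-animal
stimulus-response curves (withdrawal frequency in percent over the
graded filament set, conventionally 0.02-1.0 g with five stimulations
per filament), from which two scalar summaries are derived:

* the mechanical response threshold — the filament force at which the
  curve reaches a chosen response quantile (50% or 80% here), found by
  first-crossing linear interpolation on the log10-force axis, with
  explicit left/right censoring when the quantile is reached at the
  weakest filament or never;
* the area under the stimulus-response curve (AUC), a trapezoidal
  integral of frequency over log10 force across the full filament range
  (a linear-force abscissa is available for sensitivity analysis).

Group summaries reduce per animal first, then average, matching how
behavioural cohorts are reported (mean +/- SEM over mice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BEHAVIOR_COLUMNS = ("mouse", "group", "day", "force_g", "n_trials", "n_withdrawals")

DEFAULT_FILAMENTS_G = (0.02, 0.07, 0.16, 0.4, 1.0)
DEFAULT_N_TRIALS = 5
DEFAULT_QUANTILE = 50.0

CENSOR_NONE = "none"
CENSOR_LEFT = "left"
CENSOR_RIGHT = "right"


@dataclass(frozen=True)
class ThresholdResult:
    force_g: float
    quantile: float
    censoring: str  # none | left | right


@dataclass(frozen=True)
class AUCResult:
    value: float
    scale: str  # log10 | linear
    force_min_g: float
    force_max_g: float


def response_frequency(withdrawals: int, trials: int) -> float:
    """Withdrawal frequency in percent: 100 x withdrawals / trials."""
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= withdrawals <= trials:
        raise ValueError(f"withdrawals {withdrawals} outside [0, {trials}]")
    return 100.0 * withdrawals / trials


def _check_curve(forces: np.ndarray, freqs: np.ndarray) -> None:
    if forces.size < 2:
        raise ValueError("curve needs at least 2 filaments")
    if not np.all(np.diff(forces) > 0):
        raise ValueError(f"forces must be strictly increasing, got {forces.tolist()}")
    if not np.all(forces > 0):
        raise ValueError("forces must be positive")
    if np.any((freqs < 0) | (freqs > 100)):
        raise ValueError("frequencies must lie in [0, 100]")


def threshold(
    forces: np.ndarray | list,
    freqs: np.ndarray | list,
    q: float = DEFAULT_QUANTILE,
) -> ThresholdResult:
    """Force (grams) at which the response curve first reaches ``q`` percent.

    The first adjacent filament pair with ``f_i < q <= f_{i+1}`` is
    interpolated linearly in log10 force.  If the weakest filament already
    responds at >= q the result is left-censored at that filament; if no
    filament reaches q it is right-censored at the strongest.  An exact
    hit at a filament returns that filament's force.
    """
    forces = np.asarray(forces, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    _check_curve(forces, freqs)
    if not 0 < q < 100:
        raise ValueError(f"quantile must be in (0, 100), got {q}")
    if freqs[0] >= q:
        return ThresholdResult(float(forces[0]), q, CENSOR_LEFT)
    for i in range(len(forces) - 1):
        if freqs[i] < q <= freqs[i + 1]:
            frac = (q - freqs[i]) / (freqs[i + 1] - freqs[i])
            log_thr = np.log10(forces[i]) + frac * (np.log10(forces[i + 1]) - np.log10(forces[i]))
            return ThresholdResult(float(10.0 ** log_thr), q, CENSOR_NONE)
    return ThresholdResult(float(forces[-1]), q, CENSOR_RIGHT)


def auc(
    forces: np.ndarray | list,
    freqs: np.ndarray | list,
    scale: str = "log10",
) -> AUCResult:
    """Trapezoidal area under the frequency curve across the filament range.

    The abscissa is log10(force) by default (units: percent x log10-gram),
    or raw force with ``scale="linear"``.
    """
    forces = np.asarray(forces, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    _check_curve(forces, freqs)
    if scale == "log10":
        x = np.log10(forces)
    elif scale == "linear":
        x = forces
    else:
        raise ValueError(f"scale must be 'log10' or 'linear', got {scale!r}")
    value = float(np.trapezoid(freqs, x))
    return AUCResult(value, scale, float(forces[0]), float(forces[-1]))


def response_curves(data: pd.DataFrame) -> pd.DataFrame:
    """Per (mouse, group, day) stimulus-response curves from trial records.

    Returns long format with columns
    ``mouse, group, day, force_g, frequency_pct`` ordered by force.
    """
    missing = [c for c in BEHAVIOR_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    bad = data[(data["n_withdrawals"] < 0) | (data["n_withdrawals"] > data["n_trials"])]
    if len(bad):
        raise ValueError(
            f"withdrawals outside [0, trials] at rows {bad.index.tolist()[:10]}"
        )
    out = data.copy()
    out["frequency_pct"] = 100.0 * out["n_withdrawals"] / out["n_trials"]
    return (
        out[["mouse", "group", "day", "force_g", "frequency_pct"]]
        .sort_values(["group", "mouse", "day", "force_g"])
        .reset_index(drop=True)
    )


def animal_summaries(
    data: pd.DataFrame,
    q: float = DEFAULT_QUANTILE,
    auc_scale: str = "log10",
) -> pd.DataFrame:
    """Threshold (with censoring flag) and AUC per (mouse, day)."""
    curves = response_curves(data)
    rows = []
    for (mouse, group, day), g in curves.groupby(["mouse", "group", "day"], sort=True):
        forces = g["force_g"].to_numpy()
        freqs = g["frequency_pct"].to_numpy()
        thr = threshold(forces, freqs, q)
        area = auc(forces, freqs, scale=auc_scale)
        rows.append(
            {
                "mouse": mouse,
                "group": group,
                "day": day,
                "threshold_g": thr.force_g,
                "censoring": thr.censoring,
                "auc": area.value,
                "auc_scale": area.scale,
                "quantile": q,
            }
        )
    return pd.DataFrame(rows)


def group_timecourse(
    data: pd.DataFrame,
    q: float = DEFAULT_QUANTILE,
    auc_scale: str = "log10",
) -> dict:
    """Group-level time courses of frequency, threshold and AUC.

    Per-animal reductions are computed first, then averaged per
    (group, day) with SEM (NaN for a single animal).  Censored thresholds
    enter the mean at their censoring bound; the censored fraction is
    reported alongside.  Returns ``{"frequency": ..., "summary": ...}``
    frames.
    """
    curves = response_curves(data)
    freq = (
        curves.groupby(["group", "day", "force_g"])["frequency_pct"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
             n="count")
        .reset_index()
    )
    per_animal = animal_summaries(data, q=q, auc_scale=auc_scale)

    def _sem(v: pd.Series) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan

    summary = (
        per_animal.groupby(["group", "day"])
        .agg(
            threshold_mean=("threshold_g", "mean"),
            threshold_sem=("threshold_g", _sem),
            censored_fraction=("censoring", lambda c: float((c != CENSOR_NONE).mean())),
            auc_mean=("auc", "mean"),
            auc_sem=("auc", _sem),
            n_mice=("mouse", "nunique"),
        )
        .reset_index()
    )
    return {"frequency": freq, "summary": summary, "per_animal": per_animal}
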