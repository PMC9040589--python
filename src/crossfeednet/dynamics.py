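"""Calling consumed / secreted / unchanged ions from supernatant time courses.

For each (species, medium) culture, every annotated ion's intensity time
course is tested against the culture OD. An ion is called directional when

  * its Pearson correlation with OD is strong (|r| > 0.7, p < 0.05), OR
  * a linear or exponential (log-linear) fit against time is good
    (R^2 > 0.7, p < 0.05) — this second branch catches metabolites that
    are exhausted before the end of the growth experiment or produced at
    a constant rate,

AND the maximum fold change between the first time point and any later
point clears a calibrated threshold: a 1.37-fold decrease for consumed
ions, a 1.20-fold increase for secreted ions. Those defaults were
calibrated on a dilution series of the growth medium (see
:func:`calibrate_thresholds`): a known 2-fold dilution of real medium
reads out as less than 2-fold in ion counts because flow-injection MS is
matrix-suppressed, so the empirical fold change of genuinely
medium-derived ions across a 2-fold dilution window is the smallest
change worth believing.

Replicates of the same culture are averaged per time point before
testing (per-replicate calling is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ION_META_COLS, ion_columns

__all__ = [
    "CallerConfig",
    "DynamicCall",
    "call_dynamics",
    "calibrate_thresholds",
    "signed_max_fold_change",
    "calls_to_frame",
]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the consumption/secretion caller.

    Defaults are the calibrated values shipped with the method:
    fold-change cutoffs 1.37 (consumed) / 1.20 (secreted) from a growth-
    medium dilution series, |r| > 0.7 against OD, fit R^2 > 0.7, p < 0.05,
    and a -0.75 correlation filter for calibration ions.
    """

    r_od_threshold: float = 0.7
    p_threshold: float = 0.05
    r2_fit_threshold: float = 0.7
    fc_secreted: float = 1.20
    fc_consumed: float = 1.37
    dilution_corr_threshold: float = -0.75

    def __post_init__(self):
        if not 0 < self.r_od_threshold < 1:
            raise ValueError("r_od_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 < self.r2_fit_threshold < 1:
            raise ValueError("r2_fit_threshold must be in (0, 1)")
        if self.fc_secreted <= 1 or self.fc_consumed <= 1:
            raise ValueError("fold-change thresholds must exceed 1")
        if not -1 <= self.dilution_corr_threshold <= 0:
            raise ValueError("dilution_corr_threshold must be in [-1, 0]")


@dataclass
class DynamicCall:
    """Direction call for one ion in one culture, with full evidence."""

    metabolite: str
    species: str
    medium: str
    direction: str  # "consumed" | "secreted" | "unchanged"
    r_od: float = float("nan")
    p_r: float = float("nan")
    r2_linear: float = float("nan")
    p_linear: float = float("nan")
    r2_exponential: float = float("nan")
    p_exponential: float = float("nan")
    max_fold_change: float = float("nan")  # signed; negative = decrease
    flags: list = field(default_factory=list)


def signed_max_fold_change(x: np.ndarray) -> tuple[float, float, float, list]:
    """Fold changes of a series relative to its first time point.

    Returns ``(fc_up, fc_down, signed, flags)`` where ``fc_up`` is the
    largest increase ratio x_t/x_0 (>= 1), ``fc_down`` the largest
    decrease magnitude x_0/x_t (>= 1), and ``signed`` the extreme of the
    two with decreases negative. Zero intensities are floored at half the
    smallest positive value in the series (flagged); an all-zero series
    returns unit fold changes with a "degenerate" flag.
    """
    x = np.asarray(x, dtype=float)
    flags: list = []
    pos = x[x > 0]
    if pos.size == 0:
        return 1.0, 1.0, 1.0, ["degenerate"]
    floor = float(pos.min()) * 0.5
    if np.any(x <= 0):
        x = np.where(x > 0, x, floor)
        flags.append("intensity_floored")
    x0 = x[0]
    fc_up = float(np.max(x) / x0)
    fc_down = float(x0 / np.min(x))
    signed = fc_up if fc_up >= fc_down else -fc_down
    return fc_up, fc_down, signed, flags


def _pearson_vs(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p (t distribution); NaN when degenerate."""
    if np.ptp(x) == 0 or np.ptp(y) == 0 or len(x) < 3:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _fit_vs_time(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """OLS of x on t: returns (R^2, slope p-value, slope sign)."""
    if np.ptp(x) == 0 or len(t) < 3:
        return float("nan"), float("nan"), 0.0
    res = stats.linregress(t, x)
    return float(res.rvalue**2), float(res.pvalue), float(np.sign(res.slope))


def _call_series(
    metabolite: str,
    species: str,
    medium: str,
    t: np.ndarray,
    od: np.ndarray,
    x: np.ndarray,
    config: CallerConfig,
) -> DynamicCall:
    call = DynamicCall(metabolite=metabolite, species=species, medium=medium,
                       direction="unchanged")

    fc_up, fc_down, signed_fc, fc_flags = signed_max_fold_change(x)
    call.max_fold_change = signed_fc
    call.flags.extend(fc_flags)
    if "degenerate" in call.flags or np.ptp(x) == 0:
        if "degenerate" not in call.flags:
            call.flags.append("degenerate")
        return call

    # work on the floored series so the log fit is defined
    pos = x[x > 0]
    xf = np.where(x > 0, x, pos.min() * 0.5)

    call.r_od, call.p_r = _pearson_vs(xf, od)
    call.r2_linear, call.p_linear, lin_sign = _fit_vs_time(t, xf)
    call.r2_exponential, call.p_exponential, exp_sign = _fit_vs_time(t, np.log(xf))

    corr_pass = (
        math.isfinite(call.r_od)
        and abs(call.r_od) > config.r_od_threshold
        and call.p_r < config.p_threshold
    )
    lin_pass = (
        math.isfinite(call.r2_linear)
        and call.r2_linear > config.r2_fit_threshold
        and call.p_linear < config.p_threshold
    )
    exp_pass = (
        math.isfinite(call.r2_exponential)
        and call.r2_exponential > config.r2_fit_threshold
        and call.p_exponential < config.p_threshold
    )

    if corr_pass:
        trend = float(np.sign(call.r_od))
    elif lin_pass:
        trend = lin_sign
    elif exp_pass:
        trend = exp_sign
    else:
        return call

    if trend > 0 and fc_up >= config.fc_secreted:
        call.direction = "secreted"
        call.max_fold_change = fc_up
    elif trend < 0 and fc_down >= config.fc_consumed:
        call.direction = "consumed"
        call.max_fold_change = -fc_down
    return call


def call_dynamics(
    table: pd.DataFrame,
    config: CallerConfig | None = None,
    per_replicate: bool = False,
) -> list[DynamicCall]:
    """Call every ion in every (species, medium) culture of the table.

    ``table`` is a wide ion time-course frame (columns ``species, medium,
    replicate, time_h, od`` plus one column per ion). Replicates are
    averaged per time point before testing unless ``per_replicate`` is
    set, in which case all replicate points are pooled.
    """
    config = config or CallerConfig()
    ions = ion_columns(table)
    calls: list[DynamicCall] = []
    for (species, medium), grp in table.groupby(["species", "medium"], sort=True):
        if per_replicate:
            agg = grp.sort_values(["time_h", "replicate"])
        else:
            agg = (
                grp.groupby("time_h", sort=True)[["od", *ions]]
                .mean()
                .reset_index()
            )
        t = agg["time_h"].to_numpy(dtype=float)
        if len(np.unique(t)) < 4:
            raise ValueError(
                f"culture ({species}, {medium}) has fewer than 4 time points"
            )
        od = agg["od"].to_numpy(dtype=float)
        for ion in ions:
            calls.append(
                _call_series(ion, str(species), str(medium), t, od,
                             agg[ion].to_numpy(dtype=float), config)
            )
    return calls


def calls_to_frame(calls: list[DynamicCall]) -> pd.DataFrame:
    """Tabulate calls (one row per ion x culture) for TSV export."""
    return pd.DataFrame(
        [
            {
                "metabolite": c.metabolite,
                "species": c.species,
                "medium": c.medium,
                "direction": c.direction,
                "r_od": c.r_od,
                "p_r": c.p_r,
                "r2_lin": c.r2_linear,
                "r2_exp": c.r2_exponential,
                "max_fc": c.max_fold_change,
                "flags": ";".join(c.flags),
            }
            for c in calls
        ]
    )


def calibrate_thresholds(
    dilution_table: pd.DataFrame,
    config: CallerConfig | None = None,
    consumed_window: tuple[float, float] = (40.0, 80.0),
    secreted_window: tuple[float, float] = (20.0, 40.0),
) -> tuple[float, float]:
    """Calibrate fold-change thresholds from a medium dilution series.

    Ions whose intensity correlates strongly and negatively with the
    dilution factor (Pearson r below ``config.dilution_corr_threshold``)
    are genuinely medium-derived; background ions are flat across
    dilutions and are discarded. The consumed-ion threshold is the mean
    fold change of kept ions across the ``consumed_window`` (intensity at
    40x over 80x dilution, a true 2-fold decrease); the secreted-ion
    threshold is the mean across ``secreted_window`` (20x over 40x, a
    true 2-fold increase read in reverse).

    ``dilution_table`` has columns ``dilution`` (fold factor),
    ``replicate`` and one column per ion; replicates are averaged per
    dilution level.

    Returns ``(fc_consumed, fc_secreted)``.
    """
    config = config or CallerConfig()
    ions = [c for c in dilution_table.columns if c not in ("dilution", "replicate")]
    if not ions:
        raise ValueError("dilution table contains no ion columns")
    agg = dilution_table.groupby("dilution", sort=True)[ions].mean()
    levels = agg.index.to_numpy(dtype=float)
    if len(levels) < 3:
        raise ValueError("need at least 3 dilution levels")
    for d in (*consumed_window, *secreted_window):
        if not np.any(np.isclose(levels, d)):
            raise ValueError(f"dilution level {d} missing from the series")

    def _at(d: float) -> pd.Series:
        idx = levels[np.isclose(levels, d)][0]
        return agg.loc[idx]

    kept: list[str] = []
    for ion in ions:
        x = agg[ion].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        r = stats.pearsonr(x, levels).statistic
        if r < config.dilution_corr_threshold:
            kept.append(ion)
    if not kept:
        raise ValueError(
            "no ion passed the dilution-correlation filter; "
            "cannot calibrate fold-change thresholds"
        )

    lo_c, hi_c = consumed_window
    lo_s, hi_s = secreted_window
    fc_consumed = float(np.mean([_at(lo_c)[i] / _at(hi_c)[i] for i in kept]))
    fc_secreted = float(np.mean([_at(lo_s)[i] / _at(hi_s)[i] for i in kept]))
    return fc_consumed, fc_secreted
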