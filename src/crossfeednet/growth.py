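"""Four-parameter logistic growth fitting and derived physiology.

Batch OD time courses are fit with the four-parameter logistic (4PL)

    OD(t) = A + (K - A) / (1 + exp(-r (t - t0)))

with baseline A, asymptote K (= maximum OD), shape rate r (1/h) and
inflection time t0 (h). The specific growth rate mu is the maximum of
d ln(OD)/dt evaluated on the fitted curve — the rate a microbiologist
reads off a log-OD plot — not the raw shape parameter r.

Also provided: maximum OD in spent medium relative to fresh medium, and
supplementation-effect statistics (ratios of mu / max OD / area under
the OD curve between treated and control arms, with Welch t tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GrowthFit",
    "logistic4",
    "fit_logistic4",
    "relative_max_od",
    "supplementation_effect",
    "auc_od",
]

#: Fitted K - A below this (OD units) is treated as no growth.
NO_GROWTH_DELTA_OD = 0.05


def logistic4(t, A, K, r, t0):
    """Four-parameter logistic OD(t) = A + (K-A)/(1+exp(-r(t-t0)))."""
    t = np.asarray(t, dtype=float)
    # clip the exponent so extreme r*(t-t0) cannot overflow
    z = np.clip(-r * (t - t0), -700.0, 700.0)
    return A + (K - A) / (1.0 + np.exp(z))


@dataclass
class GrowthFit:
    """Result of a 4PL fit plus derived physiology."""

    A: float
    K: float
    r: float
    t0: float
    mu: float          # max specific growth rate d ln(OD)/dt, 1/h
    max_od: float      # equals K for a successful fit
    r_squared: float
    converged: bool
    grew: bool         # False when K - A < NO_GROWTH_DELTA_OD


def _max_specific_rate(A: float, K: float, r: float, t0: float,
                       t_lo: float, t_hi: float) -> float:
    """max_t d ln(OD)/dt of the fitted 4PL, on a dense grid over the data span."""
    grid = np.linspace(t_lo, t_hi, 2001)
    od = logistic4(grid, A, K, r, t0)
    s = np.clip(-r * (grid - t0), -700.0, 700.0)
    sig = 1.0 / (1.0 + np.exp(s))
    d_od = (K - A) * r * sig * (1.0 - sig)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(od > 0, d_od / od, 0.0)
    return float(np.max(rate))


def fit_logistic4(times, od) -> GrowthFit:
    """Least-squares 4PL fit of an OD time course.

    Requires at least 5 distinct time points and strictly positive OD.
    A fit with K - A below 0.05 OD units is flagged non-growing and
    reported with mu = 0. Non-convergence is flagged, never silent.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and od must be 1-D arrays of equal length")
    if len(np.unique(t)) < 5:
        raise ValueError("need at least 5 distinct time points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in growth data")
    if np.any(y <= 0):
        raise ValueError("all OD values must be positive")

    y_min, y_max = float(np.min(y)), float(np.max(y))
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0

    if y_max - y_min < NO_GROWTH_DELTA_OD:
        # flat series: no growth, nothing to optimize
        mean = float(np.mean(y))
        ss_tot = float(np.sum((y - mean) ** 2))
        return GrowthFit(A=mean, K=mean, r=0.0, t0=float(np.median(t)), mu=0.0,
                         max_od=mean, r_squared=1.0 if ss_tot == 0 else 0.0,
                         converged=True, grew=False)

    # initialization: steepest log-slope locates t0; log-linear middle third
    # gives the rate scale
    logy = np.log(y)
    dlog = np.diff(logy) / np.diff(t)
    i_steep = int(np.argmax(dlog))
    t0_init = float(0.5 * (t[i_steep] + t[i_steep + 1]))
    third = max(len(t) // 3, 2)
    mid = slice(third, min(2 * third + 1, len(t)))
    try:
        slope = float(np.polyfit(t[mid], logy[mid], 1)[0])
    except Exception:
        slope = 1.0 / span
    r_init = max(abs(slope) * 4.0, 1e-3)

    p0 = [max(y_min, 1e-6), y_max, r_init, t0_init]
    lower = [1e-9, 1e-9, 1e-6, t[0] - 5.0 * span]
    upper = [y_max * 2.0, y_max * 10.0, 1e3, t[-1] + 5.0 * span]
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, lower, upper)]

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            logistic4, t, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning):
        converged = False
        popt = np.array(p0)
    A, K, r, t0 = (float(v) for v in popt)
    if K < A:  # bounds allow it; canonicalize
        A, K = K, A

    resid = y - logistic4(t, A, K, r, t0)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r_squared = float(min(max(r_squared, 0.0), 1.0))

    grew = (K - A) >= NO_GROWTH_DELTA_OD
    mu = _max_specific_rate(A, K, r, t0, float(t[0]), float(t[-1])) if grew else 0.0
    return GrowthFit(A=A, K=K, r=r, t0=t0, mu=max(mu, 0.0), max_od=K,
                     r_squared=r_squared, converged=converged, grew=grew)


def relative_max_od(spent_fit: GrowthFit, fresh_fit: GrowthFit) -> float:
    """Maximum OD in spent medium relative to fresh medium.

    A non-growing spent culture scores 0; a ratio of 0.5 is the neutral
    expectation under a pure 1:1 dilution of the medium.
    """
    if fresh_fit.max_od <= 0:
        raise ValueError("fresh-medium max OD must be positive")
    if not spent_fit.grew:
        return 0.0
    return spent_fit.max_od / fresh_fit.max_od


def auc_od(times, od) -> float:
    """Area under the raw OD curve by the trapezoid rule (OD * h)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    return float(np.trapezoid(y, t))


def supplementation_effect(control_reps, treated_reps):
    """Effect of nutrient supplementation on growth physiology.

    Parameters
    ----------
    control_reps, treated_reps : list of (times, od) per replicate.

    Returns
    -------
    dict with ``relative_mu``, ``relative_max_od``, ``relative_auc``
    (ratios of treated to control per-replicate means) and ``p_mu``,
    ``p_max_od`` (two-sided Welch t tests on the per-replicate values;
    NaN when either arm has a single replicate).
    """
    if not control_reps or not treated_reps:
        raise ValueError("both arms need at least one replicate")

    def _fit_arm(reps):
        fits = [fit_logistic4(t, y) for t, y in reps]
        mu = np.array([f.mu for f in fits])
        mx = np.array([f.max_od for f in fits])
        auc = np.array([auc_od(t, y) for t, y in reps])
        return mu, mx, auc

    mu_c, mx_c, auc_c = _fit_arm(control_reps)
    mu_t, mx_t, auc_t = _fit_arm(treated_reps)

    def _ratio(a, b):
        return float(np.mean(a) / np.mean(b)) if np.mean(b) != 0 else np.nan

    if len(mu_c) >= 2 and len(mu_t) >= 2:
        if np.ptp(mu_c) == 0 and np.ptp(mu_t) == 0 and np.mean(mu_c) == np.mean(mu_t):
            p_mu = 1.0  # identical degenerate arms
        else:
            p_mu = float(stats.ttest_ind(mu_t, mu_c, equal_var=False).pvalue)
        if np.ptp(mx_c) == 0 and np.ptp(mx_t) == 0 and np.mean(mx_c) == np.mean(mx_t):
            p_max = 1.0
        else:
            p_max = float(stats.ttest_ind(mx_t, mx_c, equal_var=False).pvalue)
    else:
        p_mu = p_max = float("nan")

    return {
        "relative_mu": _ratio(mu_t, mu_c),
        "relative_max_od": _ratio(mx_t, mx_c),
        "relative_auc": _ratio(auc_t, auc_c),
        "p_mu": p_mu,
        "p_max_od": p_max,
    }
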