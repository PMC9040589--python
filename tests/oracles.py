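"""Independent brute-force oracles used by the tests.

These re-derive every statistic from raw formulas (numpy arithmetic and
the t distribution only) so the checks do not collapse onto the same
library calls the implementation uses.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def pearson_r_p(x, y):
    """Pearson r and two-sided p from the t statistic, by hand."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    dx, dy = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0 or sy == 0 or n < 3:
        return float("nan"), float("nan")
    r = float(dx @ dy) / (sx * sy)
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, p


def linfit_r2_p_sign(t, x):
    """OLS of x on t by normal equations: R^2, slope p, slope sign."""
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    n = len(t)
    if np.ptp(x) == 0 or n < 3:
        return float("nan"), float("nan"), 0.0
    dt = t - t.mean()
    slope = float(dt @ (x - x.mean())) / float(dt @ dt)
    intercept = x.mean() - slope * t.mean()
    resid = x - (intercept + slope * t)
    ss_res = float(resid @ resid)
    ss_tot = float((x - x.mean()) @ (x - x.mean()))
    r2 = 1.0 - ss_res / ss_tot
    if ss_res <= 0:
        return 1.0, 0.0, float(np.sign(slope))
    se = math.sqrt(ss_res / (n - 2) / float(dt @ dt))
    tt = slope / se
    p = 2.0 * float(t_dist.sf(abs(tt), n - 2))
    return r2, p, float(np.sign(slope))


def brute_force_call(times, od, x, config):
    """Exhaustive evaluation of every caller criterion; returns the direction."""
    times = np.asarray(times, float)
    od = np.asarray(od, float)
    x = np.asarray(x, float)

    pos = x[x > 0]
    if pos.size == 0 or np.ptp(x) == 0:
        return "unchanged"
    floor = float(pos.min()) * 0.5
    xf = np.where(x > 0, x, floor)

    fc_up = float(np.max(xf) / xf[0])
    fc_down = float(xf[0] / np.min(xf))

    r_od, p_r = pearson_r_p(xf, od)
    r2_lin, p_lin, s_lin = linfit_r2_p_sign(times, xf)
    r2_exp, p_exp, s_exp = linfit_r2_p_sign(times, np.log(xf))

    corr_pass = (
        not math.isnan(r_od)
        and abs(r_od) > config.r_od_threshold
        and p_r < config.p_threshold
    )
    lin_pass = (
        not math.isnan(r2_lin)
        and r2_lin > config.r2_fit_threshold
        and p_lin < config.p_threshold
    )
    exp_pass = (
        not math.isnan(r2_exp)
        and r2_exp > config.r2_fit_threshold
        and p_exp < config.p_threshold
    )

    if corr_pass:
        trend = math.copysign(1.0, r_od)
    elif lin_pass:
        trend = s_lin
    elif exp_pass:
        trend = s_exp
    else:
        return "unchanged"

    if trend > 0 and fc_up >= config.fc_secreted:
        return "secreted"
    if trend < 0 and fc_down >= config.fc_consumed:
        return "consumed"
    return "unchanged"


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration:
    sum of probabilities of all tables with the same margins whose
    probability does not exceed the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa: int) -> float:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        return (
            math.comb(r1, aa) * math.comb(r2, cc) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for aa in range(lo, hi + 1):
        p = prob(aa)
        if p <= p_obs * (1.0 + 1e-9):
            total += p
    return min(total, 1.0)


def random_intensity_series(rng, n):
    """A random short series mixing the caller's regimes: noisy flats,
    monotone trends, OD-coupled consumption/secretion, exhaustion, spikes."""
    kind = rng.integers(0, 6)
    base = rng.uniform(100.0, 5000.0)
    t = np.sort(rng.uniform(0.0, 24.0, size=n))
    while len(np.unique(t)) < n:
        t = np.sort(rng.uniform(0.0, 24.0, size=n))
    od = 0.05 + 1.5 / (1.0 + np.exp(-rng.uniform(0.5, 2.0) * (t - rng.uniform(3, 10))))
    od = od * rng.lognormal(0.0, 0.02, size=n)
    if kind == 0:  # flat plus noise
        x = base * rng.lognormal(0.0, rng.uniform(0.0, 0.1), size=n)
    elif kind == 1:  # constant
        x = np.full(n, base)
    elif kind == 2:  # OD-coupled consumption
        g = (od - od[0]) / (np.max(od) - od[0] + 1e-9)
        x = base * (1.0 - rng.uniform(0.2, 0.95) * g)
        x = x * rng.lognormal(0.0, rng.uniform(0.0, 0.08), size=n)
    elif kind == 3:  # OD-coupled secretion
        x = base + rng.uniform(0.1, 3.0) * base * (od - od[0])
        x = x * rng.lognormal(0.0, rng.uniform(0.0, 0.08), size=n)
    elif kind == 4:  # exponential decay to exhaustion, flat after
        x = base * np.exp(-rng.uniform(0.1, 1.0) * t)
        x[x < base * 0.01] = 0.0
    else:  # random walk
        x = base * np.exp(np.cumsum(rng.normal(0.0, 0.2, size=n)))
    return t, od, np.clip(x, 0.0, None)
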