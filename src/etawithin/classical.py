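"""t-tests and the d family of standardized mean differences.

Three d statistics are distinguished because they answer different
questions:

* Cohen's d (independent groups): mean difference over the average of
  the two group SDs, ``(Mx - My) / sqrt((SDx^2 + SDy^2) / 2)``.
* d_z (paired): mean difference over the SD of the difference scores —
  the effect relative to the variability that the repeated-measures
  design actually tests against.
* d_av (paired): mean difference over the average condition SD — the
  between-groups-comparable effect, used e.g. in meta-analysis across
  design types.

Confidence intervals for d use inversion of the noncentral-t pivot.
All SDs use the n-1 denominator and all p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TestResult",
    "DFamily",
    "t_independent",
    "t_paired",
    "cohens_d_independent",
    "d_paired",
    "noncentral_d_ci",
    "eta2_to_dav",
    "dav_to_eta2",
    "eta2p_to_dz",
    "dz_to_eta2p",
]


@dataclass(frozen=True)
class TestResult:
    """Mean-difference test: estimate (response units), t, df, two-sided
    p, and a confidence interval for the estimate."""

    estimate: float
    t: float
    df: float
    p: float
    ci: tuple[float, float]
    conf_level: float = 0.95


@dataclass(frozen=True)
class DFamily:
    """Standardized mean differences.  ``d`` is the independent-groups
    statistic; ``d_z`` and ``d_av`` exist only for paired data.  ``ci``
    belongs to the statistic named in ``ci_for``."""

    d: float | None = None
    d_z: float | None = None
    d_av: float | None = None
    ci: tuple[float, float] | None = None
    ci_for: str | None = None
    conf_level: float = 0.95


def _two_sided_p(t: float, df: float) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def _mean_sd(x) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float)
    return float(np.mean(x)), float(np.std(x, ddof=1)), len(x)


def t_independent(x, y, variant: str = "welch",
                  conf_level: float = 0.95) -> TestResult:
    """Two-sample t-test.

    ``variant='student'`` pools the variances (df = n1 + n2 - 2);
    ``variant='welch'`` (default) uses the Welch statistic with
    Welch-Satterthwaite degrees of freedom and is the safer choice when
    group variances may differ.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    mx, sx, nx = _mean_sd(x)
    my, sy, ny = _mean_sd(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 values")
    est = mx - my
    if sx == 0.0 and sy == 0.0:
        if est == 0.0:
            return TestResult(0.0, 0.0, nx + ny - 2, 1.0, (0.0, 0.0), conf_level)
        raise ZeroDivisionError("zero variance in both samples with unequal means")
    if variant == "student":
        df = nx + ny - 2
        sp2 = ((nx - 1) * sx**2 + (ny - 1) * sy**2) / df
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    else:
        vx, vy = sx**2 / nx, sy**2 / ny
        se = np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (nx - 1) + vy**2 / (ny - 1))
    t = est / se
    q = stats.t.ppf(0.5 + conf_level / 2, df)
    return TestResult(est, float(t), float(df), _two_sided_p(t, df),
                      (est - q * se, est + q * se), conf_level)


def t_paired(x, y, conf_level: float = 0.95) -> TestResult:
    """Paired t-test: one-sample t of the position-wise differences
    against zero, df = N - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    md, sd, n = _mean_sd(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    df = n - 1
    if sd == 0.0:
        p = 1.0 if md == 0.0 else 0.0
        t = 0.0 if md == 0.0 else np.inf * np.sign(md)
        return TestResult(md, float(t), df, p, (md, md), conf_level)
    se = sd / np.sqrt(n)
    t = md / se
    q = stats.t.ppf(0.5 + conf_level / 2, df)
    return TestResult(md, float(t), float(df), _two_sided_p(t, df),
                      (md - q * se, md + q * se), conf_level)


def noncentral_d_ci(t: float, df: float, scale: float,
                    conf_level: float = 0.95) -> tuple[float, float]:
    """CI for a d-type effect size by inverting the noncentral-t pivot.

    ``scale`` converts a noncentrality parameter to the d scale
    (sqrt(1/n1 + 1/n2) for independent groups, 1/sqrt(N) for paired).
    Bounds are located by bisection on the nct CDF.
    """
    alpha = 1.0 - conf_level

    def bound(target: float) -> float:
        # solve nct.cdf(t; df, ncp) = target for ncp
        f = lambda ncp: stats.nct.cdf(t, df, ncp) - target
        lo, hi = t - 2, t + 2
        while f(lo) < 0:
            lo -= 5
        while f(hi) > 0:
            hi += 5
        return optimize.brentq(f, lo, hi, xtol=1e-8)

    ncp_lo = bound(1 - alpha / 2)
    ncp_hi = bound(alpha / 2)
    return (ncp_lo * scale, ncp_hi * scale)


def cohens_d_independent(x, y, conf_level: float = 0.95) -> DFamily:
    """Cohen's d for two independent samples with a noncentral-t CI."""
    mx, sx, nx = _mean_sd(x)
    my, sy, ny = _mean_sd(y)
    sav = np.sqrt((sx**2 + sy**2) / 2.0)
    if sav == 0.0:
        raise ZeroDivisionError("both samples have zero variance; d undefined")
    d = (mx - my) / sav
    res = t_independent(x, y, variant="student")
    ci = noncentral_d_ci(res.t, res.df, np.sqrt(1 / nx + 1 / ny), conf_level)
    return DFamily(d=float(d), ci=ci, ci_for="d", conf_level=conf_level)


def d_paired(x, y, conf_level: float = 0.95) -> DFamily:
    """d_z and d_av for paired samples; the CI (noncentral t) is for d_z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diff = x - y
    md, sdiff, n = _mean_sd(diff)
    mx, sx, _ = _mean_sd(x)
    my, sy, _ = _mean_sd(y)
    sav = np.sqrt((sx**2 + sy**2) / 2.0)
    d_av = (mx - my) / sav if sav > 0 else (0.0 if md == 0 else None)
    if sdiff == 0.0:
        if md == 0.0:
            return DFamily(d_z=0.0, d_av=0.0 if d_av is None else d_av,
                           ci=(0.0, 0.0), ci_for="d_z", conf_level=conf_level)
        raise ZeroDivisionError("zero SD of differences; d_z undefined")
    d_z = md / sdiff
    t = d_z * np.sqrt(n)
    ci = noncentral_d_ci(t, n - 1, 1 / np.sqrt(n), conf_level)
    return DFamily(d_z=float(d_z), d_av=None if d_av is None else float(d_av),
                   ci=ci, ci_for="d_z", conf_level=conf_level)


# -- conversions between the eta-squared and d families ----------------
#
# eta squared plays the role of d_av (share of *total* variance), while
# partial eta squared plays the role of d_z (effect against its own
# error term only).  The factor 2 appears in the d_av pair because two
# condition distributions are compared, versus the single distribution
# of difference scores behind d_z.

def _check_unit_interval(v: float) -> None:
    if not (0.0 <= v < 1.0):
        raise ValueError(f"eta-squared value must be in [0, 1), got {v}")


def eta2_to_dav(eta2: float) -> float:
    """d_av ~= 2 * sqrt(eta^2 / (1 - eta^2))."""
    _check_unit_interval(eta2)
    return 2.0 * np.sqrt(eta2 / (1.0 - eta2))


def dav_to_eta2(d_av: float) -> float:
    """Inverse of :func:`eta2_to_dav`: eta^2 = (d/2)^2 / (1 + (d/2)^2)."""
    h = (d_av / 2.0) ** 2
    return h / (1.0 + h)


def eta2p_to_dz(eta2p: float) -> float:
    """d_z ~= sqrt(eta_p^2 / (1 - eta_p^2))."""
    _check_unit_interval(eta2p)
    return float(np.sqrt(eta2p / (1.0 - eta2p)))


def dz_to_eta2p(d_z: float) -> float:
    """Inverse of :func:`eta2p_to_dz`: eta_p^2 = d_z^2 / (1 + d_z^2)."""
    return d_z**2 / (1.0 + d_z**2)
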