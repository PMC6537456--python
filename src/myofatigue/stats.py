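"""Repeated-measures statistics: relative changes, one-way RM-ANOVA,
Fisher's LSD post hoc contrasts, and the within-factor power / sample-size
calculation.

The ANOVA partitions SS_total = SS_subjects + SS_time + SS_error for a
balanced subjects x time matrix and tests F = MS_time / MS_error on
(m-1, (n-1)(m-1)) degrees of freedom with no sphericity correction.  The
power computation uses the noncentral-F with the G*Power within-factor
convention lambda = f^2 * n * m / (1 - rho) * epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .errors import (IncompleteDesignError, InsufficientDataError,
                     InvalidControlError)


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    df1: float
    df2: float
    p: float
    ms_time: float
    ms_error: float
    n_subjects: int
    n_timepoints: int


@dataclass(frozen=True)
class LsdResult:
    """Fisher LSD contrasts of each time point against the reference.

    ``tested`` is False when the omnibus test did not reach the gate
    (contrast statistics are still reported for inspection); the reference
    column carries NaN.
    """

    t: np.ndarray
    p: np.ndarray
    df: float
    tested: bool
    reference_index: int


def relative_change(values, control_index: int = 0) -> np.ndarray:
    """Percent change of each entry relative to the control entry:
    100 * (v_t - v_0) / v_0."""
    v = np.asarray(values, dtype=float)
    v0 = v[..., control_index]
    if np.any(v0 == 0):
        raise InvalidControlError("control value is zero")
    return 100.0 * (v - v0[..., None]) / v0[..., None] if v.ndim > 1 \
        else 100.0 * (v - v0) / v0


def _check_matrix(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError(
            "need a 2-D matrix with >= 2 subjects and >= 2 time points")
    if not np.all(np.isfinite(x)):
        raise IncompleteDesignError("matrix has missing cells")
    return x


def rm_anova_oneway(matrix) -> RMAnovaResult:
    """One-way repeated-measures ANOVA (time as the within factor).

    Subjects x time matrix, balanced and complete.  A zero error mean
    square (degenerate exact fit) is reported as F = inf with p = 0.
    """
    x = _check_matrix(matrix)
    n, m = x.shape
    grand = x.mean()
    ss_subj = m * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_time = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((x - grand) ** 2) - ss_subj - ss_time
    ss_err = max(float(ss_err), 0.0)
    df1 = m - 1
    df2 = (n - 1) * (m - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    if ms_err == 0.0:
        f = 0.0 if ms_time == 0.0 else float("inf")
        p = 1.0 if ms_time == 0.0 else 0.0
    else:
        f = float(ms_time / ms_err)
        p = float(sst.f.sf(f, df1, df2))
    return RMAnovaResult(f, df1, df2, p, float(ms_time), float(ms_err), n, m)


def fisher_lsd(matrix, reference_index: int = 0, alpha: float = 0.05,
               anova: RMAnovaResult | None = None,
               require_omnibus: bool = True) -> LsdResult:
    """Fisher's LSD contrasts of each time point against the reference.

    t = (mean_t - mean_ref) / sqrt(2 * MS_error / n) on the ANOVA's error
    degrees of freedom, two-sided, with no multiplicity adjustment.  By
    definition the LSD is protected by the omnibus test: when the omnibus
    p >= alpha the result is flagged not-tested (``require_omnibus=False``
    bypasses the gate).
    """
    x = _check_matrix(matrix)
    n, m = x.shape
    if anova is None:
        anova = rm_anova_oneway(x)
    means = x.mean(axis=0)
    se = np.sqrt(2.0 * anova.ms_error / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (means - means[reference_index]) / se
    p = 2.0 * sst.t.sf(np.abs(t), anova.df2)
    if anova.ms_error == 0.0:
        delta = means - means[reference_index]
        t = np.where(delta == 0.0, 0.0,
                     np.where(delta > 0.0, np.inf, -np.inf))
        p = np.where(delta == 0.0, 1.0, 0.0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    t[reference_index] = np.nan
    p[reference_index] = np.nan
    tested = (not require_omnibus) or (anova.p < alpha)
    return LsdResult(t, p, float(anova.df2), tested, reference_index)


def rm_power(n: int, f: float, alpha: float = 0.05, m: int = 7,
             corr: float = 0.5, epsilon: float = 1.0) -> float:
    """Power of the within-factor RM-ANOVA test at sample size ``n``.

    lambda = f^2 * n * m / (1 - corr) * epsilon;
    df1 = (m - 1) * epsilon;  df2 = (n - 1) * (m - 1) * epsilon.
    """
    lam = f * f * n * m / (1.0 - corr) * epsilon
    df1 = (m - 1) * epsilon
    df2 = (n - 1) * (m - 1) * epsilon
    fcrit = sst.f.ppf(1.0 - alpha, df1, df2)
    return float(sst.ncf.sf(fcrit, df1, df2, lam))


def rm_power_sample_size(f: float, alpha: float = 0.05,
                         target_power: float = 0.95, m: int = 7,
                         corr: float = 0.5, epsilon: float = 1.0,
                         n_max: int = 10_000) -> int:
    """Smallest sample size reaching ``target_power`` for the within-factor
    repeated-measures F test (G*Power convention)."""
    if f <= 0:
        raise ValueError("effect size f must be positive")
    if not (0.0 < alpha < 1.0 and 0.0 < target_power < 1.0):
        raise ValueError("alpha and target power must be in (0, 1)")
    if m < 2:
        raise ValueError("need at least 2 repeated measures")
    if not 0.0 <= corr < 1.0:
        raise ValueError("correlation must be in [0, 1)")
    for n in range(2, n_max + 1):
        if rm_power(n, f, alpha, m, corr, epsilon) >= target_power:
            return n
    raise InsufficientDataError(
        f"no n <= {n_max} reaches power {target_power}")
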