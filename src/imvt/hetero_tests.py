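"""Two-sample mean- and variance-heterogeneity tests.

Each probe contributes two independent samples of (normalized, possibly
residualized) expression values, one per experimental condition.  A gene is
*mean differentially expressed* (MDE) when the condition-specific means
differ, and *mean-variance differentially expressed* (MVDE) when the means
and/or the variances differ.  This module provides the single-hypothesis
building blocks:

mean heterogeneity (H01: mu1 == mu2)
    ``student_t``  -- pooled-variance Student t, df n1 + n2 - 2
    ``welch_t``    -- Welch t with Welch-Satterthwaite degrees of freedom
    ``stsd_t``     -- Student t on data standardized by the
                      condition-specific sample standard deviations

variance heterogeneity (H02: sigma1^2 == sigma2^2)
    ``f_var_test``          -- classical variance-ratio F test
    ``levene_test``         -- Levene test (mean-centered absolute deviations)
    ``brown_forsythe_test`` -- Brown-Forsythe test (median-centered)

All tests return a :class:`TestResult` with a two-sided p-value.  The
functions accept a :class:`TwoGroupSample`; vectorized kernels operating on
stacked replicate matrices (one row per probe or Monte-Carlo replicate)
back both the scalar API and the simulation engine, so a single code path
is exercised everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

logger = logging.getLogger("imvt")

__all__ = [
    "TwoGroupSample",
    "TestResult",
    "DegenerateSampleError",
    "student_t",
    "welch_t",
    "stsd_t",
    "f_var_test",
    "levene_test",
    "brown_forsythe_test",
    "MEAN_TESTS",
    "VARIANCE_TESTS",
    "register_mean_test",
    "register_variance_test",
]


class DegenerateSampleError(ValueError):
    """Raised when a test statistic is undefined for the given sample."""


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} must contain at least 2 values (got {arr.size})")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TwoGroupSample:
    """Expression values of one probe split by condition.

    Parameters
    ----------
    group1, group2
        Per-condition expression vectors; each needs n >= 2 finite values
        so that sample variances exist.
    probe_id
        Optional identifier carried through to warnings and results.
    """

    group1: np.ndarray
    group2: np.ndarray
    probe_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "group1", _as_group(self.group1, "group1"))
        object.__setattr__(self, "group2", _as_group(self.group2, "group2"))

    @property
    def n1(self) -> int:
        return self.group1.size

    @property
    def n2(self) -> int:
        return self.group2.size

    def _label(self) -> str:
        return self.probe_id if self.probe_id is not None else "<unnamed probe>"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single test: statistic, reference df, two-sided p."""

    test_name: str
    statistic: float
    df: tuple[float, ...] = field(default_factory=tuple)
    p_value: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Vectorized kernels.  Each takes stacked samples g1 (R, n1) and g2 (R, n2)
# -- one row per probe or replicate -- and returns per-row statistics and
# p-values.  Degenerate rows yield NaN, which the scalar wrappers turn into
# explicit errors; the stat-0/p-1 conventions are applied where defined.
# ---------------------------------------------------------------------------


def _moments(g: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    n = g.shape[1]
    return n, g.mean(axis=1), g.var(axis=1, ddof=1)


def batch_student(g1: np.ndarray, g2: np.ndarray):
    """Pooled-variance Student t per row: (statistic, df, p)."""
    n1, m1, v1 = _moments(g1)
    n2, m2, v2 = _moments(g2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = m1 - m2
    scale = 1.0 / np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = scale * diff / np.sqrt(sp2)
    # zero pooled variance: identical constants -> 0; distinct -> undefined
    stat = np.where((sp2 == 0) & (diff == 0), 0.0, stat)
    stat = np.where((sp2 == 0) & (diff != 0), np.nan, stat)
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    return stat, float(df), p


def batch_welch(g1: np.ndarray, g2: np.ndarray):
    """Welch t per row: (statistic, nu, p) with Welch-Satterthwaite nu."""
    n1, m1, v1 = _moments(g1)
    n2, m2, v2 = _moments(g2)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / np.sqrt(se2)
        nu = se2**2 / (
            v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1))
        )
    zero = se2 == 0
    stat = np.where(zero & (diff == 0), 0.0, stat)
    stat = np.where(zero & (diff != 0), np.nan, stat)
    nu = np.where(zero, float(n1 + n2 - 2), nu)
    p = 2.0 * stats.t.sf(np.abs(stat), nu)
    return stat, nu, p


def batch_stsd(g1: np.ndarray, g2: np.ndarray):
    """Student t on groups divided by their own sample SD: (stat, df, p).

    Only a rescaling -- no centering -- so the mean signal survives while a
    pure change of scale becomes invisible.  Rows with a zero-variance group
    are NaN (the standardization is undefined there).
    """
    _, _, v1 = _moments(g1)
    _, _, v2 = _moments(g2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z1 = g1 / np.sqrt(v1)[:, None]
        z2 = g2 / np.sqrt(v2)[:, None]
    bad = (v1 == 0) | (v2 == 0)
    if np.any(bad):
        z1 = np.where(bad[:, None], 1.0, z1)  # placeholder rows, masked below
        z2 = np.where(bad[:, None], 1.0, z2)
    stat, df, p = batch_student(z1, z2)
    stat = np.where(bad, np.nan, stat)
    p = np.where(bad, np.nan, p)
    return stat, df, p


def batch_f(g1: np.ndarray, g2: np.ndarray):
    """Variance-ratio F per row: (statistic, (df1, df2), two-sided p)."""
    n1, _, v1 = _moments(g1)
    n2, _, v2 = _moments(g2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = v1 / v2
    stat = np.where(v2 == 0, np.nan, stat)
    cdf = stats.f.cdf(stat, n1 - 1, n2 - 1)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, 1.0 - cdf))
    return stat, (float(n1 - 1), float(n2 - 1)), p


def _batch_spread(g1: np.ndarray, g2: np.ndarray, center: str):
    """Levene-family F ratio on absolute deviations from a group center."""
    n1, n2 = g1.shape[1], g2.shape[1]
    n = n1 + n2
    if center == "mean":
        c1, c2 = g1.mean(axis=1), g2.mean(axis=1)
    else:
        c1, c2 = np.median(g1, axis=1), np.median(g2, axis=1)
    z1 = np.abs(g1 - c1[:, None])
    z2 = np.abs(g2 - c2[:, None])
    zb1, zb2 = z1.mean(axis=1), z2.mean(axis=1)
    zbar = (n1 * zb1 + n2 * zb2) / n
    num = (n - 2) * (n1 * (zb1 - zbar) ** 2 + n2 * (zb2 - zbar) ** 2)
    den = ((z1 - zb1[:, None]) ** 2).sum(axis=1) + ((z2 - zb2[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = num / den
    # constant |deviations| within groups: no dispersion to compare
    stat = np.where((den == 0) & (num == 0), 0.0, stat)
    p = stats.f.sf(stat, 1, n - 2)
    p = np.where((den == 0) & (num == 0), 1.0, p)
    p = np.where((den == 0) & (num > 0), 0.0, p)
    stat = np.where((den == 0) & (num > 0), np.inf, stat)
    return stat, (1.0, float(n - 2)), p


def batch_levene(g1: np.ndarray, g2: np.ndarray):
    return _batch_spread(g1, g2, "mean")


def batch_brown_forsythe(g1: np.ndarray, g2: np.ndarray):
    return _batch_spread(g1, g2, "median")


def batch_lrt(g1: np.ndarray, g2: np.ndarray):
    """Two-sample normal likelihood-ratio statistic -2 ln(Lambda): (stat, df, p).

    Lambda compares condition-specific normal fits against a single normal
    fit with common mean and variance; computed in log space to stay finite
    at large n.  Referred to chi^2 with 2 df (asymptotic).
    """
    n1, m1, v1 = _moments(g1)
    n2, m2, v2 = _moments(g2)
    n = n1 + n2
    v1m = (n1 - 1) / n1 * v1
    v2m = (n2 - 1) / n2 * v2
    mu = (n1 * m1 + n2 * m2) / n
    vpm = (((g1 - mu[:, None]) ** 2).sum(axis=1) + ((g2 - mu[:, None]) ** 2).sum(axis=1)) / n
    bad = (v1m <= 0) | (v2m <= 0) | (vpm <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lam = 0.5 * (n1 * np.log(v1m) + n2 * np.log(v2m) - n * np.log(vpm))
    stat = np.maximum(-2.0 * log_lam, 0.0)  # Lambda <= 1 up to round-off
    stat = np.where(bad, np.nan, stat)
    p = stats.chi2.sf(stat, 2)
    return stat, 2.0, p


# ---------------------------------------------------------------------------
# Scalar API
# ---------------------------------------------------------------------------


def _rows(sample: TwoGroupSample) -> tuple[np.ndarray, np.ndarray]:
    return sample.group1[None, :], sample.group2[None, :]


def _warn_degenerate(sample: TwoGroupSample, message: str) -> None:
    logger.warning("probe %s: %s", sample._label(), message)


def student_t(sample: TwoGroupSample) -> TestResult:
    """Pooled-variance Student t test of mean equality.

    The statistic is (1/n1 + 1/n2)^(-1/2) (mu1 - mu2) / sigma_p with
    sigma_p^2 the (n_c - 1)-weighted pooled sample variance, referred to a
    central t with n1 + n2 - 2 degrees of freedom.
    """
    g1, g2 = _rows(sample)
    stat, df, p = batch_student(g1, g2)
    if np.isnan(stat[0]):
        raise DegenerateSampleError(
            f"zero pooled variance with unequal means (probe {sample._label()})"
        )
    if stat[0] == 0.0 and p[0] == 1.0 and np.var(sample.group1) == 0 and np.var(sample.group2) == 0:
        _warn_degenerate(sample, "zero pooled variance with equal means; statistic set to 0")
    return TestResult("ST", float(stat[0]), (df,), float(p[0]))


def welch_t(sample: TwoGroupSample) -> TestResult:
    """Welch t test of mean equality under possibly unequal variances.

    Uses the Welch-Satterthwaite degrees of freedom nu, kept non-integer.
    """
    g1, g2 = _rows(sample)
    stat, nu, p = batch_welch(g1, g2)
    if np.isnan(stat[0]):
        raise DegenerateSampleError(
            f"both group variances zero with unequal means (probe {sample._label()})"
        )
    return TestResult("WT", float(stat[0]), (float(nu[0]),), float(p[0]))


def stsd_t(sample: TwoGroupSample) -> TestResult:
    """Student t on data standardized by condition-specific sample SDs."""
    g1, g2 = _rows(sample)
    stat, df, p = batch_stsd(g1, g2)
    if np.isnan(stat[0]):
        raise DegenerateSampleError(
            f"zero variance, STSD undefined (probe {sample._label()})"
        )
    return TestResult("STSD", float(stat[0]), (df,), float(p[0]))


def f_var_test(sample: TwoGroupSample) -> TestResult:
    """Classical two-sample variance-ratio F test of variance equality.

    Two-sided p = 2 min(P(F <= f), P(F >= f)) capped at 1: variance
    heterogeneity carries no preferred direction here.
    """
    g1, g2 = _rows(sample)
    stat, df, p = batch_f(g1, g2)
    if np.isnan(stat[0]):
        raise DegenerateSampleError(
            f"zero denominator variance (probe {sample._label()})"
        )
    return TestResult("F", float(stat[0]), df, float(p[0]))


def _spread_result(sample: TwoGroupSample, name: str, center: str) -> TestResult:
    g1, g2 = _rows(sample)
    stat, df, p = _batch_spread(g1, g2, center)
    if np.isinf(stat[0]):
        _warn_degenerate(
            sample,
            f"{name}: zero within-group deviation spread with unequal group "
            "levels; p set to 0",
        )
    elif p[0] == 1.0 and stat[0] == 0.0:
        pass  # includes the degenerate all-constant case; nothing to flag
    return TestResult(name, float(stat[0]), df, float(p[0]))


def levene_test(sample: TwoGroupSample) -> TestResult:
    """Levene test of variance equality (mean-centered absolute deviations).

    The one-way ANOVA F ratio on Z_jc = |G_jc - mean(G_c)|, referred to
    F(1, n1 + n2 - 2).
    """
    return _spread_result(sample, "LEVENE", "mean")


def brown_forsythe_test(sample: TwoGroupSample) -> TestResult:
    """Brown-Forsythe test: as Levene but deviations from the group median."""
    return _spread_result(sample, "BF", "median")


# Registries let callers select component tests by name and plug in
# alternatives (e.g. a moderated t) without touching the joint tests.
TestFunc = Callable[[TwoGroupSample], TestResult]

MEAN_TESTS: dict[str, TestFunc] = {"WT": welch_t, "ST": student_t, "STSD": stsd_t}
VARIANCE_TESTS: dict[str, TestFunc] = {
    "LEVENE": levene_test,
    "BF": brown_forsythe_test,
    "F": f_var_test,
}


def register_mean_test(name: str, func: TestFunc) -> None:
    """Register a custom mean-heterogeneity test under ``name``."""
    MEAN_TESTS[name.upper()] = func


def register_variance_test(name: str, func: TestFunc) -> None:
    """Register a custom variance-heterogeneity test under ``name``."""
    VARIANCE_TESTS[name.upper()] = func
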