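"""Tests of the dual null hypothesis of simultaneous mean and variance equality.

H03 = H01 ∩ H02 holds when a probe has both equal means and equal variances
across the two conditions.  Because mean-heterogeneity statistics (Student t,
Welch t) are independent of variance-heterogeneity statistics (F, Levene,
Brown-Forsythe) under H03 for spherically symmetric data, their p-values can
be combined by Fisher's method:

    IMVT  = -2 (ln p_WT + ln p_Levene)   ~  chi^2 with 4 df
    FWT   = -2 (ln p_WT + ln p_F)
    BFWT  = -2 (ln p_WT + ln p_BF)

Alternatives provided for comparison: the separate-tests framework SMVT
(reject H03 when either component rejects at split levels alpha1, alpha2
with overall level alpha = alpha1 + alpha2 - alpha1*alpha2) and the
two-sample normal likelihood-ratio test referred to chi^2 with 2 df.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hetero_tests import (
    MEAN_TESTS,
    VARIANCE_TESTS,
    TestResult,
    TwoGroupSample,
    batch_lrt,
)

logger = logging.getLogger("imvt")

__all__ = [
    "JointTestConfig",
    "SmvtConfig",
    "fisher_combine",
    "imvt",
    "fwt",
    "bfwt",
    "smvt",
    "smvt_p_value",
    "smvt_split_level",
    "lrt_test",
]

#: Smallest p-value fed to a logarithm; avoids -inf without ever moving a
#: decision at any realistic significance level.
DEFAULT_P_FLOOR = 1e-300

_COMBINED_NAME = {"LEVENE": "IMVT", "F": "FWT", "BF": "BFWT"}


@dataclass(frozen=True)
class JointTestConfig:
    """Pairing of component tests for a Fisher combination."""

    mean_test: str = "WT"
    variance_test: str = "LEVENE"
    p_floor: float = DEFAULT_P_FLOOR

    def __post_init__(self):
        if not 0.0 < self.p_floor <= 1e-300:
            raise ValueError("p_floor must be in (0, 1e-300]")
        if self.mean_test.upper() not in MEAN_TESTS:
            raise ValueError(f"unknown mean test {self.mean_test!r}")
        if self.variance_test.upper() not in VARIANCE_TESTS:
            raise ValueError(f"unknown variance test {self.variance_test!r}")

    @property
    def combined_name(self) -> str:
        return _COMBINED_NAME.get(self.variance_test.upper(), "FISHER")


@dataclass(frozen=True)
class SmvtConfig:
    """Split significance levels for the separate mean and variance tests.

    The overall level satisfies alpha = alpha1 + alpha2 - alpha1*alpha2,
    which is exact under the null independence of the two component tests.
    """

    alpha: float
    alpha1: float
    alpha2: float

    def __post_init__(self):
        for name in ("alpha", "alpha1", "alpha2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        implied = self.alpha1 + self.alpha2 - self.alpha1 * self.alpha2
        if abs(implied - self.alpha) > 1e-12:
            raise ValueError(
                f"alpha {self.alpha} != alpha1 + alpha2 - alpha1*alpha2 = {implied}"
            )

    @classmethod
    def equal_split(cls, alpha: float) -> "SmvtConfig":
        """Equal component levels alpha1 = alpha2 = 1 - sqrt(1 - alpha)."""
        a = smvt_split_level(alpha)
        return cls(alpha=alpha, alpha1=a, alpha2=a)


def smvt_split_level(alpha: float) -> float:
    """Per-component level 1 - sqrt(1 - alpha) of the equal-split SMVT."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - math.sqrt(1.0 - alpha)


def _check_p(p: float, what: str) -> float:
    if not (np.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValueError(f"invalid p-value for {what}: {p}")
    return float(p)


def fisher_combine(
    p_mean: float, p_var: float, cfg: JointTestConfig | None = None
) -> TestResult:
    """Fisher's combination of a mean and a variance p-value.

    statistic = -2 (ln p_mean + ln p_var), referred to chi^2 with 4 df.
    Component p-values below ``cfg.p_floor`` are clamped (and logged) so the
    logarithm stays finite.
    """
    cfg = cfg or JointTestConfig()
    p_mean = _check_p(p_mean, "mean test")
    p_var = _check_p(p_var, "variance test")
    floored = []
    if p_mean < cfg.p_floor:
        floored.append("mean")
        p_mean = cfg.p_floor
    if p_var < cfg.p_floor:
        floored.append("variance")
        p_var = cfg.p_floor
    if floored:
        logger.warning(
            "fisher_combine: %s p-value(s) clamped to floor %.3g",
            " and ".join(floored),
            cfg.p_floor,
        )
    stat = -2.0 * (math.log(p_mean) + math.log(p_var))
    return TestResult(cfg.combined_name, stat, (4.0,), float(stats.chi2.sf(stat, 4)))


def batch_fisher(p_mean: np.ndarray, p_var: np.ndarray, p_floor: float = DEFAULT_P_FLOOR):
    """Vectorized Fisher combination: (statistic, p) arrays."""
    pm = np.clip(np.asarray(p_mean, dtype=float), p_floor, 1.0)
    pv = np.clip(np.asarray(p_var, dtype=float), p_floor, 1.0)
    stat = -2.0 * (np.log(pm) + np.log(pv))
    return stat, stats.chi2.sf(stat, 4)


def imvt(sample: TwoGroupSample, cfg: JointTestConfig | None = None) -> TestResult:
    """Integrative mean-variance test: Fisher combination of the Welch t and
    Levene p-values (the recommended pairing), or of the pairing in ``cfg``.
    """
    cfg = cfg or JointTestConfig()
    p_m = MEAN_TESTS[cfg.mean_test.upper()](sample).p_value
    p_v = VARIANCE_TESTS[cfg.variance_test.upper()](sample).p_value
    return fisher_combine(p_m, p_v, cfg)


def fwt(sample: TwoGroupSample) -> TestResult:
    """Fisher combination of Welch t with the variance-ratio F test."""
    return imvt(sample, JointTestConfig(variance_test="F"))


def bfwt(sample: TwoGroupSample) -> TestResult:
    """Fisher combination of Welch t with the Brown-Forsythe test."""
    return imvt(sample, JointTestConfig(variance_test="BF"))


def smvt_p_value(p_mean, p_var):
    """Combined p-value of the equal-split separate-tests rule.

    p_SMVT = 1 - (1 - min(p_mean, p_var))^2.  With alpha1 = alpha2 =
    1 - sqrt(1 - alpha), "p_SMVT <= alpha" holds exactly when either
    component p-value falls at or below its split level, so the reported
    p-value reproduces the split decision rule.  This Sidak-style transform
    is a reporting convention: the framework itself is the decision rule.
    """
    pmin = np.minimum(p_mean, p_var)
    return 1.0 - (1.0 - pmin) ** 2


def smvt(sample: TwoGroupSample, cfg: SmvtConfig | None = None) -> TestResult:
    """Separate mean and variance tests of H03 (Welch t + Levene).

    Rejects when p_WT <= alpha1 or p_Levene <= alpha2.  The returned
    statistic is min(p_WT, p_Levene) and the p-value the equal-split
    combined p (see :func:`smvt_p_value`).
    """
    cfg = cfg or SmvtConfig.equal_split(0.05)
    p_m = MEAN_TESTS["WT"](sample).p_value
    p_v = VARIANCE_TESTS["LEVENE"](sample).p_value
    p = float(smvt_p_value(p_m, p_v))
    return TestResult("SMVT", float(min(p_m, p_v)), (), p)


def smvt_rejects(p_mean: float, p_var: float, cfg: SmvtConfig) -> bool:
    """The split decision rule itself: reject H03 if either component does."""
    return p_mean <= cfg.alpha1 or p_var <= cfg.alpha2


def lrt_test(sample: TwoGroupSample) -> TestResult:
    """Two-sample normal likelihood-ratio test of H03.

    -2 ln(Lambda) with Lambda the ratio of the maximized likelihood under a
    common N(mu, sigma^2) to that under condition-specific normals (MLE
    variances (n_c - 1)/n_c * s_c^2), referred to chi^2 with 2 df.  The
    chi^2 approximation is asymptotic and known to fail at small n.
    """
    stat, df, p = batch_lrt(sample.group1[None, :], sample.group2[None, :])
    if np.isnan(stat[0]):
        raise ValueError(f"degenerate LRT: zero variance (probe {sample._label()})")
    return TestResult("LRT", float(stat[0]), (df,), float(p[0]))
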