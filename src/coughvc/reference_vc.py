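"""LMS reference vital capacity and the lower limit of normal (LLN).

The median reference value is

    male:   VC = exp(-8.8317 + 2.1043 ln(h) - 0.1382 ln(a) + spline(a))
    female: VC = exp(-8.0707 + 1.9399 ln(h) - 0.1678 ln(a) + spline(a))

with height h in cm and age a in years. The age-specific spline contribution
(m - s) is external lookup data not bundled here; it defaults to zero and is
pluggable via :class:`LMSConfig`. The LLN is the LMS percentile at a
configurable z (default -1.645, the 5th percentile); the sigma (coefficient
of variation) and lambda (skewness) values are configuration with documented
defaults used only for synthetic demos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["SexCoefficients", "LMSConfig", "vc_lms", "lln", "spline_from_table"]

Sex = str  # "male" | "female"


@dataclass(frozen=True)
class SexCoefficients:
    intercept: float
    ln_height_coef: float
    ln_age_coef: float


def _zero_spline(age: float) -> float:
    return 0.0


def _default_sigma(sex: Sex, age: float) -> float:
    # Conservative placeholder coefficient of variation; NOT a published
    # lookup value. Used by the synthetic generator and demos only.
    return 0.12


def _default_lambda(sex: Sex, age: float) -> float:
    return 1.0


@dataclass(frozen=True)
class LMSConfig:
    male: SexCoefficients = field(
        default_factory=lambda: SexCoefficients(-8.8317, 2.1043, -0.1382)
    )
    female: SexCoefficients = field(
        default_factory=lambda: SexCoefficients(-8.0707, 1.9399, -0.1678)
    )
    #: age (years) -> dimensionless m - s spline contribution
    spline: Callable[[float], float] = _zero_spline
    #: standard-normal quantile defining the LLN (default 5th percentile)
    lln_z: float = -1.645
    #: (sex, age) -> coefficient of variation S_cv (> 0)
    sigma_fn: Callable[[Sex, float], float] = _default_sigma
    #: (sex, age) -> skewness L_skew; 1 reduces the percentile to M(1 + S z)
    lambda_fn: Callable[[Sex, float], float] = _default_lambda
    #: use M*exp(S*z) instead of the Box-Cox percentile
    lognormal_lln: bool = False

    def coefficients(self, sex: Sex) -> SexCoefficients:
        key = sex.strip().lower()
        if key in ("male", "m"):
            return self.male
        if key in ("female", "f"):
            return self.female
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")


DEFAULT_LMS_CONFIG = LMSConfig()


def _check_range(height: float, age: float) -> None:
    if not 100.0 < height < 230.0:
        raise ValueError(f"height {height} cm outside supported range (100, 230)")
    if age < 18.0:
        raise ValueError(f"age {age} below adult minimum 18")


def vc_lms(sex: Sex, height: float, age: float, cfg: LMSConfig = DEFAULT_LMS_CONFIG) -> float:
    """Reference (median) vital capacity in liters."""
    _check_range(height, age)
    c = cfg.coefficients(sex)
    return float(
        np.exp(
            c.intercept
            + c.ln_height_coef * np.log(height)
            + c.ln_age_coef * np.log(age)
            + cfg.spline(age)
        )
    )


def lln(sex: Sex, height: float, age: float, cfg: LMSConfig = DEFAULT_LMS_CONFIG) -> float:
    """Lower limit of normal: the LMS percentile at z = ``cfg.lln_z``.

    LLN = M * (1 + L*S*z)^(1/L); L -> 1 gives M * (1 + S*z), and the
    log-normal option gives M * exp(S*z).
    """
    m = vc_lms(sex, height, age, cfg)
    s_cv = cfg.sigma_fn(sex, age)
    if s_cv < 0:
        raise ValueError("sigma_fn must return a non-negative value")
    z = cfg.lln_z
    if cfg.lognormal_lln:
        return m * float(np.exp(s_cv * z))
    l_skew = cfg.lambda_fn(sex, age)
    if l_skew == 1.0:
        factor = 1.0 + s_cv * z
        if factor <= 0:
            raise ValueError("invalid LMS percentile: 1 + S*z <= 0")
        return m * factor
    base = 1.0 + l_skew * s_cv * z
    if base <= 0:
        raise ValueError("invalid LMS percentile: 1 + L*S*z <= 0")
    return m * float(base ** (1.0 / l_skew))


def spline_from_table(ages, values) -> Callable[[float], float]:
    """Linear-interpolation spline from an (age, m - s) table, e.g. a CSV of
    external lookup values; constant beyond the table's ends."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size != values.size or ages.size == 0:
        raise ValueError("ages and values must be equal-length and non-empty")
    order = np.argsort(ages)
    ages, values = ages[order], values[order]

    def spline(age: float) -> float:
        return float(np.interp(age, ages, values))

    return spline
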