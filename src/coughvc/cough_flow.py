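"""Cough peak flow computed from sound: CPS = (a1 + a2*age) * (exp(beta*SPL) - 1).

Also provides the algebraic inverse (needed by the waveform generator) and a
calibration fit of the three constants from (age, SPL, flow) triples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["CPSParams", "compute_cps", "invert_cps", "fit_cps_params", "CPSFit"]


@dataclass(frozen=True)
class CPSParams:
    """Constants of the flow-from-sound model.

    a1 in L/min, a2 in (L/min)/year, beta in 1/dB. ``a1 + a2*age`` must be
    positive over the supported age range.
    """

    a1: float
    a2: float
    beta: float
    age_min: float = 18.0
    age_max: float = 100.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def age_gain(self, age: float) -> float:
        g = self.a1 + self.a2 * np.asarray(age, dtype=float)
        if np.any(g <= 0):
            raise ValueError(
                "age outside calibrated range: a1 + a2*age must be positive"
            )
        return g


#: Documented default constants used by the synthetic generator and demos.
#: These are NOT calibrated study values; they merely put typical adult cough
#: peak flows (150-450 L/min) at plausible cough SPLs (90-110 dB).
DEFAULT_CPS_PARAMS = CPSParams(a1=3.0, a2=-0.01, beta=0.05)


def compute_cps(spl, age, params: CPSParams):
    """Cough peak flow (L/min) from SPL (dB) and age (years).

    Strictly increasing and convex in SPL; exactly 0 at SPL = 0.
    """
    spl = np.asarray(spl, dtype=float)
    if np.any(spl < 0):
        raise ValueError("spl must be >= 0")
    gain = params.age_gain(age)
    out = gain * np.expm1(params.beta * spl)
    return float(out) if out.ndim == 0 else out


def invert_cps(cpf, age, params: CPSParams):
    """SPL (dB) that produces the given flow: spl = ln(cpf/gain + 1) / beta."""
    cpf = np.asarray(cpf, dtype=float)
    gain = params.age_gain(age)
    ratio = cpf / gain
    if np.any(ratio <= -1):
        raise ValueError("cpf / (a1 + a2*age) <= -1: inverse undefined")
    out = np.log1p(ratio) / params.beta
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CPSFit:
    params: CPSParams
    rmse: float
    converged: bool
    message: str
    warnings: tuple[str, ...] = ()


def _init_guess(age: np.ndarray, spl: np.ndarray, cpf: np.ndarray) -> np.ndarray:
    # beta from a log-linear regression of ln(cpf + 1) on spl, the a-terms
    # from a subsequent linear solve; removes any seed dependence.
    A = np.column_stack([np.ones_like(spl), spl])
    coef, *_ = np.linalg.lstsq(A, np.log1p(cpf), rcond=None)
    beta0 = max(coef[1], 1e-4)
    gain = cpf / np.expm1(beta0 * np.maximum(spl, 1e-9))
    B = np.column_stack([np.ones_like(age), age])
    a, *_ = np.linalg.lstsq(B, gain, rcond=None)
    return np.array([a[0], a[1], beta0])


def fit_cps_params(
    age,
    spl,
    cpf,
    init: CPSParams | None = None,
    beta_bounds: tuple[float, float] = (1e-6, 1.0),
    loss: str = "linear",
) -> CPSFit:
    """Least-squares fit of (a1, a2, beta) to calibration triples.

    Requires >= 10 triples spanning >= 2 distinct ages and >= 3 distinct
    SPLs. A single-age design leaves a1 and a2 jointly unidentified (only
    a1 + a2*age is determined); this is reported as a warning, not an error.
    ``loss`` is passed to :func:`scipy.optimize.least_squares` ("soft_l1"
    etc. for robust fits).
    """
    age = np.asarray(age, dtype=float)
    spl = np.asarray(spl, dtype=float)
    cpf = np.asarray(cpf, dtype=float)
    if not (age.shape == spl.shape == cpf.shape):
        raise ValueError("age, spl, cpf must have identical shapes")
    if age.size < 10:
        raise ValueError("need at least 10 calibration triples")
    if np.unique(spl).size < 3:
        raise ValueError("need at least 3 distinct SPL values")
    warnings: list[str] = []
    if np.unique(age).size < 2:
        warnings.append(
            "single-age design: a1 and a2 are jointly unidentifiable; only "
            "a1 + a2*age is determined"
        )

    x0 = (
        np.array([init.a1, init.a2, init.beta])
        if init is not None
        else _init_guess(age, spl, cpf)
    )
    x0[2] = np.clip(x0[2], *beta_bounds)

    def residuals(x: np.ndarray) -> np.ndarray:
        a1, a2, beta = x
        return (a1 + a2 * age) * np.expm1(beta * spl) - cpf

    lb = [-np.inf, -np.inf, beta_bounds[0]]
    ub = [np.inf, np.inf, beta_bounds[1]]
    res = least_squares(
        residuals, x0, bounds=(lb, ub), loss=loss, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not res.success:
        raise RuntimeError(f"CPS calibration did not converge: {res.message}")
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    fitted = CPSParams(
        a1=float(res.x[0]),
        a2=float(res.x[1]),
        beta=float(res.x[2]),
        age_min=float(age.min()),
        age_max=float(age.max()),
    )
    return CPSFit(
        params=fitted,
        rmse=rmse,
        converged=bool(res.success),
        message=str(res.message),
        warnings=tuple(warnings),
    )
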