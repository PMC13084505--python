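"""Whole-isotherm goodness of fit: the fitscore.

Point-wise errors are measured on the square-root-uptake scale,
``(sqrt(Q_exp) - sqrt(Q_model))**2`` — a compromise between absolute error
(which over-weights the high-uptake region) and relative error (which blows
up where the measured uptake is near zero).  Errors are then integrated over
the *cube root* of the activity, ``d(x**(1/3))``, so that the result does
not depend on how densely an experimentalist happened to sample each
pressure region, and so that isotherms that rise at x ~ 1e-3 and at x ~ 0.4
are scored on a comparable axis.

With the integrated error Gamma and the integrated experimental uptake
Lambda (same trapezoid weights), the fitscore is ``Lambda / (Lambda +
Gamma)``: 1 for a perfect fit, 0 for an infinitely bad one.  A fitscore
>= 0.95 is good, >= 0.99 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "IsothermData",
    "cube_root_weights",
    "gamma_error",
    "lambda_norm",
    "fitscore",
    "fitscore_of",
]


@dataclass(frozen=True)
class IsothermData:
    """An adsorption isotherm: ordered ``(x, Q)`` observations.

    ``x`` is the activity abscissa (relative pressure, water activity,
    concentration — caller-defined); ``q`` the absolute uptake, e.g. in
    mmol/g.  On construction the table is validated (strictly increasing
    non-negative ``x``, non-negative ``q``) and a ``(0, 0)`` anchor is
    prepended if absent, so the integration always starts at the origin of
    the cube-root axis; ``anchored`` records whether that happened.
    """

    x: np.ndarray
    q: np.ndarray
    units: str = "mmol/g"
    name: str = ""
    anchored: bool = field(default=False, compare=False)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if x.ndim != 1 or q.ndim != 1 or x.size != q.size:
            raise ValidationError("x and q must be 1-d sequences of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(q))):
            raise ValidationError("isotherm data must be finite")
        if np.any(x < 0.0):
            raise ValidationError("activities x must be >= 0")
        if np.any(q < 0.0):
            raise ValidationError("uptakes Q must be >= 0")
        if np.any(np.diff(x) == 0.0):
            raise ValidationError("duplicate x values are not allowed")
        if np.any(np.diff(x) < 0.0):
            raise ValidationError("x must be strictly increasing (sort the table first)")
        anchored = self.anchored
        if x.size == 0 or x[0] > 0.0:
            x = np.concatenate(([0.0], x))
            q = np.concatenate(([0.0], q))
            anchored = True
        if x.size < 2:
            raise ValidationError("an isotherm needs at least 2 points")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "anchored", anchored)

    def __len__(self) -> int:
        return self.x.size

    @property
    def max_q(self) -> float:
        return float(np.max(self.q))


def cube_root_weights(x: Sequence[float]) -> np.ndarray:
    """Multitrapezoid weights on the cube-root-activity axis.

    With ``u_i = x_i**(1/3)``: the endpoints carry half their adjacent gap,
    interior points half the bracketing span, so the weights telescope to
    ``sum(w) = u_N - u_1`` exactly.
    """
    xa = np.asarray(x, dtype=float)
    if xa.ndim != 1 or xa.size < 2:
        raise ValidationError("weights need at least 2 abscissa values")
    if np.any(np.diff(xa) <= 0.0):
        raise ValidationError("abscissa must be strictly increasing")
    if np.any(xa < 0.0):
        raise ValidationError("abscissa must be >= 0")
    u = np.cbrt(xa)
    w = np.empty_like(u)
    w[0] = 0.5 * (u[1] - u[0])
    w[-1] = 0.5 * (u[-1] - u[-2])
    if u.size > 2:
        w[1:-1] = 0.5 * (u[2:] - u[:-2])
    return w


def gamma_error(data: IsothermData, q_model: Sequence[float]) -> float:
    """Integrated squared error Gamma on the sqrt-uptake / cube-root-x axes.

    ``Gamma = sum_i w_i (sqrt(Q_exp,i) - sqrt(Q_model,i))**2``; zero exactly
    when the model reproduces every data point.
    """
    qm = np.asarray(q_model, dtype=float)
    if qm.shape != data.q.shape:
        raise ValidationError(
            f"model uptakes have shape {qm.shape}, data has {data.q.shape}"
        )
    if not np.all(np.isfinite(qm)):
        raise DomainError("model uptakes must be finite")
    if np.any(qm < 0.0):
        raise DomainError("model uptakes must be >= 0")
    w = cube_root_weights(data.x)
    resid = np.sqrt(data.q) - np.sqrt(qm)
    return float(np.sum(w * resid**2))


def lambda_norm(data: IsothermData) -> float:
    """Normalizer Lambda: the experimental uptake integrated over x**(1/3)."""
    w = cube_root_weights(data.x)
    return float(np.sum(w * data.q))


def fitscore(gamma: float, lam: float) -> float:
    """``Lambda / (Lambda + Gamma)``, bounded in [0, 1]."""
    if gamma < 0.0 or lam < 0.0:
        raise DomainError("Gamma and Lambda must be >= 0")
    if gamma == 0.0 and lam == 0.0:
        raise ValidationError("fitscore undefined for the all-zero isotherm with zero error")
    return lam / (lam + gamma)


def fitscore_of(data: IsothermData, q_model: Sequence[float]) -> float:
    """Convenience: fitscore of a model prediction against a dataset."""
    return fitscore(gamma_error(data, q_model), lambda_norm(data))
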