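"""Multilayer adsorption isotherm models.

The core model describes adsorption on a *sitegroup* — a class of surface
regions sharing one parameter set — through a stepwise equilibrium picture:

* the first molecule binds a region with effective constant ``K1`` and a
  cooperativity exponent ``alpha`` (Freundlich/Sips-like heterogeneity or
  lateral interactions), contributing a factor ``(K1*x)**alpha``;
* each of the ``m`` subsequent layers binds with a common constant ``K2``,
  contributing factors of ``K2*x`` per layer;
* the last step is enhanced by a *condensation term* that diverges as
  ``K2*x`` grows, modelling capillary condensation (pore filling) as the
  activity approaches the condensation point ``K2*x -> 1``.

``x`` is a caller-defined activity: relative pressure ``P/P_sat`` for
subcritical gases, pressure itself for supercritical fluids, or
concentration / water activity for solutions.  The library never converts
pressures.

Summing the state populations and normalizing by the region balance yields a
closed form with five parameters per sitegroup (``alpha, K1, K2, m, N``).
Special cases recover the classical isotherm family: Langmuir (``m=0,
alpha=1``), Sips (``m=0``), BET (``m=inf, K2=1, alpha=1``), Anderson / GAB
(``m=inf, alpha=1, K2<1``).  Those classical forms, and the parameter
mappings between their equivalent printed variants, are implemented here as
well.

The total uptake of a model with several sitegroups is the sum of the
per-sitegroup uptakes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import DomainError, RangeOverflowError, ValidationError

__all__ = [
    "INFINITE_LAYERS",
    "Sitegroup",
    "MultilayerModel",
    "ClassicalModel",
    "condensation_term",
    "uptake_single",
    "uptake",
    "plateau",
    "low_coverage_asymptote",
    "classical_uptake",
    "anderson_from_capacity_fraction",
    "anderson_from_layer_constants",
    "gab_to_anderson",
    "zeta_from_2007",
]

#: Sentinel for an unlimited number of multilayers (BET/Anderson/GAB limit).
INFINITE_LAYERS = math.inf

# |1 - K2*x| below which the two indeterminate layer-sum ratios are evaluated
# by binomial series around K2*x = 1 instead of the closed forms, whose
# (1 - K2*x)**2 denominators lose ~half the mantissa near the singular point.
_SERIES_WINDOW = 1e-2

# Cap on exponents of (K2*x)**m and (K1*x)**alpha; beyond this double
# precision overflows and a range error is raised instead of returning inf.
_EXP_CAP = 690.0

ArrayLike = Union[float, Sequence[float], np.ndarray]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sitegroup:
    """One sitegroup of the multilayer model.

    Parameters
    ----------
    alpha : float
        Cooperativity exponent for the first adsorption step; must be
        strictly positive and finite.  ``alpha < 1`` models site-energy
        heterogeneity / lateral repulsion, ``alpha > 1`` positive
        cooperativity.
    K1 : float
        First-step equilibrium constant, units of ``1/x``.  ``K1 = 0`` is
        allowed and yields the null isotherm (Q identically zero).
    K2 : float
        Equilibrium constant shared by all subsequent steps, units ``1/x``.
        Condensation occurs as ``K2*x -> 1``.
    m : float
        Effective (capacity-averaged) number of layers beyond the first;
        continuous, ``m >= 0``; may be ``INFINITE_LAYERS`` for unlimited
        stacking (then the model is only defined for ``K2*x < 1``).
    N : float
        First-layer capacity in uptake units (e.g. mmol/g).
    """

    alpha: float
    K1: float
    K2: float
    m: float
    N: float

    def __post_init__(self) -> None:
        a, k1, k2, m, n = self.alpha, self.K1, self.K2, self.m, self.N
        if not (a > 0.0 and math.isfinite(a)):
            raise ValidationError(f"alpha must satisfy 0 < alpha < inf, got {a!r}")
        for name, v in (("K1", k1), ("K2", k2), ("N", n)):
            if not (v >= 0.0 and math.isfinite(v)):
                raise ValidationError(f"{name} must satisfy 0 <= {name} < inf, got {v!r}")
        if not (m >= 0.0):  # inf allowed
            raise ValidationError(f"m must satisfy 0 <= m <= inf, got {m!r}")

    @property
    def infinite_layers(self) -> bool:
        return math.isinf(self.m)


@dataclass(frozen=True)
class MultilayerModel:
    """A multilayer isotherm model: one or more sitegroups, uptakes additive."""

    sitegroups: tuple[Sitegroup, ...]

    def __post_init__(self) -> None:
        if len(self.sitegroups) < 1:
            raise ValidationError("a model needs at least one sitegroup")
        object.__setattr__(self, "sitegroups", tuple(self.sitegroups))

    @classmethod
    def single(cls, alpha: float, K1: float, K2: float, m: float, N: float) -> "MultilayerModel":
        return cls((Sitegroup(alpha, K1, K2, m, N),))

    def __call__(self, x: ArrayLike) -> np.ndarray:
        return uptake(self, x)


# ---------------------------------------------------------------------------
# numerically safe primitives
# ---------------------------------------------------------------------------


def _as_activity(x: ArrayLike) -> np.ndarray:
    xa = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(xa)):
        raise DomainError("activity x must be finite")
    if np.any(xa < 0.0):
        raise DomainError("activity x must be >= 0")
    return xa


def _safe_pow(base: np.ndarray, expo: float) -> np.ndarray:
    """``base**expo`` for ``base >= 0``, ``expo > 0`` finite, in log space.

    Underflow flushes to 0; an exponent that would overflow raises
    :class:`RangeOverflowError` instead of returning ``inf``.
    """
    out = np.zeros_like(base)
    pos = base > 0.0
    if np.any(pos):
        with np.errstate(divide="ignore", over="raise", under="ignore"):
            lg = expo * np.log(base[pos])
            if np.any(lg > _EXP_CAP):
                raise RangeOverflowError(
                    f"power base**{expo} overflows double precision "
                    f"(max exponent {float(np.max(lg)):.1f})"
                )
            out[pos] = np.exp(lg)
    return out


def condensation_term(z: ArrayLike) -> Union[float, np.ndarray]:
    """Condensation enhancement factor ``(1 + z + z^2 + z^3 + z^4)**1.5``.

    ``z = K2*x`` is the dimensionless subsequent-step loading variable.  The
    factor equals 1 at ``z = 0``, is strictly increasing, and diverges as
    ``z`` grows — this is what drives pore filling near ``K2*x ~ 1`` without
    requiring a saturation pressure (so the model extends to supercritical
    fluids and solutions).
    """
    za = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(za)):
        raise DomainError("condensation term argument must be finite")
    if np.any(za < 0.0):
        raise DomainError("condensation term argument must be >= 0")
    if np.any(za > 1e70):
        raise RangeOverflowError("condensation term argument too large for double precision")
    poly = 1.0 + za + za**2 + za**3 + za**4
    out = poly**1.5
    return out if out.ndim else float(out)


def _binom_ratio_series(m: float, eps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Series values of the two indeterminate layer-sum ratios near z = 1.

    With ``z = 1 + eps``:

    * ``R1 = (1 - z**(m+1)) / (1 - z) = sum_k C(m+1, k+1) eps**k``
    * ``R2 = (1 - (m+2) z**(m+1) + (m+1) z**(m+2)) / (1 - z)**2
          = sum_k [(m+1) C(m+2, k+2) - (m+2) C(m+1, k+2)] eps**k``

    using generalized binomial coefficients (valid for continuous m).  At
    ``eps = 0`` these reduce to the limit values ``m+1`` and
    ``(m+1)(m+2)/2``.  Terms are accumulated until machine convergence;
    within the series window ``|eps| <= 1e-2`` a few terms suffice.
    """
    r1 = np.zeros_like(eps)
    r2 = np.zeros_like(eps)
    # generalized binomials via the ratio recurrence C(v, k+1)/C(v, k) = (v-k)/(k+1)
    ck1 = m + 1.0                     # C(m+1, 1)  -> R1 term k=0 coefficient
    ck2_hi = (m + 2.0) * (m + 1.0) / 2.0   # C(m+2, 2) -> part of R2 k=0 coefficient
    ck2_lo = (m + 1.0) * m / 2.0           # C(m+1, 2)
    epow = np.ones_like(eps)
    for k in range(200):
        r1 += ck1 * epow
        coef2 = (m + 1.0) * ck2_hi - (m + 2.0) * ck2_lo
        r2 += coef2 * epow
        if k > 2 and float(np.max(np.abs(ck1 * epow))) < 1e-18 * max(float(np.max(np.abs(r1))), 1.0) \
                and float(np.max(np.abs(coef2 * epow))) < 1e-18 * max(float(np.max(np.abs(r2))), 1.0):
            break
        # advance: C(m+1, k+1) -> C(m+1, k+2); C(m+2, k+2) -> C(m+2, k+3); C(m+1, k+2) -> C(m+1, k+3)
        ck1 = ck1 * (m + 1.0 - (k + 1.0)) / (k + 2.0)
        ck2_hi = ck2_hi * (m + 2.0 - (k + 2.0)) / (k + 3.0)
        ck2_lo = ck2_lo * (m + 1.0 - (k + 2.0)) / (k + 3.0)
        epow = epow * eps
    return r1, r2


def _layer_sum_ratios(m: float, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two finite-geometric-sum ratios of the closed-form uptake.

    ``R1`` is the region-balance sum ``(1 - z**(m+1)) / (1 - z)`` and ``R2``
    the loading-weighted sum ``(1 - (m+2) z**(m+1) + (m+1) z**(m+2)) /
    (1 - z)**2``.  Both are indeterminate at ``z = 1`` with limits ``m+1``
    and ``(m+1)(m+2)/2``; near the singular point a binomial series around
    ``z = 1`` replaces the catastrophically cancelling closed forms.
    """
    r1 = np.empty_like(z)
    r2 = np.empty_like(z)
    near = np.abs(1.0 - z) < _SERIES_WINDOW
    far = ~near
    if np.any(far):
        zf = z[far]
        zm1 = _safe_pow(zf, m + 1.0)
        zm2 = _safe_pow(zf, m + 2.0)
        om = 1.0 - zf
        r1[far] = (1.0 - zm1) / om
        r2[far] = (1.0 - (m + 2.0) * zm1 + (m + 1.0) * zm2) / om**2
    if np.any(near):
        s1, s2 = _binom_ratio_series(m, z[near] - 1.0)
        r1[near] = s1
        r2[near] = s2
    return r1, r2


# ---------------------------------------------------------------------------
# multilayer model evaluation
# ---------------------------------------------------------------------------


def uptake_single(sg: Sitegroup, x: ArrayLike) -> Union[float, np.ndarray]:
    """Uptake of one sitegroup at activity ``x``.

    Handles every corner case analytically: ``Q = 0`` exactly at ``x = 0``
    (the ``0**0`` subterm for ``m = 0`` is multiplied by zero); ``m = 0``
    reduces to the Sips form; the ``K2*x = 1`` indeterminacies are replaced
    by their limits; the infinite-``m`` sentinel uses the analytic
    Anderson-type limit (valid only for ``K2*x < 1``).
    """
    xa = _as_activity(x)
    scalar = xa.ndim == 0
    xv = np.atleast_1d(xa)
    q = np.zeros_like(xv)

    if sg.infinite_layers:
        z = sg.K2 * xv
        if np.any(z >= 1.0):
            raise DomainError(
                "with unlimited layers (m = inf) the isotherm is only defined for K2*x < 1"
            )
        if sg.K1 > 0.0:
            t = _safe_pow(sg.K1 * xv, sg.alpha)
            om = 1.0 - z
            q = sg.N * t / (om * (om + t))
        q = np.where(xv == 0.0, 0.0, q)
        return float(q[0]) if scalar else q

    if sg.K1 == 0.0 or sg.N == 0.0:
        return float(q[0]) if scalar else q

    pos = xv > 0.0
    if np.any(pos):
        xp = xv[pos]
        t = _safe_pow(sg.K1 * xp, sg.alpha)
        if sg.m == 0.0:
            qp = sg.N * t / (1.0 + t)
        else:
            z = sg.K2 * xp
            r1, r2 = _layer_sum_ratios(sg.m, z)
            zm = _safe_pow(z, sg.m)
            ct_m1 = condensation_term(z) - 1.0
            with np.errstate(over="ignore", invalid="ignore"):
                num = r2 + sg.m * zm * ct_m1
                den = 1.0 + t * (r1 + (sg.m / (sg.m + 1.0)) * zm * ct_m1)
                qp = sg.N * t * num / den
            if not np.all(np.isfinite(qp)):
                raise RangeOverflowError("uptake evaluation overflowed double precision")
        q[pos] = qp
    return float(q[0]) if scalar else q


def uptake(model: MultilayerModel, x: ArrayLike) -> Union[float, np.ndarray]:
    """Total uptake: sum of :func:`uptake_single` over the model's sitegroups."""
    total = uptake_single(model.sitegroups[0], x)
    for sg in model.sitegroups[1:]:
        total = total + uptake_single(sg, x)
    return total


def plateau(sg: Sitegroup) -> float:
    """Saturation uptake ``(1 + m) N`` reached as ``K2*x -> inf`` (finite m > 0).

    ``m`` is thereby interpretable as the capacity-averaged number of layers
    beyond the first.  For ``m = 0`` the saturation value is ``N`` (Sips /
    Langmuir) and for unlimited layers the uptake is unbounded, so both are
    rejected here.
    """
    if not (0.0 < sg.m < math.inf):
        raise DomainError(
            f"plateau (1+m)N requires 0 < m < inf (got m={sg.m!r}); "
            "m=0 saturates at N, m=inf is unbounded"
        )
    return (1.0 + sg.m) * sg.N


def low_coverage_asymptote(sg: Sitegroup, x: ArrayLike) -> Union[float, np.ndarray]:
    """Leading-order uptake as ``x -> 0``: the Sips form ``N t / (1 + t)``.

    Here ``t = (K1*x)**alpha``.  Only ``N``, ``K1`` and ``alpha`` survive in
    the low-coverage limit; the full uptake divided by this asymptote tends
    to 1 as ``x -> 0+``.
    """
    xa = _as_activity(x)
    scalar = xa.ndim == 0
    xv = np.atleast_1d(xa)
    q = np.zeros_like(xv)
    if sg.K1 > 0.0:
        pos = xv > 0.0
        t = _safe_pow(sg.K1 * xv[pos], sg.alpha)
        q[pos] = sg.N * t / (1.0 + t)
    return float(q[0]) if scalar else q


# ---------------------------------------------------------------------------
# classical isotherm family
# ---------------------------------------------------------------------------

#: kind -> required parameter names
CLASSICAL_KINDS: Mapping[str, tuple[str, ...]] = {
    "henry": ("N", "K1"),
    "freundlich": ("N", "K1", "alpha"),
    "langmuir": ("N", "K1"),
    "sips": ("N", "K1", "alpha"),
    "bet": ("N", "K1"),
    "eta_bet": ("N", "K1", "eta"),
    "pickett": ("N", "K1", "eta"),
    "anderson": ("N", "K1", "K2"),
    "gab": ("Q_monolayer", "c_G", "k"),
    "zeta": ("N", "K1", "K2", "eta"),
    "two_site_langmuir": ("N1", "K1", "N2", "K2"),
}


@dataclass(frozen=True)
class ClassicalModel:
    """A tagged parameter set for one member of the classical isotherm family."""

    kind: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        object.__setattr__(self, "kind", kind)
        if kind not in CLASSICAL_KINDS:
            raise ValidationError(
                f"unknown classical kind {kind!r}; choose from {sorted(CLASSICAL_KINDS)}"
            )
        required = CLASSICAL_KINDS[kind]
        missing = [p for p in required if p not in self.params]
        if missing:
            raise ValidationError(f"{kind} requires parameters {missing}")
        object.__setattr__(self, "params", dict(self.params))
        for name, v in self.params.items():
            if not (math.isfinite(v) and v >= 0.0):
                raise ValidationError(f"{kind} parameter {name} must be finite and >= 0, got {v!r}")
        if "eta" in required and self.params["eta"] < 1.0:
            raise ValidationError(f"{kind} requires eta >= 1, got {self.params['eta']!r}")
        if kind in ("freundlich", "sips") and self.params["alpha"] <= 0.0:
            raise ValidationError(f"{kind} requires alpha > 0")

    def __call__(self, x: ArrayLike) -> Union[float, np.ndarray]:
        return classical_uptake(self, x)


def _require(cond: np.ndarray, message: str) -> None:
    if not np.all(cond):
        raise DomainError(message)


def classical_uptake(model: ClassicalModel, x: ArrayLike) -> Union[float, np.ndarray]:
    """Evaluate a classical isotherm exactly in its printed closed form.

    Domain checks name the offending denominator:  BET / eta-BET / Pickett
    need ``0 <= x < 1`` for the ``1/(1-x)`` factor; Anderson and the zeta
    isotherm need ``K2*x < 1``; GAB needs ``k*x < 1``.
    """
    xa = _as_activity(x)
    scalar = xa.ndim == 0
    xv = np.atleast_1d(xa)
    p = model.params
    kind = model.kind

    if kind == "henry":
        q = p["N"] * p["K1"] * xv
    elif kind == "freundlich":
        q = p["N"] * _safe_pow(p["K1"] * xv, p["alpha"])
    elif kind == "langmuir":
        kx = p["K1"] * xv
        q = p["N"] * kx / (1.0 + kx)
    elif kind == "sips":
        t = _safe_pow(p["K1"] * xv, p["alpha"])
        q = p["N"] * t / (1.0 + t)
    elif kind == "bet":
        _require(xv < 1.0, "BET denominator (1 - x) requires x < 1")
        den2 = 1.0 + (p["K1"] - 1.0) * xv
        _require(den2 > 0.0, "BET denominator (1 + (K1-1) x) must be positive")
        q = p["N"] * p["K1"] * xv / ((1.0 - xv) * den2)
    elif kind == "eta_bet":
        _require(xv < 1.0, "eta-BET denominator (1 - x) requires x < 1")
        eta = p["eta"]
        xe = _safe_pow(xv, eta)
        xe1 = xe * xv
        den2 = 1.0 + (p["K1"] - 1.0) * xv - p["K1"] * xe1
        _require(den2 > 0.0, "eta-BET denominator (1 + (K1-1)x - K1 x^(eta+1)) must be positive")
        q = p["N"] * p["K1"] * xv * (1.0 - (eta + 1.0) * xe + eta * xe1) / ((1.0 - xv) * den2)
    elif kind == "pickett":
        _require(xv < 1.0, "Pickett denominator (1 - x) requires x < 1")
        den2 = 1.0 + (p["K1"] - 1.0) * xv
        _require(den2 > 0.0, "Pickett denominator (1 + (K1-1) x) must be positive")
        q = p["N"] * p["K1"] * xv * (1.0 - _safe_pow(xv, p["eta"])) / ((1.0 - xv) * den2)
    elif kind == "anderson":
        z = p["K2"] * xv
        _require(z < 1.0, "Anderson denominator (1 - K2 x) requires K2*x < 1")
        den2 = 1.0 + (p["K1"] - p["K2"]) * xv
        _require(den2 > 0.0, "Anderson denominator (1 + (K1-K2) x) must be positive")
        q = p["N"] * p["K1"] * xv / ((1.0 - z) * den2)
    elif kind == "gab":
        z = p["k"] * xv
        _require(z < 1.0, "GAB denominator (1 - k a_w) requires k*a_w < 1")
        den2 = 1.0 + (p["c_G"] - 1.0) * z
        _require(den2 > 0.0, "GAB denominator (1 + (c_G - 1) k a_w) must be positive")
        q = p["Q_monolayer"] * p["c_G"] * z / ((1.0 - z) * den2)
    elif kind == "zeta":
        z = p["K2"] * xv
        _require(z < 1.0, "zeta-isotherm denominator (1 - K2 x) requires K2*x < 1")
        eta = p["eta"]
        ze = _safe_pow(z, eta)
        ze1 = ze * z
        geo = (1.0 - ze) / (1.0 - z)
        num = 1.0 - (eta + 1.0) * ze + eta * ze1
        q = p["N"] * p["K1"] * xv * num / ((1.0 - z) ** 2 * (1.0 + p["K1"] * xv * geo))
    elif kind == "two_site_langmuir":
        k1x = p["K1"] * xv
        k2x = p["K2"] * xv
        q = p["N1"] * k1x / (1.0 + k1x) + p["N2"] * k2x / (1.0 + k2x)
    else:  # pragma: no cover - guarded by ClassicalModel validation
        raise ValidationError(f"unknown classical kind {kind!r}")
    return float(q[0]) if scalar else q


# ---------------------------------------------------------------------------
# parameter mappings between equivalent printed forms
# ---------------------------------------------------------------------------


def anderson_from_capacity_fraction(c: float, f: float, V_monolayer: float) -> ClassicalModel:
    """Anderson model from the capacity-fraction parameterization.

    The variant in which each layer holds a fraction ``0 < f < 1`` of the
    previous layer's capacity, ``Q = V_m c x / ((1 - f x)(1 + (c-1) x))``,
    is the same isotherm as the ``(N, K1, K2)`` form under ``K2 = f``,
    ``K1 = c - 1 + f``, ``N = V_m c / (c - 1 + f)``.
    """
    if not (c > 0.0 and math.isfinite(c)):
        raise DomainError(f"c must be positive and finite, got {c!r}")
    if not (0.0 < f < 1.0):
        raise DomainError(f"capacity fraction f must lie in (0, 1), got {f!r}")
    if V_monolayer < 0.0:
        raise DomainError("V_monolayer must be >= 0")
    k1 = c - 1.0 + f
    if k1 <= 0.0:
        raise DomainError(f"mapping requires c - 1 + f > 0, got {k1!r}")
    return ClassicalModel("anderson", {"N": V_monolayer * c / k1, "K1": k1, "K2": f})


def anderson_from_layer_constants(V_m: float, c: float, k: float, j: float) -> ClassicalModel:
    """Anderson model from the ``(V_m, c, k, j)`` parameterization.

    ``Q = V_m c k x / ((1 - j k x)(1 + (c - j) k x))`` maps onto the
    ``(N, K1, K2)`` form via ``N = V_m``, ``K1 = c k``, ``K2 = j k``.
    """
    for name, v in (("V_m", V_m), ("c", c), ("k", k), ("j", j)):
        if not (v >= 0.0 and math.isfinite(v)):
            raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
    return ClassicalModel("anderson", {"N": V_m, "K1": c * k, "K2": j * k})


def gab_to_anderson(c_G: float, k: float, Q_monolayer: float) -> ClassicalModel:
    """Anderson model equivalent to a GAB water-sorption model.

    The GAB isotherm (moisture sorption on foods and other hygroscopic
    solids) equals the Anderson form under ``N = Q_monolayer``,
    ``K1 = c_G * k``, ``K2 = k``, on the domain ``k * a_w < 1``.
    """
    for name, v in (("c_G", c_G), ("k", k), ("Q_monolayer", Q_monolayer)):
        if not (v >= 0.0 and math.isfinite(v)):
            raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
    return ClassicalModel("anderson", {"N": Q_monolayer, "K1": c_G * k, "K2": k})


def zeta_from_2007(M: float, alpha_Z: float, c: float, zeta: float) -> ClassicalModel:
    """Zeta isotherm from its 2007 ``(M, alpha_Z, c, zeta)`` parameterization.

    The two printed representations are the same model under ``N = M``,
    ``K2 = alpha_Z``, ``K1 = c * alpha_Z``, ``eta = zeta``.
    """
    for name, v in (("M", M), ("alpha_Z", alpha_Z), ("c", c), ("zeta", zeta)):
        if not (v >= 0.0 and math.isfinite(v)):
            raise DomainError(f"{name} must be finite and >= 0, got {v!r}")
    return ClassicalModel(
        "zeta", {"N": M, "K2": alpha_Z, "K1": c * alpha_Z, "eta": zeta}
    )
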