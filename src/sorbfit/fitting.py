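"""Fitscore-maximizing isotherm fitting.

Maximizing the fitscore is equivalent to minimizing the integrated error
Gamma, which is a weighted sum of squares on the sqrt-uptake scale — a
standard bound-constrained nonlinear least-squares problem.  It is solved
with a trust-region reflective solver (:func:`scipy.optimize.least_squares`)
in log-parameter coordinates (the equilibrium constants span many decades),
from a seeded multi-start initialization; the best local optimum across all
starts is returned and then polished at tight tolerance.

Parameters may be fixed by mask (e.g. ``m = 0, alpha = 1`` turns the
multilayer model into a Langmuir fit) and bounds tightened; in
*surface-area mode* the subsequent-layer constant is confined to
``2/3 <= K2 <= 3/2`` (the condensation point should lie near the bulk
saturation activity) and the first-layer capacity to at most twice the
highest measured uptake, which stabilizes whole-isotherm surface areas.

The classical BET linear-regression analysis over a restricted pressure
window is provided for comparison with the whole-isotherm approach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DomainError, RangeOverflowError, ValidationError
from .fitscore import IsothermData, cube_root_weights, fitscore, lambda_norm
from .models import (
    CLASSICAL_KINDS,
    ClassicalModel,
    MultilayerModel,
    Sitegroup,
    classical_uptake,
    uptake,
)

__all__ = [
    "FitConstraints",
    "FitResult",
    "fit",
    "BetRegression",
    "bet_linear_regression",
    "bet_model_fitscore",
    "MULTILAYER_PARAMS",
]

MULTILAYER_PARAMS = ("alpha", "K1", "K2", "m", "N")

#: fitted m above which the plateau is considered unresolved by the data
LARGE_M_THRESHOLD = 1e3

# positive floors for the log-coordinate transform, per parameter name
_LOG_FLOORS = {
    "alpha": 1e-3,
    "K1": 1e-10,
    "K2": 1e-10,
    "m": 1e-10,
    "N": 1e-15,
    "N1": 1e-15,
    "N2": 1e-15,
    "Q_monolayer": 1e-15,
    "eta": 1.0,
    "c_G": 1e-10,
    "k": 1e-10,
}

_CAPACITY_PARAMS = {"N", "N1", "N2", "Q_monolayer"}


@dataclass(frozen=True)
class FitConstraints:
    """Bounds, fixed-parameter masks and the surface-area mode switch.

    ``lower`` / ``upper`` override the per-parameter default bounds by name
    (applied to every sitegroup).  ``fixed`` pins parameters at exact
    values: a mapping applies to every sitegroup, a sequence of mappings
    gives one mask per sitegroup (``m = math.inf`` is a legal fixed value
    selecting the unlimited-multilayer limit).  ``surface_area_mode``
    tightens ``K2`` to [2/3, 3/2] and caps ``N`` at twice the highest
    measured uptake.
    """

    lower: Mapping[str, float] = field(default_factory=dict)
    upper: Mapping[str, float] = field(default_factory=dict)
    fixed: Union[Mapping[str, float], Sequence[Mapping[str, float]], None] = None
    surface_area_mode: bool = False

    def fixed_for_group(self, g: int) -> dict[str, float]:
        if self.fixed is None:
            return {}
        if isinstance(self.fixed, Mapping):
            return dict(self.fixed)
        return dict(self.fixed[g]) if g < len(self.fixed) else {}


@dataclass(frozen=True)
class FitResult:
    """Outcome of a fitscore-maximizing fit."""

    model: Union[MultilayerModel, ClassicalModel]
    fitscore: float
    gamma: float
    lam: float
    n_starts: int
    converged: bool
    start_scores: tuple[float, ...]
    seed: Optional[int]
    large_m: bool = False
    surface_area_mode: bool = False
    notes: tuple[str, ...] = ()

    def predict(self, x) -> np.ndarray:
        if isinstance(self.model, ClassicalModel):
            return np.asarray(classical_uptake(self.model, x))
        return np.asarray(uptake(self.model, x))

    @property
    def params(self) -> dict[str, float]:
        """Flat parameter mapping; multi-sitegroup names are suffixed _g1, _g2, ..."""
        return flat_params(self.model)


def flat_params(model: Union[MultilayerModel, ClassicalModel]) -> dict[str, float]:
    """Flatten a model's parameters into a name -> value mapping."""
    if isinstance(model, ClassicalModel):
        return dict(model.params)
    groups = model.sitegroups
    if len(groups) == 1:
        g = groups[0]
        return {"alpha": g.alpha, "K1": g.K1, "K2": g.K2, "m": g.m, "N": g.N}
    out: dict[str, float] = {}
    for i, g in enumerate(groups, start=1):
        for name in MULTILAYER_PARAMS:
            out[f"{name}_g{i}"] = getattr(g, name)
    return out


# ---------------------------------------------------------------------------
# problem setup: bounds, masks, log coordinates
# ---------------------------------------------------------------------------


def _default_bounds(name: str, data: IsothermData, family: str, fixed: dict) -> tuple[float, float]:
    x_max = float(data.x[-1])
    max_q = data.max_q
    if name == "alpha":
        return (1e-2, 1e2)
    if name in _CAPACITY_PARAMS:
        return (0.0, 10.0 * max_q if max_q > 0 else 1.0)
    if name == "eta":
        return (1.0, 1e4)
    if name == "m":
        return (0.0, 1e6)
    if name in ("K1", "c_G"):
        return (0.0, 1e8)
    if name == "K2":
        if family == "multilayer":
            # keep the condensation point reachable but bounded; tightened
            # further in surface-area mode and for fixed m = inf
            if math.isinf(fixed.get("m", 0.0)):
                return (0.0, (1.0 - 1e-9) / x_max)
            return (0.0, 10.0)
        if family in ("anderson", "zeta"):
            return (0.0, (1.0 - 1e-9) / x_max)
        return (0.0, 1e8)  # two_site_langmuir second site
    if name == "k":
        return (0.0, (1.0 - 1e-9) / x_max)
    raise ValidationError(f"no default bounds for parameter {name!r}")


class _FitProblem:
    """Maps between model parameters and bounded log coordinates.

    Free parameters are optimized as ``theta = ln(p)`` with lower bounds
    floored at a small positive value (so Langmuir-like optima with
    ``K2 -> 0`` or ``m -> 0`` remain reachable to numerical precision
    without a true zero, which the mask mechanism provides exactly).
    """

    def __init__(
        self,
        data: IsothermData,
        family: str,
        n_sitegroups: int,
        constraints: FitConstraints,
    ) -> None:
        family = family.lower().replace("md", "multilayer")
        if family != "multilayer" and family not in CLASSICAL_KINDS:
            raise ValidationError(
                f"unknown model family {family!r}; use 'multilayer' or one of "
                f"{sorted(CLASSICAL_KINDS)}"
            )
        if family != "multilayer" and n_sitegroups != 1:
            raise ValidationError("sitegroups only apply to the multilayer family")
        if n_sitegroups < 1:
            raise ValidationError("need at least one sitegroup")
        if family in ("bet", "eta_bet", "pickett") and float(data.x[-1]) >= 1.0:
            raise ValidationError(
                f"{family} is only defined for x < 1 but the data reach x = {data.x[-1]}"
            )
        self.data = data
        self.family = family
        self.n_sitegroups = n_sitegroups
        self.constraints = constraints

        if family == "multilayer":
            names = MULTILAYER_PARAMS
            groups = range(n_sitegroups)
        else:
            names = CLASSICAL_KINDS[family]
            groups = range(1)

        self.free: list[tuple[int, str]] = []
        self.fixed: list[dict[str, float]] = []
        lo_list: list[float] = []
        hi_list: list[float] = []
        self.raw_lo: list[float] = []
        for g in groups:
            fx = constraints.fixed_for_group(g)
            self.fixed.append(fx)
            for name in names:
                if name in fx:
                    continue
                lo, hi = _default_bounds(name, data, family, fx)
                if constraints.surface_area_mode and family == "multilayer":
                    if name == "K2":
                        lo, hi = max(lo, 2.0 / 3.0), min(hi, 1.5)
                    elif name == "N":
                        hi = min(hi, 2.0 * data.max_q)
                lo = constraints.lower.get(name, lo)
                hi = constraints.upper.get(name, hi)
                if lo > hi:
                    raise ValidationError(
                        f"infeasible bounds for {name}: lower {lo} > upper {hi}"
                    )
                self.free.append((g, name))
                self.raw_lo.append(lo)
                lo_list.append(math.log(max(lo, _LOG_FLOORS[name])))
                hi_list.append(math.log(max(hi, _LOG_FLOORS[name] * (1 + 1e-9))))
        self.theta_lo = np.array(lo_list)
        self.theta_hi = np.array(hi_list)
        self.n_free = len(self.free)
        if self.n_free == 0:
            raise ValidationError("all parameters are fixed; nothing to fit")

        self._w_sqrt = np.sqrt(cube_root_weights(data.x))
        self._y_exp = np.sqrt(data.q)
        self.lam = lambda_norm(data)

    # -- coordinate transforms ------------------------------------------------

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.theta_lo, self.theta_hi)

    def theta_of(self, values: Sequence[float]) -> np.ndarray:
        """Log coordinates of raw free-parameter values (clipped into bounds)."""
        v = np.asarray(values, dtype=float)
        floors = np.exp(self.theta_lo)
        return self.clip(np.log(np.maximum(v, floors)))

    def model_of(self, theta: np.ndarray) -> Union[MultilayerModel, ClassicalModel]:
        vals = np.exp(theta)
        by_group: list[dict[str, float]] = [dict(fx) for fx in self.fixed]
        for (g, name), v in zip(self.free, vals):
            by_group[g][name] = float(v)
        if self.family == "multilayer":
            return MultilayerModel(tuple(Sitegroup(**p) for p in by_group))
        return ClassicalModel(self.family, by_group[0])

    def free_values(self, model: Union[MultilayerModel, ClassicalModel]) -> np.ndarray:
        if isinstance(model, ClassicalModel):
            params = [dict(model.params)]
        else:
            params = [
                {"alpha": g.alpha, "K1": g.K1, "K2": g.K2, "m": g.m, "N": g.N}
                for g in model.sitegroups
            ]
        return np.array([params[g][name] for g, name in self.free])

    # -- objective ------------------------------------------------------------

    def residuals(self, theta: np.ndarray, y_target: Optional[np.ndarray] = None) -> np.ndarray:
        y = self._y_exp if y_target is None else y_target
        try:
            model = self.model_of(theta)
            if isinstance(model, ClassicalModel):
                q = np.asarray(classical_uptake(model, self.data.x), dtype=float)
            else:
                q = np.asarray(uptake(model, self.data.x), dtype=float)
        except (DomainError, RangeOverflowError, ValidationError):
            return np.full_like(y, 1e6)
        if not np.all(np.isfinite(q)):
            return np.full_like(y, 1e6)
        return self._w_sqrt * (y - np.sqrt(np.maximum(q, 0.0)))

    def gamma_of(self, theta: np.ndarray, y_target: Optional[np.ndarray] = None) -> float:
        r = self.residuals(theta, y_target)
        return float(np.dot(r, r))

    def solve_from(
        self,
        theta0: np.ndarray,
        y_target: Optional[np.ndarray] = None,
        tol: float = 1e-10,
        max_nfev: Optional[int] = None,
    ) -> tuple[np.ndarray, float, bool]:
        """One bounded local solve; returns (theta, gamma, success)."""
        theta0 = self.clip(np.asarray(theta0, dtype=float))
        try:
            sol = optimize.least_squares(
                self.residuals,
                theta0,
                bounds=(self.theta_lo, self.theta_hi),
                method="trf",
                args=() if y_target is None else (y_target,),
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=max_nfev,
            )
        except Exception:
            return theta0, self.gamma_of(theta0, y_target), False
        gamma = 2.0 * float(sol.cost)
        return sol.x, gamma, bool(sol.success)


# ---------------------------------------------------------------------------
# multi-start initialization
# ---------------------------------------------------------------------------


def _draw_start(problem: _FitProblem, rng: np.random.Generator) -> np.ndarray:
    """One random start: equilibrium constants log-uniform over decades,
    exponents near 1, capacities uniform up to their bound."""
    data = problem.data
    x_max = float(data.x[-1])
    vals = np.empty(problem.n_free)
    k2_draws: dict[int, float] = {}
    for j, (g, name) in enumerate(problem.free):
        lo = math.exp(problem.theta_lo[j])
        hi = math.exp(problem.theta_hi[j])
        if name == "alpha":
            v = math.exp(rng.uniform(math.log(0.25), math.log(4.0)))
        elif name in ("K1", "c_G"):
            v = math.exp(rng.uniform(math.log(1e-2), math.log(1e6))) / x_max
        elif name in ("K2", "k"):
            v = rng.uniform(lo, hi)
            # stagger later sitegroups toward higher condensation activities
            if g > 0:
                v = lo + (v - lo) / (2.0**g)
            k2_draws[g] = v
        elif name == "m":
            v = math.exp(rng.uniform(math.log(0.05), math.log(50.0)))
        elif name == "eta":
            v = math.exp(rng.uniform(0.0, math.log(100.0)))
        elif name in _CAPACITY_PARAMS:
            v = rng.uniform(0.0, hi) / max(problem.n_sitegroups, 1)
        else:  # pragma: no cover
            v = math.sqrt(lo * hi)
        vals[j] = min(max(v, lo), hi)
    return problem.theta_of(vals)


def _sort_sitegroups(model: MultilayerModel) -> MultilayerModel:
    """Report sitegroups in K1-descending order (label switching is a pure
    reporting ambiguity for the additive model)."""
    groups = sorted(model.sitegroups, key=lambda g: -g.K1)
    return MultilayerModel(tuple(groups))


def fit(
    data: IsothermData,
    family: str = "multilayer",
    n_sitegroups: int = 1,
    constraints: Optional[FitConstraints] = None,
    n_starts: int = 32,
    seed: Optional[int] = 0,
    tol: float = 1e-12,
    start_values: Optional[Sequence[Mapping[str, float]]] = None,
) -> FitResult:
    """Fit an isotherm model to data by maximizing the fitscore.

    Parameters
    ----------
    data : IsothermData
        The isotherm to fit (anchored at (0, 0)).
    family : str
        ``"multilayer"`` (the five-parameter model; alias ``"md"``) or a
        classical kind (``"langmuir"``, ``"sips"``, ``"bet"``, ...).
    n_sitegroups : int
        Number of sitegroups (multilayer family only).
    constraints : FitConstraints, optional
        Bounds, fixed-parameter masks, surface-area mode.
    n_starts : int
        Random multi-starts; each runs a bounded trust-region local solve.
    seed : int, optional
        Seed for the start-generation RNG; same data + seed + options give
        an identical result.
    tol : float
        Convergence tolerance of the final polish.
    start_values : sequence of mappings, optional
        User-supplied starting parameter sets (one mapping per sitegroup per
        start is a mapping list); tried in addition to the random starts.

    Returns
    -------
    FitResult
        Best local optimum across all starts, with per-start fitscores.
    """
    constraints = constraints or FitConstraints()
    problem = _FitProblem(data, family, n_sitegroups, constraints)
    rng = np.random.default_rng(seed)

    thetas: list[np.ndarray] = []
    if start_values:
        for sv in start_values:
            groups = [sv] if isinstance(sv, Mapping) else list(sv)
            vals = []
            for g, name in problem.free:
                src = groups[g] if g < len(groups) else groups[-1]
                if name not in src:
                    raise ValidationError(f"start values missing {name} for sitegroup {g+1}")
                vals.append(float(src[name]))
            thetas.append(problem.theta_of(vals))
    for _ in range(n_starts):
        thetas.append(_draw_start(problem, rng))

    best_theta = None
    best_gamma = math.inf
    any_ok = False
    start_scores: list[float] = []
    for theta0 in thetas:
        theta, gamma, ok = problem.solve_from(theta0, tol=1e-8, max_nfev=200 * problem.n_free)
        any_ok = any_ok or ok
        start_scores.append(fitscore(gamma, problem.lam))
        if gamma < best_gamma:
            best_gamma, best_theta = gamma, theta
    if best_theta is None or not any_ok:
        raise ConvergenceError(
            f"all {len(thetas)} starts failed to converge "
            f"(best Gamma {best_gamma!r}); check data and constraints"
        )

    theta, gamma, ok = problem.solve_from(best_theta, tol=tol)
    if gamma > best_gamma:
        theta, gamma = best_theta, best_gamma
    model = problem.model_of(theta)
    large_m = False
    if isinstance(model, MultilayerModel):
        large_m = any(
            (not g.infinite_layers) and g.m > LARGE_M_THRESHOLD for g in model.sitegroups
        )
        if len(model.sitegroups) > 1:
            model = _sort_sitegroups(model)
    notes = ()
    if large_m:
        notes = (
            "fitted m is large; the plateau is unresolved by the data and the "
            "precise m value does not significantly affect the uptake",
        )
    return FitResult(
        model=model,
        fitscore=fitscore(gamma, problem.lam),
        gamma=gamma,
        lam=problem.lam,
        n_starts=len(thetas),
        converged=any_ok,
        start_scores=tuple(start_scores),
        seed=seed,
        large_m=large_m,
        surface_area_mode=constraints.surface_area_mode,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# classical BET linear regression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetRegression:
    """Result of the linearized BET analysis over a pressure window.

    ``valid`` is False when the intercept is non-positive — there is then no
    valid linear range and no BET surface area is defined (typical for
    Type III / weak-interaction isotherms such as water on hydrophobic
    materials).
    """

    N: float
    K1: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_range: tuple[float, float]
    valid: bool


def bet_linear_regression(
    data: IsothermData, x_range: tuple[float, float] = (0.05, 0.30)
) -> BetRegression:
    """Ordinary least squares of ``x / (Q (1 - x))`` against ``x``.

    The BET transform is linear with slope ``(K1 - 1)/(N K1)`` and intercept
    ``1/(N K1)``, so ``N = 1/(slope + intercept)`` and ``K1 = 1 +
    slope/intercept``.  At least 3 points with ``0 < x < 1`` and ``Q > 0``
    inside ``x_range`` are required.
    """
    lo, hi = x_range
    if not (lo < hi):
        raise ValidationError("x_range must be an increasing interval")
    mask = (data.x >= lo) & (data.x <= hi) & (data.x > 0) & (data.x < 1) & (data.q > 0)
    n = int(np.sum(mask))
    if n < 3:
        raise ValidationError(
            f"BET regression needs >= 3 usable points in [{lo}, {hi}], found {n}"
        )
    x = data.x[mask]
    v = x / (data.q[mask] * (1.0 - x))
    reg = stats.linregress(x, v)
    slope, intercept = float(reg.slope), float(reg.intercept)
    r2 = float(reg.rvalue) ** 2
    valid = intercept > 0.0 and (slope + intercept) > 0.0
    if valid:
        n_cap = 1.0 / (slope + intercept)
        k1 = 1.0 + slope / intercept
    else:
        n_cap, k1 = math.nan, math.nan
    return BetRegression(
        N=n_cap,
        K1=k1,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=n,
        x_range=(lo, hi),
        valid=valid,
    )


def bet_model_fitscore(data: IsothermData, reg: BetRegression) -> float:
    """Fitscore of the BET model (from a linear regression) over the whole
    data range; requires all activities below 1 and a valid regression."""
    if not reg.valid:
        raise DomainError("no valid BET linear range: intercept <= 0")
    if float(data.x[-1]) >= 1.0:
        raise DomainError("BET model undefined at x >= 1; cannot score the full range")
    model = ClassicalModel("bet", {"N": reg.N, "K1": reg.K1})
    q = np.asarray(classical_uptake(model, data.x), dtype=float)
    from .fitscore import fitscore_of

    return fitscore_of(data, q)
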