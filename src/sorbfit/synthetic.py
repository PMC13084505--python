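"""Synthetic isotherm generation with known ground truth.

Every downstream stage (scoring, fitting, bootstrapping, surface areas) is
testable against data whose generating parameters are known exactly.  The
default design mirrors the fitting machinery: 40 points uniform in
``x**(1/3)`` on (0, 1] — the same abscissa the fitscore integrates over —
plus the (0, 0) anchor.  The default noise model is multiplicative Gaussian
with a 1% relative magnitude, a generic stand-in for instrument scatter;
uptakes are clipped at zero.

``iupac_presets`` returns model parameter sets whose simulated shapes show
the qualitative signatures of the six IUPAC physisorption types (monolayer
saturation, unrestricted multilayer, weak-interaction convex, condensation
step with plateau, convex-then-condensation, and a stepwise two-sitegroup
layer-by-layer shape).  The numerical values are this package's own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import DomainError, ValidationError
from .fitscore import IsothermData
from .models import (
    INFINITE_LAYERS,
    ClassicalModel,
    MultilayerModel,
    Sitegroup,
    classical_uptake,
    uptake,
)

__all__ = ["NoiseModel", "simulate_isotherm", "iupac_presets", "activity_grid"]

_NOISE_KINDS = ("none", "multiplicative_gaussian", "additive_gaussian_on_sqrt")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic isotherms.

    ``multiplicative_gaussian`` scales each uptake by ``1 + magnitude * z``;
    ``additive_gaussian_on_sqrt`` adds ``magnitude * z`` on the sqrt-uptake
    scale (the scale the fitting residuals live on) and squares back.  In
    both cases ``z ~ N(0,1)`` and the result is clipped at zero.
    """

    kind: str = "multiplicative_gaussian"
    magnitude: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValidationError(f"noise kind must be one of {_NOISE_KINDS}")
        if self.magnitude < 0.0:
            raise ValidationError("noise magnitude must be >= 0")

    def apply(self, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.magnitude == 0.0:
            return q
        z = rng.standard_normal(q.shape)
        if self.kind == "multiplicative_gaussian":
            out = q * (1.0 + self.magnitude * z)
        else:
            out = np.maximum(np.sqrt(q) + self.magnitude * z, 0.0) ** 2
        return np.clip(out, 0.0, None)


NOISELESS = NoiseModel(kind="none", magnitude=0.0)


def activity_grid(n_points: int = 40, x_max: float = 1.0, spacing: str = "cbrt") -> np.ndarray:
    """Positive activity grid; ``cbrt`` spacing is uniform in ``x**(1/3)``."""
    if n_points < 2:
        raise ValidationError("need at least 2 grid points")
    if not (x_max > 0.0 and math.isfinite(x_max)):
        raise ValidationError("x_max must be positive and finite")
    frac = np.arange(1, n_points + 1) / n_points
    if spacing == "cbrt":
        return (frac**3) * x_max
    if spacing == "linear":
        return frac * x_max
    raise ValidationError("spacing must be 'cbrt' or 'linear'")


def simulate_isotherm(
    model: Union[MultilayerModel, ClassicalModel],
    n_points: int = 40,
    x_max: float = 1.0,
    spacing: str = "cbrt",
    noise: NoiseModel = NOISELESS,
    seed: Optional[int] = None,
    name: str = "synthetic",
    units: str = "mmol/g",
) -> IsothermData:
    """Evaluate ``model`` on a grid, add noise, and package as IsothermData.

    The (0, 0) anchor is exact (noise-free); noise applies only to the
    positive-activity points.  ``seed`` overrides ``noise.seed``.  The
    generating model and seed are recorded in the dataset's ``meta``.
    """
    x = activity_grid(n_points, x_max, spacing)
    if isinstance(model, ClassicalModel):
        q = np.asarray(classical_uptake(model, x), dtype=float)
        meta_model: dict = {"kind": model.kind, "params": dict(model.params)}
    else:
        q = np.asarray(uptake(model, x), dtype=float)
        meta_model = {
            "kind": "multilayer",
            "sitegroups": [
                {"alpha": g.alpha, "K1": g.K1, "K2": g.K2, "m": g.m, "N": g.N}
                for g in model.sitegroups
            ],
        }
    eff_seed = seed if seed is not None else noise.seed
    rng = np.random.default_rng(eff_seed)
    q = noise.apply(q, rng)
    return IsothermData(
        x=x,
        q=q,
        units=units,
        name=name,
        meta={
            "generator": meta_model,
            "noise": {"kind": noise.kind, "magnitude": noise.magnitude, "seed": eff_seed},
            "grid": {"n_points": n_points, "x_max": x_max, "spacing": spacing},
        },
    )


def iupac_presets() -> dict[str, MultilayerModel]:
    """Model parameter sets reproducing the six IUPAC physisorption shapes.

    type1  monolayer saturation (m = 0, strong first step)
    type2  unrestricted multilayer, no condensation step before x = 1
    type3  weak adsorbent-adsorbate interaction, convex throughout
    type4  strong first step + capillary condensation to a plateau
    type5  weak first step + capillary condensation (hydrophobic-like)
    type6  stepwise layer-by-layer: two sitegroups with well-separated
           condensation activities K2*x = 1
    """
    return {
        "type1": MultilayerModel.single(alpha=1.0, K1=300.0, K2=0.0, m=0.0, N=1.0),
        "type2": MultilayerModel.single(alpha=1.0, K1=150.0, K2=1.0, m=30.0, N=1.0),
        "type3": MultilayerModel.single(alpha=1.0, K1=0.4, K2=1.0, m=30.0, N=1.0),
        "type4": MultilayerModel.single(alpha=1.0, K1=200.0, K2=1.25, m=2.5, N=1.0),
        "type5": MultilayerModel.single(alpha=1.0, K1=0.3, K2=1.3, m=4.0, N=1.0),
        "type6": MultilayerModel(
            (
                Sitegroup(alpha=2.0, K1=10.0, K2=3.0, m=1.0, N=1.0),
                Sitegroup(alpha=4.0, K1=1.2, K2=1.15, m=1.0, N=1.0),
            )
        ),
    }
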