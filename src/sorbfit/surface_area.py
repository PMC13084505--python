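"""Whole-isotherm surface areas from fitted first-layer capacities.

Unlike the classical BET method, which linearizes a narrow pressure window,
the whole-isotherm approach takes the fitted first-layer capacity ``N_g``
(mmol/g) of every sitegroup and converts it to area with the adsorbate's
molecular cross-section ``sigma_g`` (nm^2):

    SA (m^2/g) = 602.214 * sum_g N_g * sigma_g

The prefactor is Avogadro's number times 1e-18 m^2/nm^2 times 1e-3
mol/mmol.  Conventional cross-sections are registered for the common
surface-area probes: N2 at 77 K (0.162 nm^2), Ar at 87 K (0.142 nm^2) and
water near room temperature (0.114 nm^2 by default; 0.106 nm^2 is also in
use, and literature values span roughly 0.079-0.165 nm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .errors import ValidationError
from .models import MultilayerModel

__all__ = [
    "AVOGADRO_PREFACTOR",
    "AdsorbateSpec",
    "CROSS_SECTIONS",
    "cross_section",
    "whole_isotherm_surface_area",
]

#: 6.02214e23 / mol * 1e-18 m^2/nm^2 * 1e-3 mol/mmol
AVOGADRO_PREFACTOR = 602.214


@dataclass(frozen=True)
class AdsorbateSpec:
    """An adsorbate and its effective molecular cross-sectional area."""

    name: str
    sigma: float  # nm^2 per molecule
    temperature_note: str = ""

    def __post_init__(self) -> None:
        if not (self.sigma > 0.0 and math.isfinite(self.sigma)):
            raise ValidationError(f"sigma must be positive and finite, got {self.sigma!r}")


CROSS_SECTIONS: dict[str, AdsorbateSpec] = {
    "N2": AdsorbateSpec("N2", 0.162, "at 77 K"),
    "Ar": AdsorbateSpec("Ar", 0.142, "at 87 K"),
    "H2O": AdsorbateSpec("H2O", 0.114, "near room temperature (0.106 also in use)"),
    "H2O_alt": AdsorbateSpec("H2O_alt", 0.106, "alternate water cross-section"),
}


def cross_section(adsorbate: str) -> float:
    """Registered cross-sectional area (nm^2) for a named adsorbate."""
    try:
        return CROSS_SECTIONS[adsorbate].sigma
    except KeyError:
        raise ValidationError(
            f"unknown adsorbate {adsorbate!r}; registered: {sorted(CROSS_SECTIONS)}; "
            "pass sigma explicitly for other species"
        ) from None


def whole_isotherm_surface_area(
    model: MultilayerModel,
    sigma: Union[float, Sequence[float], str],
    units: Optional[str] = None,
) -> float:
    """Surface area ``602.214 * sum_g N_g * sigma_g`` in m^2/g.

    Parameters
    ----------
    model : MultilayerModel
        Fitted model; each sitegroup's ``N`` must be in mmol/g.
    sigma : float, sequence of float, or adsorbate name
        Cross-section(s) in nm^2: a scalar applies to every sitegroup, a
        sequence gives one value per sitegroup, a string looks up the
        registry (e.g. ``"N2"``).
    units : str, optional
        If given, must be ``"mmol/g"``; guards against feeding capacities in
        other uptake units into the fixed prefactor.
    """
    if units is not None and units.replace(" ", "") != "mmol/g":
        raise ValidationError(
            f"whole-isotherm surface area requires N in mmol/g, got units {units!r}; "
            "convert the uptake column before fitting"
        )
    n_groups = len(model.sitegroups)
    if isinstance(sigma, str):
        sigmas = [cross_section(sigma)] * n_groups
    elif isinstance(sigma, (int, float)):
        sigmas = [float(sigma)] * n_groups
    else:
        sigmas = [float(s) for s in sigma]
        if len(sigmas) != n_groups:
            raise ValidationError(
                f"got {len(sigmas)} sigma values for {n_groups} sitegroups"
            )
    for s in sigmas:
        if not (s > 0.0 and math.isfinite(s)):
            raise ValidationError(f"sigma must be positive and finite, got {s!r}")
    return AVOGADRO_PREFACTOR * sum(
        sg.N * s for sg, s in zip(model.sitegroups, sigmas)
    )
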