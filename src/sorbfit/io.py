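"""Reading and writing isotherm tables, fit reports, and fit configs.

The CSV dialect is deliberately plain: comma-separated UTF-8 with a header
row, ``#`` comment lines, and two numeric columns.  The activity column may
be named ``x_A``, ``p_po``, ``a_w`` or ``x`` (relative pressure, water
activity and concentration data all flow through the same pipeline); the
uptake column ``Q_A``, ``Q`` or ``uptake``.  Reports are JSON and round-trip
the fitted model to full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .bootstrap import BootstrapResult
from .errors import ValidationError
from .fitscore import IsothermData
from .fitting import FitResult, flat_params
from .models import ClassicalModel, MultilayerModel, Sitegroup

__all__ = [
    "X_COLUMN_SYNONYMS",
    "Q_COLUMN_SYNONYMS",
    "FitConfig",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "write_report",
    "read_report",
    "model_from_report",
]

X_COLUMN_SYNONYMS = ("x_A", "x", "p_po", "p/p0", "a_w", "activity")
Q_COLUMN_SYNONYMS = ("Q_A", "Q", "q", "uptake")


class FitConfig(BaseModel):
    """Schema-validated fitting configuration (YAML or JSON file).

    Defaults match the library defaults: 5000 bootstrap replicates, 32
    multi-starts, surface-area mode off.  Unknown keys are rejected so a
    typo cannot silently change a run.
    """

    model_config = ConfigDict(extra="forbid")

    family: str = "multilayer"
    n_sitegroups: int = Field(default=1, ge=1)
    surface_area_mode: bool = False
    adsorbate: Optional[str] = None
    sigma: Optional[float] = Field(default=None, gt=0)
    n_bootstrap: int = Field(default=5000, ge=1)
    n_starts: int = Field(default=32, ge=1)
    seed: int = 0
    lower: dict[str, float] = Field(default_factory=dict)
    upper: dict[str, float] = Field(default_factory=dict)
    fixed: Union[dict[str, float], list[dict[str, float]], None] = None

    @field_validator("family")
    @classmethod
    def _norm_family(cls, v: str) -> str:
        return v.lower()

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FitConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must contain a mapping")
        return cls(**raw)


def _find_column(columns: list[str], synonyms: tuple[str, ...], label: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for syn in synonyms:
        if syn.lower() in lowered:
            return lowered[syn.lower()]
    raise ValidationError(
        f"no {label} column found; expected one of {synonyms}, got {columns}"
    )


def read_isotherm_csv(
    path: Union[str, Path],
    x_col: Optional[str] = None,
    q_col: Optional[str] = None,
    units: str = "mmol/g",
) -> IsothermData:
    """Read a two-column isotherm table.

    Rows are sorted by activity; duplicate activities, negative values and
    non-numeric cells are rejected with their row numbers.  A (0, 0) anchor
    is prepended when absent (recorded in ``.anchored``).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")
    cols = list(df.columns)
    xc = x_col or _find_column(cols, X_COLUMN_SYNONYMS, "activity")
    qc = q_col or _find_column(cols, Q_COLUMN_SYNONYMS, "uptake")
    x_raw = pd.to_numeric(df[xc], errors="coerce")
    q_raw = pd.to_numeric(df[qc], errors="coerce")
    bad = df.index[x_raw.isna() | q_raw.isna()].tolist()
    if bad:
        raise ValidationError(f"{path}: non-numeric cells in data rows {bad}")
    x = x_raw.to_numpy(dtype=float)
    q = q_raw.to_numpy(dtype=float)
    neg = np.nonzero((x < 0) | (q < 0))[0].tolist()
    if neg:
        raise ValidationError(f"{path}: negative values in data rows {neg}")
    order = np.argsort(x, kind="stable")
    x, q = x[order], q[order]
    dup = np.nonzero(np.diff(x) == 0.0)[0]
    if dup.size:
        rows = sorted({int(order[i]) for i in dup} | {int(order[i + 1]) for i in dup})
        raise ValidationError(f"{path}: duplicate activity values in data rows {rows}")
    return IsothermData(x=x, q=q, units=units, name=path.stem, meta={"source": str(path)})


def write_isotherm_csv(data: IsothermData, path: Union[str, Path]) -> None:
    """Write an isotherm table, with metadata as ``#`` header comments."""
    path = Path(path)
    lines = [f"# name: {data.name}", f"# units: {data.units}"]
    for key, val in data.meta.items():
        lines.append(f"# {key}: {json.dumps(val)}")
    lines.append("x_A,Q_A")
    for xi, qi in zip(data.x, data.q):
        lines.append(f"{float(xi)!r},{float(qi)!r}")
    path.write_text("\n".join(lines) + "\n")


def _model_payload(model: Union[MultilayerModel, ClassicalModel]) -> dict:
    if isinstance(model, ClassicalModel):
        return {"family": model.kind, "params": dict(model.params)}
    return {
        "family": "multilayer",
        "sitegroups": [
            {"alpha": g.alpha, "K1": g.K1, "K2": g.K2, "m": g.m, "N": g.N}
            for g in model.sitegroups
        ],
    }


def model_from_report(doc: dict) -> Union[MultilayerModel, ClassicalModel]:
    """Reconstruct the fitted model from a report document."""
    payload = doc["model"]
    if payload["family"] == "multilayer":
        return MultilayerModel(tuple(Sitegroup(**g) for g in payload["sitegroups"]))
    return ClassicalModel(payload["family"], payload["params"])


def _jsonable(value):
    if isinstance(value, float) and value == float("inf"):
        return "inf"
    return value


def write_report(
    result: FitResult,
    path: Union[str, Path],
    bootstrap: Optional[BootstrapResult] = None,
    surface_area: Optional[float] = None,
    adsorbate: Optional[str] = None,
) -> dict:
    """Write a machine-readable JSON fit report; returns the document.

    Infinite ``m`` (the unlimited-multilayer sentinel) is serialized as the
    string ``"inf"`` since JSON has no infinity literal.
    """
    doc: dict = {
        "tool": "sorbfit",
        "version": __version__,
        "model": _model_payload(result.model),
        "parameters": {k: _jsonable(v) for k, v in flat_params(result.model).items()},
        "fitscore": result.fitscore,
        "gamma": result.gamma,
        "lambda": result.lam,
        "n_starts": result.n_starts,
        "converged": result.converged,
        "seed": result.seed,
        "surface_area_mode": result.surface_area_mode,
        "large_m": result.large_m,
        "notes": list(result.notes),
    }
    if bootstrap is not None:
        doc["bootstrap"] = {
            "n_bootstrap": bootstrap.n_bootstrap,
            "n_failed": bootstrap.n_failed,
            "seed": bootstrap.seed,
            "ci": {k: list(v) for k, v in bootstrap.ci.items()},
            "sa_ci": list(bootstrap.sa_ci) if bootstrap.sa_ci is not None else None,
            "warnings": list(bootstrap.warnings),
        }
    if surface_area is not None:
        doc["surface_area"] = {"value_m2_per_g": surface_area, "adsorbate": adsorbate}
    # sitegroup m may be inf inside the model payload too
    if doc["model"]["family"] == "multilayer":
        for g in doc["model"]["sitegroups"]:
            g["m"] = _jsonable(g["m"])
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def read_report(path: Union[str, Path]) -> dict:
    """Read a JSON fit report, restoring the infinite-m sentinel."""
    doc = json.loads(Path(path).read_text())
    model = doc.get("model", {})
    for g in model.get("sitegroups", []):
        if g.get("m") == "inf":
            g["m"] = float("inf")
    params = doc.get("parameters", {})
    for k, v in params.items():
        if v == "inf":
            params[k] = float("inf")
    return doc
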