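"""Composition-dependent material properties of Co_x Fe_(3-x) O_4 ferrite.

Substituting Co2+ for Fe2+ in the octahedral sites of magnetite tunes the
magnetocrystalline anisotropy over more than an order of magnitude while the
spontaneous magnetization changes only mildly. The model here carries three
room-temperature properties as functions of the Co2+ atomic fraction ``x``:

* ``K(x)`` — anisotropy constant, J/m³: a shape-preserving monotone cubic
  (PCHIP) interpolant through the tabulated anchor values, exact at every
  anchor, with a single interior maximum at x = 0.67.
* ``Ms(x)`` — spontaneous magnetization, A/m: affine between the magnetite
  (480 kA/m) and cobalt-ferrite (425 kA/m) end members.
* ``rho(x)`` — mass density, kg/m³: affine between 5.24e3 and 5.29e3.

All quantities are strict SI internally; kA/m and "×10³" scalings appear only
at I/O boundaries. The anchor table ships as a CSV so experimentally measured
anchors can be substituted via :meth:`MaterialModel.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MaterialProperties",
    "MaterialModel",
    "anisotropy_constant",
    "spontaneous_magnetization",
    "density",
    "properties",
    "anchor_table",
]

# Affine coefficients fixed by the printed end-member values.
_MS_INTERCEPT = 480e3  # A/m at x = 0 (magnetite)
_MS_SLOPE = -55e3      # A/m per unit x; gives 425 kA/m at x = 1 (CoFe2O4)
_RHO_INTERCEPT = 5.24e3  # kg/m³ at x = 0
_RHO_SLOPE = 0.05e3      # kg/m³ per unit x


@dataclass(frozen=True)
class MaterialProperties:
    """Room-temperature properties of the ferrite at one composition."""

    K: float    # magnetocrystalline anisotropy constant, J/m³
    Ms: float   # spontaneous magnetization, A/m
    rho: float  # mass density, kg/m³


def _check_domain(x, lo: float, hi: float, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what}: composition x must be finite")
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(
            f"{what}: composition x={x} outside the valid range [{lo:g}, {hi:g}]"
        )
    return arr


class MaterialModel:
    """Property model built from an anchor table of (x, K, Ms, rho) rows.

    The anisotropy interpolant passes exactly through every anchor; Ms and
    rho use the affine laws above (they agree with the anchors to printed
    precision). The anchor set for K extends to x = 1.1; Ms and rho are
    defined on [0, 1] only.
    """

    def __init__(self, anchors: pd.DataFrame):
        required = {"x", "K_J_per_m3"}
        if not required.issubset(anchors.columns):
            raise ValueError(f"anchor table must have columns {sorted(required)}")
        anchors = anchors.sort_values("x").reset_index(drop=True)
        xs = anchors["x"].to_numpy(dtype=float)
        if len(xs) < 3 or np.any(np.diff(xs) <= 0):
            raise ValueError("anchor x values must be strictly increasing (>= 3 rows)")
        self.anchors = anchors
        self._x_min = float(xs[0])
        self._x_max = float(xs[-1])
        self._k_interp = PchipInterpolator(
            xs, anchors["K_J_per_m3"].to_numpy(dtype=float), extrapolate=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MaterialModel":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "MaterialModel":
        with resources.files("ferroheat.data").joinpath("material_anchors.csv").open() as fh:
            return cls(pd.read_csv(fh))

    def anisotropy_constant(self, x):
        """K(x) in J/m³ on [x_min, x_max] (default [0, 1.1])."""
        arr = _check_domain(x, self._x_min, self._x_max, "anisotropy_constant")
        out = self._k_interp(arr)
        return float(out) if np.isscalar(x) or arr.ndim == 0 else out

    def spontaneous_magnetization(self, x):
        """Ms(x) in A/m, affine on [0, 1]."""
        arr = _check_domain(x, 0.0, 1.0, "spontaneous_magnetization")
        out = _MS_INTERCEPT + _MS_SLOPE * arr
        return float(out) if arr.ndim == 0 else out

    def density(self, x):
        """rho(x) in kg/m³, affine on [0, 1]."""
        arr = _check_domain(x, 0.0, 1.0, "density")
        out = _RHO_INTERCEPT + _RHO_SLOPE * arr
        return float(out) if arr.ndim == 0 else out

    def properties(self, x: float) -> MaterialProperties:
        """Bundle (K, Ms, rho) at a single composition."""
        return MaterialProperties(
            K=self.anisotropy_constant(x),
            Ms=self.spontaneous_magnetization(x),
            rho=self.density(x),
        )


_DEFAULT_MODEL: MaterialModel | None = None


def _default_model() -> MaterialModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = MaterialModel.default()
    return _DEFAULT_MODEL


def anchor_table() -> pd.DataFrame:
    """The packaged anchor table (copy)."""
    return _default_model().anchors.copy()


def anisotropy_constant(x):
    return _default_model().anisotropy_constant(x)


def spontaneous_magnetization(x):
    return _default_model().spontaneous_magnetization(x)


def density(x):
    return _default_model().density(x)


def properties(x: float) -> MaterialProperties:
    return _default_model().properties(x)
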