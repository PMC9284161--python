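"""Humidity-dependent tissue elasticity and the drying path.

The seed scale of *Pinus wallichiana* bends because two tissue layers respond
differently to relative humidity (rh): the abaxial sclereid layer swells and
shrinks strongly along the scale axis (the *active* layer), while the adaxial
sclerenchyma fiber strands act as a stiff *passive* layer whose Young's
modulus drops by roughly a factor of four on wetting.  This module provides

* :class:`MaterialCurve` -- a piecewise-linear Young's modulus vs. rh curve,
  clamped to its endpoint values outside the measured range,
* :class:`TissueMaterial` -- a curve plus the elastic idealization flags
  (Poisson's ratio, optional plane-strain stiffening),
* :class:`DryingPath` -- the scalar drying coordinate ``xi`` in [0, 1]
  (0 = fully wet, 1 = fully dry) along which the active-layer contraction
  and the passive-layer modulus are assumed to vary linearly and in lockstep,

together with the measured preset curves shipped as a CSV resource.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "MaterialCurve",
    "TissueMaterial",
    "DryingPath",
    "young_modulus",
    "sclereid_regression",
    "active_strain",
    "xi_from_rh",
    "preset_curve",
    "available_presets",
    "load_material_curves",
]

#: Maximal longitudinal contraction of the sclereid layer, fully wet -> fully
#: dry (22 % shortening seen in the micro-CT comparison of the bending zone).
EPS_MAX_DEFAULT = 0.22

#: Passive-layer (sclerenchyma) modulus endpoints of the drying path, MPa.
E_PASSIVE_WET_DEFAULT = 70.0
E_PASSIVE_DRY_DEFAULT = 1170.0


@dataclass(frozen=True)
class MaterialCurve:
    """Piecewise-linear Young's modulus as a function of relative humidity.

    Parameters
    ----------
    tissue_name : str
        Label of the tissue the curve describes.
    knots : sequence of (rh, E) pairs
        Measured (rh [%], modulus [MPa]) support points, strictly increasing
        in rh, all moduli positive.
    clamp : bool
        Evaluation outside the knot range returns the nearest endpoint value.
        Clamping is the only supported extrapolation (it cannot produce
        negative moduli); the flag is kept for introspection.
    """

    tissue_name: str
    knots: tuple[tuple[float, float], ...]
    clamp: bool = True

    def __post_init__(self) -> None:
        if len(self.knots) == 0:
            raise ConfigurationError(
                f"material curve {self.tissue_name!r}: empty knot list"
            )
        knots = tuple((float(r), float(e)) for r, e in self.knots)
        object.__setattr__(self, "knots", knots)
        rh = np.array([k[0] for k in knots])
        e = np.array([k[1] for k in knots])
        if not np.all(np.isfinite(rh)) or not np.all(np.isfinite(e)):
            raise ConfigurationError(
                f"material curve {self.tissue_name!r}: non-finite knot"
            )
        if np.any(np.diff(rh) <= 0):
            raise ConfigurationError(
                f"material curve {self.tissue_name!r}: rh knots must be "
                "strictly increasing"
            )
        if np.any(e <= 0):
            raise ConfigurationError(
                f"material curve {self.tissue_name!r}: all moduli must be > 0"
            )

    @property
    def rh_knots(self) -> np.ndarray:
        return np.array([k[0] for k in self.knots])

    @property
    def modulus_knots(self) -> np.ndarray:
        return np.array([k[1] for k in self.knots])

    def __call__(self, rh):
        """Modulus [MPa] at relative humidity ``rh`` [%], clamped outside."""
        rh = np.asarray(rh, dtype=float)
        if not np.all(np.isfinite(rh)):
            raise DomainError("rh must be finite")
        # np.interp clamps to endpoint values outside the support
        out = np.interp(rh, self.rh_knots, self.modulus_knots)
        return float(out) if out.ndim == 0 else out

    def rh_at_modulus(self, modulus):
        """Inverse evaluation: rh [%] at which the curve takes ``modulus``.

        Requires the curve to be monotone in E; the result is clamped to the
        knot range.  Used to label drying-path states with an rh equivalent.
        """
        e = self.modulus_knots
        r = self.rh_knots
        d = np.diff(e)
        if np.all(d > 0):
            order = slice(None)
        elif np.all(d < 0):
            order = slice(None, None, -1)
        else:
            raise DomainError(
                f"curve {self.tissue_name!r} is not monotone; rh_at_modulus "
                "is undefined"
            )
        out = np.interp(np.asarray(modulus, dtype=float), e[order], r[order])
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TissueMaterial:
    """A tissue's elasticity curve plus its elastic idealization.

    The default mechanics are uniaxial (beam theory), in which case the
    Poisson ratio is carried but unused.  With ``plane_strain=True`` the
    effective modulus is stiffened to ``E / (1 - nu**2)``, mimicking the
    lateral constraint a wide plate-like section would add.
    """

    curve: MaterialCurve
    poisson_ratio: float = 0.3
    plane_strain: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ConfigurationError(
                f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}"
            )

    def modulus(self, rh):
        e = self.curve(rh)
        if self.plane_strain:
            e = e / (1.0 - self.poisson_ratio**2)
        return e


def young_modulus(material: TissueMaterial | MaterialCurve, rh) -> float:
    """Young's modulus [MPa] of ``material`` at relative humidity ``rh`` [%].

    Piecewise-linear interpolation between the measured knots, clamped to the
    endpoint values outside the measured range.
    """
    if isinstance(material, MaterialCurve):
        return material(rh)
    return material.modulus(rh)


@dataclass(frozen=True)
class DryingPath:
    """Linear coupling of active contraction and passive stiffening.

    The drying coordinate ``xi`` runs from 0 (fully wet, the 0-degree
    reference shape) to 1 (fully dry).  Along the path the active-layer
    longitudinal strain is ``-eps_max * xi`` and the passive-layer modulus is
    interpolated linearly between its fully wet and fully dry values --
    shrinkage and stiffening are assumed to progress together while drying.
    """

    eps_max: float = EPS_MAX_DEFAULT
    e_passive_wet: float = E_PASSIVE_WET_DEFAULT
    e_passive_dry: float = E_PASSIVE_DRY_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps_max <= 1.0):
            raise ConfigurationError(f"eps_max must be in [0, 1], got {self.eps_max}")
        if self.e_passive_wet <= 0 or self.e_passive_dry <= 0:
            raise ConfigurationError("passive-modulus endpoints must be > 0")

    def active_strain(self, xi):
        """Signed longitudinal strain of the active layer at ``xi`` (<= 0)."""
        xi = np.asarray(xi, dtype=float)
        if np.any((xi < 0) | (xi > 1)):
            raise DomainError(f"xi must be in [0, 1], got {xi}")
        out = -self.eps_max * xi
        return float(out) if out.ndim == 0 else out

    def passive_modulus(self, xi):
        """Passive-layer modulus [MPa] at ``xi``, linear between endpoints."""
        xi = np.asarray(xi, dtype=float)
        if np.any((xi < 0) | (xi > 1)):
            raise DomainError(f"xi must be in [0, 1], got {xi}")
        out = self.e_passive_wet + (self.e_passive_dry - self.e_passive_wet) * xi
        return float(out) if out.ndim == 0 else out

    def xi_from_modulus(self, e_passive):
        """Drying coordinate at which the passive modulus equals ``e_passive``.

        Clipped to [0, 1]; degenerate paths (equal endpoints) are rejected.
        """
        span = self.e_passive_dry - self.e_passive_wet
        if span <= 0:
            raise ConfigurationError(
                "degenerate drying path: e_passive_dry must exceed e_passive_wet"
            )
        xi = (np.asarray(e_passive, dtype=float) - self.e_passive_wet) / span
        out = np.clip(xi, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def with_dry_modulus(self, e_passive_dry: float) -> "DryingPath":
        return DryingPath(self.eps_max, self.e_passive_wet, float(e_passive_dry))


def active_strain(path: DryingPath, xi) -> float:
    """Active-layer longitudinal strain at drying coordinate ``xi``."""
    return path.active_strain(xi)


def xi_from_rh(path: DryingPath, e_curve: MaterialCurve | TissueMaterial, rh) -> float:
    """Map a relative humidity to the drying coordinate.

    The passive-modulus curve pins the humidity to a modulus; the drying
    path pins that modulus to a coordinate:
    ``xi = (E(rh) - E_wet) / (E_dry - E_wet)``, clipped to [0, 1].
    """
    return path.xi_from_modulus(young_modulus(e_curve, rh))


# ---------------------------------------------------------------------------
# Preset curves
# ---------------------------------------------------------------------------

def _preset_table() -> pd.DataFrame:
    with resources.as_file(
        resources.files("conescale.data") / "material_presets.csv"
    ) as p:
        return pd.read_csv(p, comment="#")


def load_material_curves(path: str | Path | None = None) -> dict[str, MaterialCurve]:
    """Load material curves from a CSV with columns tissue,rh_percent,E_MPa.

    With ``path=None`` the packaged preset table is loaded.
    """
    df = _preset_table() if path is None else pd.read_csv(path, comment="#")
    required = {"tissue", "rh_percent", "E_MPa"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"material CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    curves: dict[str, MaterialCurve] = {}
    for name, grp in df.groupby("tissue", sort=False):
        grp = grp.sort_values("rh_percent")
        curves[str(name)] = MaterialCurve(
            str(name), tuple(zip(grp["rh_percent"], grp["E_MPa"]))
        )
    return curves


@functools.lru_cache(maxsize=1)
def _presets() -> Mapping[str, MaterialCurve]:
    return load_material_curves(None)


def available_presets() -> tuple[str, ...]:
    return tuple(_presets().keys())


def preset_curve(name: str) -> MaterialCurve:
    """Return a packaged preset curve by name.

    Presets
    -------
    ``sclerenchyma_sim``
        Passive-layer modulus used in the bending simulations:
        800 MPa at 30 % rh down to 180 MPa at 80 % rh.
    ``sclerenchyma_afm``
        Microindentation values: 800 MPa at 30 % rh, 200 MPa at 75 % rh.
    ``sclereid_regression``
        Linear regression of the sclereid (active layer) modulus:
        37 MPa at the dry end (30 % rh), 21 MPa at the wet end (80 % rh).
    ``sclereid_afm``
        Step-like measured course: 35 MPa up to 50 % rh, 25 MPa from 60 % rh.
    ``brown_tissue``
        52 MPa, constant from 30 to 70 % rh, dipping to 43 MPa at 80 % rh.
    """
    try:
        return _presets()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown material preset {name!r}; available: {available_presets()}"
        ) from None


def sclereid_regression(rh) -> float:
    """Active-layer (sclereid) modulus [MPa] from the linear regression.

    37 MPa at the dry end (30 % rh) falling to 21 MPa at the wet end
    (80 % rh), clamped outside that range.
    """
    return preset_curve("sclereid_regression")(rh)
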