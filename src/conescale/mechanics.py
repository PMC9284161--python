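"""Eigenstrain bending of the layered, tapered bending zone.

Each cross-section is a stack of rectangular layers with individual Young's
moduli and prescribed stress-free (eigen)strains -- here the hygroscopic
longitudinal contraction of the active sclereid layer.  Plane sections
remain plane, the axial strain field is ``eps(z) = eps0 + kappa * z``, and
with no external load the stress resultants of the relieved state vanish:

    [ sum E*A     sum E*S ] [eps0]   [ sum E*A*eps_star ]
    [ sum E*S     sum E*I ] [kappa] = [ sum E*S*eps_star ]

with per-layer exact rectangle integrals A = w*t, S = A*zc,
I = A*zc**2 + w*t**3/12.  The classic bimetallic-strip curvature formula is
provided as an independent closed-form oracle for the uniform two-layer case.

Because pure eigenstrain bending carries no external load, the curvature is
a local state function of each section; large rotations enter only through
the finite-rotation integration of ``kappa(s)`` into the deformed
centerline (theta by composite trapezoid, then x,y by integrating
(cos theta, sin theta)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import ConfigurationError, DomainError, GeometryError
from .geometry import ScaleModel, validate_geometry

__all__ = [
    "Layer",
    "SectionState",
    "SectionResponse",
    "TissueState",
    "BendResult",
    "section_response",
    "timoshenko_curvature",
    "bilayer_section",
    "bend_scale",
    "angular_change",
]


@dataclass(frozen=True)
class Layer:
    """One rectangular layer of a cross-section.

    ``z_center`` is measured from the reference axis (by convention the
    active/passive interface), positive toward the adaxial (passive) side.
    Fields may be scalars or broadcastable arrays (one entry per station).
    """

    thickness: float | np.ndarray  # mm
    width: float | np.ndarray  # mm
    modulus: float | np.ndarray  # MPa
    eigenstrain: float | np.ndarray = 0.0  # dimensionless, signed
    z_center: float | np.ndarray = 0.0  # mm


@dataclass(frozen=True)
class SectionState:
    """A full cross-section: a contiguous stack of layers."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise GeometryError("section needs at least one layer")


@dataclass(frozen=True)
class SectionResponse:
    """Free membrane strain and curvature of an unloaded section."""

    eps0: float | np.ndarray  # strain at the reference axis
    kappa: float | np.ndarray  # curvature, 1/mm


def _check_layers(layers: Sequence[Layer]) -> None:
    for i, lay in enumerate(layers):
        t = np.asarray(lay.thickness, float)
        e = np.asarray(lay.modulus, float)
        if np.any(t <= 0):
            raise GeometryError(f"layer {i}: thickness must be > 0")
        if np.any(e <= 0):
            raise GeometryError(f"layer {i}: modulus must be > 0")


def _check_contiguous(layers: Sequence[Layer], rtol: float = 1e-9) -> None:
    """Scalar-only check that layers tile the thickness without gaps."""
    try:
        info = sorted(
            (float(l.z_center), float(l.thickness)) for l in layers
        )
    except TypeError:
        return  # array-valued stations: contiguity is enforced by construction
    scale = max(t for _, t in info)
    for (zc_lo, t_lo), (zc_hi, t_hi) in zip(info, info[1:]):
        gap = (zc_hi - t_hi / 2) - (zc_lo + t_lo / 2)
        if abs(gap) > rtol * scale:
            raise GeometryError(
                f"layers not contiguous: gap/overlap of {gap:g} mm between "
                "adjacent layers"
            )


def section_response(state: SectionState) -> SectionResponse:
    """Membrane strain and curvature of one unloaded multilayer section.

    Solves the 2x2 section-equilibrium system; the solution is unique as long
    as the section has positive area.  Vectorizes over stations when layer
    fields are arrays.
    """
    layers = state.layers
    _check_layers(layers)
    _check_contiguous(layers)
    EA = ES = EI = N = M = 0.0
    for lay in layers:
        t = np.asarray(lay.thickness, float)
        w = np.asarray(lay.width, float)
        e = np.asarray(lay.modulus, float)
        zc = np.asarray(lay.z_center, float)
        eps = np.asarray(lay.eigenstrain, float)
        a = w * t
        EA = EA + e * a
        ES = ES + e * a * zc
        EI = EI + e * (a * zc**2 + w * t**3 / 12.0)
        N = N + e * a * eps
        M = M + e * a * zc * eps
    det = EA * EI - ES**2
    if np.any(np.asarray(det) <= 0) or np.any(np.asarray(EA) <= 0):
        raise GeometryError("singular section stiffness (zero area?)")
    eps0 = (EI * N - ES * M) / det
    kappa = (EA * M - ES * N) / det
    if np.ndim(eps0) == 0:
        return SectionResponse(float(eps0), float(kappa))
    return SectionResponse(eps0, kappa)


def timoshenko_curvature(t1, t2, e1, e2, delta_eps):
    """Closed-form curvature [1/mm] of a uniform two-layer strip.

    Layer 1 lies above layer 2; ``delta_eps`` is the stress-free strain of
    layer 1 minus that of layer 2 (for the drying scale: 0 minus the active
    contraction, i.e. positive).  With ``m = t1/t2``, ``n = E1/E2`` and
    ``h = t1 + t2``::

        kappa = 6 * delta_eps * (1+m)**2
                / ( h * ( 3*(1+m)**2 + (1+m*n) * (m**2 + 1/(m*n)) ) )

    The sign of the curvature equals the sign of ``delta_eps``.
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise DomainError("layer thicknesses must be > 0")
    if np.any(e1 <= 0) or np.any(e2 <= 0):
        raise DomainError("layer moduli must be > 0")
    m = t1 / t2
    n = e1 / e2
    h = t1 + t2
    out = (
        6.0 * np.asarray(delta_eps, float) * (1.0 + m) ** 2
        / (h * (3.0 * (1.0 + m) ** 2 + (1.0 + m * n) * (m**2 + 1.0 / (m * n))))
    )
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class TissueState:
    """Material state of the bilayer at one point of the drying history."""

    e_active: float  # MPa, sclereid layer
    e_passive: float  # MPa, sclerenchyma layer
    eps_active: float  # signed longitudinal eigenstrain (contraction < 0)
    eps_passive: float = 0.0

    def __post_init__(self) -> None:
        if self.e_active <= 0 or self.e_passive <= 0:
            raise DomainError("tissue moduli must be > 0")


def bilayer_section(t_active, t_passive, width, state: TissueState) -> SectionState:
    """Assemble the standard bilayer section (active below, passive above).

    The reference axis sits at the layer interface; z is positive toward the
    passive (adaxial) side.
    """
    t_a = np.asarray(t_active, float)
    t_p = np.asarray(t_passive, float)
    return SectionState(
        layers=(
            Layer(t_a, width, state.e_active, state.eps_active, -t_a / 2.0),
            Layer(t_p, width, state.e_passive, state.eps_passive, +t_p / 2.0),
        )
    )


@dataclass(frozen=True)
class BendResult:
    """Deformed shape of the scale for one tissue state.

    ``gamma_deg`` is the angular change of the distal end of the bending
    zone relative to the (straight) wet reference, in degrees.  The
    centerline has one row per station plus the lever tip.
    """

    stations: np.ndarray  # mm
    kappa_field: np.ndarray  # 1/mm
    theta_field: np.ndarray  # rad
    centerline: np.ndarray  # (n_stations + 1, 2) mm, incl. lever tip
    gamma_deg: float

    @property
    def tip(self) -> np.ndarray:
        return self.centerline[-1]


def bend_scale(model: ScaleModel, state: TissueState) -> BendResult:
    """Curvature field, rotation and deformed centerline for one state.

    kappa(s) comes from :func:`section_response` at every station;
    theta(s) = integral of kappa by composite trapezoid; the centerline
    follows by integrating (cos theta, sin theta) and the rigid lever is
    appended at the final rotation.
    """
    problems = validate_geometry(model)
    if problems:
        raise GeometryError("invalid scale model: " + "; ".join(problems))
    zone = model.zone
    if zone.n_stations < 2:
        raise ConfigurationError("n_stations must be >= 2")
    s = zone.stations()
    sec = zone.section_at(s)
    section = bilayer_section(sec.t_active, sec.t_passive, sec.width, state)
    resp = section_response(section)
    kappa = np.atleast_1d(resp.kappa)
    if not model.active_below:
        kappa = -kappa
    theta = cumulative_trapezoid(kappa, s, initial=0.0)
    x = cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    y = cumulative_trapezoid(np.sin(theta), s, initial=0.0)
    tip = np.array(
        [x[-1] + model.lever_mm * np.cos(theta[-1]),
         y[-1] + model.lever_mm * np.sin(theta[-1])]
    )
    centerline = np.vstack([np.column_stack([x, y]), tip])
    return BendResult(
        stations=s,
        kappa_field=kappa,
        theta_field=theta,
        centerline=centerline,
        gamma_deg=float(np.degrees(theta[-1])),
    )


def angular_change(model: ScaleModel, state_a: TissueState,
                   state_b: TissueState) -> float:
    """gamma(B) - gamma(A) in degrees; antisymmetric under swapping states."""
    return bend_scale(model, state_b).gamma_deg - bend_scale(model, state_a).gamma_deg
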