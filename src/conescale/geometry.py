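"""Bending-zone geometry of the seed scale.

The proximal few millimetres of the scale -- the *bending zone* -- are a
near-continuous bilayer of sclereid tissue (abaxial, active) and sclerenchyma
fiber strands (adaxial, passive).  Essentially all curvature is generated
there; the long distal remainder of the scale acts as a rigid lever that
amplifies the rotation into a visible tip displacement.

The zone is idealized as a stack of two rectangular layers whose thicknesses
and common width vary linearly between the two measured cross-sections
(start of the zone: 0.8 mm sclereid / 0.6 mm sclerenchyma, 1.8 mm wide;
end: 0.65 / 0.43 mm, 3.5 mm wide; dry-state dimensions).  The zone length is
not measurable from the published cuts and is a configurable model parameter
(see docs/methods.md for how the default was chosen).

Constructors are deliberately permissive: invalid geometries can be built
and then reported on by :func:`validate_geometry`; the mechanics layer
refuses to operate on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError

__all__ = [
    "LayerProfile",
    "BendingZone",
    "ScaleModel",
    "Section",
    "section_at",
    "validate_geometry",
    "default_bending_zone",
    "default_scale_model",
]

#: Default bending-zone length [mm]; unprinted in the source data, chosen so
#: that the dry-state calibration lands at the reported passive modulus.
LENGTH_DEFAULT_MM = 3.0


@dataclass(frozen=True)
class LayerProfile:
    """Linearly tapered thickness of one layer along the bending zone."""

    layer_name: str  # "active" (sclereid) or "passive" (sclerenchyma)
    t_start: float  # mm, at the clamped proximal end
    t_end: float  # mm, at the distal end of the zone

    def thickness(self, frac):
        """Thickness at fractional arclength ``frac`` in [0, 1]."""
        return self.t_start + (self.t_end - self.t_start) * np.asarray(frac, float)


@dataclass(frozen=True)
class BendingZone:
    """Two-layer tapered stack between the two measured cross-sections."""

    length_mm: float = LENGTH_DEFAULT_MM
    w_start: float = 1.8
    w_end: float = 3.5
    active: LayerProfile = field(
        default_factory=lambda: LayerProfile("active", 0.8, 0.65)
    )
    passive: LayerProfile = field(
        default_factory=lambda: LayerProfile("passive", 0.6, 0.43)
    )
    n_stations: int = 201

    def stations(self) -> np.ndarray:
        """Uniform arclength grid [mm], proximal (clamped) end at 0."""
        return np.linspace(0.0, self.length_mm, self.n_stations)

    def width(self, frac):
        return self.w_start + (self.w_end - self.w_start) * np.asarray(frac, float)

    def section_at(self, s):
        """Cross-section dimensions at arclength ``s`` [mm] (scalar or array)."""
        s = np.asarray(s, dtype=float)
        if np.any((s < 0) | (s > self.length_mm)):
            raise DomainError(
                f"arclength s must lie in [0, {self.length_mm}] mm"
            )
        frac = s / self.length_mm
        return Section(
            width=self.width(frac),
            t_active=self.active.thickness(frac),
            t_passive=self.passive.thickness(frac),
        )


@dataclass(frozen=True)
class Section:
    """Dimensions of one rectangular bilayer cross-section [mm]."""

    width: float | np.ndarray
    t_active: float | np.ndarray
    t_passive: float | np.ndarray

    @property
    def total_thickness(self):
        return self.t_active + self.t_passive

    @property
    def area(self):
        return self.width * self.total_thickness


@dataclass(frozen=True)
class ScaleModel:
    """Bending zone plus the rigid distal lever.

    The lever does not contribute to the mechanical response; it is carried
    for postprocessing only (tip position of the deformed scale).  With
    ``active_below=True`` the active sclereid layer sits on the abaxial
    (negative-z) side, so drying -- contraction of the active layer -- bends
    the scale toward positive angles (the cone opens).
    """

    zone: BendingZone = field(default_factory=BendingZone)
    lever_mm: float = 40.0
    active_below: bool = True

    def with_length(self, length_mm: float) -> "ScaleModel":
        zone = BendingZone(
            length_mm=float(length_mm),
            w_start=self.zone.w_start,
            w_end=self.zone.w_end,
            active=self.zone.active,
            passive=self.zone.passive,
            n_stations=self.zone.n_stations,
        )
        return ScaleModel(zone=zone, lever_mm=self.lever_mm,
                          active_below=self.active_below)


def default_bending_zone(**overrides) -> BendingZone:
    """The measured cross-sections with the package default length."""
    return BendingZone(**overrides)


def default_scale_model(**overrides) -> ScaleModel:
    return ScaleModel(zone=default_bending_zone(), **overrides)


def section_at(zone: BendingZone, s):
    """Functional alias of :meth:`BendingZone.section_at`."""
    return zone.section_at(s)


def validate_geometry(model: ScaleModel) -> list[str]:
    """Return a list of violated invariants (empty for a valid model)."""
    report: list[str] = []
    z = model.zone
    if not (z.length_mm > 0):
        report.append(f"length_mm must be > 0, got {z.length_mm}")
    if z.w_start <= 0 or z.w_end <= 0:
        report.append(f"widths must be > 0, got ({z.w_start}, {z.w_end})")
    for prof in (z.active, z.passive):
        if prof.t_start <= 0 or prof.t_end <= 0:
            report.append(
                f"{prof.layer_name} layer thicknesses must be > 0, "
                f"got ({prof.t_start}, {prof.t_end})"
            )
    if z.n_stations < 2:
        report.append(f"n_stations must be >= 2, got {z.n_stations}")
    if model.lever_mm < 0:
        report.append(f"lever_mm must be >= 0, got {model.lever_mm}")
    # interpolated dimensions are linear, so endpoint positivity implies
    # positivity everywhere; still assert on the grid for belt and braces
    if not report and z.n_stations >= 2:
        sec = z.section_at(z.stations())
        if np.any(sec.area <= 0):
            report.append("non-positive section area at an interior station")
    return report
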