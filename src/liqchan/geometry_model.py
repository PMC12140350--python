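"""Closed-form physics of the liquid-walled microchannel.

A strip of aqueous medium is pinned at a fixed width ``w`` on a patterned
substrate under an immiscible oil overlay.  Both contact lines sit on
exclusive-liquid-repellency (ELR) boundaries, so the oil-media interface
forms a surface of constant mean curvature: in the channel cross-section
(``xz`` plane) a circular arc through the pinned edges with apex height
``h``, and flat along the channel axis (``yz`` plane) away from cells.

The confining pressure follows the Law of Laplace,

    P = gamma * (1/R_xz + 1/R_yz),

with ``gamma`` the oil-media interfacial tension (41.8 mN/m for water
against silicone oil) and the two principal radii of curvature.  With
lengths in um and tensions in mN/m the pressure comes out in Pa
(1 mN/m / 1 um = 1000 Pa); the conversion is centralized in
:func:`laplace_pressure`.  An infinite radius is representable
(``math.inf``) and contributes exactly zero curvature.

The pressure reported here is the pressure jump at the media-oil interface;
it is used as an approximation of the confining pressure experienced by
cells under the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InterfacialSystem",
    "ChannelGeometry",
    "ArcCrossSection",
    "PressureEstimate",
    "young_contact_angle",
    "arc_from_width_height",
    "laplace_pressure",
    "channel_pressure",
]

#: Conversion factor: (mN/m) / um  ->  Pa.
PA_PER_MN_PER_M_PER_UM = 1000.0

#: Oil-media interfacial tension for water against 5 cSt silicone oil (mN/m).
GAMMA_OM_WATER_SILICONE = 41.8


@dataclass(frozen=True)
class InterfacialSystem:
    """Interfacial energies of a solid in contact with two immiscible liquids.

    Parameters
    ----------
    gamma_s1 : float
        Solid / liquid-1 interfacial energy (mN/m).
    gamma_s2 : float
        Solid / liquid-2 interfacial energy (mN/m).
    gamma_12 : float
        Liquid-1 / liquid-2 interfacial tension (mN/m); must be positive.
    """

    gamma_s1: float
    gamma_s2: float
    gamma_12: float

    def __post_init__(self) -> None:
        for name in ("gamma_s1", "gamma_s2", "gamma_12"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.gamma_12 <= 0:
            raise ValueError("gamma_12 must be positive")


@dataclass(frozen=True)
class ChannelGeometry:
    """A pinned-width aqueous channel under oil.

    Parameters
    ----------
    width_w : float
        Pinned strip width (um); 30-200 um in practice.
    gamma_om : float
        Oil-media interfacial tension (mN/m).
    length : float
        Channel length (um).
    """

    width_w: float
    gamma_om: float = GAMMA_OM_WATER_SILICONE
    length: float = 300.0

    def __post_init__(self) -> None:
        if self.width_w <= 0:
            raise ValueError("width_w must be positive")
        if self.gamma_om <= 0:
            raise ValueError("gamma_om must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class ArcCrossSection:
    """Circular-arc cross-section of the interface pinned at x = +/- w/2, z = 0."""

    width_w: float
    apex_h: float
    radius_R: float
    curvature_kappa: float


@dataclass(frozen=True)
class PressureEstimate:
    """Laplace pressure from the two principal radii of curvature (um -> Pa)."""

    r_xz: float
    r_yz: float
    pressure: float


def young_contact_angle(system: InterfacialSystem) -> float:
    """Young's contact angle of liquid 1 on the solid under liquid 2, in degrees.

    The Young balance gives ``cos(theta) = (gamma_s2 - gamma_s1) / gamma_12``.
    The ratio is clamped to [-1, 1]: beyond the physical range the contact
    angle is pinned at 0 deg (complete wetting) or 180 deg (exclusive liquid
    repellency, complete repulsion of liquid 1).

    Examples
    --------
    >>> young_contact_angle(InterfacialSystem(20.0, 20.0, 40.0))
    90.0
    """
    ratio = (system.gamma_s2 - system.gamma_s1) / system.gamma_12
    if ratio <= -1.0:
        return 180.0
    if ratio >= 1.0:
        return 0.0
    return math.degrees(math.acos(ratio))


def arc_from_width_height(width_w: float, apex_h: float) -> ArcCrossSection:
    """Circular arc through the pinned edges ``(+/- w/2, 0)`` and apex ``(0, h)``.

    The circumscribed radius is ``R = h/2 + w^2 / (8 h)``; for shallow arcs
    this approaches the parabolic-sag limit ``w^2 / (8 h)``, and ``R = w/2``
    when ``h = w/2`` (a hemicircle).

    Parameters
    ----------
    width_w : float
        Chord width (um), positive.
    apex_h : float
        Apex height above the substrate (um), positive.
    """
    if width_w <= 0:
        raise ValueError("width_w must be positive")
    if apex_h <= 0:
        raise ValueError("apex_h must be positive")
    radius = apex_h / 2.0 + width_w**2 / (8.0 * apex_h)
    return ArcCrossSection(
        width_w=width_w,
        apex_h=apex_h,
        radius_R=radius,
        curvature_kappa=1.0 / radius,
    )


def laplace_pressure(r_xz: float, r_yz: float, gamma: float) -> float:
    """Young-Laplace pressure ``P = gamma * (1/R_xz + 1/R_yz)`` in Pa.

    Parameters
    ----------
    r_xz, r_yz : float
        Principal radii of curvature (um).  ``math.inf`` denotes a flat
        plane and contributes zero; zero or negative radii are invalid.
    gamma : float
        Interfacial tension (mN/m).

    Returns
    -------
    float
        Pressure in Pa (1 mN/m over 1 um curvature radius = 1000 Pa).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    for name, r in (("r_xz", r_xz), ("r_yz", r_yz)):
        if math.isnan(r) or r <= 0:
            raise ValueError(f"{name} must be positive or infinite, got {r!r}")
    curvature = (0.0 if math.isinf(r_xz) else 1.0 / r_xz) + (
        0.0 if math.isinf(r_yz) else 1.0 / r_yz
    )
    return gamma * curvature * PA_PER_MN_PER_M_PER_UM


def channel_pressure(geom: ChannelGeometry, apex_h: float) -> PressureEstimate:
    """Equilibrium interfacial pressure of an undeformed channel section.

    Composes the arc cross-section (for ``R_xz``) with a translationally
    flat axis (``R_yz = inf``) and the Laplace relation.  At fixed apex
    height the pressure decreases with channel width; at fixed width it
    increases with apex height up to the hemicircle limit ``h = w/2``.
    """
    arc = arc_from_width_height(geom.width_w, apex_h)
    pressure = laplace_pressure(arc.radius_R, math.inf, geom.gamma_om)
    return PressureEstimate(r_xz=arc.radius_R, r_yz=math.inf, pressure=pressure)
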