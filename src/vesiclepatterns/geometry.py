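"""Closed-form membrane and lattice geometry for plate-bearing giant vesicles.

This module collects the exact geometric relations used throughout the
package:

* **Excess area** ``Axs = A / ((4π)^(1/3) (3V)^(2/3))`` — the vesicle
  membrane area normalised on the area of a sphere of equal enclosed
  volume.  ``Axs = 1`` for a sphere and ``Axs > 1`` for every other shape
  (isoperimetric inequality).  The related *reduced volume* is
  ``vr = Axs^(-3/2)``.
* **Domain-size relation** ``Dd/Dv = sqrt(4 φ / N)`` linking the number
  ``N`` of monodisperse circular solid domains on a vesicle of diameter
  ``Dv`` to their diameter ``Dd`` at solid area fraction ``φ``, and the
  companion centre–centre spacing relation ``Dcc/Dv = sqrt(4/N)`` for
  domains spread uniformly over the sphere.
* **Hexagonal-cell edge separation**: one disk of diameter ``Dd`` per
  hexagonal cell of spacing ``Dcc`` gives
  ``φ = (π Dd²/4) / ((√3/2) Dcc²)``, hence
  ``Dee/Dd = sqrt(π / (2√3 φ)) − 1`` for the edge–edge gap of an ideal
  flat hexagonal lattice of circular domains.
* **Belt capacity** ``floor(π Dv / Dd)`` — the largest number of plates
  that fit in a single chain encircling the vesicle equator.
* **Micropipette-aspiration shape reconstruction**: a vesicle gently
  aspirated into a pipette is modelled as an outer sphere truncated at
  the pipette mouth, a cylindrical projection inside the pipette, and a
  hemispherical cap at the projection tip.  This low-suction
  decomposition yields closed-form area and volume from the three
  measurable lengths (vesicle radius, pipette radius, projection
  length), from which the excess area follows.

Units are μm for lengths, μm² for areas, μm³ for volumes; ratios are
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import (
    GeometricInconsistencyError,
    InvalidInputError,
    NoSolutionError,
)

__all__ = [
    "HEX_PACKING_BOUND",
    "AspirationGeometry",
    "LatticeGeometry",
    "excess_area",
    "reduced_volume",
    "excess_area_from_vr",
    "excess_area_after_deflation",
    "domain_size_ratio",
    "lattice_spacing_ratio",
    "hex_edge_separation",
    "belt_capacity",
    "single_belt_limit",
    "aspiration_surface",
    "projection_length_for_excess_area",
    "sphere_area",
    "sphere_volume",
]

#: Area fraction of one disk per hexagonal cell at close packing, π/(2√3).
HEX_PACKING_BOUND = math.pi / (2.0 * math.sqrt(3.0))

#: Relative tolerance below which a computed Axs < 1 is treated as rounding.
_SPHERE_TOL = 1e-9


def sphere_area(radius: float) -> float:
    """Surface area ``4 π r²`` of a sphere."""
    return 4.0 * math.pi * radius * radius


def sphere_volume(radius: float) -> float:
    """Volume ``(4/3) π r³`` of a sphere."""
    return (4.0 / 3.0) * math.pi * radius**3


def excess_area(area: float, volume: float) -> float:
    """Excess membrane area ``Axs`` of a closed shape.

    Parameters
    ----------
    area : float
        Membrane area (μm²), strictly positive.
    volume : float
        Enclosed volume (μm³), strictly positive.

    Returns
    -------
    float
        ``A / ((4π)^(1/3) (3V)^(2/3))`` — always ≥ 1; exactly 1 for a
        sphere.  Values within ``1e-9`` relative below 1 are clamped to 1.

    Raises
    ------
    InvalidInputError
        If ``area`` or ``volume`` is not strictly positive.
    GeometricInconsistencyError
        If the area lies below the isoperimetric minimum for the given
        volume by more than the tolerance (no closed shape can do that).
    """
    if not (area > 0.0) or not (volume > 0.0):
        raise InvalidInputError(
            f"area and volume must be positive, got area={area}, volume={volume}"
        )
    equivalent_sphere_area = (4.0 * math.pi) ** (1.0 / 3.0) * (3.0 * volume) ** (2.0 / 3.0)
    axs = area / equivalent_sphere_area
    if axs < 1.0 - _SPHERE_TOL:
        raise GeometricInconsistencyError(
            f"area {area} is below the isoperimetric minimum "
            f"{equivalent_sphere_area} for volume {volume} (Axs={axs})"
        )
    return axs if axs >= 1.0 else 1.0


def reduced_volume(axs: float) -> float:
    """Reduced volume ``vr = Axs^(−3/2)`` — volume normalised on the
    volume of a sphere of equal area.  Lies in (0, 1], equal to 1 for a
    sphere."""
    if not (axs >= 1.0):
        raise InvalidInputError(f"excess area must be >= 1, got {axs}")
    return axs ** (-1.5)


def excess_area_from_vr(vr: float) -> float:
    """Inverse of :func:`reduced_volume`: ``Axs = vr^(−2/3)``."""
    if not (0.0 < vr <= 1.0):
        raise InvalidInputError(f"reduced volume must be in (0, 1], got {vr}")
    return vr ** (-2.0 / 3.0)


def excess_area_after_deflation(volume_fraction_removed: float) -> float:
    """Excess area of an initially spherical vesicle after osmotic
    removal of a volume fraction at fixed membrane area.

    At fixed area, ``Axs ∝ V^(−2/3)``, so removing a fraction ``f`` of
    the volume gives ``Axs = (1 − f)^(−2/3)``.
    """
    f = volume_fraction_removed
    if not (0.0 <= f < 1.0):
        raise InvalidInputError(f"volume fraction removed must be in [0, 1), got {f}")
    return (1.0 - f) ** (-2.0 / 3.0)


def domain_size_ratio(phi: float, n_domains: int) -> float:
    """Domain-to-vesicle diameter ratio ``Dd/Dv = sqrt(4 φ / N)``.

    Follows from distributing a solid area fraction ``φ`` of the sphere
    surface ``π Dv²`` over ``N`` flat circular domains of area
    ``π Dd²/4`` each.
    """
    if not (0.0 < phi < 1.0):
        raise InvalidInputError(f"solid area fraction must be in (0, 1), got {phi}")
    if n_domains < 1 or int(n_domains) != n_domains:
        raise InvalidInputError(f"domain count must be a positive integer, got {n_domains}")
    return math.sqrt(4.0 * phi / n_domains)


def lattice_spacing_ratio(n_domains: int) -> float:
    """Centre–centre spacing ratio ``Dcc/Dv = sqrt(4/N)`` for ``N``
    domains spread uniformly over the sphere.

    Note the companion identity ``Dee/Dd = sqrt(1/φ) − 1`` obtained by
    combining this with ``Dd/Dv = sqrt(4φ/N)``; that uniform-spreading
    estimate is distinct from the hexagonal-cell result of
    :func:`hex_edge_separation` and is not used for the lattice
    edge–edge predictions.
    """
    if n_domains < 1 or int(n_domains) != n_domains:
        raise InvalidInputError(f"domain count must be a positive integer, got {n_domains}")
    return math.sqrt(4.0 / n_domains)


def hex_edge_separation(phi: float) -> float:
    """Edge–edge separation of an ideal hexagonal lattice of disks,
    normalised on the disk diameter.

    One disk of diameter ``Dd`` per hexagonal cell of centre spacing
    ``Dcc`` has area fraction ``φ = (π Dd²/4)/((√3/2) Dcc²)``, hence::

        Dee/Dd = Dcc/Dd − 1 = sqrt(π / (2 √3 φ)) − 1

    Equals 0 at hexagonal close packing, ``φ = π/(2√3) ≈ 0.9069``, and
    increases as the lattice dilates.
    """
    if not (0.0 < phi <= HEX_PACKING_BOUND):
        raise InvalidInputError(
            f"solid area fraction must be in (0, {HEX_PACKING_BOUND:.4f}], got {phi}"
        )
    return math.sqrt(math.pi / (2.0 * math.sqrt(3.0) * phi)) - 1.0


def belt_capacity(vesicle_diameter: float, domain_diameter: float) -> int:
    """Largest number of plates, ``floor(π Dv / Dd)``, that fit in a
    single chain encircling the vesicle equator."""
    if not (0.0 < domain_diameter < vesicle_diameter):
        raise InvalidInputError(
            f"need 0 < Dd < Dv, got Dd={domain_diameter}, Dv={vesicle_diameter}"
        )
    # guard against 10.0000000001-style float noise at exact multiples
    return int(math.floor(math.pi * vesicle_diameter / domain_diameter + 1e-12))


def single_belt_limit(phi: float) -> float:
    """Largest ``N`` compatible with a single belt at fixed area
    fraction: substituting ``Dd/Dv = sqrt(4φ/N)`` into ``N ≤ π Dv/Dd``
    gives ``N ≤ π²/(4φ)``."""
    if not (0.0 < phi < 1.0):
        raise InvalidInputError(f"solid area fraction must be in (0, 1), got {phi}")
    return math.pi**2 / (4.0 * phi)


@dataclass(frozen=True)
class AspirationGeometry:
    """Measured geometry of a vesicle held at low suction in a micropipette.

    Attributes
    ----------
    vesicle_radius : float
        Radius ``Rv`` (μm) of the outer spherical portion.
    pipette_radius : float
        Inner radius ``Rp`` (μm) of the pipette.
    projection_length : float
        Length ``L`` (μm) of the membrane projection, measured from the
        pipette mouth to the projection tip.  ``L ≥ Rp`` so the
        hemispherical cap is fully formed.
    """

    vesicle_radius: float
    pipette_radius: float
    projection_length: float

    def __post_init__(self) -> None:
        rv, rp, length = self.vesicle_radius, self.pipette_radius, self.projection_length
        if not (0.0 < rp < rv):
            raise InvalidInputError(f"need 0 < Rp < Rv, got Rp={rp}, Rv={rv}")
        if not (length >= rp):
            raise InvalidInputError(
                f"projection length must be >= Rp (cap fully formed), got L={length}, Rp={rp}"
            )


def aspiration_surface(geom: AspirationGeometry) -> tuple[float, float]:
    """Membrane area and enclosed volume of the aspirated-vesicle shape.

    The shape is the classic low-suction decomposition: an outer sphere
    of radius ``Rv`` truncated at the pipette mouth (removing a spherical
    cap of height ``h = Rv − sqrt(Rv² − Rp²)``), a cylinder of radius
    ``Rp`` and length ``L − Rp`` inside the pipette, and a hemispherical
    cap of radius ``Rp`` at the projection tip::

        A = [4π Rv² − 2π Rv h] + 2π Rp (L − Rp) + 2π Rp²
        V = [(4/3)π Rv³ − (π h²/3)(3 Rv − h)] + π Rp² (L − Rp) + (2/3)π Rp³

    As ``Rp → 0`` with ``L = Rp`` the intact sphere is recovered.

    Returns
    -------
    (area, volume) : tuple of float
        Both strictly positive.
    """
    rv, rp, length = geom.vesicle_radius, geom.pipette_radius, geom.projection_length
    h = rv - math.sqrt(rv * rv - rp * rp)
    area = (
        4.0 * math.pi * rv * rv
        - 2.0 * math.pi * rv * h
        + 2.0 * math.pi * rp * (length - rp)
        + 2.0 * math.pi * rp * rp
    )
    volume = (
        (4.0 / 3.0) * math.pi * rv**3
        - (math.pi * h * h / 3.0) * (3.0 * rv - h)
        + math.pi * rp * rp * (length - rp)
        + (2.0 / 3.0) * math.pi * rp**3
    )
    return area, volume


def projection_length_for_excess_area(
    axs: float,
    vesicle_radius: float,
    pipette_radius: float,
    bracket_factor: float = 4.0,
) -> float:
    """Projection length ``L`` producing a target excess area.

    Inverts :func:`aspiration_surface` composed with :func:`excess_area`
    by bracketed root finding on ``L ∈ [Rp, bracket_factor · Rv]``.  The
    excess area of the aspirated shape is strictly increasing in ``L``
    within the bracket (verified numerically before solving), so the
    root is unique.

    Raises
    ------
    NoSolutionError
        If the target lies below the minimum reachable ``Axs`` (at
        ``L = Rp``) or above the value at the bracket end.
    """
    rv, rp = vesicle_radius, pipette_radius

    def axs_of(length: float) -> float:
        return excess_area(*aspiration_surface(AspirationGeometry(rv, rp, length)))

    axs_min = axs_of(rp)
    if axs < axs_min - 1e-12:
        raise NoSolutionError(
            f"target Axs={axs} below minimum {axs_min} reachable at L=Rp for "
            f"Rv={rv}, Rp={rp}"
        )
    if axs <= axs_min:
        return rp
    hi = bracket_factor * rv
    if axs_of(hi) < axs:
        raise NoSolutionError(
            f"target Axs={axs} not reachable with L <= {hi} for Rv={rv}, Rp={rp}"
        )
    # monotonicity check across the bracket (uniqueness of the root)
    grid = np.linspace(rp, hi, 9)
    values = [axs_of(g) for g in grid]
    if np.any(np.diff(values) <= 0.0):
        raise GeometricInconsistencyError(
            "excess area is not strictly increasing in L within the bracket"
        )
    length = brentq(lambda x: axs_of(x) - axs, rp, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(axs_of(length) - axs) > 1e-9:
        raise NoSolutionError(f"root finding failed to reach Axs={axs} within 1e-9")
    return float(length)


@dataclass(frozen=True)
class LatticeGeometry:
    """Planar hexagonal-cell geometry of a lattice of circular domains.

    One disk of diameter ``Dd`` per hexagonal cell of centre spacing
    ``Dcc``; the edge separation is ``Dee = Dcc − Dd``.
    """

    solid_area_fraction: float
    domain_diameter: float
    center_spacing: float
    edge_separation: float

    def __post_init__(self) -> None:
        phi, dd, dcc, dee = (
            self.solid_area_fraction,
            self.domain_diameter,
            self.center_spacing,
            self.edge_separation,
        )
        if not (0.0 < phi < HEX_PACKING_BOUND):
            raise InvalidInputError(
                f"solid area fraction must be in (0, {HEX_PACKING_BOUND:.4f}), got {phi}"
            )
        if dd <= 0.0 or dcc <= 0.0:
            raise InvalidInputError("diameters must be positive")
        if dee < -1e-12 or abs((dcc - dd) - dee) > 1e-9 * max(dcc, 1.0):
            raise InvalidInputError(
                f"edge separation {dee} inconsistent with Dcc - Dd = {dcc - dd}"
            )
        implied_phi = (math.pi * dd * dd / 4.0) / ((math.sqrt(3.0) / 2.0) * dcc * dcc)
        if abs(implied_phi - phi) > 1e-6:
            raise InvalidInputError(
                f"phi={phi} inconsistent with hexagonal cell (implied {implied_phi})"
            )

    @classmethod
    def from_phi(cls, phi: float, domain_diameter: float) -> "LatticeGeometry":
        """Build the cell geometry from area fraction and disk diameter."""
        ratio = hex_edge_separation(phi)  # Dee/Dd
        dcc = domain_diameter * (1.0 + ratio)
        return cls(
            solid_area_fraction=phi,
            domain_diameter=domain_diameter,
            center_spacing=dcc,
            edge_separation=dcc - domain_diameter,
        )
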