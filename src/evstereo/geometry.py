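"""Closed-form geometry of the pancake-cell and sphere–slab models.

Adherent endothelial cells are modelled as flat cylinders ("pancakes"):
two circular faces of diameter *d* joined by a lateral wall of height *H*.
Organelles and extracellular vesicles are idealised spheres, optionally
nested (an MVB inside an MCMV, ILVs inside an MVB).  Serial *en face*
sections are contiguous half-open slabs of constant thickness cut from the
coverslip plane (z = 0) upward.

Conventions
-----------
* z = 0 at the coverslip; z increases away from it.
* Internal unit is the micrometre.  Interfaces that naturally speak in
  nanometres say so in their names; :func:`nm_to_um` / :func:`um_to_nm`
  convert.
* Slab *k* occupies the half-open interval ``[k*T, (k+1)*T)`` so that
  contiguous sections partition z without double counting — this is what
  makes "the first section in which a structure appears" unambiguous.
* A sphere merely tangent to a slab boundary from outside does not
  intersect it (measure-zero contact is excluded, consistent with
  half-open slabs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

from .errors import InvalidGeometryError, InvalidInputError

NM_PER_UM = 1000.0


def nm_to_um(x: float) -> float:
    """Convert nanometres to micrometres."""
    return x / NM_PER_UM


def um_to_nm(x: float) -> float:
    """Convert micrometres to nanometres."""
    return x * NM_PER_UM


class BodyKind(str, Enum):
    """What a spherical body represents in the culture model."""

    MCMV = "MCMV"
    MVB = "MVB"
    ILV = "ILV"
    GENERIC = "generic"


@dataclass(frozen=True)
class PancakeCell:
    """Flat-cylinder model of an adherent cell.

    Parameters
    ----------
    diameter : float
        Cell diameter in μm; must be positive.
    height : float
        Cell height in μm; may be zero (degenerate disk).
    """

    diameter: float
    height: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise InvalidGeometryError(
                f"cell diameter must be positive, got {self.diameter}"
            )
        if self.height < 0:
            raise InvalidGeometryError(
                f"cell height must be non-negative, got {self.height}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def face_area(self) -> float:
        """Area of one circular face, μm²."""
        return math.pi * self.radius**2

    @property
    def lateral_area(self) -> float:
        """Area of the full lateral wall, μm²."""
        return math.pi * self.diameter * self.height


@dataclass(frozen=True)
class SphereBody:
    """A spherical organelle or vesicle, optionally nested inside another.

    ``center`` is (x, y, z) in μm with z measured from the coverslip.  If
    ``parent`` is given, the body must lie entirely inside it.
    """

    center: Tuple[float, float, float]
    diameter: float
    kind: BodyKind = BodyKind.GENERIC
    parent: Optional["SphereBody"] = None
    body_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise InvalidGeometryError(
                f"sphere diameter must be positive, got {self.diameter}"
            )
        if len(self.center) != 3:
            raise InvalidGeometryError("center must be a 3-vector")
        if self.parent is not None:
            gap = (self.parent.diameter - self.diameter) / 2.0
            dist = math.dist(self.center, self.parent.center)
            # small tolerance: containment checked at machine precision only
            if dist > gap + 1e-9:
                raise InvalidGeometryError(
                    f"body (d={self.diameter}) at distance {dist:.6g} from "
                    f"parent centre exceeds containment bound {gap:.6g}"
                )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def z(self) -> float:
        return self.center[2]

    @property
    def z_bottom(self) -> float:
        return self.z - self.radius

    @property
    def z_top(self) -> float:
        return self.z + self.radius


@dataclass(frozen=True)
class SectionSlab:
    """One thin section: the half-open z-interval ``[z_lo, z_lo + thickness)``.

    For contiguous serial sections ``z_lo == index * thickness``; a slab
    drawn at arbitrary z (single-section survey mode) carries its own
    ``z_lo`` and ``index = floor(z_lo / thickness)``.
    """

    index: int
    thickness: float
    z_lo: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise InvalidGeometryError(
                f"section thickness must be positive, got {self.thickness}"
            )
        if self.index < 0:
            raise InvalidGeometryError(f"slab index must be >= 0, got {self.index}")
        if self.z_lo is None:
            object.__setattr__(self, "z_lo", self.index * self.thickness)

    @property
    def z_hi(self) -> float:
        return self.z_lo + self.thickness


def pancake_surface_area(cell: PancakeCell) -> float:
    """Total membrane area of the pancake model, μm².

    ``A = 2·π·(d/2)² + π·d·H`` — two faces plus the lateral wall.  For the
    literature values d = 24 μm, H = 4 μm this is 1206.37 μm², commonly
    rounded to "about 1200 μm²".
    """
    return 2.0 * cell.face_area + cell.lateral_area


def lateral_band_area(cell: PancakeCell, band_height: float) -> float:
    """Area of a lateral-wall band of height ``band_height``, μm² (π·d·h).

    The band is the portion of cell surface a stack of sections spanning
    ``band_height`` in z can sample.  ``band_height`` must lie in
    ``[0, cell.height]``.
    """
    if band_height < 0 or band_height > cell.height:
        raise InvalidGeometryError(
            f"band height {band_height} outside [0, {cell.height}]"
        )
    return math.pi * cell.diameter * band_height


def band_fraction(cell: PancakeCell, band_height: float) -> float:
    """Dimensionless ratio ``lateral_band_area / pancake_surface_area``.

    This is the single-section detection probability of a surface feature
    whose vertical extent equals ``band_height``: p = dh / (d²/2 + dH).
    Invariant under uniform rescaling of all lengths.
    """
    total = pancake_surface_area(cell)
    return lateral_band_area(cell, band_height) / total


def sphere_slab_profile(body: SphereBody, slab: SectionSlab) -> Optional[float]:
    """Largest circular cross-section of ``body`` visible inside ``slab``.

    Returns ``None`` when the sphere's z-extent is disjoint from the slab
    (tangent contact counts as disjoint).  If the equatorial plane lies in
    the slab the full diameter is returned; otherwise the chord circle
    ``2·√(r² − δ²)`` at the in-slab plane nearest the centre, δ being the
    distance from the centre to that plane.  This matches how a
    microscopist measures the widest visible extent of a profile.
    """
    r = body.radius
    zc = body.z
    if zc - r >= slab.z_hi or zc + r <= slab.z_lo:
        return None
    if slab.z_lo <= zc < slab.z_hi:
        return body.diameter
    delta = slab.z_lo - zc if zc < slab.z_lo else zc - slab.z_hi
    if delta >= r:  # pragma: no cover - excluded by the disjointness test
        return None
    return 2.0 * math.sqrt(r * r - delta * delta)


def sections_spanned(diameter: float, thickness: float, z_offset: float) -> int:
    """Number of contiguous slabs intersected by ``[z_offset, z_offset + diameter)``.

    ``z_offset`` is the object's bottom height above the nearest slab
    boundary and must satisfy ``0 <= z_offset < thickness``.  Over all
    offsets the count takes exactly the two values ⌈d/T⌉ and ⌈d/T⌉ + 1.
    Any consistent length unit may be used.
    """
    if not diameter > 0:
        raise InvalidInputError(f"diameter must be positive, got {diameter}")
    if not thickness > 0:
        raise InvalidInputError(f"thickness must be positive, got {thickness}")
    if not 0 <= z_offset < thickness:
        raise InvalidInputError(
            f"z_offset {z_offset} outside [0, thickness={thickness})"
        )
    # last slab k satisfies k*T < z_offset + diameter (half-open object interval)
    top = z_offset + diameter
    last = math.ceil(top / thickness) - 1
    if last * thickness >= top:  # guard against float round-up at exact multiples
        last -= 1
    return last + 1
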