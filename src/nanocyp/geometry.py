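"""Geometric models of a P450 molecule, a carbon nanotube and attachment modes.

Cytochrome P450 is approximated by its crystallographic envelope: a triangular
prism of roughly 4.5-5 nm x 5-6.5 nm with a thickness of 3.5-4.5 nm.  The
multi-walled carbon nanotube is a cylinder (10 nm diameter).  For packing
purposes the cylinder is unrolled into a flat rectangle of width pi*diameter
with a periodic arc coordinate; protein footprints become axis-aligned
rectangles on that surface.  Curvature enters only through the contact-strip
construction: a flat protein face tangent to the cylinder touches it over a
narrow strip whose width is set by how large a face-to-wall gap still counts
as "in contact".

All lengths are nanometres internally; contact areas are exposed in square
angstroms (1 nm^2 = 100 A^2) to match the units used for buried-surface
energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

#: Default face-to-wall gap (nm) below which a point of a flat face counts as
#: in contact with the nanotube wall.  Calibrated once so that the lateral
#: (largest) face of the midpoint protein (4.75 x 5.75 x 4.0 nm) on a 10 nm
#: tube yields a contact area inside the 272-378 A^2 range estimated for the
#: P450-nanotube complex.
DEFAULT_CONTACT_CUTOFF = 0.008

#: Fraction of an edge's length that contributes contact when the prism rests
#: on an edge (a wedge presents far less surface than a flat face) and when it
#: touches on a corner.  These keep the face-down modes dominant.
EDGE_CONTACT_FRACTION = 0.5
CORNER_CONTACT_FRACTION = 0.25

MODE_IDS = ("lateral", "triangular", "long_edge", "short_edge", "corner")


@dataclass(frozen=True)
class ProteinPrism:
    """Triangular-prism envelope of a cytochrome P450 molecule (nm).

    ``edge_a`` is the triangular base edge, ``edge_b`` the long prism edge and
    ``thickness`` the prism height.  Crystallographic ranges: 4.5-5, 5-6.5 and
    3.5-4.5 nm respectively; defaults are the range midpoints.
    """

    edge_a: float = 4.75
    edge_b: float = 5.75
    thickness: float = 4.0

    def __post_init__(self) -> None:
        if min(self.edge_a, self.edge_b, self.thickness) <= 0:
            raise InvalidParameterError("protein dimensions must be positive")
        if self.edge_a > self.edge_b:
            raise InvalidParameterError("edge_a must not exceed edge_b")
        if self.thickness > self.edge_a:
            raise InvalidParameterError("thickness must not exceed edge_a")

    @property
    def max_dimension(self) -> float:
        return self.edge_b

    @property
    def min_dimension(self) -> float:
        return self.thickness


@dataclass(frozen=True)
class Nanotube:
    """Multi-walled carbon nanotube modelled as a cylinder (nm)."""

    diameter: float = 10.0
    length: float = 1000.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("tube diameter must be positive")
        if self.length <= 0:
            raise InvalidParameterError("tube length must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def circumference(self) -> float:
        """Period of the arc coordinate on the unrolled surface."""
        return math.pi * self.diameter


@dataclass(frozen=True)
class Orientation:
    """One of the five attachment modes of the prism on the tube wall.

    ``contact_area`` is in A^2; ``radial_extent`` is how far the adsorbed
    molecule protrudes above the wall; the footprint is the axial x arc
    bounding rectangle it occupies on the unrolled surface (nm).
    """

    mode_id: str
    contact_area: float
    radial_extent: float
    footprint_axial: float
    footprint_arc: float


@dataclass(frozen=True)
class SurfaceRect:
    """Axis-aligned rectangle on the unrolled cylinder surface (nm).

    The arc coordinate is periodic; ``s_max`` may exceed the period to
    represent a footprint that wraps around the seam (width stays < period).
    """

    z_min: float
    z_max: float
    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if self.z_max <= self.z_min:
            raise InvalidParameterError("z_max must exceed z_min")
        if self.s_max <= self.s_min:
            raise InvalidParameterError("s_max must exceed s_min")


def contact_strip_area(face_length: float, tube_radius: float, cutoff: float) -> float:
    """Contact area (A^2) of a flat face of length ``face_length`` tangent to
    a cylinder of radius ``tube_radius``.

    The gap between a tangent plane and the cylinder at transverse offset x is
    g(x) = r - sqrt(r^2 - x^2) ~ x^2 / (2r).  Points with g <= cutoff form a
    strip of width w = 2*sqrt(2*r*cutoff) (small-gap approximation, valid for
    cutoff << r); the contact patch is w * face_length.
    """
    if face_length < 0 or tube_radius < 0 or cutoff < 0:
        raise InvalidParameterError("face_length, tube_radius and cutoff must be >= 0")
    if cutoff > tube_radius:
        raise InvalidParameterError("cutoff must not exceed the tube radius")
    width = 2.0 * math.sqrt(2.0 * tube_radius * cutoff)
    return width * face_length * 100.0  # nm^2 -> A^2


def make_orientation_set(
    protein: ProteinPrism,
    tube: Nanotube,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Orientation]:
    """The five attachment modes of the prism on the tube wall.

    Modes (contacting length along the tube axis, radial extent):

    * ``lateral``     - largest rectangular face down; contact along edge_b,
      protrudes by ``thickness``.  This is the energetically preferred mode.
    * ``triangular``  - a triangular end face down; contact along edge_a,
      protrudes by ``edge_b``.
    * ``long_edge``   - resting on a long edge (wedge contact), protrudes by
      ``edge_a``.
    * ``short_edge``  - resting on a short (triangle) edge, protrudes by
      ``edge_b``.
    * ``corner``      - tilted corner contact, protrudes by the largest
      dimension.

    Edge and corner contacts use reduced effective contact lengths
    (``EDGE_CONTACT_FRACTION``, ``CORNER_CONTACT_FRACTION``) since a wedge or
    vertex buries far less surface than a flat face.
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    r = tube.radius
    a, b, t = protein.edge_a, protein.edge_b, protein.thickness

    def area(face_length: float) -> float:
        return contact_strip_area(face_length, r, cutoff)

    return [
        Orientation("lateral", area(b), t, b, a),
        Orientation("triangular", area(a), b, a, a),
        Orientation("long_edge", area(EDGE_CONTACT_FRACTION * b), a, b, t),
        Orientation("short_edge", area(EDGE_CONTACT_FRACTION * a), b, a, t),
        Orientation("corner", area(CORNER_CONTACT_FRACTION * t), b, t, t),
    ]


def rects_overlap(a: SurfaceRect, b: SurfaceRect, period: float) -> bool:
    """True iff two footprints intersect on the unrolled cylinder.

    Axial positions are absolute; arc positions are compared modulo
    ``period`` (azimuthal wrap-around).  Touching boundaries do not count as
    overlap.  Symmetric in its arguments.
    """
    if period <= 0:
        raise InvalidParameterError("period must be positive")
    if a.z_max <= b.z_min or b.z_max <= a.z_min:
        return False
    ca = 0.5 * (a.s_min + a.s_max)
    cb = 0.5 * (b.s_min + b.s_max)
    ha = 0.5 * (a.s_max - a.s_min)
    hb = 0.5 * (b.s_max - b.s_min)
    d = abs(ca - cb) % period
    d = min(d, period - d)
    return d < ha + hb
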