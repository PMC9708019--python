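"""Parametric aortic-root geometry, anatomical landmarks and the conduction-system ROI.

The aortic root is represented on a cylindrical-coordinate grid attached to the
annular plane: axial stations ``z`` in mm with the annular plane at ``z = 0`` and
``z`` increasing toward the left ventricle (the direction of implantation), and
circumferential angles ``theta`` in degrees. The wall is described by its free
(unloaded) radius at every grid node, a linear radial stiffness, and a set of
calcification nodules that locally stiffen the wall.

Landmarks follow the standard membranous-septum convention: P1 and P3 mark the
beginning and end of the inferior border of the membranous septum (IBMS), with an
optional intermediate point P2 tracking its course. Derived scalar measures are
the IBMS length (‖P3 − P1‖), the IBMS angle α to the annular plane, and the
signed distance D3 of P3 from the plane (negative on the ventricular side).

The region of interest (ROI) for contact-pressure analysis is the wall patch
between the IBMS curve — extended 25° circumferentially toward the right
coronary cusp — and the plane 15 mm below (ventricular to) the annulus, which
covers the proximal left bundle branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnularPlane",
    "Landmarks",
    "CalcificationNodule",
    "AorticRootGeometry",
    "ROIPatch",
    "ProceduralInputs",
    "ibms_length",
    "ibms_angle",
    "p3_depth",
    "perimeter_derived_diameter",
    "sizing_index",
    "doi_from_frame",
    "build_roi",
]

_UNIT_TOL = 1e-9


def _as_point(p, name: str) -> np.ndarray:
    if p is None:
        raise ValueError(f"missing landmark/point: {name}")
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AnnularPlane:
    """Annular plane: origin (mm) and unit normal pointing from ventricle toward aorta."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin, "origin"))
        n = _as_point(self.normal, "normal")
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise ValueError("plane normal must have unit length")
        object.__setattr__(self, "normal", n)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic orthonormal in-plane basis (e1, e2)."""
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(seed, n)) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - np.dot(seed, n) * n
        e1 /= np.linalg.norm(e1)
        # right-handed about the grid axis (-normal, toward the ventricle) so
        # angles agree with atan2(y, x) for the canonical plane
        e2 = np.cross(e1, n)
        return e1, e2

    def axial_coordinate(self, point) -> float:
        """Grid axial coordinate of a point: positive toward the ventricle."""
        p = _as_point(point, "point")
        return float(-np.dot(p - self.origin, self.normal))

    def circumferential_angle(self, point) -> float:
        """In-plane angle of a point's projection, degrees in [0, 360)."""
        p = _as_point(point, "point")
        e1, e2 = self.basis()
        d = p - self.origin
        return float(np.degrees(np.arctan2(np.dot(d, e2), np.dot(d, e1))) % 360.0)


@dataclass(frozen=True)
class Landmarks:
    """Membranous-septum landmarks P1..P3 plus the circumferential RCC reference angle."""

    p1: np.ndarray
    p3: np.ndarray
    p2: np.ndarray | None = None
    rcc_reference_angle: float = 90.0

    def __post_init__(self):
        object.__setattr__(self, "p1", _as_point(self.p1, "P1"))
        object.__setattr__(self, "p3", _as_point(self.p3, "P3"))
        if self.p2 is not None:
            object.__setattr__(self, "p2", _as_point(self.p2, "P2"))
        if np.array_equal(self.p1, self.p3):
            raise ValueError("P1 and P3 must be distinct points")


@dataclass(frozen=True)
class CalcificationNodule:
    """Localized wall stiffening: centre (z, theta), half-widths and stiffness multiplier."""

    z: float
    theta: float
    angular_half_width: float  # degrees
    axial_half_width: float  # mm
    stiffness_multiplier: float

    def __post_init__(self):
        if self.stiffness_multiplier < 1.0:
            raise ValueError("calcification stiffness multiplier must be >= 1")


@dataclass
class AorticRootGeometry:
    """Aortic-root wall on an axial x circumferential grid.

    ``z`` (mm, increasing, annular plane at 0, positive toward the ventricle),
    ``theta`` (degrees, uniform, covering the full circumference),
    ``r_free`` (mm, shape ``(len(z), len(theta))``): unloaded wall radius,
    ``annular_perimeter`` (mm), ``wall_stiffness`` (MPa per mm of radial
    displacement) and calcification nodules.
    """

    z: np.ndarray
    theta: np.ndarray
    r_free: np.ndarray
    annular_perimeter: float
    wall_stiffness: float
    calcifications: list[CalcificationNodule] = field(default_factory=list)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.r_free = np.asarray(self.r_free, dtype=float)
        if self.r_free.shape != (self.z.size, self.theta.size):
            raise ValueError("r_free shape must be (len(z), len(theta))")
        if np.any(self.r_free <= 0):
            raise ValueError("free radius must be positive everywhere")
        if self.wall_stiffness <= 0:
            raise ValueError("wall stiffness must be positive")
        if self.annular_perimeter <= 0:
            raise ValueError("annular perimeter must be positive")

    # -- grid helpers -------------------------------------------------------
    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def dtheta(self) -> float:
        return float(self.theta[1] - self.theta[0])

    def cell_area(self) -> np.ndarray:
        """Per-node patch area r * dtheta_rad * dz (mm^2)."""
        return self.r_free * math.radians(self.dtheta) * self.dz

    def stiffness_map(self) -> np.ndarray:
        """Effective radial stiffness k_eff = k_w * calcification multiplier, per node."""
        k = np.full(self.r_free.shape, self.wall_stiffness)
        if not self.calcifications:
            return k
        zz = self.z[:, None]
        tt = self.theta[None, :]
        for nod in self.calcifications:
            dthe = np.abs((tt - nod.theta + 180.0) % 360.0 - 180.0)
            inside = (np.abs(zz - nod.z) <= nod.axial_half_width) & (
                dthe <= nod.angular_half_width
            )
            k = np.where(inside, np.maximum(k, self.wall_stiffness * nod.stiffness_multiplier), k)
        return k

    @classmethod
    def cylinder(
        cls,
        radius: float,
        z_min: float = -5.0,
        z_max: float = 16.0,
        dz: float = 0.25,
        dtheta: float = 1.0,
        wall_stiffness: float = 0.2,
        calcifications: list[CalcificationNodule] | None = None,
    ) -> "AorticRootGeometry":
        """Uniform circular cylinder — the analytically tractable reference geometry."""
        z = np.arange(z_min, z_max + 0.5 * dz, dz)
        theta = np.arange(0.0, 360.0, dtheta)
        r = np.full((z.size, theta.size), float(radius))
        return cls(
            z=z,
            theta=theta,
            r_free=r,
            annular_perimeter=2.0 * math.pi * radius,
            wall_stiffness=wall_stiffness,
            calcifications=list(calcifications or []),
        )


@dataclass
class ROIPatch:
    """Boolean mask over the geometry grid with per-cell surface areas (mm^2)."""

    mask: np.ndarray
    cell_area: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        if self.mask.shape != self.cell_area.shape:
            raise ValueError("mask and cell_area shapes differ")
        if self.area <= 0:
            raise ValueError("ROI has zero area")

    @property
    def area(self) -> float:
        return float(self.cell_area[self.mask].sum())


@dataclass(frozen=True)
class ProceduralInputs:
    """Procedure description: device, depth of implantation, frame rotation."""

    device_id: str
    doi: float  # mm, positive = frame inflow below (ventricular to) the annulus
    frame_rotation: float = 0.0  # degrees


# ---------------------------------------------------------------------------
# scalar anatomical / procedural measures
# ---------------------------------------------------------------------------

def ibms_length(landmarks: Landmarks) -> float:
    """IBMS length: Euclidean distance from P1 to P3 (mm)."""
    return float(np.linalg.norm(landmarks.p3 - landmarks.p1))


def ibms_angle(landmarks: Landmarks, plane: AnnularPlane) -> float:
    """Angle α (degrees, in [0, 90]) between the P1–P3 segment and the annular plane."""
    d = landmarks.p3 - landmarks.p1
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("P1 and P3 coincide: IBMS segment has zero length")
    sin_a = abs(np.dot(d, plane.normal)) / norm
    return float(np.degrees(np.arcsin(min(1.0, sin_a))))


def p3_depth(landmarks: Landmarks, plane: AnnularPlane) -> float:
    """Signed distance D3 of P3 from the annular plane (mm).

    Negative when P3 lies on the ventricular side of the plane (the normal
    points from ventricle toward aorta), matching the clinical sign convention
    under which the cohort mean is negative.
    """
    return float(np.dot(landmarks.p3 - plane.origin, plane.normal))


def perimeter_derived_diameter(perimeter: float) -> float:
    """Perimeter-based annular diameter: perimeter / π (mm)."""
    if perimeter <= 0:
        raise ValueError("annular perimeter must be positive")
    return perimeter / math.pi


def sizing_index(nominal_device_diameter: float, annular_diameter: float) -> float:
    """Nominal device diameter over perimeter-derived annular diameter (dimensionless)."""
    if nominal_device_diameter <= 0 or annular_diameter <= 0:
        raise ValueError("diameters must be positive")
    return nominal_device_diameter / annular_diameter


def doi_from_frame(frame_inflow_depths, plane: AnnularPlane | None = None) -> float:
    """Depth of implantation: mean of the signed inflow-edge depths on the NCC and LCC sides.

    ``frame_inflow_depths`` is a (ncc, lcc) pair of signed depths in mm. The
    optional ``plane`` argument is accepted for symmetry with the other
    measures; depths are assumed already expressed relative to it.
    """
    try:
        ncc, lcc = frame_inflow_depths
    except (TypeError, ValueError) as exc:
        raise ValueError("frame inflow depths must be a (NCC, LCC) pair") from exc
    if ncc is None or lcc is None:
        raise ValueError("both NCC and LCC inflow depths are required")
    return (float(ncc) + float(lcc)) / 2.0


# ---------------------------------------------------------------------------
# conduction-system ROI
# ---------------------------------------------------------------------------

def _circular_signed_diff(a: float, b: float) -> float:
    """Signed circular difference a - b in (-180, 180]."""
    return (a - b + 180.0) % 360.0 - 180.0


def build_roi(
    geometry: AorticRootGeometry,
    landmarks: Landmarks,
    plane: AnnularPlane | None = None,
    extension_deg: float = 25.0,
    depth_limit: float = 15.0,
) -> ROIPatch:
    """Conduction-system ROI on the wall grid.

    The patch covers grid cells whose circumferential angle lies within the
    IBMS angular span extended ``extension_deg`` toward the RCC reference
    angle, and whose axial coordinate lies between the (piecewise-linearly
    interpolated) IBMS curve and ``z = depth_limit`` mm below the annulus.
    In the extension region the IBMS curve is continued at its endpoint depth.
    """
    if plane is None:
        plane = AnnularPlane(origin=np.zeros(3), normal=np.array([0.0, 0.0, -1.0]))

    pts = [landmarks.p1] + ([landmarks.p2] if landmarks.p2 is not None else []) + [landmarks.p3]
    ang = [plane.circumferential_angle(p) for p in pts]
    zed = [plane.axial_coordinate(p) for p in pts]

    # unwrap angles around P1 so the curve is monotone-friendly
    ref = ang[0]
    rel = [0.0] + [_circular_signed_diff(a, ref) for a in ang[1:]]
    order = np.argsort(rel)
    rel_sorted = np.asarray(rel)[order]
    z_sorted = np.asarray(zed)[order]

    lo, hi = float(rel_sorted[0]), float(rel_sorted[-1])
    # extend toward the RCC
    rcc_rel = _circular_signed_diff(landmarks.rcc_reference_angle, ref)
    if rcc_rel >= (lo + hi) / 2.0:
        hi += extension_deg
    else:
        lo -= extension_deg

    zmin, zmax = float(geometry.z.min()), float(geometry.z.max())
    if np.any(z_sorted < zmin) or np.any(z_sorted > zmax) or depth_limit > zmax:
        raise ValueError("IBMS curve or depth limit falls outside the geometry grid")

    # membership decided at cell centres (cell = node + half-widths) so the
    # summed patch area converges to the analytic area of the region
    theta_c = geometry.theta + geometry.dtheta / 2.0
    z_c = geometry.z + geometry.dz / 2.0
    theta_rel = np.array([_circular_signed_diff(t, ref) for t in theta_c])
    in_span = (theta_rel >= lo - 1e-9) & (theta_rel <= hi + 1e-9)
    # IBMS depth per column: piecewise-linear inside the landmark span,
    # endpoint-constant in the extension
    z_curve = np.interp(
        np.clip(theta_rel, rel_sorted[0], rel_sorted[-1]), rel_sorted, z_sorted
    )
    zz = z_c[:, None]
    mask = in_span[None, :] & (zz >= z_curve[None, :] - 1e-9) & (zz <= depth_limit + 1e-9)
    return ROIPatch(mask=mask, cell_area=geometry.cell_area())
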