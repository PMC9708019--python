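"""Device catalogue and the simplified mechanistic valve-deployment model.

Valve deployment is modelled as an independent radial-spring equilibrium at
every wall grid node. The wall responds linearly to radial displacement,

    p_wall(r) = k_eff * (r - r_free)   for r > r_free, else 0,

with k_eff the wall stiffness scaled by the local calcification multiplier.
Self-expanding (force-controlled) frames exert a radial contact pressure
``p_dev(d)`` that is non-increasing in the local diameter ``d`` and vanishes at
the nominal diameter; the equilibrium radius solves ``p_wall(r) = p_dev(2r)``,
which is unique because one side is strictly increasing and the other
non-increasing. Mechanically expanding (displacement-controlled) frames are
driven to their nominal diameter, so the wall carries ``p_wall(d_nom / 2)``
wherever the frame interferes with the unloaded wall.

From the resulting contact-pressure field and a conduction-system ROI the two
mechanistic biomarkers are computed: ``Cpmax`` (the maximum contact pressure in
the ROI, MPa) and ``CPI`` (the percentage of the ROI area subjected to contact
pressure).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Callable

import numpy as np
import yaml

from .geometry import AorticRootGeometry, ProceduralInputs, ROIPatch

__all__ = [
    "DeviceModel",
    "ContactPressureField",
    "device_catalogue",
    "get_device",
    "deploy",
    "cp_max",
    "cpi",
    "export_field",
    "CONTACT_EPS",
]

#: contact threshold (MPa) below which a node does not count toward CPI
CONTACT_EPS = 1e-6


@dataclass(frozen=True)
class DeviceModel:
    """A transcatheter valve frame and its radial mechanical behaviour."""

    device_id: str
    family: str  # "self-expanding" | "mechanically-expanding"
    frame_length: float  # mm
    nominal_diameter: float  # mm
    crimped_diameter: float = 6.0  # mm
    peak_pressure: float = 2.0  # MPa, radial pressure at the crimped diameter
    deployment: str = "force"  # "force" | "displacement"
    pressure_curve: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.frame_length <= 0:
            raise ValueError("frame length must be positive")
        if self.nominal_diameter <= self.crimped_diameter:
            raise ValueError("nominal diameter must exceed crimped diameter")

    @property
    def device_type(self) -> str:
        """Device category label: 'CV', 'ER/EPRO' or 'LT'."""
        return self.device_id.rsplit(" ", 1)[0]

    def radial_pressure(self, d) -> np.ndarray:
        """Contact pressure (MPa) the frame can exert at local diameter ``d`` (mm).

        Default curve: linear ramp from ``peak_pressure`` at the crimped
        diameter to zero at the nominal diameter, clipped to be non-negative
        and non-increasing. Overridable via ``pressure_curve``.
        """
        d = np.asarray(d, dtype=float)
        if self.pressure_curve is not None:
            return np.maximum(0.0, np.asarray(self.pressure_curve(d), dtype=float))
        frac = (self.nominal_diameter - d) / (self.nominal_diameter - self.crimped_diameter)
        return self.peak_pressure * np.clip(frac, 0.0, 1.0)

    def scaled(self, factor: float) -> "DeviceModel":
        """Same device with the nominal diameter scaled (oversizing sweeps)."""
        return DeviceModel(
            device_id=self.device_id,
            family=self.family,
            frame_length=self.frame_length,
            nominal_diameter=self.nominal_diameter * factor,
            crimped_diameter=self.crimped_diameter,
            peak_pressure=self.peak_pressure,
            deployment=self.deployment,
            pressure_curve=self.pressure_curve,
        )


@dataclass
class ContactPressureField:
    """Per-node contact pressure (MPa) and equilibrium wall radius (mm)."""

    pressure: np.ndarray
    r_eq: np.ndarray

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.r_eq = np.asarray(self.r_eq, dtype=float)
        if self.pressure.shape != self.r_eq.shape:
            raise ValueError("pressure and r_eq shapes differ")
        if np.any(self.pressure < 0):
            raise ValueError("contact pressure must be non-negative")


def device_catalogue() -> list[DeviceModel]:
    """The eight device sizes of the study cohort, from the packaged catalogue."""
    ref = importlib.resources.files("tavica") / "data" / "devices.yaml"
    spec = yaml.safe_load(ref.read_text())
    out = []
    for entry in spec["devices"]:
        out.append(
            DeviceModel(
                device_id=entry["id"],
                family=entry["family"],
                frame_length=float(entry["frame_length"]),
                nominal_diameter=float(entry["nominal_diameter"]),
                crimped_diameter=float(entry["crimped_diameter"]),
                peak_pressure=float(entry["peak_pressure"]),
                deployment=entry["deployment"],
            )
        )
    return out


def get_device(device_id: str) -> DeviceModel:
    for dev in device_catalogue():
        if dev.device_id == device_id:
            return dev
    raise KeyError(f"unknown device id: {device_id!r}")


def deploy(
    geometry: AorticRootGeometry,
    device: DeviceModel,
    procedural: ProceduralInputs,
    tol: float = 1e-9,
) -> ContactPressureField:
    """Virtually implant ``device`` at the given depth and solve the contact field.

    The frame occupies axial positions ``z`` in ``[DOI - frame_length, DOI]``
    (inflow edge at ``z = DOI``, the frame extending toward the aorta). Nodes
    outside the frame carry zero pressure.
    """
    doi = float(procedural.doi)
    # coverage decided at cell centres, consistent with the ROI area convention
    z = geometry.z + geometry.dz / 2.0
    covered = (z >= doi - device.frame_length - 1e-12) & (z <= doi + 1e-12)
    if not covered.any():
        raise ValueError(
            f"DOI {doi} mm positions no part of the {device.frame_length} mm frame "
            "across the grid's axial range"
        )

    r_free = geometry.r_free
    k_eff = geometry.stiffness_map()
    r_eq = r_free.copy()
    p = np.zeros_like(r_free)
    cov = np.broadcast_to(covered[:, None], r_free.shape)

    if device.deployment == "displacement":
        r_nom = device.nominal_diameter / 2.0
        interf = cov & (r_nom > r_free)
        r_eq[interf] = r_nom
        p[interf] = k_eff[interf] * (r_nom - r_free[interf])
        return ContactPressureField(pressure=p, r_eq=r_eq)

    # force-controlled: solve k_eff (r - r_free) = p_dev(2r) by bisection on
    # [r_free, d_nom/2]; contact only where the frame still pushes at r_free
    active = cov & (device.radial_pressure(2.0 * r_free) > 0)
    if active.any():
        rf = r_free[active]
        ke = k_eff[active]
        lo = rf.copy()
        hi = np.full_like(rf, device.nominal_diameter / 2.0)
        if device.pressure_curve is not None:
            # custom curves may stay positive beyond d_nom: expand the bracket
            while np.any(device.radial_pressure(2.0 * hi) > ke * (hi - rf)):
                hi = np.where(device.radial_pressure(2.0 * hi) > ke * (hi - rf), hi * 1.5, hi)
                if np.any(hi > 1e4):
                    raise ArithmeticError("deployment equilibrium bracket did not close")
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            h = ke * (mid - rf) - device.radial_pressure(2.0 * mid)
            lo = np.where(h < 0, mid, lo)
            hi = np.where(h < 0, hi, mid)
            if float(np.max(hi - lo)) < tol:
                break
        root = 0.5 * (lo + hi)
        r_eq[active] = root
        p[active] = np.maximum(0.0, ke * (root - rf))
    return ContactPressureField(pressure=p, r_eq=r_eq)


def _check_roi(roi: ROIPatch) -> None:
    if not roi.mask.any():
        raise ValueError("ROI is empty")


def cp_max(field: ContactPressureField, roi: ROIPatch) -> float:
    """Maximum contact pressure over the ROI (MPa); 0 when there is no contact."""
    _check_roi(roi)
    return float(field.pressure[roi.mask].max())


def cpi(field: ContactPressureField, roi: ROIPatch, eps: float = CONTACT_EPS) -> float:
    """Contact pressure index: percentage of ROI area with contact pressure > eps."""
    _check_roi(roi)
    areas = roi.cell_area[roi.mask]
    pressed = field.pressure[roi.mask] > eps
    return float(min(100.0, 100.0 * areas[pressed].sum() / areas.sum()))


def export_field(
    field: ContactPressureField, geometry: AorticRootGeometry, path
) -> None:
    """Write the contact field as a delimited table (z, theta, r_eq, p)."""
    zz, tt = np.meshgrid(geometry.z, geometry.theta, indexing="ij")
    table = np.column_stack(
        [zz.ravel(), tt.ravel(), field.r_eq.ravel(), field.pressure.ravel()]
    )
    header = "z_mm\ttheta_deg\tr_eq_mm\tpressure_mpa"
    np.savetxt(path, table, delimiter="\t", header=header, comments="")
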