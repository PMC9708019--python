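"""Cohort and geometry file formats with provenance headers.

Cohorts are CSV (UTF-8, '.' decimal, header row) preceded by ``# key: value``
comment lines carrying provenance (generator mode, seed, config hash, package
version), enough to regenerate the file bit-identically in statistical mode.
Device categories are the literal strings "CV", "ER/EPRO", "LT". Geometry and
landmarks travel as a YAML document with units mm/degrees.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import AnnularPlane, AorticRootGeometry, CalcificationNodule, Landmarks
from .synth import DEVICE_SIZES, DEVICE_TYPES

__all__ = [
    "COHORT_COLUMNS",
    "write_cohort",
    "read_cohort",
    "save_geometry",
    "load_geometry",
    "config_hash",
]

#: column dictionary: name -> (kind, description)
COHORT_COLUMNS = {
    "patient_id": ("int", "row identifier"),
    "ibms_length": ("float", "IBMS length P1-P3 (mm)"),
    "ibms_angle": ("float", "IBMS angle to the annular plane (deg)"),
    "d3": ("float", "signed distance of P3 from the annular plane (mm)"),
    "annular_diameter": ("float", "perimeter-derived annular diameter (mm)"),
    "device_type": ("category", "device category: CV | ER/EPRO | LT"),
    "device_size": ("category", "device size id, e.g. 'CV 29'"),
    "sizing_index": ("float", "nominal device diameter / annular diameter"),
    "doi": ("float", "depth of implantation (mm)"),
    "cpmax": ("float", "maximum contact pressure in the ROI (MPa)"),
    "cpi": ("float", "contact pressure index (% of ROI area in contact)"),
    "ca": ("binary", "new conduction abnormality (composite outcome)"),
    "lbbb_rbbb": ("binary", "new left/right bundle branch block"),
    "ppi": ("binary", "new permanent pacemaker implantation"),
}

REQUIRED_COLUMNS = list(COHORT_COLUMNS)


def config_hash(meta: dict) -> str:
    """Short deterministic hash of a provenance/config mapping."""
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_cohort(cohort: pd.DataFrame, path, mode: str = "unknown",
                 seed: int | None = None, extra_meta: dict | None = None) -> None:
    """Write a cohort CSV with a provenance comment header."""
    meta = {"format": "tavica-cohort/1", "version": __version__, "mode": mode,
            "seed": seed, **(extra_meta or {})}
    meta["config_hash"] = config_hash(meta)
    buf = _io.StringIO()
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    cohort.to_csv(buf, index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required column(s): {missing}")
    if df.empty:
        raise ValueError("cohort file contains no rows")
    bad_type = ~df["device_type"].isin(DEVICE_TYPES)
    if bad_type.any():
        row = int(df.index[bad_type][0])
        raise ValueError(
            f"unknown device_type {df.loc[row, 'device_type']!r} at row {row}"
        )
    bad_size = ~df["device_size"].isin(DEVICE_SIZES)
    if bad_size.any():
        row = int(df.index[bad_size][0])
        raise ValueError(
            f"unknown device_size {df.loc[row, 'device_size']!r} at row {row}"
        )
    for col, (kind, _) in COHORT_COLUMNS.items():
        if kind == "float" and not np.isfinite(df[col].to_numpy(dtype=float)).all():
            row = int(df.index[~np.isfinite(df[col].to_numpy(dtype=float))][0])
            raise ValueError(f"non-finite value in column {col!r} at row {row}")
        if kind == "binary" and not df[col].isin([0, 1]).all():
            row = int(df.index[~df[col].isin([0, 1])][0])
            raise ValueError(f"non-binary value in column {col!r} at row {row}")
    if (df["cpi"].lt(0) | df["cpi"].gt(100)).any():
        raise ValueError("cpi outside [0, 100]")
    if df["cpmax"].lt(0).any():
        raise ValueError("negative cpmax")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; provenance lands in ``df.attrs['meta']``."""
    text = Path(path).read_text(encoding="utf-8")
    meta = {}
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if ":" in line:
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
        else:
            break
    body = "".join(lines[body_start:])
    if not body.strip():
        raise ValueError(f"cohort file {path} is empty")
    df = pd.read_csv(_io.StringIO(body))
    _validate(df)
    df.attrs["meta"] = meta
    return df


# ---------------------------------------------------------------------------
# geometry + landmarks config
# ---------------------------------------------------------------------------

def save_geometry(
    geometry: AorticRootGeometry, path,
    landmarks: Landmarks | None = None, plane: AnnularPlane | None = None,
) -> None:
    doc = {
        "units": {"length": "mm", "angle": "degrees", "pressure": "MPa"},
        "geometry": {
            "z": geometry.z.tolist(),
            "theta": geometry.theta.tolist(),
            "r_free": geometry.r_free.tolist(),
            "annular_perimeter": float(geometry.annular_perimeter),
            "wall_stiffness": float(geometry.wall_stiffness),
            "calcifications": [
                {
                    "z": c.z, "theta": c.theta,
                    "angular_half_width": c.angular_half_width,
                    "axial_half_width": c.axial_half_width,
                    "stiffness_multiplier": c.stiffness_multiplier,
                }
                for c in geometry.calcifications
            ],
        },
    }
    if landmarks is not None:
        doc["landmarks"] = {
            "p1": landmarks.p1.tolist(),
            "p3": landmarks.p3.tolist(),
            "p2": landmarks.p2.tolist() if landmarks.p2 is not None else None,
            "rcc_reference_angle": float(landmarks.rcc_reference_angle),
        }
    if plane is not None:
        doc["annular_plane"] = {
            "origin": plane.origin.tolist(),
            "normal": plane.normal.tolist(),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_geometry(path):
    """Load (geometry, landmarks, plane); the latter two may be None."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    g = doc["geometry"]
    geometry = AorticRootGeometry(
        z=np.asarray(g["z"], dtype=float),
        theta=np.asarray(g["theta"], dtype=float),
        r_free=np.asarray(g["r_free"], dtype=float),
        annular_perimeter=float(g["annular_perimeter"]),
        wall_stiffness=float(g["wall_stiffness"]),
        calcifications=[
            CalcificationNodule(
                z=float(c["z"]), theta=float(c["theta"]),
                angular_half_width=float(c["angular_half_width"]),
                axial_half_width=float(c["axial_half_width"]),
                stiffness_multiplier=float(c["stiffness_multiplier"]),
            )
            for c in g.get("calcifications", [])
        ],
    )
    landmarks = None
    if doc.get("landmarks"):
        lm = doc["landmarks"]
        landmarks = Landmarks(
            p1=np.asarray(lm["p1"], dtype=float),
            p3=np.asarray(lm["p3"], dtype=float),
            p2=np.asarray(lm["p2"], dtype=float) if lm.get("p2") is not None else None,
            rcc_reference_angle=float(lm.get("rcc_reference_angle", 90.0)),
        )
    plane = None
    if doc.get("annular_plane"):
        pl = doc["annular_plane"]
        plane = AnnularPlane(
            origin=np.asarray(pl["origin"], dtype=float),
            normal=np.asarray(pl["normal"], dtype=float),
        )
    return geometry, landmarks, plane
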