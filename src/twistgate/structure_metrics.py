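"""Structural geometry: superposition, helix axes, rotation/tilt angles
between two channel states, and a simplified pore-radius profiler.

The pore profiler is a slice-based reimplementation of the classic
sphere-fitting approach: at each position along the channel axis the pore
center is optimized in-plane so as to maximize the clearance

    r(c) = min_i ( |c - atom_i| - vdW_i )

over atoms near the slice, warm-started from the previous slice's center.
It is an approximation of full Monte-Carlo sphere tracing, exact on
cylindrically symmetric geometries (validated on constructed fixtures).

Rotation/tilt sign conventions (used consistently package-wide): the
membrane normal +z points extracellular; a positive rotation about +z
(right-hand rule) appears clockwise when viewed from the intracellular
side; positive tilt change means the helix C-terminal end tilts up
(extracellular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InputError
from .model_io import FrameSequence, MolecularStructure, SeriesTable

__all__ = [
    "PoreProfile",
    "HelixStatePair",
    "BONDI_RADII",
    "superpose",
    "helix_axis",
    "rotation_tilt_angles",
    "pore_radius_profile",
    "min_radius_series",
    "vdw_radii_for",
]

#: Bondi-style element -> van der Waals radius table, nm.
BONDI_RADII = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "F": 0.147, "CL": 0.175,
}
DEFAULT_VDW = 0.170


def vdw_radii_for(structure: MolecularStructure) -> np.ndarray:
    """Per-atom vdW radii: explicit per-atom values if present, else the
    bundled element table."""
    if structure.vdw_radius is not None:
        return np.asarray(structure.vdw_radius, dtype=float)
    return np.array(
        [BONDI_RADII.get(str(e).upper(), DEFAULT_VDW) for e in structure.element]
    )


@dataclass
class PoreProfile:
    """Pore radius samples along the channel axis."""

    z: np.ndarray        # (M,) nm, strictly increasing
    center: np.ndarray   # (M, 2) in-plane center, nm
    radius: np.ndarray   # (M,) nm, >= 0 where defined, NaN where undefined
    defined: np.ndarray  # (M,) bool

    def min_radius(self) -> tuple[float, float]:
        """(r_min, z at r_min) over defined samples."""
        if not np.any(self.defined):
            raise DegenerateGeometryError("profile has no defined samples")
        r = np.where(self.defined, self.radius, np.inf)
        i = int(np.argmin(r))
        return float(self.radius[i]), float(self.z[i])


@dataclass
class HelixStatePair:
    """Signed rotation/tilt change of a helix between two superposed states."""

    rotation_deg: float      # + = clockwise viewed from the intracellular side
    tilt_change_deg: float   # + = tilt-up (C-terminus toward extracellular)
    rmsd: float              # superposition RMSD over the shared scaffold, nm
    axis1: np.ndarray
    axis2: np.ndarray
    tilt1_deg: float = 0.0
    tilt2_deg: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > 180.0 or self.rmsd < 0:
            raise InputError("invalid HelixStatePair")


# ---------------------------------------------------------------------------


def superpose(reference: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping mobile points onto
    the reference frame; R is a proper rotation (det +1).  Points must be
    matched index-by-index (same residue order in both states).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InputError(f"point sets must both be (N, 3); got {ref.shape}, {mob.shape}")
    n = len(ref)
    if n < 3:
        raise DegenerateGeometryError("need >= 3 points for superposition")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise DegenerateGeometryError("reference points are collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    rmsd = float(rssd) / np.sqrt(n)
    return R, t, rmsd


def helix_axis(calpha: np.ndarray) -> np.ndarray:
    """Principal axis of an ordered (N->C) backbone trace, unit length,
    oriented so the N->C direction projects positively onto it."""
    pts = np.asarray(calpha, dtype=float)
    if len(pts) < 5:
        raise DegenerateGeometryError("helix axis needs >= 5 residues")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(pts[-1] - pts[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _signed_inplane_angle(a: np.ndarray, b: np.ndarray, normal: np.ndarray,
                          min_sin: float = np.sin(np.deg2rad(5.0))) -> float:
    """Signed angle (rad) from a to b about +normal, using in-plane
    projections; degenerate if either axis is within 5 deg of the normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    pa = a - np.dot(a, n) * n
    pb = b - np.dot(b, n) * n
    if np.linalg.norm(pa) < min_sin or np.linalg.norm(pb) < min_sin:
        raise DegenerateGeometryError(
            "helix axis within 5 deg of the membrane normal; "
            "in-plane rotation undefined"
        )
    return float(np.arctan2(np.dot(np.cross(pa, pb), n), np.dot(pa, pb)))


def rotation_tilt_angles(helix1: np.ndarray, helix2: np.ndarray,
                         scaffold1: np.ndarray, scaffold2: np.ndarray,
                         normal=(0.0, 0.0, 1.0)) -> HelixStatePair:
    """Rotation and tilt change of a helix between two states.

    State 2 is rigidly superposed onto state 1 via the shared scaffold
    (e.g. the S1-S4 helices); the helix axes are then compared.  Rotation
    is the signed in-plane angle about the membrane normal (+ = clockwise
    from the intracellular side); tilt change is the difference of the
    axis elevations above the membrane plane (+ = tilt-up).
    """
    R, t, rmsd = superpose(np.asarray(scaffold1, float), np.asarray(scaffold2, float))
    h2 = np.asarray(helix2, dtype=float) @ R.T + t
    a1 = helix_axis(helix1)
    a2 = helix_axis(h2)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rot = np.rad2deg(_signed_inplane_angle(a1, a2, n))
    tilt1 = np.rad2deg(np.arcsin(np.clip(np.dot(a1, n), -1, 1)))
    tilt2 = np.rad2deg(np.arcsin(np.clip(np.dot(a2, n), -1, 1)))
    return HelixStatePair(
        rotation_deg=float(rot),
        tilt_change_deg=float(tilt2 - tilt1),
        rmsd=rmsd,
        axis1=a1,
        axis2=a2,
        tilt1_deg=float(tilt1),
        tilt2_deg=float(tilt2),
    )


# ---------------------------------------------------------------------------
# pore profiling


def _slice_radius(center2d: np.ndarray, z: float, pts: np.ndarray,
                  radii: np.ndarray) -> float:
    c = np.array([center2d[0], center2d[1], z])
    d = np.linalg.norm(pts - c, axis=1) - radii
    return float(d.min())


def pore_radius_profile(positions: np.ndarray, axis=(0.0, 0.0, 1.0),
                        z_window: tuple[float, float] | None = None,
                        n_samples: int = 50,
                        neighborhood: float = 0.6,
                        vdw_radii: np.ndarray | None = None,
                        origin=(0.0, 0.0, 0.0)) -> PoreProfile:
    """Pore radius along the channel axis for one frame.

    ``positions`` are atom coordinates (nm) with per-atom ``vdw_radii``;
    coordinates are expressed in a frame whose z is the channel axis.
    For each of ``n_samples`` z positions in ``z_window`` the in-plane
    pore center is optimized (Nelder-Mead, warm-started from the previous
    slice) to maximize the minimum sphere clearance over atoms within
    ``neighborhood`` of the slice along z.  Slices with no nearby atoms
    are flagged undefined rather than reported as zero.
    """
    pts = np.asarray(positions, dtype=float)
    if vdw_radii is None:
        vdw_radii = np.full(len(pts), DEFAULT_VDW)
    vdw_radii = np.asarray(vdw_radii, dtype=float)
    if len(vdw_radii) != len(pts):
        raise InputError("vdw_radii length does not match atom count")
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    # orthonormal frame with third axis = channel axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    basis = np.vstack([e1, e2, a])          # rows: new axes
    local = (pts - np.asarray(origin, float)) @ basis.T
    if z_window is None:
        z_window = (float(local[:, 2].min()), float(local[:, 2].max()))
    zs = np.linspace(z_window[0], z_window[1], n_samples)
    centers = np.full((n_samples, 2), np.nan)
    radii = np.full(n_samples, np.nan)
    defined = np.zeros(n_samples, dtype=bool)
    prev_center: np.ndarray | None = None
    for m, z in enumerate(zs):
        near = np.abs(local[:, 2] - z) <= neighborhood
        if not np.any(near):
            prev_center = None
            continue
        sub, sub_r = local[near], vdw_radii[near]
        start = prev_center if prev_center is not None else sub[:, :2].mean(axis=0)
        res = minimize(
            lambda c: -_slice_radius(c, z, sub, sub_r),
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
        )
        centers[m] = res.x
        radii[m] = max(0.0, -res.fun)
        defined[m] = True
        prev_center = res.x
    return PoreProfile(z=zs, center=centers, radius=radii, defined=defined)


def min_radius_series(frames: FrameSequence, structure: MolecularStructure,
                      axis=(0.0, 0.0, 1.0),
                      gate_window: tuple[float, float] | None = None,
                      n_samples: int = 30, neighborhood: float = 0.6,
                      origin=(0.0, 0.0, 0.0)) -> SeriesTable:
    """Per-frame minimum pore radius within the gate window.

    Frames whose window contains no defined slice get NaN (flagged via
    the table's ``allow_missing``).
    """
    frames.check_against(structure)
    radii = vdw_radii_for(structure)
    out_t, out_r, out_z = [], [], []
    for f in range(frames.n_frames):
        profile = pore_radius_profile(
            frames.positions[f], axis=axis, z_window=gate_window,
            n_samples=n_samples, neighborhood=neighborhood,
            vdw_radii=radii, origin=origin,
        )
        out_t.append(frames.times[f])
        if np.any(profile.defined):
            r, z = profile.min_radius()
            out_r.append(r)
            out_z.append(z)
        else:
            out_r.append(np.nan)
            out_z.append(np.nan)
    df = pd.DataFrame({"time": out_t, "r_min": out_r, "z_min": out_z})
    return SeriesTable(df, units={"time": "ps", "r_min": "nm", "z_min": "nm"},
                       allow_missing=True)
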