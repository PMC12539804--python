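"""Mechanical readouts: local frames, force decomposition, torque,
rotation/length series, and the elasticity fits of the ankyrin-repeat
spring.

The two elastic constants of the twist-to-open model are obtained here:

* torsion coefficient c from the linear law M = c * phi (torque applied
  to both ends of the AR bundle vs. mean twist of its lower block),
  fitted through the origin because the law has no intercept;
* compression-twist coupling k_ct from L = L0 - k_ct * phi (bundle
  length vs. twist); k_ct > 0 means the bundle shortens as it twists.

Sign convention everywhere: the membrane normal +z points extracellular;
positive torque/rotation about +z (right-hand rule) appears clockwise
when viewed from the intracellular side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, FitError, InputError, SelectionError
from .model_io import FrameSequence, MolecularStructure, SeriesTable, select_group
from .structure_metrics import helix_axis
from .units import convert_force  # re-exported: unit boundary lives in units

__all__ = [
    "LocalFrame",
    "ElasticityFit",
    "build_local_frame",
    "decompose_force",
    "torque_about_axis",
    "rotation_angle",
    "ar_length",
    "fit_torsion_coefficient",
    "fit_compression_twist",
    "convert_force",
]


@dataclass
class LocalFrame:
    """Right-handed orthonormal frame attached to one subunit.

    x points from the pore center outward along the TRP helix direction,
    z is the membrane normal (extracellular positive), y = z cross x.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for ax in (self.x_axis, self.y_axis, self.z_axis):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise InputError("frame axes must be unit length")
        if np.linalg.norm(np.cross(self.x_axis, self.y_axis) - self.z_axis) > 1e-9:
            raise InputError("frame must be right-handed (x cross y = z)")


@dataclass
class ElasticityFit:
    """A fitted elastic constant with its standard error.

    ``kind`` is "torsion" (estimate = c, kJ/mol/rad) or
    "compression_twist" (estimate = k_ct, nm/rad).
    """

    kind: str
    estimate: float
    stderr: float
    n: int
    residuals: np.ndarray
    intercept: float | None = None
    extension_coupled: bool = False

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise FitError("standard error must be >= 0")

    @property
    def residual_rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if self.n else 0.0


# ---------------------------------------------------------------------------
# frames & decomposition


def build_local_frame(structure: MolecularStructure, chain: str,
                      trp_selector: str, pore_axis=(0.0, 0.0, 1.0),
                      center: np.ndarray | None = None) -> LocalFrame:
    """Per-subunit frame from the TRP helix geometry.

    z = membrane normal; x = the TRP-helix axis component perpendicular
    to z, sign-oriented from the pore center toward the helix centroid
    (pore -> membrane); y completes the right-handed set.  The helix axis
    is the principal axis of the selection's CA atoms (all atoms if no CA
    present), oriented N->C.
    """
    ids = select_group(structure, f"chain {chain} and {trp_selector}")
    idx = structure.index_of(ids)
    ca = idx[np.asarray([structure.atom_name[i] == "CA" for i in idx])]
    use = ca if len(ca) >= 5 else idx
    pts = structure.positions[use]
    if len(pts) < 5:
        raise SelectionError("TRP helix selection has fewer than 5 atoms")
    axis = helix_axis(pts)
    z = np.asarray(pore_axis, dtype=float)
    z = z / np.linalg.norm(z)
    if center is None:
        center = structure.positions.mean(axis=0)
    center = np.asarray(center, dtype=float)
    x = axis - np.dot(axis, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise DegenerateGeometryError("TRP helix axis is parallel to the pore axis")
    x = x / nx
    centroid = pts.mean(axis=0)
    radial = centroid - center
    radial -= np.dot(radial, z) * z
    if np.dot(x, radial) < 0:
        x = -x
    y = np.cross(z, x)
    return LocalFrame(origin=centroid, x_axis=x, y_axis=y, z_axis=z)


def decompose_force(force, frame: LocalFrame) -> tuple[np.ndarray, float]:
    """Split a force vector into membrane-parallel (x', y') components and
    the membrane-normal (z') scalar; the decomposition is exactly
    invertible since the frame is orthonormal."""
    f = np.asarray(force, dtype=float)
    parallel = np.array([np.dot(f, frame.x_axis), np.dot(f, frame.y_axis)])
    normal = float(np.dot(f, frame.z_axis))
    return parallel, normal


def torque_about_axis(applications, axis, origin=(0.0, 0.0, 0.0)) -> float:
    """Total torque (kJ/mol) of point forces about an axis through origin.

    ``applications`` is an iterable of (point nm, force kJ/mol/nm).
    Positive values mean the torque vector points along +axis — with the
    membrane normal as axis, toward the extracellular side, driving
    rotation that appears clockwise from the intracellular side.
    """
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if abs(n - 1.0) > 1e-9:
        raise InputError("axis must be unit-norm")
    o = np.asarray(origin, dtype=float)
    total = 0.0
    for point, force in applications:
        lever = np.asarray(point, dtype=float) - o
        total += float(np.dot(np.cross(lever, np.asarray(force, float)), a))
    return total


# ---------------------------------------------------------------------------
# trajectory readouts


def rotation_angle(frames: FrameSequence, group: np.ndarray,
                   reference: int = 0, axis=(0.0, 0.0, 1.0),
                   origin=(0.0, 0.0, 0.0)) -> SeriesTable:
    """Mean rotation angle of an atom group about a fixed axis, per frame.

    Uses the in-plane least-squares ("norm method") closed form: with
    a_i, b_i the in-plane components of reference and current positions
    relative to the axis origin,

        phi = atan2( sum_i (a_i x b_i) . n,  sum_i a_i . b_i )

    which minimizes sum_i |R(phi) a_i - b_i|^2 over phi.  Angles are
    unwrapped across frames for continuity.
    """
    group = np.asarray(group, dtype=int)
    if len(group) < 2:
        raise InputError("rotation group needs >= 2 atoms")
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    o = np.asarray(origin, dtype=float)

    def inplane(pos: np.ndarray) -> np.ndarray:
        rel = pos[group] - o
        return rel - np.outer(rel @ n, n)

    a = inplane(frames.positions[reference])
    if np.linalg.norm(a, axis=1).max() < 1e-9:
        raise DegenerateGeometryError("all group atoms lie on the rotation axis")
    phis = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        b = inplane(frames.positions[f])
        s = float(np.sum(np.cross(a, b) @ n))
        c = float(np.sum(np.einsum("ij,ij->i", a, b)))
        phis[f] = np.arctan2(s, c)
    phis = np.unwrap(phis)
    df = pd.DataFrame({"time": frames.times, "phi": phis})
    return SeriesTable(df, units={"time": "ps", "phi": "rad"})


def ar_length(frames: FrameSequence, lh_group: np.ndarray,
              ar8_group: np.ndarray) -> SeriesTable:
    """Distance between the (mass-unweighted) centroids of two groups,
    per frame — the bundle-length readout L(t)."""
    lh = np.asarray(lh_group, dtype=int)
    ar8 = np.asarray(ar8_group, dtype=int)
    if len(lh) == 0 or len(ar8) == 0:
        raise InputError("centroid groups must be non-empty")
    c1 = frames.positions[:, lh].mean(axis=1)
    c2 = frames.positions[:, ar8].mean(axis=1)
    dist = np.linalg.norm(c1 - c2, axis=1)
    df = pd.DataFrame({"time": frames.times, "L": dist})
    return SeriesTable(df, units={"time": "ps", "L": "nm"})


# ---------------------------------------------------------------------------
# elasticity fits


def fit_torsion_coefficient(points, with_intercept: bool = False) -> ElasticityFit:
    """Fit the torsion law M = c * phi.

    ``points`` is a sequence of (phi rad, M kJ/mol) window means.  The
    default fit is origin-constrained (the law has no intercept); an
    intercept is available for diagnostics only.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise FitError("need >= 2 (phi, M) points")
    phi, m = pts[:, 0], pts[:, 1]
    if np.allclose(phi, 0.0):
        raise FitError("all twist angles are zero; torsion fit undefined")
    if with_intercept:
        design = np.column_stack([phi, np.ones_like(phi)])
        coef, *_ = np.linalg.lstsq(design, m, rcond=None)
        c, b = float(coef[0]), float(coef[1])
        resid = m - (c * phi + b)
        dof = max(len(pts) - 2, 1)
        se = float(np.sqrt(np.sum(resid**2) / dof /
                           np.sum((phi - phi.mean()) ** 2)))
        return ElasticityFit("torsion", c, se, len(pts), resid, intercept=b)
    c = float(np.sum(phi * m) / np.sum(phi * phi))
    resid = m - c * phi
    dof = max(len(pts) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / np.sum(phi * phi)))
    return ElasticityFit("torsion", c, se, len(pts), resid)


def fit_compression_twist(points) -> ElasticityFit:
    """Fit the coupling law L = L0 - k_ct * phi.

    ``points`` is a sequence of (phi rad, L nm).  k_ct is positive when
    the bundle shortens with increasing twist; a negative value is
    flagged ``extension_coupled``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise FitError("need >= 2 (phi, L) points")
    phi, length = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((phi - phi.mean()) ** 2))
    if sxx < 1e-30:
        raise FitError("twist angles are all identical; coupling fit undefined")
    slope = float(np.sum((phi - phi.mean()) * (length - length.mean())) / sxx)
    l0 = float(length.mean() - slope * phi.mean())
    resid = length - (l0 + slope * phi)
    dof = max(len(pts) - 2, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    k_ct = -slope
    return ElasticityFit(
        "compression_twist", k_ct, se, len(pts), resid,
        intercept=l0, extension_coupled=k_ct < 0,
    )
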