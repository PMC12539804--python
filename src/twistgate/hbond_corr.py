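"""Hydrogen-bond occupancy and force/occupancy correlation analysis.

The analysis mirrors the force-transmission question for the ankyrin
repeat (AR) bundle: does the spatial pattern of non-bonded residue-pair
net forces track the hydrogen bonding network?  Residue-pair H-bond
occupancies and net-force magnitudes form two symmetric residue x residue
matrices; dividing both into AR-unit sub-blocks and correlating each
block pair yields a unit x unit Pearson grid whose diagonal (intra-AR)
and first off-diagonals (inter-AR) summarize the coupling.

H-bond geometric criteria default to donor-acceptor distance <= 0.35 nm
and hydrogen-donor-acceptor angle <= 30 deg, the common trajectory-
analysis convention; both are configurable and recorded in output
metadata by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, MappingError
from .model_io import FrameSequence, MolecularStructure
from .net_fda import NetForceTable
from .pairwise_forces import ResidueKey
from .units import KJ_MOL_NM_TO_PN

__all__ = [
    "HBondRoles",
    "OccupancyMatrix",
    "CorrelationGrid",
    "detect_hbonds",
    "occupancy_matrix",
    "force_magnitude_matrix",
    "grouped_pcc",
    "diagonal_summary",
]


@dataclass
class HBondRoles:
    """Donor/acceptor role assignment (0-based atom indices).

    ``donors`` pairs each donor heavy atom with its attached hydrogen —
    a donor without a hydrogen cannot be expressed, which is the point.
    """

    donors: list[tuple[int, int]] = field(default_factory=list)   # (D, H)
    acceptors: list[int] = field(default_factory=list)

    def validate(self, n_atoms: int) -> None:
        for d, h in self.donors:
            if not (0 <= d < n_atoms and 0 <= h < n_atoms):
                raise InputError(f"donor pair ({d},{h}) out of range")
            if d == h:
                raise InputError(f"donor {d} lists itself as its hydrogen")
        for a in self.acceptors:
            if not 0 <= a < n_atoms:
                raise InputError(f"acceptor {a} out of range")


@dataclass
class OccupancyMatrix:
    """Symmetric residue x residue H-bond occupancy fractions in [0, 1]."""

    residues: list[ResidueKey]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.residues)
        if m.shape != (n, n):
            raise InputError("occupancy matrix shape mismatch")
        if np.any(m < 0) or np.any(m > 1):
            raise InputError("occupancies must lie in [0, 1]")
        if not np.allclose(m, m.T):
            raise InputError("occupancy matrix must be symmetric")


@dataclass
class CorrelationGrid:
    """Unit x unit Pearson correlations with per-block sample counts.

    Undefined blocks (too few pairs, or zero variance) are NaN.
    """

    units: list[str]
    pcc: np.ndarray
    n: np.ndarray


def detect_hbonds(positions: np.ndarray, roles: HBondRoles,
                  d_max: float = 0.35, angle_max_deg: float = 30.0) -> set:
    """Hydrogen bonds present in one frame.

    A (donor, acceptor) pair is reported iff the donor-acceptor distance
    is <= ``d_max`` (nm) and the H-donor-acceptor angle is <=
    ``angle_max_deg``.  Symmetric under any relabeling that preserves
    the role assignment.
    """
    pos = np.asarray(positions, dtype=float)
    roles.validate(len(pos))
    cos_min = np.cos(np.deg2rad(angle_max_deg))
    found: set[tuple[int, int]] = set()
    for d, h in roles.donors:
        for a in roles.acceptors:
            if a == d or a == h:
                continue
            da = pos[a] - pos[d]
            dist = float(np.linalg.norm(da))
            if dist > d_max or dist == 0.0:
                continue
            dh = pos[h] - pos[d]
            nh = float(np.linalg.norm(dh))
            if nh == 0.0:
                continue
            cos_angle = float(np.dot(dh, da) / (nh * dist))
            if cos_angle >= cos_min:  # angle <= angle_max
                found.add((d, a))
    return found


def occupancy_matrix(frames: FrameSequence, structure: MolecularStructure,
                     roles: HBondRoles,
                     residues: list[ResidueKey] | None = None,
                     d_max: float = 0.35,
                     angle_max_deg: float = 30.0) -> OccupancyMatrix:
    """Fraction of frames with >= 1 H-bond between each residue pair.

    Bonds in either donor->acceptor direction count; residues outside
    ``residues`` (default: all residues of the structure) are ignored.
    """
    frames.check_against(structure)
    if frames.n_frames == 0:
        raise InputError("need >= 1 frame")
    if residues is None:
        residues = structure.residue_keys()
    if not residues:
        raise InputError("empty residue range")
    index = {r: i for i, r in enumerate(residues)}
    atom_res = [
        (str(structure.chain_id[i]), int(structure.residue_id[i]))
        for i in range(structure.n_atoms)
    ]
    counts = np.zeros((len(residues), len(residues)))
    for f in range(frames.n_frames):
        bonds = detect_hbonds(frames.positions[f], roles, d_max, angle_max_deg)
        seen_pairs: set[tuple[int, int]] = set()
        for d, a in bonds:
            ri, rj = atom_res[d], atom_res[a]
            if ri == rj or ri not in index or rj not in index:
                continue
            i, j = sorted((index[ri], index[rj]))
            seen_pairs.add((i, j))
        for i, j in seen_pairs:
            counts[i, j] += 1
            counts[j, i] += 1
    return OccupancyMatrix(residues=list(residues),
                           matrix=counts / frames.n_frames)


def force_magnitude_matrix(net: NetForceTable,
                           residues: list[ResidueKey],
                           classes=("coulomb", "lj")) -> np.ndarray:
    """Symmetric residue x residue matrix of net-force magnitudes in pN.

    Each entry is the Euclidean norm of the summed selected-class net
    vector for that pair (norms are invariant to the antisymmetric pair
    ordering, so the matrix is symmetric by construction).
    """
    index = {r: i for i, r in enumerate(residues)}
    out = np.zeros((len(residues), len(residues)))
    for (ri, rj), classed in net.entries.items():
        if ri not in index or rj not in index:
            continue
        vec = np.zeros(3)
        for cls in classes:
            if cls in classed:
                vec = vec + classed[cls]
        mag = float(np.linalg.norm(vec)) * KJ_MOL_NM_TO_PN
        i, j = index[ri], index[rj]
        out[i, j] = out[j, i] = mag
    return out


def grouped_pcc(a: np.ndarray, b: np.ndarray, labels,
                min_pairs: int = 2) -> CorrelationGrid:
    """Blockwise Pearson correlation of two residue x residue matrices.

    ``labels`` assigns a unit label (e.g. the AR unit) to each matrix
    row; for every unit pair (u, v) the entries of the corresponding
    sub-blocks of ``a`` and ``b`` are vectorized and correlated.
    Diagonal (self-pair) matrix entries are excluded.  Blocks with fewer
    than ``min_pairs`` entries or zero variance in either vector are NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError(f"matrices must be square and same shape; got {a.shape}, {b.shape}")
    labels = list(labels)
    if len(labels) != a.shape[0]:
        raise MappingError("labels must cover every matrix row")
    units: list[str] = []
    for lab in labels:
        if lab not in units:
            units.append(lab)
    rows = {u: np.array([i for i, lab in enumerate(labels) if lab == u]) for u in units}
    nu = len(units)
    pcc = np.full((nu, nu), np.nan)
    counts = np.zeros((nu, nu), dtype=int)
    for ui, u in enumerate(units):
        for vi, v in enumerate(units):
            ri, rj = rows[u], rows[v]
            block_a = a[np.ix_(ri, rj)].ravel()
            block_b = b[np.ix_(ri, rj)].ravel()
            if ui == vi:
                keep = ~np.eye(len(ri), dtype=bool).ravel()
                block_a, block_b = block_a[keep], block_b[keep]
            counts[ui, vi] = len(block_a)
            if len(block_a) < min_pairs:
                continue
            if np.std(block_a) == 0 or np.std(block_b) == 0:
                continue
            pcc[ui, vi] = float(np.corrcoef(block_a, block_b)[0, 1])
    return CorrelationGrid(units=units, pcc=pcc, n=counts)


def diagonal_summary(grid: CorrelationGrid) -> dict:
    """Intra-unit (diagonal) and inter-unit (first off-diagonal) statistics.

    Returns mean/sd over the defined diagonal and the defined super/sub-
    diagonal entries, plus the counts of excluded (undefined) entries.
    """
    m = grid.pcc
    if m.shape[0] < 2:
        raise InputError("grid must be at least 2x2")
    diag = np.diag(m)
    off = np.concatenate([np.diag(m, 1), np.diag(m, -1)])
    diag_ok = diag[~np.isnan(diag)]
    off_ok = off[~np.isnan(off)]
    if len(diag_ok) == 0:
        raise InputError("all diagonal entries undefined")
    return {
        "intra_mean": float(np.mean(diag_ok)),
        "intra_sd": float(np.std(diag_ok)),
        "intra_excluded": int(np.isnan(diag).sum()),
        "inter_mean": float(np.mean(off_ok)) if len(off_ok) else float("nan"),
        "inter_sd": float(np.std(off_ok)) if len(off_ok) else float("nan"),
        "inter_excluded": int(np.isnan(off).sum()),
    }
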