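"""Pairwise force engine (force distribution analysis).

Computes, for given trajectory frames, the force each residue exerts on
each other residue, resolved by interaction class (bonded, Coulomb,
Lennard-Jones).  Atomic pair forces are evaluated analytically and summed
over the atoms of the two residues; multi-atom bonded terms (angles,
dihedrals) are decomposed into central pairwise contributions whose sum
reproduces every atom's force from that term exactly.

Electrostatics here are short-range switched pairwise only.  A
reciprocal-space (PME) contribution has no pairwise decomposition and is
deliberately out of scope; analyses built on condition differences are
insensitive to this at short range but absolute Coulomb forces beyond the
cutoff are not represented.

The switched potential multiplies U(r) by a quintic smoothstep S(r) that
falls from 1 at the switch-on radius to 0 at the cutoff with zero slope at
both ends, so the reported force -d(U*S)/dr is continuous everywhere and
exactly zero beyond the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DegenerateGeometryError, ParameterError
from .model_io import FrameSequence, InteractionParameters, MolecularStructure
from .units import KE_COULOMB

__all__ = [
    "PairForceTable",
    "coulomb_pair_force",
    "lj_pair_force",
    "bonded_pair_forces",
    "atomic_pair_forces",
    "residue_pairwise_forces",
    "combine_lj",
]

CLASSES = ("bonded", "coulomb", "lj")

ResidueKey = tuple[str, int]
PairKey = tuple[ResidueKey, ResidueKey]


@dataclass
class PairForceTable:
    """Per-frame residue-residue force vectors, classed by interaction.

    ``forces[(ri, rj)][cls]`` is an (n_frames, 3) array holding the force
    exerted ON ri BY rj, in kJ mol^-1 nm^-1, with ri < rj by (chain,
    resid).  The reverse force is the exact negation and is not stored.
    """

    residues: list[ResidueKey]
    n_frames: int
    forces: dict[PairKey, dict[str, np.ndarray]] = field(default_factory=dict)
    times: np.ndarray | None = None

    def add(self, ri: ResidueKey, rj: ResidueKey, cls: str, frame: int, vec) -> None:
        key, sign = self.canonical(ri, rj)
        entry = self.forces.setdefault(key, {})
        arr = entry.setdefault(cls, np.zeros((self.n_frames, 3)))
        arr[frame] += sign * np.asarray(vec, dtype=float)

    @staticmethod
    def canonical(ri: ResidueKey, rj: ResidueKey) -> tuple[PairKey, float]:
        if ri == rj:
            raise ValueError("self-pairs are not stored")
        return ((ri, rj), 1.0) if ri < rj else ((rj, ri), -1.0)

    def get(self, ri: ResidueKey, rj: ResidueKey, cls: str | None = None) -> np.ndarray:
        """Force on ri by rj, (n_frames, 3); zero array if absent."""
        key, sign = self.canonical(ri, rj)
        entry = self.forces.get(key, {})
        if cls is not None:
            arr = entry.get(cls)
            return sign * arr if arr is not None else np.zeros((self.n_frames, 3))
        total = np.zeros((self.n_frames, 3))
        for arr in entry.values():
            total += arr
        return sign * total


# ---------------------------------------------------------------------------
# switching


def _switch(r: float, r_on: float, r_off: float) -> tuple[float, float]:
    """Quintic smoothstep S(r) and dS/dr on [r_on, r_off]."""
    if r <= r_on:
        return 1.0, 0.0
    if r >= r_off:
        return 0.0, 0.0
    t = (r - r_on) / (r_off - r_on)
    s = 1.0 - t * t * t * (10.0 - 15.0 * t + 6.0 * t * t)
    ds = -30.0 * t * t * (1.0 - t) ** 2 / (r_off - r_on)
    return s, ds


def _switched_force(r_vec: np.ndarray, u: float, dudr: float,
                    r: float, r_on: float, r_off: float) -> np.ndarray:
    """Force on atom i for U_sw = U(r) S(r), with r_vec = r_i - r_j."""
    if r >= r_off:
        return np.zeros(3)
    s, ds = _switch(r, r_on, r_off)
    fmag = -(dudr * s + u * ds)  # force along +r_vec when positive
    return fmag * (r_vec / r)


# ---------------------------------------------------------------------------
# nonbonded pair forces


def coulomb_pair_force(qi: float, qj: float, r_vec, switch_on: float = 1.0,
                       cutoff: float = 1.2) -> np.ndarray:
    """Switched Coulomb force on atom i from atom j (r_vec = r_i - r_j, nm).

    Below the switch-on radius the magnitude is ke*qi*qj/r^2 with
    ke = 138.935458 kJ mol^-1 nm e^-2; it goes smoothly to zero at the
    cutoff.  Positive along +r_vec for like charges (repulsion).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise DegenerateGeometryError("zero separation in Coulomb pair")
    if qi == 0.0 or qj == 0.0 or r >= cutoff:
        return np.zeros(3)
    u = KE_COULOMB * qi * qj / r
    dudr = -KE_COULOMB * qi * qj / r**2
    return _switched_force(r_vec, u, dudr, r, switch_on, cutoff)


def lj_pair_force(sigma_ij: float, epsilon_ij: float, r_vec,
                  switch_on: float = 1.0, cutoff: float = 1.2) -> np.ndarray:
    """Switched 12-6 Lennard-Jones force on atom i from atom j.

    Below switch-on: 24*eps*(2*(sigma/r)^12 - (sigma/r)^6)/r along r_vec.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise DegenerateGeometryError("zero separation in LJ pair")
    if epsilon_ij == 0.0 or r >= cutoff:
        return np.zeros(3)
    sr6 = (sigma_ij / r) ** 6
    u = 4.0 * epsilon_ij * (sr6 * sr6 - sr6)
    dudr = -24.0 * epsilon_ij * (2.0 * sr6 * sr6 - sr6) / r
    return _switched_force(r_vec, u, dudr, r, switch_on, cutoff)


def combine_lj(sigma_i: float, sigma_j: float, eps_i: float, eps_j: float,
               rule: str = "lorentz-berthelot") -> tuple[float, float]:
    """Combination rule for unlike LJ pairs; Lorentz–Berthelot default."""
    if rule == "lorentz-berthelot":
        return 0.5 * (sigma_i + sigma_j), float(np.sqrt(eps_i * eps_j))
    if rule == "geometric":
        return float(np.sqrt(sigma_i * sigma_j)), float(np.sqrt(eps_i * eps_j))
    raise ParameterError(f"unknown combination rule {rule!r}")


# ---------------------------------------------------------------------------
# bonded terms: analytic atomic forces


def _bond_forces(pos: np.ndarray, i: int, j: int, k: float, r0: float):
    r_vec = pos[i] - pos[j]
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise DegenerateGeometryError(f"zero bond length between atoms {i},{j}")
    fmag = -k * (r - r0)  # along +r_vec on i; attractive when stretched
    f_i = fmag * r_vec / r
    return {i: f_i, j: -f_i}


def _angle_forces(pos: np.ndarray, i: int, j: int, k: int,
                  k_theta: float, theta0: float):
    """Harmonic angle U = 1/2 k (theta - theta0)^2 with vertex j."""
    rij = pos[i] - pos[j]
    rkj = pos[k] - pos[j]
    nij = float(np.linalg.norm(rij))
    nkj = float(np.linalg.norm(rkj))
    cos_t = float(np.dot(rij, rkj) / (nij * nkj))
    cos_t = min(1.0, max(-1.0, cos_t))
    theta = float(np.arccos(cos_t))
    sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 0.0)))
    if sin_t < 1e-12:
        # collinear: dU/dtheta is zero at theta0 = 0/pi; otherwise undefined
        if abs(theta - theta0) < 1e-9:
            return {i: np.zeros(3), j: np.zeros(3), k: np.zeros(3)}
        raise DegenerateGeometryError(f"collinear angle term {i}-{j}-{k}")
    dudtheta = k_theta * (theta - theta0)
    dti = (cos_t * rij / nij - rkj / nkj) / (nij * sin_t)
    dtk = (cos_t * rkj / nkj - rij / nij) / (nkj * sin_t)
    f_i = -dudtheta * dti
    f_k = -dudtheta * dtk
    return {i: f_i, j: -(f_i + f_k), k: f_k}


def _dihedral_forces(pos: np.ndarray, i: int, j: int, k: int, l: int,
                     k_phi: float, mult: int, phi0: float):
    """Periodic dihedral U = k (1 + cos(n*phi - phi0))."""
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if n1sq < 1e-18 or n2sq < 1e-18 or nb2 < 1e-12:
        raise DegenerateGeometryError(f"degenerate dihedral {i}-{j}-{k}-{l}")
    phi = float(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    dudphi = -k_phi * mult * np.sin(mult * phi - phi0)
    dphi_i = -(nb2 / n1sq) * n1
    dphi_l = (nb2 / n2sq) * n2
    c12 = float(np.dot(b1, b2)) / (nb2 * nb2)
    c32 = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_j = -(1.0 + c12) * dphi_i + c32 * dphi_l
    dphi_k = -(1.0 + c32) * dphi_l + c12 * dphi_i
    return {
        i: -dudphi * dphi_i,
        j: -dudphi * dphi_j,
        k: -dudphi * dphi_k,
        l: -dudphi * dphi_l,
    }


def _central_decomposition(pos: np.ndarray, atom_forces: dict[int, np.ndarray]):
    """Decompose a zero-net-force, zero-net-torque atomic force set into
    central pairwise forces over the participating atoms.

    For <= 4 atoms such a decomposition always exists; the linear system
    is solved in the least-squares sense and the reconstruction is exact
    (checked by the caller's tests).  Returns {(a, b): vec} meaning the
    force on a exerted by b (a < b stored once; reverse is negation).
    """
    atoms = sorted(atom_forces)
    pairs = [(a, b) for ai, a in enumerate(atoms) for b in atoms[ai + 1:]]
    units = {}
    for a, b in pairs:
        d = pos[a] - pos[b]
        n = np.linalg.norm(d)
        units[(a, b)] = d / n if n > 0 else np.zeros(3)
    # rows: 3 per atom; cols: one scalar per pair
    mat = np.zeros((3 * len(atoms), len(pairs)))
    rhs = np.concatenate([atom_forces[a] for a in atoms])
    for col, (a, b) in enumerate(pairs):
        ia, ib = atoms.index(a), atoms.index(b)
        mat[3 * ia : 3 * ia + 3, col] = units[(a, b)]
        mat[3 * ib : 3 * ib + 3, col] = -units[(a, b)]
    scalars, *_ = np.linalg.lstsq(mat, rhs, rcond=None)
    return {pair: s * units[pair] for pair, s in zip(pairs, scalars)}


def bonded_pair_forces(params: InteractionParameters, positions) -> dict:
    """All bonded pairwise force contributions for one frame.

    Returns {(i, j): vec} with i < j, vec = force on i by j in
    kJ mol^-1 nm^-1, summed over bond, angle and dihedral terms.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    out: dict[tuple[int, int], np.ndarray] = {}

    def accumulate(pairmap: dict) -> None:
        for (a, b), vec in pairmap.items():
            key = (a, b) if a < b else (b, a)
            sign = 1.0 if a < b else -1.0
            out[key] = out.get(key, np.zeros(3)) + sign * vec

    for i, j, k, r0 in params.bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ParameterError(f"bond references invalid atom index ({i},{j})")
        af = _bond_forces(pos, i, j, k, r0)
        accumulate({(i, j): af[i]})
    for i, j, k, kt, t0 in params.angles:
        for idx in (i, j, k):
            if not 0 <= idx < n:
                raise ParameterError(f"angle references invalid atom index {idx}")
        af = _angle_forces(pos, i, j, k, kt, t0)
        if all(np.allclose(f, 0.0) for f in af.values()):
            continue
        accumulate(_central_decomposition(pos, af))
    for i, j, k, l, kp, mult, p0 in params.dihedrals:
        for idx in (i, j, k, l):
            if not 0 <= idx < n:
                raise ParameterError(f"dihedral references invalid atom index {idx}")
        af = _dihedral_forces(pos, i, j, k, l, kp, mult, p0)
        accumulate(_central_decomposition(pos, af))
    return out


# ---------------------------------------------------------------------------
# exclusions


def build_exclusions(params: InteractionParameters) -> set[tuple[int, int]]:
    """Atom pairs removed from the nonbonded sums under the policy.

    "1-2" excludes directly bonded pairs, "1-3" pairs two bonds apart,
    "1-4" pairs three bonds apart (kept by default).
    """
    depth_of = {"1-2": 1, "1-3": 2, "1-4": 3}
    max_depth = max((depth_of[p] for p in params.exclusions if p in depth_of), default=0)
    if max_depth == 0:
        return set()
    adj: dict[int, set[int]] = {}
    for i, j, *_ in params.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    wanted_depths = {depth_of[p] for p in params.exclusions if p in depth_of}
    excluded: set[tuple[int, int]] = set()
    for start in adj:
        dist = {start: 0}
        frontier = [start]
        for d in range(1, max_depth + 1):
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d in wanted_depths and start < v:
                excluded.add((start, v))
    return excluded


# ---------------------------------------------------------------------------
# full evaluation


def atomic_pair_forces(structure: MolecularStructure, positions,
                       params: InteractionParameters,
                       combination_rule: str = "lorentz-berthelot") -> dict:
    """All atomic pairwise forces for one frame.

    Returns {(i, j): {"bonded"|"coulomb"|"lj": vec}} with i < j and vec =
    force on atom i by atom j.  Nonbonded pairs honour the exclusion
    policy and cutoff of ``params``.
    """
    pos = np.asarray(positions, dtype=float)
    n = structure.n_atoms
    if params.n_atoms != n:
        raise ParameterError(
            f"parameters cover {params.n_atoms} atoms, structure has {n}"
        )
    out: dict[tuple[int, int], dict[str, np.ndarray]] = {}
    for (i, j), vec in bonded_pair_forces(params, pos).items():
        out.setdefault((i, j), {})["bonded"] = vec
    excluded = build_exclusions(params)
    # O(n^2) double loop in numpy: desk-scale systems only
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] < params.cutoff
    for i, j in zip(iu[within], ju[within]):
        i, j = int(i), int(j)
        if (i, j) in excluded:
            continue
        r_vec = diff[i, j]
        fc = coulomb_pair_force(params.charge[i], params.charge[j], r_vec,
                                params.switch_on, params.cutoff)
        sig, eps = combine_lj(params.lj_sigma[i], params.lj_sigma[j],
                              params.lj_epsilon[i], params.lj_epsilon[j],
                              combination_rule)
        fl = lj_pair_force(sig, eps, r_vec, params.switch_on, params.cutoff)
        if np.any(fc):
            out.setdefault((i, j), {})["coulomb"] = fc
        if np.any(fl):
            out.setdefault((i, j), {})["lj"] = fl
    return out


def residue_pairwise_forces(structure: MolecularStructure,
                            frames: FrameSequence | np.ndarray,
                            params: InteractionParameters,
                            combination_rule: str = "lorentz-berthelot") -> PairForceTable:
    """Residue-residue pairwise forces for every frame (the FDA table).

    Sums atomic pair contributions within each residue pair, keeping the
    bonded / Coulomb / LJ classes separate and every frame stored.
    """
    if isinstance(frames, FrameSequence):
        frames.check_against(structure)
        all_pos = frames.positions
        times = frames.times
    else:
        all_pos = np.asarray(frames, dtype=float)
        if all_pos.ndim == 2:
            all_pos = all_pos[None]
        times = np.arange(len(all_pos), dtype=float)
    res_keys = structure.residue_keys()
    atom_res = [
        (str(structure.chain_id[i]), int(structure.residue_id[i]))
        for i in range(structure.n_atoms)
    ]
    table = PairForceTable(residues=res_keys, n_frames=len(all_pos), times=times)
    for f in range(len(all_pos)):
        for (i, j), classed in atomic_pair_forces(
            structure, all_pos[f], params, combination_rule
        ).items():
            ri, rj = atom_res[i], atom_res[j]
            if ri == rj:
                continue  # intra-residue forces are not pairwise entries
            for cls, vec in classed.items():
                table.add(ri, rj, cls, f, vec)
    return table
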