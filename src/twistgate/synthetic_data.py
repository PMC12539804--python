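"""Synthetic fixtures emulating the study conditions of the gating analysis.

Every generator is deterministic given the seed and returns a truth
manifest recording exactly what was injected, so analyses can be checked
against known ground truth:

* toy interacting systems for the force engine (brute-force friendly);
* paired "forced"/"free" pairwise-force series with a known injected
  difference, emulating the compressive vs. free trajectory pairs that
  feed the condition-difference (net-FDA) analysis;
* a C4-symmetric four-chain channel with radial TRP helices and a
  central pore;
* a bead-spring helical AR bundle whose twist windows follow the steered
  rotation protocol (2.5 deg snapshots, torque and length readouts) with
  prescribed torsion coefficient c and compression-twist coupling k_ct —
  the generator defaults are the fitted values of the study
  (c = 2300 kJ/mol/rad, k_ct = 1.32 nm/rad);
* donor-acceptor geometries with prescribed per-pair H-bond occupancy
  (defaults 0.57/0.71/0.24, the printed occupancies of the three
  LH-TRP interface bonds);
* cylindrical pores with known radius profiles, including a gate that
  dilates linearly through the 0.2 nm opening threshold;
* helix pairs on a rigid scaffold with known rotation/tilt angles.

The bead-spring bundle applies twist as a rigid rotation of the lower
block and compression as axial scaling, mirroring the two controlled
ends of the rotation protocol (lower block driven, upper end restrained).
Noise scales are relative to signal so tolerance statements are
scale-free.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .hbond_corr import HBondRoles
from .model_io import (
    DomainMap,
    FrameSequence,
    InteractionParameters,
    MolecularStructure,
    SeriesTable,
)
from .pairwise_forces import PairForceTable

__all__ = [
    "GeneratorConfig",
    "make_toy_system",
    "make_net_force_pair",
    "make_torsion_trajectory",
    "make_channel",
    "make_hbond_frames",
    "make_pore",
    "make_dilating_pore",
    "make_helix_pair",
    "write_manifest",
]


@dataclass
class GeneratorConfig:
    """Shared configuration for all generators.

    Truth parameters default to the study conditions; the seed fixes all
    stochastic output bit-for-bit.
    """

    seed: int = 0
    # sizes
    n_atoms: int = 20
    n_residues: int = 5
    n_frames: int = 100
    # elastic truths (AR-bundle torsion protocol)
    c_true: float = 2300.0            # kJ/mol/rad
    kct_true: float = 1.32            # nm/rad
    l0: float = 10.0                  # nm, relaxed bundle length
    twist_angles_deg: tuple = (2.5, 5.0, 7.5, 10.0)
    n_window_samples: int = 100       # raw torque/length samples per window
    # injected condition difference (force on TRP residue by LH residue)
    delta_pairs: dict = field(default_factory=lambda: {
        ((("A", 1571)), (("A", 1244))): (2.0, 35.0, 14.0),
        ((("A", 1581)), (("A", 1236))): (6.5, 46.0, 30.0),
        ((("A", 1577)), (("A", 1256))): (0.5, 3.0, 1.5),
    })
    # H-bond occupancy targets per residue pair
    occupancy_targets: dict = field(default_factory=lambda: {
        (1244, 1571): 0.57,
        (1236, 1581): 0.71,
        (1256, 1577): 0.24,
    })
    # pore geometry (accessible radii, nm)
    pore_radius: float = 0.35
    constriction_radius: float = 0.10
    pore_atom_vdw: float = 0.15
    # helix-pair truths
    rotation_deg: float = 15.0
    tilt_deg: float = 8.0
    # noise scales (relative to signal unless stated)
    noise_frac: float = 0.1
    coord_noise_nm: float = 0.0


def write_manifest(manifest: dict, path) -> None:
    """Serialize a truth manifest to JSON (numpy-safe)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=default)


def _rng(config: GeneratorConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_offsets(n: int, radius: float, turns: float = 3.0) -> np.ndarray:
    """(n, 2) helical winding offsets, orthogonalized against constant and
    linear axial trends so a finite helix built with them has its
    principal axis exactly along the construction axis."""
    t = np.arange(n) * (2 * np.pi * turns / n)
    k = np.arange(n, dtype=float)
    out = np.column_stack([np.cos(t), np.sin(t)])
    for b in (np.ones(n), k - k.mean()):
        out -= np.outer(b @ out / (b @ b), b).T
    return radius * out


# ---------------------------------------------------------------------------
# toy force systems


def make_toy_system(config: GeneratorConfig, preset: str | None = None):
    """A small parameterized system for the force engine.

    ``preset``:
      * None — random compact cluster with a bonded chain backbone;
      * "coulomb-pair" — two +1/-1 e atoms 0.5 nm apart, no LJ/bonded;
      * "chain5" — five bonded atoms with angles and one dihedral.
    """
    rng = _rng(config, 1)
    if preset == "coulomb-pair":
        n = 2
        pos = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        charge = np.array([1.0, -1.0])
        sigma = np.full(n, 0.3)
        eps = np.zeros(n)
        bonds, angles, dihedrals = [], [], []
        resid = np.array([1, 2])
    elif preset == "chain5":
        n = 5
        base = np.array([[0.0, 0.0, 0.0], [0.15, 0.02, 0.0], [0.28, 0.12, 0.03],
                         [0.40, 0.05, 0.12], [0.55, 0.10, 0.08]])
        pos = base
        charge = np.array([0.3, -0.2, 0.1, -0.3, 0.1])
        sigma = np.full(n, 0.3)
        eps = np.full(n, 0.5)
        bonds = [(i, i + 1, 1000.0, 0.15) for i in range(4)]
        angles = [(i, i + 1, i + 2, 100.0, np.deg2rad(110.0)) for i in range(3)]
        dihedrals = [(0, 1, 2, 3, 5.0, 3, 0.0), (1, 2, 3, 4, 5.0, 3, 0.0)]
        resid = np.array([1, 1, 2, 2, 3])
    else:
        n = min(config.n_atoms, 100)
        pos = rng.uniform(-0.6, 0.6, size=(n, 3))
        # push apart anything closer than 0.25 nm to keep forces tame
        for _ in range(50):
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] >= 0.25:
                break
            pos[i] += 0.30 * (pos[i] - pos[j]) / (d[i, j] + 1e-12)
        charge = rng.uniform(-0.5, 0.5, size=n)
        sigma = rng.uniform(0.25, 0.35, size=n)
        eps = rng.uniform(0.1, 0.8, size=n)
        bonds = [(i, i + 1, 800.0, 0.2) for i in range(min(n - 1, 6))]
        angles = [(i, i + 1, i + 2, 80.0, np.deg2rad(115.0))
                  for i in range(min(n - 2, 5))]
        dihedrals = [(i, i + 1, i + 2, i + 3, 4.0, 2, 0.3)
                     for i in range(min(n - 3, 4))]
        per_res = max(1, n // config.n_residues)
        resid = np.arange(n) // per_res + 1
    structure = MolecularStructure(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array([f"X{i}" for i in range(n)], dtype=object),
        element=np.array(["C"] * n, dtype=object),
        residue_id=resid,
        residue_name=np.array(["TOY"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        positions=pos,
    )
    params = InteractionParameters(
        charge=charge, lj_sigma=sigma, lj_epsilon=eps,
        bonds=bonds, angles=angles, dihedrals=dihedrals,
    )
    return structure, params


# ---------------------------------------------------------------------------
# paired forced/free pairwise-force series


def make_net_force_pair(config: GeneratorConfig):
    """Two forced and two free pairwise-force replicates with injected delta.

    The free condition is zero-mean Gaussian noise per pair per frame;
    the forced condition is the same distribution shifted by the truth
    delta on the designated pairs (force ON the TRP residue BY the LH
    residue, kJ/mol/nm).  The manifest records the deltas exactly.
    """
    rng = _rng(config, 2)
    deltas = {k: np.asarray(v, dtype=float) for k, v in config.delta_pairs.items()}
    max_delta = max((np.linalg.norm(v) for v in deltas.values()), default=1.0)
    sigma = config.noise_frac * max_delta
    # residue universe: the designated pairs plus background LH/TRP pairs
    universe: set = set()
    pairs: list = []
    for (trp, lh) in deltas:
        universe.update([trp, lh])
        pairs.append((trp, lh))
    background = [(("A", 1570), ("A", 1240)), (("A", 1583), ("A", 1250))]
    for trp, lh in background:
        universe.update([trp, lh])
        pairs.append((trp, lh))
    residues = sorted(universe)

    def replicate(shift: bool) -> PairForceTable:
        t = PairForceTable(residues=residues, n_frames=config.n_frames,
                           times=np.arange(config.n_frames, dtype=float))
        for trp, lh in pairs:
            noise = rng.normal(0.0, sigma, size=(config.n_frames, 3))
            mean = deltas.get((trp, lh), np.zeros(3)) if shift else np.zeros(3)
            series = noise + mean
            for f in range(config.n_frames):
                t.add(trp, lh, "coulomb", f, series[f])
        return t

    forced = [replicate(True), replicate(True)]
    free = [replicate(False), replicate(False)]
    manifest = {
        "seed": config.seed,
        "n_frames": config.n_frames,
        "noise_sigma": sigma,
        "delta": {f"{t[0]}:{t[1]}<-{l[0]}:{l[1]}": d.tolist()
                  for (t, l), d in deltas.items()},
    }
    return forced, free, manifest


# ---------------------------------------------------------------------------
# bead-spring AR bundle torsion protocol


def make_torsion_trajectory(config: GeneratorConfig):
    """Bead-spring helical bundle under the stepwise twist protocol.

    Returns ``(structure, frames, series, manifest)``.  Frame 0 is the
    untwisted reference; each subsequent frame is a twist window in which
    the lower block (AR1-8) has been rigidly rotated about z by the
    window angle and the bundle length axially rescaled per
    L = L0 - k_ct * phi.

    Each window emulates a long restrained relaxation whose torque and
    length readouts are sampled many times and averaged: the series holds
    per-window means of M = c * phi and L = L0 - k_ct * phi over
    ``n_window_samples`` draws with per-sample noise sigma =
    noise_frac * max|M| (resp. noise_frac * max compression).
    """
    if config.c_true <= 0:
        raise ConfigError("c_true must be > 0")
    rng = _rng(config, 3)
    n_units = 29
    beads_per_chain = n_units + 2  # AR1..AR29 + 2 LH beads on top
    chains = ["A", "B", "C", "D"]
    radius = 1.5
    pitch_turns = 1.25  # total helical turns bottom->top
    z_span = 11.0

    def chain_coords(phase: float) -> np.ndarray:
        k = np.arange(beads_per_chain)
        theta = phase + 2 * np.pi * pitch_turns * k / (beads_per_chain - 1)
        z = z_span * k / (beads_per_chain - 1)
        return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])

    coords = np.vstack([chain_coords(i * np.pi / 2) for i in range(4)])
    n_atoms = len(coords)
    resid = np.tile(np.arange(1, beads_per_chain + 1), 4)
    chain_id = np.repeat(chains, beads_per_chain)
    labels = np.tile(
        [f"AR{u}" for u in range(1, n_units + 1)] + ["LH", "LH"], 4
    )
    structure = MolecularStructure(
        atom_id=np.arange(1, n_atoms + 1),
        atom_name=np.array(["CA"] * n_atoms, dtype=object),
        element=np.array(["C"] * n_atoms, dtype=object),
        residue_id=resid,
        residue_name=np.array(["BEA"] * n_atoms, dtype=object),
        chain_id=np.array(chain_id, dtype=object),
        positions=coords,
    )
    lower = np.nonzero(np.isin(labels, [f"AR{u}" for u in range(1, 9)]))[0]
    ar8 = np.nonzero(labels == "AR8")[0]
    lh = np.nonzero(labels == "LH")[0]
    # C4 symmetry puts both centroids on the axis: L is a pure z distance
    l0_actual = float(coords[lh][:, 2].mean() - coords[ar8][:, 2].mean())
    phis = np.deg2rad(np.asarray(config.twist_angles_deg, dtype=float))
    nw = max(int(config.n_window_samples), 1)
    m_clean = config.c_true * phis
    sigma_m = config.noise_frac * np.abs(m_clean).max()
    m_vals = m_clean + rng.normal(0.0, sigma_m, size=(len(phis), nw)).mean(axis=1)
    l_clean = config.l0 - config.kct_true * phis
    sigma_l = config.noise_frac * config.kct_true * phis.max()
    l_vals = l_clean + rng.normal(0.0, sigma_l, size=(len(phis), nw)).mean(axis=1)

    frames = [coords * np.array([1.0, 1.0, config.l0 / l0_actual])]
    for phi, length in zip(phis, l_vals):
        pos = coords.copy()
        pos[lower] = pos[lower] @ _rot_z(phi).T
        pos[:, 2] *= length / l0_actual  # axial compression
        if config.coord_noise_nm > 0:
            pos = pos + rng.normal(0.0, config.coord_noise_nm, size=pos.shape)
        frames.append(pos)
    seq = FrameSequence(
        times=np.arange(len(frames), dtype=float),
        positions=np.array(frames),
        box=np.zeros((len(frames), 3)),
    )
    series = SeriesTable(
        pd.DataFrame({"window": np.arange(1, len(phis) + 1, dtype=float),
                      "phi": phis, "M": m_vals, "L": l_vals}),
        units={"phi": "rad", "M": "kJ/mol", "L": "nm"},
    )
    manifest = {
        "seed": config.seed,
        "c_true": config.c_true,
        "kct_true": config.kct_true,
        "l0": config.l0,
        "phi_rad": phis.tolist(),
        "M": m_vals.tolist(),
        "L": l_vals.tolist(),
        "noise_sigma_M": sigma_m,
        "noise_sigma_L": sigma_l,
        "n_window_samples": nw,
        "window_se_M": sigma_m / np.sqrt(nw),
        "window_se_L": sigma_l / np.sqrt(nw),
        "groups": {"ar1_8": lower.tolist(), "ar8": ar8.tolist(), "lh": lh.tolist()},
    }
    return structure, seq, series, manifest


# ---------------------------------------------------------------------------
# C4 channel


def make_channel(config: GeneratorConfig):
    """Four-chain channel with radial TRP helices and a central pore.

    Exactly C4-symmetric about z; overall centroid at the origin.
    Returns ``(structure, domain_map, manifest)``; the manifest records
    each chain's true local frame (radial x, tangential y, z up).
    """
    chains = ["A", "B", "C", "D"]
    per_chain: list[tuple[int, str, np.ndarray]] = []  # (resid, name, pos)
    # TRP helix: 11 CA on an ideal helix whose axis is radial (+x), z = 0
    n_trp = 11
    trp_first = 1567
    wind = _helix_offsets(n_trp, 0.23)
    for k in range(n_trp):
        pos = np.array([2.0 + 0.15 * k, wind[k, 0], wind[k, 1]])
        per_chain.append((trp_first + k, "CA", pos))
    # pore-lining segment near the axis (gate region)
    for k in range(6):
        per_chain.append((1550 + k, "CA",
                          np.array([0.55, 0.15 * (k - 2.5), -0.9 + 0.35 * k])))
    # LH beads below the membrane
    for k in range(8):
        per_chain.append((1230 + 4 * k, "CA",
                          np.array([1.2 + 0.1 * k, 0.3, -2.2 - 0.12 * k])))
    ids, names, resids, chain_col, coords = [], [], [], [], []
    aid = 1
    for c_idx, chain in enumerate(chains):
        rot = _rot_z(np.pi / 2 * c_idx)
        for resid, name, pos in per_chain:
            ids.append(aid)
            aid += 1
            names.append(name)
            resids.append(resid)
            chain_col.append(chain)
            coords.append(rot @ pos)
    coords = np.array(coords)
    coords -= coords.mean(axis=0)  # centroid exactly at the origin
    structure = MolecularStructure(
        atom_id=np.array(ids),
        atom_name=np.array(names, dtype=object),
        element=np.array(["C"] * len(ids), dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(["SYN"] * len(ids), dtype=object),
        chain_id=np.array(chain_col, dtype=object),
        positions=coords,
    )
    domain_map = DomainMap(
        [("TRP", c, trp_first, trp_first + n_trp - 1) for c in chains]
        + [("S6", c, 1550, 1555) for c in chains]
        + [("LH", c, 1230, 1258) for c in chains]
    )
    manifest = {
        "chains": chains,
        "trp_resids": [trp_first, trp_first + n_trp - 1],
        "local_frames": {
            chain: {
                "x": (_rot_z(np.pi / 2 * k) @ np.array([1.0, 0.0, 0.0])).tolist(),
                "z": [0.0, 0.0, 1.0],
            }
            for k, chain in enumerate(chains)
        },
    }
    return structure, domain_map, manifest


# ---------------------------------------------------------------------------
# H-bond occupancy frames


def make_hbond_frames(config: GeneratorConfig):
    """Donor-acceptor geometries realizing prescribed occupancies.

    For each (donor residue, acceptor residue) target, exactly
    round(target * n_frames) frames satisfy the default criteria
    (D-A = 0.29 nm, linear D-H...A); the rest violate the distance
    criterion (D-A = 0.45 nm).  Valid frames are a seeded random subset.
    Returns ``(structure, frames, roles, manifest)``.
    """
    rng = _rng(config, 4)
    targets = dict(config.occupancy_targets)
    for v in targets.values():
        if not 0.0 <= v <= 1.0:
            raise ConfigError("occupancy targets must lie in [0, 1]")
    n_frames = config.n_frames
    ids, names, elements, resids, coords = [], [], [], [], []
    donors, acceptors = [], []
    base_positions = []
    aid = 0
    for p, ((res_d, res_a), _) in enumerate(targets.items()):
        origin = np.array([3.0 * p, 0.0, 0.0])  # pairs far apart: no cross bonds
        d_pos = origin
        h_pos = origin + np.array([0.1, 0.0, 0.0])
        a_pos = origin + np.array([0.29, 0.0, 0.0])
        for name, elem, resid, pos in (
            ("ND", "N", res_d, d_pos),
            ("HD", "H", res_d, h_pos),
            ("OA", "O", res_a, a_pos),
        ):
            ids.append(aid + 1)
            names.append(name)
            elements.append(elem)
            resids.append(resid)
            coords.append(pos)
            aid += 1
        donors.append((aid - 3, aid - 2))
        acceptors.append(aid - 1)
        base_positions.append((aid - 3, aid - 2, aid - 1, origin))
    structure = MolecularStructure(
        atom_id=np.array(ids),
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(["SYN"] * len(ids), dtype=object),
        chain_id=np.array(["A"] * len(ids), dtype=object),
        positions=np.array(coords),
    )
    valid_sets = []
    for (pair, target) in targets.items():
        n_valid = int(round(target * n_frames))
        chosen = rng.permutation(n_frames)[:n_valid]
        valid_sets.append(set(int(c) for c in chosen))
    frames_pos = []
    for f in range(n_frames):
        pos = np.array(coords, dtype=float)
        for p, (d_i, h_i, a_i, origin) in enumerate(base_positions):
            if f not in valid_sets[p]:
                pos[a_i] = origin + np.array([0.45, 0.0, 0.0])  # break distance
        frames_pos.append(pos)
    frames = FrameSequence(
        times=np.arange(n_frames, dtype=float),
        positions=np.array(frames_pos),
        box=np.zeros((n_frames, 3)),
    )
    roles = HBondRoles(donors=donors, acceptors=acceptors)
    manifest = {
        "seed": config.seed,
        "n_frames": n_frames,
        "targets": {f"{k[0]}-{k[1]}": v for k, v in targets.items()},
        "realized": {
            f"{k[0]}-{k[1]}": round(v * n_frames) / n_frames
            for k, v in targets.items()
        },
    }
    return structure, frames, roles, manifest


# ---------------------------------------------------------------------------
# pores


def _pore_structure(ring_z: np.ndarray, ring_radius: np.ndarray,
                    vdw: float, atoms_per_ring: int = 16) -> MolecularStructure:
    ids, coords, resids = [], [], []
    aid = 1
    for ri, (z, acc) in enumerate(zip(ring_z, ring_radius)):
        atom_r = acc + vdw  # accessible radius = ring radius - vdW
        angles = 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
        for ang in angles:
            coords.append([atom_r * np.cos(ang), atom_r * np.sin(ang), z])
            ids.append(aid)
            resids.append(ri + 1)
            aid += 1
    n = len(ids)
    return MolecularStructure(
        atom_id=np.array(ids),
        atom_name=np.array(["PO"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(["POR"] * n, dtype=object),
        chain_id=np.array(["A"] * n, dtype=object),
        positions=np.array(coords),
        vdw_radius=np.full(n, vdw),
    )


def make_pore(config: GeneratorConfig, constriction: bool = True):
    """Cylindrical pore of stacked atom rings with a known radius profile.

    Rings every 0.5 nm over z in [-2, 2] — spaced widely enough that no
    ring shadows the sphere clearance at a neighbouring ring's height, so
    the analytic accessible radius at each ring equals the prescribed
    value exactly.  The accessible radius is ``config.pore_radius``
    everywhere except (optionally) a constriction ring at z = 0 with
    ``config.constriction_radius``.  Returns ``(structure, manifest)``.
    """
    ring_z = np.arange(-2.0, 2.0 + 1e-9, 0.5)
    radii = np.full(len(ring_z), config.pore_radius)
    if constriction:
        gate = int(np.argmin(np.abs(ring_z)))
        radii[gate] = config.constriction_radius
    structure = _pore_structure(ring_z, radii, config.pore_atom_vdw)
    manifest = {
        "ring_z": ring_z.tolist(),
        "accessible_radius": radii.tolist(),
        "constriction_z": 0.0 if constriction else None,
        "vdw": config.pore_atom_vdw,
    }
    return structure, manifest


def make_dilating_pore(config: GeneratorConfig, r_start: float = 0.08,
                       r_end: float = 0.25, n_frames: int | None = None):
    """A pore whose gate constriction widens linearly over the frames,
    crossing the 0.2 nm opening threshold.  Returns
    ``(structure, frames, manifest)``."""
    n_frames = n_frames or max(config.n_frames // 10, 5)
    ring_z = np.arange(-2.0, 2.0 + 1e-9, 0.5)
    gate = int(np.argmin(np.abs(ring_z)))
    radii0 = np.full(len(ring_z), config.pore_radius)
    radii0[gate] = r_start
    structure = _pore_structure(ring_z, radii0, config.pore_atom_vdw)
    gate_r = np.linspace(r_start, r_end, n_frames)
    frames_pos = []
    for r in gate_r:
        radii = radii0.copy()
        radii[gate] = r
        frames_pos.append(
            _pore_structure(ring_z, radii, config.pore_atom_vdw).positions
        )
    frames = FrameSequence(
        times=np.arange(n_frames, dtype=float),
        positions=np.array(frames_pos),
        box=np.zeros((n_frames, 3)),
    )
    manifest = {
        "gate_z": float(ring_z[gate]),
        "gate_radius": gate_r.tolist(),
        "outer_radius": config.pore_radius,
    }
    return structure, frames, manifest


# ---------------------------------------------------------------------------
# helix pairs


def make_helix_pair(config: GeneratorConfig, rigid_motion: bool = True):
    """Two states of a TRP-like helix on a rigid S1-S4 scaffold.

    State 2's helix is rotated about the pore axis by ``rotation_deg``
    (positive = clockwise viewed from the intracellular side) and tilted
    up by ``tilt_deg``; unless ``rigid_motion`` is disabled, the whole
    state-2 system then receives a random rigid-body motion so that only
    scaffold superposition can recover the angles.  Returns
    ``(state1, state2, manifest)``.
    """
    if abs(config.rotation_deg) > 180 or abs(config.tilt_deg) >= 85:
        raise ConfigError("rotation must be within 180 deg, tilt below 85 deg")
    rng = _rng(config, 5)
    # scaffold: four vertical helices around the pore
    scaffold = []
    for k in range(4):
        ang = np.pi / 2 * k + np.pi / 4
        base = np.array([1.6 * np.cos(ang), 1.6 * np.sin(ang), -0.8])
        for m in range(8):
            scaffold.append(base + np.array([0.05 * np.cos(m * 1.75),
                                             0.05 * np.sin(m * 1.75),
                                             0.22 * m]))
    scaffold = np.array(scaffold)
    # TRP helix: radial, in-plane, winding orthogonalized so its principal
    # axis is exactly the construction direction
    n_trp = 11
    wind = _helix_offsets(n_trp, 0.23)
    helix = np.column_stack([
        0.8 + 0.15 * np.arange(n_trp),
        wind[:, 0],
        wind[:, 1] - 0.4,
    ])
    anchor = helix[0].copy()

    def tilt_then_rotate(pts: np.ndarray) -> np.ndarray:
        # tilt-up about the in-plane axis perpendicular to the helix (y),
        # pivoting at the N-terminal anchor, then rotate about the pore z
        tau = np.deg2rad(config.tilt_deg)
        c, s = np.cos(-tau), np.sin(-tau)
        rot_y = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
        out = (pts - anchor) @ rot_y.T + anchor
        return out @ _rot_z(np.deg2rad(config.rotation_deg)).T

    helix2 = tilt_then_rotate(helix)
    # global rigid-body motion applied to all of state 2
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 2 * np.pi)
    kx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    rglob = np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * (kx @ kx)
    tglob = rng.uniform(-2, 2, size=3)
    if rigid_motion:
        scaffold2 = scaffold @ rglob.T + tglob
        helix2 = helix2 @ rglob.T + tglob
    else:
        scaffold2 = scaffold.copy()

    def as_structure(scaf: np.ndarray, hel: np.ndarray) -> MolecularStructure:
        coords = np.vstack([scaf, hel])
        n = len(coords)
        resids = np.concatenate([
            np.arange(1400, 1400 + len(scaf)),
            np.arange(1567, 1567 + len(hel)),
        ])
        return MolecularStructure(
            atom_id=np.arange(1, n + 1),
            atom_name=np.array(["CA"] * n, dtype=object),
            element=np.array(["C"] * n, dtype=object),
            residue_id=resids,
            residue_name=np.array(["SYN"] * n, dtype=object),
            chain_id=np.array(["A"] * n, dtype=object),
            positions=coords,
        )

    manifest = {
        "seed": config.seed,
        "rotation_deg": config.rotation_deg,
        "tilt_deg": config.tilt_deg,
        "n_scaffold": len(scaffold),
        "n_helix": n_trp,
    }
    return as_structure(scaffold, helix), as_structure(scaffold2, helix2), manifest
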