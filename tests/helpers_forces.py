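"""Independent brute-force oracle for the pairwise force engine.

Everything here is written from the physics down, separately from the
package implementation: a plain double-loop total energy (switched
Coulomb + Lennard-Jones with exclusions, harmonic bonds and angles,
periodic dihedrals) and per-atom forces obtained as its negative central
finite-difference gradient.  Used by tests only.
"""

from __future__ import annotations

import numpy as np

KE = 138.935458  # kJ mol^-1 nm e^-2


def _smoothstep(r, r_on, r_off):
    if r <= r_on:
        return 1.0
    if r >= r_off:
        return 0.0
    x = (r - r_on) / (r_off - r_on)
    return 1.0 - (10 * x**3 - 15 * x**4 + 6 * x**5)


def _excluded_pairs(params):
    adj = {}
    for i, j, *_ in params.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    want = set()
    depth = {"1-2": 1, "1-3": 2, "1-4": 3}
    depths = {depth[p] for p in params.exclusions if p in depth}
    if not depths:
        return want
    maxd = max(depths)
    for s in adj:
        dist = {s: 0}
        frontier = [s]
        for d in range(1, maxd + 1):
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if d in depths and s < v:
                want.add((s, v))
    return want


def total_energy(pos, params):
    """Plain double-loop total potential energy (kJ/mol)."""
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    excl = _excluded_pairs(params)
    u = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r >= params.cutoff:
                continue
            s = _smoothstep(r, params.switch_on, params.cutoff)
            u += s * KE * params.charge[i] * params.charge[j] / r
            sig = 0.5 * (params.lj_sigma[i] + params.lj_sigma[j])
            eps = np.sqrt(params.lj_epsilon[i] * params.lj_epsilon[j])
            if eps > 0:
                sr6 = (sig / r) ** 6
                u += s * 4 * eps * (sr6**2 - sr6)
    for i, j, k, r0 in params.bonds:
        r = float(np.linalg.norm(pos[i] - pos[j]))
        u += 0.5 * k * (r - r0) ** 2
    for i, j, k, kt, t0 in params.angles:
        a = pos[i] - pos[j]
        b = pos[k] - pos[j]
        ct = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        theta = np.arccos(np.clip(ct, -1, 1))
        u += 0.5 * kt * (theta - t0) ** 2
    for i, j, k, l, kp, mult, p0 in params.dihedrals:
        b1, b2, b3 = pos[j] - pos[i], pos[k] - pos[j], pos[l] - pos[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        phi = np.arctan2(
            np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2), np.dot(n1, n2)
        )
        u += kp * (1 + np.cos(mult * phi - p0))
    return u


def brute_force_atom_forces(pos, params, h=1e-6):
    """Per-atom total forces as -grad of the double-loop energy."""
    pos = np.asarray(pos, dtype=float)
    forces = np.zeros_like(pos)
    for a in range(len(pos)):
        for d in range(3):
            pp = pos.copy()
            pm = pos.copy()
            pp[a, d] += h
            pm[a, d] -= h
            forces[a, d] = -(total_energy(pp, params) - total_energy(pm, params)) / (2 * h)
    return forces


def assemble_atom_forces(n_atoms, atomic_pairs):
    """Total per-atom forces from a {(i, j): {cls: vec}} pairwise table."""
    out = np.zeros((n_atoms, 3))
    for (i, j), classed in atomic_pairs.items():
        for vec in classed.values():
            out[i] += vec
            out[j] -= vec
    return out
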