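"""Condition-difference force analysis (net-FDA).

The net force table is the time-averaged pairwise force field of the
perturbed ("forced") trajectories minus that of the unperturbed ("free")
trajectories.  With two replicates per condition this is
(A1 + A2 - B1 - B2) / 2: replicates are averaged with equal weight
regardless of frame count, then the condition means are differenced.

Downstream steps implemented here: four-fold rotational symmetrization
about the pore axis (the channel is a C4 homotetramer, so the four
chain-equivalent entries are rotated into a reference chain frame and
averaged), magnitude thresholding (e.g. the 5 pN display filter), and
residue->domain aggregation (e.g. total force on the TRP domain exerted
by the LH domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError, MappingError
from .model_io import DomainMap
from .pairwise_forces import CLASSES, PairForceTable, PairKey, ResidueKey
from .units import KJ_MOL_NM_TO_PN

__all__ = [
    "NetForceTable",
    "SymmetryMap",
    "time_average",
    "net_fda",
    "symmetrize_c4",
    "threshold_filter",
    "aggregate_domains",
    "pair_table_to_frame",
    "net_table_to_frame",
]


@dataclass
class NetForceTable:
    """Mean (or condition-difference) residue-pair force vectors.

    ``entries[(ri, rj)][cls]`` is a 3-vector in kJ mol^-1 nm^-1: the force
    on ri by rj.  ``n_forced``/``n_free`` record sample counts per
    condition (frames x replicates); zero n_free marks a plain average.
    """

    entries: dict[PairKey, dict[str, np.ndarray]] = field(default_factory=dict)
    n_forced: int = 0
    n_free: int = 0

    def pairs(self) -> list[PairKey]:
        return list(self.entries)

    def total(self, key: PairKey) -> np.ndarray:
        return sum(
            (v for v in self.entries.get(key, {}).values()),
            start=np.zeros(3),
        )

    def get(self, ri: ResidueKey, rj: ResidueKey, cls: str | None = None) -> np.ndarray:
        key, sign = PairForceTable.canonical(ri, rj)
        if cls is None:
            return sign * self.total(key)
        vec = self.entries.get(key, {}).get(cls)
        return sign * vec if vec is not None else np.zeros(3)


@dataclass
class SymmetryMap:
    """C4 symmetry description: pore axis, center, and the chain cycle.

    Applying the cycle four times returns each chain to itself; residues
    correspond across chains by identical author resid (plus an optional
    constant offset).
    """

    axis: np.ndarray
    center: np.ndarray
    chain_cycle: tuple[str, str, str, str]
    resid_offset: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ConfigError("symmetry axis must be nonzero")
        self.axis = self.axis / n
        self.center = np.asarray(self.center, dtype=float)
        if len(set(self.chain_cycle)) != 4:
            raise ConfigError("chain cycle must name four distinct chains")

    def shift_chain(self, chain: str, k: int) -> str:
        cyc = self.chain_cycle
        try:
            idx = cyc.index(chain)
        except ValueError:
            raise MappingError(f"chain {chain!r} not in symmetry cycle {cyc}") from None
        return cyc[(idx + k) % 4]


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


# ---------------------------------------------------------------------------


def time_average(table: PairForceTable, window: slice | None = None) -> NetForceTable:
    """Arithmetic per-pair mean of the per-frame vectors over a frame window."""
    window = window if window is not None else slice(None)
    idx = np.arange(table.n_frames)[window]
    if len(idx) == 0:
        raise InputError("empty frame window for time_average")
    out = NetForceTable(n_forced=len(idx), n_free=0)
    for key, classed in table.forces.items():
        out.entries[key] = {
            cls: arr[idx].mean(axis=0) for cls, arr in classed.items()
        }
    return out


def _condition_mean(tables: list[PairForceTable]) -> dict[PairKey, dict[str, np.ndarray]]:
    """Equal-weight mean over replicates of the per-replicate time averages."""
    means = [time_average(t).entries for t in tables]
    keys = {k for m in means for k in m}
    out: dict[PairKey, dict[str, np.ndarray]] = {}
    for key in keys:
        out[key] = {}
        for cls in CLASSES:
            vecs = [m.get(key, {}).get(cls) for m in means]
            vecs = [v if v is not None else np.zeros(3) for v in vecs]
            total = np.mean(vecs, axis=0)
            if np.any(total):
                out[key][cls] = total
    return out


def net_fda(forced: list[PairForceTable], free: list[PairForceTable]) -> NetForceTable:
    """Condition-difference table: mean(forced) - mean(free), per pair/class."""
    if not forced or not free:
        raise InputError("both forced and free replicate lists must be non-empty")
    universes = {tuple(sorted(t.residues)) for t in forced + free}
    if len(universes) != 1:
        raise InputError("replicates disagree on the residue universe")
    mean_f = _condition_mean(forced)
    mean_0 = _condition_mean(free)
    out = NetForceTable(
        n_forced=sum(t.n_frames for t in forced),
        n_free=sum(t.n_frames for t in free),
    )
    for key in set(mean_f) | set(mean_0):
        entry: dict[str, np.ndarray] = {}
        for cls in CLASSES:
            vf = mean_f.get(key, {}).get(cls, np.zeros(3))
            v0 = mean_0.get(key, {}).get(cls, np.zeros(3))
            d = vf - v0
            if np.any(d):
                entry[cls] = d
        if entry:
            out.entries[key] = entry
    return out


def symmetrize_c4(net: NetForceTable, sym: SymmetryMap) -> NetForceTable:
    """Average the four chain-equivalent copies of every pair entry.

    Each pair on chain(s) c is mapped back to the reference chain
    (cycle[0]) by shifting chains along the cycle and rotating the force
    vector about the pore axis by the corresponding multiple of -90 deg;
    the four images are averaged (missing images count as zero).  The
    output is reported on the reference chain and is a fixed point of the
    operation.
    """
    rots = [_rotation_about(sym.axis, -np.pi / 2 * k) for k in range(4)]

    def image(key: PairKey, k: int) -> tuple[PairKey, float]:
        (ci, ri), (cj, rj) = key
        a = (sym.shift_chain(ci, k), ri + sym.resid_offset * k)
        b = (sym.shift_chain(cj, k), rj + sym.resid_offset * k)
        return PairForceTable.canonical(a, b)

    out = NetForceTable(n_forced=net.n_forced, n_free=net.n_free)
    seen: set[PairKey] = set()
    for key in net.entries:
        # canonical representative: the image whose first chain is cycle[0]
        (ci, _), _ = key
        k_ref = (-sym.chain_cycle.index(ci)) % 4
        rep_key, _ = image(key, k_ref)
        if rep_key in seen:
            continue
        seen.add(rep_key)
        acc: dict[str, np.ndarray] = {}
        for k in range(4):
            img_key, sign = image(rep_key, k)
            classed = net.entries.get(img_key, {})
            # vector lives on chain k; rotate back into the reference frame
            for cls, vec in classed.items():
                back = rots[k] @ (sign * vec)
                acc[cls] = acc.get(cls, np.zeros(3)) + back
        entry = {cls: v / 4.0 for cls, v in acc.items() if np.any(v)}
        if not entry:
            continue
        # write the averaged entry on the reference chain and its exact
        # rotated images on the other three chains, so the output is fully
        # C4-symmetric (and the operation idempotent)
        fwd = [_rotation_about(sym.axis, np.pi / 2 * k) for k in range(4)]
        for k in range(4):
            img_key, sign = image(rep_key, k)
            out.entries[img_key] = {
                cls: sign * (fwd[k] @ vec) for cls, vec in entry.items()
            }
    return out


def threshold_filter(net: NetForceTable, min_force_pn: float) -> NetForceTable:
    """Drop entries whose total vector magnitude is below ``min_force_pn``.

    The comparison is strict (<): an entry exactly at the threshold
    survives.  Magnitudes are taken on the class-summed vector after
    conversion to pN.
    """
    if min_force_pn < 0:
        raise ConfigError("threshold must be >= 0")
    out = NetForceTable(n_forced=net.n_forced, n_free=net.n_free)
    for key, classed in net.entries.items():
        mag_pn = np.linalg.norm(net.total(key)) * KJ_MOL_NM_TO_PN
        if mag_pn < min_force_pn:
            continue
        out.entries[key] = {cls: vec.copy() for cls, vec in classed.items()}
    return out


def aggregate_domains(net: NetForceTable, mapping: DomainMap,
                      source: str, target: str):
    """Net force on each target-domain residue exerted by the source domain.

    Returns ``(per_residue, total)`` where ``per_residue`` maps each
    (chain, resid) of the target domain to the summed 3-vector from all
    source-domain residues, and ``total`` is the domain-level sum.
    """
    src = set(mapping.residues_of(source))
    tgt = set(mapping.residues_of(target))
    if not src or not tgt:
        raise MappingError(f"domain {source!r} or {target!r} maps to no residues")
    per_residue: dict[ResidueKey, np.ndarray] = {t: np.zeros(3) for t in tgt}
    for (ri, rj), _ in net.entries.items():
        if ri in tgt and rj in src:
            per_residue[ri] = per_residue[ri] + net.get(ri, rj)
        elif rj in tgt and ri in src:
            per_residue[rj] = per_residue[rj] + net.get(rj, ri)
    total = sum(per_residue.values(), start=np.zeros(3))
    return per_residue, total


# ---------------------------------------------------------------------------
# tabular export


def pair_table_to_frame(table: PairForceTable):
    """Flatten a per-frame pairwise force table to a tidy DataFrame with
    columns chain_i, resid_i, chain_j, resid_j, class, frame, time,
    Fx, Fy, Fz (kJ/mol/nm)."""
    import pandas as pd

    rows = []
    times = table.times if table.times is not None else np.arange(table.n_frames)
    for ((ci, ri), (cj, rj)), classed in sorted(table.forces.items()):
        for cls, arr in sorted(classed.items()):
            for f in range(table.n_frames):
                rows.append((ci, ri, cj, rj, cls, f, float(times[f]),
                             arr[f, 0], arr[f, 1], arr[f, 2]))
    return pd.DataFrame(rows, columns=[
        "chain_i", "resid_i", "chain_j", "resid_j", "class",
        "frame", "time", "Fx", "Fy", "Fz",
    ])


def net_table_to_frame(net: NetForceTable):
    """Flatten a net force table; one row per pair and class, plus a
    'total' row per pair with the class-summed vector and its magnitude
    in pN."""
    import pandas as pd

    rows = []
    for ((ci, ri), (cj, rj)), classed in sorted(net.entries.items()):
        for cls, vec in sorted(classed.items()):
            rows.append((ci, ri, cj, rj, cls, vec[0], vec[1], vec[2],
                         float(np.linalg.norm(vec)) * KJ_MOL_NM_TO_PN))
        tot = sum(classed.values(), start=np.zeros(3))
        rows.append((ci, ri, cj, rj, "total", tot[0], tot[1], tot[2],
                     float(np.linalg.norm(tot)) * KJ_MOL_NM_TO_PN))
    return pd.DataFrame(rows, columns=[
        "chain_i", "resid_i", "chain_j", "resid_j", "class",
        "Fx", "Fy", "Fz", "magnitude_pN",
    ])


def pair_table_from_frame(df) -> PairForceTable:
    """Rebuild a PairForceTable from the tidy layout of
    :func:`pair_table_to_frame` (CSV round-trip support)."""
    needed = {"chain_i", "resid_i", "chain_j", "resid_j", "class", "frame",
              "Fx", "Fy", "Fz"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"pairwise table missing columns {sorted(missing)}")
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    residues = sorted(
        {(str(c), int(r)) for c, r in zip(df["chain_i"], df["resid_i"])}
        | {(str(c), int(r)) for c, r in zip(df["chain_j"], df["resid_j"])}
    )
    times = None
    if "time" in df.columns and len(df):
        times = (
            df.drop_duplicates("frame").sort_values("frame")["time"].to_numpy(float)
        )
    table = PairForceTable(residues=residues, n_frames=n_frames, times=times)
    cols = [df[c].to_numpy() for c in
            ("chain_i", "resid_i", "chain_j", "resid_j", "class", "frame",
             "Fx", "Fy", "Fz")]
    for ci, ri, cj, rj, cls, f, fx, fy, fz in zip(*cols):
        table.add((str(ci), int(ri)), (str(cj), int(rj)), str(cls),
                  int(f), (fx, fy, fz))
    return table
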