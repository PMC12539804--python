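"""Input/output layer and shared data model.

Everything downstream (force engine, mechanics, geometry) consumes the
containers defined here: :class:`MolecularStructure` for coordinates,
:class:`FrameSequence` for trajectories, :class:`InteractionParameters`
for the nonbonded/bonded terms, :class:`SeriesTable` for whitespace
time-series tables, and :class:`DomainMap` for residue->domain labels.

Units: coordinates are stored in nm internally; PDB files are converted
at the boundary (A / 10).  Residue numbering is taken verbatim from the
input files — no renumbering ever happens, so author residue ids such as
1571/1581 survive round trips.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MappingError,
    ParameterError,
    ParseError,
    SelectionError,
    ShapeError,
)

__all__ = [
    "MolecularStructure",
    "FrameSequence",
    "SeriesTable",
    "InteractionParameters",
    "DomainMap",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_series_table",
    "write_series_table",
    "read_parameters",
    "write_parameters",
    "read_domain_map",
    "select_group",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MolecularStructure:
    """A static set of atoms with chain/residue identity, positions in nm."""

    atom_id: np.ndarray          # (N,) int
    atom_name: np.ndarray        # (N,) str
    element: np.ndarray          # (N,) str
    residue_id: np.ndarray       # (N,) int
    residue_name: np.ndarray     # (N,) str
    chain_id: np.ndarray         # (N,) str
    positions: np.ndarray        # (N, 3) float, nm
    vdw_radius: np.ndarray | None = None  # (N,) float, nm

    def __post_init__(self) -> None:
        self.atom_id = np.asarray(self.atom_id, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        for name in ("atom_name", "element", "residue_name", "chain_id"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.residue_id = np.asarray(self.residue_id, dtype=int)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_id)

    def validate(self) -> None:
        n = self.n_atoms
        if self.positions.shape != (n, 3):
            raise ShapeError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if len(np.unique(self.atom_id)) != n:
            dup = pd.Series(self.atom_id).value_counts()
            bad = dup[dup > 1].index.tolist()
            raise ParseError(f"duplicate atom_id(s): {bad}")
        if not np.all(np.isfinite(self.positions)):
            raise ParseError("non-finite coordinate in structure")

    def index_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        """Map atom ids to 0-based array indices."""
        lut = {a: i for i, a in enumerate(self.atom_id)}
        try:
            return np.array([lut[a] for a in atom_ids], dtype=int)
        except KeyError as exc:
            raise SelectionError(f"unknown atom_id {exc.args[0]}") from None

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_id) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_id, self.residue_id):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def atoms_of_residue(self, chain: str, resid: int) -> np.ndarray:
        mask = (self.chain_id == chain) & (self.residue_id == resid)
        return np.nonzero(mask)[0]


@dataclass
class FrameSequence:
    """An ordered set of trajectory frames with fixed atom order."""

    times: np.ndarray       # (F,) ps, strictly increasing
    positions: np.ndarray   # (F, N, 3) nm
    box: np.ndarray         # (F, 3) nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ShapeError(f"positions must be (F, N, 3), got {self.positions.shape}")
        if len(self.times) != len(self.positions):
            raise ShapeError("times and positions disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ParseError("frame times are not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ParseError("non-finite coordinate in trajectory")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def check_against(self, structure: MolecularStructure) -> None:
        if self.n_atoms != structure.n_atoms:
            raise ShapeError(
                f"trajectory has {self.n_atoms} atoms, structure has {structure.n_atoms}"
            )


@dataclass
class SeriesTable:
    """Named numeric columns of equal length plus unit metadata."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    allow_missing: bool = False  # NaN entries permitted only when flagged

    def __post_init__(self) -> None:
        if not self.allow_missing and self.data.isna().any().any():
            raise ParseError("SeriesTable contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


@dataclass
class InteractionParameters:
    """Per-atom nonbonded parameters and bonded-term lists.

    Bonded indices are 0-based positions into the owning structure's atom
    order.  ``exclusions`` names which bonded separations are removed from
    the nonbonded sums ("1-2", "1-3"); separations not listed are kept
    ("1-4" included unscaled by default, CHARMM-style).
    """

    charge: np.ndarray       # (N,) e
    lj_sigma: np.ndarray     # (N,) nm
    lj_epsilon: np.ndarray   # (N,) kJ/mol
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    # (i, j, k [kJ/mol/nm^2], r0 [nm])
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    # (i, j, k, k_theta [kJ/mol/rad^2], theta0 [rad])
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)
    # (i, j, k, l, k_phi [kJ/mol], multiplicity, phi0 [rad])
    exclusions: frozenset[str] = frozenset({"1-2", "1-3"})
    switch_on: float = 1.0   # nm
    cutoff: float = 1.2      # nm

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        n = len(self.charge)
        if not (len(self.lj_sigma) == len(self.lj_epsilon) == n):
            raise ParameterError("charge/sigma/epsilon length mismatch")
        if np.any(self.lj_sigma <= 0):
            raise ParameterError("lj_sigma must be > 0")
        if np.any(self.lj_epsilon < 0):
            raise ParameterError("lj_epsilon must be >= 0")
        if not self.switch_on < self.cutoff:
            raise ParameterError(
                f"switch_on ({self.switch_on}) must be < cutoff ({self.cutoff})"
            )
        for term in self.bonds:
            self._check_idx(term[:2], n)
        for term in self.angles:
            self._check_idx(term[:3], n)
        for term in self.dihedrals:
            self._check_idx(term[:4], n)

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    @staticmethod
    def _check_idx(idx: Sequence[int], n: int) -> None:
        for i in idx:
            if not 0 <= int(i) < n:
                raise ParameterError(f"bonded term references invalid atom index {i}")


class DomainMap:
    """Residue-range -> label mapping ("AR9", "LH", "TRP", ...).

    Ranges are (chain, first_resid, last_resid) inclusive; a residue may
    carry at most one label.  The AR-unit boundaries of the channel are
    not standardized, so they are always user- (or generator-) supplied.
    """

    def __init__(self, ranges: list[tuple[str, str, int, int]]):
        # entries: (label, chain, first, last)
        self.ranges = list(ranges)
        self._check_overlap()

    def _check_overlap(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for label, chain, lo, hi in self.ranges:
            for r in range(int(lo), int(hi) + 1):
                prev = seen.get((chain, r))
                if prev is not None and prev != label:
                    raise MappingError(
                        f"residue {chain}:{r} mapped to both {prev!r} and {label!r}"
                    )
                seen[(chain, r)] = label
        self._lut = seen

    def label_of(self, chain: str, resid: int) -> str | None:
        return self._lut.get((str(chain), int(resid)))

    def residues_of(self, label: str) -> list[tuple[str, int]]:
        out = [(c, r) for (c, r), lab in self._lut.items() if lab == label]
        return sorted(out)

    def labels(self) -> list[str]:
        out: dict[str, None] = {}
        for label, *_ in self.ranges:
            out.setdefault(label, None)
        return list(out)


# ---------------------------------------------------------------------------
# structure I/O

_PDB_ATOM = ("ATOM  ", "HETATM")


def read_structure(path, format: str = "pdb") -> MolecularStructure:
    """Read a structure file.  ``format`` is ``pdb`` or ``plain-xyz``.

    PDB coordinates (A) are converted to nm.  The plain-xyz format is one
    header line ``natoms`` followed by whitespace rows
    ``atom_id chain resid resname name element x y z`` with x/y/z in nm.
    """
    if format == "pdb":
        return _read_pdb(path)
    if format == "plain-xyz":
        return _read_plain_xyz(path)
    raise ParseError(f"unsupported structure format {format!r}")


def _read_pdb(path) -> MolecularStructure:
    ids, names, elems, resids, resnames, chains, xyz = [], [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(_PDB_ATOM):
                continue
            try:
                ids.append(int(line[6:11]))
                name = line[12:16].strip()
                names.append(name)
                resnames.append(line[17:20].strip())
                chains.append(line[21].strip() or "A")
                resids.append(int(line[22:26]))
                xyz.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                elem = line[76:78].strip() if len(line) >= 78 else ""
                elems.append(elem or _guess_element(name))
            except (ValueError, IndexError):
                raise ParseError(f"{path}: malformed PDB record at line {lineno}") from None
    if not ids:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return MolecularStructure(
        atom_id=np.array(ids),
        atom_name=np.array(names, dtype=object),
        element=np.array(elems, dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(resnames, dtype=object),
        chain_id=np.array(chains, dtype=object),
        positions=np.array(xyz) / 10.0,  # A -> nm
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2] in ("CL", "NA", "MG", "ZN", "CA"):
        # two-letter ions only when the full name is the element symbol
        if stripped == stripped[:2]:
            return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def _read_plain_xyz(path) -> MolecularStructure:
    with open(path) as fh:
        lines = [ln for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty plain-xyz file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed header at line 1") from None
    ids, names, elems, resids, resnames, chains, xyz = [], [], [], [], [], [], []
    for lineno, line in enumerate(lines[1 : natoms + 1], start=2):
        tok = line.split()
        if len(tok) != 9:
            raise ParseError(f"{path}: expected 9 tokens at line {lineno}")
        try:
            ids.append(int(tok[0]))
            chains.append(tok[1])
            resids.append(int(tok[2]))
            resnames.append(tok[3])
            names.append(tok[4])
            elems.append(tok[5])
            xyz.append([float(tok[6]), float(tok[7]), float(tok[8])])
        except ValueError:
            raise ParseError(f"{path}: malformed row at line {lineno}") from None
    if len(ids) != natoms:
        raise ParseError(f"{path}: header promised {natoms} atoms, found {len(ids)}")
    return MolecularStructure(
        atom_id=np.array(ids),
        atom_name=np.array(names, dtype=object),
        element=np.array(elems, dtype=object),
        residue_id=np.array(resids),
        residue_name=np.array(resnames, dtype=object),
        chain_id=np.array(chains, dtype=object),
        positions=np.array(xyz),
    )


def write_structure(structure: MolecularStructure, path, format: str = "pdb") -> None:
    if format == "pdb":
        with open(path, "w") as fh:
            for i in range(structure.n_atoms):
                x, y, z = structure.positions[i] * 10.0  # nm -> A
                fh.write(
                    "ATOM  {:>5d} {:<4s} {:<3s} {:1s}{:>4d}    "
                    "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}          {:>2s}\n".format(
                        int(structure.atom_id[i]),
                        str(structure.atom_name[i])[:4],
                        str(structure.residue_name[i])[:3],
                        str(structure.chain_id[i])[:1],
                        int(structure.residue_id[i]),
                        x, y, z, 1.0, 0.0,
                        str(structure.element[i])[:2],
                    )
                )
            fh.write("END\n")
    elif format == "plain-xyz":
        with open(path, "w") as fh:
            fh.write(f"{structure.n_atoms}\n")
            for i in range(structure.n_atoms):
                x, y, z = structure.positions[i]
                fh.write(
                    f"{int(structure.atom_id[i])} {structure.chain_id[i]} "
                    f"{int(structure.residue_id[i])} {structure.residue_name[i]} "
                    f"{structure.atom_name[i]} {structure.element[i]} "
                    f"{x:.9f} {y:.9f} {z:.9f}\n"
                )
    else:
        raise ParseError(f"unsupported structure format {format!r}")


# ---------------------------------------------------------------------------
# trajectory I/O (plain whitespace frame format)


def read_trajectory(path, structure: MolecularStructure | None = None) -> FrameSequence:
    """Read the plain trajectory format.

    Each frame: a header ``natoms time_ps [bx by bz]`` followed by natoms
    rows ``x y z`` in nm.  If ``structure`` is given the atom count is
    checked against it.
    """
    times: list[float] = []
    frames: list[np.ndarray] = []
    boxes: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i, lineno = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        lineno += 1
        if not line or line.startswith(("#", "@")):
            continue
        tok = line.split()
        if len(tok) not in (2, 5):
            raise ParseError(f"{path}: malformed frame header at line {lineno}")
        try:
            natoms = int(tok[0])
            t = float(tok[1])
            box = [float(v) for v in tok[2:5]] if len(tok) == 5 else [0.0, 0.0, 0.0]
        except ValueError:
            raise ParseError(f"{path}: malformed frame header at line {lineno}") from None
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            if i >= len(lines):
                raise ParseError(f"{path}: truncated frame starting at line {lineno}")
            row = lines[i].split()
            i += 1
            lineno += 1
            if len(row) != 3:
                raise ParseError(f"{path}: expected 3 coordinates at line {lineno}")
            try:
                coords[k] = [float(v) for v in row]
            except ValueError:
                raise ParseError(f"{path}: non-numeric coordinate at line {lineno}") from None
        times.append(t)
        frames.append(coords)
        boxes.append(box)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    counts = {f.shape[0] for f in frames}
    if len(counts) != 1:
        raise ShapeError(f"{path}: frames have inconsistent atom counts {sorted(counts)}")
    seq = FrameSequence(np.array(times), np.array(frames), np.array(boxes))
    if structure is not None:
        seq.check_against(structure)
    return seq


def write_trajectory(frames: FrameSequence, path) -> None:
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            bx, by, bz = frames.box[f]
            fh.write(f"{frames.n_atoms} {frames.times[f]:.6f} {bx:.6f} {by:.6f} {bz:.6f}\n")
            for x, y, z in frames.positions[f]:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


# ---------------------------------------------------------------------------
# series tables (xvg-style)


def read_series_table(path, column_names: Sequence[str] | None = None) -> SeriesTable:
    """Read a whitespace/comma numeric table; '#'/'@' lines are comments."""
    rows: list[list[float]] = []
    ncol: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            tok = re.split(r"[,\s]+", s)
            try:
                vals = [float(v) for v in tok if v]
            except ValueError:
                raise ParseError(f"{path}: non-numeric token at row (line {lineno})") from None
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(vals)} columns, expected {ncol})"
                )
            rows.append(vals)
    if ncol is None:
        ncol = len(column_names) if column_names else 0
    names = list(column_names) if column_names else [f"col{i}" for i in range(ncol)]
    if rows and len(names) != ncol:
        raise ParseError(f"{path}: {ncol} columns but {len(names)} names given")
    df = pd.DataFrame(rows, columns=names, dtype=float)
    return SeriesTable(df)


def write_series_table(table: SeriesTable, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        if table.units:
            fh.write(f"# units: {table.units}\n")
        fh.write("# columns: " + " ".join(table.data.columns) + "\n")
        buf = io.StringIO()
        table.data.to_csv(buf, sep=" ", header=False, index=False, float_format="%.10g")
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# interaction parameters


def read_parameters(path) -> InteractionParameters:
    """Read the columnar parameter file.

    Sections introduced by ``[atoms]``, ``[bonds]``, ``[angles]``,
    ``[dihedrals]``, ``[settings]``.  Atom rows: ``index charge sigma
    epsilon`` (0-based index, order = structure order).  Bonded rows use
    the same 0-based indices.  Settings rows: ``key value``.
    """
    section = None
    n_declared: int | None = None
    atoms: dict[int, tuple[float, float, float]] = {}
    bonds, angles, dihedrals = [], [], []
    settings: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.split("#")[0].strip()
            if not s:
                continue
            m = re.match(r"\[(\w+)\]", s)
            if m:
                section = m.group(1).lower()
                continue
            tok = s.split()
            try:
                if section == "atoms":
                    i = int(tok[0])
                    atoms[i] = (float(tok[1]), float(tok[2]), float(tok[3]))
                elif section == "bonds":
                    bonds.append((int(tok[0]), int(tok[1]), float(tok[2]), float(tok[3])))
                elif section == "angles":
                    angles.append(
                        (int(tok[0]), int(tok[1]), int(tok[2]), float(tok[3]), float(tok[4]))
                    )
                elif section == "dihedrals":
                    dihedrals.append(
                        (int(tok[0]), int(tok[1]), int(tok[2]), int(tok[3]),
                         float(tok[4]), int(tok[5]), float(tok[6]))
                    )
                elif section == "settings":
                    settings[tok[0]] = tok[1]
                else:
                    raise ParseError(f"{path}: data before any section at line {lineno}")
            except (ValueError, IndexError):
                raise ParseError(f"{path}: malformed row at line {lineno}") from None
    if not atoms:
        raise ParameterError(f"{path}: no [atoms] section")
    n = max(atoms) + 1
    missing = [i for i in range(n) if i not in atoms]
    if missing:
        raise ParameterError(f"{path}: missing parameters for atom index {missing[0]}")
    charge = np.array([atoms[i][0] for i in range(n)])
    sigma = np.array([atoms[i][1] for i in range(n)])
    eps = np.array([atoms[i][2] for i in range(n)])
    excl = settings.get("exclusions", "1-2,1-3")
    return InteractionParameters(
        charge=charge,
        lj_sigma=sigma,
        lj_epsilon=eps,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        exclusions=frozenset(x for x in excl.split(",") if x),
        switch_on=float(settings.get("switch_on", 1.0)),
        cutoff=float(settings.get("cutoff", 1.2)),
    )


def write_parameters(params: InteractionParameters, path) -> None:
    with open(path, "w") as fh:
        fh.write("[settings]\n")
        fh.write(f"switch_on {params.switch_on}\n")
        fh.write(f"cutoff {params.cutoff}\n")
        fh.write(f"exclusions {','.join(sorted(params.exclusions))}\n")
        fh.write("[atoms]\n")
        for i in range(params.n_atoms):
            fh.write(
                f"{i} {params.charge[i]:.9g} {params.lj_sigma[i]:.9g} "
                f"{params.lj_epsilon[i]:.9g}\n"
            )
        fh.write("[bonds]\n")
        for i, j, k, r0 in params.bonds:
            fh.write(f"{i} {j} {k:.9g} {r0:.9g}\n")
        fh.write("[angles]\n")
        for i, j, k, kt, t0 in params.angles:
            fh.write(f"{i} {j} {k} {kt:.9g} {t0:.9g}\n")
        fh.write("[dihedrals]\n")
        for i, j, k, l, kp, mult, p0 in params.dihedrals:
            fh.write(f"{i} {j} {k} {l} {kp:.9g} {mult} {p0:.9g}\n")


# ---------------------------------------------------------------------------
# domain maps


def read_domain_map(path) -> DomainMap:
    """Read ``label chain first_resid last_resid`` lines into a DomainMap."""
    ranges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.split("#")[0].strip()
            if not s:
                continue
            tok = s.split()
            if len(tok) != 4:
                raise ParseError(f"{path}: expected 4 tokens at line {lineno}")
            try:
                ranges.append((tok[0], tok[1], int(tok[2]), int(tok[3])))
            except ValueError:
                raise ParseError(f"{path}: malformed row at line {lineno}") from None
    return DomainMap(ranges)


# ---------------------------------------------------------------------------
# selections

_RANGE = re.compile(r"^(-?\d+)-(-?\d+)$")


def select_group(structure: MolecularStructure, selector: str) -> list[int]:
    """Evaluate a small selection language, returning sorted unique atom_ids.

    Clauses: ``chain A [B ...]``, ``resid 5 8-12 ...``, ``name CA [CB ...]``,
    ``resname GLY ...``; joined by ``and`` (intersection, binds tighter)
    and ``or`` (union).  An empty result raises SelectionError rather than
    silently returning nothing.
    """
    selector = selector.strip()
    if not selector:
        raise SelectionError("empty selector")
    union: np.ndarray | None = None
    for disjunct in re.split(r"\s+or\s+", selector):
        mask = np.ones(structure.n_atoms, dtype=bool)
        for clause in re.split(r"\s+and\s+", disjunct.strip()):
            mask &= _clause_mask(structure, clause.strip())
        union = mask if union is None else (union | mask)
    ids = structure.atom_id[union]
    if len(ids) == 0:
        raise SelectionError(f"selector {selector!r} matched no atoms")
    return sorted(int(a) for a in np.unique(ids))


def _clause_mask(structure: MolecularStructure, clause: str) -> np.ndarray:
    tok = clause.split()
    if len(tok) < 2:
        raise SelectionError(f"malformed selection clause {clause!r}")
    kind, args = tok[0].lower(), tok[1:]
    if kind == "chain":
        present = set(map(str, structure.chain_id))
        missing = [a for a in args if a not in present]
        if missing:
            raise SelectionError(f"chain(s) {missing} not present in structure")
        return np.isin(structure.chain_id.astype(str), args)
    if kind == "resid":
        wanted: set[int] = set()
        for a in args:
            m = _RANGE.match(a)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                wanted.update(range(lo, hi + 1))
            else:
                try:
                    wanted.add(int(a))
                except ValueError:
                    raise SelectionError(f"bad resid token {a!r}") from None
        return np.isin(structure.residue_id, sorted(wanted))
    if kind == "name":
        return np.isin(structure.atom_name.astype(str), args)
    if kind == "resname":
        return np.isin(structure.residue_name.astype(str), args)
    raise SelectionError(f"unknown selection keyword {kind!r}")
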