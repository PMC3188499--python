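"""Threading of Cxxx sequences onto the template backbone, side-chain
construction from a rotamer library, and rotamer packing.

A :class:`PoseModel` couples Cartesian coordinates with a torsion-space
kinematic chart: peptide phi/psi/omega and chi angles, a 6-DOF rigid-body
placement of the peptide, receptor side-chain chi angles and ligand chain
dihedrals. Internal coordinates (bond lengths, angles, torsion offsets) are
measured once at threading time, so rebuilding with an unchanged torsion
state reproduces the input coordinates exactly.
"""
from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._geometry import bond_angle, bond_length, dihedral, place_atom, rotation_matrix
from .structio import TemplateComplex
from .topology import (
    AA1_TO_3,
    AA3_TO_1,
    BB,
    CHI_ATOMS,
    SIDECHAIN_ZMAT,
    assign_atom_type,
    n_chi,
    residue_bonds,
    sidechain_atom_names,
)

__all__ = [
    "PeptideSequence",
    "RotamerLibrary",
    "PoseModel",
    "thread_sequence",
    "build_sidechain",
    "pack_sidechains",
]

ROLES = ("C", "a1", "a2", "X")


@dataclass(frozen=True)
class PeptideSequence:
    """A four-residue Cxxx motif (positions C, a1, a2, X)."""

    letters: str

    def __post_init__(self) -> None:
        if len(self.letters) != 4:
            raise ValueError(f"Cxxx motif must have 4 residues, got {self.letters!r}")
        if self.letters[0] != "C":
            raise ValueError(
                f"motif position 1 must be cysteine, got {self.letters!r}"
            )
        for ch in self.letters:
            if ch not in AA1_TO_3:
                raise ValueError(f"non-standard amino acid letter {ch!r}")

    @property
    def roles(self) -> Tuple[str, ...]:
        return ROLES

    def type3(self, i: int) -> str:
        return AA1_TO_3[self.letters[i]]

    def __str__(self) -> str:
        return self.letters


class RotamerLibrary:
    """Coarse backbone-independent chi-angle rotamer library."""

    def __init__(self, rotamers: Dict[str, List[Tuple[float, ...]]]):
        self._rot = rotamers
        for res3, entries in rotamers.items():
            if not entries:
                raise ValueError(f"residue {res3} has no rotamer entries")

    @classmethod
    def from_file(cls, path) -> "RotamerLibrary":
        rot: Dict[str, List[Tuple[float, ...]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                parts = line.split()
                rot.setdefault(parts[0], []).append(tuple(float(x) for x in parts[1:]))
        return cls(rot)

    _default: Optional["RotamerLibrary"] = None

    @classmethod
    def default(cls) -> "RotamerLibrary":
        if cls._default is None:
            ref = resources.files("caaxbind") / "data" / "rotamers.txt"
            with resources.as_file(ref) as path:
                cls._default = cls.from_file(path)
        return cls._default

    def rotamers(self, res3: str, extra_chi: bool = False) -> List[Tuple[float, ...]]:
        """Rotamers for a residue type; ``extra_chi`` adds +-10 degree
        sub-rotamers on chi1 and chi2."""
        base = self._rot[res3]
        expected = n_chi(res3)
        out: List[Tuple[float, ...]] = []
        for entry in base:
            if len(entry) != expected:
                raise ValueError(
                    f"rotamer {entry} for {res3} has {len(entry)} chis, "
                    f"expected {expected}"
                )
            if not extra_chi or expected == 0:
                out.append(entry)
                continue
            n_expand = min(2, expected)
            offsets = itertools.product((-10.0, 0.0, 10.0), repeat=n_expand)
            for off in offsets:
                expanded = tuple(
                    entry[k] + (off[k] if k < n_expand else 0.0)
                    for k in range(expected)
                )
                out.append(expanded)
        return out


# ---------------------------------------------------------------------------
# Side-chain construction
# ---------------------------------------------------------------------------

def build_sidechain(
    residue_type: str,
    backbone_frame: Dict[str, np.ndarray],
    chi_tuple: Sequence[float],
) -> Dict[str, np.ndarray]:
    """Build side-chain heavy atoms (CB outward) at ideal geometry.

    ``backbone_frame`` must provide N, CA and C coordinates. Returns an
    ordered mapping of atom name to position; GLY returns an empty mapping.
    """
    if residue_type not in SIDECHAIN_ZMAT:
        raise ValueError(f"unknown residue type {residue_type!r}")
    expected = n_chi(residue_type)
    if len(chi_tuple) != expected:
        raise ValueError(
            f"{residue_type} takes {expected} chi angles, got {len(chi_tuple)}"
        )
    out: Dict[str, np.ndarray] = {}
    if residue_type == "GLY":
        return out
    n, ca, c = backbone_frame["N"], backbone_frame["CA"], backbone_frame["C"]
    coords = {"N": n, "CA": ca, "C": c}
    cb = place_atom(n, c, ca, BB["CB_bond"], BB["CB_angle"], BB["CB_improper"])
    coords["CB"] = cb
    out["CB"] = cb
    for name, refs, bond, angle, torspec in SIDECHAIN_ZMAT[residue_type]:
        if isinstance(torspec, tuple):
            _, k, offset = torspec
            torsion = chi_tuple[k - 1] + offset
        else:
            torsion = float(torspec)
        pos = place_atom(
            coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, angle, torsion
        )
        coords[name] = pos
        out[name] = pos
    return out


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass
class _ZEntry:
    atom: int
    ia: int
    ib: int
    ic: int
    r: float
    theta: float
    driver: Optional[int]  # DOF index, or None for a constant torsion
    offset: float          # torsion = state[driver] + offset (or just offset)


@dataclass
class _ResInfo:
    segment: int  # 0 receptor, 1 peptide, 2 ligand
    chain: str
    seqpos: int
    type3: str
    atoms: Dict[str, int] = field(default_factory=dict)


class PoseModel:
    """Full-atom model of one threaded Cxxx sequence in the template pocket."""

    SEG_RECEPTOR, SEG_PEPTIDE, SEG_LIGAND = 0, 1, 2

    def __init__(self) -> None:
        self.template: Optional[TemplateComplex] = None
        self.sequence: Optional[PeptideSequence] = None
        self.names: List[str] = []
        self.segment: np.ndarray = np.empty(0, dtype=np.int8)
        self.res_of: np.ndarray = np.empty(0, dtype=np.int32)
        self.residues: List[_ResInfo] = []
        self.base_coords: np.ndarray = np.empty((0, 3))
        self.coords: np.ndarray = np.empty((0, 3))
        self.bonds: List[Tuple[int, int]] = []
        self.entries: List[_ZEntry] = []
        self.dof_names: List[tuple] = []
        self.dof_pos: Dict[tuple, int] = {}
        self.state: np.ndarray = np.empty(0)
        self._pep_atom_idx: np.ndarray = np.empty(0, dtype=np.int64)
        self._pep_centroid: np.ndarray = np.zeros(3)

    # -- lookup ------------------------------------------------------------
    def atom_index(self, address: tuple) -> int:
        """Resolve ('pep', pos, name), ('rec', chain, seqpos, name) or
        ('lig', name) to a flat atom index."""
        kind = address[0]
        if kind == "pep":
            _, pos, name = address
            res = self.residues[self._pep_res_start + pos]
        elif kind == "rec":
            _, chain, seqpos, name = address
            res = next(
                (
                    r
                    for r in self.residues
                    if r.segment == self.SEG_RECEPTOR
                    and r.chain == chain
                    and r.seqpos == seqpos
                ),
                None,
            )
            if res is None:
                raise KeyError(f"no receptor residue {chain}:{seqpos}")
        elif kind == "lig":
            _, name = address
            res = next(
                (r for r in self.residues if r.segment == self.SEG_LIGAND), None
            )
            if res is None:
                raise KeyError("pose has no ligand")
        else:
            raise KeyError(f"unknown atom address kind {kind!r}")
        try:
            return res.atoms[name]
        except KeyError:
            raise KeyError(f"no atom {name!r} at address {address}") from None

    @property
    def peptide_residue_indices(self) -> List[int]:
        return [
            i for i, r in enumerate(self.residues) if r.segment == self.SEG_PEPTIDE
        ]

    def chi_state(self, pos: int) -> Tuple[float, ...]:
        res3 = self.sequence.type3(pos)
        return tuple(
            self.state[self.dof_pos[("pchi", pos, k)]]
            for k in range(1, n_chi(res3) + 1)
        )

    # -- rebuild -----------------------------------------------------------
    def rebuild(self, state: Optional[np.ndarray] = None) -> np.ndarray:
        """Rebuild Cartesian coordinates from the torsion state."""
        if state is None:
            state = self.state
        if len(state) != len(self.dof_names):
            raise ValueError(
                f"torsion state has {len(state)} entries, expected "
                f"{len(self.dof_names)}"
            )
        # inlined scalar NeRF placement (hot loop: called inside minimization)
        from math import cos, radians, sin, sqrt

        cl = self.base_coords.tolist()
        for e in self.entries:
            torsion = e.offset if e.driver is None else state[e.driver] + e.offset
            ax, ay, az = cl[e.ia]
            bx, by, bz = cl[e.ib]
            cx, cy, cz = cl[e.ic]
            # bc = normalize(c - b); n = normalize(bc x (b - a)); m = bc x n
            ux, uy, uz = cx - bx, cy - by, cz - bz
            inv = 1.0 / sqrt(ux * ux + uy * uy + uz * uz)
            ux, uy, uz = ux * inv, uy * inv, uz * inv
            vx, vy, vz = bx - ax, by - ay, bz - az
            nx = uy * vz - uz * vy
            ny = uz * vx - ux * vz
            nz = ux * vy - uy * vx
            inv = 1.0 / sqrt(nx * nx + ny * ny + nz * nz)
            nx, ny, nz = nx * inv, ny * inv, nz * inv
            mx = uy * nz - uz * ny
            my = uz * nx - ux * nz
            mz = ux * ny - uy * nx
            th = radians(e.theta)
            ph = radians(torsion)
            d0 = -e.r * cos(th)
            st = e.r * sin(th)
            d1 = st * cos(ph)
            d2 = st * sin(ph)
            cl[e.atom] = [
                cx + d0 * ux + d1 * mx + d2 * nx,
                cy + d0 * uy + d1 * my + d2 * ny,
                cz + d0 * uz + d1 * mz + d2 * nz,
            ]
        coords = np.asarray(cl)
        # rigid-body DOFs applied last, about the initial peptide centroid
        rb = state[self._rb_slice]
        if np.any(rb != 0.0):
            rot = rotation_matrix(np.radians(rb[:3]))
            pep = self._pep_atom_idx
            c0 = self._pep_centroid
            coords[pep] = (coords[pep] - c0) @ rot.T + c0 + rb[3:]
        return coords

    def set_state(self, state: np.ndarray) -> None:
        self.state = np.asarray(state, dtype=float).copy()
        self.coords = self.rebuild(self.state)

    def set_dofs(self, values: Dict[tuple, float]) -> None:
        state = self.state.copy()
        for key, val in values.items():
            state[self.dof_pos[key]] = val
        self.set_state(state)

    def copy(self) -> "PoseModel":
        new = PoseModel.__new__(PoseModel)
        new.__dict__.update(self.__dict__)
        new.state = self.state.copy()
        new.coords = self.coords.copy()
        return new


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------

def thread_sequence(
    template: TemplateComplex,
    sequence: PeptideSequence | str,
    rotamer_library: Optional[RotamerLibrary] = None,
    ligand_flexible: bool = True,
) -> PoseModel:
    """Thread a Cxxx sequence onto the fixed template peptide backbone.

    Backbone heavy atoms (N, CA, C, O, OXT) are copied from the template;
    side chains are built at ideal geometry in the library's first rotamer.
    """
    if isinstance(sequence, str):
        sequence = PeptideSequence(sequence)
    lib = rotamer_library or RotamerLibrary.default()

    pose = PoseModel()
    pose.template = template
    pose.sequence = sequence

    names: List[str] = []
    seg: List[int] = []
    res_of: List[int] = []
    coords: List[np.ndarray] = []
    bonds: List[Tuple[int, int]] = []

    def add_atom(res_idx: int, name: str, xyz: np.ndarray, segment: int) -> int:
        idx = len(names)
        names.append(name)
        seg.append(segment)
        res_of.append(res_idx)
        coords.append(np.asarray(xyz, dtype=float))
        pose.residues[res_idx].atoms[name] = idx
        return idx

    # receptor ------------------------------------------------------------
    prev_c: Optional[int] = None
    prev_chain: Optional[str] = None
    for chain_id, residues in template.receptor.chains.items():
        for res in residues:
            ri = len(pose.residues)
            pose.residues.append(
                _ResInfo(PoseModel.SEG_RECEPTOR, res.chain, res.seqpos, res.type3)
            )
            for atom in res.atoms:
                add_atom(ri, atom.name, atom.xyz, PoseModel.SEG_RECEPTOR)
            amap = pose.residues[ri].atoms
            for a, b in residue_bonds(res.type3, c_terminal="OXT" in amap):
                if a in amap and b in amap:
                    bonds.append((amap[a], amap[b]))
            if (
                prev_c is not None
                and prev_chain == chain_id
                and "N" in amap
                and bond_length(coords[prev_c], coords[amap["N"]]) < 1.8
            ):
                bonds.append((prev_c, amap["N"]))
            prev_c = amap.get("C")
            prev_chain = chain_id

    # peptide --------------------------------------------------------------
    pose._pep_res_start = len(pose.residues)
    pep_chain = template.peptide_chain
    for i, tres in enumerate(template.peptide):
        type3 = sequence.type3(i)
        ri = len(pose.residues)
        pose.residues.append(_ResInfo(PoseModel.SEG_PEPTIDE, pep_chain, tres.seqpos, type3))
        frame = {nm: tres.atom(nm).xyz for nm in ("N", "CA", "C")}
        for nm in ("N", "CA", "C", "O"):
            add_atom(ri, nm, tres.atom(nm).xyz, PoseModel.SEG_PEPTIDE)
        if i == 3:
            add_atom(ri, "OXT", tres.atom("OXT").xyz, PoseModel.SEG_PEPTIDE)
        first_rot = lib.rotamers(type3)[0]
        for nm, xyz in build_sidechain(type3, frame, first_rot).items():
            add_atom(ri, nm, xyz, PoseModel.SEG_PEPTIDE)
        amap = pose.residues[ri].atoms
        for a, b in residue_bonds(type3, c_terminal=(i == 3)):
            if a in amap and b in amap:
                bonds.append((amap[a], amap[b]))
        if i > 0:
            prev = pose.residues[ri - 1].atoms
            bonds.append((prev["C"], amap["N"]))

    # ligand ---------------------------------------------------------------
    if template.ligand is not None:
        ri = len(pose.residues)
        lig = template.ligand
        pose.residues.append(_ResInfo(PoseModel.SEG_LIGAND, lig.chain, lig.seqpos, lig.type3))
        lig_idx = [
            add_atom(ri, a.name, a.xyz, PoseModel.SEG_LIGAND) for a in lig.atoms
        ]
        for a, b in zip(lig_idx, lig_idx[1:]):  # chain topology
            if bond_length(coords[a], coords[b]) < 2.1:
                bonds.append((a, b))
    else:
        lig_idx = []

    pose.names = names
    pose.segment = np.array(seg, dtype=np.int8)
    pose.res_of = np.array(res_of, dtype=np.int32)
    pose.base_coords = np.array(coords)
    pose.bonds = bonds
    _build_kinematics(pose, lig_idx, ligand_flexible)
    # threading copies the template backbone bitwise; rebuilding with the
    # measured torsion state must reproduce it (to numerical precision)
    pose.coords = pose.base_coords.copy()
    if not np.allclose(pose.rebuild(), pose.base_coords, atol=1e-6):
        raise RuntimeError("kinematic chart inconsistent with coordinates")
    return pose


def _build_kinematics(pose: PoseModel, lig_idx: List[int], ligand_flexible: bool) -> None:
    """Create the DOF layout and z-matrix entries, measuring internal
    coordinates from the current base coordinates."""
    X = pose.base_coords
    dof_names: List[tuple] = []

    pep_res = pose.peptide_residue_indices
    bb = [pose.residues[ri].atoms for ri in pep_res]

    for i in range(4):
        dof_names.append(("psi", i))
    for i in range(1, 4):
        dof_names.append(("phi", i))
        dof_names.append(("omega", i))
    for i in range(4):
        for k in range(1, n_chi(pose.sequence.type3(i)) + 1):
            dof_names.append(("pchi", i, k))
    rb_start = len(dof_names)
    for j in range(6):
        dof_names.append(("rb", j))
    for gi, res in enumerate(pose.residues):
        if res.segment != PoseModel.SEG_RECEPTOR:
            continue
        chis = CHI_ATOMS.get(res.type3, [])
        if not chis:
            continue
        if not all(
            all(nm in res.atoms for nm in quad) for quad in chis
        ):
            continue  # incomplete side chain: keep rigid
        for k in range(1, len(chis) + 1):
            dof_names.append(("rchi", gi, k))
    if ligand_flexible and len(lig_idx) >= 4:
        for k in range(len(lig_idx) - 3):
            dof_names.append(("lig", k))

    pose.dof_names = dof_names
    pose.dof_pos = {name: i for i, name in enumerate(dof_names)}
    pose._rb_slice = slice(rb_start, rb_start + 6)
    state = np.zeros(len(dof_names))

    def tors(i0: int, i1: int, i2: int, i3: int) -> float:
        return dihedral(X[i0], X[i1], X[i2], X[i3])

    # measure backbone DOFs
    for i in range(4):
        n_, ca_, c_ = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        if i < 3:
            state[pose.dof_pos[("psi", i)]] = tors(n_, ca_, c_, bb[i + 1]["N"])
        else:
            state[pose.dof_pos[("psi", i)]] = tors(n_, ca_, c_, bb[i]["O"]) - 180.0
        if i > 0:
            state[pose.dof_pos[("omega", i)]] = tors(
                bb[i - 1]["CA"], bb[i - 1]["C"], n_, ca_
            )
            state[pose.dof_pos[("phi", i)]] = tors(bb[i - 1]["C"], n_, ca_, c_)

    # measure chi DOFs (peptide + receptor)
    for i in range(4):
        res3 = pose.sequence.type3(i)
        amap = bb[i]
        for k, quad in enumerate(CHI_ATOMS.get(res3, []), start=1):
            state[pose.dof_pos[("pchi", i, k)]] = tors(*(amap[nm] for nm in quad))
    for name in dof_names:
        if name[0] == "rchi":
            _, gi, k = name
            res = pose.residues[gi]
            quad = CHI_ATOMS[res.type3][k - 1]
            state[pose.dof_pos[name]] = tors(*(res.atoms[nm] for nm in quad))

    entries: List[_ZEntry] = []

    def add_entry(atom: int, refs: Tuple[int, int, int], driver: Optional[tuple]) -> None:
        ia, ib, ic = refs
        r = bond_length(X[ic], X[atom])
        theta = bond_angle(X[ib], X[ic], X[atom])
        measured = dihedral(X[ia], X[ib], X[ic], X[atom])
        if driver is None:
            entries.append(_ZEntry(atom, ia, ib, ic, r, theta, None, measured))
        else:
            di = pose.dof_pos[driver]
            offset = measured - state[di]
            entries.append(_ZEntry(atom, ia, ib, ic, r, theta, di, offset))

    # peptide backbone beyond the seed triad (N1, CA1, C1)
    for i in range(1, 4):
        p, q = bb[i - 1], bb[i]
        add_entry(q["N"], (p["N"], p["CA"], p["C"]), ("psi", i - 1))
        add_entry(q["CA"], (p["CA"], p["C"], q["N"]), ("omega", i))
        add_entry(q["C"], (p["C"], q["N"], q["CA"]), ("phi", i))
    for i in range(4):
        amap = bb[i]
        add_entry(amap["O"], (amap["N"], amap["CA"], amap["C"]), ("psi", i))
        if "OXT" in amap:
            add_entry(amap["OXT"], (amap["N"], amap["CA"], amap["C"]), ("psi", i))
        res3 = pose.sequence.type3(i)
        if "CB" in amap:
            add_entry(amap["CB"], (amap["N"], amap["C"], amap["CA"]), None)
        for nm, refs, _, _, torspec in SIDECHAIN_ZMAT.get(res3, []):
            driver = ("pchi", i, torspec[1]) if isinstance(torspec, tuple) else None
            add_entry(amap[nm], tuple(amap[r] for r in refs), driver)

    # receptor side chains (beyond CB) for residues with measured chis
    rchi_res = sorted({name[1] for name in dof_names if name[0] == "rchi"})
    for gi in rchi_res:
        res = pose.residues[gi]
        amap = res.atoms
        for nm, refs, _, _, torspec in SIDECHAIN_ZMAT.get(res.type3, []):
            if nm not in amap or not all(r in amap for r in refs):
                continue
            driver = ("rchi", gi, torspec[1]) if isinstance(torspec, tuple) else None
            add_entry(amap[nm], tuple(amap[r] for r in refs), driver)

    # ligand chain dihedrals
    if ligand_flexible and len(lig_idx) >= 4:
        for k in range(len(lig_idx) - 3):
            a, b, c, d = lig_idx[k : k + 4]
            state[pose.dof_pos[("lig", k)]] = dihedral(X[a], X[b], X[c], X[d])
            add_entry(d, (a, b, c), ("lig", k))

    pose.entries = entries
    pose.state = state
    pose._pep_atom_idx = np.where(pose.segment == PoseModel.SEG_PEPTIDE)[0]
    pose._pep_centroid = X[pose._pep_atom_idx].mean(axis=0)


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------

def sequence_seed(seed: int, sequence: str) -> int:
    """Stable per-sequence RNG seed (independent of evaluation order)."""
    return zlib.crc32(f"{seed}:{sequence}".encode()) & 0x7FFFFFFF


def pack_sidechains(
    pose: PoseModel,
    flexible_positions: Sequence[int],
    extra_chi: bool = False,
    energy_fn=None,
    seed: int = 0,
    rotamer_library: Optional[RotamerLibrary] = None,
    exhaustive_limit: int = 100_000,
    anneal_sweeps: int = 300,
) -> PoseModel:
    """Find the lowest-energy rotamer assignment for the peptide side chains.

    Exhaustive enumeration is used when the rotamer combination count is at
    most ``exhaustive_limit``; larger search spaces fall back to seeded
    simulated annealing on the precomputed single/pair energy tables. The
    receptor stays fixed during packing. Ties break toward the lowest
    library index.
    """
    from .energy import EnergyFunction, ScoringModel  # local import, no cycle

    if not flexible_positions:
        return pose.copy()
    flexible_positions = sorted(set(flexible_positions))
    for p in flexible_positions:
        if p not in range(4):
            raise ValueError(f"flexible position {p} outside peptide (0-3)")
    efn = energy_fn or EnergyFunction.default()
    lib = rotamer_library or RotamerLibrary.default()

    model = ScoringModel(pose, efn)
    base_state = pose.state.copy()

    # candidate chi tuples per position (current assignment kept as candidate
    # so packing can never increase the energy)
    candidates: List[List[Tuple[float, ...]]] = []
    positions: List[int] = []
    for p in flexible_positions:
        res3 = pose.sequence.type3(p)
        if n_chi(res3) == 0:
            continue
        cands = list(lib.rotamers(res3, extra_chi=extra_chi))
        current = pose.chi_state(p)
        cands.append(current)
        candidates.append(cands)
        positions.append(p)
    if not positions:
        return pose.copy()

    # moving atom sets: side-chain atoms beyond CB for each flexible position
    moving: List[np.ndarray] = []
    for p in positions:
        res = pose.residues[pose._pep_res_start + p]
        idx = [
            res.atoms[nm]
            for nm in sidechain_atom_names(res.type3)
            if nm != "CB" and nm in res.atoms
        ]
        moving.append(np.array(idx, dtype=np.int64))
    fixed_mask = np.ones(len(pose.names), dtype=bool)
    for idx in moving:
        fixed_mask[idx] = False

    # per-rotamer coordinates of the moving atoms
    rot_coords: List[List[np.ndarray]] = []
    for pi, p in enumerate(positions):
        per_rot = []
        for chis in candidates[pi]:
            st = base_state.copy()
            for k, chi in enumerate(chis, start=1):
                st[pose.dof_pos[("pchi", p, k)]] = chi
            coords = pose.rebuild(st)
            per_rot.append(coords[moving[pi]])
        rot_coords.append(per_rot)

    # energy tables, using pair subsets restricted to the relevant atom sets
    fixed_idx = np.where(fixed_mask)[0]
    work = pose.coords.copy()
    singles = []
    for pi in range(len(positions)):
        sub = model.restricted_between(moving[pi], fixed_idx)
        intra = model.restricted_within(moving[pi])
        e = np.empty(len(candidates[pi]))
        for r, block in enumerate(rot_coords[pi]):
            work[moving[pi]] = block
            e[r] = sub.total(work) + intra.total(work)
        work[moving[pi]] = pose.coords[moving[pi]]
        singles.append(e)
    pairs: Dict[Tuple[int, int], np.ndarray] = {}
    for pi in range(len(positions)):
        for qi in range(pi + 1, len(positions)):
            sub = model.restricted_between(moving[pi], moving[qi])
            tab = np.empty((len(candidates[pi]), len(candidates[qi])))
            for r, block_r in enumerate(rot_coords[pi]):
                work[moving[pi]] = block_r
                for s, block_s in enumerate(rot_coords[qi]):
                    work[moving[qi]] = block_s
                    tab[r, s] = sub.total(work)
                work[moving[qi]] = pose.coords[moving[qi]]
            work[moving[pi]] = pose.coords[moving[pi]]
            pairs[(pi, qi)] = tab

    n_comb = int(np.prod([len(c) for c in candidates]))
    if n_comb <= exhaustive_limit:
        assignment = _pack_exhaustive(singles, pairs)
    else:
        assignment = _pack_anneal(
            singles, pairs, rng=np.random.default_rng(seed), sweeps=anneal_sweeps
        )

    new_pose = pose.copy()
    updates: Dict[tuple, float] = {}
    for pi, p in enumerate(positions):
        for k, chi in enumerate(candidates[pi][assignment[pi]], start=1):
            updates[("pchi", p, k)] = chi
    new_pose.set_dofs(updates)
    return new_pose


def _pack_exhaustive(singles, pairs) -> Tuple[int, ...]:
    shapes = [len(s) for s in singles]
    n = len(shapes)
    total = np.zeros(shapes)
    for pi, s in enumerate(singles):
        shape = [1] * n
        shape[pi] = shapes[pi]
        total = total + s.reshape(shape)
    for (pi, qi), tab in pairs.items():
        shape = [1] * n
        shape[pi] = shapes[pi]
        shape[qi] = shapes[qi]
        total = total + tab.reshape(shape)
    flat = int(np.argmin(total))  # argmin takes the first (lowest-index) tie
    return tuple(int(i) for i in np.unravel_index(flat, shapes))


def _pack_anneal(singles, pairs, rng, sweeps: int) -> Tuple[int, ...]:
    n = len(singles)
    assignment = [0] * n

    def energy_of(asgn) -> float:
        e = sum(singles[pi][asgn[pi]] for pi in range(n))
        for (pi, qi), tab in pairs.items():
            e += tab[asgn[pi], asgn[qi]]
        return float(e)

    # greedy start from single-body minima
    assignment = [int(np.argmin(s)) for s in singles]
    current = energy_of(assignment)
    best, best_e = list(assignment), current
    t0, t1 = 5.0, 0.05
    for sweep in range(sweeps):
        temp = t0 * (t1 / t0) ** (sweep / max(1, sweeps - 1))
        for pi in range(n):
            prop = int(rng.integers(len(singles[pi])))
            if prop == assignment[pi]:
                continue
            old = assignment[pi]
            assignment[pi] = prop
            trial = energy_of(assignment)
            if trial <= current or rng.random() < np.exp(-(trial - current) / temp):
                current = trial
                if current < best_e - 1e-12:
                    best_e, best = current, list(assignment)
            else:
                assignment[pi] = old
    return tuple(best)
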