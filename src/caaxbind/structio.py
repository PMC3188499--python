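"""PDB structure I/O and scoring-template preparation.

The reader implements a deliberately narrow PDB dialect: first MODEL only,
altLoc resolved to the highest-occupancy conformer (ties broken by the
alphabetically first altLoc code), insertion codes kept as part of the
residue key. Structures are handled heavy-atom-or-as-deposited; no repair is
attempted beyond building a missing C-terminal OXT.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._geometry import bond_length, dihedral, place_atom
from .topology import element_of

__all__ = [
    "Atom", "Residue", "Structure", "TemplateComplex",
    "PDBParseError", "TemplateError",
    "read_pdb", "write_pdb", "prepare_template", "parse_anchor_address",
]

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}
METAL_CODES = {"ZN", "MG", "MN", "FE", "CA", "NA", "K", "CD", "NI", "CU"}


class PDBParseError(ValueError):
    pass


class TemplateError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite values")


@dataclass
class Residue:
    type3: str
    seqpos: int
    chain: str
    atoms: List[Atom] = field(default_factory=list)
    icode: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.chain}:{self.seqpos} {self.type3}"
            )

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {self.chain}:{self.seqpos} {self.type3}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain, self.seqpos, self.icode)


@dataclass
class Structure:
    chains: Dict[str, List[Residue]] = field(default_factory=dict)
    title: str = ""

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def get_residue(self, chain: str, seqpos: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain, []):
            if res.seqpos == seqpos and res.icode == icode:
                return res
        raise KeyError(f"no residue {chain}:{seqpos}{icode}")


@dataclass
class TemplateComplex:
    """A prepared scoring template: receptor, 4-residue Cxxx peptide
    (positions C, a1, a2, X) and an optional rigid ligand, plus the resolved
    anchor atoms used to derive the conserved distance constraints."""

    receptor: Structure
    peptide: List[Residue]
    ligand: Optional[Residue]
    anchor_atoms: Dict[str, Tuple[str, int, str]]  # name -> (chain, seqpos, atom)
    peptide_chain: str = "B"

    ANCHOR_NAMES = ("q_alpha", "r_beta", "zn_triad_1", "zn_triad_2", "zn_triad_3")

    def __post_init__(self) -> None:
        if len(self.peptide) != 4:
            raise TemplateError("template peptide must contain exactly 4 residues")
        if self.peptide[0].type3 != "CYS":
            raise TemplateError(
                "template peptide must present Cys at motif position 1"
            )
        if not self.peptide[0].has_atom("SG"):
            raise TemplateError("template Cys lacks an SG atom")
        xres = self.peptide[3]
        if not (xres.has_atom("O") and xres.has_atom("OXT")):
            raise TemplateError("X residue must carry both carboxylate oxygens")
        for name in self.ANCHOR_NAMES:
            if name not in self.anchor_atoms:
                raise TemplateError(f"unresolved anchor {name!r}")
            self.anchor_atom(name)  # raises if unresolvable

    def anchor_atom(self, name: str) -> Atom:
        chain, seqpos, atom_name = self.anchor_atoms[name]
        try:
            return self.receptor.get_residue(chain, seqpos).atom(atom_name)
        except KeyError as exc:
            raise TemplateError(
                f"anchor {name!r} does not resolve: missing {chain}:{seqpos}:{atom_name}"
            ) from exc

    def peptide_sequence(self) -> str:
        from .topology import AA3_TO_1

        return "".join(AA3_TO_1.get(r.type3, "X") for r in self.peptide)

    def to_structure(self) -> Structure:
        """Merge receptor, peptide and ligand back into a single Structure
        (e.g. for writing to PDB or re-running prepare_template)."""
        merged = Structure(title=self.receptor.title)
        for chain_id, residues in self.receptor.chains.items():
            merged.chains[chain_id] = list(residues)
        merged.chains.setdefault(self.peptide_chain, []).extend(self.peptide)
        if self.ligand is not None:
            merged.chains.setdefault(self.ligand.chain, []).append(self.ligand)
        return merged

    def carboxylate_oxygen(self) -> str:
        """Name of the carboxylate oxygen nearer the Q-anchor atom (the
        hydrogen-bond partner used for the carboxylate constraint)."""
        q = self.anchor_atom("q_alpha").xyz
        xres = self.peptide[3]
        return min(("O", "OXT"), key=lambda n: bond_length(xres.atom(n).xyz, q))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_pdb(source: str | Path) -> Structure:
    """Parse PDB-format text (or a path to it) into a Structure."""
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source.strip()
        and "\n" not in source
        and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if not text.strip():
        raise PDBParseError("empty PDB input")

    title = ""
    # residue key -> {atom name -> list of (altloc, occupancy, Atom)}
    order: List[Tuple[str, int, str]] = []
    residue_info: Dict[Tuple[str, int, str], Tuple[str, bool]] = {}
    atom_alts: Dict[Tuple[str, int, str], Dict[str, List[Tuple[str, float, Atom]]]] = {}
    atom_order: Dict[Tuple[str, int, str], List[str]] = {}
    n_records = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "TITLE ":
            title += line[10:].rstrip() + " "
        elif rec == "ENDMDL":
            break  # first MODEL only
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                res3 = line[17:20].strip()
                chain = line[21].strip() or " "
                seqpos = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ_field = line[54:60].strip()
                occ = float(occ_field) if occ_field else 1.0
                elem = line[76:78].strip() or element_of(name)
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"malformed {rec.strip()} record at line {lineno}: {exc}"
                ) from None
            n_records += 1
            key = (chain, seqpos, icode)
            if key not in residue_info:
                residue_info[key] = (res3, rec == "HETATM")
                order.append(key)
                atom_alts[key] = {}
                atom_order[key] = []
            atom = Atom(name=name, element=elem, xyz=np.array([x, y, z]),
                        occupancy=occ, is_hetero=(rec == "HETATM"))
            if name not in atom_alts[key]:
                atom_order[key].append(name)
                atom_alts[key][name] = []
            atom_alts[key][name].append((altloc, occ, atom))

    if n_records == 0:
        raise PDBParseError("no ATOM/HETATM records found")

    structure = Structure(title=title.strip())
    for key in order:
        chain, seqpos, icode = key
        res3, _ = residue_info[key]
        atoms = []
        for name in atom_order[key]:
            # highest occupancy wins; ties -> alphabetically first altLoc
            best = sorted(atom_alts[key][name], key=lambda t: (-t[1], t[0]))[0][2]
            atoms.append(best)
        res = Residue(type3=res3, seqpos=seqpos, chain=chain, atoms=atoms,
                      icode=icode)
        structure.chains.setdefault(chain, []).append(res)
    return structure


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pdb(structure: Structure) -> str:
    """Serialize a Structure to fixed-column PDB text."""
    if structure.n_atoms() == 0:
        raise ValueError("cannot write an empty structure")
    lines: List[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    serial = 1
    chain_ids = list(structure.chains)
    for chain_id in chain_ids:
        last = None
        for res in structure.chains[chain_id]:
            for atom in res.atoms:
                if len(atom.name) > 4:
                    raise ValueError(f"atom name too long for PDB: {atom.name!r}")
                rec = "HETATM" if atom.is_hetero else "ATOM  "
                # standard alignment: 1-3 char names start in column 14
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                lines.append(
                    f"{rec}{serial:>5d} {name}{'':1s}{res.type3:>3s} "
                    f"{res.chain:1s}{res.seqpos:>4d}{res.icode:1s}   "
                    f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:>5d}      {last.type3:>3s} "
                f"{last.chain:1s}{last.seqpos:>4d}{last.icode:1s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Template preparation
# ---------------------------------------------------------------------------

def parse_anchor_address(text: str) -> Tuple[str, int, str]:
    """Parse 'chain:seqpos:atom' anchor addresses."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ValueError(f"anchor address must be chain:seqpos:atom, got {text!r}")
    return parts[0], int(parts[1]), parts[2]


def _build_oxt(res: Residue) -> None:
    """Construct a missing C-terminal OXT at ideal sp2 carboxylate geometry:
    in the N-CA-C plane, completing the O=C-OXT fork."""
    n, ca, c, o = (res.atom(x).xyz for x in ("N", "CA", "C", "O"))
    tor_o = dihedral(n, ca, c, o)
    oxt = place_atom(n, ca, c, 1.25, 117.0, tor_o + 180.0)
    res.atoms.append(Atom(name="OXT", element="O", xyz=oxt))


def prepare_template(
    structure: Structure,
    peptide_chain: str,
    ligand_codes: Sequence[str] = (),
    receptor_chains: Optional[Sequence[str]] = None,
    anchors: Optional[Dict[str, str]] = None,
) -> TemplateComplex:
    """Prepare the scoring template from a receptor-peptide complex.

    The peptide chain is truncated to its last four residues; ligand residues
    matching ``ligand_codes`` are retained as one rigid unit; waters and metal
    ions are dropped; a missing C-terminal OXT is built at ideal geometry.
    ``anchors`` maps the five constraint anchor names to 'chain:seqpos:atom'
    addresses on the receptor.
    """
    if anchors is None:
        raise TemplateError(
            "anchor addresses are required: "
            + ", ".join(TemplateComplex.ANCHOR_NAMES)
        )
    if peptide_chain not in structure.chains:
        raise TemplateError(f"no peptide chain {peptide_chain!r} in structure")
    pep_all = [
        r for r in structure.chains[peptide_chain]
        if r.type3 not in WATER_CODES and r.type3 not in METAL_CODES
    ]
    if len(pep_all) < 4:
        raise TemplateError("peptide chain must contain at least 4 residues")
    peptide = pep_all[-4:]
    if peptide[0].type3 != "CYS":
        raise TemplateError("template peptide must present Cys at motif position 1")
    ligand_codes = {c.upper() for c in ligand_codes}

    receptor = Structure(title=structure.title)
    ligand: Optional[Residue] = None
    for chain_id, residues in structure.chains.items():
        if receptor_chains is not None and chain_id not in receptor_chains:
            if chain_id != peptide_chain:
                continue
        for res in residues:
            if chain_id == peptide_chain and res in peptide:
                continue
            code = res.type3.upper()
            if code in WATER_CODES or code in METAL_CODES:
                continue
            if code in ligand_codes:
                if ligand is not None:
                    # multiple ligand residues are merged into one rigid unit
                    for a in res.atoms:
                        ligand.atoms.append(a)
                else:
                    for a in res.atoms:
                        a.is_hetero = True
                    ligand = res
                continue
            if chain_id == peptide_chain:
                continue  # upstream peptide residues are discarded
            receptor.chains.setdefault(chain_id, []).append(res)

    xres = peptide[3]
    if not xres.has_atom("OXT"):
        _build_oxt(xres)

    anchor_map = {name: parse_anchor_address(addr) for name, addr in anchors.items()}
    missing = [n for n in TemplateComplex.ANCHOR_NAMES if n not in anchor_map]
    if missing:
        raise TemplateError(f"missing anchor addresses: {', '.join(missing)}")

    return TemplateComplex(
        receptor=receptor,
        peptide=peptide,
        ligand=ligand,
        anchor_atoms=anchor_map,
        peptide_chain=peptide_chain,
    )
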