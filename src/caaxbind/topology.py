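"""Residue chemistry tables: side-chain internal coordinates, chi definitions,
bond graphs and atom typing.

Side chains are described as z-matrix entries built outward from the backbone.
Each entry places one heavy atom from three previously-placed reference atoms
with an ideal bond length, bond angle and a torsion that is either a constant
or driven by a chi angle (optionally with a fixed offset, e.g. the second
branch of VAL at chi1 + 122 degrees).
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

AA1_TO_3: Dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA3_TO_1: Dict[str, str] = {v: k for k, v in AA1_TO_3.items()}
STANDARD_AA3 = frozenset(AA1_TO_3.values())

# ---------------------------------------------------------------------------
# Backbone ideal geometry (used when constructing atoms fresh; measured values
# are used when rebuilding an existing structure).
# ---------------------------------------------------------------------------
BB = {
    "N_CA": 1.458, "CA_C": 1.524, "C_N": 1.329, "C_O": 1.231, "C_OXT": 1.250,
    "ang_N_CA_C": 111.2, "ang_CA_C_N": 116.2, "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.5, "ang_CA_C_OXT": 117.0,
    "CB_bond": 1.53, "CB_angle": 109.5, "CB_improper": -120.0,  # refs N, C, CA
}

# torsion spec: ("chi", k, offset_deg) with k 1-based, or float constant.
ZEntry = Tuple[str, Tuple[str, str, str], float, float, object]

_RING120 = 120.0

SIDECHAIN_ZMAT: Dict[str, List[ZEntry]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.5, ("chi", 2, 122.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.46, 111.5, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.7, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.37, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.49, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.36, 111.7, 0.0),
    ],
    # Proline ring is built at fixed torsions; the CD-N ring closure is
    # approximate (no explicit ring-closure refinement).
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.49, 104.5, -28.0),
        ("CD", ("CA", "CB", "CG"), 1.50, 106.1, 36.0),
    ],
}

# chi angle atom quadruples per residue (for measurement)
CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "GLY": [], "ALA": [], "PRO": [],
}


def n_chi(res3: str) -> int:
    return len(CHI_ATOMS.get(res3, []))


def sidechain_atom_names(res3: str) -> List[str]:
    names = [] if res3 == "GLY" else ["CB"]
    names.extend(e[0] for e in SIDECHAIN_ZMAT.get(res3, []))
    return names


def residue_bonds(res3: str, c_terminal: bool = False) -> List[Tuple[str, str]]:
    """Covalent bonds within one residue (heavy atoms)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if c_terminal:
        bonds.append(("C", "OXT"))
    if res3 != "GLY":
        bonds.append(("CA", "CB"))
    for name, refs, _, _, _ in SIDECHAIN_ZMAT.get(res3, []):
        bonds.append((refs[2], name))
    # ring closures not represented by the z-matrix parent links
    extra = {
        "PHE": [("CE2", "CZ")], "TYR": [("CE2", "CZ")],
        "HIS": [("CD2", "NE2")],
        "TRP": [("NE1", "CE2"), ("CE3", "CZ3"), ("CZ3", "CH2")],
        "PRO": [("CD", "N")],
    }
    bonds.extend(extra.get(res3, []))
    return bonds


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

_AROMATIC_C = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}
_POLAR_C = {  # carbonyl / carboxyl / amide / guanidinium carbons
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"}, "ARG": {"CZ"},
}

_SIDECHAIN_TYPE = {
    ("SER", "OG"): "O_oh", ("THR", "OG1"): "O_oh", ("TYR", "OH"): "O_oh",
    ("CYS", "SG"): "S_thi", ("MET", "SD"): "S_thi",
    ("ASP", "OD1"): "O_coo", ("ASP", "OD2"): "O_coo",
    ("GLU", "OE1"): "O_coo", ("GLU", "OE2"): "O_coo",
    ("ASN", "OD1"): "O_carb", ("GLN", "OE1"): "O_carb",
    ("ASN", "ND2"): "N_don", ("GLN", "NE2"): "N_don",
    ("TRP", "NE1"): "N_don",
    ("HIS", "ND1"): "N_arom", ("HIS", "NE2"): "N_don",
    ("LYS", "NZ"): "N_lys",
    ("ARG", "NE"): "N_don", ("ARG", "NH1"): "N_pos", ("ARG", "NH2"): "N_pos",
}

_ELEMENT_FALLBACK = {"C": "C_ali", "N": "N_don", "O": "O_carb", "S": "S_thi",
                     "P": "C_pol"}


class UnknownAtomTypeError(KeyError):
    pass


def assign_atom_type(res3: str, name: str, is_hetero: bool = False) -> str:
    """Map a (residue, atom name) pair to a nonbonded atom type."""
    if is_hetero or res3 not in STANDARD_AA3:
        el = element_of(name)
        try:
            return _ELEMENT_FALLBACK[el]
        except KeyError:
            raise UnknownAtomTypeError(
                f"no nonbonded parameters for hetero atom {res3}:{name}"
            ) from None
    if name == "N":
        return "N_bb"
    if name in ("O", "OXT"):
        return "O_coo" if name == "OXT" else "O_bb"
    if name == "C":
        return "C_pol"
    if name == "CA":
        return "C_ali"
    key = (res3, name)
    if key in _SIDECHAIN_TYPE:
        return _SIDECHAIN_TYPE[key]
    if name in _AROMATIC_C.get(res3, ()):
        return "C_aro"
    if name in _POLAR_C.get(res3, ()):
        return "C_pol"
    el = element_of(name)
    if el in _ELEMENT_FALLBACK:
        return _ELEMENT_FALLBACK[el]
    raise UnknownAtomTypeError(f"no nonbonded parameters for atom {res3}:{name}")


def element_of(name: str) -> str:
    """Guess the element from a PDB atom name."""
    stripped = name.strip()
    if stripped[:2].upper() in ("ZN", "MG", "FE", "MN", "CL", "BR", "NA"):
        return stripped[:2].upper().capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")
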