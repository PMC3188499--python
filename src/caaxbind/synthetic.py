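"""Self-contained synthetic fixtures: a toy receptor-peptide-ligand template
and labeled Cxxx peptide sets.

The toy pocket emulates the qualitative architecture of the farnesyl-
transferase Cxxx binding site: a solvent-facing a1 position, a buried
hydrophobic a2 pocket lined by aliphatic walls and a hydrophobic chain
ligand, a moderate X-reading pocket, a polar side chain donating a hydrogen
bond to the C-terminal carboxylate, a second donor for the a2 backbone
carbonyl, and a three-residue sulfur-coordination triad replacing the
catalytic zinc. It is a synthetic stand-in for a real crystallographic
template: geometry is ideal and the receptor is tiny, so absolute energies
are meaningful only within this toy system.

Labeled peptide sets draw binders from aliphatic-biased position pools and
non-binders from bulky/charged anti-pools; the separability parameter mixes
the biased pools with uniform draws (1.0 = fully biased).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._geometry import normalize, place_atom
from .conformers import build_sidechain
from .structio import Atom, Residue, Structure, TemplateComplex, prepare_template
from .topology import AA1_TO_3, BB, n_chi

__all__ = [
    "SyntheticConfig",
    "make_toy_structure",
    "make_toy_template",
    "make_labeled_peptides",
    "TOY_ANCHORS",
]

TOY_ANCHORS = {
    "q_alpha": "A:1:NE2",
    "r_beta": "A:2:NH1",
    "zn_triad_1": "A:3:OD2",
    "zn_triad_2": "A:4:SG",
    "zn_triad_3": "A:5:NE2",
}

# biased position pools for labeled-set generation (qualitative profile:
# aliphatic a2 strongly favored in binders, bulky/charged disfavored)
POS_POOLS = {"a1": "AST", "a2": "ILV", "X": "MQTC"}
NEG_POOLS = {"a1": "AST", "a2": "RD", "X": "D"}
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    seed: int = 0
    pocket_size: int = 8
    hbond_distance: float = 2.8   # anchor hydrogen-bond target lengths (A)
    triad_distance: float = 2.3   # sulfur-triad coordination lengths (A)
    separability: float = 1.0     # 0..1, binder/non-binder pool bias

    def __post_init__(self) -> None:
        if self.hbond_distance <= 0 or self.triad_distance <= 0:
            raise ValueError("anchor distances must be positive")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Peptide construction
# ---------------------------------------------------------------------------

def _build_backbone(n_res: int, phi: float = -120.0, psi: float = 130.0,
                    omega: float = 180.0) -> List[Dict[str, np.ndarray]]:
    """Extended-strand backbone (N, CA, C, O per residue) built by NeRF."""
    res: List[Dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BB["N_CA"], 0.0, 0.0])
    ang = np.radians(180.0 - BB["ang_N_CA_C"])
    c0 = ca0 + BB["CA_C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        p = res[i - 1]
        n = place_atom(p["N"], p["CA"], p["C"], BB["C_N"], BB["ang_CA_C_N"], psi)
        ca = place_atom(p["CA"], p["C"], n, BB["N_CA"], BB["ang_C_N_CA"], omega)
        c = place_atom(p["C"], n, ca, BB["CA_C"], BB["ang_N_CA_C"], phi)
        res.append({"N": n, "CA": ca, "C": c})
    for i in range(n_res):
        nxt = res[i + 1]["N"] if i + 1 < n_res else None
        if nxt is not None:
            # carbonyl O opposite the next N
            from ._geometry import dihedral

            psi_i = dihedral(res[i]["N"], res[i]["CA"], res[i]["C"], nxt)
        else:
            psi_i = psi
        res[i]["O"] = place_atom(
            res[i]["N"], res[i]["CA"], res[i]["C"], BB["C_O"], BB["ang_CA_C_O"],
            psi_i + 180.0,
        )
    return res


def _residue_from_atoms(type3: str, seqpos: int, chain: str,
                        atoms: Dict[str, np.ndarray], hetero: bool = False) -> Residue:
    from .topology import element_of

    return Residue(
        type3=type3, seqpos=seqpos, chain=chain,
        atoms=[
            Atom(name=nm, element=element_of(nm), xyz=xyz, is_hetero=hetero)
            for nm, xyz in atoms.items()
        ],
    )


def _default_chi(type3: str) -> Tuple[float, ...]:
    from .conformers import RotamerLibrary

    return RotamerLibrary.default().rotamers(type3)[0]


def _best_chi_toward(type3: str, frame: Dict[str, np.ndarray],
                     direction: np.ndarray) -> Tuple[float, ...]:
    """Library rotamer whose side-chain tip points furthest along a target
    direction (used to orient the template peptide's side chains)."""
    from .conformers import RotamerLibrary

    best, best_proj = None, -np.inf
    for chis in RotamerLibrary.default().rotamers(type3):
        sc = build_sidechain(type3, frame, chis)
        tip = list(sc.values())[-1]
        proj = float(np.dot(tip - frame["CA"], direction))
        if proj > best_proj:
            best, best_proj = chis, proj
    return best


def _place_residue_with_tip(
    type3: str,
    seqpos: int,
    chis: Tuple[float, ...],
    tip_name: str,
    tip_target: np.ndarray,
    away_dir: np.ndarray,
) -> Residue:
    """Build an ideal residue and rigidly place it so ``tip_name`` sits at
    ``tip_target`` with the residue body extending along ``away_dir``."""
    from scipy.spatial.transform import Rotation

    bb = _build_backbone(1)[0]
    atoms = dict(bb)
    atoms.update(build_sidechain(type3, bb, chis))
    tip = atoms[tip_name]
    v = tip - atoms["CA"]
    rot, _ = Rotation.align_vectors([-normalize(away_dir)], [normalize(v)])
    R = rot.as_matrix()
    placed = {nm: R @ (xyz - tip) + tip_target for nm, xyz in atoms.items()}
    return _residue_from_atoms(type3, seqpos, "A", placed)


def make_toy_structure(
    config: Optional[SyntheticConfig] = None,
    include_water: bool = True,
    include_metal: bool = True,
    include_oxt: bool = False,
    peptide_extra: str = "TK",
) -> Tuple[Structure, Dict[str, str]]:
    """Deterministic toy receptor-peptide complex as a raw Structure
    (plus the anchor address map). The peptide chain carries upstream
    residues (default TK) ahead of the CNIQ motif so template truncation is
    exercised; water and a metal ion are included by default so solvent
    stripping is exercised too."""
    cfg = config or SyntheticConfig()

    pep_seq = [AA1_TO_3[ch] for ch in peptide_extra] + ["CYS", "ASN", "ILE", "GLN"]
    bb = _build_backbone(len(pep_seq))
    motif0 = len(pep_seq) - 4  # index of Cys

    # frame vectors from the built backbone
    cys_bb, a1_bb, a2_bb, x_bb = bb[motif0], bb[motif0 + 1], bb[motif0 + 2], bb[motif0 + 3]
    axis = normalize(x_bb["CA"] - cys_bb["CA"])
    cys_cb = build_sidechain("CYS", cys_bb, (0.0,))["CB"]
    down = normalize(cys_cb - cys_bb["CA"])  # odd motif positions point "down"
    lateral = normalize(np.cross(axis, down))

    # orient template side chains: Cys and a2 into the pocket ("down")
    pep_res: List[Residue] = []
    atoms_per_res: List[Dict[str, np.ndarray]] = []
    for i, type3 in enumerate(pep_seq):
        atoms = dict(bb[i])
        if n_chi(type3) > 0 or type3 not in ("GLY",):
            if i == motif0:  # CYS
                chis = _best_chi_toward(type3, bb[i], down)
            elif i == motif0 + 2:  # a2
                chis = _best_chi_toward(type3, bb[i], down)
            elif i == motif0 + 3:  # X
                chis = _best_chi_toward(type3, bb[i], down + 0.5 * axis)
            else:
                chis = _default_chi(type3)
            atoms.update(build_sidechain(type3, bb[i], chis))
        if include_oxt and i == len(pep_seq) - 1:
            from ._geometry import dihedral

            tor_o = dihedral(atoms["N"], atoms["CA"], atoms["C"], atoms["O"])
            atoms["OXT"] = place_atom(
                atoms["N"], atoms["CA"], atoms["C"], 1.25, 117.0, tor_o + 180.0
            )
        atoms_per_res.append(atoms)
        pep_res.append(_residue_from_atoms(type3, i + 1, "B", atoms))

    cys_atoms = atoms_per_res[motif0]
    a2_atoms = atoms_per_res[motif0 + 2]
    x_atoms = atoms_per_res[motif0 + 3]
    sg = cys_atoms["SG"]
    a2_tip = a2_atoms.get("CD1", a2_atoms.get("CG1", a2_atoms["CB"]))
    a2_dir = normalize(a2_tip - a2_atoms["CB"])
    x_tip = list(x_atoms.values())[-1]

    # approximate carboxylate oxygen direction (OXT is built later by
    # prepare_template; aim the donor at where it will sit)
    from ._geometry import dihedral as _dih

    tor_o = _dih(x_atoms["N"], x_atoms["CA"], x_atoms["C"], x_atoms["O"])
    oxt_pos = place_atom(
        x_atoms["N"], x_atoms["CA"], x_atoms["C"], 1.25, 117.0, tor_o + 180.0
    )

    receptor: List[Residue] = []
    d_hb, d_zn = cfg.hbond_distance, cfg.triad_distance

    # 1-2: conserved hydrogen-bond donors
    u1 = normalize(oxt_pos - x_atoms["C"])
    receptor.append(_place_residue_with_tip(
        "GLN", 1, _default_chi("GLN"), "NE2", oxt_pos + d_hb * u1, u1))
    u2 = normalize(a2_atoms["O"] - a2_atoms["C"])
    receptor.append(_place_residue_with_tip(
        "ARG", 2, _default_chi("ARG"), "NH1", a2_atoms["O"] + d_hb * u2, u2))

    # 3-5: sulfur-coordination triad (tetrahedral-ish tripod around SG)
    w = normalize(sg - cys_atoms["CB"])
    e1 = normalize(np.cross(w, lateral))
    e2 = np.cross(w, e1)
    for k, (type3, tip) in enumerate([("ASP", "OD2"), ("CYS", "SG"), ("HIS", "NE2")]):
        phi_k = np.radians(120.0 * k)
        d_k = normalize(
            np.cos(np.radians(50)) * w
            + np.sin(np.radians(50)) * (np.cos(phi_k) * e1 + np.sin(phi_k) * e2)
        )
        receptor.append(_place_residue_with_tip(
            type3, 3 + k, _default_chi(type3), tip, sg + d_zn * d_k, d_k))

    # 6: a2 pocket floor. Aliphatic a2 side chains make ideal contact with
    # the leucine tip; longer side chains clash.
    a2_cb = a2_atoms["CB"]
    seq_no = 6
    receptor.append(_place_residue_with_tip(
        "LEU", seq_no, _default_chi("LEU"), "CD1", a2_cb + 6.6 * a2_dir, a2_dir))
    seq_no += 1

    # 7-8: X-reading channel floor (deep enough for Met/Gln) and a polar
    # rim serine
    x_dir = normalize(x_tip - x_atoms["CB"]) if "CB" in x_atoms else down
    receptor.append(_place_residue_with_tip(
        "VAL", seq_no, _default_chi("VAL"), "CG1", x_atoms["CB"] + 8.3 * x_dir,
        x_dir))
    seq_no += 1
    xring_e1 = normalize(np.cross(x_dir, axis))
    rim_dir = normalize(x_dir + 0.8 * xring_e1)
    receptor.append(_place_residue_with_tip(
        "SER", seq_no, _default_chi("SER"), "OG",
        x_atoms["CB"] + 5.2 * rim_dir, rim_dir))
    seq_no += 1

    # 9+: optional alanine pocket residues lining the groove walls
    mid = 0.5 * (cys_bb["CA"] + x_bb["CA"])
    up = -down
    n_fill = max(0, cfg.pocket_size - (seq_no - 1))
    for k in range(n_fill):
        angle = np.radians(25.0 + 310.0 * k / max(1, n_fill))
        direction = normalize(
            np.cos(angle) * down + np.sin(angle) * lateral
        )
        target = mid + 9.0 * direction
        receptor.append(_place_residue_with_tip(
            "ALA", seq_no + k, (), "CB", target, direction))
    seq_no += n_fill

    # ligand: hydrophobic chain probe along the floor of the a2 pocket
    lig_start = sg + 3.8 * normalize(down + 0.3 * axis)
    lig_dir = normalize(0.75 * axis + 0.35 * down)
    lig_atoms: Dict[str, np.ndarray] = {}
    for k in range(8):
        zig = 0.45 * lateral * (1 if k % 2 else -1)
        lig_atoms[f"C{k + 1}"] = lig_start + 1.35 * k * lig_dir + zig
    ligand = _residue_from_atoms("FAR", 1, "L", lig_atoms, hetero=True)

    # simple steric relief: nudge wall/filler residues off any hard clash
    protected = {(r.chain, r.seqpos) for r in receptor[:5]}
    fixed_pts = np.array(
        [a.xyz for r in pep_res for a in r.atoms]
        + [a.xyz for a in ligand.atoms]
    )
    for res in receptor:
        if (res.chain, res.seqpos) in protected:
            continue
        for _ in range(50):
            pts = np.array([a.xyz for a in res.atoms])
            d = np.linalg.norm(pts[:, None, :] - fixed_pts[None, :, :], axis=2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] >= 3.1:
                break
            push = normalize(pts[i] - fixed_pts[j])
            for a in res.atoms:
                a.xyz = a.xyz + 0.25 * push
    # relieve receptor-receptor overlaps (movable residues only)
    movable = [r for r in receptor if (r.chain, r.seqpos) not in protected]
    for _ in range(100):
        worst = None
        for r1 in movable:
            pts1 = np.array([a.xyz for a in r1.atoms])
            for r2 in receptor:
                if r2 is r1:
                    continue
                pts2 = np.array([a.xyz for a in r2.atoms])
                d = np.linalg.norm(pts1[:, None, :] - pts2[None, :, :], axis=2)
                i, j = np.unravel_index(np.argmin(d), d.shape)
                if d[i, j] < 3.0 and (worst is None or d[i, j] < worst[0]):
                    worst = (d[i, j], r1, pts1[i], pts2[j])
        if worst is None:
            break
        _, r1, p1, p2 = worst
        push = normalize(p1 - p2)
        for a in r1.atoms:
            a.xyz = a.xyz + 0.3 * push

    # enclosing wall shell: single-atom pseudo-residues on an ellipsoid
    # around the motif, open on the solvent (a1) face and at the X channel.
    # This emulates the bulk protein that buries the site: side chains that
    # cannot fit the pocket cannot escape sideways or lie on an open surface.
    shell_center = mid + 1.0 * down
    a_ax, b_lat, c_dn = 9.5, 6.2, 7.0
    existing_pts = np.array(
        [a.xyz for r in receptor for a in r.atoms]
        + [a.xyz for r in pep_res for a in r.atoms]
        + [a.xyz for a in ligand.atoms]
    )
    gold = np.pi * (1.0 + 5.0**0.5)
    kk = np.arange(140) + 0.5
    dirs = np.column_stack([
        np.cos(gold * kk) * np.sin(np.arccos(1 - 2 * kk / 140)),
        np.sin(gold * kk) * np.sin(np.arccos(1 - 2 * kk / 140)),
        np.cos(np.arccos(1 - 2 * kk / 140)),
    ])
    for d3 in dirs:
        d3 = d3 / np.linalg.norm(d3)
        if np.dot(d3, down) < -0.45:
            continue  # leave the solvent face open
        if np.dot(d3, x_dir) > 0.848:
            continue  # leave the X channel open
        r_ell = 1.0 / np.sqrt(
            (np.dot(d3, axis) / a_ax) ** 2
            + (np.dot(d3, lateral) / b_lat) ** 2
            + (np.dot(d3, down) / c_dn) ** 2
        )
        p = shell_center + r_ell * d3
        if np.min(np.linalg.norm(existing_pts - p, axis=1)) < 3.4:
            continue
        receptor.append(_residue_from_atoms("WAL", seq_no, "A", {"C1": p}))
        existing_pts = np.vstack([existing_pts, p])  # keep shell self-spaced
        seq_no += 1

    structure = Structure(title="synthetic toy Cxxx binding pocket")
    structure.chains["A"] = receptor
    structure.chains["B"] = pep_res
    structure.chains["L"] = [ligand]
    extras = []
    if include_water:
        far = mid + 14.0 * lateral
        extras.append(_residue_from_atoms("HOH", 1, "W", {"O": far}, hetero=True))
    if include_metal:
        far = mid - 14.0 * lateral
        extras.append(_residue_from_atoms("ZN", 2, "W", {"ZN": far}, hetero=True))
    if extras:
        structure.chains["W"] = extras
    return structure, dict(TOY_ANCHORS)


def make_toy_template(config: Optional[SyntheticConfig] = None) -> TemplateComplex:
    """Prepared toy template (truncated peptide, stripped solvent/metal,
    OXT built, anchors resolved)."""
    structure, anchors = make_toy_structure(config)
    return prepare_template(
        structure,
        peptide_chain="B",
        ligand_codes=["FAR"],
        receptor_chains=["A", "L", "W"],
        anchors=anchors,
    )


# ---------------------------------------------------------------------------
# Labeled peptide sets
# ---------------------------------------------------------------------------

def make_labeled_peptides(
    config: Optional[SyntheticConfig] = None,
    n_pos: int = 25,
    n_neg: int = 25,
):
    """Seeded binder/non-binder Cxxx sets with designed separability.

    Binders draw a1/a2/X from aliphatic-biased pools, non-binders are forced
    to carry at least one bulky or charged residue at a buried position.
    All sequences are unique across the two sets.
    """
    from .evaluation import LabeledPeptideSet, PeptideRecord

    cfg = config or SyntheticConfig()
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    s = cfg.separability
    seen: set = set()
    records: List[PeptideRecord] = []

    def draw(pool: str) -> str:
        if rng.random() < s:
            return pool[rng.integers(len(pool))]
        return ALL_AA[rng.integers(len(ALL_AA))]

    def sample(positive: bool) -> str:
        for _ in range(20000):
            if positive:
                seq = "C" + draw(POS_POOLS["a1"]) + draw(POS_POOLS["a2"]) \
                    + draw(POS_POOLS["X"])
            else:
                # at least one buried position carries a charged residue;
                # the remaining positions look binder-like, so the buried
                # defect is the only systematic difference between classes
                bad_a2 = rng.random() < 0.7
                bad_x = rng.random() < 0.7
                if not bad_a2 and not bad_x:
                    bad_a2 = True
                a1 = NEG_POOLS["a1"][rng.integers(len(NEG_POOLS["a1"]))]
                a2 = (NEG_POOLS["a2"][rng.integers(len(NEG_POOLS["a2"]))]
                      if bad_a2 else draw(POS_POOLS["a2"]))
                x = (NEG_POOLS["X"][rng.integers(len(NEG_POOLS["X"]))]
                     if bad_x else draw(POS_POOLS["X"]))
                seq = "C" + a1 + a2 + x
            if seq not in seen:
                seen.add(seq)
                return seq
        raise ValueError(
            "could not draw the requested number of distinct sequences"
        )

    for _ in range(n_pos):
        records.append(PeptideRecord(sequence=sample(True), label="binder"))
    for _ in range(n_neg):
        records.append(PeptideRecord(sequence=sample(False), label="non_binder"))
    return LabeledPeptideSet(records=records)
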