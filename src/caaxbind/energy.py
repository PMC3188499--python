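"""Decomposable nonbonded energy model, harmonic distance constraints and the
five scoring schemes (total, interface, peptide, peptide-no-reference, iBSA).

The functional forms are intentionally simple and self-contained: a 6-12
Lennard-Jones potential with linearized repulsion at short range, a
distance-and-angle modulated hydrogen-bond well, Gaussian-exclusion implicit
solvation, Coulomb electrostatics with a distance-dependent dielectric, and
an 8 A pair cutoff with switching. Scores are in dimensionless energy units;
they are NOT numerically comparable to any other force field, so
classification thresholds should be calibrated on labeled data (see
:mod:`caaxbind.evaluation`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformers import PoseModel
from .structio import TemplateComplex
from .topology import AA3_TO_1, assign_atom_type

__all__ = [
    "EnergyFunction",
    "DistanceConstraint",
    "EnergyBreakdown",
    "ScoringModel",
    "derive_constraints",
    "constraint_energy",
    "score_pose",
    "peptide_score",
    "interface_score",
    "buried_surface_area",
    "shrake_rupley_sasa",
]

CUTOFF = 8.0
SWITCH_START = 5.5
HB_D0 = 2.9       # hydrogen-bond heavy-atom distance optimum
HB_SIGMA = 0.35
HB_CUT = 4.5
SOLV_SIGMA = 1.7  # Gaussian-exclusion width beyond contact
COULOMB_K = 332.0
PROBE_RADIUS = 1.4

DEFAULT_WEIGHTS = {
    "lj_attractive": 1.0,
    "lj_repulsive": 0.55,
    "hbond": 1.2,
    "solvation": 0.65,
    "electrostatics": 0.5,
    "constraint": 1.0,
}


def _load_param_table() -> Dict[str, dict]:
    table = {}
    ref = resources.files("caaxbind") / "data" / "atom_params.txt"
    for line in ref.read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        t, radius, eps, charge, gfree, vol, don, acc = line.split()
        table[t] = {
            "radius": float(radius), "eps": float(eps), "charge": float(charge),
            "gfree": float(gfree), "vol": float(vol),
            "donor": bool(int(don)), "acceptor": bool(int(acc)),
        }
    return table


@dataclass
class EnergyFunction:
    """Term weights, atom-type parameters and per-amino-acid reference
    energies. The default reference table is all zeros; a fitted table can be
    supplied (or produced by the calibration routine) without touching the
    physical terms."""

    weights: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    params: Dict[str, dict] = field(default_factory=_load_param_table)
    reference_energies: Dict[str, float] = field(
        default_factory=lambda: {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    )

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weight {name} must be >= 0, got {w}")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.reference_energies)
        if missing:
            raise ValueError(f"reference energies missing for {sorted(missing)}")

    @classmethod
    def default(cls) -> "EnergyFunction":
        return cls()


@dataclass(frozen=True)
class DistanceConstraint:
    """Harmonic distance restraint: ((d - d0) / sd)**2."""

    atom_a: tuple
    atom_b: tuple
    d0: float
    sd: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("constraint reference length d0 must be > 0")
        if self.sd <= 0:
            raise ValueError("constraint standard deviation must be > 0")

    def energy(self, d: float) -> float:
        return ((d - self.d0) / self.sd) ** 2


@dataclass
class EnergyBreakdown:
    """Per-residue decomposition of a scored pose.

    ``sum(per_residue) + constraint_total == total`` and ``cross_interface``
    equals the complex energy minus the separated-parts energies (pair terms
    across the peptide/receptor+ligand interface only).
    """

    per_residue: np.ndarray
    residue_segments: np.ndarray
    peptide_residue_indices: List[int]
    peptide_letters: str
    cross_interface: float
    constraint_total: float
    total: float
    ibsa: float
    reference_energies: Dict[str, float]

    @property
    def peptide_energies(self) -> np.ndarray:
        return self.per_residue[self.peptide_residue_indices]


# ---------------------------------------------------------------------------
# Scoring model (pairwise machinery)
# ---------------------------------------------------------------------------

class ScoringModel:
    """Precomputed pairwise scoring machinery for one pose topology.

    Excludes covalently linked pairs (bond-graph distance <= 3) and any atom
    pair that participates in a distance constraint (the 2.3 A sulfur-triad
    coordination contacts would otherwise sit deep in LJ repulsion)."""

    def __init__(
        self,
        pose: PoseModel,
        efn: EnergyFunction,
        constraints: Sequence[DistanceConstraint] = (),
    ):
        self.efn = efn
        n = len(pose.names)
        self.n_atoms = n
        radius = np.empty(n)
        eps = np.empty(n)
        charge = np.empty(n)
        gfree = np.empty(n)
        vol = np.empty(n)
        donor = np.zeros(n, dtype=bool)
        acceptor = np.zeros(n, dtype=bool)
        for i, name in enumerate(pose.names):
            res = pose.residues[pose.res_of[i]]
            t = assign_atom_type(
                res.type3, name, is_hetero=(res.segment == PoseModel.SEG_LIGAND)
            )
            p = efn.params.get(t)
            if p is None:
                raise KeyError(f"atom type {t!r} (atom {res.type3}:{name}) "
                               "missing from parameter table")
            radius[i], eps[i] = p["radius"], p["eps"]
            charge[i], gfree[i], vol[i] = p["charge"], p["gfree"], p["vol"]
            donor[i], acceptor[i] = p["donor"], p["acceptor"]
        self.radius = radius

        # neighbor lists (for hydrogen-bond directionality)
        nbrs: List[List[int]] = [[] for _ in range(n)]
        for a, b in pose.bonds:
            nbrs[a].append(b)
            nbrs[b].append(a)
        self._nbrs = nbrs
        # padded neighbor matrix (pad with self-index: zero contribution)
        width = max((len(x) for x in nbrs), default=1) or 1
        self._nbr_pad = np.array(
            [x + [i] * (width - len(x)) for i, x in enumerate(nbrs)],
            dtype=np.int64,
        )

        # bond-graph exclusions (<= 3 bonds apart)
        excluded = set()
        for start in range(n):
            frontier = {start}
            seen = {start}
            for _ in range(3):
                frontier = {
                    x for f in frontier for x in nbrs[f] if x not in seen
                }
                seen |= frontier
            for j in seen:
                if j > start:
                    excluded.add((start, j))
        for c in constraints:
            ia, ib = pose.atom_index(c.atom_a), pose.atom_index(c.atom_b)
            # a constraint acts like a (coordination) bond: exclude the pair
            # and its 1-3 neighbors across the pseudo-bond
            for a in [ia, *nbrs[ia]]:
                for b in [ib, *nbrs[ib]]:
                    if a != b:
                        excluded.add((min(a, b), max(a, b)))

        iu, ju = np.triu_indices(n, k=1)
        keep = np.array(
            [(int(a), int(b)) not in excluded for a, b in zip(iu, ju)], dtype=bool
        )
        self.pi = iu[keep]
        self.pj = ju[keep]
        self.res_of = pose.res_of
        self.segment = pose.segment
        self.n_res = len(pose.residues)

        # precomputed pair parameters
        self.pair_R = radius[self.pi] + radius[self.pj]
        self.pair_eps = np.sqrt(eps[self.pi] * eps[self.pj])
        self.pair_qq = charge[self.pi] * charge[self.pj]
        self.pair_solv = (
            gfree[self.pi] * vol[self.pj] + gfree[self.pj] * vol[self.pi]
        ) / 100.0
        hb_ij = donor[self.pi] & acceptor[self.pj]
        hb_ji = donor[self.pj] & acceptor[self.pi]
        self.pair_hb = hb_ij | hb_ji
        # orient so hb pair is (donor, acceptor)
        self.hb_don = np.where(hb_ij, self.pi, self.pj)[self.pair_hb]
        self.hb_acc = np.where(hb_ij, self.pj, self.pi)[self.pair_hb]
        self.hb_pair_index = np.where(self.pair_hb)[0]

    # -- term evaluation ---------------------------------------------------

    def _direction_away_from_neighbors(self, coords, atoms) -> np.ndarray:
        """Unit vectors opposite the mean direction of each atom's covalent
        neighbors (approximate H / lone-pair direction); vectorized."""
        nb = self._nbr_pad[atoms]                     # (k, width)
        vecs = coords[nb] - coords[atoms][:, None, :]  # (k, width, 3)
        norms = np.linalg.norm(vecs, axis=2, keepdims=True)
        unit = np.divide(vecs, norms, out=np.zeros_like(vecs),
                         where=norms > 1e-9)
        u = -unit.sum(axis=1)
        nu = np.linalg.norm(u, axis=1, keepdims=True)
        return np.divide(u, nu, out=np.zeros_like(u), where=nu > 1e-9)

    def pair_energies(self, coords: np.ndarray):
        """Weighted pair energies for all in-range pairs.

        Returns (pair_subset_indices, energies) where indices refer to the
        precomputed candidate pair arrays."""
        w = self.efn.weights
        dvec = coords[self.pi] - coords[self.pj]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        mask = d < CUTOFF
        idx = np.where(mask)[0]
        d = d[idx]
        R = self.pair_R[idx]
        eps = self.pair_eps[idx]

        # switching envelope (1 below SWITCH_START, 0 at CUTOFF, C1 smooth)
        t = np.clip((d - SWITCH_START) / (CUTOFF - SWITCH_START), 0.0, 1.0)
        sw = 1.0 - t * t * (3.0 - 2.0 * t)

        # Lennard-Jones split into attractive and repulsive branches
        x = R / np.maximum(d, 1e-6)
        lj = eps * (x**12 - 2.0 * x**6)
        atr = np.where(d >= R, lj, -eps)
        rep = np.where(d < R, lj + eps, 0.0)
        # linearize the repulsion below 0.6 R for minimization stability
        d_lin = 0.6 * R
        x_lin = 1.0 / 0.6
        e_lin = eps * (x_lin**12 - 2.0 * x_lin**6) + eps
        slope = eps * 12.0 * (x_lin**12 - x_lin**6) / d_lin
        close = d < d_lin
        rep = np.where(close, e_lin + slope * (d_lin - d), rep)

        solv = self.pair_solv[idx] * np.exp(
            -((np.maximum(d - R, 0.0) / SOLV_SIGMA) ** 2)
        )

        qq = self.pair_qq[idx]
        elec = np.where(
            qq != 0.0, COULOMB_K * qq / (4.0 * np.maximum(d, 1.0) ** 2), 0.0
        )

        e = (
            w["lj_attractive"] * atr
            + w["lj_repulsive"] * rep
            + w["solvation"] * solv
            + w["electrostatics"] * elec
        ) * sw

        # hydrogen bonds (distance well x donor/acceptor directionality)
        if w["hbond"] > 0 and len(self.hb_pair_index):
            hb_sel = np.where(self.pair_hb[idx])[0]
            if len(hb_sel):
                sub = idx[hb_sel]
                pos_in_hb = np.searchsorted(self.hb_pair_index, sub)
                dons = self.hb_don[pos_in_hb]
                accs = self.hb_acc[pos_in_hb]
                dd = d[hb_sel]
                near = dd < HB_CUT
                if np.any(near):
                    dons_n, accs_n = dons[near], accs[near]
                    u_don = self._direction_away_from_neighbors(coords, dons_n)
                    u_acc = self._direction_away_from_neighbors(coords, accs_n)
                    da = coords[accs_n] - coords[dons_n]
                    da_u = da / np.linalg.norm(da, axis=1, keepdims=True)
                    f_don = np.clip(np.einsum("ij,ij->i", u_don, da_u), 0, 1) ** 2
                    f_acc = np.clip(np.einsum("ij,ij->i", u_acc, -da_u), 0, 1)
                    well = np.exp(-(((dd[near] - HB_D0) / HB_SIGMA) ** 2))
                    e_hb = -w["hbond"] * well * f_don * f_acc
                    hb_e = np.zeros(len(hb_sel))
                    hb_e[near] = e_hb
                    e[hb_sel] += hb_e * sw[hb_sel]
        return idx, e

    def total(self, coords: np.ndarray) -> float:
        _, e = self.pair_energies(coords)
        return float(e.sum())

    def set_interaction(self, coords, idx_a, idx_b) -> float:
        """Sum of pair terms with one atom in set a and the other in set b."""
        in_a = np.zeros(self.n_atoms, dtype=bool)
        in_b = np.zeros(self.n_atoms, dtype=bool)
        in_a[idx_a] = True
        in_b[idx_b] = True
        idx, e = self.pair_energies(coords)
        cross = (in_a[self.pi[idx]] & in_b[self.pj[idx]]) | (
            in_b[self.pi[idx]] & in_a[self.pj[idx]]
        )
        return float(e[cross].sum())

    def set_internal(self, coords, idx_set) -> float:
        inside = np.zeros(self.n_atoms, dtype=bool)
        inside[idx_set] = True
        idx, e = self.pair_energies(coords)
        both = inside[self.pi[idx]] & inside[self.pj[idx]]
        return float(e[both].sum())

    def restricted_to_movable(
        self,
        movable: np.ndarray,
        ref_coords: Optional[np.ndarray] = None,
        margin: float = 10.0,
    ) -> "ScoringModel":
        """A view of this model keeping only candidate pairs that touch a
        movable atom (the static-static remainder is constant during
        minimization and can be computed once). With ``ref_coords``, pairs
        farther than cutoff + margin at the reference geometry are dropped
        too; the margin must exceed the largest displacement expected
        during the minimization trajectory."""
        mv = np.zeros(self.n_atoms, dtype=bool)
        mv[movable] = True
        keep = mv[self.pi] | mv[self.pj]
        if ref_coords is not None:
            d = np.linalg.norm(ref_coords[self.pi] - ref_coords[self.pj], axis=1)
            keep &= d < CUTOFF + margin
        return _restricted(self, np.where(keep)[0])

    def restricted_between(self, idx_a, idx_b) -> "ScoringModel":
        """View keeping only candidate pairs with one atom in each set."""
        in_a = np.zeros(self.n_atoms, dtype=bool)
        in_b = np.zeros(self.n_atoms, dtype=bool)
        in_a[idx_a] = True
        in_b[idx_b] = True
        sel = np.where(
            (in_a[self.pi] & in_b[self.pj]) | (in_b[self.pi] & in_a[self.pj])
        )[0]
        return _restricted(self, sel)

    def restricted_within(self, idx_set) -> "ScoringModel":
        """View keeping only candidate pairs internal to a set."""
        inside = np.zeros(self.n_atoms, dtype=bool)
        inside[idx_set] = True
        sel = np.where(inside[self.pi] & inside[self.pj])[0]
        return _restricted(self, sel)


def _restricted(model: ScoringModel, sel: np.ndarray) -> ScoringModel:
    sub = ScoringModel.__new__(ScoringModel)
    sub.efn = model.efn
    sub.n_atoms = model.n_atoms
    sub.radius = model.radius
    sub._nbrs = model._nbrs
    sub._nbr_pad = model._nbr_pad
    sub.pi = model.pi[sel]
    sub.pj = model.pj[sel]
    sub.res_of = model.res_of
    sub.segment = model.segment
    sub.n_res = model.n_res
    sub.pair_R = model.pair_R[sel]
    sub.pair_eps = model.pair_eps[sel]
    sub.pair_qq = model.pair_qq[sel]
    sub.pair_solv = model.pair_solv[sel]
    sub.pair_hb = model.pair_hb[sel]
    hb_sel = np.where(sub.pair_hb)[0]
    pos = np.searchsorted(model.hb_pair_index, sel[hb_sel])
    sub.hb_don = model.hb_don[pos]
    sub.hb_acc = model.hb_acc[pos]
    sub.hb_pair_index = hb_sel
    return sub


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def derive_constraints(
    template: TemplateComplex, sd: float = 0.1
) -> List[DistanceConstraint]:
    """The five conserved structural constraints: carboxylate to Q-anchor,
    a2 backbone carbonyl O to R-anchor, and Cys S-gamma to each of the three
    zinc-triad side-chain atoms. Reference lengths are the distances measured
    in the template."""
    constraints = []
    pep = template.peptide

    def make(name: str, pep_addr: tuple, pep_xyz) -> DistanceConstraint:
        rec_chain, rec_seqpos, rec_atom = template.anchor_atoms[name]
        rec_xyz = template.anchor_atom(name).xyz
        d0 = float(np.linalg.norm(pep_xyz - rec_xyz))
        return DistanceConstraint(
            atom_a=("rec", rec_chain, rec_seqpos, rec_atom),
            atom_b=pep_addr,
            d0=d0,
            sd=sd,
            name=name,
        )

    carbox = template.carboxylate_oxygen()
    constraints.append(make("q_alpha", ("pep", 3, carbox), pep[3].atom(carbox).xyz))
    constraints.append(make("r_beta", ("pep", 2, "O"), pep[2].atom("O").xyz))
    sg = pep[0].atom("SG").xyz
    for k in (1, 2, 3):
        constraints.append(make(f"zn_triad_{k}", ("pep", 0, "SG"), sg))
    return constraints


def resolve_constraints(
    pose: PoseModel, constraints: Sequence[DistanceConstraint]
) -> List[Tuple[int, int, float, float]]:
    out = []
    for c in constraints:
        out.append((pose.atom_index(c.atom_a), pose.atom_index(c.atom_b), c.d0, c.sd))
    return out


def constraint_energy(
    pose: PoseModel | np.ndarray,
    constraints: Sequence[DistanceConstraint],
    resolved: Optional[List[Tuple[int, int, float, float]]] = None,
) -> float:
    """Sum of harmonic penalties ((d - d0) / sd)**2 over the constraints."""
    if isinstance(pose, PoseModel):
        coords = pose.coords
        if resolved is None:
            resolved = resolve_constraints(pose, constraints)
    else:
        coords = pose
        if resolved is None:
            raise ValueError("resolved indices required when passing raw coords")
    e = 0.0
    for ia, ib, d0, sd in resolved:
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        e += ((d - d0) / sd) ** 2
    return e


# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------

def score_pose(
    pose: PoseModel,
    energy_fn: Optional[EnergyFunction] = None,
    constraints: Sequence[DistanceConstraint] = (),
    compute_sasa: bool = True,
) -> EnergyBreakdown:
    """Score a full-atom pose, populating the per-residue decomposition,
    the cross-interface sum, the constraint total and (optionally) the
    buried interface surface area."""
    efn = energy_fn or EnergyFunction.default()
    model = ScoringModel(pose, efn, constraints)
    coords = pose.coords
    idx, e = model.pair_energies(coords)

    per_res = np.zeros(model.n_res)
    ri = model.res_of[model.pi[idx]]
    rj = model.res_of[model.pj[idx]]
    np.add.at(per_res, ri, 0.5 * e)
    np.add.at(per_res, rj, 0.5 * e)

    pep_i = model.segment[model.pi[idx]] == PoseModel.SEG_PEPTIDE
    pep_j = model.segment[model.pj[idx]] == PoseModel.SEG_PEPTIDE
    cross = pep_i != pep_j
    cross_interface = float(e[cross].sum())

    ctot = float(
        efn.weights["constraint"] * constraint_energy(pose, constraints)
    ) if constraints else 0.0
    total = float(e.sum()) + ctot

    ibsa = buried_surface_area(pose) if compute_sasa else float("nan")
    segments = np.array([r.segment for r in pose.residues], dtype=np.int8)
    return EnergyBreakdown(
        per_residue=per_res,
        residue_segments=segments,
        peptide_residue_indices=pose.peptide_residue_indices,
        peptide_letters=pose.sequence.letters,
        cross_interface=cross_interface,
        constraint_total=ctot,
        total=total,
        ibsa=ibsa,
        reference_energies=dict(efn.reference_energies),
    )


def peptide_score(breakdown: EnergyBreakdown, include_ref: bool = False) -> float:
    """Sum of the four peptide residues' energy contributions; with
    ``include_ref=False`` (the default scheme) the per-amino-acid reference
    constant is subtracted for each residue."""
    e = float(breakdown.peptide_energies.sum())
    if include_ref:
        return e
    ref = sum(breakdown.reference_energies[aa] for aa in breakdown.peptide_letters)
    return e - ref


def interface_score(breakdown: EnergyBreakdown) -> float:
    """Complex energy minus separated-parts energies (cross-interface pair
    terms only)."""
    return breakdown.cross_interface


# ---------------------------------------------------------------------------
# Buried surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


_SPHERE_CACHE: Dict[int, np.ndarray] = {}


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = 100,
) -> float:
    """Total solvent-accessible surface area (Shrake-Rupley, A^2)."""
    if n_points not in _SPHERE_CACHE:
        _SPHERE_CACHE[n_points] = _fibonacci_sphere(n_points)
    sphere = _SPHERE_CACHE[n_points]
    n = len(coords)
    R = radii + probe
    total = 0.0
    for i in range(n):
        dvec = coords - coords[i]
        d = np.linalg.norm(dvec, axis=1)
        nbr = np.where((d < R[i] + R) & (np.arange(n) != i))[0]
        pts = coords[i] + R[i] * sphere
        if len(nbr):
            diff = pts[:, None, :] - coords[nbr][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = (d2 < (R[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * R[i] ** 2 * frac
    return float(total)


def buried_surface_area(pose: PoseModel, n_points: int = 100) -> float:
    """iBSA: SASA(peptide) + SASA(receptor+ligand) - SASA(complex)."""
    efn = EnergyFunction.default()
    radii = np.empty(len(pose.names))
    for i, name in enumerate(pose.names):
        res = pose.residues[pose.res_of[i]]
        t = assign_atom_type(
            res.type3, name, is_hetero=(res.segment == PoseModel.SEG_LIGAND)
        )
        radii[i] = efn.params[t]["radius"]
    pep = pose.segment == PoseModel.SEG_PEPTIDE
    other = ~pep
    coords = pose.coords
    sasa_pep = shrake_rupley_sasa(coords[pep], radii[pep], n_points=n_points)
    sasa_rec = shrake_rupley_sasa(coords[other], radii[other], n_points=n_points)
    sasa_cpx = shrake_rupley_sasa(coords, radii, n_points=n_points)
    return sasa_pep + sasa_rec - sasa_cpx
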