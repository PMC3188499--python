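"""Torsion-space quasi-Newton minimization of a pose under constraints.

Degrees of freedom follow the simple-minimization protocol: all peptide
phi/psi/omega and chi angles, the peptide's 6-DOF rigid-body placement,
receptor interface side-chain chi angles (C-beta within 8 A of the peptide;
C-alpha proxy for glycine) and the ligand chain dihedrals. The receptor
backbone never moves.

The minimizer is a Davidon-Fletcher-Powell (DFP) quasi-Newton with an Armijo
backtracking line search and central-difference gradients; convergence is
declared when the absolute energy change falls below the tolerance
(default 1e-4).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .conformers import PoseModel
from .energy import (
    DistanceConstraint,
    EnergyFunction,
    ScoringModel,
    constraint_energy,
    resolve_constraints,
)
from .topology import n_chi

__all__ = [
    "DOFSelection",
    "MinimizeResult",
    "select_interface_sidechains",
    "rebuild_coordinates",
    "minimize_pose",
    "dfp_minimize",
]


@dataclass
class DOFSelection:
    """Which degree-of-freedom groups are free during minimization."""

    peptide_torsions: bool = True
    rigid_body: bool = True
    receptor_chis: bool = True
    ligand_dihedrals: bool = True
    interface_cutoff: float = 8.0


@dataclass
class MinimizeResult:
    pose: PoseModel
    start_energy: float
    end_energy: float
    iterations: int
    converged: bool
    tolerance: float

    def __post_init__(self) -> None:
        if self.end_energy > self.start_energy + 1e-9:
            raise RuntimeError(
                "minimization increased the objective "
                f"({self.start_energy} -> {self.end_energy})"
            )


def select_interface_sidechains(pose: PoseModel, cutoff: float = 8.0) -> List[int]:
    """Receptor residues whose C-beta (C-alpha for glycine) lies within
    ``cutoff`` A of any peptide atom. Returns global residue indices."""
    if cutoff <= 0:
        raise ValueError("interface cutoff must be > 0")
    pep_coords = pose.coords[pose.segment == PoseModel.SEG_PEPTIDE]
    out = []
    for gi, res in enumerate(pose.residues):
        if res.segment != PoseModel.SEG_RECEPTOR:
            continue
        probe = "CA" if res.type3 == "GLY" else "CB"
        if probe not in res.atoms:
            continue
        xyz = pose.coords[res.atoms[probe]]
        if np.min(np.linalg.norm(pep_coords - xyz, axis=1)) <= cutoff:
            out.append(gi)
    return out


def rebuild_coordinates(pose: PoseModel, torsion_state: np.ndarray) -> PoseModel:
    """Return a copy of the pose with coordinates rebuilt from the given
    torsion state (fixed measured bond lengths/angles; kinematic root at the
    peptide N-terminus; rigid-body DOFs applied last)."""
    new = pose.copy()
    new.set_state(np.asarray(torsion_state, dtype=float))
    return new


# ---------------------------------------------------------------------------
# DFP quasi-Newton core
# ---------------------------------------------------------------------------

def dfp_minimize(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
    fd_step: float = 1e-3,
    jac: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Tuple[np.ndarray, float, int, bool]:
    """Minimize ``fun`` with the DFP quasi-Newton update and an Armijo
    backtracking line search. Gradients default to central differences.

    Returns (x, f, iterations, converged); converged means the absolute
    objective change in the last accepted step fell below ``tol``.
    Accepted steps never increase the objective.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = len(x)

    if jac is None:
        def jac(z: np.ndarray) -> np.ndarray:
            g = np.empty(n)
            for i in range(n):
                zp = z.copy(); zp[i] += fd_step
                zm = z.copy(); zm[i] -= fd_step
                g[i] = (fun(zp) - fun(zm)) / (2.0 * fd_step)
            return g

    f = fun(x)
    if not np.isfinite(f):
        raise ValueError(
            "objective is non-finite at the starting point; relieve clashes "
            "before minimizing"
        )
    g = jac(x)
    H = np.eye(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = -H @ g
        gp = float(g @ p)
        if gp >= 0.0:  # not a descent direction: reset to steepest descent
            H = np.eye(n)
            p = -g
            gp = float(g @ p)
            if gp >= -1e-16:
                converged = True
                break
        alpha = 1.0
        f_new = None
        for _ in range(40):
            x_new = x + alpha * p
            f_try = fun(x_new)
            if np.isfinite(f_try) and f_try <= f + 1e-4 * alpha * gp:
                f_new = f_try
                break
            alpha *= 0.5
        if f_new is None:
            converged = True  # no improving step representable
            break
        s = alpha * p
        g_new = jac(x_new)
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            Hy = H @ y
            H = H + np.outer(s, s) / sy - np.outer(Hy, Hy) / float(y @ Hy)
        df = f - f_new
        x, f, g = x_new, f_new, g_new
        if df < tol:
            converged = True
            break
    return x, f, it, converged


# ---------------------------------------------------------------------------
# Pose minimization
# ---------------------------------------------------------------------------

def _selected_dof_indices(pose: PoseModel, dofs: DOFSelection) -> List[int]:
    interface = (
        set(select_interface_sidechains(pose, dofs.interface_cutoff))
        if dofs.receptor_chis
        else set()
    )
    sel = []
    for i, name in enumerate(pose.dof_names):
        kind = name[0]
        if kind in ("phi", "psi", "omega", "pchi"):
            if dofs.peptide_torsions:
                sel.append(i)
        elif kind == "rb":
            if dofs.rigid_body:
                sel.append(i)
        elif kind == "rchi":
            if dofs.receptor_chis and name[1] in interface:
                sel.append(i)
        elif kind == "lig":
            if dofs.ligand_dihedrals:
                sel.append(i)
    return sel


def minimize_pose(
    pose: PoseModel,
    energy_fn: Optional[EnergyFunction] = None,
    constraints: Sequence[DistanceConstraint] = (),
    dofs: Optional[DOFSelection] = None,
    tolerance: float = 1e-4,
    max_iter: int = 500,
    constraint_weight: Optional[float] = None,
) -> MinimizeResult:
    """Minimize the pose energy plus weighted constraint energy over the
    selected torsion and rigid-body space. Deterministic for fixed input."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    efn = energy_fn or EnergyFunction.default()
    dofs = dofs or DOFSelection()
    w_cst = (
        efn.weights.get("constraint", 1.0)
        if constraint_weight is None
        else constraint_weight
    )

    sel = _selected_dof_indices(pose, dofs)
    model = ScoringModel(pose, efn, constraints)
    resolved = resolve_constraints(pose, constraints) if constraints else []

    # atoms that can move: anything placed by a z-matrix entry whose driver is
    # selected, plus everything downstream; conservatively, all peptide and
    # ligand atoms plus the side chains of selected receptor residues
    movable = set(np.where(pose.segment != PoseModel.SEG_RECEPTOR)[0])
    sel_res = {pose.dof_names[i][1] for i in sel if pose.dof_names[i][0] == "rchi"}
    for e in pose.entries:
        if e.driver is not None and pose.dof_names[e.driver][0] == "rchi":
            if pose.dof_names[e.driver][1] in sel_res:
                movable.add(e.atom)
    movable = np.array(sorted(movable), dtype=np.int64)
    sub = model.restricted_to_movable(movable, ref_coords=pose.coords)
    e_static = model.total(pose.coords) - sub.total(pose.coords)

    full_state = pose.state.copy()

    def objective(x: np.ndarray) -> float:
        st = full_state.copy()
        st[sel] = x
        coords = pose.rebuild(st)
        e = e_static + sub.total(coords)
        if resolved:
            e += w_cst * constraint_energy(coords, constraints, resolved)
        return e

    x0 = full_state[sel]

    def jac_fwd(z: np.ndarray) -> np.ndarray:
        # forward differences: cheaper than central at desk-scale accuracy
        h = 2e-3
        f0 = objective(z)
        g = np.empty(len(z))
        for i in range(len(z)):
            zp = z.copy()
            zp[i] += h
            g[i] = (objective(zp) - f0) / h
        return g

    start = objective(x0)
    if not np.isfinite(start):
        raise ValueError(
            "non-finite energy at start of minimization; relieve clashes first"
        )
    if len(sel) == 0:
        new_pose = pose.copy()
        return MinimizeResult(new_pose, start, start, 0, True, tolerance)

    x, f, iters, converged = dfp_minimize(
        objective, x0, tol=tolerance, max_iter=max_iter, jac=jac_fwd
    )
    if f > start:  # safety net; the line search should prevent this
        x, f = x0, start
    new_state = full_state.copy()
    new_state[sel] = x
    new_pose = pose.copy()
    new_pose.set_state(new_state)
    return MinimizeResult(new_pose, start, f, iters, converged, tolerance)
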