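"""TOML configuration loading for templates, energy weights, minimization
and classification thresholds."""
from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Dict, Optional

from .energy import DEFAULT_WEIGHTS, EnergyFunction
from .minimize import DOFSelection
from .specificity import ClassifierConfig, PipelineConfig

__all__ = ["DEFAULTS", "load_config", "pipeline_from_config"]

DEFAULTS: Dict[str, Any] = {
    "template": {
        "peptide_chain": "B",
        "ligand_codes": ["FAR"],
        "receptor_chains": None,
        "anchors": {},  # name -> "chain:seqpos:atom"
    },
    "energy": {
        "weights": dict(DEFAULT_WEIGHTS),
    },
    "minimize": {
        "tolerance": 1e-4,
        "max_iter": 120,
        "interface_cutoff": 8.0,
        "dofs": {
            "peptide_torsions": True,
            "rigid_body": True,
            "receptor_chis": True,
            "ligand_dihedrals": True,
        },
    },
    "constraints": {"sd": 0.1},
    "classifier": {"loose_threshold": -0.4, "stringent_threshold": -1.1},
    "packing": {"extra_chi": True, "exhaustive_limit": 100_000,
                "anneal_sweeps": 300},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    """Merge a TOML config file over the built-in defaults."""
    if path is None:
        return _deep_merge(DEFAULTS, {})
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    return _deep_merge(DEFAULTS, user)


def pipeline_from_config(cfg: Dict[str, Any]) -> PipelineConfig:
    efn = EnergyFunction.default()
    efn.weights.update(cfg["energy"]["weights"])
    dofs_cfg = cfg["minimize"]["dofs"]
    return PipelineConfig(
        energy_fn=efn,
        classifier=ClassifierConfig(
            loose_threshold=cfg["classifier"]["loose_threshold"],
            stringent_threshold=cfg["classifier"]["stringent_threshold"],
        ),
        constraint_sd=cfg["constraints"]["sd"],
        extra_chi=cfg["packing"]["extra_chi"],
        exhaustive_limit=cfg["packing"]["exhaustive_limit"],
        anneal_sweeps=cfg["packing"]["anneal_sweeps"],
        tolerance=cfg["minimize"]["tolerance"],
        max_iter=cfg["minimize"]["max_iter"],
        dofs=DOFSelection(
            peptide_torsions=dofs_cfg["peptide_torsions"],
            rigid_body=dofs_cfg["rigid_body"],
            receptor_chis=dofs_cfg["receptor_chis"],
            ligand_dihedrals=dofs_cfg["ligand_dihedrals"],
            interface_cutoff=cfg["minimize"]["interface_cutoff"],
        ),
    )
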