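"""The threading pipeline: thread -> pack -> minimize -> score -> classify,
plus Cxxx sequence-space enumeration, proteome C-terminal motif scanning and
position frequency matrices.

Scores use the peptide scheme without the per-amino-acid reference constant
(the scheme found most discriminating for substrate prediction); lower is
better. A score exactly equal to a threshold classifies into the more
favorable class.
"""
from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .conformers import (
    PeptideSequence,
    PoseModel,
    RotamerLibrary,
    pack_sidechains,
    sequence_seed,
    thread_sequence,
)
from .energy import (
    DistanceConstraint,
    EnergyFunction,
    derive_constraints,
    peptide_score,
    score_pose,
)
from .minimize import DOFSelection, minimize_pose
from .structio import TemplateComplex
from .topology import AA1_TO_3

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "ScoreRecord",
    "MotifHit",
    "PositionFrequencyMatrix",
    "PipelineConfig",
    "score_sequence",
    "score_sequences",
    "classify",
    "enumerate_cxxx",
    "scan_proteome",
    "position_frequency_matrix",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CLASSES = ("strong_binder", "binder", "non_binder")


@dataclass(frozen=True)
class ClassifierConfig:
    """Two-threshold classifier on peptide energies (lower = better)."""

    loose_threshold: float = -0.4
    stringent_threshold: float = -1.1

    def __post_init__(self) -> None:
        if self.stringent_threshold > self.loose_threshold:
            raise ValueError(
                "stringent threshold must be <= loose threshold "
                f"({self.stringent_threshold} > {self.loose_threshold})"
            )


@dataclass
class ScoreRecord:
    sequence: PeptideSequence
    score: float
    scheme: str
    classification: str
    diagnostics: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: PeptideSequence
    protein_length: int


@dataclass
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies over the 4 motif columns."""

    freq: pd.DataFrame  # index: 20 amino acids; columns: C, a1, a2, X

    def __post_init__(self) -> None:
        sums = self.freq.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PFM columns must each sum to 1")

    def column(self, role: str) -> pd.Series:
        return self.freq[role]


@dataclass
class PipelineConfig:
    """Tunable knobs of the scoring pipeline."""

    energy_fn: EnergyFunction = field(default_factory=EnergyFunction.default)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    constraint_sd: float = 0.1
    extra_chi: bool = True
    exhaustive_limit: int = 100_000
    anneal_sweeps: int = 300
    tolerance: float = 1e-4
    max_iter: int = 200
    dofs: DOFSelection = field(default_factory=DOFSelection)
    rotamer_library: Optional[RotamerLibrary] = None
    compute_sasa: bool = False


def classify(score: float, config: ClassifierConfig) -> str:
    """Scores at a threshold fall into the more favorable class."""
    if score <= config.stringent_threshold:
        return "strong_binder"
    if score <= config.loose_threshold:
        return "binder"
    return "non_binder"


def score_sequence(
    template: TemplateComplex,
    sequence: PeptideSequence | str,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> ScoreRecord:
    """Run the full pipeline for one Cxxx sequence.

    Stages: thread onto the template backbone, pack peptide side chains
    (receptor fixed), minimize all pipeline degrees of freedom under the
    five conserved constraints, score with the peptide-no-reference scheme,
    classify against the thresholds in force.
    """
    cfg = config or PipelineConfig()
    if isinstance(sequence, str):
        sequence = PeptideSequence(sequence)
    constraints = derive_constraints(template, sd=cfg.constraint_sd)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed for "
                               f"{sequence}: {exc}") from exc

    pose = stage("thread", thread_sequence, template, sequence,
                 rotamer_library=cfg.rotamer_library)
    pose = stage(
        "pack", pack_sidechains, pose, [0, 1, 2, 3],
        extra_chi=cfg.extra_chi, energy_fn=cfg.energy_fn,
        seed=sequence_seed(seed, sequence.letters),
        rotamer_library=cfg.rotamer_library,
        exhaustive_limit=cfg.exhaustive_limit,
        anneal_sweeps=cfg.anneal_sweeps,
    )
    result = stage(
        "minimize", minimize_pose, pose, cfg.energy_fn, constraints,
        dofs=cfg.dofs, tolerance=cfg.tolerance, max_iter=cfg.max_iter,
    )
    breakdown = stage(
        "score", score_pose, result.pose, cfg.energy_fn, constraints,
        compute_sasa=cfg.compute_sasa,
    )
    score = peptide_score(breakdown, include_ref=False)
    return ScoreRecord(
        sequence=sequence,
        score=score,
        scheme="peptide_no_ref",
        classification=classify(score, cfg.classifier),
        diagnostics={
            "constraint_total": breakdown.constraint_total,
            "iterations": float(result.iterations),
            "converged": float(result.converged),
            "start_energy": result.start_energy,
            "end_energy": result.end_energy,
            "cross_interface": breakdown.cross_interface,
        },
    )


def score_sequences(
    template: TemplateComplex,
    sequences: Iterable[PeptideSequence | str],
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> List[ScoreRecord]:
    """Score a batch of sequences. Per-sequence seeds are derived from the
    sequence itself, so results are independent of evaluation order."""
    return [score_sequence(template, s, config=config, seed=seed)
            for s in sequences]


def records_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    rows = [
        {
            "sequence": r.sequence.letters,
            "score": r.score,
            "classification": r.classification,
            "scheme": r.scheme,
            **{f"diag_{k}": v for k, v in r.diagnostics.items()},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence space and proteome scanning
# ---------------------------------------------------------------------------

def enumerate_cxxx() -> List[PeptideSequence]:
    """All 20^3 = 8000 Cxxx sequences, lexicographic by one-letter code."""
    return [
        PeptideSequence("C" + "".join(t))
        for t in itertools.product(ALPHABET, repeat=3)
    ]


def scan_proteome(
    fasta_source,
    unique: bool = False,
):
    """Scan protein FASTA records for a C-terminal Cxxx motif.

    Returns a list of :class:`MotifHit` (one per protein whose last four
    residues match C-x-x-x in standard letters). Proteins shorter than four
    residues or with non-standard letters in the motif are skipped with a
    logged warning. With ``unique=True``, returns a dict motif -> list of
    protein ids instead.
    """
    if isinstance(fasta_source, (str, Path)) and "\n" not in str(fasta_source):
        handle = open(fasta_source)
    elif isinstance(fasta_source, str):
        handle = io.StringIO(fasta_source)
    else:
        handle = fasta_source
    hits: List[MotifHit] = []
    try:
        n_records = 0
        for rec in SeqIO.parse(handle, "fasta"):
            n_records += 1
            seq = str(rec.seq).upper().rstrip("*")
            if len(seq) < 4:
                logger.warning("skipping %s: shorter than 4 residues", rec.id)
                continue
            tail = seq[-4:]
            if tail[0] != "C":
                continue
            if any(ch not in ALPHABET for ch in tail):
                logger.warning(
                    "skipping %s: non-standard letters in motif %s", rec.id, tail
                )
                continue
            hits.append(
                MotifHit(
                    protein_id=rec.id,
                    motif=PeptideSequence(tail),
                    protein_length=len(seq),
                )
            )
        if n_records == 0:
            raise ValueError("no FASTA records found in input")
    finally:
        if handle is not fasta_source:
            handle.close()
    if unique:
        by_motif: Dict[str, List[str]] = {}
        for h in hits:
            by_motif.setdefault(h.motif.letters, []).append(h.protein_id)
        return by_motif
    return hits


def position_frequency_matrix(
    sequences: Iterable[PeptideSequence | str],
    pseudocount: float = 0.0,
) -> PositionFrequencyMatrix:
    """Per-position relative amino-acid frequencies of a set of Cxxx motifs."""
    seqs = [
        s.letters if isinstance(s, PeptideSequence) else PeptideSequence(s).letters
        for s in sequences
    ]
    if not seqs:
        raise ValueError("need at least one sequence")
    counts = np.full((len(ALPHABET), 4), float(pseudocount))
    aa_index = {aa: i for i, aa in enumerate(ALPHABET)}
    for seq in seqs:
        for j, ch in enumerate(seq):
            counts[aa_index[ch], j] += 1.0
    freq = counts / counts.sum(axis=0, keepdims=True)
    df = pd.DataFrame(freq, index=list(ALPHABET), columns=["C", "a1", "a2", "X"])
    return PositionFrequencyMatrix(freq=df)
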