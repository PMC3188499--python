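"""Labeled peptide sets, ROC/AUC with a lower-is-better score orientation,
operating-point statistics and threshold calibration.

Orientation note: peptide energies are binding scores where LOWER means a
stronger predicted binder, so a prediction is positive when score <= the
threshold. Most ROC libraries assume the opposite orientation; negate scores
before handing them to such libraries.
Ties at a threshold count as positive calls ("<= passes").
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "LabeledPeptideSet",
    "ROCCurve",
    "CalibrationTarget",
    "read_labeled_set",
    "roc_curve",
    "rates_at_threshold",
    "calibrate_thresholds",
]

DEFAULT_VOCABULARY = frozenset({"MTO", "STO", "NON", "binder", "non_binder"})
DEFAULT_POSITIVE = frozenset({"MTO", "binder"})


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    label: str
    score: Optional[float] = None


@dataclass
class LabeledPeptideSet:
    records: List[PeptideRecord]
    vocabulary: frozenset = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.records]
        dups = {s for s in seqs if seqs.count(s) > 1}
        if dups:
            raise ValueError(f"duplicate sequences in labeled set: {sorted(dups)}")
        unknown = {r.label for r in self.records} - self.vocabulary
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")

    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for r in self.records:
            out[r.label] = out.get(r.label, 0) + 1
        return out

    def sequences(self) -> List[str]:
        return [r.sequence for r in self.records]

    def binary_labels(self, positive_labels: Iterable[str] = DEFAULT_POSITIVE):
        pos = set(positive_labels)
        return np.array([r.label in pos for r in self.records], dtype=bool)

    def scores(self) -> np.ndarray:
        if any(r.score is None for r in self.records):
            raise ValueError("labeled set has records without scores")
        return np.array([r.score for r in self.records], dtype=float)


def read_labeled_set(
    table_source,
    positive_labels: Iterable[str] = DEFAULT_POSITIVE,
    vocabulary: Optional[Iterable[str]] = None,
) -> LabeledPeptideSet:
    """Read a TSV with header ``sequence<TAB>label[<TAB>score]``.

    Duplicate sequences and labels outside the vocabulary are errors.
    """
    if isinstance(table_source, (str, Path)) and "\n" not in str(table_source):
        df = pd.read_csv(table_source, sep="\t")
    elif isinstance(table_source, str):
        df = pd.read_csv(io.StringIO(table_source), sep="\t")
    else:
        df = pd.read_csv(table_source, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sequence" not in cols or "label" not in cols:
        raise ValueError("labeled table needs 'sequence' and 'label' columns")
    vocab = frozenset(vocabulary) if vocabulary is not None else DEFAULT_VOCABULARY
    score_col = cols.get("score")
    records = [
        PeptideRecord(
            sequence=str(row[cols["sequence"]]).strip().upper(),
            label=str(row[cols["label"]]).strip(),
            score=(float(row[score_col]) if score_col is not None
                   and pd.notna(row[score_col]) else None),
        )
        for _, row in df.iterrows()
    ]
    pos = set(positive_labels)
    unknown_pos = pos - set(vocab)
    if unknown_pos:
        raise ValueError(f"positive labels {sorted(unknown_pos)} not in vocabulary")
    return LabeledPeptideSet(records=records, vocabulary=vocab)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < -1e-12) or np.any(np.diff(self.tpr) < -1e-12):
            raise ValueError("ROC rates must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must span (0,0) to (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def _validate_binary(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or (~labels).all():
        raise ValueError("ROC needs at least one positive and one negative")
    return scores, labels


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over all score thresholds, lower-is-positive orientation.

    The AUC is computed by the trapezoid rule and cross-checked against the
    concordant-pair (Mann-Whitney) statistic with ties counted 1/2.
    """
    scores, labels = _validate_binary(scores, labels)
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]
    P, N = int(y.sum()), int((~y).sum())
    uniq = np.unique(s)
    tpr = [0.0]
    fpr = [0.0]
    for thr in uniq:  # ascending thresholds = increasingly permissive
        tpr.append(float((scores[labels] <= thr).sum()) / P)
        fpr.append(float((scores[~labels] <= thr).sum()) / N)
    tpr, fpr = np.array(tpr), np.array(fpr)
    thresholds = np.concatenate([[-np.inf], uniq])
    auc_trap = float(np.trapezoid(tpr, fpr))

    # concordant-pair cross-check
    pos = scores[labels]
    neg = scores[~labels]
    less = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc_mw = float((less + 0.5 * ties) / (P * N))
    if abs(auc_trap - auc_mw) > 1e-9:
        raise RuntimeError(
            f"AUC cross-check failed: trapezoid {auc_trap} vs pairs {auc_mw}"
        )
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_trap)


def rates_at_threshold(scores, labels, threshold: float) -> Tuple[float, float]:
    """(TPR, FPR) at a threshold; score <= threshold is a positive call."""
    scores, labels = _validate_binary(scores, labels)
    tpr = float((scores[labels] <= threshold).mean())
    fpr = float((scores[~labels] <= threshold).mean())
    return tpr, fpr


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTarget:
    """Operating-point request: ``loose_max_fpr`` bounds the false-positive
    rate of the loose threshold (None selects the Youden-J optimum);
    ``stringent_max_fpr`` bounds the stringent threshold."""

    loose_max_fpr: Optional[float] = None
    stringent_max_fpr: float = 0.02


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo = uniq[0] - 1.0
    hi = uniq[-1]
    return np.concatenate([[lo], mids, [hi]])


def calibrate_thresholds(scores, labels, target: Optional[CalibrationTarget] = None):
    """Fit loose/stringent classification thresholds to labeled scores.

    The loose threshold maximizes Youden's J (or the TPR subject to the
    requested FPR bound); the stringent threshold is the most permissive
    threshold meeting the stricter FPR bound. Ties break toward the lower
    (more conservative) threshold. An unattainable FPR bound returns the
    closest attainable point with a warning.
    """
    from .specificity import ClassifierConfig

    scores, labels = _validate_binary(scores, labels)
    target = target or CalibrationTarget()
    cands = _candidate_thresholds(scores)
    tprs = np.array([(scores[labels] <= t).mean() for t in cands])
    fprs = np.array([(scores[~labels] <= t).mean() for t in cands])

    def pick(max_fpr: Optional[float]) -> float:
        if max_fpr is None:
            j = tprs - fprs
            best = np.max(j)
            idx = np.where(j >= best - 1e-12)[0]
            return float(cands[idx[0]])  # tie -> lower threshold
        ok = np.where(fprs <= max_fpr + 1e-12)[0]
        if len(ok) == 0:
            warnings.warn(
                f"FPR bound {max_fpr} unattainable; using the closest point",
                stacklevel=2,
            )
            return float(cands[int(np.argmin(fprs))])
        best_tpr = tprs[ok].max()
        if best_tpr == 0.0:
            warnings.warn(
                f"FPR bound {max_fpr} only attainable with zero TPR",
                stacklevel=2,
            )
        idx = ok[np.where(tprs[ok] >= best_tpr - 1e-12)[0]]
        return float(cands[idx[0]])

    loose = pick(target.loose_max_fpr)
    stringent = pick(target.stringent_max_fpr)
    stringent = min(stringent, loose)
    return ClassifierConfig(loose_threshold=loose, stringent_threshold=stringent)
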