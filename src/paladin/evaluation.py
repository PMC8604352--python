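"""Classifier evaluation (ROC/PR) and structural benchmarking.

ROC/PR curves summarize how well 13-mer scores separate the peptide-array
binding classes (lower score = predicted binder).  Structural benchmarking
checks register and orientation predictions against peptides whose bound
configuration is known from crystal structures of chaperone-substrate
complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics as _metrics

from .core import AA_INDEX, KT, PSSM, PaladinError, WeightSet
from .energetics import PropensityScales
from .scanner import predict_orientation, sanitize_sequence, scan_sequence

logger = logging.getLogger(__name__)


class EvaluationError(PaladinError, ValueError):
    pass


@dataclass(frozen=True)
class StructureBenchmarkRecord:
    """A structurally characterized chaperone-bound peptide.

    ``core`` is the observed five-residue binding core at 0-based ``offset``
    within ``sequence``; ``orientation`` is the observed backbone direction.
    """

    sequence: str
    orientation: str
    core: str
    offset: int
    structure_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "core", self.core.upper())
        if self.orientation not in ("forward", "reverse"):
            raise EvaluationError(
                f"orientation must be forward or reverse; got {self.orientation!r}"
            )
        if len(self.core) != 5:
            raise EvaluationError(f"core must be a five-mer; got {self.core!r}")
        if self.sequence[self.offset : self.offset + 5] != self.core:
            raise EvaluationError(
                f"core {self.core!r} is not the substring of {self.sequence!r} "
                f"at offset {self.offset}"
            )

    def has_standard_residues(self) -> bool:
        return all(r in AA_INDEX for r in self.sequence)


@dataclass
class Curve:
    """An evaluation curve with the thresholds that produced each point."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    auc: float
    kind: str = ""

    def plot(self, ax=None, **kwargs):
        """Plot the curve (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", f"{self.kind} (AUC = {self.auc:.3f})")
        ax.plot(self.x, self.y, label=label, **kwargs)
        if self.kind == "roc":
            ax.plot([0, 1], [0, 1], "r--", lw=0.8)
            ax.set_xlabel("False positive rate")
            ax.set_ylabel("True positive rate")
        elif self.kind == "pr":
            ax.set_xlabel("Recall")
            ax.set_ylabel("Precision")
        ax.legend()
        return ax


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError(
            "labels contain a single class; ROC/PR AUC is undefined"
        )
    return labels


def roc_curve(scores, labels) -> Curve:
    """ROC curve with trapezoidal AUC; lower score = predicted positive.

    The AUC equals the rank (concordance) statistic on the same data: the
    fraction of (positive, negative) pairs where the positive scores lower,
    ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    fpr, tpr, thr = _metrics.roc_curve(labels, -scores)
    return Curve(
        x=fpr, y=tpr, thresholds=-thr, auc=float(_metrics.auc(fpr, tpr)),
        kind="roc",
    )


def pr_curve(scores, labels) -> Curve:
    """Precision-recall curve; AUC by trapezoid over recall."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    precision, recall, thr = _metrics.precision_recall_curve(labels, -scores)
    # points arrive recall-descending; integrate in reversed (ascending) order
    # preserving the within-tie sequence, so tied-recall boundaries are kept
    auc = float(np.trapezoid(precision[::-1], recall[::-1]))
    thresholds = np.concatenate([-thr, [np.nan]])  # pad to len(points)
    return Curve(x=recall, y=precision, thresholds=thresholds, auc=auc, kind="pr")


def dichotomy_labels(records, positive=("strong", "binder")):
    """Binary labels for a class dichotomy vs nonbinders.

    Returns (labels, mask): ``mask`` selects records that are either in
    ``positive`` or nonbinders (neutral records are excluded), ``labels`` is
    True for the positive class within the mask.
    """
    pos = set(positive)
    mask = np.array([r.label in pos or r.label == "nonbinder" for r in records])
    labels = np.array([r.label in pos for r in records])[mask]
    return labels, mask


@dataclass
class BenchmarkReport:
    """Counts plus a per-record table for a structural benchmark run."""

    n_correct: int
    n_total: int
    n_ambiguous: int = 0
    n_excluded: int = 0
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def benchmark_registers(
    records: list[StructureBenchmarkRecord],
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
) -> BenchmarkReport:
    """Register benchmark over forward-bound peptides longer than five residues.

    A record is correct iff its observed (core five-mer, orientation) attains
    the global minimum score across all windows in both orientations.
    Peptides with non-standard residues are excluded and counted.
    """
    rows = []
    n_correct = 0
    n_total = 0
    n_excluded = 0
    for rec in records:
        seq = sanitize_sequence(rec.sequence)
        if rec.orientation != "forward" or len(seq) < 6:
            continue
        if not rec.has_standard_residues():
            n_excluded += 1
            logger.info(
                "excluding %s (%s): non-standard residues",
                rec.sequence, rec.structure_id,
            )
            rows.append(
                {
                    "sequence": rec.sequence,
                    "structure_id": rec.structure_id,
                    "observed_core": rec.core,
                    "predicted_core": None,
                    "predicted_orientation": None,
                    "margin": np.nan,
                    "correct": None,
                    "excluded": "non-standard residue",
                }
            )
            continue
        n_total += 1
        result = scan_sequence(seq, pssm, weights, scales, rec.structure_id)
        best = result.best
        observed = next(
            (
                s
                for s in result.scores
                if s.start == rec.offset and s.orientation == rec.orientation
            ),
            None,
        )
        correct = (
            best is not None
            and observed is not None
            and best.start == rec.offset
            and best.orientation == rec.orientation
            and best.total == min(s.total for s in result.scores)
        )
        if correct:
            n_correct += 1
        if -10.0 <= (observed.total if observed else np.nan) <= -5.0:
            pass
        elif observed is not None:
            logger.info(
                "observed register of %s scores %.2f kcal/mol "
                "(outside the typical -10..-5 range)",
                rec.sequence, observed.total,
            )
        rows.append(
            {
                "sequence": rec.sequence,
                "structure_id": rec.structure_id,
                "observed_core": rec.core,
                "predicted_core": best.window if best else None,
                "predicted_orientation": best.orientation if best else None,
                "observed_score": observed.total if observed else np.nan,
                "best_score": best.total if best else np.nan,
                "margin": (
                    (observed.total - best.total)
                    if best is not None and observed is not None
                    else np.nan
                ),
                "correct": correct,
                "excluded": "",
            }
        )
    return BenchmarkReport(
        n_correct=n_correct,
        n_total=n_total,
        n_excluded=n_excluded,
        table=pd.DataFrame(rows),
    )


def benchmark_orientations(
    records: list[StructureBenchmarkRecord],
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    threshold: float = KT,
) -> BenchmarkReport:
    """Orientation benchmark over all peptides with >= 5 standard residues.

    Correct iff the orientation call equals the observed orientation; calls
    with |forward - reverse| gap below the kT threshold are counted
    ambiguous, not correct.
    """
    rows = []
    n_correct = 0
    n_ambiguous = 0
    n_total = 0
    n_excluded = 0
    for rec in records:
        seq = sanitize_sequence(rec.sequence)
        if len(seq) < 5:
            continue
        if not rec.has_standard_residues():
            n_excluded += 1
            logger.info(
                "excluding %s (%s): non-standard residues",
                rec.sequence, rec.structure_id,
            )
            rows.append(
                {
                    "sequence": rec.sequence,
                    "structure_id": rec.structure_id,
                    "observed": rec.orientation,
                    "call": None,
                    "delta": np.nan,
                    "correct": None,
                    "excluded": "non-standard residue",
                }
            )
            continue
        n_total += 1
        call = predict_orientation(
            seq, pssm, weights, scales, ambiguity_threshold=threshold,
            seq_id=rec.structure_id,
        )
        if call.call == "ambiguous":
            n_ambiguous += 1
        elif call.call == rec.orientation:
            n_correct += 1
        rows.append(
            {
                "sequence": rec.sequence,
                "structure_id": rec.structure_id,
                "observed": rec.orientation,
                "call": call.call,
                "delta": call.delta,
                "correct": call.call == rec.orientation,
                "excluded": "",
            }
        )
    return BenchmarkReport(
        n_correct=n_correct,
        n_total=n_total,
        n_ambiguous=n_ambiguous,
        n_excluded=n_excluded,
        table=pd.DataFrame(rows),
    )
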