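"""Weight training against classed peptide-array data.

The peptide-array assay classifies tiled 13-mers of client proteins into four
semi-quantitative classes (strong binder / binder / neutral / nonbinder).
The model's weights are fitted by maximizing a combined class-separation
objective

    Z = 4 z_sb-nb + 2 z_bi-nb + z_bi-sb + 1/2 z_nu-nb,

where each z = (mu_1 - mu_2) / sqrt((sigma_1^2 + sigma_2^2)/2) separates two
classes.  Because better binders have lower (more negative) scores, z-scores
are computed on negated 13-mer scores so that stronger separation yields a
larger Z.  The search is a Monte-Carlo walk over the trainable weights with
an annealed acceptance threshold.

The fitting surface follows the Model/Results convention:
``PeptideArrayModel(records, terms).fit()`` returns a
:class:`PeptideArrayResults` carrying the fitted weights, the objective
breakdown, the Z trace and a ``summary()``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    AA_INDEX,
    SITE_LABELS,
    SITES,
    TERMS,
    EnergyTermMatrix,
    PaladinError,
    PSSM,
    WeightSet,
    combine_terms,
    default_weights,
)
from .energetics import PropensityScales

logger = logging.getLogger(__name__)

CLASSES: tuple[str, ...] = ("strong", "binder", "neutral", "nonbinder")
CLASS_Z_WEIGHTS: dict[str, float] = {
    "z_sb_nb": 4.0,
    "z_bi_nb": 2.0,
    "z_bi_sb": 1.0,
    "z_nu_nb": 0.5,
}
#: Cap for saturated (zero-variance) z components.
Z_CAP: float = 10.0

#: Weights that may move during the default search: the six per-residue term
#: weights plus the backbone coil-propensity weight.  Site weights and the
#: reverse penalty stay fixed.
DEFAULT_TRAINABLE: tuple[str, ...] = TERMS + ("w_cp",)


class TrainingError(PaladinError, ValueError):
    pass


@dataclass(frozen=True)
class PeptideArrayRecord:
    """A 13-mer and its binding class from the peptide array."""

    sequence: str
    label: str
    protein_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != 13:
            raise TrainingError(
                f"array peptide must be a 13-mer; got {len(seq)} residues: {seq!r}"
            )
        bad = [r for r in seq if r not in AA_INDEX]
        if bad:
            raise TrainingError(
                f"array peptide {seq!r} has non-standard residues: {bad}"
            )
        if self.label not in CLASSES:
            raise TrainingError(
                f"label must be one of {CLASSES}; got {self.label!r}"
            )


@dataclass
class TrainingConfig:
    """Monte-Carlo search settings.

    ``steps`` defaults to the published total of 1e7 (divided across parallel
    searches in the original protocol; here a single search).  The acceptance
    threshold for worsening moves anneals linearly from ``threshold_start``
    to ``threshold_end`` across the run.
    """

    steps: int = 10_000_000
    threshold_start: float = 0.25
    threshold_end: float = 0.0
    train_fraction: float = 0.8
    seed: int = 0
    trainable: tuple[str, ...] = DEFAULT_TRAINABLE
    step_size: float = 0.05
    weight_bounds: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold_end <= self.threshold_start <= 1.0):
            raise TrainingError(
                "require 0 <= threshold_end <= threshold_start <= 1; got "
                f"{self.threshold_end}, {self.threshold_start}"
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise TrainingError(
                f"train_fraction must be in (0, 1); got {self.train_fraction}"
            )
        known = set(TERMS) | {"w_cp", "e_reverse"} | {f"site_{s}" for s in SITES}
        unknown = set(self.trainable) - known
        if unknown:
            raise TrainingError(f"unknown trainable parameters: {sorted(unknown)}")


@dataclass
class ObjectiveBreakdown:
    """The combined objective Z and its four class-separation components."""

    z_sb_nb: float
    z_bi_nb: float
    z_bi_sb: float
    z_nu_nb: float

    @property
    def Z(self) -> float:
        return (
            4.0 * self.z_sb_nb
            + 2.0 * self.z_bi_nb
            + self.z_bi_sb
            + 0.5 * self.z_nu_nb
        )


def class_zscore(scores_a, scores_b) -> float:
    """Separation z-score (mu_a - mu_b) / sqrt((sigma_a^2 + sigma_b^2)/2).

    Degenerate inputs: zero pooled spread with equal means -> 0; zero spread
    with unequal means -> signed infinity (callers cap it).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TrainingError("each class needs at least 2 scores")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise TrainingError("scores must be finite")
    num = a.mean() - b.mean()
    pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
    if pooled == 0.0:
        if num == 0.0:
            return 0.0
        logger.warning("zero pooled variance with unequal means: saturated z")
        return math.inf if num > 0 else -math.inf
    return float(num / math.sqrt(pooled))


def _capped(z: float) -> float:
    if math.isinf(z):
        return Z_CAP if z > 0 else -Z_CAP
    return z


def combined_objective(scores_by_class: dict[str, np.ndarray]) -> ObjectiveBreakdown:
    """Z objective from per-class 13-mer scores (lower score = better binder).

    z-scores are computed on negated scores so that binders separating below
    nonbinders give positive components.  Saturated (infinite) components are
    capped at +/-10 with a warning.
    """
    missing = [c for c in CLASSES if c not in scores_by_class]
    if missing:
        raise TrainingError(f"missing classes in objective input: {missing}")
    neg = {c: -np.asarray(scores_by_class[c], dtype=float) for c in CLASSES}
    return ObjectiveBreakdown(
        z_sb_nb=_capped(class_zscore(neg["strong"], neg["nonbinder"])),
        z_bi_nb=_capped(class_zscore(neg["binder"], neg["nonbinder"])),
        z_bi_sb=_capped(class_zscore(neg["binder"], neg["strong"])),
        z_nu_nb=_capped(class_zscore(neg["neutral"], neg["nonbinder"])),
    )


def split_dataset(
    records: list[PeptideArrayRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[PeptideArrayRecord], list[PeptideArrayRecord]]:
    """Stratified, reproducible train/validation split.

    Disjoint and exhaustive; within each class the train share is within one
    record of ``train_fraction``.
    """
    if len(records) < 10:
        raise TrainingError(f"need at least 10 records to split; got {len(records)}")
    if not (0.0 < train_fraction < 1.0):
        raise TrainingError(f"train_fraction must be in (0,1); got {train_fraction}")
    present = {r.label for r in records}
    if len(records) < len(present):
        raise TrainingError("fewer records than classes")
    rng = np.random.default_rng(seed)
    train: list[PeptideArrayRecord] = []
    valid: list[PeptideArrayRecord] = []
    for label in CLASSES:
        group = [r for r in records if r.label == label]
        if not group:
            continue
        order = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 0), len(group))
        for rank, idx in enumerate(order):
            (train if rank < n_train else valid).append(group[idx])
    return train, valid


class _ArrayDesign:
    """Precomputed scoring tensors for fast objective evaluation.

    For each 13-mer and each of its 9 forward windows, ``site_terms`` holds
    the raw per-site, per-term energies (n, 9, 5, 6) and ``ecp`` the window
    coil propensity (n, 9).  A window score under weights (s, t, w_cp) is
    einsum('st,s,t', site_terms[i, w], s, t) + w_cp * ecp[i, w]; the 13-mer
    score is the window minimum.
    """

    def __init__(
        self,
        records: list[PeptideArrayRecord],
        terms: EnergyTermMatrix,
        scales: PropensityScales | None = None,
    ) -> None:
        n = len(records)
        self.records = records
        self.site_terms = np.empty((n, 9, 5, 6))
        self.ecp = np.zeros((n, 9))
        coil = None
        if scales is not None:
            coil = np.array(
                [1.0 - scales.helical[a] for a in sorted(AA_INDEX, key=AA_INDEX.get)]
            )
        for i, rec in enumerate(records):
            idx = np.array([AA_INDEX[r] for r in rec.sequence])
            for w in range(9):
                window = idx[w : w + 5]
                # forward orientation: window position j occupies site j
                self.site_terms[i, w] = terms.values[np.arange(5), window, :]
                if coil is not None:
                    self.ecp[i, w] = coil[window].mean()
        self.class_masks = {
            c: np.array([r.label == c for r in records]) for c in CLASSES
        }
        self._collapsed_key: tuple | None = None
        self._collapsed: np.ndarray | None = None

    def _site_collapsed(self, sw: np.ndarray) -> np.ndarray:
        # site weights rarely move, so cache the site-collapsed (n, 9, 6) tensor
        key = tuple(sw)
        if key != self._collapsed_key:
            self._collapsed = np.einsum("nwst,s->nwt", self.site_terms, sw)
            self._collapsed_key = key
        return self._collapsed

    def scores(self, weights: WeightSet) -> np.ndarray:
        """Forward-only min-over-windows score of every 13-mer."""
        sw = weights.site_vector()
        tw = weights.term_vector()
        window_scores = self._site_collapsed(sw) @ tw
        if weights.w_cp != 0.0:
            window_scores = window_scores + weights.w_cp * self.ecp
        return window_scores.min(axis=1)

    def objective(self, weights: WeightSet) -> ObjectiveBreakdown:
        s = self.scores(weights)
        by_class = {c: s[m] for c, m in self.class_masks.items()}
        for c, v in by_class.items():
            if v.size < 2:
                raise TrainingError(f"class {c!r} has fewer than 2 records")
        return combined_objective(by_class)


def _get_param(w: WeightSet, name: str) -> float:
    if name in TERMS:
        return w.term_weights[name]
    if name == "w_cp":
        return w.w_cp
    if name == "e_reverse":
        return w.e_reverse
    return w.site_weights[int(name.split("_", 1)[1])]


def _set_param(w: WeightSet, name: str, value: float) -> None:
    if name in TERMS:
        w.term_weights[name] = value
    elif name == "w_cp":
        w.w_cp = value
    elif name == "e_reverse":
        w.e_reverse = value
    else:
        w.site_weights[int(name.split("_", 1)[1])] = value


def monte_carlo_search(
    terms: EnergyTermMatrix,
    records: list[PeptideArrayRecord],
    config: TrainingConfig,
    initial: WeightSet | None = None,
    scales: PropensityScales | None = None,
    design: "_ArrayDesign | None" = None,
) -> tuple[WeightSet, np.ndarray]:
    """Annealed Monte-Carlo maximization of Z over the trainable weights.

    At each step one trainable weight is perturbed by a uniform step in
    [-step_size, +step_size], clipped to the weight bounds.  Improvements are
    always accepted; a worsening move is accepted iff uniform(0,1) is below
    the current threshold, which decreases linearly from ``threshold_start``
    to ``threshold_end`` across the run.  Returns the best-ever weights and
    the trace of the current Z after every step (trace[0] is the initial Z).
    """
    if design is None:
        design = _ArrayDesign(records, terms, scales)
    rng = np.random.default_rng(config.seed)
    current = (initial or default_weights()).copy()
    current_z = design.objective(current).Z
    best = current.copy()
    best_z = current_z
    trace = np.empty(config.steps + 1)
    trace[0] = current_z
    n_steps = config.steps
    lo, hi = config.weight_bounds
    for step in range(n_steps):
        frac = step / max(n_steps - 1, 1)
        threshold = (
            config.threshold_start
            + (config.threshold_end - config.threshold_start) * frac
        )
        name = config.trainable[rng.integers(len(config.trainable))]
        proposal = current.copy()
        old = _get_param(proposal, name)
        new = float(np.clip(old + rng.uniform(-config.step_size, config.step_size),
                            lo, hi))
        _set_param(proposal, name, new)
        try:
            z = design.objective(proposal).Z
        except TrainingError:
            z = math.nan
        if not math.isfinite(z):
            logger.warning(
                "step %d: non-finite Z for %s=%.4f; proposal rejected",
                step, name, new,
            )
            trace[step + 1] = current_z
            continue
        accept = z > current_z or rng.uniform() < threshold
        if accept:
            current, current_z = proposal, z
            if z > best_z:
                best, best_z = proposal.copy(), z
        trace[step + 1] = current_z
    return best, trace


# ---------------------------------------------------------------------------
# Model / Results fitting surface
# ---------------------------------------------------------------------------


class PeptideArrayModel:
    """Linear binding model to be fitted against classed peptide-array data.

    Parameters
    ----------
    records : list of PeptideArrayRecord
        The classed 13-mers.
    terms : EnergyTermMatrix
        The physical basis set (per site/residue/term energies).
    scales : PropensityScales, optional
        Needed only if the backbone coil-propensity weight is trainable or
        nonzero.
    start_weights : WeightSet, optional
        Search start; defaults to the published weight set.
    """

    def __init__(
        self,
        records: list[PeptideArrayRecord],
        terms: EnergyTermMatrix,
        scales: PropensityScales | None = None,
        start_weights: WeightSet | None = None,
    ) -> None:
        if not records:
            raise TrainingError("no records supplied")
        self.records = list(records)
        self.terms = terms
        self.scales = scales
        self.start_weights = start_weights or default_weights()

    @classmethod
    def from_dataframe(
        cls, df, terms: EnergyTermMatrix, scales: PropensityScales | None = None,
        **kwargs,
    ) -> "PeptideArrayModel":
        """Build from a DataFrame with columns sequence, label[, protein_id]."""
        records = [
            PeptideArrayRecord(
                sequence=row.sequence,
                label=row.label,
                protein_id=getattr(row, "protein_id", "") or "",
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, terms, scales, **kwargs)

    def fit(
        self,
        config: TrainingConfig | None = None,
        steps: int | None = None,
        seed: int | None = None,
    ) -> "PeptideArrayResults":
        """Run the Monte-Carlo search and return a results object.

        The records are split (stratified, ``config.train_fraction``) into a
        training set driving the objective and a validation set retained for
        reporting.
        """
        config = config or TrainingConfig()
        if steps is not None:
            config = replace(config, steps=steps)
        if seed is not None:
            config = replace(config, seed=seed)
        if self.scales is None and "w_cp" in config.trainable:
            # without propensity scales the coil term is identically zero;
            # training its weight would be a random walk
            logger.info("no propensity scales supplied; w_cp not trained")
            config = replace(
                config,
                trainable=tuple(t for t in config.trainable if t != "w_cp"),
            )
        train, valid = split_dataset(
            self.records, config.train_fraction, config.seed
        )
        design = _ArrayDesign(train, self.terms, self.scales)
        weights, trace = monte_carlo_search(
            self.terms, train, config, initial=self.start_weights,
            scales=self.scales, design=design,
        )
        objective = design.objective(weights)
        valid_objective = None
        if valid and all(
            sum(r.label == c for r in valid) >= 2 for c in CLASSES
        ):
            valid_design = _ArrayDesign(valid, self.terms, self.scales)
            valid_objective = valid_design.objective(weights)
        return PeptideArrayResults(
            model=self,
            weights=weights,
            objective=objective,
            valid_objective=valid_objective,
            z_trace=trace,
            config=config,
            train_records=train,
            valid_records=valid,
        )


@dataclass
class PeptideArrayResults:
    """Fit results: weights, objective breakdown, Z trace and diagnostics."""

    model: PeptideArrayModel
    weights: WeightSet
    objective: ObjectiveBreakdown
    valid_objective: ObjectiveBreakdown | None
    z_trace: np.ndarray
    config: TrainingConfig
    train_records: list[PeptideArrayRecord]
    valid_records: list[PeptideArrayRecord]

    @property
    def params(self) -> WeightSet:
        return self.weights

    def pssm(self) -> PSSM:
        """Working PSSM under the fitted weights."""
        return combine_terms(self.model.terms, self.weights)

    def scores(self, records: list[PeptideArrayRecord] | None = None) -> np.ndarray:
        """Forward-only 13-mer scores under the fitted weights."""
        recs = records if records is not None else self.valid_records
        design = _ArrayDesign(recs, self.model.terms, self.model.scales)
        return design.scores(self.weights)

    def roc_auc(
        self, positive=("strong",), records=None
    ) -> float:
        """ROC AUC of the fitted model for a class dichotomy vs nonbinders."""
        from .evaluation import dichotomy_labels, roc_curve

        recs = records if records is not None else self.valid_records
        scores = self.scores(recs)
        labels, mask = dichotomy_labels(recs, positive=positive)
        return roc_curve(scores[mask], labels).auc

    def summary(self) -> str:
        lines = [
            "Peptide-array binding model fit (Monte-Carlo Z maximization)",
            "=" * 62,
            f"records: {len(self.model.records)} "
            f"(train {len(self.train_records)}, validation {len(self.valid_records)})",
            f"steps: {self.config.steps}   threshold: "
            f"{self.config.threshold_start} -> {self.config.threshold_end}   "
            f"seed: {self.config.seed}",
            "",
            "Fitted weights",
            "-" * 62,
        ]
        for t in TERMS:
            lines.append(f"  {t:<20s} {self.weights.term_weights[t]:8.4f}")
        lines.append(f"  {'w_cp':<20s} {self.weights.w_cp:8.4f}")
        for s in SITES:
            lines.append(
                f"  {'site ' + SITE_LABELS[s]:<20s} {self.weights.site_weights[s]:8.4f}"
            )
        lines.append(f"  {'e_reverse':<20s} {self.weights.e_reverse:8.4f} kcal/mol")
        lines += ["", "Objective (training set)", "-" * 62]
        o = self.objective
        lines.append(
            f"  Z = {o.Z:.4f}   [z_sb-nb {o.z_sb_nb:.3f}, z_bi-nb {o.z_bi_nb:.3f}, "
            f"z_bi-sb {o.z_bi_sb:.3f}, z_nu-nb {o.z_nu_nb:.3f}]"
        )
        if self.valid_objective is not None:
            v = self.valid_objective
            lines.append(f"  validation Z = {v.Z:.4f}")
        return "\n".join(lines)
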