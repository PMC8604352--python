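"""Sliding-window scoring of sequences: binding register and orientation.

Every five-residue window of a sequence is scored in both backbone
orientations.  In the forward (N->C) orientation window positions 1..5 occupy
binding sites -2,-1,0,+1,+2; in the reverse (C->N) orientation the same
window threads the cleft backwards, so positions 1..5 occupy +2,+1,0,-1,-2.
Lower scores are more favorable; the predicted register is the window
attaining the minimum, and the orientation call compares the forward and
reverse minima against a kT = 0.6 kcal/mol ambiguity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AA_INDEX,
    KT,
    SITES,
    PSSM,
    AlphabetError,
    PaladinError,
    WeightSet,
)
from .energetics import PropensityScales, backbone_propensity

logger = logging.getLogger(__name__)


class SequenceError(PaladinError, ValueError):
    pass


class ConfigError(PaladinError, ValueError):
    pass


WINDOW = 5


def sanitize_sequence(seq: str) -> str:
    """Uppercase and strip stop marks ('*') and whitespace."""
    return "".join(seq.split()).replace("*", "").upper()


def _window_is_standard(window: str) -> bool:
    return all(r in AA_INDEX for r in window)


def assign_sites(window: str, orientation: str) -> dict[int, str]:
    """Map binding sites to window residues for the given orientation.

    Forward: positions 1..5 (N->C) occupy sites -2..+2.  Reverse: the window
    threads C->N, so positions 1..5 occupy sites +2..-2; equivalently,
    ``assign_sites(w, "reverse") == assign_sites(w[::-1], "forward")``.
    """
    if len(window) != WINDOW:
        raise SequenceError(f"window must be 5 residues; got {window!r}")
    if orientation == "forward":
        return dict(zip(SITES, window))
    if orientation == "reverse":
        return dict(zip(SITES, window[::-1]))
    raise ConfigError(f"orientation must be 'forward' or 'reverse'; got {orientation!r}")


@dataclass
class FivemerScore:
    """Score of one five-residue window in one orientation.

    ``window`` is written N->C as it appears in the parent sequence;
    ``site_assignment``/``site_contributions`` are keyed by binding site.
    ``total`` = sum of site contributions + w_cp * E_cp + e_reverse (reverse
    orientation only).
    """

    window: str
    start: int
    orientation: str
    site_assignment: dict[int, str]
    site_contributions: dict[int, float]
    e_cp_contribution: float
    total: float

    def site0_position(self) -> int:
        """1-based position in the parent sequence of the site-0 residue."""
        return self.start + 3  # site 0 is the central residue either way


def score_fivemer(
    window: str,
    orientation: str,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    start: int = 0,
) -> FivemerScore:
    """Score one window: sum of per-site PSSM cells plus the window terms.

    Site weights are already folded into the PSSM.  The backbone
    coil-propensity term w_cp * E_cp needs ``scales`` only when w_cp != 0;
    the reverse penalty applies to reverse-orientation windows.
    """
    assignment = assign_sites(window, orientation)
    for res in window:
        if res not in AA_INDEX:
            raise AlphabetError(
                f"window {window!r} contains non-standard residue {res!r}"
            )
    contributions = {s: pssm.score(s, r) for s, r in assignment.items()}
    if weights.w_cp != 0.0:
        if scales is None:
            raise ConfigError(
                "w_cp is nonzero but no propensity scales were supplied"
            )
        e_cp = weights.w_cp * backbone_propensity(window, scales)
    else:
        e_cp = 0.0
    total = sum(contributions.values()) + e_cp
    if orientation == "reverse":
        total += weights.e_reverse
    return FivemerScore(
        window=window,
        start=start,
        orientation=orientation,
        site_assignment=assignment,
        site_contributions=contributions,
        e_cp_contribution=e_cp,
        total=total,
    )


@dataclass
class ScanResult:
    """All admissible (window, orientation) scores of one sequence."""

    seq_id: str
    sequence: str
    scores: list[FivemerScore]
    best_forward: FivemerScore | None = None
    best_reverse: FivemerScore | None = None
    skipped_windows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def best(self) -> FivemerScore | None:
        cands = [s for s in (self.best_forward, self.best_reverse) if s is not None]
        if not cands:
            return None
        # tie-break: lower total, then smaller start, then forward first
        return min(
            cands,
            key=lambda s: (s.total, s.start, 0 if s.orientation == "forward" else 1),
        )


def scan_sequence(
    seq: str,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    seq_id: str = "",
) -> ScanResult:
    """Score every five-mer window of ``seq`` in both orientations.

    Windows containing non-standard residues are skipped with a logged
    warning and excluded from the per-orientation bests.  Ordering of
    ``scores`` is deterministic: by start offset, forward before reverse.
    """
    clean = sanitize_sequence(seq)
    if len(clean) < WINDOW:
        raise SequenceError(
            f"sequence {seq_id or clean!r} shorter than 5 residues after sanitization"
        )
    scores: list[FivemerScore] = []
    skipped: list[tuple[int, str]] = []
    for start in range(len(clean) - WINDOW + 1):
        window = clean[start : start + WINDOW]
        if not _window_is_standard(window):
            bad = next(r for r in window if r not in AA_INDEX)
            skipped.append((start, window))
            logger.warning(
                "skipping window %s at offset %d of %s: non-standard residue %r",
                window, start, seq_id or "<sequence>", bad,
            )
            continue
        for orientation in ("forward", "reverse"):
            scores.append(
                score_fivemer(window, orientation, pssm, weights, scales, start)
            )
    result = ScanResult(seq_id, clean, scores, skipped_windows=skipped)
    for orientation in ("forward", "reverse"):
        cands = [s for s in scores if s.orientation == orientation]
        if cands:
            best = min(cands, key=lambda s: (s.total, s.start))
            ties = [s for s in cands if s.total == best.total]
            if len(ties) > 1:
                logger.info(
                    "register tie in %s (%s): %s",
                    seq_id or "<sequence>", orientation,
                    [s.window for s in ties],
                )
            if orientation == "forward":
                result.best_forward = best
            else:
                result.best_reverse = best
    return result


def predict_register(
    seq: str,
    orientation: str,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    seq_id: str = "",
) -> FivemerScore:
    """Minimum-score window within one orientation (ties: smallest offset)."""
    if orientation not in ("forward", "reverse"):
        raise ConfigError(f"orientation must be forward or reverse; got {orientation!r}")
    result = scan_sequence(seq, pssm, weights, scales, seq_id)
    best = result.best_forward if orientation == "forward" else result.best_reverse
    if best is None:
        raise SequenceError(
            f"no scoreable window in {seq_id or seq!r} (non-standard residues?)"
        )
    return best


@dataclass
class OrientationCall:
    """Orientation prediction with its forward-minus-reverse score gap."""

    call: str  # forward | reverse | ambiguous
    delta: float  # min forward total - min reverse total, kcal/mol
    best_forward: FivemerScore
    best_reverse: FivemerScore


def predict_orientation(
    seq: str,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    ambiguity_threshold: float = KT,
    seq_id: str = "",
) -> OrientationCall:
    """Call the binding orientation from the forward/reverse score minima.

    delta = min forward - min reverse.  Calls forward when delta <
    -threshold, reverse when delta > +threshold, otherwise ambiguous
    (|delta| below kT is not considered resolved).
    """
    result = scan_sequence(seq, pssm, weights, scales, seq_id)
    bf, br = result.best_forward, result.best_reverse
    if bf is None or br is None:
        raise SequenceError(
            f"no scoreable window in {seq_id or seq!r} (non-standard residues?)"
        )
    delta = bf.total - br.total
    if delta < -ambiguity_threshold:
        call = "forward"
    elif delta > ambiguity_threshold:
        call = "reverse"
    else:
        call = "ambiguous"
    return OrientationCall(call=call, delta=delta, best_forward=bf, best_reverse=br)


def score_13mer(
    seq13: str,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
) -> float:
    """Peptide-array score of a 13-mer: forward-only minimum over its 9 windows."""
    clean = sanitize_sequence(seq13)
    if len(clean) != 13:
        raise SequenceError(f"expected a 13-mer; got {len(clean)} residues")
    totals = [
        score_fivemer(clean[i : i + WINDOW], "forward", pssm, weights, scales, i).total
        for i in range(9)
    ]
    return float(min(totals))


def find_reverse_candidates(
    sequences,
    pssm: PSSM,
    weights: WeightSet,
    scales: PropensityScales | None = None,
    margin: float = 3.0,
) -> list[tuple[str, str, float]]:
    """Sequences predicted to bind reverse by more than ``margin`` kcal/mol.

    ``sequences`` is an iterable of (id, sequence) pairs or bare strings.
    Returns (id, sequence, delta) with delta = min reverse - min forward,
    ranked ascending (strongest reverse preference first).
    """
    out: list[tuple[str, str, float]] = []
    for item in sequences:
        seq_id, seq = item if isinstance(item, tuple) else ("", item)
        result = scan_sequence(seq, pssm, weights, scales, seq_id)
        if result.best_forward is None or result.best_reverse is None:
            continue
        delta = result.best_reverse.total - result.best_forward.total
        if delta < -margin:
            out.append((seq_id, result.sequence, delta))
    out.sort(key=lambda t: t[2])
    return out


def normalize_array_prediction(
    scores, low: float = -10.0, high: float = -6.0
) -> np.ndarray:
    """Min-max normalize 13-mer scores to predicted intensities in [0, 1].

    Scores are clamped to [low, high] and mapped linearly so that ``low``
    (strongest predicted binder) -> 1 and ``high`` -> 0.
    """
    if low >= high:
        raise ConfigError(f"low must be < high; got low={low}, high={high}")
    s = np.clip(np.asarray(scores, dtype=float), low, high)
    return (high - s) / (high - low)
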