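import logging

import numpy as np
import pytest

from paladin.core import AMINO_ACIDS, AlphabetError, PSSM, default_weights
from paladin.scanner import (
    ConfigError,
    SequenceError,
    assign_sites,
    find_reverse_candidates,
    normalize_array_prediction,
    predict_orientation,
    predict_register,
    sanitize_sequence,
    scan_sequence,
    score_13mer,
    score_fivemer,
)

from conftest import random_pssm, random_sequence


def brute_force_best(seq, pssm, weights, orientation=None):
    """Independent enumeration: dict-based window sums, no scanner code."""
    table = pssm.to_frame()
    cell = {(site, res): table.loc[lab, res]
            for site, lab in zip((-2, -1, 0, 1, 2), ("-2", "-1", "0", "+1", "+2"))
            for res in AMINO_ACIDS}
    best = None
    for start in range(len(seq) - 4):
        window = seq[start : start + 5]
        for orient in ("forward", "reverse"):
            if orientation and orient != orientation:
                continue
            resid = window if orient == "forward" else window[::-1]
            total = sum(cell[(site, r)] for site, r in zip((-2, -1, 0, 1, 2), resid))
            if orient == "reverse":
                total += weights.e_reverse
            key = (total, start, 0 if orient == "forward" else 1)
            if best is None or key < best[0]:
                best = (key, start, orient, window, total)
    return best[1:]


class TestAssignSites:
    def test_reverse_example_places_hydrophobics_at_inner_sites(self):
        # KTLFI threaded C->N puts I, F, L at sites -2, -1, 0
        assert assign_sites("KTLFI", "reverse") == {
            2: "K", 1: "T", 0: "L", -1: "F", -2: "I"
        }

    def test_forward_example(self):
        assert assign_sites("LLLTG", "forward") == {
            -2: "L", -1: "L", 0: "L", 1: "T", 2: "G"
        }

    @pytest.mark.parametrize("seed", range(10))
    def test_reverse_equals_reversed_forward(self, seed):
        rng = np.random.default_rng(seed)
        w = random_sequence(rng, 5)
        assert assign_sites(w, "reverse") == assign_sites(w[::-1], "forward")

    def test_wrong_length(self):
        with pytest.raises(SequenceError):
            assign_sites("KTLF", "forward")

    def test_unknown_orientation(self):
        with pytest.raises(ConfigError):
            assign_sites("KTLFI", "sideways")


class TestScoreFivemer:
    def test_zero_pssm_scores_zero(self):
        pssm = PSSM(np.zeros((5, 20)))
        w = default_weights()
        assert score_fivemer("KTLFI", "forward", pssm, w).total == 0.0
        assert score_fivemer("KTLFI", "reverse", pssm, w).total == 0.0

    def test_nonstandard_residue_named_in_error(self):
        pssm = PSSM(np.zeros((5, 20)))
        with pytest.raises(AlphabetError, match="X"):
            score_fivemer("KTXFI", "forward", pssm, default_weights())

    @pytest.mark.parametrize("seed", range(20))
    def test_reverse_orientation_identity(self, seed):
        # score(w, reverse) == score(reversed w, forward) + e_reverse, exactly
        rng = np.random.default_rng(seed)
        pssm = random_pssm(rng)
        w = default_weights()
        w.e_reverse = float(rng.uniform(-1, 1))
        window = random_sequence(rng, 5)
        rev = score_fivemer(window, "reverse", pssm, w).total
        fwd = score_fivemer(window[::-1], "forward", pssm, w).total
        assert rev == fwd + w.e_reverse

    def test_constant_pssm_shift_moves_totals_by_5c(self):
        rng = np.random.default_rng(5)
        pssm = random_pssm(rng)
        c = 0.37
        shifted = PSSM(pssm.scores + c)
        w = default_weights()
        window = "KTLFI"
        for orientation in ("forward", "reverse"):
            base = score_fivemer(window, orientation, pssm, w).total
            moved = score_fivemer(window, orientation, shifted, w).total
            assert moved == pytest.approx(base + 5 * c, abs=1e-9)

    def test_total_decomposition(self):
        rng = np.random.default_rng(6)
        pssm = random_pssm(rng)
        s = score_fivemer("WYKDE", "reverse", pssm, default_weights())
        assert s.total == pytest.approx(
            sum(s.site_contributions.values()) + s.e_cp_contribution, abs=1e-12
        )
        assert sorted(s.site_assignment) == [-2, -1, 0, 1, 2]


class TestScan:
    def test_window_count(self, truth, weights):
        pssm, _ = truth
        result = scan_sequence("GKTLFIS", pssm, weights)
        assert len(result.scores) == 6  # 3 windows x 2 orientations

    def test_sanitization(self):
        assert sanitize_sequence(" gktl fis* ") == "GKTLFIS"

    def test_too_short_rejected(self, truth, weights):
        pssm, _ = truth
        with pytest.raises(SequenceError):
            scan_sequence("GKTL", pssm, weights)

    def test_nonstandard_windows_skipped_with_warning(self, truth, weights, caplog):
        pssm, _ = truth
        with caplog.at_level(logging.WARNING):
            result = scan_sequence("GKTLFXSLIVMK", pssm, weights)
        # windows overlapping the X are absent; the rest are scored
        starts = {s.start for s in result.scores}
        assert starts == {0, 6, 7}
        assert len(result.skipped_windows) == 5
        assert "non-standard" in caplog.text

    @pytest.mark.parametrize("seed", range(15))
    def test_bests_match_brute_force(self, seed, weights):
        rng = np.random.default_rng(seed)
        pssm = random_pssm(rng)
        seq = random_sequence(rng, 12)
        result = scan_sequence(seq, pssm, weights)
        start, orient, window, total = brute_force_best(seq, pssm, weights)
        assert result.best.start == start
        assert result.best.orientation == orient
        assert result.best.total == pytest.approx(total, abs=1e-9)


class TestPredictRegister:
    def test_planted_site0_preference(self):
        # a PSSM favoring W at site 0 only must center the W
        scores = np.zeros((5, 20))
        scores[2, AMINO_ACIDS.index("W")] = -5.0
        pssm = PSSM(scores)
        best = predict_register("AAAWAAA", "forward", pssm, default_weights())
        assert best.window == "AAWAA"  # W at the central position = site 0
        assert best.site_assignment[0] == "W"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_orientation_restricted_brute_force(self, seed, weights):
        rng = np.random.default_rng(100 + seed)
        pssm = random_pssm(rng)
        seq = random_sequence(rng, 15)
        for orientation in ("forward", "reverse"):
            best = predict_register(seq, orientation, pssm, weights)
            start, _, window, total = brute_force_best(seq, pssm, weights, orientation)
            assert (best.start, best.window) == (start, window)
            assert best.total == pytest.approx(total, abs=1e-9)


class TestPredictOrientation:
    def test_palindrome_is_ambiguous(self, weights):
        rng = np.random.default_rng(8)
        pssm = random_pssm(rng)
        call = predict_orientation("KLVLK", pssm, weights)
        assert call.delta == 0.0
        assert call.call == "ambiguous"

    def test_threshold_splits_calls(self):
        scores = np.zeros((5, 20))
        # favor I at site -2: reverse threading of a window ending in I wins
        scores[0, AMINO_ACIDS.index("I")] = -3.0
        pssm = PSSM(scores)
        call = predict_orientation("KTLFI", pssm, default_weights())
        assert call.call == "reverse"
        assert call.delta == pytest.approx(3.0)
        narrow = predict_orientation("KTLFI", pssm, default_weights(),
                                     ambiguity_threshold=4.0)
        assert narrow.call == "ambiguous"


class TestScore13mer:
    def test_zero_pssm(self):
        pssm = PSSM(np.zeros((5, 20)))
        assert score_13mer("G" * 13, pssm, default_weights()) == 0.0

    def test_homopolymer_equals_single_window(self, truth, weights):
        pssm, _ = truth
        expected = score_fivemer("LLLLL", "forward", pssm, weights).total
        assert score_13mer("L" * 13, pssm, weights) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_min(self, seed, weights):
        rng = np.random.default_rng(200 + seed)
        pssm = random_pssm(rng)
        seq = random_sequence(rng, 13)
        expected = min(
            score_fivemer(seq[i : i + 5], "forward", pssm, weights).total
            for i in range(9)
        )
        assert score_13mer(seq, pssm, weights) == pytest.approx(expected)

    def test_wrong_length(self, truth, weights):
        pssm, _ = truth
        with pytest.raises(SequenceError):
            score_13mer("LLLLL", pssm, weights)


class TestReverseCandidates:
    def test_huge_reverse_penalty_empties_selection(self, truth):
        pssm, _ = truth
        w = default_weights()
        w.e_reverse = 1e6
        seqs = [("a", "GKTLFIS"), ("b", "LLKWYSA")]
        assert find_reverse_candidates(seqs, pssm, w) == []

    def test_membership_matches_brute_force(self, weights):
        rng = np.random.default_rng(9)
        pssm = random_pssm(rng)
        seqs = [(f"s{i}", random_sequence(rng, 10)) for i in range(30)]
        got = {sid for sid, _, _ in find_reverse_candidates(seqs, pssm, weights,
                                                            margin=1.0)}
        expected = set()
        for sid, seq in seqs:
            _, _, _, f = brute_force_best(seq, pssm, weights, "forward")
            _, _, _, r = brute_force_best(seq, pssm, weights, "reverse")
            if r - f < -1.0:
                expected.add(sid)
        assert got == expected

    def test_ranked_ascending(self, weights):
        rng = np.random.default_rng(10)
        pssm = random_pssm(rng)
        seqs = [(f"s{i}", random_sequence(rng, 10)) for i in range(40)]
        deltas = [d for _, _, d in find_reverse_candidates(seqs, pssm, weights,
                                                           margin=0.5)]
        assert deltas == sorted(deltas)


class TestNormalization:
    @pytest.mark.parametrize(
        "score, expected",
        [(-10.0, 1.0), (-6.0, 0.0), (-8.0, 0.5), (-12.0, 1.0), (0.0, 0.0)],
    )
    def test_minmax_mapping(self, score, expected):
        assert normalize_array_prediction([score])[0] == pytest.approx(expected)

    def test_bad_thresholds(self):
        with pytest.raises(ConfigError):
            normalize_array_prediction([-8.0], low=-6.0, high=-10.0)
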