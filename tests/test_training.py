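import logging
import math

import numpy as np
import pytest

from paladin.core import SITES, TERMS, WeightSet, default_weights
from paladin.training import (
    CLASSES,
    ObjectiveBreakdown,
    PeptideArrayModel,
    PeptideArrayRecord,
    TrainingConfig,
    TrainingError,
    class_zscore,
    combined_objective,
    monte_carlo_search,
    split_dataset,
)


def uniform_start():
    return WeightSet(
        term_weights={t: 0.5 for t in TERMS},
        w_cp=0.0,
        site_weights=dict(default_weights().site_weights),
        e_reverse=0.0,
    )


class TestClassZscore:
    def test_identical_lists(self):
        assert class_zscore([1.0, 2, 3], [1.0, 2, 3]) == 0.0

    def test_unit_separation(self):
        # means differ by 1, both sds 1 -> |z| = 1
        a = [0.0, 1.0, 2.0]
        b = [1.0, 2.0, 3.0]
        assert class_zscore(a, b) == pytest.approx(-1.0)
        assert class_zscore(b, a) == pytest.approx(1.0)

    def test_one_degenerate_class(self):
        # mu difference 2, sd_a = 0, sd_b = 2 -> 2 / sqrt(2)
        a = [4.0, 4.0, 4.0]
        b = [0.0, 2.0, 4.0]  # sd = 2
        assert class_zscore(a, b) == pytest.approx(2.0 / math.sqrt(2.0))

    def test_degenerate_zero_variance(self):
        assert class_zscore([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert class_zscore([2.0, 2.0], [1.0, 1.0]) == math.inf
        assert class_zscore([0.0, 0.0], [1.0, 1.0]) == -math.inf

    def test_too_few_scores(self):
        with pytest.raises(TrainingError):
            class_zscore([1.0], [1.0, 2.0])


class TestCombinedObjective:
    def test_weighted_sum(self):
        assert ObjectiveBreakdown(1, 1, 1, 1).Z == pytest.approx(7.5)
        assert ObjectiveBreakdown(2, 1, 0, 0).Z == pytest.approx(10.0)

    def test_no_separation_gives_small_z(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(size=400)
        by_class = {
            "strong": pool[:30], "binder": pool[30:120],
            "neutral": pool[120:200], "nonbinder": pool[200:],
        }
        assert abs(combined_objective(by_class).Z) < 1.5

    def test_sign_convention_rewards_low_binder_scores(self):
        rng = np.random.default_rng(1)
        by_class = {
            "strong": rng.normal(-8, 1, 50),
            "binder": rng.normal(-6, 1, 50),
            "neutral": rng.normal(-4, 1, 50),
            "nonbinder": rng.normal(-2, 1, 50),
        }
        breakdown = combined_objective(by_class)
        assert breakdown.z_sb_nb > 3
        assert breakdown.Z > 10

    def test_shift_invariance_and_negation_flip(self):
        rng = np.random.default_rng(2)
        by_class = {c: rng.normal(i, 1, 40) for i, c in enumerate(CLASSES)}
        base = combined_objective(by_class)
        shifted = combined_objective({c: v + 11.3 for c, v in by_class.items()})
        assert shifted.Z == pytest.approx(base.Z, abs=1e-9)
        negated = combined_objective({c: -v for c, v in by_class.items()})
        assert negated.Z == pytest.approx(-base.Z, abs=1e-9)
        assert negated.z_sb_nb == pytest.approx(-base.z_sb_nb, abs=1e-9)

    def test_missing_class_rejected(self):
        with pytest.raises(TrainingError, match="neutral"):
            combined_objective({"strong": [1, 2], "binder": [1, 2],
                                "nonbinder": [1, 2]})

    def test_saturated_components_capped(self, caplog):
        by_class = {
            "strong": [-9.0, -9.0], "binder": [-6.0, -6.0],
            "neutral": [-4.0, -4.0], "nonbinder": [-2.0, -2.0],
        }
        with caplog.at_level(logging.WARNING):
            breakdown = combined_objective(by_class)
        assert breakdown.z_sb_nb == 10.0
        assert math.isfinite(breakdown.Z)


class TestSplit:
    def test_counts_and_determinism(self, array_fixture):
        records, _ = array_fixture
        train, valid = split_dataset(records, 0.8, seed=5)
        assert len(train) + len(valid) == len(records)
        assert abs(len(train) - 0.8 * len(records)) <= len(CLASSES)
        train2, valid2 = split_dataset(records, 0.8, seed=5)
        assert train == train2 and valid == valid2
        assert split_dataset(records, 0.8, seed=6)[0] != train

    def test_disjoint_and_exhaustive(self, array_fixture):
        records, _ = array_fixture
        train, valid = split_dataset(records, 0.8, seed=1)
        ids = lambda recs: sorted(id(r) for r in recs)
        assert set(ids(train)).isdisjoint(ids(valid))
        assert sorted(ids(train) + ids(valid)) == ids(records)

    def test_stratified_within_one_record(self, array_fixture):
        records, _ = array_fixture
        train, _ = split_dataset(records, 0.8, seed=2)
        for label in CLASSES:
            n_class = sum(r.label == label for r in records)
            n_train = sum(r.label == label for r in train)
            assert abs(n_train - 0.8 * n_class) <= 1.0

    def test_too_few_records(self):
        recs = [PeptideArrayRecord("L" * 13, "binder")] * 5
        with pytest.raises(TrainingError):
            split_dataset(recs, 0.8, seed=0)


class TestRecordValidation:
    def test_rejects_wrong_length(self):
        with pytest.raises(TrainingError, match="13-mer"):
            PeptideArrayRecord("LLLLL", "binder")

    def test_rejects_unknown_label(self):
        with pytest.raises(TrainingError, match="label"):
            PeptideArrayRecord("L" * 13, "super-binder")

    def test_rejects_nonstandard_residue(self):
        with pytest.raises(TrainingError, match="non-standard"):
            PeptideArrayRecord("LLLLLZLLLLLLL", "binder")


class TestMonteCarlo:
    def test_zero_steps_returns_initial(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        config = TrainingConfig(steps=0, seed=0)
        start = uniform_start()
        best, trace = monte_carlo_search(terms, records, config, initial=start)
        assert best.term_weights == start.term_weights
        assert len(trace) == 1

    def test_greedy_trace_is_nondecreasing(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        config = TrainingConfig(steps=300, threshold_start=0.0,
                                threshold_end=0.0, seed=1)
        _, trace = monte_carlo_search(terms, records, config,
                                      initial=uniform_start())
        assert np.all(np.diff(trace) >= 0)

    def test_best_ever_never_below_initial(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        from paladin.training import _ArrayDesign

        design = _ArrayDesign(records, terms)
        for seed in range(3):
            config = TrainingConfig(steps=200, seed=seed)
            start = uniform_start()
            best, trace = monte_carlo_search(terms, records, config,
                                             initial=start, design=design)
            assert design.objective(best).Z >= trace[0]

    def test_reproducible_under_seed(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        config = TrainingConfig(steps=400, seed=9)
        b1, t1 = monte_carlo_search(terms, records, config, initial=uniform_start())
        b2, t2 = monte_carlo_search(terms, records, config, initial=uniform_start())
        assert b1.term_weights == b2.term_weights
        np.testing.assert_array_equal(t1, t2)

    def test_planted_truth_recovery(self, truth, array_fixture):
        # the array was generated by the default weights; a short search from
        # uniform weights must recover >= 95% of the truth-weight objective
        _, terms = truth
        records, _ = array_fixture
        from paladin.training import _ArrayDesign

        design = _ArrayDesign(records, terms)
        truth_z = design.objective(default_weights()).Z
        config = TrainingConfig(steps=10_000, seed=3)
        best, _ = monte_carlo_search(terms, records, config,
                                     initial=uniform_start(), design=design)
        assert design.objective(best).Z >= 0.95 * truth_z

    def test_inert_terms_have_minimal_effect(self, truth, array_fixture, caplog):
        # training only the strain / side-chain-propensity weights barely
        # moves Z on data generated with those weights at zero (soft check)
        _, terms = truth
        records, _ = array_fixture
        from paladin.training import _ArrayDesign

        design = _ArrayDesign(records, terms)
        start = default_weights()
        z0 = design.objective(start).Z
        config = TrainingConfig(steps=2_000, seed=4,
                                trainable=("strain", "sc_propensity"))
        best, _ = monte_carlo_search(terms, records, config, initial=start,
                                     design=design)
        z1 = design.objective(best).Z
        rel = (z1 - z0) / abs(z0)
        logging.getLogger(__name__).info(
            "strain/sc-propensity-only training: Z %.3f -> %.3f (+%.1f%%)",
            z0, z1, 100 * rel,
        )
        assert 0.0 <= rel < 0.25


class TestModelResults:
    def test_fit_returns_results_with_summary(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        model = PeptideArrayModel(records, terms)
        results = model.fit(steps=500, seed=0)
        assert results.objective.Z >= results.z_trace[0]
        text = results.summary()
        assert "desolv_substrate" in text and "Z =" in text
        assert results.pssm().scores.shape == (5, 20)

    def test_from_dataframe_roundtrip(self, truth, array_fixture):
        import pandas as pd

        _, terms = truth
        records, _ = array_fixture
        df = pd.DataFrame(
            [{"sequence": r.sequence, "label": r.label} for r in records]
        )
        model = PeptideArrayModel.from_dataframe(df, terms)
        assert model.records == [
            PeptideArrayRecord(r.sequence, r.label) for r in records
        ]

    def test_validation_auc_exceeds_chance(self, truth, array_fixture):
        _, terms = truth
        records, _ = array_fixture
        results = PeptideArrayModel(records, terms).fit(steps=2_000, seed=1)
        assert results.roc_auc(positive=("strong", "binder")) > 0.6
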