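"""Feature extraction, cell-count calibration and SVM probabilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isvs import (
    CellTable,
    ParameterError,
    SimParams,
    build_cell_table,
    build_cohort,
    empirical_classify,
    evaluate_classifiers,
    extract_features,
    likelihood_ratio,
    run_isvs,
    sample_spectra,
    summarize_accuracy,
    train_model,
)
from isvs.classify import LR_CAP, FEATURE_COLUMNS
from isvs.fixtures import cohort_from_genotypes, single_homozygote, uniform_spectrum


def toy_features(rows):
    """rows: iterable of (sim_id, x, y, true_class)."""
    return pd.DataFrame(
        [(s, f"v{i}", x, y, c) for i, (s, x, y, c) in enumerate(rows)],
        columns=FEATURE_COLUMNS,
    )


class TestExtractFeatures:
    def test_single_homozygote_is_its_own_trans_partner(self, rng):
        cohort = single_homozygote()
        feats = extract_features(cohort, run_isvs(cohort, rng))
        assert len(feats) == 1
        assert (feats.iloc[0].x, feats.iloc[0].y) == (1, 1)

    def test_in_cis_co_occurrence_does_not_count(self, rng):
        # patient 1 carries P1 and P2 on the same (maternal) haplotype
        spectrum = uniform_spectrum(2, 0)
        cohort = cohort_from_genotypes([["1|0", "0|1"], ["1|0", "1|0"]], spectrum)
        feats = extract_features(cohort, run_isvs(cohort, rng)).set_index("variant_id")
        assert feats.loc["P1", "x"] == 2  # both patients carry P1
        assert feats.loc["P1", "y"] == 1  # only the compound het is in trans
        assert feats.loc["P2", "x"] == 2
        assert feats.loc["P2", "y"] == 1

    def test_y_never_exceeds_x_on_simulated_runs(self):
        rng = np.random.default_rng(8)
        params = SimParams(cohort_size=500)
        for _ in range(10):
            cohort = build_cohort(params, sample_spectra(params, rng), rng)
            result = run_isvs(cohort, rng)
            if result.degenerate:
                continue
            feats = extract_features(cohort, result)
            assert (feats.y <= feats.x).all()
            assert (feats.x >= 1).all()
            # feature rows exist exactly for detected variants
            assert len(feats) == int(result.detected.sum())


class TestCellTable:
    def test_cumulative_rule_spec_example(self):
        table = CellTable.from_observed({(3, 3): (5, 0), (3, 2): (4, 0), (3, 1): (2, 1)})
        assert table.cumulative(3, 3) == (9, 0)
        assert table.cumulative(3, 1) == (2, 1)

    def test_impure_cell_keeps_observed_counts(self):
        table = CellTable.from_observed({(4, 2): (10, 3), (4, 1): (7, 0)})
        assert table.cumulative(4, 2) == (10, 3)

    def test_aggregation_skips_empty_cells_and_floors_at_zero(self):
        table = CellTable.from_observed({(5, 4): (2, 0), (5, 1): (3, 0), (5, 0): (1, 0)})
        assert table.cumulative(5, 4) == (6, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.dictionaries(
            st.tuples(st.integers(1, 4), st.integers(0, 4)),
            st.tuples(st.integers(0, 20), st.integers(0, 5)),
            min_size=1,
        )
    )
    def test_cumulative_invariants(self, observed):
        observed = {(x, y): c for (x, y), c in observed.items() if y <= x}
        table = CellTable.from_observed(observed)
        for (x, y), (n_pat, n_nonpat) in observed.items():
            cum_pat, cum_nonpat = table.cumulative(x, y)
            assert cum_pat >= n_pat
            if n_nonpat > 0:
                assert (cum_pat, cum_nonpat) == (n_pat, n_nonpat)
            else:
                assert cum_nonpat == 0
                # independent oracle: walk down y, stop at first impure cell
                expected = n_pat
                for y2 in range(y - 1, -1, -1):
                    if (x, y2) not in observed:
                        continue
                    if observed[(x, y2)][1] > 0:
                        break
                    expected += observed[(x, y2)][0]
                assert cum_pat == expected

    def test_build_from_feature_rows(self):
        feats = toy_features(
            [(0, 2, 2, "pathogenic"), (0, 2, 2, "pathogenic"), (1, 2, 2, "non-pathogenic"),
             (1, 3, 0, "non-pathogenic")]
        )
        table = build_cell_table(feats)
        assert table.observed(2, 2) == (2, 1)
        assert table.observed(3, 0) == (0, 1)

    def test_frame_round_trip(self):
        table = CellTable.from_observed({(3, 3): (5, 0), (3, 1): (2, 1)})
        back = CellTable.from_frame(table.to_frame())
        assert back.cells == table.cells


class TestEmpiricalClassify:
    def test_published_cell_arithmetic(self):
        table = CellTable.from_observed({(2, 2): (4709, 57)})
        label, prob = empirical_classify(table, 2, 2, confidence=0.95)
        assert prob == pytest.approx(4709 / 4766, abs=1e-12)
        assert label == "pathogenic"

    def test_pure_benign_cell(self):
        table = CellTable.from_observed({(3, 0): (0, 5)})
        label, prob = empirical_classify(table, 3, 0, confidence=0.5)
        assert (label, prob) == ("non-pathogenic", 0.0)

    def test_unseen_cell_is_conservative(self):
        table = CellTable.from_observed({(1, 1): (3, 1)})
        label, prob = empirical_classify(table, 9, 9, confidence=0.5)
        assert label == "non-pathogenic" and prob is None

    def test_confidence_domain(self):
        with pytest.raises(ParameterError):
            empirical_classify(CellTable(), 1, 1, confidence=0.4)


class TestModel:
    def test_separable_toy_problem(self):
        feats = toy_features(
            [(i % 5, 1, 0, "non-pathogenic") for i in range(50)]
            + [(i % 5, 10, 10, "pathogenic") for i in range(50)]
        )
        model = train_model(feats)
        assert model.predict_proba(10, 10)[0] > 0.99
        assert model.predict_proba(1, 0)[0] < 0.01

    def test_single_class_training_error(self):
        feats = toy_features([(0, 3, 3, "pathogenic")] * 10)
        with pytest.raises(ParameterError):
            train_model(feats)

    def test_same_data_gives_identical_predictions(self, small_experiment):
        f = small_experiment.features
        m1 = train_model(f)
        m2 = train_model(f)
        grid = np.array([[x, y] for x in range(1, 20) for y in range(0, x + 1)])
        np.testing.assert_array_equal(
            m1.predict_proba(grid[:, 0], grid[:, 1]), m2.predict_proba(grid[:, 0], grid[:, 1])
        )

    def test_likelihood_ratio_formula_and_cap(self):
        class Stub:
            lr_cap = LR_CAP

            def __init__(self, p):
                self._p = p

            def predict_proba(self, x, y):
                return np.atleast_1d(self._p)

        assert likelihood_ratio(Stub(0.5), 1, 1) == pytest.approx(1.0)
        assert likelihood_ratio(Stub(1.0), 1, 1) == LR_CAP
        assert likelihood_ratio(Stub(1 - 1e-12), 1, 1) == LR_CAP

    def test_lr_increases_with_model_probability(self, small_experiment):
        model = train_model(small_experiment.features)
        pts = [(1, 0), (1, 1), (2, 2), (5, 4), (10, 10)]
        probs = [model.predict_proba(x, y)[0] for x, y in pts]
        lrs = [likelihood_ratio(model, x, y) for x, y in pts]
        order = np.argsort(probs)
        assert (np.diff(np.array(lrs)[order]) >= 0).all()
        assert all(0 < lr <= LR_CAP for lr in lrs)


class TestEvaluateClassifiers:
    def test_fold_confusion_arithmetic(self):
        # every sim: two pathogenic rows in a 2/3-pure cell, one benign row
        rows = []
        for s in range(4):
            rows += [(s, 5, 5, "pathogenic"), (s, 5, 5, "pathogenic"),
                     (s, 5, 5, "non-pathogenic"), (s, 7, 0, "non-pathogenic")]
        report = evaluate_classifiers(toy_features(rows), confidences=(0.5, 0.95), folds=2)
        emp = report[report.classifier == "empirical"].set_index(["confidence", "fold"])
        # at 0.5 the 2/3-pure cell is called pathogenic: benign row there is wrong
        assert emp.loc[(0.5, 0)].accuracy == pytest.approx(3 / 4)
        # at 0.95 it flips: both pathogenic rows wrong, benign rows right
        assert emp.loc[(0.95, 0)].accuracy == pytest.approx(2 / 4)

    def test_requires_enough_simulations(self):
        feats = toy_features([(0, 1, 1, "pathogenic"), (0, 2, 0, "non-pathogenic")])
        with pytest.raises(ParameterError):
            evaluate_classifiers(feats, folds=5)

    def test_folds_partition_simulations(self, small_experiment):
        report = evaluate_classifiers(small_experiment.features, folds=5)
        n_test_total = report[report.classifier == "empirical"].groupby("fold").n_test.first().sum()
        assert n_test_total == len(small_experiment.features)

    def test_threshold_monotonicity_on_default_experiment(self, small_experiment):
        acc = summarize_accuracy(
            evaluate_classifiers(small_experiment.features, confidences=(0.5, 0.95), folds=5)
        ).set_index(["classifier", "confidence"])
        assert acc.loc[("empirical", 0.5), "accuracy"] >= acc.loc[("empirical", 0.95), "accuracy"]
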