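"""Split semantics, confusion metrics, leakage accounting and k-fold mechanics."""

import itertools

import numpy as np
import pytest

from ibistress import (
    CNNConfig,
    ConfusionCounts,
    ImageDataset,
    SplitSpec,
    default_test_triples,
    encode_cohort,
    evaluate,
    kfold_cv,
    leakage_report,
    make_split,
    metrics_from_counts,
    run_regime,
)


def toy_dataset(n_per_class=500, n_subjects=1, window=28):
    """Dataset of blank images with balanced labels and sequential starts."""
    images, labels, subjects, starts = [], [], [], []
    for s in range(n_subjects):
        for cls in (0, 1):
            for i in range(n_per_class):
                images.append(np.zeros((window, window), np.float32))
                labels.append(cls)
                subjects.append(f"S{s}")
                starts.append(i)
    return ImageDataset(
        images=np.stack(images),
        labels=np.asarray(labels, np.int8),
        subjects=np.asarray(subjects),
        starts=np.asarray(starts, np.int64),
        domain="spatial",
        window=window,
    )


class TestMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(tp=96, fn=4, tn=98, fp=2)
        m = metrics_from_counts(c)
        assert m["sensitivity"] == pytest.approx(0.96)
        assert m["specificity"] == pytest.approx(0.98)
        assert m["accuracy"] == pytest.approx(194 / 200)
        assert m["precision"] == pytest.approx(96 / 98)

    def test_all_correct_gives_ones(self):
        y = np.array([0, 1, 1, 0, 1])
        counts, m = evaluate(y, y)
        assert counts.fp == counts.fn == 0
        for k in ("accuracy", "sensitivity", "specificity", "precision"):
            assert m[k] == 1.0

    def test_exhaustive_tables_match_independent_formulas(self):
        """Every confusion table with total <= 20 against a brute-force re-derivation."""
        for tp, tn, fp, fn in itertools.product(range(21), repeat=4):
            if not 0 < tp + tn + fp + fn <= 20:
                continue
            # reconstruct label/prediction vectors and run the full path
            y = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            p = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            counts, m = evaluate(np.array(y), np.array(p))
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)
            # independent formula evaluation
            def safe(n, d):
                return n / d if d else None
            for name, want in (
                ("accuracy", safe(tp + tn, tp + tn + fp + fn)),
                ("sensitivity", safe(tp, fn + tp)),
                ("specificity", safe(tn, tn + fp)),
                ("precision", safe(tp, tp + fp)),
            ):
                if want is None:
                    assert np.isnan(m[name]) and name in m["undefined"]
                else:
                    assert m[name] == want

    def test_agrees_with_sklearn_on_random_vectors(self):
        from sklearn.metrics import accuracy_score, precision_score, recall_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 300)
        p = rng.integers(0, 2, 300)
        _, m = evaluate(y, p)
        assert m["accuracy"] == pytest.approx(accuracy_score(y, p))
        assert m["sensitivity"] == pytest.approx(recall_score(y, p))
        assert m["precision"] == pytest.approx(precision_score(y, p))

    def test_undefined_ratio_is_nan_with_flag(self):
        y = np.zeros(10)
        p = np.zeros(10)
        _, m = evaluate(y, p)
        assert np.isnan(m["sensitivity"]) and "sensitivity" in m["undefined"]
        assert np.isnan(m["precision"]) and "precision" in m["undefined"]
        assert m["specificity"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(3), np.zeros(4))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestSplits:
    def test_person_specific_70_15_15(self):
        ds = toy_dataset(n_per_class=500)
        sp = make_split(ds, "person_specific", subject="S0", seed=1)
        assert (sp.train.size, sp.val.size, sp.test.size) == (700, 150, 150)

    def test_floor_rounding_remainder_goes_to_training(self):
        ds = toy_dataset(n_per_class=101)  # 15% of 101 = 15.15 -> 15 per class
        sp = make_split(ds, "person_specific", subject="S0", seed=1)
        assert sp.val.size == 30 and sp.test.size == 30
        assert sp.train.size == 202 - 60

    def test_person_specific_is_stratified(self):
        ds = toy_dataset(n_per_class=200)
        sp = make_split(ds, "person_specific", subject="S0", seed=3)
        for part in (sp.train, sp.val, sp.test):
            counts = np.bincount(ds.labels[part], minlength=2)
            assert counts[0] == counts[1]

    def test_generic_holds_out_whole_subjects(self):
        ds = toy_dataset(n_per_class=40, n_subjects=6)
        test_subjects = ["S3", "S4", "S5"]
        sp = make_split(ds, "generic", test_subjects=test_subjects, seed=0)
        assert set(ds.subjects[sp.test]) == set(test_subjects)
        for part in (sp.train, sp.val):
            assert not set(ds.subjects[part]) & set(test_subjects)
        assert sp.test.size == 3 * 80

    def test_calibrated_moves_exact_fraction_per_subject(self):
        ds = toy_dataset(n_per_class=250, n_subjects=2)  # S1 test: 500 images
        sp = make_split(ds, "calibrated_generic", test_subjects=["S1"], seed=0)
        assert sp.calibration.size == 100  # floor(0.2 * 250) per class
        assert sp.test.size == 400
        assert set(sp.calibration.tolist()) <= set(sp.train.tolist())
        # calibration images are gone from test
        assert not set(sp.calibration.tolist()) & set(sp.test.tolist())
        # exactly 50 per class
        counts = np.bincount(ds.labels[sp.calibration], minlength=2)
        assert counts.tolist() == [50, 50]

    def test_generic_leakage_report_is_clean(self):
        ds = toy_dataset(n_per_class=50, n_subjects=4)
        sp = make_split(ds, "generic", test_subjects=["S3"], seed=0)
        rep = leakage_report(ds, sp)
        assert rep["n_overlapping_test"] == 0
        assert rep["n_exact_shared"] == 0

    def test_person_specific_random_split_overlaps_and_exclusion_removes_it(self):
        ds = toy_dataset(n_per_class=300)
        sp = make_split(ds, "person_specific", subject="S0", seed=2)
        assert leakage_report(ds, sp)["n_overlapping_test"] > 0
        sp2 = make_split(ds, "person_specific", subject="S0", seed=2, exclude_overlap=True)
        assert leakage_report(ds, sp2)["n_overlapping_test"] == 0
        assert sp2.train.size < sp.train.size

    def test_chronological_mode_orders_by_start(self):
        ds = toy_dataset(n_per_class=100)
        sp = make_split(ds, "person_specific", subject="S0", mode="chronological", seed=0)
        for cls in (0, 1):
            tr = sp.train[ds.labels[sp.train] == cls]
            te = sp.test[ds.labels[sp.test] == cls]
            assert ds.starts[tr].max() < ds.starts[te].min()

    def test_disjointness_enforced(self):
        idx = np.arange(10, dtype=np.intp)
        with pytest.raises(ValueError, match="disjoint"):
            SplitSpec("generic", idx[:5], idx[4:6], idx[6:])

    def test_missing_subject_errors_name_the_subject(self):
        ds = toy_dataset(n_per_class=10, n_subjects=2)
        with pytest.raises(ValueError, match="S9"):
            make_split(ds, "generic", test_subjects=["S9"], seed=0)

    def test_single_class_subject_rejected(self):
        ds = toy_dataset(n_per_class=10, n_subjects=2)
        mask = ~((ds.subjects == "S1") & (ds.labels == 1))
        broken = ImageDataset(
            ds.images[mask], ds.labels[mask], ds.subjects[mask], ds.starts[mask], "spatial"
        )
        with pytest.raises(ValueError, match="S1"):
            make_split(broken, "generic", test_subjects=["S1"], seed=0)


class TestTriples:
    def test_wesad_ids_use_paper_groups(self):
        ids = [f"S{i}" for i in range(2, 18) if i != 12]
        triples = default_test_triples(ids)
        assert triples[2] == ("S8", "S9", "S10")
        assert len(triples) == 5
        covered = {s for t in triples for s in t}
        assert covered == set(ids)

    def test_other_ids_fall_back_to_contiguous(self):
        triples = default_test_triples([f"S{i}" for i in range(9)])
        assert triples == [("S0", "S1", "S2"), ("S3", "S4", "S5"), ("S6", "S7", "S8")]


class TestKFold:
    def test_partition_each_image_validated_once(self):
        ds = toy_dataset(n_per_class=50)
        seen = []

        def fn(x_tr, y_tr, x_va):
            seen.append(x_va.shape[0])
            return np.zeros(x_va.shape[0])

        out = kfold_cv(ds.images, ds.labels, CNNConfig(seed=0, epochs=1), k=5, classifier_fn=fn)
        assert seen == [20] * 5
        assert out["fold_sizes"] == [20] * 5

    def test_fold_aggregate_equals_pooled_accuracy_for_deterministic_classifier(self):
        rng = np.random.default_rng(6)
        images = rng.random((80, 28, 28)).astype(np.float32)
        labels = (images.mean(axis=(1, 2)) > 0.5).astype(np.int8)
        if np.unique(labels).size < 2 or min(np.bincount(labels)) < 5:
            labels[:40] = 0
            labels[40:] = 1

        def threshold_classifier(x_tr, y_tr, x_va):
            return (x_va.mean(axis=(1, 2)) > 0.501).astype(int)

        out = kfold_cv(images, labels, CNNConfig(seed=1, epochs=1), k=5,
                       classifier_fn=threshold_classifier)
        weighted = np.average(out["fold_accuracies"], weights=out["fold_sizes"])
        assert out["pooled_accuracy"] == pytest.approx(weighted)

    def test_k_below_two_rejected(self):
        ds = toy_dataset(n_per_class=10)
        with pytest.raises(ValueError):
            kfold_cv(ds.images, ds.labels, CNNConfig(seed=0, epochs=1), k=1)

    def test_too_few_per_class_rejected(self):
        ds = toy_dataset(n_per_class=3)
        with pytest.raises(ValueError):
            kfold_cv(ds.images, ds.labels, CNNConfig(seed=0, epochs=1), k=5)


class TestRunRegime:
    def test_report_metrics_recompute_from_counts(self, tiny_spatial):
        ds, _ = tiny_spatial
        cfg = CNNConfig(epochs=1, seed=2)
        rep = run_regime(ds, "person_specific", cfg, subject="S0", seed=2)
        m = metrics_from_counts(rep.counts)
        assert rep.test_accuracy == m["accuracy"]
        for name in ("sensitivity", "specificity", "precision"):
            got = getattr(rep, name)
            want = m[name]
            assert (np.isnan(got) and np.isnan(want)) or got == want
        assert rep.counts.total == rep.n_test

    def test_same_seed_reports_identical(self, tiny_spatial):
        ds, _ = tiny_spatial
        cfg = CNNConfig(epochs=1, seed=7)
        a = run_regime(ds, "generic", cfg, test_subjects=["S1"], seed=7)
        b = run_regime(ds, "generic", cfg, test_subjects=["S1"], seed=7)
        assert a == b

    def test_row_formatting_rounds_to_one_decimal(self, tiny_spatial):
        ds, _ = tiny_spatial
        cfg = CNNConfig(epochs=1, seed=2)
        rep = run_regime(ds, "person_specific", cfg, subject="S0", seed=2)
        row = rep.to_row()
        for key in ("Train %", "Valid %", "Test %"):
            assert row[key] == round(row[key], 1)
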