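"""Selection, boosted-tree classification, voting and record prediction."""

import numpy as np
import pandas as pd
import pytest

from pcgpah.fusion_classify import (
    BoostConfig,
    fit_selection,
    importance_select,
    majority_vote,
    split_records,
    train_classifier,
    variance_filter,
    vote_record,
)


def _separable_table(n_per_class=100, n_noise=5, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, label in enumerate(("Normal", "CHD", "CHD-PAH")):
        x = rng.normal(loc=3.0 * k, scale=0.5, size=(n_per_class, 2))
        noise = rng.normal(size=(n_per_class, n_noise))
        rows.append(np.hstack([x, noise]))
        labels += [label] * n_per_class
    cols = ["sig_a", "sig_b"] + [f"noise_{i}" for i in range(n_noise)]
    return pd.DataFrame(np.vstack(rows), columns=cols), labels


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"c": np.ones(50), "v": np.arange(50, dtype=float)})
        out, keep = variance_filter(df)
        assert list(out.columns) == ["v"]
        assert keep.tolist() == [False, True]

    def test_boundary_variance_kept(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        x = (x - x.mean()) / x.std() * np.sqrt(0.05)  # variance exactly 0.05
        df = pd.DataFrame({"edge": x, "tiny": 0.01 * rng.normal(size=400)})
        _, keep = variance_filter(df, 0.05)
        assert keep.tolist() == [True, False]

    def test_matches_bruteforce_per_column(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 1, (200, 12)))
        df.columns = [f"f{i}" for i in range(12)]
        _, keep = variance_filter(df, 0.05)
        for i, col in enumerate(df.columns):
            v = float(np.mean((df[col] - df[col].mean()) ** 2))
            assert keep[i] == (v >= 0.05)

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.raises(ValueError):
            variance_filter(df)


class TestImportanceSelect:
    def test_informative_features_outrank_noise(self):
        config = BoostConfig(n_trees=50, learning_rate=0.3)
        wins = 0
        for seed in range(5):
            table, labels = _separable_table(seed=seed)
            _, keep, _ = importance_select(table, labels, config, target_dim=2)
            kept = [c for c, k in zip(table.columns, keep) if k]
            wins += set(kept) == {"sig_a", "sig_b"}
        assert wins >= 4

    def test_identity_when_target_covers_all(self):
        table, labels = _separable_table(n_per_class=30)
        out, keep, flagged = importance_select(table, labels, target_dim=7)
        assert keep.all() and not flagged
        _, _, flagged2 = importance_select(table, labels, target_dim=100)
        assert flagged2

    def test_deterministic_mask(self):
        table, labels = _separable_table(n_per_class=40)
        config = BoostConfig(n_trees=30, seed=3)
        _, k1, _ = importance_select(table, labels, config, target_dim=3)
        _, k2, _ = importance_select(table, labels, config, target_dim=3)
        np.testing.assert_array_equal(k1, k2)

    def test_deep_block_exempt(self):
        rng = np.random.default_rng(2)
        table, labels = _separable_table(n_per_class=50)
        for i in range(4):
            table[f"deep_{i:02d}"] = rng.normal(size=len(table))
        _, keep, _ = importance_select(
            table, labels, BoostConfig(n_trees=30), target_dim=6
        )
        kept = [c for c, k in zip(table.columns, keep) if k]
        assert sum(c.startswith("deep_") for c in kept) == 4
        assert len(kept) == 6

    def test_fit_selection_keeps_deep_block_through_variance(self):
        table, labels = _separable_table(n_per_class=50)
        table["deep_00"] = 0.001  # variance ~0: would fail a plain filter
        masks = fit_selection(table, labels, target_dim=5)
        assert "deep_00" in masks.selected_columns


class TestClassifier:
    def test_separable_data_high_training_accuracy(self):
        table, labels = _separable_table()
        model, classes = train_classifier(table, labels)
        pred = model.predict(table.to_numpy())
        acc = np.mean([classes[int(i)] == l for i, l in zip(pred, labels)])
        assert acc >= 0.98

    def test_permuted_labels_near_chance_on_holdout(self):
        table, labels = _separable_table(n_per_class=60)
        rng = np.random.default_rng(7)
        labels = list(labels)
        rng.shuffle(labels)
        half = len(table) // 2
        config = BoostConfig(n_trees=60)
        model, classes = train_classifier(table.iloc[:half], labels[:half], config)
        pred = model.predict(table.iloc[half:].to_numpy())
        acc = np.mean(
            [classes[int(i)] == l for i, l in zip(pred, labels[half:])]
        )
        assert abs(acc - 1 / 3) <= 0.12

    def test_same_seed_identical_predictions(self):
        table, labels = _separable_table(n_per_class=40)
        a, _ = train_classifier(table, labels, BoostConfig(n_trees=40, seed=9))
        b, _ = train_classifier(table, labels, BoostConfig(n_trees=40, seed=9))
        np.testing.assert_array_equal(
            a.predict(table.to_numpy()), b.predict(table.to_numpy())
        )

    def test_degenerate_labels_fail(self):
        table, _ = _separable_table(n_per_class=10)
        with pytest.raises(ValueError):
            train_classifier(table, ["CHD"] * len(table))


class TestMajorityVote:
    def test_examples(self):
        assert majority_vote(["A", "A", "B"]) == "A"
        assert majority_vote(["A"]) == "A"
        with pytest.raises(ValueError):
            majority_vote([])

    def test_matches_mode_on_strict_majority_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            majority = str(rng.integers(3))
            n_major = n // 2 + 1
            seq = [majority] * n_major + [
                str(rng.integers(3)) for _ in range(n - n_major)
            ]
            rng.shuffle(seq)
            assert majority_vote(seq) == majority

    def test_no_majority_falls_back_to_count_with_tiebreak(self):
        # Boyer-Moore alone would return "CHD-PAH" here; counting finds a tie
        seq = ["Normal", "CHD", "Normal", "CHD", "CHD-PAH"]
        label, counts = vote_record(seq)
        assert counts == {"Normal": 2, "CHD": 2, "CHD-PAH": 1}
        assert label == "Normal"  # class-order tiebreak

    def test_verification_confirms_true_majority(self):
        label, counts = vote_record(["CHD"] * 5 + ["Normal"] * 3)
        assert label == "CHD" and counts["CHD"] == 5


class TestSplit:
    def test_stratified_fractions_and_determinism(self):
        ids = [f"r{i:03d}" for i in range(60)]
        labels = (["Normal"] * 20) + (["CHD"] * 20) + (["CHD-PAH"] * 20)
        a = split_records(ids, labels, seed=4)
        b = split_records(ids, labels, seed=4)
        assert a == b
        for lab in set(labels):
            rids = [r for r, l in zip(ids, labels) if l == lab]
            splits = [a[r] for r in rids]
            assert splits.count("train") == 12
            assert splits.count("val") == 4
            assert splits.count("test") == 4
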