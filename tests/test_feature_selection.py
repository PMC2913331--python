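import itertools

import numpy as np
import pandas as pd
import pytest

from devtox.feature_selection import (
    GeneticParams,
    HSAConfig,
    SelectionError,
    clustering_fitness,
    drop_near_constant,
    fcm_memberships,
    fuzzy_cmeans,
    greedy_wrapper_select,
    hsa_select,
)
from devtox.fixtures import SyntheticSpec, make_mechanism_table, make_table


class TestDropNearConstant:
    def _table(self, col):
        return pd.DataFrame({"x": col, "keep": np.arange(len(col), dtype=float)})

    def test_ninety_five_percent_dropped(self):
        col = [0.0] * 95 + [1.0] * 5
        out = drop_near_constant(self._table(col))
        assert list(out.columns) == ["keep"]

    def test_exactly_ninety_percent_kept(self):
        col = [0.0] * 90 + [float(i) for i in range(1, 11)]
        out = drop_near_constant(self._table(col))
        assert "x" in out.columns

    def test_constant_dropped(self):
        out = drop_near_constant(self._table([7.0] * 50))
        assert list(out.columns) == ["keep"]

    def test_all_dropped_raises(self):
        with pytest.raises(SelectionError):
            drop_near_constant(pd.DataFrame({"x": [1.0] * 10}))

    def test_informative_column_survives(self):
        # 50/50 binary separator: modal frequency 0.5 < 0.9
        X = pd.DataFrame({"sep": [0.0] * 50 + [1.0] * 50})
        assert "sep" in drop_near_constant(X).columns


class TestFuzzyCMeans:
    def test_memberships_row_normalised(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        _, U = fuzzy_cmeans(X, c=3, seed=1)
        assert np.allclose(U.sum(axis=1), 1.0)

    def test_two_blob_centroid_recovery(self):
        rng = np.random.default_rng(2)
        a = rng.normal([-3, 0], 0.2, size=(40, 2))
        b = rng.normal([3, 0], 0.2, size=(40, 2))
        centroids, _ = fuzzy_cmeans(np.vstack([a, b]), c=2, seed=0, iters=100, tol=1e-6)
        centroids = centroids[np.argsort(centroids[:, 0])]
        assert np.abs(centroids[0] - [-3, 0]).max() < 0.1
        assert np.abs(centroids[1] - [3, 0]).max() < 0.1

    def test_low_m_limit_is_nearly_hard(self):
        rng = np.random.default_rng(3)
        a = rng.normal([-5, 0], 0.1, size=(30, 2))
        b = rng.normal([5, 0], 0.1, size=(30, 2))
        _, U = fuzzy_cmeans(np.vstack([a, b]), c=2, m=1.05, seed=0, iters=100)
        assert U.max(axis=1).min() >= 0.99

    def test_too_few_rows_rejected(self):
        with pytest.raises(SelectionError):
            fuzzy_cmeans(np.zeros((3, 2)), c=6)


class TestClusteringFitness:
    def test_separable_blobs_near_one(self):
        X, y = make_table(
            SyntheticSpec(n_compounds=120, n_descriptors=2, n_informative=2,
                          class_balance=0.5, effect_size=4.0, seed=0)
        )
        assert clustering_fitness(X, y, seed=0) >= 0.95

    def test_noise_near_chance_over_seeds(self):
        vals = []
        for s in range(10):
            X, y = make_table(
                SyntheticSpec(n_compounds=120, n_descriptors=2, n_informative=0,
                              class_balance=0.5, effect_size=0.0, seed=s)
            )
            vals.append(clustering_fitness(X, y, seed=s))
        assert abs(float(np.mean(vals)) - 0.5) <= 0.1

    def test_bounded(self):
        for s in range(5):
            X, y = make_table(SyntheticSpec(n_compounds=60, seed=s))
            f = clustering_fitness(X, y, seed=s)
            assert 0.0 <= f <= 1.0

    def test_zero_variance_scores_zero(self):
        X = np.zeros((40, 3))
        y = ["D"] * 20 + ["N"] * 20
        assert clustering_fitness(X, y) == 0.0

    def test_informative_beats_noise_subsets(self):
        diffs = []
        for s in range(10):
            X, y = make_mechanism_table(
                SyntheticSpec(n_compounds=120, n_descriptors=6, n_informative=2,
                              class_balance=0.5, effect_size=3.0, seed=s)
            )
            f_inf = clustering_fitness(X[["inf1", "inf2"]], y, seed=s)
            f_noise = clustering_fitness(X[["noise1", "noise2"]], y, seed=s)
            diffs.append(f_inf - f_noise)
        assert float(np.mean(diffs)) > 0.0


class TestHSASelect:
    def test_single_descriptor_returned(self):
        X = pd.DataFrame({"only": np.arange(10, dtype=float)})
        y = ["D"] * 5 + ["N"] * 5
        sel, _ = hsa_select(X, y)
        assert sel == ["only"]

    def test_reproducible_for_seed(self):
        X, y = make_mechanism_table(
            SyntheticSpec(n_compounds=80, n_descriptors=8, n_informative=2,
                          class_balance=0.5, effect_size=3.0, seed=4)
        )
        cfg = HSAConfig(seed=11)
        a, loga = hsa_select(X, y, cfg)
        b, logb = hsa_select(X, y, cfg)
        assert a == b
        assert [g.best_fitness for g in loga] == [g.best_fitness for g in logb]

    def test_recovers_planted_mechanisms(self):
        X, y = make_mechanism_table(
            SyntheticSpec(n_compounds=120, n_descriptors=20, n_informative=2,
                          class_balance=0.5, effect_size=3.0, seed=100)
        )
        sel, log = hsa_select(X, y, HSAConfig(seed=0))
        assert {"inf1", "inf2"} <= set(sel)
        assert len(log) == 10  # one entry per generation

    def test_invalid_config_rejected(self):
        with pytest.raises(SelectionError):
            HSAConfig(genetic=GeneticParams(mutation=1.5))


class TestGreedyWrapper:
    def test_oracle_evaluator_recovers_informative_set(self):
        X = pd.DataFrame(np.zeros((4, 4)), columns=["i1", "i2", "n1", "n2"])
        informative = {"i1", "i2"}

        def evaluator(cols):
            cols = set(cols)
            return len(cols & informative) - 0.1 * len(cols - informative)

        sel = greedy_wrapper_select(X, None, evaluator, direction="forward")
        assert set(sel) == informative

    def test_zero_patience_keeps_initial_set_when_worsening(self):
        X = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "c"])
        sel = greedy_wrapper_select(
            X, None, lambda cols: -len(cols), direction="forward", patience=0
        )
        assert sel == []

    def test_forward_matches_exhaustive_search(self):
        X = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "c"])
        weights = {"a": 0.5, "b": 0.3, "c": -0.2}

        def evaluator(cols):
            return sum(weights[c] for c in cols)

        sel = greedy_wrapper_select(X, None, evaluator, direction="forward", patience=0)
        best_subset = max(
            (
                subset
                for r in range(4)
                for subset in itertools.combinations(["a", "b", "c"], r)
            ),
            key=evaluator,
        )
        assert set(sel) == set(best_subset)

    def test_backward_direction_runs(self):
        X = pd.DataFrame(np.zeros((2, 3)), columns=["a", "b", "c"])
        sel = greedy_wrapper_select(
            X, None, lambda cols: -abs(len(cols) - 2), direction="backward"
        )
        assert len(sel) == 2

    def test_unknown_direction_rejected(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        with pytest.raises(SelectionError):
            greedy_wrapper_select(X, None, len, direction="sideways")
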