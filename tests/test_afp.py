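"""Adaptive-fuzzy-partition tests: membership geometry, rule scoring,
training against exhaustive-search oracles, defuzzification and the
range-based domain behaviour."""

import numpy as np
import pandas as pd
import pytest

from devtox.afp import (
    AFPError,
    AFPHyperparameters,
    AFPResults,
    AdaptiveFuzzyPartition,
    FuzzyRule,
    NOT_PREDICTABLE,
    TrapezoidalInterval,
    membership,
    rule_activation,
    rule_score,
)


class TestTrapezoid:
    def test_midpoint_is_plateau(self):
        iv = TrapezoidalInterval.from_crisp(0.0, 1.0)
        assert iv.membership(0.5) == 1.0

    def test_beyond_support_is_zero(self):
        iv = TrapezoidalInterval.from_crisp(0.0, 1.0)
        assert iv.membership(1.2) == 0.0
        assert iv.membership(-0.2) == 0.0

    def test_crisp_edge_ramp_two_thirds(self):
        # interval (0,1), q/w=0.9, p/w=1.2: plateau edge 0.95, support 1.1
        iv = TrapezoidalInterval.from_crisp(0.0, 1.0)
        assert iv.membership(1.0) == pytest.approx(2 / 3)

    def test_boundary_edge_stays_crisp(self):
        iv = TrapezoidalInterval.from_crisp(0.0, 1.0, left_boundary=True)
        assert iv.membership(0.0) == 1.0
        assert iv.membership(-1e-9) == 0.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(AFPError):
            TrapezoidalInterval.from_crisp(1.0, 1.0)

    def test_membership_function_wrapper(self):
        iv = TrapezoidalInterval.from_crisp(0.0, 2.0)
        assert membership(1.0, iv) == 1.0


class TestRuleActivation:
    def _rule(self):
        return FuzzyRule(
            intervals={
                "a": TrapezoidalInterval.from_crisp(0.0, 1.0),
                "b": TrapezoidalInterval.from_crisp(0.0, 1.0),
            },
            class_scores={"D": 1.0, "N": 0.0},
            support_count=2,
        )

    def test_all_plateau_gives_one(self):
        assert rule_activation({"a": 0.5, "b": 0.5}, self._rule()) == 1.0

    def test_min_is_absorbing_at_zero(self):
        assert rule_activation({"a": 0.5, "b": 5.0}, self._rule()) == 0.0

    def test_min_combination(self):
        act = rule_activation({"a": 0.5, "b": 1.0}, self._rule())
        iv = TrapezoidalInterval.from_crisp(0.0, 1.0)
        assert act == pytest.approx(min(1.0, iv.membership(1.0)))

    def test_missing_descriptor_rejected(self):
        with pytest.raises(AFPError):
            rule_activation({"a": 0.5}, self._rule())


class TestRuleScore:
    def test_single_member_full_activation(self):
        assert rule_score([(1.0, "D")], "D") == 1.0

    def test_weighted_average(self):
        assert rule_score([(0.5, "N"), (1.0, "D")], "D") == pytest.approx(2 / 3)

    def test_homogeneous_members_score_one(self):
        assert rule_score([(0.2, "D"), (0.9, "D"), (0.4, "D")], "D") == 1.0

    def test_all_zero_activation_undefined(self):
        with pytest.raises(AFPError):
            rule_score([(0.0, "D")], "D")


def _separable_1d(n_per_class=10, seed=1):
    rng = np.random.default_rng(seed)
    x = np.concatenate(
        [rng.uniform(-1.0, -0.1, n_per_class), rng.uniform(0.1, 1.0, n_per_class)]
    )
    y = np.array(["D"] * n_per_class + ["N"] * n_per_class, dtype=object)
    return pd.DataFrame({"d1": x}), y


def oracle_first_split(X: pd.DataFrame, y, positive="D", min_leaf=2):
    """Exhaustive search over every (column, midpoint cut) candidate."""
    best = None
    yv = np.asarray(y, dtype=object)
    for col_idx, col in enumerate(X.columns):
        vals = X[col].to_numpy()
        for cut in 0.5 * (np.unique(vals)[:-1] + np.unique(vals)[1:]):
            left, right = yv[vals <= cut], yv[vals > cut]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            q = abs(np.mean(left == positive) - np.mean(right == positive))
            if best is None or q > best[0] + 1e-12:
                best = (q, col_idx, cut)
    return best


def first_split_of(results: AFPResults):
    """Recover the first applied cut from a two-rule model."""
    assert len(results.rules) == 2
    (name_a, iv_a), = results.rules[0].intervals.items()
    (name_b, iv_b), = results.rules[1].intervals.items()
    assert name_a == name_b
    cut = iv_a.upper if iv_a.upper == iv_b.lower else iv_a.lower
    return name_a, cut


class TestTraining:
    def test_separable_1d_single_cut(self):
        X, y = _separable_1d()
        res = AdaptiveFuzzyPartition(X, y).fit()
        assert len(res.rules) == 2
        scores = sorted(
            (r.class_scores["D"], r.class_scores["N"]) for r in res.rules
        )
        # each rule is pure for its own class
        assert scores[0][1] == pytest.approx(1.0, abs=1e-6)
        assert scores[1][0] == pytest.approx(1.0, abs=1e-6)
        # cut position agrees with brute-force search
        _, cut = first_split_of(res)
        oracle = oracle_first_split(X, y)
        assert cut == pytest.approx(oracle[2])

    def test_single_class_degenerate_model(self):
        X = pd.DataFrame({"d1": [0.0, 1.0, 2.0]})
        res = AdaptiveFuzzyPartition(X, ["D", "D", "D"]).fit()
        assert len(res.rules) == 1
        assert res.rules[0].class_scores["D"] == 1.0

    def test_xor_needs_more_than_two_rules(self):
        rng = np.random.default_rng(0)
        pts, labels = [], []
        for cx, cy, cls in [(0, 0, "D"), (1, 1, "D"), (0, 1, "N"), (1, 0, "N")]:
            for _ in range(5):
                pts.append((cx + rng.normal(0, 0.05), cy + rng.normal(0, 0.05)))
                labels.append(cls)
        X = pd.DataFrame(pts, columns=["a", "b"])
        res = AdaptiveFuzzyPartition(X, labels).fit()
        assert len(res.rules) >= 3
        # greedy cutting cannot be perfect on XOR, but must beat chance
        preds = res.predict_classes(X)
        assert np.mean(np.array(preds) == np.array(labels)) >= 0.75

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = np.where(X["b"] + 0.3 * rng.normal(size=n) > 0, "D", "N")
        hyper = AFPHyperparameters(max_rules_per_class=1)
        res = AdaptiveFuzzyPartition(X, y, hyper).fit()
        name, cut = first_split_of(res)
        q, col_idx, oracle_cut = oracle_first_split(X, y)
        assert name == X.columns[col_idx]
        assert cut == pytest.approx(oracle_cut)

    def test_deterministic_given_input(self):
        X, y = _separable_1d(seed=7)
        a = AdaptiveFuzzyPartition(X, y).fit()
        b = AdaptiveFuzzyPartition(X, y).fit()
        assert a.to_dict() == b.to_dict()

    def test_empty_input_rejected(self):
        with pytest.raises(AFPError):
            AdaptiveFuzzyPartition(pd.DataFrame({"a": []}), [])

    def test_nan_cells_rejected(self):
        X = pd.DataFrame({"a": [1.0, float("nan")]})
        with pytest.raises(AFPError):
            AdaptiveFuzzyPartition(X, ["D", "N"])


class TestPrediction:
    def test_plateau_point_of_pure_rule(self):
        X, y = _separable_1d()
        res = AdaptiveFuzzyPartition(X, y).fit()
        pred = res.predict_one({"d1": -0.6})
        assert pred.assigned_class == "D"
        assert pred.degrees["D"] > 0.5

    def test_out_of_range_not_predictable(self):
        X, y = _separable_1d()
        res = AdaptiveFuzzyPartition(X, y).fit()
        pred = res.predict_one({"d1": 99.0})
        assert pred.assigned_class == NOT_PREDICTABLE
        assert pred.out_of_domain_descriptors == ("d1",)

    def test_degrees_sum_to_one_binary(self):
        X, y = _separable_1d(seed=3)
        res = AdaptiveFuzzyPartition(X, y).fit()
        for x in np.linspace(-0.9, 0.9, 13):
            p = res.predict_one({"d1": float(x)})
            if p.assigned_class != NOT_PREDICTABLE:
                assert sum(p.degrees.values()) == pytest.approx(1.0, abs=1e-9)

    def test_exact_half_degree_not_assigned(self):
        rules = [
            FuzzyRule(
                intervals={"a": TrapezoidalInterval.from_crisp(0.0, 1.0)},
                class_scores={"D": 1.0, "N": 0.0},
                support_count=2,
            ),
            FuzzyRule(
                intervals={"a": TrapezoidalInterval.from_crisp(0.0, 1.0)},
                class_scores={"D": 0.0, "N": 1.0},
                support_count=2,
            ),
        ]
        res = AFPResults(
            model=None,
            rules=rules,
            ranges={"a": (0.0, 1.0)},
            columns=["a"],
            classes=("D", "N"),
        )
        pred = res.predict_one({"a": 0.5})
        assert pred.degrees["D"] == pytest.approx(0.5)
        assert pred.assigned_class == NOT_PREDICTABLE

    def test_fit_consistency_on_separable_training_points(self):
        X, y = _separable_1d(seed=11)
        res = AdaptiveFuzzyPartition(X, y).fit()
        assert res.predict_classes(X) == list(y)


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = _separable_1d(seed=5)
        res = AdaptiveFuzzyPartition(X, y).fit()
        path = tmp_path / "model.json"
        res.save(path)
        back = AFPResults.load(path)
        grid = pd.DataFrame({"d1": np.linspace(-1, 1, 21)})
        assert back.predict_classes(grid) == res.predict_classes(grid)

    def test_summary_mentions_hyperparameters(self):
        X, y = _separable_1d()
        text = AdaptiveFuzzyPartition(X, y).fit().summary()
        assert "max_cuts/axis=4" in text and "q/w=0.9" in text
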