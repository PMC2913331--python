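"""Adaptive Fuzzy Partition (AFP) binary classifier.

AFP recursively partitions descriptor space into fuzzy subspaces.  At
each step the algorithm searches exhaustively over (descriptor, cut)
candidates — cut positions are the midpoints between consecutive
distinct sorted training values — and applies the split that maximises
the difference between the class scores of the two resulting
subspaces.  Each final subspace becomes a fuzzy rule: per-axis
trapezoidal membership functions (plateau q/w = 0.9 of the crisp
interval, support p/w = 1.2, so each rule overhangs its neighbours)
combined by the Min operator, plus per-class scores given by the
activation-weighted class frequency over the training vectors the rule
touches.

Prediction uses centroid defuzzification: the degree of membership for
class c is sum_k act_k * O_k(c) / sum_k act_k over all rules, and a
compound is assigned to a class only when its degree exceeds 0.5.
Queries with any descriptor outside the training range (or with an
undefined descriptor value) are reported as not predictable — the
range component of the applicability domain.

The module follows a Model/fit/Results shape::

    results = AdaptiveFuzzyPartition(X, y).fit()
    results.predict(X_new)
    print(results.summary())
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NOT_PREDICTABLE = "not_predictable"


class AFPError(ValueError):
    pass


@dataclass(frozen=True)
class AFPHyperparameters:
    """Partitioning limits and trapezoid geometry.

    ``support_ratio`` (p/w) and ``plateau_ratio`` (q/w) size the
    trapezoid relative to the crisp interval width w: the plateau of
    full membership covers the central q, the support overhangs each
    side by (p - w)/2.
    """

    max_rules_per_class: int = 30
    min_compounds_per_rule: int = 2
    max_cuts_per_axis: int = 4
    class_threshold: float = 0.5
    plateau_ratio: float = 0.9
    support_ratio: float = 1.2

    def __post_init__(self) -> None:
        if not (0 < self.plateau_ratio <= 1 <= self.support_ratio):
            raise AFPError("need 0 < q/w <= 1 <= p/w")
        if self.min_compounds_per_rule < 1 or self.max_cuts_per_axis < 0:
            raise AFPError("invalid partitioning limits")


@dataclass(frozen=True)
class TrapezoidalInterval:
    """A fuzzified crisp interval [lower, upper].

    Membership is 1 on [plateau_lower, plateau_upper], ramps linearly
    to 0 at the support edges, and is 0 outside the support.  An edge
    that coincides with the training range boundary is left crisp
    (plateau and support meet the boundary exactly).
    """

    lower: float
    upper: float
    plateau_lower: float
    plateau_upper: float
    support_lower: float
    support_upper: float

    @classmethod
    def from_crisp(
        cls,
        lower: float,
        upper: float,
        plateau_ratio: float = 0.9,
        support_ratio: float = 1.2,
        left_boundary: bool = False,
        right_boundary: bool = False,
    ) -> "TrapezoidalInterval":
        if not lower < upper:
            raise AFPError(f"need lower < upper, got [{lower}, {upper}]")
        w = upper - lower
        c = 0.5 * (lower + upper)
        ph = 0.5 * plateau_ratio * w
        sh = 0.5 * support_ratio * w
        pl, pu = c - ph, c + ph
        sl, su = c - sh, c + sh
        if left_boundary:
            pl = sl = lower
        if right_boundary:
            pu = su = upper
        return cls(lower, upper, pl, pu, sl, su)

    def membership(self, x: float) -> float:
        if math.isnan(x):
            return 0.0
        if x < self.support_lower or x > self.support_upper:
            return 0.0
        if self.plateau_lower <= x <= self.plateau_upper:
            return 1.0
        if x < self.plateau_lower:
            return (x - self.support_lower) / (self.plateau_lower - self.support_lower)
        return (self.support_upper - x) / (self.support_upper - self.plateau_upper)


def membership(x: float, interval: TrapezoidalInterval) -> float:
    """Trapezoidal membership of a value in a fuzzified interval."""
    return interval.membership(x)


@dataclass
class FuzzyRule:
    """One fuzzy subspace: per-axis intervals plus per-class scores."""

    intervals: dict[str, TrapezoidalInterval]
    class_scores: dict[str, float]
    support_count: int

    def activation(self, point: Mapping[str, float]) -> float:
        """Min-combined membership; axes the rule does not partition give 1."""
        act = 1.0
        for name, iv in self.intervals.items():
            if name not in point:
                raise AFPError(f"descriptor {name!r} missing from input vector")
            act = min(act, iv.membership(float(point[name])))
            if act == 0.0:
                return 0.0
        return act

    @property
    def majority_class(self) -> str:
        return max(sorted(self.class_scores), key=lambda c: self.class_scores[c])


def rule_activation(point: Mapping[str, float], rule: FuzzyRule) -> float:
    return rule.activation(point)


def rule_score(members: Sequence[tuple[float, str]], cls: str) -> float:
    """Activation-weighted frequency of class ``cls`` among members."""
    total = sum(act for act, _ in members)
    if total <= 0:
        raise AFPError("rule score undefined: all activations zero")
    return sum(act for act, a in members if a == cls) / total


@dataclass(frozen=True)
class AFPPrediction:
    """Per-class degrees of membership and the crisp assignment."""

    degrees: dict[str, float]
    assigned_class: str
    out_of_domain_descriptors: tuple[str, ...] = ()
    reason: str = ""


# ---------------------------------------------------------------------------
# Training internals


@dataclass
class _Node:
    indices: np.ndarray
    box: dict[str, tuple[float, float]]
    cuts_used: dict[str, int]
    cut_axes: list[str] = field(default_factory=list)


def _crisp_class_fraction(y: np.ndarray, idx: np.ndarray, positive: str) -> float:
    return float(np.mean(y[idx] == positive))


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str],
    node: _Node,
    hyper: AFPHyperparameters,
    positive: str,
) -> tuple[float, int, float] | None:
    """Exhaustive (descriptor, cut) search inside a node.

    Returns (quality, column index, cut value) maximising the absolute
    difference between the two child subspace scores, or None if no
    admissible split exists.  Ties break on column order then lower
    cut value (strict improvement required to displace the incumbent).
    """
    best: tuple[float, int, float] | None = None
    for col, name in enumerate(columns):
        if node.cuts_used[name] >= hyper.max_cuts_per_axis:
            continue
        vals = X[node.indices, col]
        distinct = np.unique(vals)
        if len(distinct) < 2:
            continue
        cuts = 0.5 * (distinct[:-1] + distinct[1:])
        for cut in cuts:
            left = node.indices[vals <= cut]
            right = node.indices[vals > cut]
            if (
                len(left) < hyper.min_compounds_per_rule
                or len(right) < hyper.min_compounds_per_rule
            ):
                continue
            quality = abs(
                _crisp_class_fraction(y, left, positive)
                - _crisp_class_fraction(y, right, positive)
            )
            if best is None or quality > best[0] + 1e-12:
                best = (quality, col, float(cut))
    return best


class AdaptiveFuzzyPartition:
    """AFP model specification bound to training data.

    Parameters
    ----------
    X : DataFrame
        Descriptor matrix (rows = compounds, columns = descriptors).
    y : sequence of str
        Class labels aligned with the rows of ``X`` (binary ``N``/``D``
        in the toxicity setting, but any label alphabet works).
    hyper : AFPHyperparameters, optional
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        hyper: AFPHyperparameters | None = None,
    ):
        if len(X) == 0:
            raise AFPError("empty training matrix")
        if len(X) != len(y):
            raise AFPError("X and y length mismatch")
        if X.isna().any().any():
            raise AFPError("training matrix contains undefined descriptor cells")
        self.X = X
        self.y = np.asarray(list(y), dtype=object)
        self.hyper = hyper or AFPHyperparameters()
        self.classes = tuple(sorted(set(self.y)))
        if len(self.classes) > 2:
            # scores generalise, but the partition quality criterion is binary
            raise AFPError("AFP is a binary classifier; got >2 classes")

    def fit(self) -> "AFPResults":
        hyper = self.hyper
        columns = list(self.X.columns)
        Xv = self.X.to_numpy(dtype=float)
        y = self.y
        positive = self.classes[-1]
        ranges = {
            c: (float(self.X[c].min()), float(self.X[c].max())) for c in columns
        }

        root = _Node(
            indices=np.arange(len(y)),
            box={c: ranges[c] for c in columns},
            cuts_used={c: 0 for c in columns},
        )
        leaves: list[_Node] = []
        counter = 0
        heap: list[tuple[float, int, _Node, tuple[float, int, float]]] = []

        def push(node: _Node) -> None:
            nonlocal counter
            split = _best_split(Xv, y, columns, node, hyper, positive)
            if split is None or split[0] <= 0.0:
                leaves.append(node)
            else:
                heapq.heappush(heap, (-split[0], counter, node, split))
                counter += 1

        push(root)
        max_leaves = hyper.max_rules_per_class * len(self.classes)
        while heap:
            if len(heap) + len(leaves) >= max_leaves:
                # rule budget exhausted: freeze remaining nodes as leaves
                leaves.extend(item[2] for item in heap)
                heap.clear()
                break
            _, _, node, (quality, col, cut) = heapq.heappop(heap)
            name = columns[col]
            vals = Xv[node.indices, col]
            lo, hi = node.box[name]
            left = _Node(
                indices=node.indices[vals <= cut],
                box={**node.box, name: (lo, cut)},
                cuts_used={**node.cuts_used, name: node.cuts_used[name] + 1},
                cut_axes=sorted(set(node.cut_axes) | {name}),
            )
            right = _Node(
                indices=node.indices[vals > cut],
                box={**node.box, name: (cut, hi)},
                cuts_used=dict(left.cuts_used),
                cut_axes=list(left.cut_axes),
            )
            push(left)
            push(right)

        rules = [self._make_rule(node, columns, ranges) for node in leaves]
        self._score_rules(rules)
        return AFPResults(
            model=self,
            rules=rules,
            ranges=ranges,
            columns=columns,
        )

    def _make_rule(
        self,
        node: _Node,
        columns: Sequence[str],
        ranges: Mapping[str, tuple[float, float]],
    ) -> FuzzyRule:
        intervals: dict[str, TrapezoidalInterval] = {}
        for name in node.cut_axes:
            lo, hi = node.box[name]
            mn, mx = ranges[name]
            intervals[name] = TrapezoidalInterval.from_crisp(
                lo,
                hi,
                plateau_ratio=self.hyper.plateau_ratio,
                support_ratio=self.hyper.support_ratio,
                left_boundary=(lo == mn),
                right_boundary=(hi == mx),
            )
        return FuzzyRule(
            intervals=intervals,
            class_scores={},
            support_count=len(node.indices),
        )

    def _score_rules(self, rules: list[FuzzyRule]) -> None:
        points = self.X.to_dict("records")
        for rule in rules:
            members = [
                (rule.activation(p), a)
                for p, a in zip(points, self.y)
            ]
            members = [(act, a) for act, a in members if act > 0]
            for c in self.classes:
                rule.class_scores[c] = rule_score(members, c)


class AFPResults:
    """A fitted adaptive-fuzzy-partition model.

    Carries the fuzzy rules, the per-descriptor training ranges used by
    the applicability-domain range check, and the hyperparameters.
    """

    def __init__(
        self,
        model: AdaptiveFuzzyPartition | None,
        rules: list[FuzzyRule],
        ranges: dict[str, tuple[float, float]],
        columns: list[str],
        hyper: AFPHyperparameters | None = None,
        classes: tuple[str, ...] | None = None,
    ):
        self.model = model
        self.rules = rules
        self.ranges = ranges
        self.columns = columns
        self.hyper = hyper or (model.hyper if model else AFPHyperparameters())
        self.classes = classes or (model.classes if model else ("D", "N"))

    # -- prediction ---------------------------------------------------------

    def predict_one(self, point: Mapping[str, float]) -> AFPPrediction:
        offenders = []
        for name in self.columns:
            if name not in point:
                raise AFPError(f"descriptor {name!r} missing from input vector")
            x = float(point[name])
            mn, mx = self.ranges[name]
            if math.isnan(x) or x < mn or x > mx:
                offenders.append(name)
        if offenders:
            return AFPPrediction(
                degrees={c: float("nan") for c in self.classes},
                assigned_class=NOT_PREDICTABLE,
                out_of_domain_descriptors=tuple(offenders),
                reason="descriptor(s) outside the training range",
            )
        acts = np.array([r.activation(point) for r in self.rules])
        total = float(acts.sum())
        if total <= 0.0:
            return AFPPrediction(
                degrees={c: float("nan") for c in self.classes},
                assigned_class=NOT_PREDICTABLE,
                reason="no active rule",
            )
        degrees = {}
        for c in self.classes:
            scores = np.array([r.class_scores[c] for r in self.rules])
            degrees[c] = float((acts * scores).sum() / total)
        assigned = NOT_PREDICTABLE
        best = max(sorted(degrees), key=lambda c: degrees[c])
        if degrees[best] > self.hyper.class_threshold:
            assigned = best
        return AFPPrediction(degrees=degrees, assigned_class=assigned)

    def predict(self, X: pd.DataFrame) -> list[AFPPrediction]:
        return [self.predict_one(row) for row in X.to_dict("records")]

    def predict_classes(self, X: pd.DataFrame) -> list[str]:
        return [p.assigned_class for p in self.predict(X)]

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Adaptive Fuzzy Partition results",
            "================================",
            f"descriptors: {', '.join(self.columns)}",
            f"classes:     {', '.join(self.classes)}",
            f"rules:       {len(self.rules)}",
            f"hyper:       max_rules/class={self.hyper.max_rules_per_class}, "
            f"min_compounds={self.hyper.min_compounds_per_rule}, "
            f"max_cuts/axis={self.hyper.max_cuts_per_axis}, "
            f"q/w={self.hyper.plateau_ratio}, p/w={self.hyper.support_ratio}",
            "",
            f"{'rule':>4}  {'n':>4}  scores  intervals",
        ]
        for i, r in enumerate(self.rules):
            scores = ", ".join(
                f"{c}={r.class_scores[c]:.3f}" for c in self.classes
            )
            ivs = "; ".join(
                f"{n}∈[{iv.lower:.4g},{iv.upper:.4g}]"
                for n, iv in sorted(r.intervals.items())
            ) or "(whole space)"
            lines.append(f"{i:>4}  {r.support_count:>4}  {scores}  {ivs}")
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "devtox-afp",
            "version": 1,
            "columns": self.columns,
            "classes": list(self.classes),
            "hyper": {
                "max_rules_per_class": self.hyper.max_rules_per_class,
                "min_compounds_per_rule": self.hyper.min_compounds_per_rule,
                "max_cuts_per_axis": self.hyper.max_cuts_per_axis,
                "class_threshold": self.hyper.class_threshold,
                "plateau_ratio": self.hyper.plateau_ratio,
                "support_ratio": self.hyper.support_ratio,
            },
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "rules": [
                {
                    "intervals": {
                        n: [
                            iv.lower,
                            iv.upper,
                            iv.plateau_lower,
                            iv.plateau_upper,
                            iv.support_lower,
                            iv.support_upper,
                        ]
                        for n, iv in r.intervals.items()
                    },
                    "class_scores": r.class_scores,
                    "support_count": r.support_count,
                }
                for r in self.rules
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "AFPResults":
        if doc.get("format") != "devtox-afp":
            raise AFPError("not an AFP model document")
        hyper = AFPHyperparameters(**doc["hyper"])
        rules = [
            FuzzyRule(
                intervals={
                    n: TrapezoidalInterval(*vals)
                    for n, vals in r["intervals"].items()
                },
                class_scores={k: float(v) for k, v in r["class_scores"].items()},
                support_count=int(r["support_count"]),
            )
            for r in doc["rules"]
        ]
        return cls(
            model=None,
            rules=rules,
            ranges={k: (float(a), float(b)) for k, (a, b) in doc["ranges"].items()},
            columns=list(doc["columns"]),
            hyper=hyper,
            classes=tuple(doc["classes"]),
        )

    @classmethod
    def load(cls, path) -> "AFPResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
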