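"""Validation: splits, cross-validation and classification statistics.

Implements the seven standard binary-classification metrics (accuracy,
false-positive and false-negative rates, sensitivity, specificity, PPV
and NPV) with integer-percent rendering, the rational (structurally
sorted, systematically sampled) train/test split, k-fold /
leave-one-out / leave-several-out cross-validation, and the
similarity-group analysis comparing the neighbourhood similarity of
correctly versus incorrectly predicted compounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from devtox.chem_io import CompoundSet, ValidationError
from devtox.descriptors import atom_counts, ring_counts
from devtox.fgroups import DEFAULT_CATALOG, compile_catalog, first_matching_group

POSITIVE_CLASS = "D"  # developmental toxicant
NEGATIVE_CLASS = "N"
UNPREDICTABLE = "not_predictable"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the toxicant class D as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls,
        experimental: Sequence[str],
        predicted: Sequence[str],
        positive: str = POSITIVE_CLASS,
    ) -> "ConfusionCounts":
        """Confusion table from label pairs.

        Compounds the model declines to predict (``not_predictable``)
        are excluded from the counts, mirroring how the published
        statistics dropped the one test compound outside the AFP
        domain; use :func:`count_unpredictable` to report them.
        """
        if len(experimental) != len(predicted):
            raise ValidationError("label sequences differ in length")
        tp = tn = fp = fn = 0
        for e, p in zip(experimental, predicted):
            if p == UNPREDICTABLE:
                continue
            if e == positive:
                if p == positive:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive:
                    fp += 1
                else:
                    tn += 1
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def count_unpredictable(predicted: Sequence[str]) -> int:
    return sum(1 for p in predicted if p == UNPREDICTABLE)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def round_half_up_percent(x: float) -> int:
    """Integer percent with ties rounded up (0.845 -> 85 at percent scale)."""
    if math.isnan(x):
        raise ValidationError("cannot render an undefined metric as percent")
    return int(math.floor(100.0 * x + 0.5))


@dataclass(frozen=True)
class StatsReport:
    """The seven classification metrics, as fractions in [0, 1].

    Metrics with a zero denominator are NaN ("undefined") rather than
    silently 0.  ``percent()`` renders the printed-table form.
    """

    accuracy: float
    fp_rate: float
    fn_rate: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    @classmethod
    def from_confusion(cls, c: ConfusionCounts) -> "StatsReport":
        if c.total < 1:
            raise ValidationError("empty confusion table")
        return cls(
            accuracy=_ratio(c.tp + c.tn, c.total),
            fp_rate=_ratio(c.fp, c.fp + c.tn),
            fn_rate=_ratio(c.fn, c.fn + c.tp),
            sensitivity=_ratio(c.tp, c.tp + c.fn),
            specificity=_ratio(c.tn, c.fp + c.tn),
            ppv=_ratio(c.tp, c.tp + c.fp),
            npv=_ratio(c.tn, c.tn + c.fn),
        )

    def percent(self) -> dict[str, int]:
        return {
            "Accuracy": round_half_up_percent(self.accuracy),
            "FP%": round_half_up_percent(self.fp_rate),
            "FN%": round_half_up_percent(self.fn_rate),
            "PPV": round_half_up_percent(self.ppv),
            "NPV": round_half_up_percent(self.npv),
            "Sensitivity": round_half_up_percent(self.sensitivity),
            "Specificity": round_half_up_percent(self.specificity),
        }

    def summary(self) -> str:
        rows = self.percent()
        width = max(len(k) for k in rows)
        return "\n".join(f"{k:<{width}}  {v}%" for k, v in rows.items())


def confusion_stats(c: ConfusionCounts) -> StatsReport:
    """All seven metrics from a confusion table."""
    return StatsReport.from_confusion(c)


# ---------------------------------------------------------------------------
# Rational train/test split


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def _structural_sort_key(record, compiled) -> tuple:
    mol = record.mol
    ac = atom_counts(mol)
    rc = ring_counts(mol)
    bond_order_sum = sum(b.GetBondTypeAsDouble() for b in mol.GetBonds())
    aromatic_rings = sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    return (
        first_matching_group(mol, compiled),
        ac["nX"],
        aromatic_rings,
        bond_order_sum,
        rc["nCIR"],
        mol.GetNumAtoms(),
        record.id,
    )


def _systematic_pick(n: int, k: int) -> list[int]:
    """k evenly spaced positions out of n (deterministic, centred strides)."""
    if k <= 0:
        return []
    step = n / k
    return sorted({min(n - 1, int(step / 2 + i * step)) for i in range(k)})


def rational_split(cset: CompoundSet, test_fraction: float = 0.20) -> SplitResult:
    """Structurally sorted, class-preserving systematic train/test split.

    Compounds are sorted by (functional-group class, halogen count,
    aromatic-ring count, total bond order, ring count, atom count, id)
    and the test set is drawn systematically from the sorted list of
    each toxicity class.  The overall test size is
    ``floor(test_fraction * n)``, allocated to classes by largest
    remainder.  Fully deterministic.
    """
    if not (0.0 < test_fraction <= 0.5):
        raise ValidationError("test_fraction must lie in (0, 0.5]")
    n = len(cset)
    if n < 5:
        raise ValidationError("need at least 5 compounds to split")
    compiled = compile_catalog(DEFAULT_CATALOG)
    keyed = sorted(cset.records, key=lambda r: _structural_sort_key(r, compiled))
    classes = sorted({r.binary_class for r in keyed}, key=lambda c: (c is None, c))
    n_test = int(math.floor(test_fraction * n))
    # largest-remainder allocation of the test quota across classes
    sizes = {c: sum(1 for r in keyed if r.binary_class == c) for c in classes}
    quotas = {c: test_fraction * sizes[c] for c in classes}
    alloc = {c: int(math.floor(quotas[c])) for c in classes}
    short = n_test - sum(alloc.values())
    for c in sorted(classes, key=lambda c: -(quotas[c] - alloc[c])):
        if short <= 0:
            break
        alloc[c] += 1
        short -= 1
    test_ids: list[str] = []
    for c in classes:
        members = [r.id for r in keyed if r.binary_class == c]
        picks = _systematic_pick(len(members), alloc[c])
        test_ids.extend(members[i] for i in picks)
    test_set = set(test_ids)
    train_ids = [r.id for r in cset.records if r.id not in test_set]
    ordered_test = [r.id for r in cset.records if r.id in test_set]
    return SplitResult(train_ids=tuple(train_ids), test_ids=tuple(ordered_test))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    unpredictable: int = 0


@dataclass
class CVResult:
    folds: list[FoldResult]
    skipped: list[int]

    @property
    def unpredictable(self) -> int:
        return sum(f.unpredictable for f in self.folds)

    @property
    def pooled(self) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0, 0)
        for f in self.folds:
            total = total + f.counts
        return total

    @property
    def accuracy(self) -> float:
        c = self.pooled
        return (c.tp + c.tn) / c.total

    def stats(self) -> StatsReport:
        return confusion_stats(self.pooled)


Trainer = Callable[[pd.DataFrame, Sequence[str]], Callable[[pd.DataFrame], list[str]]]


def _fold_indices(
    n: int, scheme: str, k: int, frac: float, reps: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    folds = []
    if scheme == "kfold":
        perm = rng.permutation(idx)
        for part in np.array_split(perm, k):
            mask = np.zeros(n, dtype=bool)
            mask[part] = True
            folds.append((idx[~mask], idx[mask]))
    elif scheme == "leave_one_out":
        for i in range(n):
            mask = np.zeros(n, dtype=bool)
            mask[i] = True
            folds.append((idx[~mask], idx[mask]))
    elif scheme == "leave_several_out":
        m = max(1, int(round(frac * n)))
        for _ in range(reps):
            out = rng.choice(n, size=m, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[out] = True
            folds.append((idx[~mask], idx[mask]))
    else:
        raise ValidationError(f"unknown CV scheme {scheme!r}")
    return folds


def cross_validate(
    trainer: Trainer,
    X: pd.DataFrame,
    y: Sequence[str],
    scheme: str = "kfold",
    k: int = 10,
    frac: float = 0.2,
    reps: int = 10,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> CVResult:
    """Cross-validate a trainer callback.

    ``trainer(X_train, y_train)`` must return a predict function
    mapping a descriptor frame to class labels.  Folds whose training
    part holds a single class are skipped with a record.
    """
    y = np.asarray(list(y), dtype=object)
    folds = _fold_indices(len(y), scheme, k, frac, reps, seed)
    results: list[FoldResult] = []
    skipped: list[int] = []
    for i, (tr, te) in enumerate(folds):
        if len(set(y[tr])) < 2:
            skipped.append(i)
            continue
        predict = trainer(X.iloc[tr], y[tr])
        pred = predict(X.iloc[te])
        results.append(
            FoldResult(
                fold=i,
                counts=ConfusionCounts.from_labels(y[te], pred, positive=positive),
                unpredictable=count_unpredictable(pred),
            )
        )
    if not results:
        raise ValidationError("every fold was skipped")
    return CVResult(folds=results, skipped=skipped)


# ---------------------------------------------------------------------------
# Similarity-group analysis


@dataclass(frozen=True)
class GroupStats:
    mean: float
    sd: float
    n: int


@dataclass
class SimilarityGroupAnalysis:
    """Per-outcome and pooled neighbourhood-similarity statistics."""

    per_group: dict[str, GroupStats]
    correct: GroupStats
    incorrect: GroupStats
    t_statistic: float
    p_value: float
    t_test_note: str = ""

    def summary(self) -> str:
        lines = ["outcome  mean    sd      n"]
        for g in ("TN", "TP", "FP", "FN"):
            if g in self.per_group:
                s = self.per_group[g]
                lines.append(f"{g:<7}  {s.mean:.3f}  {s.sd:.3f}  {s.n}")
        lines.append(
            f"correct  {self.correct.mean:.3f}  {self.correct.sd:.3f}  {self.correct.n}"
        )
        lines.append(
            f"incorrect  {self.incorrect.mean:.3f}  {self.incorrect.sd:.3f}  "
            f"{self.incorrect.n}"
        )
        if self.t_test_note:
            lines.append(f"t-test: {self.t_test_note}")
        else:
            lines.append(f"t = {self.t_statistic:.4f}, p = {self.p_value:.6g}")
        return "\n".join(lines)


def pooled_mean(groups: Iterable[tuple[float, int]]) -> float:
    """Size-weighted mean of group means."""
    num = sum(m * n for m, n in groups)
    den = sum(n for _, n in groups)
    if den == 0:
        raise ValidationError("pooled mean of empty groups")
    return num / den


def _group_stats(values: Sequence[float]) -> GroupStats:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupStats(mean=float(arr.mean()), sd=sd, n=len(arr))


def similarity_group_analysis(
    outcomes: Sequence[str],
    scores: Sequence[float],
    welch: bool = False,
) -> SimilarityGroupAnalysis:
    """Mean +/- sd of similarity scores per outcome group and pooled.

    ``outcomes`` contains TP/TN/FP/FN tags; the pooled correct group is
    TP+TN and incorrect is FP+FN, compared by a two-sided two-sample
    t-test (Student's pooled-variance by default, Welch optionally).
    """
    if len(outcomes) != len(scores):
        raise ValidationError("outcomes and scores differ in length")
    by_group: dict[str, list[float]] = {}
    for o, s in zip(outcomes, scores):
        if o not in ("TP", "TN", "FP", "FN"):
            raise ValidationError(f"unknown outcome tag {o!r}")
        by_group.setdefault(o, []).append(float(s))
    per_group = {g: _group_stats(v) for g, v in by_group.items()}
    correct = [s for o, s in zip(outcomes, scores) if o in ("TP", "TN")]
    incorrect = [s for o, s in zip(outcomes, scores) if o in ("FP", "FN")]
    if not correct or not incorrect:
        raise ValidationError("both pooled groups must be non-empty")
    t_stat, p_val, note = float("nan"), float("nan"), ""
    if len(correct) < 2 or len(incorrect) < 2:
        note = "skipped: a pooled group has fewer than 2 compounds"
    elif np.var(correct) == 0.0 and np.var(incorrect) == 0.0:
        if np.mean(correct) == np.mean(incorrect):
            t_stat, p_val = 0.0, 1.0  # identical degenerate groups
        else:
            note = "skipped: zero variance in both groups"
    else:
        res = sps.ttest_ind(correct, incorrect, equal_var=not welch)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        if math.isnan(t_stat):
            if np.isclose(np.mean(correct), np.mean(incorrect)):
                t_stat, p_val = 0.0, 1.0  # identical degenerate groups
            else:
                note = "skipped: zero variance in both groups"
    return SimilarityGroupAnalysis(
        per_group=per_group,
        correct=_group_stats(correct),
        incorrect=_group_stats(incorrect),
        t_statistic=t_stat,
        p_value=p_val,
        t_test_note=note,
    )
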