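"""Applicability-domain battery.

Three independent checks per query compound:

1. descriptor-range check against the model's training ranges
   (closed interval: values exactly at the training min/max are in);
2. the six most similar training compounds with their similarity
   breakdowns;
3. a local-error report — experimental versus model-predicted class
   for those neighbours, flagging in particular any false negative
   nearby ("the model under-predicts toxicity for similar compounds").

The battery annotates rather than vetoes: every failure path produces
a remark, never an exception, so a report row always exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from devtox.chem_io import CompoundSet, MoleculeRecord, ValidationError
from devtox.similarity import NeighborReport, k_nearest


@dataclass(frozen=True)
class RangeOffender:
    name: str
    value: float
    train_min: float
    train_max: float


@dataclass(frozen=True)
class LocalError:
    neighbor_id: str
    experimental_class: str | None
    predicted_class: str | None
    correct: bool | None
    direction: str  # "", "false_negative_like", "false_positive_like"


@dataclass
class ADReport:
    query_id: str
    in_range: bool
    offending_descriptors: list[RangeOffender]
    neighbors: NeighborReport
    local_errors: list[LocalError]
    remarks: str


def range_check(
    ranges: Mapping[str, tuple[float, float]],
    point: Mapping[str, float],
) -> tuple[bool, list[RangeOffender]]:
    """Closed-interval descriptor-range check against training ranges."""
    offenders: list[RangeOffender] = []
    for name, (mn, mx) in ranges.items():
        if name not in point:
            raise ValidationError(f"descriptor {name!r} missing from query vector")
        x = float(point[name])
        if x != x or x < mn or x > mx:  # NaN or strictly outside
            offenders.append(RangeOffender(name, x, mn, mx))
    return (not offenders, offenders)


def local_error_report(
    neighbors: NeighborReport,
    train_predictions: Mapping[str, str],
) -> tuple[list[LocalError], str]:
    """Experimental-vs-predicted comparison for each neighbour.

    Returns the per-neighbour records and a directional summary:
    "locally reliable" when every neighbour is predicted correctly,
    an under-prediction warning when any neighbour is a false negative
    (experimental toxicant predicted non-toxic).
    """
    errors: list[LocalError] = []
    for nb in neighbors.neighbors:
        pred = nb.predicted_class or train_predictions.get(nb.id)
        exp = nb.experimental_class
        if pred is None or exp is None:
            errors.append(LocalError(nb.id, exp, pred, None, ""))
            continue
        correct = pred == exp
        direction = ""
        if not correct:
            direction = (
                "false_negative_like" if exp == "D" else "false_positive_like"
            )
        errors.append(LocalError(nb.id, exp, pred, correct, direction))
    n_known = sum(1 for e in errors if e.correct is not None)
    n_fn = sum(1 for e in errors if e.direction == "false_negative_like")
    n_wrong = sum(1 for e in errors if e.correct is False)
    if n_known == 0:
        summary = "no neighbour predictions available"
    elif n_fn > 0:
        summary = (
            f"model under-predicts toxicity nearby "
            f"({n_fn} false-negative neighbour{'s' if n_fn > 1 else ''}); "
            "the prediction should not be trusted"
        )
    elif n_wrong > 0:
        summary = f"{n_wrong} neighbour(s) mispredicted (false-positive-like)"
    else:
        summary = "locally reliable: all neighbours predicted correctly"
    if len(errors) < 6:
        summary += f" [only {len(errors)} training neighbours available]"
    return errors, summary


def assess(
    query: MoleculeRecord,
    descriptor_point: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]],
    train: CompoundSet,
    train_predictions: Mapping[str, str],
    k: int = 6,
) -> ADReport:
    """Run the full three-tool battery for one query compound."""
    in_range, offenders = range_check(ranges, descriptor_point)
    neighbors = k_nearest(
        query, train, k=k, include_self=False, predictions=dict(train_predictions)
    )
    local_errors, local_summary = local_error_report(neighbors, train_predictions)
    remarks: list[str] = []
    if not in_range:
        names = ", ".join(o.name for o in offenders)
        remarks.append(
            f"out of applicability domain: descriptor(s) {names} outside the "
            "training range"
        )
    top = neighbors.neighbors[0].breakdown.s if neighbors.neighbors else 0.0
    if top < 0.5:
        remarks.append(
            f"no similar training compound (best similarity {top:.2f})"
        )
    if "under-predicts" in local_summary or "mispredicted" in local_summary:
        remarks.append(local_summary)
    remark_text = "; ".join(remarks) if remarks else "none"
    return ADReport(
        query_id=query.id,
        in_range=in_range,
        offending_descriptors=offenders,
        neighbors=neighbors,
        local_errors=local_errors,
        remarks=remark_text,
    )
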