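"""Four-component molecular similarity index.

The combined score ``S`` is a weight-normalised linear utility over
four Tanimoto sub-indices, each in [0, 1]:

* ``FGs`` — functional-group occurrence counts,
* ``Cs``  — the 13 constitutional atom counts,
* ``Rs``  — the 13 ring counts,
* ``FPs`` — hashed linear-path fingerprints (1024 bits, depth 7).

Count vectors use the continuous Tanimoto u.v / (|u|^2 + |v|^2 - u.v);
bit vectors the set form c / (a + b - c).  Two molecules with identical
graphs score exactly 1.  Weights default to (1, 1, 1, 1); the utility
is S = sum(w_i * sub_i) / sum(w_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from devtox.chem_io import CompoundSet, MoleculeRecord, ValidationError
from devtox.descriptors import atom_counts, functional_group_counts, ring_counts
from devtox.fingerprints import Fingerprint, path_fingerprint

DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0)


def tanimoto_counts(u: Sequence[float], v: Sequence[float]) -> float:
    """Continuous Tanimoto for non-negative count vectors.

    Two all-zero vectors (identical empty profiles) score 1.
    """
    ua = np.asarray(u, dtype=float)
    va = np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValidationError(f"length mismatch: {ua.shape} vs {va.shape}")
    if (ua < 0).any() or (va < 0).any():
        raise ValidationError("count vectors must be non-negative")
    dot = float(ua @ va)
    denom = float(ua @ ua) + float(va @ va) - dot
    if denom == 0.0:
        return 1.0
    return dot / denom


def tanimoto_bits(a: Fingerprint, b: Fingerprint) -> float:
    """Set Tanimoto c/(na+nb-c) on fingerprints; both-empty scores 1."""
    if a.nbits != b.nbits:
        raise ValidationError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    common = len(a.bits & b.bits)
    denom = len(a.bits) + len(b.bits) - common
    if denom == 0:
        return 1.0
    return common / denom


@dataclass(frozen=True)
class SimilarityBreakdown:
    """The four sub-indices and the combined score."""

    fgs: float
    cs: float
    rs: float
    fps: float
    s: float
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS


@dataclass(frozen=True)
class Neighbor:
    id: str
    breakdown: SimilarityBreakdown
    experimental_class: str | None = None
    predicted_class: str | None = None


@dataclass
class NeighborReport:
    """Top-k most similar training compounds, sorted by S descending."""

    query_id: str
    neighbors: list[Neighbor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.neighbors)


class _Profile:
    """Cached per-molecule similarity inputs."""

    __slots__ = ("fg", "atoms", "rings", "fp")

    def __init__(self, mol: MoleculeRecord):
        m = mol.mol
        self.fg = list(functional_group_counts(m).values())
        self.atoms = list(atom_counts(m).values())
        self.rings = list(ring_counts(m).values())
        self.fp = path_fingerprint(m)


_profile_cache: dict[str, _Profile] = {}


def _profile(mol: MoleculeRecord) -> _Profile:
    prof = _profile_cache.get(mol.smiles)
    if prof is None:
        prof = _Profile(mol)
        _profile_cache[mol.smiles] = prof
    return prof


def similarity_score(
    query: MoleculeRecord,
    ref: MoleculeRecord,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> SimilarityBreakdown:
    """Four sub-indices and the weighted combined score for a molecule pair."""
    w = tuple(float(x) for x in weights)
    if len(w) != 4 or any(x <= 0 for x in w):
        raise ValidationError("weights must be four positive reals")
    pq, pr = _profile(query), _profile(ref)
    fgs = tanimoto_counts(pq.fg, pr.fg)
    cs = tanimoto_counts(pq.atoms, pr.atoms)
    rs = tanimoto_counts(pq.rings, pr.rings)
    fps = tanimoto_bits(pq.fp, pr.fp)
    s = (w[0] * fgs + w[1] * cs + w[2] * rs + w[3] * fps) / sum(w)
    return SimilarityBreakdown(fgs=fgs, cs=cs, rs=rs, fps=fps, s=s, weights=w)


def k_nearest(
    query: MoleculeRecord,
    train: CompoundSet,
    k: int = 6,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    include_self: bool = True,
    predictions: dict[str, str] | None = None,
) -> NeighborReport:
    """The k most similar training compounds for a query.

    Ties are broken deterministically by (score descending, id
    ascending).  With ``include_self=False`` a training record with the
    query's id is excluded (for assessing a compound against the pool
    it came from).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(train) == 0:
        raise ValidationError("training set is empty")
    scored: list[Neighbor] = []
    for rec in train:
        if not include_self and rec.id == query.id:
            continue
        bd = similarity_score(query, rec, weights)
        scored.append(
            Neighbor(
                id=rec.id,
                breakdown=bd,
                experimental_class=rec.binary_class,
                predicted_class=(predictions or {}).get(rec.id),
            )
        )
    scored.sort(key=lambda nb: (-nb.breakdown.s, nb.id))
    return NeighborReport(query_id=query.id, neighbors=scored[:k])


def mean_neighbor_similarity(
    query: MoleculeRecord,
    pool: CompoundSet,
    top: int = 3,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    include_self: bool = False,
) -> float:
    """Mean similarity of the ``top`` most similar pool compounds."""
    report = k_nearest(
        query, pool, k=top, weights=weights, include_self=include_self
    )
    if len(report) < top:
        raise ValidationError(
            f"pool provides only {len(report)} compounds, need {top}"
        )
    return float(np.mean([nb.breakdown.s for nb in report.neighbors]))


def neighbor_report_rows(report: NeighborReport) -> list[dict]:
    """Flatten a neighbour report for TSV export."""
    rows = []
    for rank, nb in enumerate(report.neighbors, start=1):
        bd = nb.breakdown
        rows.append(
            {
                "query_id": report.query_id,
                "rank": rank,
                "neighbor_id": nb.id,
                "s": bd.s,
                "fgs": bd.fgs,
                "cs": bd.cs,
                "rs": bd.rs,
                "fps": bd.fps,
                "experimental_class": nb.experimental_class or "",
                "predicted_class": nb.predicted_class or "",
            }
        )
    return rows
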