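"""2D molecular descriptors.

Implements the descriptor families consumed by the classifiers and by
the similarity index:

* constitutional atom counts (nH, nC, ..., nX) and ring counts
  (nCIC, nCIR, nR03..nR12, nBnz);
* functional-group occurrence counts against a SMARTS catalog;
* Burden-matrix extreme eigenvalues (BEHwk / BELwk) weighted by atomic
  mass, polarizability, van der Waals volume or Sanderson
  electronegativity, all scaled relative to carbon;
* Broto-Moreau (ATS), Moran (MATS) and Geary (GATS) topological
  autocorrelations over the H-depleted graph distance matrix;
* Kier-Hall electrotopological states and the atom-type sums SsOH,
  SdssC, ShssNH plus the molecular minimum Gmin;
* Icycem, the mean information on vertex cycle-membership equality.

Cells that are structurally undefined for a molecule (an eigenvalue
rank above the atom count, an autocorrelation at an unpopulated lag)
are reported as NaN; model layers treat such compounds as outside the
applicability domain.
"""

from __future__ import annotations

import math
import re
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from devtox.atomdata import SCHEME_CODES, carbon_scaled
from devtox.chem_io import CompoundSet, MoleculeRecord
from devtox.fgroups import DEFAULT_CATALOG, compile_catalog, group_counts


class ConfigurationError(ValueError):
    """Bad descriptor name, pattern or parameter."""


ATOM_COUNT_NAMES = (
    "nH", "nC", "nN", "nO", "nP", "nS", "nF", "nCL", "nBR", "nI", "nB", "nHM", "nX",
)
RING_COUNT_NAMES = (
    "nCIC", "nCIR", "nR03", "nR04", "nR05", "nR06", "nR07", "nR08", "nR09",
    "nR10", "nR11", "nR12", "nBnz",
)

#: 13-descriptor preset of the random-forest model.
RF_DESCRIPTORS = (
    "Icycem", "BEHm1", "BELp3", "BELv1", "BELv8", "GATS1p", "GATS2m",
    "GATS3v", "MATS1p", "MATS4p", "MATS4v", "SdssC", "ShssNH",
)
#: 6-descriptor preset of the adaptive-fuzzy-partition model.
AFP_DESCRIPTORS = ("SsOH", "Gmin", "BEHv1", "BELe1", "BELp2", "ATS8m")

_ORGANIC_SET = {"H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "B"}
_HALOGENS = {"F", "Cl", "Br", "I"}


def _as_mol(mol: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    return mol.mol if isinstance(mol, MoleculeRecord) else mol


# ---------------------------------------------------------------------------
# Constitutional counts


def atom_counts(mol: MoleculeRecord | Chem.Mol) -> dict[str, int]:
    """The 13 constitutional atom counts.

    ``nX`` is the total halogen count and ``nHM`` counts heteroatoms
    outside the common organic set (heavy metals / metalloids).
    """
    m = _as_mol(mol)
    counts = dict.fromkeys(ATOM_COUNT_NAMES, 0)
    for atom in m.GetAtoms():
        sym = atom.GetSymbol()
        counts["nH"] += atom.GetTotalNumHs()
        if sym == "C":
            counts["nC"] += 1
        elif sym == "N":
            counts["nN"] += 1
        elif sym == "O":
            counts["nO"] += 1
        elif sym == "P":
            counts["nP"] += 1
        elif sym == "S":
            counts["nS"] += 1
        elif sym == "F":
            counts["nF"] += 1
        elif sym == "Cl":
            counts["nCL"] += 1
        elif sym == "Br":
            counts["nBR"] += 1
        elif sym == "I":
            counts["nI"] += 1
        elif sym == "B":
            counts["nB"] += 1
        elif sym == "H":
            counts["nH"] += 1
        else:
            counts["nHM"] += 1
        if sym in _HALOGENS:
            counts["nX"] += 1
    return counts


def ring_counts(mol: MoleculeRecord | Chem.Mol) -> dict[str, int]:
    """Ring census: cyclomatic number, SSSR size distribution, benzene rings."""
    m = _as_mol(mol)
    counts = dict.fromkeys(RING_COUNT_NAMES, 0)
    n_atoms = m.GetNumAtoms()
    n_bonds = m.GetNumBonds()
    n_frags = len(Chem.GetMolFrags(m))
    counts["nCIC"] = n_bonds - n_atoms + n_frags
    rings = m.GetRingInfo().AtomRings()
    counts["nCIR"] = len(rings)
    for ring in rings:
        size = len(ring)
        if 3 <= size <= 12:
            counts[f"nR{size:02d}"] += 1
        if size == 6 and all(
            m.GetAtomWithIdx(i).GetIsAromatic()
            and m.GetAtomWithIdx(i).GetSymbol() == "C"
            for i in ring
        ):
            counts["nBnz"] += 1
    return counts


def functional_group_counts(
    mol: MoleculeRecord | Chem.Mol,
    catalog: Iterable = DEFAULT_CATALOG,
) -> dict[str, int]:
    """Occurrence counts of every named group of the catalog."""
    compiled = compile_catalog(tuple(catalog))
    return group_counts(_as_mol(mol), compiled)


# ---------------------------------------------------------------------------
# Burden-matrix eigenvalues

_BOND_CONSTANTS = {
    Chem.BondType.SINGLE: 0.1,
    Chem.BondType.DOUBLE: 0.2,
    Chem.BondType.TRIPLE: 0.3,
    Chem.BondType.AROMATIC: 0.15,
}
_NONBONDED = 0.001
_TERMINAL_BONUS = 0.01


def burden_matrix(mol: MoleculeRecord | Chem.Mol, scheme: str) -> np.ndarray:
    """The Burden connectivity matrix of the H-depleted graph.

    Diagonal: carbon-scaled atomic property of the chosen weighting
    scheme.  Off-diagonal: 0.1/0.2/0.3/0.15 for single/double/triple/
    aromatic bonds (+0.01 when one partner is terminal), 0.001 for
    non-bonded pairs.
    """
    m = _as_mol(mol)
    n = m.GetNumAtoms()
    if n == 0:
        raise ConfigurationError("empty molecule")
    B = np.full((n, n), _NONBONDED)
    for i, atom in enumerate(m.GetAtoms()):
        B[i, i] = carbon_scaled(atom.GetSymbol(), scheme)
    degrees = [a.GetDegree() for a in m.GetAtoms()]
    for bond in m.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        val = _BOND_CONSTANTS.get(bond.GetBondType(), 0.1)
        if degrees[i] == 1 or degrees[j] == 1:
            val += _TERMINAL_BONUS
        B[i, j] = B[j, i] = val
    return B


def burden_eigenvalues(
    mol: MoleculeRecord | Chem.Mol,
    scheme: str,
    ranks: Sequence[int],
    highest: bool = True,
) -> list[float]:
    """Requested Burden eigenvalues, by rank from the top (BEH) or bottom (BEL).

    A rank exceeding the heavy-atom count yields NaN for that entry.
    """
    eigs = np.linalg.eigvalsh(burden_matrix(mol, scheme))  # ascending
    n = len(eigs)
    out = []
    for r in ranks:
        if r < 1:
            raise ConfigurationError(f"eigenvalue rank must be >= 1, got {r}")
        if r > n:
            out.append(float("nan"))
        elif highest:
            out.append(float(eigs[n - r]))
        else:
            out.append(float(eigs[r - 1]))
    return out


# ---------------------------------------------------------------------------
# 2D autocorrelations

def broto_moreau(dist: np.ndarray, w: np.ndarray, lag: int) -> float:
    """ATS: sum of w_i * w_j over unordered atom pairs at topological distance lag."""
    mask = np.triu(dist == lag, k=1)
    if not mask.any():
        return 0.0
    ii, jj = np.nonzero(mask)
    return float(np.sum(w[ii] * w[jj]))


def moran(dist: np.ndarray, w: np.ndarray, lag: int) -> float:
    """MATS: Moran spatial autocorrelation coefficient at the given lag.

    NaN when no atom pair sits at the lag or the weights have zero
    variance (the centred-variance convention leaves it undefined).
    """
    mask = (dist == lag) & ~np.eye(len(w), dtype=bool)
    delta = int(mask.sum())  # ordered pairs
    dev = w - w.mean()
    var = float(np.sum(dev**2)) / len(w)
    if delta == 0 or var <= 0.0:
        return float("nan")
    num = float(np.sum(np.outer(dev, dev)[mask])) / delta
    return num / var


def geary(dist: np.ndarray, w: np.ndarray, lag: int) -> float:
    """GATS: Geary spatial autocorrelation coefficient at the given lag."""
    n = len(w)
    mask = (dist == lag) & ~np.eye(n, dtype=bool)
    delta = int(mask.sum())
    dev = w - w.mean()
    denom = float(np.sum(dev**2)) / (n - 1) if n > 1 else 0.0
    if delta == 0 or denom <= 0.0:
        return float("nan")
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = float(np.sum(diff2[mask])) / (2 * delta)
    return num / denom


_AUTOCORR_FUNCS: dict[str, Callable[[np.ndarray, np.ndarray, int], float]] = {
    "ATS": broto_moreau,
    "MATS": moran,
    "GATS": geary,
}


def autocorrelation_2d(
    mol: MoleculeRecord | Chem.Mol, kind: str, lag: int, scheme: str
) -> float:
    """Topological autocorrelation over the H-depleted graph.

    Atom weights are the carbon-scaled atomic properties of ``scheme``.
    """
    if kind not in _AUTOCORR_FUNCS:
        raise ConfigurationError(f"unknown autocorrelation kind {kind!r}")
    if lag < 1:
        raise ConfigurationError("lag must be >= 1")
    m = _as_mol(mol)
    w = np.array([carbon_scaled(a.GetSymbol(), scheme) for a in m.GetAtoms()])
    if len(w) < 2:
        return 0.0 if kind == "ATS" else float("nan")
    dist = Chem.GetDistanceMatrix(m)
    return _AUTOCORR_FUNCS[kind](dist, w, lag)


# ---------------------------------------------------------------------------
# Electrotopological state

def _principal_quantum_number(atomic_num: int) -> int:
    for shell_max, period in ((2, 1), (10, 2), (18, 3), (36, 4), (54, 5), (86, 6)):
        if atomic_num <= shell_max:
            return period
    return 7


def estate_values(mol: MoleculeRecord | Chem.Mol) -> np.ndarray:
    """Per-heavy-atom Kier-Hall electrotopological state values.

    Intrinsic state I = ((2/L)^2 * dv + 1) / d with L the principal
    quantum number, dv the valence-electron count minus attached
    hydrogens and d the heavy-atom connectivity (taken as 1 for an
    isolated heavy atom); the field effect perturbation is
    sum_j (I_i - I_j)/(d_ij + 1)^2 over topological distances.
    """
    m = _as_mol(mol)
    n = m.GetNumAtoms()
    I = np.zeros(n)
    tbl = Chem.GetPeriodicTable()
    for i, atom in enumerate(m.GetAtoms()):
        z = atom.GetAtomicNum()
        dv = tbl.GetNOuterElecs(z) - atom.GetTotalNumHs()
        d = max(atom.GetDegree(), 1)
        L = _principal_quantum_number(z)
        I[i] = ((2.0 / L) ** 2 * dv + 1.0) / d
    if n == 1:
        return I
    dist = Chem.GetDistanceMatrix(m)
    S = I.copy()
    for i in range(n):
        S[i] += float(np.sum((I[i] - I) / (dist[i] + 1.0) ** 2))
    return S


_ESTATE_TYPE_SMARTS = {
    "SsOH": "[OX2H1]",
    "SdssC": "[CX3H0;!a](=*)",
    "ShssNH": "[NX3H1;!a]([#6,#7,#8,#16])[#6,#7,#8,#16]",
}


def estate_indices(mol: MoleculeRecord | Chem.Mol) -> dict[str, float]:
    """Atom-type E-state sums (SsOH, SdssC, ShssNH) and the minimum Gmin."""
    m = _as_mol(mol)
    S = estate_values(m)
    out: dict[str, float] = {}
    for name, smarts in _ESTATE_TYPE_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        matched = {match[0] for match in m.GetSubstructMatches(patt)}
        out[name] = float(sum(S[i] for i in matched))
    out["Gmin"] = float(S.min()) if len(S) else 0.0
    return out


# ---------------------------------------------------------------------------
# Cycle information index

def cycle_info_index(mol: MoleculeRecord | Chem.Mol) -> float:
    """Icycem: mean information on vertex cycle-membership equality.

    Vertices are partitioned by identical SSSR ring-membership rows; the
    value is the Shannon mean information -sum (n_g/n) log2 (n_g/n) over
    the partition class sizes.  Acyclic molecules (one all-zero class)
    score 0.
    """
    m = _as_mol(mol)
    n = m.GetNumAtoms()
    if n == 0:
        return 0.0
    rings = m.GetRingInfo().AtomRings()
    rows: dict[tuple[bool, ...], int] = {}
    for i in range(n):
        row = tuple(i in ring for ring in rings)
        rows[row] = rows.get(row, 0) + 1
    info = 0.0
    for count in rows.values():
        p = count / n
        info -= p * math.log2(p)
    return info


# ---------------------------------------------------------------------------
# Descriptor name registry and matrix assembly

_BURDEN_RE = re.compile(r"^(BEH|BEL)([mpve])(\d+)$")
_AUTOCORR_RE = re.compile(r"^(ATS|MATS|GATS)(\d+)([mpve])$")
_ESTATE_NAMES = ("SsOH", "SdssC", "ShssNH", "Gmin")


def compute_descriptor(mol: MoleculeRecord | Chem.Mol, name: str) -> float:
    """Compute a single named descriptor; raises on unknown names."""
    if name in ATOM_COUNT_NAMES:
        return float(atom_counts(mol)[name])
    if name in RING_COUNT_NAMES:
        return float(ring_counts(mol)[name])
    if name in _ESTATE_NAMES:
        return estate_indices(mol)[name]
    if name == "Icycem":
        return cycle_info_index(mol)
    m = _BURDEN_RE.match(name)
    if m:
        kind, code, rank = m.group(1), m.group(2), int(m.group(3))
        return burden_eigenvalues(
            mol, SCHEME_CODES[code], [rank], highest=(kind == "BEH")
        )[0]
    m = _AUTOCORR_RE.match(name)
    if m:
        kind, lag, code = m.group(1), int(m.group(2)), m.group(3)
        return autocorrelation_2d(mol, kind, lag, SCHEME_CODES[code])
    if name.startswith("fg_"):
        gname = name[3:]
        counts = functional_group_counts(mol)
        if gname not in counts:
            raise ConfigurationError(f"unknown functional group {gname!r}")
        return float(counts[gname])
    raise ConfigurationError(f"unknown descriptor name {name!r}")


def descriptor_vector(
    mol: MoleculeRecord | Chem.Mol, names: Sequence[str]
) -> dict[str, float]:
    return {name: compute_descriptor(mol, name) for name in names}


def build_matrix(cset: CompoundSet, names: Sequence[str]) -> pd.DataFrame:
    """Descriptor matrix for a compound set (rows in set order).

    Structurally undefined cells are NaN; downstream model layers flag
    the affected compounds as not predictable rather than imputing.
    """
    if not names:
        raise ConfigurationError("requested descriptor list is empty")
    rows = [descriptor_vector(rec, names) for rec in cset]
    return pd.DataFrame(rows, index=pd.Index(cset.ids, name="id"), columns=list(names))


def write_matrix(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
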