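"""Hashed linear-path fingerprints.

Daylight-style fingerprint: every simple linear atom-bond path of 1 to
``depth`` atoms is enumerated, written as a canonical label (the
lexicographic minimum of the forward and reversed element/bond string)
and hashed to one of ``nbits`` positions with a stable 64-bit hash, so
the same structure always lights the same bits on any platform.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from devtox.chem_io import MoleculeRecord

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


class FingerprintConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length bit vector with its generation parameters."""

    bits: frozenset[int]
    nbits: int = 1024
    depth: int = 7

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=bool)
        arr[list(self.bits)] = True
        return arr


def _stable_hash(label: str) -> int:
    digest = hashlib.blake2b(label.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def _atom_label(atom: Chem.Atom) -> str:
    sym = atom.GetSymbol()
    return sym.lower() if atom.GetIsAromatic() else sym


def _enumerate_paths(mol: Chem.Mol, depth: int) -> set[str]:
    """Canonical labels of all simple paths of 1..depth atoms."""
    labels: set[str] = set()
    atom_syms = [_atom_label(a) for a in mol.GetAtoms()]
    adjacency: list[list[tuple[int, str]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        sym = _BOND_SYMBOL.get(bond.GetBondType(), "-")
        adjacency[i].append((j, sym))
        adjacency[j].append((i, sym))

    def dfs(path: list[int], label_parts: list[str]) -> None:
        forward = "".join(label_parts)
        backward = "".join(reversed(label_parts))
        labels.add(min(forward, backward))
        if len(path) == depth:
            return
        last = path[-1]
        for nbr, bsym in adjacency[last]:
            if nbr in path:
                continue
            dfs(path + [nbr], label_parts + [bsym, atom_syms[nbr]])

    for start in range(mol.GetNumAtoms()):
        dfs([start], [atom_syms[start]])
    return labels


def path_fingerprint(
    mol: MoleculeRecord | Chem.Mol, nbits: int = 1024, depth: int = 7
) -> Fingerprint:
    """Hashed linear-path fingerprint (defaults: 1024 bits, paths up to 7 atoms)."""
    if nbits < 1 or (nbits & (nbits - 1)) != 0:
        raise FingerprintConfigError(f"nbits must be a positive power of two, got {nbits}")
    if depth < 1:
        raise FingerprintConfigError("depth must be >= 1")
    m = mol.mol if isinstance(mol, MoleculeRecord) else mol
    bits = frozenset(_stable_hash(lbl) % nbits for lbl in _enumerate_paths(m, depth))
    return Fingerprint(bits=bits, nbits=nbits, depth=depth)
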