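"""Functional-group substructure catalog.

A configurable ordered catalog of named SMARTS patterns.  The default
~30-entry catalog covers the common functional-group blocks used both
for the functional-group similarity sub-index (occurrence counts) and,
through its priority order, as the structural class key of the rational
train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem


class CatalogError(ValueError):
    """Raised when a catalog pattern does not compile."""


@dataclass(frozen=True)
class GroupPattern:
    name: str
    smarts: str

    def compile(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise CatalogError(f"invalid SMARTS for group {self.name!r}: {self.smarts}")
        return patt


# Priority order matters for the split's class key: more specific /
# higher-priority chemotypes first.
DEFAULT_CATALOG: tuple[GroupPattern, ...] = (
    GroupPattern("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    GroupPattern("ester", "[CX3](=O)[OX2H0][#6]"),
    GroupPattern("amide", "[CX3](=O)[NX3]"),
    GroupPattern("aldehyde", "[CX3H1](=O)[#6]"),
    GroupPattern("ketone", "[#6][CX3](=O)[#6]"),
    GroupPattern("carbamate", "[NX3][CX3](=O)[OX2]"),
    GroupPattern("urea", "[NX3][CX3](=O)[NX3]"),
    GroupPattern("nitrile", "[NX1]#[CX2]"),
    GroupPattern("nitro", "[NX3](=O)=O"),
    GroupPattern("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    GroupPattern("sulfone", "[SX4](=O)(=O)([#6])[#6]"),
    GroupPattern("sulfoxide", "[SX3](=O)([#6])[#6]"),
    GroupPattern("thiol", "[SX2H1]"),
    GroupPattern("thioether", "[SX2H0]([#6])[#6]"),
    GroupPattern("phosphate", "[PX4](=O)([OX2])([OX2])[OX2]"),
    GroupPattern("primary_amine", "[NX3H2;!$(NC=O)]"),
    GroupPattern("secondary_amine", "[NX3H1;!$(NC=O)]([#6])[#6]"),
    GroupPattern("tertiary_amine", "[NX3H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]"),
    GroupPattern("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    GroupPattern("imine", "[CX3]=[NX2]"),
    GroupPattern("phenol", "[OX2H1][c]"),
    GroupPattern("hydroxyl", "[OX2H1][CX4]"),
    GroupPattern("ether", "[OD2]([#6])[#6]"),
    GroupPattern("epoxide", "[OX2r3]1[#6r3][#6r3]1"),
    GroupPattern("halide_aromatic", "[F,Cl,Br,I][c]"),
    GroupPattern("halide_aliphatic", "[F,Cl,Br,I][CX4]"),
    GroupPattern("alkene", "[CX3]=[CX3]"),
    GroupPattern("alkyne", "[CX2]#[CX2]"),
    GroupPattern("aromatic_n_heterocycle", "[nX2,nX3]"),
    GroupPattern("aromatic_o_heterocycle", "[o]"),
    GroupPattern("aromatic_s_heterocycle", "[s]"),
    GroupPattern("benzene_ring", "c1ccccc1"),
)


def compile_catalog(
    catalog: tuple[GroupPattern, ...] = DEFAULT_CATALOG,
) -> list[tuple[str, Chem.Mol]]:
    """Compile an ordered catalog into (name, query) pairs, validating SMARTS."""
    return [(g.name, g.compile()) for g in catalog]


def group_counts(mol: Chem.Mol, compiled: list[tuple[str, Chem.Mol]]) -> dict[str, int]:
    """Occurrence count (unique substructure matches) per catalog group."""
    return {
        name: len(mol.GetSubstructMatches(patt, uniquify=True))
        for name, patt in compiled
    }


def first_matching_group(
    mol: Chem.Mol, compiled: list[tuple[str, Chem.Mol]]
) -> int:
    """Index of the highest-priority matching group; len(catalog) if none match."""
    for idx, (_, patt) in enumerate(compiled):
        if mol.HasSubstructMatch(patt):
            return idx
    return len(compiled)
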