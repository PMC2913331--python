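"""Reading, curating and labelling molecule collections.

Structures come in as SMILES lines (``.smi``) or SDF (V2000); each record
optionally carries an FDA pregnancy category (A/B/C/D/X) or a binary
developmental-toxicity class (``N`` non-toxicant / ``D`` toxicant).
Curation strips inorganic counter-ions and water from salt entries and
keeps the largest organic fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

FDA_CATEGORIES = ("A", "B", "C", "D", "X")

#: FDA pregnancy category -> binary developmental-toxicity class.
#: A and B merge into the non-toxicant class N; C, D and X into toxicant D.
FDA_TO_BINARY = {"A": "N", "B": "N", "C": "D", "D": "D", "X": "D"}


class ParseError(ValueError):
    """Raised when no valid molecule can be read from the input."""


class ValidationError(ValueError):
    """Raised on inconsistent labels, duplicate ids or bad arguments."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed structure with identifiers and optional toxicity labels."""

    id: str
    smiles: str
    name: str | None = None
    fda_category: str | None = None
    binary_class: str | None = None

    def __post_init__(self) -> None:
        if self.fda_category is not None and self.fda_category not in FDA_CATEGORIES:
            raise ValidationError(
                f"unknown FDA category {self.fda_category!r} for {self.id}"
            )
        if self.binary_class is not None and self.binary_class not in ("N", "D"):
            raise ValidationError(
                f"binary class must be 'N' or 'D', got {self.binary_class!r}"
            )
        if self.fda_category is not None and self.binary_class is not None:
            if FDA_TO_BINARY[self.fda_category] != self.binary_class:
                raise ValidationError(
                    f"{self.id}: binary class {self.binary_class} inconsistent "
                    f"with FDA category {self.fda_category}"
                )

    @property
    def mol(self) -> Chem.Mol:
        """The RDKit molecule (parsed lazily from the stored SMILES)."""
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - smiles is validated on construction
            raise ParseError(f"stored SMILES unparseable: {self.smiles!r}")
        return m

    def with_labels(
        self, fda_category: str | None = None, binary_class: str | None = None
    ) -> "MoleculeRecord":
        if fda_category is not None and binary_class is None:
            binary_class = map_fda_to_binary(fda_category)
        return replace(self, fda_category=fda_category, binary_class=binary_class)


@dataclass
class ParseFailure:
    """A rejected input entry with its position and reason."""

    index: int
    text: str
    reason: str


@dataclass
class CompoundSet:
    """An ordered collection of molecule records with unique ids."""

    records: list[MoleculeRecord]
    role: Literal["train", "test", "query"] = "query"
    failures: list[ParseFailure] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> MoleculeRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def labels(self) -> list[str]:
        missing = [r.id for r in self.records if r.binary_class is None]
        if missing:
            raise ValidationError(f"records without binary class: {missing}")
        return [r.binary_class for r in self.records]  # type: ignore[misc]


def map_fda_to_binary(category: str) -> str:
    """Map an FDA pregnancy category to the binary toxicity class.

    Categories A and B map to ``N`` (non-developmental toxicant); C, D and
    X map to ``D`` (developmental toxicant).
    """
    try:
        return FDA_TO_BINARY[category]
    except KeyError:
        raise ValidationError(
            f"unknown FDA category {category!r}; expected one of {FDA_CATEGORIES}"
        ) from None


def _canonical(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def parse_structures(
    source: str | Path,
    fmt: Literal["smi", "sdf"] = "smi",
    role: Literal["train", "test", "query"] = "query",
) -> CompoundSet:
    """Parse a SMILES file/text block or an SDF into a :class:`CompoundSet`.

    ``source`` may be a path or, for ``fmt='smi'``, raw SMILES text (one
    molecule per line, optional whitespace-separated id). Invalid entries
    are collected on ``CompoundSet.failures`` with their line/record
    number; an input yielding zero valid molecules raises
    :class:`ParseError`.
    """
    if fmt not in ("smi", "sdf"):
        raise ValidationError(f"unknown format {fmt!r}")
    if fmt == "smi":
        text = _read_text(source)
        records, failures = _parse_smiles_lines(text.splitlines())
    else:
        path = Path(source)
        if not path.exists():
            raise IOError(f"no such file: {path}")
        records, failures = _parse_sdf(path)
    if not records:
        raise ParseError("no valid molecules in input")
    return CompoundSet(records=records, role=role, failures=failures)


def _read_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    p = Path(source)
    # Heuristic: a short single token that exists on disk is a path.
    if "\n" not in source and p.exists():
        return p.read_text()
    return source


def _parse_smiles_lines(
    lines: Iterable[str],
) -> tuple[list[MoleculeRecord], list[ParseFailure]]:
    records: list[MoleculeRecord] = []
    failures: list[ParseFailure] = []
    n = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else None
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append(ParseFailure(lineno, line, "unparseable SMILES"))
            continue
        n += 1
        records.append(
            MoleculeRecord(
                id=name if name else f"mol{n}",
                smiles=_canonical(mol),
                name=name,
            )
        )
    return records, failures


def _parse_sdf(path: Path) -> tuple[list[MoleculeRecord], list[ParseFailure]]:
    records: list[MoleculeRecord] = []
    failures: list[ParseFailure] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    n = 0
    for idx, mol in enumerate(supplier, start=1):
        if mol is None:
            failures.append(ParseFailure(idx, f"record {idx}", "unparseable SDF record"))
            continue
        n += 1
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
        records.append(
            MoleculeRecord(
                id=name if name else f"mol{n}",
                smiles=_canonical(mol),
                name=name,
            )
        )
    return records, failures


def write_smiles(cset: CompoundSet, path: str | Path) -> None:
    """Write a compound set as a .smi file (SMILES, id per line)."""
    with open(path, "w") as fh:
        for r in cset:
            fh.write(f"{r.smiles}\t{r.id}\n")


def write_sdf(cset: CompoundSet, path: str | Path) -> None:
    """Write a compound set as an SDF (V2000)."""
    writer = Chem.SDWriter(str(path))
    for r in cset:
        mol = r.mol
        mol.SetProp("_Name", r.id)
        writer.write(mol)
    writer.close()


_WATER = {"O", "[H]O[H]", "[OH2]"}


def _is_inorganic_or_water(frag: Chem.Mol) -> bool:
    """True for fragments with no carbon, single-atom ions, or water."""
    smiles = Chem.MolToSmiles(frag)
    if smiles in _WATER:
        return True
    has_carbon = any(a.GetSymbol() == "C" for a in frag.GetAtoms())
    if not has_carbon:
        return True
    if frag.GetNumAtoms() == 1 and frag.GetAtomWithIdx(0).GetFormalCharge() != 0:
        return True
    return False


def curate_record(record: MoleculeRecord) -> MoleculeRecord | None:
    """Strip inorganic counter-ions and water; keep the largest organic fragment.

    Returns ``None`` when no organic fragment survives.
    """
    mol = record.mol
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if not _is_inorganic_or_water(f)]
    if not organic:
        return None
    keep = max(organic, key=lambda f: (f.GetNumAtoms(), Chem.MolToSmiles(f)))
    return replace(record, smiles=_canonical(keep))


def curate(cset: CompoundSet) -> CompoundSet:
    """Curate every record of a set; records with no organic fragment are
    dropped and reported on ``failures``."""
    kept: list[MoleculeRecord] = []
    failures = list(cset.failures)
    for idx, rec in enumerate(cset.records):
        out = curate_record(rec)
        if out is None:
            failures.append(
                ParseFailure(idx, rec.smiles, "no organic fragment after curation")
            )
        else:
            kept.append(out)
    return CompoundSet(records=kept, role=cset.role, failures=failures)


def read_label_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a delimited label table (id, fda_category and/or binary_class)."""
    import csv

    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        reader = csv.DictReader(fh, delimiter=delim)
        out: dict[str, dict[str, str]] = {}
        for row in reader:
            rid = row.get("id") or row.get("ID")
            if rid is None:
                raise ValidationError("label table needs an 'id' column")
            out[rid] = {k: v for k, v in row.items() if k != "id" and v}
    return out


def attach_labels(cset: CompoundSet, labels: dict[str, dict[str, str]]) -> CompoundSet:
    """Attach FDA categories / binary classes from a label table to a set."""
    records = []
    for rec in cset:
        row = labels.get(rec.id, {})
        fda = row.get("fda_category")
        binary = row.get("binary_class")
        if fda is not None and binary is None:
            binary = map_fda_to_binary(fda)
        records.append(replace(rec, fda_category=fda, binary_class=binary))
    return CompoundSet(records=records, role=cset.role, failures=list(cset.failures))
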