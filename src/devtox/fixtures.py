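"""Synthetic test data: toy molecules and planted-structure tables.

``toy_molecules`` returns a fixed set of ~40 small public-knowledge
drug-like structures with hand-assigned N/D labels at roughly the
91:201 class ratio of the developmental-toxicity data set, spanning
halogenated, aromatic, hydroxylated and aminated chemotypes and
including salt entries that exercise the curation rules.

``make_table`` generates descriptor/label matrices with a controlled
number of informative columns (class-conditional normal shifts) and
pure-noise columns, for benchmarking the classifiers and the feature
selectors without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from devtox.chem_io import CompoundSet, MoleculeRecord, curate, map_fda_to_binary
from rdkit import Chem


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted two-class descriptor table."""

    n_compounds: int = 200
    n_descriptors: int = 10
    n_informative: int = 2
    class_balance: float = 0.31  # fraction of class N, mirroring 91:292
    effect_size: float = 3.0  # standardised mean shift on informative columns
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative exceeds n_descriptors")


def make_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic descriptor matrix and N/D labels, deterministic per seed.

    Informative columns are class-conditional normals whose means differ
    by ``effect_size`` standard deviations; the remaining columns are
    label-independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_neg = int(round(spec.class_balance * n))
    y = np.array(["N"] * n_neg + ["D"] * (n - n_neg), dtype=object)
    rng.shuffle(y)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_descriptors))
    shift = spec.effect_size * spec.noise_sd
    toxic = y == "D"
    for j in range(spec.n_informative):
        X[toxic, j] += shift
    cols = [
        f"inf{j+1}" if j < spec.n_informative else f"noise{j+1-spec.n_informative}"
        for j in range(spec.n_descriptors)
    ]
    ids = [f"cmpd{i+1:04d}" for i in range(n)]
    return pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols), y


def make_mechanism_table(spec: SyntheticSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Complementary-mechanism variant of :func:`make_table`.

    Each informative column carries the signature of a different
    toxicity mechanism: the toxicant class is divided evenly among the
    informative columns and only that sub-population is shifted on its
    column.  No single informative descriptor separates the classes on
    its own, so a feature selector must keep all of them — the planted
    ground truth for selection-recovery benchmarks (in the plain
    shifted table the informative columns are mutually redundant and a
    parsimonious selector may legitimately keep just one).
    """
    if spec.n_informative < 1:
        raise ValueError("mechanism table needs at least one informative column")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_neg = int(round(spec.class_balance * n))
    y = np.array(["N"] * n_neg + ["D"] * (n - n_neg), dtype=object)
    rng.shuffle(y)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_descriptors))
    toxic_idx = np.flatnonzero(y == "D")
    rng.shuffle(toxic_idx)
    shift = spec.effect_size * spec.noise_sd
    for j, chunk in enumerate(np.array_split(toxic_idx, spec.n_informative)):
        X[chunk, j] += shift
    cols = [
        f"inf{j+1}" if j < spec.n_informative else f"noise{j+1-spec.n_informative}"
        for j in range(spec.n_descriptors)
    ]
    ids = [f"cmpd{i+1:04d}" for i in range(n)]
    return pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=cols), y


# (smiles, id, fda_category) — public-knowledge toy structures; the FDA
# letters here are illustrative labels for exercising the pipeline, not
# regulatory assignments.
_TOY_SET: tuple[tuple[str, str, str], ...] = (
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin", "C"),
    ("CC(=O)Nc1ccc(O)cc1", "paracetamol", "B"),
    ("CC(C)Cc1ccc(cc1)C(C)C(=O)O", "ibuprofen", "C"),
    ("CN1C(=O)N(C)c2ncn(C)c2C1=O", "caffeine", "B"),
    ("Clc1ccccc1-c1ccc(Cl)cc1", "dichlorobiphenyl", "X"),
    ("OCC(O)CO", "glycerol", "A"),
    ("CCO", "ethanol", "D"),
    ("OC(=O)c1ccccc1O", "salicylic_acid", "C"),
    ("Nc1ccc(cc1)S(N)(=O)=O", "sulfanilamide", "C"),
    ("CCN(CC)CC.Cl", "triethylamine_hcl", "B"),
    ("C[N+](C)(C)CCO.[Cl-]", "choline_chloride", "A"),
    ("Oc1ccc(Cl)cc1", "chlorophenol", "D"),
    ("NCC(=O)O", "glycine", "A"),
    ("CC(N)C(=O)O", "alanine", "A"),
    ("OC(=O)CC(O)(CC(=O)O)C(=O)O.O", "citric_acid_hydrate", "A"),
    ("c1ccc2ccccc2c1", "naphthalene", "C"),
    ("Cc1ccccc1", "toluene", "D"),
    ("c1ccncc1", "pyridine", "C"),
    ("OCCO", "ethylene_glycol", "D"),
    ("ClC(Cl)(Cl)Cl", "carbon_tetrachloride", "X"),
    ("BrCCBr", "dibromoethane", "X"),
    ("CC(=O)C", "acetone", "B"),
    ("O=C1CCCCC1", "cyclohexanone", "C"),
    ("Nc1ccccc1", "aniline", "C"),
    ("OC(=O)c1cc(ccc1O)[N+](=O)[O-]", "nitrosalicylic_acid", "D"),
    ("CN(C)CCCN1c2ccccc2Sc2ccccc21", "promazine_like", "C"),
    ("CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "atenolol_like", "D"),
    ("Fc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1", "haloperidol_like", "C"),
    ("CCC(C)C1(CC)C(=O)NC(=O)NC1=O", "barbiturate_like", "D"),
    ("OCC1OC(O)C(O)C(O)C1O", "glucose", "A"),
    ("CN1CCC[C@H]1c1cccnc1", "nicotine", "D"),
    ("OC(=O)C=Cc1ccccc1", "cinnamic_acid", "B"),
    ("CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", "estradiol_like", "X"),
    ("CC(=O)OCC(COC(C)=O)OC(C)=O", "triacetin", "A"),
    ("O=[N+]([O-])c1ccc(Cl)cc1", "chloronitrobenzene", "D"),
    ("SCC(N)C(=O)O", "cysteine", "B"),
    ("CSCCC(N)C(=O)O", "methionine", "B"),
    ("Ic1ccc(O)c(I)c1", "diiodophenol", "X"),
    ("CCOC(=O)c1ccccc1N", "benzocaine_like", "C"),
    ("CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", "salbutamol_like", "C"),
    ("O=C(O)CCCCCCCCC=C", "undecylenic_acid", "B"),
    ("Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl", "ddt_like", "X"),
)


def toy_molecules(curated: bool = True) -> CompoundSet:
    """The bundled labelled toy compound set (~40 structures).

    Labels derive from the illustrative FDA letters through the A/B->N,
    C/D/X->D mapping; the class balance is close to the 91:201
    toxicant-heavy ratio of the real endpoint.  Salt entries
    (hydrochloride, chloride, hydrate) are included so curation has
    work to do; pass ``curated=False`` to get the raw multi-fragment
    forms.
    """
    records = []
    for smiles, name, fda in _TOY_SET:
        mol = Chem.MolFromSmiles(smiles)
        records.append(
            MoleculeRecord(
                id=name,
                smiles=Chem.MolToSmiles(mol),
                name=name,
                fda_category=fda,
                binary_class=map_fda_to_binary(fda),
            )
        )
    cset = CompoundSet(records=records, role="train")
    return curate(cset) if curated else cset
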