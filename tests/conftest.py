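import numpy as np
import pandas as pd
import pytest

from devtox.chem_io import CompoundSet, MoleculeRecord
from devtox.descriptors import RF_DESCRIPTORS, build_matrix
from devtox.fixtures import SyntheticSpec, make_table, toy_molecules


@pytest.fixture(scope="session")
def toy_set() -> CompoundSet:
    return toy_molecules()


@pytest.fixture(scope="session")
def toy_rf_matrix(toy_set):
    """RF-preset descriptor matrix over the toy molecules with complete rows."""
    X = build_matrix(toy_set, list(RF_DESCRIPTORS))
    complete = X.dropna()
    recs = [r for r in toy_set if r.id in set(complete.index)]
    return complete.loc[[r.id for r in recs]], recs


@pytest.fixture(scope="session")
def separable_table():
    X, y = make_table(SyntheticSpec(n_compounds=200, effect_size=3.0, seed=0))
    return X, y


@pytest.fixture(scope="session")
def null_table():
    X, y = make_table(
        SyntheticSpec(n_compounds=200, effect_size=0.0, class_balance=0.5, seed=0)
    )
    return X, y


def heldout_split(X: pd.DataFrame, y: np.ndarray, frac: float = 0.2):
    n_test = int(frac * len(X))
    return X.iloc[:-n_test], X.iloc[-n_test:], y[:-n_test], y[-n_test:]
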