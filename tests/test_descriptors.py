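"""Descriptor-engine tests, including independent brute-force oracles for
the Burden eigenvalues and the electrotopological states."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem.EState.EState import EStateIndices as rdkit_estate
from scipy.linalg import eigh

from devtox.atomdata import carbon_scaled
from devtox.chem_io import MoleculeRecord
from devtox.descriptors import (
    ATOM_COUNT_NAMES,
    ConfigurationError,
    RING_COUNT_NAMES,
    atom_counts,
    autocorrelation_2d,
    broto_moreau,
    build_matrix,
    burden_eigenvalues,
    burden_matrix,
    compute_descriptor,
    cycle_info_index,
    estate_indices,
    estate_values,
    functional_group_counts,
    geary,
    moran,
    ring_counts,
)
from devtox.fixtures import toy_molecules


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None
    return m


def renumbered(m: Chem.Mol, seed: int = 5) -> Chem.Mol:
    order = list(np.random.default_rng(seed).permutation(m.GetNumAtoms()))
    return Chem.RenumberAtoms(m, [int(i) for i in order])


class TestAtomCounts:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("C", {"nH": 4, "nC": 1, "nX": 0}),
            ("ClC(Cl)Cl", {"nC": 1, "nH": 1, "nCL": 3, "nX": 3}),
            ("CCO", {"nC": 2, "nO": 1, "nH": 6}),
        ],
    )
    def test_known_counts(self, smiles, expected):
        counts = atom_counts(mol(smiles))
        for k, v in expected.items():
            assert counts[k] == v, k
        # everything not listed is zero
        for k in set(ATOM_COUNT_NAMES) - set(expected):
            assert counts[k] == 0

    def test_counts_are_nonnegative_integers(self, toy_set):
        for rec in toy_set:
            for v in atom_counts(rec).values():
                assert isinstance(v, int) and v >= 0


class TestRingCounts:
    def test_benzene(self):
        rc = ring_counts(mol("c1ccccc1"))
        assert rc["nCIC"] == 1 and rc["nR06"] == 1 and rc["nBnz"] == 1

    def test_acyclic_all_zero(self):
        rc = ring_counts(mol("CCO"))
        assert all(v == 0 for v in rc.values())

    def test_naphthalene_cyclomatic(self):
        # bonds - atoms + components = 11 - 10 + 1 = 2
        rc = ring_counts(mol("c1ccc2ccccc2c1"))
        assert rc["nCIC"] == 2
        assert rc["nR06"] == 2


class TestFunctionalGroups:
    def test_ethanol_hydroxyl(self):
        assert functional_group_counts(mol("CCO"))["hydroxyl"] == 1

    def test_benzene_has_no_polar_groups(self):
        fg = functional_group_counts(mol("c1ccccc1"))
        assert fg["hydroxyl"] == 0 and fg["primary_amine"] == 0

    def test_glycine_acid_and_amine(self):
        fg = functional_group_counts(mol("NCC(=O)O"))
        assert fg["carboxylic_acid"] == 1 and fg["primary_amine"] == 1


class TestBurdenEigenvalues:
    def test_single_heavy_atom_is_scaled_property(self):
        for scheme in ("mass", "polarizability", "vdw_volume", "electronegativity"):
            val = burden_eigenvalues(mol("O"), scheme, [1])[0]
            assert val == pytest.approx(carbon_scaled("O", scheme))

    def test_two_carbon_closed_form(self):
        # equal diagonals d, off-diagonal b: eigenvalues d +/- b
        B = burden_matrix(mol("CC"), "mass")
        d, b = B[0, 0], B[0, 1]
        eigs = burden_eigenvalues(mol("CC"), "mass", [1, 2], highest=True)
        assert eigs[0] == pytest.approx(d + b)
        assert eigs[1] == pytest.approx(d - b)

    def test_rank_beyond_atom_count_is_nan(self):
        assert math.isnan(burden_eigenvalues(mol("CC"), "mass", [3])[0])

    @pytest.mark.parametrize(
        "smiles", ["CCO", "c1ccccc1", "NCC(=O)O", "C1CC1C#N", "ClC=CBr"]
    )
    def test_matches_dense_eigensolver_oracle(self, smiles):
        """Independent oracle: explicit-loop Burden matrix + scipy eigh."""
        m = mol(smiles)
        n = m.GetNumAtoms()
        B = np.full((n, n), 0.001)
        for i in range(n):
            B[i, i] = carbon_scaled(m.GetAtomWithIdx(i).GetSymbol(), "polarizability")
        conv = {1.0: 0.1, 2.0: 0.2, 3.0: 0.3, 1.5: 0.15}
        for bond in m.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            v = conv[bond.GetBondTypeAsDouble()]
            if m.GetAtomWithIdx(i).GetDegree() == 1 or m.GetAtomWithIdx(j).GetDegree() == 1:
                v += 0.01
            B[i, j] = B[j, i] = v
        expected = eigh(B, eigvals_only=True)
        got_low = burden_eigenvalues(m, "polarizability", list(range(1, n + 1)), highest=False)
        assert np.allclose(got_low, expected, atol=1e-8)

    def test_invariant_under_atom_reindexing(self):
        m = mol("CC(=O)Oc1ccccc1C(=O)O")
        a = burden_eigenvalues(m, "mass", [1, 2, 3])
        b = burden_eigenvalues(renumbered(m), "mass", [1, 2, 3])
        assert np.allclose(a, b, atol=1e-10)


class TestAutocorrelations:
    def test_hand_enumerated_ats(self):
        # 3-atom chain, weights (1,2,1), lag 1: pairs (0,1),(1,2) -> 1*2+2*1
        dist = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        w = np.array([1.0, 2.0, 1.0])
        assert broto_moreau(dist, w, 1) == pytest.approx(4.0)
        assert broto_moreau(dist, w, 2) == pytest.approx(1.0)
        assert broto_moreau(dist, w, 3) == 0.0

    def test_zero_variance_weights_flagged(self):
        dist = np.array([[0, 1], [1, 0]], dtype=float)
        w = np.ones(2)
        assert math.isnan(moran(dist, w, 1))
        assert math.isnan(geary(dist, w, 1))

    def test_unpopulated_lag(self):
        assert autocorrelation_2d(mol("CCO"), "ATS", 8, "mass") == 0.0
        assert math.isnan(autocorrelation_2d(mol("CCO"), "MATS", 8, "mass"))

    def test_moran_geary_against_direct_formula(self):
        dist = np.array(
            [[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1, 0]], dtype=float
        )
        w = np.array([1.0, 0.5, 2.0, 1.5])
        lag = 1
        wbar = w.mean()
        pairs = [(i, j) for i in range(4) for j in range(4) if i != j and dist[i, j] == lag]
        moran_expected = (
            sum((w[i] - wbar) * (w[j] - wbar) for i, j in pairs) / len(pairs)
        ) / (np.sum((w - wbar) ** 2) / 4)
        geary_expected = (
            sum((w[i] - w[j]) ** 2 for i, j in pairs) / (2 * len(pairs))
        ) / (np.sum((w - wbar) ** 2) / 3)
        assert moran(dist, w, lag) == pytest.approx(moran_expected)
        assert geary(dist, w, lag) == pytest.approx(geary_expected)

    def test_invariant_under_atom_reindexing(self):
        m = mol("CC(C)CC(=O)Nc1ccc(O)cc1")
        for kind in ("ATS", "MATS", "GATS"):
            a = autocorrelation_2d(m, kind, 2, "mass")
            b = autocorrelation_2d(renumbered(m), kind, 2, "mass")
            assert a == pytest.approx(b)


def naive_estate(m: Chem.Mol) -> np.ndarray:
    """Brute-force oracle: intrinsic states + double-loop perturbation."""
    tbl = Chem.GetPeriodicTable()
    n = m.GetNumAtoms()
    I = []
    for atom in m.GetAtoms():
        z = atom.GetAtomicNum()
        dv = tbl.GetNOuterElecs(z) - atom.GetTotalNumHs()
        d = atom.GetDegree() or 1
        L = {1: 1, 6: 2, 7: 2, 8: 2, 9: 2, 15: 3, 16: 3, 17: 3, 35: 4, 53: 5}[z]
        I.append(((2.0 / L) ** 2 * dv + 1.0) / d)
    dist = Chem.GetDistanceMatrix(m)
    S = np.zeros(n)
    for i in range(n):
        S[i] = I[i]
        for j in range(n):
            if i != j:
                S[i] += (I[i] - I[j]) / (dist[i][j] + 1.0) ** 2
    return S


class TestEState:
    @pytest.mark.parametrize(
        "smiles",
        ["CC(C)CC", "CCO", "CC(=O)Nc1ccc(O)cc1", "NCC(=O)O", "FC(F)(F)c1ccccc1"],
    )
    def test_matches_naive_double_loop_oracle(self, smiles):
        m = mol(smiles)
        assert np.allclose(estate_values(m), naive_estate(m), atol=1e-9)

    @pytest.mark.parametrize("smiles", ["CC(C)CC", "CCO", "c1ccncc1", "CC(=O)OC"])
    def test_matches_rdkit_cross_check(self, smiles):
        m = mol(smiles)
        assert np.allclose(estate_values(m), rdkit_estate(m), atol=1e-6)

    def test_no_hydroxyl_means_zero_ssoh(self):
        assert estate_indices(mol("CCC"))["SsOH"] == 0.0

    def test_isolated_atom_equals_intrinsic_state(self):
        # methane's carbon: dv = 0, d -> 1, L = 2 => I = 1
        vals = estate_values(mol("C"))
        assert vals[0] == pytest.approx(1.0)

    def test_gmin_is_minimum(self):
        m = mol("CC(=O)Nc1ccc(O)cc1")
        assert estate_indices(m)["Gmin"] == pytest.approx(float(estate_values(m).min()))

    def test_atom_type_sums(self):
        # ethanol: one -OH oxygen; no =C<; no -NH-
        idx = estate_indices(mol("CCO"))
        assert idx["SsOH"] == pytest.approx(float(estate_values(mol("CCO"))[2]))
        assert idx["SdssC"] == 0.0 and idx["ShssNH"] == 0.0


class TestCycleInfoIndex:
    def test_acyclic_zero(self):
        assert cycle_info_index(mol("CCCCO")) == 0.0

    def test_benzene_single_class_zero(self):
        assert cycle_info_index(mol("c1ccccc1")) == 0.0

    def test_ring_plus_exocyclic_two_classes(self):
        expected = -(6 / 7) * math.log2(6 / 7) - (1 / 7) * math.log2(1 / 7)
        assert cycle_info_index(mol("Cc1ccccc1")) == pytest.approx(expected)


class TestMatrixAssembly:
    def test_three_by_two_integer_matrix(self, toy_set):
        sub = toy_set.records[:3]
        from devtox.chem_io import CompoundSet

        X = build_matrix(CompoundSet(sub), ["nC", "nO"])
        assert X.shape == (3, 2)
        assert (X >= 0).all().all()

    def test_empty_request_rejected(self, toy_set):
        with pytest.raises(ConfigurationError):
            build_matrix(toy_set, [])

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_descriptor(mol("CCO"), "XYZZY9z")

    def test_benzene_row(self, toy_set):
        from devtox.chem_io import CompoundSet, MoleculeRecord

        cs = CompoundSet([MoleculeRecord(id="bz", smiles="c1ccccc1")])
        row = build_matrix(cs, ["nC", "nR06", "nBnz"]).iloc[0]
        assert list(row) == [6, 1, 1]
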