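"""Pseudograph matrices: construction, powers, cut-offs, normalizations."""

import numpy as np
import pytest

import algomd as am
from algomd.matrices import CutoffSpec, MatrixError

from conftest import walk_count_oracle


def path_graph(orders):
    """Hand-built path with given consecutive bond orders (carbon skeleton)."""
    atoms = [am.graph.Atom("C") for _ in range(len(orders) + 1)]
    bonds = [am.graph.Bond(i, i + 1, o) for i, o in enumerate(orders)]
    return am.MolecularGraph(atoms, bonds, source_id="path")


# frozen by hand from the fixed atom order N1 C2 C3 C4 C5 C6 C7 O8 O9 and
# the Kekule assignment N1=C2, C3=C4, C5=C6, C7=O8
ISONICOTINIC_NS = np.array(
    [
        [0, 2, 0, 0, 0, 1, 0, 0, 0],
        [2, 0, 1, 0, 0, 0, 0, 0, 0],
        [0, 1, 0, 2, 0, 0, 0, 0, 0],
        [0, 0, 2, 0, 1, 0, 1, 0, 0],
        [0, 0, 0, 1, 0, 2, 0, 0, 0],
        [1, 0, 0, 0, 2, 0, 0, 0, 0],
        [0, 0, 0, 1, 0, 0, 0, 2, 1],
        [0, 0, 0, 0, 0, 0, 2, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 0, 0],
    ],
    dtype=float,
)


class TestAtomMatrix:
    def test_isonicotinic_matrix_reproduced_exactly(self, isonicotinic):
        M = am.build_ns_atom_matrix(isonicotinic)
        assert np.array_equal(M.values, ISONICOTINIC_NS)

    def test_triple_bond_entry_is_three(self):
        from rdkit import Chem

        from algomd.graph import _graph_from_rdkit

        acn = _graph_from_rdkit(Chem.MolFromSmiles("C#N"), "suppressed", "acn")
        M = am.build_ns_atom_matrix(acn)
        assert M.values[0, 1] == 3

    def test_diagonal_modes(self, isonicotinic):
        ar = am.build_ns_atom_matrix(isonicotinic, "aromatic")
        assert np.array_equal(np.diag(ar.values), [1, 1, 1, 1, 1, 1, 0, 0, 0])
        lp = am.build_ns_atom_matrix(isonicotinic, "lone_pairs")
        assert np.array_equal(np.diag(lp.values), [1, 0, 0, 0, 0, 0, 0, 2, 2])
        both = am.build_ns_atom_matrix(isonicotinic, "aromatic+lone_pairs")
        assert np.array_equal(np.diag(both.values), [2, 1, 1, 1, 1, 1, 0, 2, 2])

    def test_symmetric_with_nonnegative_integers(self, fixture_set):
        for g in fixture_set:
            v = am.build_ns_atom_matrix(g, "aromatic+lone_pairs").values
            assert np.array_equal(v, v.T)
            assert np.all(v >= 0) and np.all(v == np.round(v))


class TestBondMatrix:
    def test_shared_endpoint_semantics(self, isonicotinic):
        E = am.build_ns_bond_matrix(isonicotinic).values
        bonds = isonicotinic.bonds
        for v in range(len(bonds)):
            for w in range(len(bonds)):
                expected = (
                    0.0 if v == w
                    else float(bool({bonds[v].i, bonds[v].j} & {bonds[w].i, bonds[w].j}))
                )
                assert E[v, w] == expected

    def test_diagonal_always_zero(self, fixture_set):
        for g in fixture_set:
            if g.n_bonds:
                assert np.all(np.diag(am.build_ns_bond_matrix(g).values) == 0)

    def test_butane_terminal_bonds_not_adjacent(self):
        g = am.generate_fixtures("n_butane")[0]
        E = am.build_ns_bond_matrix(g).values
        assert E[0, 2] == 0  # C1-C2 vs C3-C4 share no atom

    def test_single_atom_has_no_bond_matrix(self):
        g = am.generate_fixtures("methane")[0]
        with pytest.raises(MatrixError, match="no edges"):
            am.build_ns_bond_matrix(g)


class TestPowers:
    def test_zeroth_power_is_identity(self, isonicotinic):
        M = am.build_ns_atom_matrix(isonicotinic)
        assert np.array_equal(am.matrix_power(M, 0).values, np.eye(9))

    def test_first_power_unchanged(self, isonicotinic):
        M = am.build_ns_atom_matrix(isonicotinic)
        assert np.array_equal(am.matrix_power(M, 1).values, M.values)

    def test_path_square_counts_length_two_walks(self):
        M = am.build_ns_atom_matrix(path_graph([1, 1]))
        M2 = am.matrix_power(M, 2).values
        assert M2[0, 2] == 1 and M2[1, 1] == 2

    def test_negative_power_rejected(self, isonicotinic):
        M = am.build_ns_atom_matrix(isonicotinic)
        with pytest.raises(ValueError):
            am.matrix_power(M, -1)

    @pytest.mark.parametrize("name", ["isonicotinic_acid", "benzene", "propanoic_acid"])
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_powers_equal_brute_force_walk_counts(self, name, k):
        g = am.generate_fixtures(name)[0]
        M = am.build_ns_atom_matrix(g, "lone_pairs")
        expected = walk_count_oracle(M.values, k).astype(float)
        assert np.array_equal(am.matrix_power(M, k).values, expected)


class TestDistances:
    def test_path_and_ring_distances(self):
        D = am.topological_distances(path_graph([2, 3]))
        assert D[0, 2] == 2  # multiplicity ignored
        benzene = am.generate_fixtures("benzene")[0]
        Db = am.topological_distances(benzene)
        assert Db[0, 3] == 3  # para pair

    def test_disconnected_pairs_are_infinite(self):
        atoms = [am.graph.Atom("C")] * 4
        bonds = [am.graph.Bond(0, 1), am.graph.Bond(2, 3)]
        g = am.MolecularGraph(list(atoms), bonds, source_id="2frag")
        D = am.topological_distances(g)
        assert np.isinf(D[0, 2]) and D[0, 1] == 1


class TestCutoffs:
    def test_srw_nsrw_reconstruct_exactly(self, fixture_set):
        for g in fixture_set:
            M = am.matrix_power(am.build_ns_atom_matrix(g, "lone_pairs"), 2)
            D = am.topological_distances(g)
            srw = am.apply_cutoff(M, D, CutoffSpec("SRW")).values
            nsrw = am.apply_cutoff(M, D, CutoffSpec("NSRW")).values
            assert np.array_equal(srw + nsrw, M.values)
            assert np.all(srw == np.diag(np.diag(M.values)))
            assert np.all(np.diag(nsrw) == 0)

    def test_lag_window_on_isonicotinic(self, isonicotinic):
        M = am.matrix_power(am.build_ns_atom_matrix(isonicotinic, "lone_pairs"), 3)
        D = am.topological_distances(isonicotinic)
        lag = am.apply_cutoff(M, D, CutoffSpec("LAG", 2, 5)).values
        assert np.all(np.diag(lag) == 0)
        keep = (D >= 2) & (D <= 5)
        assert np.array_equal(lag != 0, (M.values != 0) & keep)

    def test_lag_requires_valid_window(self):
        with pytest.raises(ValueError):
            CutoffSpec("LAG", 3, 2)

    def test_dimension_mismatch_rejected(self, isonicotinic):
        M = am.build_ns_atom_matrix(isonicotinic)
        with pytest.raises(ValueError, match="mismatch"):
            am.apply_cutoff(M, np.zeros((3, 3)), CutoffSpec("SRW"))


class TestNormalizations:
    def test_ss_rows_sum_to_one(self, fixture_set):
        for g in fixture_set:
            M = am.build_ns_atom_matrix(g, "lone_pairs")
            if M.values.sum() == 0:  # single-atom molecule without lone pairs
                continue
            S = am.normalize(M, "SS").values
            rows = S.sum(axis=1)
            nz = M.values.sum(axis=1) > 0
            assert np.allclose(rows[nz], 1.0, atol=1e-10)

    def test_mp_grand_sum_one_and_symmetric(self, fixture_set):
        for g in fixture_set:
            M = am.build_ns_atom_matrix(g, "lone_pairs")
            if M.values.sum() == 0:
                continue
            P = am.normalize(M, "MP").values
            assert abs(P.sum() - 1) < 1e-10
            assert np.array_equal(P, P.T)

    def test_ds_flat_two_by_two(self):
        M = am.SquareMatrix(np.ones((2, 2)), kind="atom")
        D = am.normalize(M, "DS").values
        assert np.allclose(D, 0.5)

    def test_ds_row_and_column_sums(self, fixture_set):
        checked = 0
        for g in fixture_set:
            if g.n_bonds == 0:
                continue
            # even powers have a positive diagonal, hence total support
            M = am.matrix_power(am.build_ns_atom_matrix(g, "lone_pairs"), 2)
            D = am.normalize(M, "DS").values
            assert np.allclose(D.sum(axis=0), 1.0, atol=1e-8)
            assert np.allclose(D.sum(axis=1), 1.0, atol=1e-8)
            checked += 1
        assert checked >= 10

    def test_all_zero_matrix_errors(self):
        Z = am.SquareMatrix(np.zeros((3, 3)), kind="atom")
        for scheme in ("SS", "MP", "DS"):
            with pytest.raises(MatrixError):
                am.normalize(Z, scheme)

    def test_ds_without_total_support_errors(self):
        # star K1,3 adjacency admits no positive-diagonal permutation
        atoms = [am.graph.Atom("C")] * 4
        bonds = [am.graph.Bond(0, i) for i in (1, 2, 3)]
        g = am.MolecularGraph(list(atoms), bonds, source_id="star")
        M = am.build_ns_atom_matrix(g)
        with pytest.raises(MatrixError):
            am.normalize(M, "DS")
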