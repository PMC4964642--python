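"""C-alpha trace parsing, distance thresholding, potential weighting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcnfold import (
    apply_contact_potentials,
    build_pcn,
    distance_matrix,
    read_ca_trace,
)
from pcnfold.errors import (
    ChainNotFoundError,
    MappingError,
    ParseError,
    TooShortError,
    ValidationError,
)
from pcnfold.structure_io import (
    CaTrace,
    ContactNetwork,
    read_edge_list,
    read_network_matrix,
    trace_to_pdb,
    write_edge_list,
    write_network_matrix,
)
from conftest import PDB_ALTLOC, PDB_THREE_RESIDUES


class TestReadCaTrace:
    def test_three_handwritten_records(self):
        trace = read_ca_trace(PDB_THREE_RESIDUES, "A")
        assert trace.n_residues == 3
        assert trace.residues == ("A", "G", "W")
        np.testing.assert_allclose(trace.coords[1], [3.0, 4.0, 0.0])

    def test_first_chain_default(self):
        trace = read_ca_trace(PDB_THREE_RESIDUES)
        assert trace.chain_id == "A"

    def test_altloc_keeps_highest_occupancy(self):
        # dedup oracle: one coordinate per residue number, count unchanged
        trace = read_ca_trace(PDB_ALTLOC, "A")
        assert trace.n_residues == 3
        np.testing.assert_allclose(trace.coords[1], [3.0, 4.0, 0.0])  # occ 0.60

    def test_unknown_chain_raises(self):
        with pytest.raises(ChainNotFoundError):
            read_ca_trace(PDB_THREE_RESIDUES, "Z")

    def test_no_ca_records_raises(self):
        with pytest.raises(ParseError):
            read_ca_trace("HEADER    EMPTY\nEND\n")

    def test_too_short_raises(self):
        one = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        with pytest.raises((TooShortError, ParseError)):
            read_ca_trace(one, "A")

    def test_nonstandard_residue_fails_loud(self):
        bad = PDB_THREE_RESIDUES.replace("GLY A   2", "XYZ A   2")
        with pytest.raises(MappingError, match="XYZ"):
            read_ca_trace(bad, "A")

    def test_mse_maps_to_methionine(self):
        text = PDB_THREE_RESIDUES.replace(
            "ATOM      3  CA  GLY", "HETATM    3  CA  MSE")
        trace = read_ca_trace(text, "A")
        assert trace.residues[1] == "M"

    def test_pdb_roundtrip_through_writer(self, rng):
        from pcnfold.synthetic import make_random_globule
        trace = make_random_globule(20, seed=3)
        back = read_ca_trace(trace_to_pdb(trace), "A")
        assert back.residues == trace.residues
        np.testing.assert_allclose(back.coords, trace.coords, atol=5e-4)


class TestDistanceMatrix:
    def test_3_4_5_triangle(self):
        trace = CaTrace(("A", "G"), [[0, 0, 0], [3, 4, 0]])
        d = distance_matrix(trace)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.normal(size=(20, 3)) * 10
        trace = CaTrace(tuple("A" * 20), pts)
        d = distance_matrix(trace)
        for i in range(20):
            for j in range(20):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((pts[i] - pts[j]) ** 2).sum()), abs=1e-12)


class TestBuildPcn:
    def test_inclusive_8A_boundary(self):
        d = np.array([[0.0, 7.99, 8.01],
                      [7.99, 0.0, 8.00],
                      [8.01, 8.00, 0.0]])
        net = build_pcn(d)
        assert net.adjacency[0, 1] == 1      # below threshold
        assert net.adjacency[0, 2] == 0      # above threshold
        assert net.adjacency[1, 2] == 1      # exactly 8 A counts as contact

    def test_all_far_gives_empty_network(self):
        d = np.full((4, 4), 9.0)
        np.fill_diagonal(d, 0.0)
        assert build_pcn(d).n_links == 0

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 5.0], [6.0, 0.0]])
        with pytest.raises(ValidationError):
            build_pcn(d)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_thresholding(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((12, 3)) * 15
        trace = CaTrace(tuple("A" * 12), pts)
        net = build_pcn(distance_matrix(trace))
        for i in range(12):
            for j in range(12):
                d = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
                expect = 1 if (i != j and 0 < d <= 8.0) else 0
                assert net.adjacency[i, j] == expect

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(15, 3)) * 5
        # random rotation via QR, plus translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ Q.T + np.array([10.0, -3.0, 7.0])
        a = build_pcn(distance_matrix(CaTrace(tuple("A" * 15), pts)))
        b = build_pcn(distance_matrix(CaTrace(tuple("A" * 15), moved)))
        np.testing.assert_array_equal(a.adjacency, b.adjacency)


class TestContactPotentials:
    def test_shift_forces_min_weight_one(self):
        # two links with raw potentials -2.0 and 0.5 -> shift 3.0
        trace = CaTrace(("A", "C", "D"), [[0, 0, 0], [4, 0, 0], [4, 4, 0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        import pandas as pd
        from pcnfold.structure_io import STANDARD_AA, PotentialMatrix
        vals = pd.DataFrame(0.0, index=list(STANDARD_AA), columns=list(STANDARD_AA))
        vals.loc["A", "C"] = vals.loc["C", "A"] = -2.0
        vals.loc["C", "D"] = vals.loc["D", "C"] = 0.5
        wnet = apply_contact_potentials(ContactNetwork(adj), trace,
                                        PotentialMatrix(vals))
        assert wnet.shift == pytest.approx(3.0)
        assert wnet.weights[0, 1] == pytest.approx(1.0)
        assert wnet.weights[1, 2] == pytest.approx(3.5)

    def test_equal_potentials_give_unit_weights(self, synthetic_potentials, rng):
        import pandas as pd
        from pcnfold.structure_io import STANDARD_AA, PotentialMatrix
        flat = PotentialMatrix(
            pd.DataFrame(-1.3, index=list(STANDARD_AA), columns=list(STANDARD_AA)))
        from pcnfold.synthetic import make_random_globule
        trace = make_random_globule(15, seed=1)
        pcn = build_pcn(distance_matrix(trace))
        wnet = apply_contact_potentials(pcn, trace, flat)
        links = wnet.weights[pcn.adjacency.astype(bool)]
        np.testing.assert_allclose(links, 1.0)

    def test_support_matches_adjacency(self, synthetic_potentials):
        from pcnfold.synthetic import make_random_globule
        trace = make_random_globule(25, seed=5)
        pcn = build_pcn(distance_matrix(trace))
        wnet = apply_contact_potentials(pcn, trace, synthetic_potentials)
        np.testing.assert_array_equal(
            (wnet.weights > 0).astype(np.uint8), pcn.adjacency)
        links = wnet.weights[pcn.adjacency.astype(bool)]
        assert links.min() == pytest.approx(1.0)

    def test_size_mismatch_rejected(self, synthetic_potentials):
        trace = CaTrace(("A", "G"), [[0, 0, 0], [3, 0, 0]])
        adj = np.zeros((3, 3), dtype=np.uint8)
        with pytest.raises(ValidationError):
            apply_contact_potentials(ContactNetwork(adj), trace,
                                     synthetic_potentials)


class TestNetworkIO:
    def test_matrix_roundtrip_bit_exact(self, tmp_path, rng):
        from pcnfold.synthetic import make_banded_network
        net = make_banded_network(12, {1, 3, 5})
        path = tmp_path / "net.mat"
        write_network_matrix(net, path)
        back = read_network_matrix(path)
        np.testing.assert_array_equal(back.adjacency, net.adjacency)

    def test_edge_list_roundtrip(self, tmp_path, rng):
        net = random_net = None
        from conftest import random_weighted_network
        while random_net is None:
            random_net = random_weighted_network(rng, 10)
        path = tmp_path / "net.edges"
        write_edge_list(random_net, path)
        back = read_edge_list(path, weighted=True)
        np.testing.assert_array_equal(back.weights, random_net.weights)
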