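"""Encoders, dihedrals, graph construction, and geometric equivariance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

import biotite.structure as struc

from gvpstab._tables import ATCHLEY_FACTORS, RESIDUE_SCORE_COLUMNS
from gvpstab.data_model import CANONICAL_AA, ValidationError
from gvpstab.featurize import (
    BackboneStructure,
    EncoderStack,
    ProteinGraph,
    RBFConfig,
    atchley_encode,
    build_graph,
    compute_dihedrals,
    knn_edges,
    load_pssm,
    load_residue_scores,
    one_hot_encode,
    read_pdb,
    structure_potential_encode,
    write_pdb,
)
from gvpstab.synthetic import (
    gen_extended_backbone,
    gen_helix_backbone,
    gen_pssm,
    gen_residue_scores,
)


class TestOneHot:
    def test_alphabetical_index(self):
        v = one_hot_encode("A")
        assert v[0] == 1.0 and v.sum() == 1.0

    @pytest.mark.parametrize("aa", list(CANONICAL_AA))
    def test_every_residue_sums_to_one(self, aa):
        v = one_hot_encode(aa)
        assert v.sum() == 1.0
        assert v[CANONICAL_AA.index(aa)] == 1.0

    def test_noncanonical_rejected(self):
        with pytest.raises(ValidationError):
            one_hot_encode("X")


class TestAtchley:
    def test_table_shape(self):
        assert len(ATCHLEY_FACTORS) == 20
        assert all(len(v) == 5 for v in ATCHLEY_FACTORS.values())

    def test_lookup_bit_exact(self):
        for aa, row in ATCHLEY_FACTORS.items():
            assert atchley_encode(aa).tolist() == list(row)

    def test_columns_standardized_near_zero_mean(self):
        table = np.array([ATCHLEY_FACTORS[a] for a in CANONICAL_AA])
        assert np.abs(table.mean(axis=0)).max() < 0.05

    def test_noncanonical_rejected(self):
        with pytest.raises(ValidationError):
            atchley_encode("B")


class TestPssm:
    def test_shape_preserved(self):
        seq = "ACDEFGHIKLMN"
        out = load_pssm(gen_pssm(seq, 0), seq)
        assert out.shape == (12, 20)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            load_pssm(np.zeros((5, 20)), "ACDEFG")

    def test_squash_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 5, size=(8, 20))
        seq = "ACDEFGHI"
        out = load_pssm(raw, seq)
        assert ((out > 0) & (out < 1)).all()
        # monotone: ordering of raw scores preserved per cell pair
        raw2 = raw + np.abs(rng.normal(0, 1, raw.shape))
        out2 = load_pssm(raw2, seq)
        assert (out2 >= out).all()

    def test_tsv_roundtrip(self, tmp_path):
        seq = "ACDEFG"
        from gvpstab.synthetic import gen_pssm_table
        df = gen_pssm_table(seq, 1)
        path = tmp_path / "pssm.tsv"
        df.to_csv(path, sep="\t", index=False)
        assert np.allclose(load_pssm(path, seq),
                           load_pssm(df.to_numpy(), seq))


class TestStructurePotential:
    def test_bounded(self):
        s = gen_helix_backbone(20, seed=0)
        pot = structure_potential_encode(s)
        assert ((pot >= 0) & (pot <= 1)).all()

    def test_extended_is_near_minimal(self):
        helix = gen_helix_backbone(21, seed=0)
        ext = gen_extended_backbone(21, seed=0)
        mid = 10
        assert structure_potential_encode(ext)[mid] < \
            structure_potential_encode(helix)[mid]
        # brute-force contact count for the extended interior residue
        d = np.linalg.norm(ext.ca - ext.ca[mid], axis=1)
        brute = int(((d > 0) & (d <= 10.0)).sum())
        assert structure_potential_encode(ext)[mid] == brute / 24

    def test_core_exceeds_terminus(self):
        s = gen_helix_backbone(25, seed=1)
        pot = structure_potential_encode(s)
        assert pot[12] > pot[0]


class TestResidueScores:
    def test_fixture_accepted(self):
        seq = "ACDEFGHIKL"
        out = load_residue_scores(gen_residue_scores(seq, 0), seq)
        assert out.shape == (10, 20)

    def test_wrong_column_count_rejected(self):
        df = pd.DataFrame(np.zeros((4, 19)),
                          columns=list(RESIDUE_SCORE_COLUMNS[:19]))
        with pytest.raises(ValidationError):
            load_residue_scores(df, "ACDE")

    def test_schema_driven_column_order(self):
        seq = "ACDEFG"
        df = gen_residue_scores(seq, 3)
        shuffled = df[list(reversed(df.columns))]
        assert np.allclose(load_residue_scores(df, seq),
                           load_residue_scores(shuffled, seq))


class TestDihedrals:
    def test_ideal_trans_omega(self):
        s = gen_helix_backbone(8, seed=0)
        d = compute_dihedrals(s)
        interior = np.abs(np.rad2deg(d.angles[2:-2, 2]))
        assert np.allclose(interior, 180.0, atol=1e-6)
        # encoded as (|sin|, cos) = (0, -1)
        assert np.allclose(d.sincos[2:-2, 4], 0.0, atol=1e-8)
        assert np.allclose(d.sincos[2:-2, 5], -1.0, atol=1e-8)

    def test_helix_angles_against_independent_torsion_oracle(self):
        s = gen_helix_backbone(12, seed=2, jitter=0.005)
        d = compute_dihedrals(s)
        ang = np.rad2deg(d.angles)
        assert np.all(np.abs(ang[1:, 0] - (-57.0)) < 2.0)
        assert np.all(np.abs(ang[:-1, 1] - (-47.0)) < 2.0)
        # independent oracle on each interior phi
        for i in range(1, len(s.sequence)):
            ref = np.rad2deg(struc.dihedral(
                s.c[i - 1], s.n[i], s.ca[i], s.c[i]))
            assert abs(ang[i, 0] - ref) < 1e-3

    def test_termini_masked(self):
        s = gen_helix_backbone(6, seed=0)
        d = compute_dihedrals(s)
        assert not d.mask[0, 0]            # first residue phi undefined
        assert not d.mask[-1, 1]           # last residue psi undefined
        assert not d.mask[-1, 2]
        assert (d.sincos[0, 0:2] == 0).all()

    def test_chain_break_masks_spanning_angles(self):
        s = gen_helix_backbone(10, seed=0)
        shifted = s.ca.copy()
        # teleport the second half far away
        for arr in (s.n, s.ca, s.c):
            arr[5:] += 100.0
        d = compute_dihedrals(s)
        assert not d.mask[5, 0]    # phi spanning the break
        assert not d.mask[4, 1]    # psi spanning the break
        assert d.mask[3, 1]
        assert shifted is not None


class TestGraph:
    def test_knn_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        ca = rng.normal(scale=8, size=(30, 3))
        edges = knn_edges(ca, 6)
        d = np.linalg.norm(ca[:, None] - ca[None], axis=-1)
        for i in range(30):
            mine = set(edges[0][edges[1] == i].tolist())
            order = np.argsort(d[i])
            brute = set(j for j in order if j != i)
            brute = set(list(sorted(brute, key=lambda j: d[i][j]))[:6])
            assert mine == brute

    def test_collinear_chain_neighbors(self):
        ca = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0.]])
        s = BackboneStructure(sequence="ACDE", n=ca - [1.2, 0, 0], ca=ca,
                              c=ca + [1.2, 0, 0])
        edges = knn_edges(s.ca, 2)
        incoming = {i: set(edges[0][edges[1] == i].tolist()) for i in range(4)}
        assert incoming[0] == {1, 2}
        assert incoming[1] == {0, 2}
        assert incoming[2] == {1, 3}
        assert incoming[3] == {1, 2}

    def test_k_truncated_for_short_chains(self):
        s = gen_helix_backbone(2, seed=0)
        g = build_graph(s, EncoderStack(pssm=False, residue_scores=False),
                        k_neighbors=30)
        assert g.n_edges == 2      # each node exactly one neighbor

    def test_rbf_center_value_one(self):
        rbf = RBFConfig(n_centers=16, d_min=0.0, d_max=20.0)
        out = rbf.expand(np.array([rbf.centers[3]]))
        assert out[0, 3] == 1.0
        assert ((out > 0) & (out <= 1)).all()

    def test_rbf_argmax_recovers_distance_within_bin(self):
        rbf = RBFConfig()
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 20, size=200)
        decoded = rbf.centers[np.argmax(rbf.expand(d), axis=1)]
        assert np.abs(decoded - d).max() <= rbf.width

    def test_too_small_graph_rejected(self):
        s = gen_helix_backbone(2, seed=0)
        one = BackboneStructure(sequence="A", n=s.n[:1], ca=s.ca[:1],
                                c=s.c[:1])
        with pytest.raises(ValidationError):
            build_graph(one, EncoderStack(pssm=False, residue_scores=False))

    def test_deterministic(self, helix, helix_graph):
        g2 = build_graph(helix, EncoderStack(), k_neighbors=8,
                         pssm=gen_pssm(helix.sequence, 1),
                         residue_scores=gen_residue_scores(helix.sequence, 1))
        assert (g2.node_scalar == helix_graph.node_scalar).all()
        assert (g2.edge_index == helix_graph.edge_index).all()

    def test_node_scalar_width(self, helix_graph):
        assert helix_graph.node_scalar.shape[1] == EncoderStack().total_width \
            == 72

    def test_unit_vectors(self, helix_graph):
        norms = np.linalg.norm(helix_graph.node_vector, axis=-1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms == 0))
        enorm = np.linalg.norm(helix_graph.edge_vector, axis=-1)
        assert np.allclose(enorm, 1.0)

    def test_no_self_loops(self, helix_graph):
        assert (helix_graph.edge_index[0] != helix_graph.edge_index[1]).all()

    def test_archive_roundtrip(self, tmp_path, helix_graph):
        path = tmp_path / "graph.npz"
        helix_graph.save(path)
        back = ProteinGraph.load(path)
        assert (back.node_scalar == helix_graph.node_scalar).all()
        assert (back.edge_index == helix_graph.edge_index).all()
        assert back.stack_signature == helix_graph.stack_signature


class TestEquivariance:
    def test_rigid_motion_invariance_and_equivariance(self, helix):
        """Over random orthogonal transforms (proper and improper) plus
        translations: Sv/Se invariant, Vv/Ve transform with the matrix."""
        stack = EncoderStack()
        pssm = gen_pssm(helix.sequence, 1)
        scores = gen_residue_scores(helix.sequence, 1)
        g0 = build_graph(helix, stack, k_neighbors=8, pssm=pssm,
                         residue_scores=scores)
        rng = np.random.default_rng(0)
        for i in range(25):
            R = ortho_group.rvs(3, random_state=i)
            if i % 2:
                R[:, 0] *= -1    # improper (reflection)
            t = rng.normal(scale=20, size=3)
            g1 = build_graph(helix.transformed(R, t), stack, k_neighbors=8,
                             pssm=pssm, residue_scores=scores)
            assert (g1.edge_index == g0.edge_index).all()
            assert np.abs(g1.node_scalar - g0.node_scalar).max() < 1e-6
            assert np.abs(g1.edge_scalar - g0.edge_scalar).max() < 1e-6
            assert np.abs(g1.node_vector - g0.node_vector @ R.T).max() < 1e-6
            assert np.abs(g1.edge_vector - g0.edge_vector @ R.T).max() < 1e-6


class TestPdbIO:
    def test_write_read_roundtrip(self, tmp_path):
        s = gen_helix_backbone(9, seed=4)
        path = tmp_path / "helix.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert back.sequence == s.sequence
        # PDB stores 3 decimals
        assert np.abs(back.ca - s.ca).max() < 1e-2
        assert np.abs(back.n - s.n).max() < 1e-2

    def test_missing_backbone_residue_skipped(self, tmp_path):
        s = gen_helix_backbone(6, seed=0)
        path = tmp_path / "full.pdb"
        write_pdb(s, path)
        # drop residue 3's N atom
        lines = [ln for ln in path.read_text().splitlines()
                 if not (ln.startswith("ATOM") and " N " in ln
                         and ln[22:26].strip() == "3")]
        broken = tmp_path / "broken.pdb"
        broken.write_text("\n".join(lines) + "\n")
        back = read_pdb(broken)
        assert len(back) == 5
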