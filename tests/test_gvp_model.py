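"""GVP layers, the dual-graph classifier, and the training harness."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from gvpstab.autodiff import Tensor, binary_cross_entropy
from gvpstab.data_model import ValidationError
from gvpstab.featurize import (
    EncoderStack,
    ProteinGraph,
    build_graph,
)
from gvpstab.gvp import GVP, GVPConvLayer
from gvpstab.model import (
    DualGraphClassifier,
    ModelConfig,
    ThermostabilityModel,
    finetune,
    pretrain,
)
from gvpstab.synthetic import (
    gen_classification_fixture,
    gen_helix_backbone,
    gen_pssm,
    gen_residue_scores,
)

TINY = dict(hidden_dim=16, vector_dim=4, n_attention_heads=4)


def tiny_config(**kw):
    base = dict(TINY)
    base.update(kw)
    return ModelConfig(**base)


def rand_tuple(rng, n, s, v):
    return Tensor(rng.normal(size=(n, s))), Tensor(rng.normal(size=(n, v, 3)))


class TestGVPLayer:
    def test_zero_vectors_give_zero_vectors(self):
        rng = np.random.default_rng(0)
        gvp = GVP((6, 3), (5, 2), rng)
        s = Tensor(rng.normal(size=(4, 6)))
        V = Tensor(np.zeros((4, 3, 3)))
        _, v_out = gvp(s, V)
        # linear mixing of zero vectors stays zero regardless of gating
        assert np.abs(v_out.data).max() < 1e-12

    @pytest.mark.parametrize("improper", [False, True])
    def test_rotation_and_reflection_equivariance(self, improper):
        rng = np.random.default_rng(1)
        gvp = GVP((6, 3), (5, 2), rng)
        s, V = rand_tuple(rng, 4, 6, 3)
        R = ortho_group.rvs(3, random_state=7)
        if improper:
            R[:, 0] *= -1
        s_out, v_out = gvp(s, V)
        s_rot, v_rot = gvp(s, Tensor(V.data @ R.T))
        assert np.abs(s_rot.data - s_out.data).max() < 1e-10
        assert np.abs(v_rot.data - v_out.data @ R.T).max() < 1e-10

    def test_width_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        gvp = GVP((6, 3), (5, 2), rng)
        with pytest.raises(ValidationError):
            gvp(Tensor(np.zeros((4, 7))), Tensor(np.zeros((4, 3, 3))))


class TestConvLayer:
    def _toy_graph(self, rng, n=5, k=2):
        import itertools
        edges = [(j, i) for i, j in itertools.product(range(n), range(n))
                 if i != j][: n * k]
        ei = np.array(edges).T
        return ei

    def test_single_node_no_edges(self):
        rng = np.random.default_rng(0)
        layer = GVPConvLayer((6, 2), (4, 1), rng)
        s = Tensor(rng.normal(size=(1, 6)))
        V = Tensor(rng.normal(size=(1, 2, 3)))
        ei = np.zeros((2, 0), dtype=int)
        s_out, v_out = layer(s, V, ei, Tensor(np.zeros((0, 4))),
                             Tensor(np.zeros((0, 1, 3))))
        assert s_out.shape == (1, 6) and v_out.shape == (1, 2, 3)

    def test_dangling_edge_rejected(self):
        rng = np.random.default_rng(0)
        layer = GVPConvLayer((6, 2), (4, 1), rng)
        s = Tensor(rng.normal(size=(2, 6)))
        V = Tensor(rng.normal(size=(2, 2, 3)))
        ei = np.array([[0, 5], [1, 0]])
        with pytest.raises(ValidationError):
            layer(s, V, ei, Tensor(np.zeros((2, 4))),
                  Tensor(np.zeros((2, 1, 3))))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n = 5
        layer = GVPConvLayer((6, 2), (4, 1), rng)
        s = rng.normal(size=(n, 6))
        V = rng.normal(size=(n, 2, 3))
        ei = self._toy_graph(rng, n)
        es = rng.normal(size=(ei.shape[1], 4))
        ev = rng.normal(size=(ei.shape[1], 1, 3))
        s1, v1 = layer(Tensor(s), Tensor(V), ei, Tensor(es), Tensor(ev))
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        s2, v2 = layer(Tensor(s[perm]), Tensor(V[perm]), inv[ei],
                       Tensor(es), Tensor(ev))
        assert np.abs(s2.data - s1.data[perm]).max() < 1e-10
        assert np.abs(v2.data - v1.data[perm]).max() < 1e-10

    def test_rotation_equivariance_through_full_layer(self):
        rng = np.random.default_rng(3)
        n = 5
        layer = GVPConvLayer((6, 2), (4, 1), rng)
        s = rng.normal(size=(n, 6))
        V = rng.normal(size=(n, 2, 3))
        ei = self._toy_graph(rng, n)
        es = rng.normal(size=(ei.shape[1], 4))
        ev = rng.normal(size=(ei.shape[1], 1, 3))
        R = ortho_group.rvs(3, random_state=11)
        s1, v1 = layer(Tensor(s), Tensor(V), ei, Tensor(es), Tensor(ev))
        s2, v2 = layer(Tensor(s), Tensor(V @ R.T), ei, Tensor(es),
                       Tensor(ev @ R.T))
        assert np.abs(s2.data - s1.data).max() < 1e-9
        assert np.abs(v2.data - v1.data @ R.T).max() < 1e-9


@pytest.fixture(scope="module")
def fixture_pairs():
    return gen_classification_fixture(12, seed=3)


class TestClassifierForward:
    def test_probability_in_unit_interval(self, fixture_pairs):
        pairs, _ = fixture_pairs
        net = DualGraphClassifier(72, 16, tiny_config())
        p = net.forward(pairs)
        assert ((p.data > 0) & (p.data < 1)).all()

    def test_rotation_invariance_end_to_end(self):
        helix = gen_helix_backbone(12, seed=9, jitter=0.05)
        stack = EncoderStack()
        pssm = gen_pssm(helix.sequence, 2)
        scores = gen_residue_scores(helix.sequence, 2)
        g0 = build_graph(helix, stack, k_neighbors=8, pssm=pssm,
                         residue_scores=scores)
        net = DualGraphClassifier(72, 16, tiny_config())
        p0 = net.forward([(g0, g0)]).data
        for i in range(5):
            R = ortho_group.rvs(3, random_state=i)
            if i % 2:
                R[:, 0] *= -1
            g1 = build_graph(helix.transformed(R, np.ones(3) * i), stack,
                             k_neighbors=8, pssm=pssm,
                             residue_scores=scores)
            p1 = net.forward([(g1, g1)]).data
            assert np.abs(p1 - p0).max() < 1e-4

    def test_consistent_reindexing_invariance(self, helix_graph):
        g = helix_graph
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        gp = ProteinGraph(
            node_scalar=g.node_scalar[perm], node_vector=g.node_vector[perm],
            edge_index=inv[g.edge_index], edge_scalar=g.edge_scalar,
            edge_vector=g.edge_vector, stack_signature=g.stack_signature)
        net = DualGraphClassifier(72, 16, tiny_config())
        pa = net.forward([(g, g)]).data
        pb = net.forward([(gp, gp)]).data
        assert np.abs(pa - pb).max() < 1e-5

    def test_stack_mismatch_rejected(self, helix_graph):
        other = ProteinGraph(
            node_scalar=helix_graph.node_scalar,
            node_vector=helix_graph.node_vector,
            edge_index=helix_graph.edge_index,
            edge_scalar=helix_graph.edge_scalar,
            edge_vector=helix_graph.edge_vector,
            stack_signature="different")
        net = DualGraphClassifier(72, 16, tiny_config())
        with pytest.raises(ValidationError):
            net.forward([(helix_graph, other)])

    def test_batch_equals_individual_forward(self, fixture_pairs):
        pairs, _ = fixture_pairs
        net = DualGraphClassifier(72, 16, tiny_config())
        batched = net.forward(pairs[:4]).data
        single = np.array([float(net.forward([p]).data[0])
                           for p in pairs[:4]])
        assert np.abs(batched - single).max() < 1e-10


class TestLossAndCheckpoint:
    def test_loss_matches_independent_scalar_bce(self, fixture_pairs):
        pairs, labels = fixture_pairs
        net = DualGraphClassifier(72, 16, tiny_config())
        probs = net.forward(pairs)
        loss = binary_cross_entropy(probs, labels)
        eps = 1e-7
        manual = 0.0
        for pi, y in zip(probs.data, labels):
            pc = pi * (1 - 2 * eps) + eps
            manual += -(y * np.log(pc) + (1 - y) * np.log(1 - pc))
        manual /= len(labels)
        assert abs(float(loss.data) - manual) < 1e-6

    def test_checkpoint_roundtrip(self, tmp_path, fixture_pairs):
        pairs, _ = fixture_pairs
        net = DualGraphClassifier(72, 16, tiny_config(seed=5))
        before = net.forward(pairs[:3]).data
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = DualGraphClassifier.load(path)
        after = back.forward(pairs[:3]).data
        assert np.array_equal(before, after)


class TestTrainingHarness:
    def test_pretrain_reports_five_folds(self, fixture_pairs):
        pairs, labels = fixture_pairs
        cfg = tiny_config(epochs=2, cv_folds=5, batch_size=12, patience=0)
        res = pretrain(pairs, labels, config=cfg, seed=0)
        assert len(res.fold_reports) == 5
        assert res.summary()

    def test_fold_assignment_deterministic(self, fixture_pairs):
        pairs, labels = fixture_pairs
        from sklearn.model_selection import KFold
        a = list(KFold(5, shuffle=True, random_state=3).split(pairs))
        b = list(KFold(5, shuffle=True, random_state=3).split(pairs))
        for (tr1, va1), (tr2, va2) in zip(a, b):
            assert (tr1 == tr2).all() and (va1 == va2).all()

    def test_single_class_fold_skipped(self, fixture_pairs):
        pairs, _ = fixture_pairs
        labels = np.ones(len(pairs), dtype=int)
        cfg = tiny_config(epochs=1, cv_folds=3, batch_size=12)
        model = ThermostabilityModel(pairs, labels, cfg)
        res = model.fit(seed=0)
        assert all(f.skipped for f in res.fold_reports)

    def test_finetune_updates_only_gvp_parameters(self, fixture_pairs):
        pairs, labels = fixture_pairs
        cfg = tiny_config(epochs=2, cv_folds=2, batch_size=12, patience=0)
        pre = pretrain(pairs, labels, config=cfg, seed=0)
        before = pre.network.state_dict()
        fin = finetune(pre, pairs, labels, config=cfg, seed=1)
        after = fin.network.state_dict()
        gvp_names = pre.network.gvp_parameter_names()
        frozen = set(before) - gvp_names
        assert frozen   # attention + head exist
        for name in frozen:
            assert np.array_equal(before[name], after[name]), name
        # at least some encoder parameters moved
        moved = [n for n in gvp_names
                 if not np.array_equal(before[n], after[n])]
        assert moved

    def test_trainable_set_is_exactly_encoder(self, fixture_pairs):
        pairs, _ = fixture_pairs
        net = DualGraphClassifier(72, 16, tiny_config())
        names = net.gvp_parameter_names()
        assert all(n.startswith("encoder.") for n in names)
        rest = set(net.parameters()) - names
        assert rest == {"attn.wq", "attn.wk", "attn.wv", "attn.wo",
                        "head.w", "head.b"}

    def test_finetune_loss_decreases_early(self, fixture_pairs):
        """Warm-started fine-tuning lowers training loss over the first
        epochs in most seeds (stochastic sanity)."""
        pairs, labels = fixture_pairs
        cfg = tiny_config(epochs=10, cv_folds=2, batch_size=12, patience=0)
        pre = pretrain(pairs, labels, config=cfg, seed=0)
        wins = 0
        for seed in range(5):
            fin = finetune(pre, pairs, labels, config=cfg, seed=seed)
            losses = [h["loss"] for h in fin.history]
            if losses[-1] < losses[0]:
                wins += 1
        assert wins >= 4

    def test_architecture_mismatch_rejected(self, fixture_pairs):
        pairs, labels = fixture_pairs
        net_a = DualGraphClassifier(72, 16, tiny_config())
        net_b = DualGraphClassifier(72, 16, tiny_config(hidden_dim=20))
        with pytest.raises(ValidationError):
            net_a.load_state_dict(net_b.state_dict())

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ModelConfig(dropout_pretrain=1.5)
        with pytest.raises(ValidationError):
            ModelConfig(hidden_dim=0)
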