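import numpy as np
import pytest

from mmgx._autograd import Tensor, segment_softmax, segment_sum
from mmgx.graphs import build_graphs
from mmgx.network import (Adam, GraphBatch, GraphScheme, MMGXNetwork,
                          ModelConfig, batch_molecules, initial_pooling)


class TestAutograd:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        x = Tensor(rng.normal(size=(5, 4)))
        seg = np.array([0, 0, 1, 1, 1])

        def loss_value():
            h = (x @ W).tanh()
            a = segment_softmax(h.sum(axis=1, keepdims=True), seg, 2)
            return (segment_sum(a * h, seg, 2).sigmoid()).sum()

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            g = W.grad[idx]
            W.data[idx] += eps
            up = loss_value().data
            W.data[idx] -= 2 * eps
            down = loss_value().data
            W.data[idx] += eps
            assert g == pytest.approx((up - down) / (2 * eps), rel=1e-5)

    def test_segment_softmax_normalizes(self):
        x = Tensor(np.random.default_rng(1).normal(size=(7, 1)))
        seg = np.array([0, 0, 0, 1, 1, 2, 2])
        y = segment_softmax(x, seg, 3).data.reshape(-1)
        sums = np.zeros(3)
        np.add.at(sums, seg, y)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestScheme:
    def test_parse_and_label(self):
        s = GraphScheme.parse("A+F+P+J")
        assert s.representations == ("A", "F", "P", "J")
        assert s.label == "A+F+P+J"

    @pytest.mark.parametrize("bad", ["", "A+A", "A+X"])
    def test_invalid_schemes_rejected(self, bad):
        with pytest.raises(ValueError):
            GraphScheme.parse(bad)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(embedding_dim=0)
        with pytest.raises(ValueError):
            ModelConfig(readout_steps=0)


@pytest.fixture(scope="module")
def small_net():
    scheme = GraphScheme.parse("A+J")
    cfg = ModelConfig(embedding_dim=32)
    return MMGXNetwork(scheme, cfg, seed=0), scheme


@pytest.fixture(scope="module")
def molecules():
    smis = ["CCO", "CC(=O)OC1=CC=CC=C1C(=O)O", "c1ccccc1CCN", "C1CC1CCO"]
    return [build_graphs(s, ("A", "J")) for s in smis]


class TestInitialPooling:
    def test_pooled_slice_is_sum_over_atom_map(self, molecules):
        gd = molecules[1]
        aug = initial_pooling(gd["A"], gd["J"])
        base_dim = gd["J"].node_features.shape[1]
        for i, atoms in enumerate(gd["J"].atom_map):
            expected = gd["A"].node_features[sorted(atoms)].sum(axis=0)
            assert np.allclose(aug[i, base_dim:], expected)

    def test_single_atom_node_copies_features(self):
        gd = build_graphs("CCCC", ("A", "J"))
        aug = initial_pooling(gd["A"], gd["J"])
        base_dim = gd["J"].node_features.shape[1]
        for i, atoms in enumerate(gd["J"].atom_map):
            if len(atoms) == 1:
                (a,) = atoms
                assert np.allclose(aug[i, base_dim:], gd["A"].node_features[a])


class TestForward:
    def test_default_embedding_width_is_256(self):
        net = MMGXNetwork(GraphScheme.parse("A"), ModelConfig(), seed=0)
        gd = [build_graphs("CC", ("A",))]
        out = net.forward(batch_molecules(gd, net.scheme))
        assert out.embeddings["A"].shape == (1, 256)

    def test_concatenated_width_for_two_graphs(self, small_net, molecules):
        net, scheme = small_net
        assert net.head_hidden.W.data.shape[0] == 2 * 32

    def test_classification_output_in_unit_interval(self, small_net, molecules):
        net, scheme = small_net
        out = net.forward(batch_molecules(molecules, scheme))
        assert np.all((out.prediction >= 0) & (out.prediction <= 1))

    def test_attention_sums_to_one_per_graph(self, small_net, molecules):
        net, scheme = small_net
        out = net.forward(batch_molecules(molecules, scheme))
        for rep, (w, gid) in out.attention.items():
            sums = np.zeros(len(molecules))
            np.add.at(sums, gid, w)
            assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_node_graph_gets_attention_one(self):
        net = MMGXNetwork(GraphScheme.parse("J"), ModelConfig(embedding_dim=16), seed=0)
        gd = [build_graphs("c1ccccc1", ("J",))]
        out = net.forward(batch_molecules(gd, net.scheme))
        w, _ = out.attention["J"]
        assert w == pytest.approx([1.0])

    def test_scheme_batch_mismatch_rejected(self, small_net, molecules):
        net, scheme = small_net
        batches = batch_molecules(molecules, scheme)
        del batches["J"]
        with pytest.raises(ValueError):
            net.forward(batches)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            GraphBatch([build_graphs("CC", ("A",))["A"].__class__(
                "A", np.zeros((0, 26)), [], [], 0)])


class TestPermutationInvariance:
    def _permuted_atom_graph(self, graph, perm):
        inv = np.argsort(perm)
        feats = graph.node_features[perm]
        edges = [(min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in graph.edges]
        import copy
        g = copy.copy(graph)
        g.node_features = feats
        g.edges = edges
        g.atom_map = [frozenset([i]) for i in range(len(perm))]
        return g

    def test_embedding_invariant_under_node_reordering(self):
        net = MMGXNetwork(GraphScheme.parse("A"), ModelConfig(embedding_dim=24), seed=4)
        g = build_graphs("CC(=O)OC1=CC=CC=C1C(=O)O", ("A",))["A"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_nodes)
        gp = self._permuted_atom_graph(g, perm)
        out1 = net.forward(batch_molecules([{"A": g}], net.scheme))
        out2 = net.forward(batch_molecules([{"A": gp}], net.scheme))
        assert np.allclose(out1.embeddings["A"], out2.embeddings["A"], atol=1e-5)
        assert out1.prediction == pytest.approx(out2.prediction, abs=1e-8)
        w1, _ = out1.attention["A"]
        w2, _ = out2.attention["A"]
        assert np.allclose(w1[perm], w2, atol=1e-8)


class TestTrainingStep:
    def test_gradient_reaches_every_encoder(self, small_net, molecules):
        net, scheme = small_net
        out = net.forward(batch_molecules(molecules, scheme))
        loss = net.loss(out, np.array([1.0, 0.0, 1.0, 0.0]))
        for p in net.parameters():
            p.grad = None
        loss.backward()
        for enc in net.encoders:
            norm = np.sqrt(sum((p.grad ** 2).sum() for p in enc.parameters()
                               if p.grad is not None))
            assert np.isfinite(norm) and norm > 0

    def test_adam_step_reduces_loss_on_fixed_batch(self, molecules):
        net = MMGXNetwork(GraphScheme.parse("A"), ModelConfig(embedding_dim=16), seed=1)
        batches = batch_molecules(molecules, net.scheme)
        y = np.array([1.0, 0.0, 1.0, 0.0])
        opt = Adam(net.parameters(), lr=5e-3)
        first = net.loss(net.forward(batches), y).data
        for _ in range(30):
            loss = net.loss(net.forward(batches), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert net.loss(net.forward(batches), y).data < first * 0.5

    def test_state_roundtrip(self, small_net, molecules):
        net, scheme = small_net
        batches = batch_molecules(molecules, scheme)
        before = net.forward(batches).prediction
        state = net.state()
        for p in net.parameters():
            p.data = p.data + 0.1
        net.load_state(state)
        assert np.array_equal(net.forward(batches).prediction, before)
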