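"""Graph propagation transformer: loop oracles, invariants, readout."""

import numpy as np
import pytest
from rdkit import Chem

from molfuse.autodiff import Tensor
from molfuse.fusion_model import MolPropertyModel
from molfuse.gptrans import (
    GPTransParams,
    attention_bias,
    edge_to_node,
    encode_graph,
    layer_forward,
    node_attention,
    node_to_edge,
)
from molfuse.hier_graph import build_hier_graph, project_latents

RNG = np.random.default_rng(7)
TOL = 1e-6


def _sm(v):
    e = np.exp(v - v.max())
    return e / e.sum()


@pytest.fixture(scope="module")
def params():
    return GPTransParams.init(seed=3, trainable=False)


@pytest.fixture(scope="module")
def small_state():
    n = 5
    return RNG.normal(size=(n, 256)), RNG.normal(size=(n, n, 64))


def _oracle_layer(xn, xe, p):
    """Straight-line reimplementation with explicit loops."""
    n = xn.shape[0]
    nh, dh, dv = 4, 4, 64
    phi = np.zeros((nh, n, n))
    for i in range(n):
        for j in range(n):
            for h in range(nh):
                phi[h, i, j] = xe[i, j] @ p.W_reduce[:, h]
    A = np.zeros((nh, n, n))
    xprime = np.zeros((n, 256))
    for h in range(nh):
        Q = xn @ p.W_Q[:, h * dh : (h + 1) * dh]
        K = xn @ p.W_K[:, h * dh : (h + 1) * dh]
        V = xn @ p.W_V[:, h * dv : (h + 1) * dv]
        for i in range(n):
            for j in range(n):
                A[h, i, j] = Q[i] @ K[j] / np.sqrt(dh) + phi[h, i, j]
        for i in range(n):
            xprime[i, h * dv : (h + 1) * dv] = _sm(A[h, i]) @ V
    xe_p = np.zeros((n, n, 64))
    for i in range(n):
        for j in range(n):
            t = np.array([A[h, i, j] + _sm(A[h, i])[j] for h in range(4)])
            xe_p[i, j] = t @ p.W_expand
    xpp = np.zeros((n, 256))
    for i in range(n):
        s = np.zeros(64)
        for c in range(64):
            col = xe_p[i, :, c]
            s[c] = (col * _sm(col)).sum()
        xpp[i] = s @ p.W_fc + p.b_fc
    return (xprime + xpp) @ p.W_O, xe_p, phi, A, xprime, xpp


class TestAttentionBias:
    def test_zero_edges_zero_bias(self, params):
        phi = attention_bias(np.zeros((3, 3, 64)), params.W_reduce)
        assert phi.shape == (4, 3, 3)
        assert np.allclose(phi, 0)

    def test_single_edge_scalar_arithmetic(self, params):
        xe = np.zeros((2, 2, 64))
        xe[0, 1] = RNG.normal(size=64)
        phi = attention_bias(xe, params.W_reduce)
        for h in range(4):
            assert abs(phi[h, 0, 1] - xe[0, 1] @ params.W_reduce[:, h]) < TOL

    def test_matches_loop_oracle(self, params, small_state):
        _, xe = small_state
        phi = attention_bias(xe, params.W_reduce)
        _, _, phi_o, _, _, _ = _oracle_layer(*small_state, params)
        assert np.allclose(phi, phi_o, rtol=TOL, atol=TOL)


class TestNodeAttention:
    def test_single_node_returns_value(self, params):
        xn = RNG.normal(size=(1, 256))
        phi = RNG.normal(size=(4, 1, 1))
        xp, _ = node_attention(xn, phi, params)
        v = np.concatenate([xn @ params.W_V[:, h * 64 : (h + 1) * 64] for h in range(4)], -1)
        assert np.allclose(xp, v, rtol=TOL)

    def test_masked_bias_reduces_to_self_attention(self, params):
        n = 4
        xn = RNG.normal(size=(n, 256))
        phi = np.full((4, n, n), -1e9)
        for h in range(4):
            np.fill_diagonal(phi[h], 0.0)
        xp, _ = node_attention(xn, phi, params)
        v = np.concatenate([xn @ params.W_V[:, h * 64 : (h + 1) * 64] for h in range(4)], -1)
        assert np.allclose(xp, v, rtol=1e-5, atol=1e-5)

    def test_matches_loop_oracle(self, params, small_state):
        xn, xe = small_state
        phi = attention_bias(xe, params.W_reduce)
        xp, A = node_attention(xn, phi, params)
        _, _, _, A_o, xp_o, _ = _oracle_layer(xn, xe, params)
        assert np.allclose(A, A_o, rtol=TOL, atol=TOL)
        assert np.allclose(xp, xp_o, rtol=TOL, atol=TOL)

    def test_softmax_rows_normalized(self, params, small_state):
        xn, xe = small_state
        phi = attention_bias(xe, params.W_reduce)
        _, A = node_attention(xn, phi, params)
        from molfuse.gptrans import _softmax

        s = _softmax(A, -1)
        assert np.allclose(s.sum(axis=-1), 1.0, atol=TOL)


class TestNodeToEdge:
    def test_uniform_softmax_case(self, params):
        A = np.zeros((4, 2, 2))
        out = node_to_edge(A, params.W_expand)
        expect = (0.5 * np.ones(4)) @ params.W_expand
        for i in range(2):
            for j in range(2):
                assert np.allclose(out[i, j], expect, rtol=TOL)

    def test_zero_map_zero_output(self):
        assert np.allclose(node_to_edge(RNG.normal(size=(4, 3, 3)), np.zeros((4, 64))), 0)

    def test_matches_loop_oracle(self, params, small_state):
        xn, xe = small_state
        phi = attention_bias(xe, params.W_reduce)
        _, A = node_attention(xn, phi, params)
        _, xe_o, _, _, _, _ = _oracle_layer(xn, xe, params)
        assert np.allclose(node_to_edge(A, params.W_expand), xe_o, rtol=TOL, atol=TOL)


class TestEdgeToNode:
    def test_singleton_reduction(self, params):
        xe = RNG.normal(size=(1, 1, 64))
        out = edge_to_node(xe, params.W_fc, params.b_fc)
        assert np.allclose(out[0], xe[0, 0] @ params.W_fc + params.b_fc, rtol=TOL)

    def test_constant_tensor_symmetry(self, params):
        xe = np.full((3, 3, 64), 1.7)
        out = edge_to_node(xe, params.W_fc, params.b_fc)
        # softmax uniform over neighbours; gated sum returns the constant
        assert np.allclose(out, np.tile(xe[0, 0] @ params.W_fc + params.b_fc, (3, 1)), rtol=1e-5)

    def test_matches_loop_oracle(self, params, small_state):
        xn, xe = small_state
        _, xe_o, _, _, _, xpp_o = _oracle_layer(xn, xe, params)
        assert np.allclose(edge_to_node(xe_o, params.W_fc, params.b_fc), xpp_o, rtol=TOL, atol=TOL)


class TestLayerForward:
    def test_full_layer_matches_composed_oracle(self, params, small_state):
        out_n, out_e = layer_forward(*small_state, params)
        o_n, o_e, *_ = _oracle_layer(*small_state, params)
        assert np.abs(out_n - o_n).max() / np.abs(o_n).max() < TOL
        assert np.abs(out_e - o_e).max() / np.abs(o_e).max() < TOL

    def test_tensor_path_equals_numpy_path(self, params, small_state):
        xn, xe = small_state
        pt = GPTransParams.init(seed=3, trainable=True)
        tn, te = layer_forward(Tensor(xn), Tensor(xe), pt)
        nn, ne = layer_forward(xn, xe, params)
        assert np.allclose(tn.data, nn, rtol=1e-9)
        assert np.allclose(te.data, ne, rtol=1e-9)

    def test_zero_params_zero_output(self, small_state):
        z = GPTransParams(*[np.zeros_like(a) for a in
                            GPTransParams.init(seed=0, trainable=False).parameters()])
        out_n, _ = layer_forward(*small_state, z)
        assert np.allclose(out_n, 0)


class TestEncodeGraph:
    def _projected(self, smiles, seed=5):
        rng = np.random.default_rng(seed)
        g = build_hier_graph(smiles)
        project_latents(g, rng.normal(size=(31, 256)) * 0.1, np.zeros(256),
                        rng.normal(size=(6, 64)) * 0.1, np.zeros(64), rng.normal(size=64) * 0.1)
        return g

    def test_smallest_graph_finite(self, params):
        g = self._projected("C")  # 1 atom + 1 motif + super
        out = encode_graph(g, params)
        assert out.shape == (256,)
        assert np.isfinite(out).all()

    def test_permutation_invariance_of_readout(self, params):
        mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        rng = np.random.default_rng(2)
        g1 = self._projected(Chem.MolToSmiles(mol))
        e1 = encode_graph(g1, params)
        for _ in range(3):
            perm = [int(p) for p in rng.permutation(mol.GetNumAtoms())]
            mol2 = Chem.RenumberAtoms(mol, perm)
            rng2 = np.random.default_rng(5)
            g2 = build_hier_graph(mol2)
            project_latents(g2, rng2.normal(size=(31, 256)) * 0.1, np.zeros(256),
                            rng2.normal(size=(6, 64)) * 0.1, np.zeros(64),
                            rng2.normal(size=64) * 0.1)
            e2 = encode_graph(g2, params)
            assert np.abs(e1 - e2).max() < 1e-5

    def test_unprojected_graph_raises(self, params):
        with pytest.raises(ValueError):
            encode_graph(build_hier_graph("CCO"), params)

    def test_finiteness_on_fixture_molecules(self, molecules_300):
        """No NaN/Inf across a large diverse fixture sweep (full model path)."""
        model = MolPropertyModel(n_tasks=1, seed=0)
        from molfuse.autodiff import no_grad

        with no_grad():
            for smi in molecules_300:
                emb = model.graph_embedding(build_hier_graph(smi)).data
                assert np.isfinite(emb).all(), smi
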