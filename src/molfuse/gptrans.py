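"""Graph propagation transformer message passing.

One layer runs three propagation paths over the hierarchical graph and is
applied (weight-shared) for a fixed number of iterations:

1. node→node: multi-head attention over *all* node pairs, with an additive
   per-head bias ``phi`` predicted from the edge embeddings — graph structure
   enters through the bias, not through masking:
   ``A = Q K^T / sqrt(d_head) + phi``, ``x' = softmax(A) V``.
2. node→edge: the pre- and post-softmax attention maps are summed and lifted
   from the ``n_head`` channels into edge space:
   ``x_edge' = (A + softmax(A)) W_expand``.
3. edge→node: edges are gated by a softmax over the neighbour axis,
   summed out, and mapped back to node width:
   ``x'' = FC(sum_j x_edge'[i,j] ⊙ softmax_j(x_edge'[i,j]))``.

The residual aggregation ``x''' = (x' + x'') W_O`` closes the layer. The
molecule-level readout is the super-node row after the final iteration.

Head shapes follow the printed constants ``d = 64``, ``n_head = 4``,
``d_head = 4``: query/key width per head is ``d_head`` (used in the
attention scaling), while the per-head value width is ``256 / n_head = 64``
so that the head concatenation restores the 256-d node width.

Every function operates identically on NumPy arrays and autodiff Tensors;
the NumPy path doubles as an inference/reference route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat

NODE_DIM = 256
EDGE_DIM = 64
N_HEAD = 4
D_HEAD = 4


def glorot(rng: np.random.Generator, shape: tuple, dtype=np.float64) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


def _softmax(x, axis: int):
    if isinstance(x, Tensor):
        return x.softmax(axis=axis)
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def _cat(parts, axis: int):
    if any(isinstance(p, Tensor) for p in parts):
        return concat(parts, axis=axis)
    return np.concatenate(parts, axis=axis)


@dataclass
class GPTransParams:
    """Weight-shared parameters of one propagation layer.

    ``W_K``/``W_Q``: 256 → n_head·d_head, ``W_V``: 256 → 256 (64 per head),
    ``W_reduce``: 64 → n_head (edge bias), ``W_expand``: n_head → 64,
    ``W_fc``/``b_fc``: 64 → 256 (edge→node), ``W_O``: 256 → 256.
    """

    W_K: object
    W_Q: object
    W_V: object
    W_reduce: object
    W_expand: object
    W_fc: object
    b_fc: object
    W_O: object
    n_head: int = N_HEAD
    d_head: int = D_HEAD

    @classmethod
    def init(cls, seed: int = 0, trainable: bool = True, n_head: int = N_HEAD, d_head: int = D_HEAD,
             dtype=np.float64):
        rng = np.random.default_rng(seed)
        dv = NODE_DIM // n_head
        mk = (lambda s: Parameter(glorot(rng, s, dtype))) if trainable else (lambda s: glorot(rng, s, dtype))
        zeros = (lambda s: Parameter(np.zeros(s, dtype))) if trainable else (lambda s: np.zeros(s, dtype))
        assert n_head * dv == NODE_DIM
        return cls(
            W_K=mk((NODE_DIM, n_head * d_head)),
            W_Q=mk((NODE_DIM, n_head * d_head)),
            W_V=mk((NODE_DIM, NODE_DIM)),
            W_reduce=mk((EDGE_DIM, n_head)),
            W_expand=mk((n_head, EDGE_DIM)),
            W_fc=mk((EDGE_DIM, NODE_DIM)),
            b_fc=zeros((NODE_DIM,)),
            W_O=mk((NODE_DIM, NODE_DIM)),
        )

    def parameters(self) -> list:
        return [self.W_K, self.W_Q, self.W_V, self.W_reduce, self.W_expand, self.W_fc, self.b_fc, self.W_O]


def attention_bias(x_edge, W_reduce):
    """Per-head attention biases phi: (n_head, N, N) from edge latents (N, N, 64)."""
    return (x_edge @ W_reduce).transpose((2, 0, 1))


def node_attention(x_node, phi, params: GPTransParams):
    """Biased multi-head self-attention over all node pairs.

    Returns ``(x_node', A)`` where ``A`` stacks the per-head pre-softmax
    logits as (n_head, N, N).
    """
    nh, dh = params.n_head, params.d_head
    dv = NODE_DIM // nh
    scale = 1.0 / math.sqrt(dh)
    n = x_node.shape[0]
    # per-head projections as one matmul each, then (n_head, N, width) views
    Q = (x_node @ params.W_Q).reshape((n, nh, dh)).transpose((1, 0, 2))
    K = (x_node @ params.W_K).reshape((n, nh, dh)).transpose((1, 0, 2))
    V = (x_node @ params.W_V).reshape((n, nh, dv)).transpose((1, 0, 2))
    A = (Q @ K.transpose((0, 2, 1))) * scale + phi  # (n_head, N, N)
    out = _softmax(A, -1) @ V  # (n_head, N, dv)
    return out.transpose((1, 0, 2)).reshape((n, NODE_DIM)), A


def node_to_edge(A, W_expand):
    """Lift attention channels into edge space: (A + softmax(A)) W_expand."""
    T = A + _softmax(A, -1)  # (n_head, N, N)
    return T.transpose((1, 2, 0)) @ W_expand  # (N, N, 64)


def edge_to_node(x_edge_p, W_fc, b_fc):
    """Gate edges by a neighbour-axis softmax, sum out, map to node width."""
    gate = _softmax(x_edge_p, 1)
    s = (x_edge_p * gate).sum(axis=1)  # (N, 64)
    return s @ W_fc + b_fc


def layer_forward(x_node, x_edge, params: GPTransParams):
    """One full propagation layer; returns the next (x_node, x_edge)."""
    phi = attention_bias(x_edge, params.W_reduce)
    x_p, A = node_attention(x_node, phi, params)
    x_edge_p = node_to_edge(A, params.W_expand)
    x_pp = edge_to_node(x_edge_p, params.W_fc, params.b_fc)
    x_ppp = (x_p + x_pp) @ params.W_O
    return x_ppp, x_edge_p


def encode_graph(g_or_latents, params: GPTransParams, n_iterations: int = 3):
    """Run the weight-shared layer ``n_iterations`` times and read out the
    super node. Accepts a projected :class:`~molfuse.hier_graph.HierMolGraph`
    or a ``(node_latent, edge_latent)`` pair."""
    if hasattr(g_or_latents, "node_latent"):
        x_node, x_edge = g_or_latents.node_latent, g_or_latents.edge_latent
        if x_node is None:
            raise ValueError("graph has no latent features; call project_latents first")
    else:
        x_node, x_edge = g_or_latents
    for _ in range(n_iterations):
        x_node, x_edge = layer_forward(x_node, x_edge, params)
    return x_node[-1]
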