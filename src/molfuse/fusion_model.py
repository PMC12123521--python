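"""Cross-modal alignment, bottleneck-attention fusion, and prediction head.

The 256-d graph readout and the 768-d frozen image embedding are aligned by
dimension-preserving linear maps, concatenated into a 1024-d vector, passed
through a channel-only bottleneck attention module (BAM) in its residual
form ``x ⊙ (1 + σ(MLP(x)))``, and mapped 1024→256→64 by two rectified
linear layers before the sigmoid task output. Training uses masked binary
cross-entropy so multi-label datasets with missing labels contribute only
their observed entries.

:class:`MolPropertyModel` assembles every trainable part of the pipeline
(feature projections, the weight-shared propagation layer, fusion and head);
the image encoder is pretrained separately, frozen, and therefore never a
member of this parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import gptrans, hier_graph
from .autodiff import Parameter, Tensor, concat
from .gptrans import GPTransParams, glorot

GRAPH_DIM = 256
IMAGE_DIM = 768
CONCAT_DIM = GRAPH_DIM + IMAGE_DIM  # 1024
CLAMP_EPS = 1e-7


def _cat(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        return concat(parts, axis=axis)
    return np.concatenate(parts, axis=axis)


def _sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0.0)


@dataclass
class FusionParams:
    """Alignment maps, BAM gate MLP, and the 1024→256→64→C head."""

    W_g: object  # 256 -> 256
    W_i: object  # 768 -> 768
    W_bam1: object  # 1024 -> 1024/r
    b_bam1: object
    W_bam2: object  # 1024/r -> 1024
    b_bam2: object
    W_h1: object  # 1024 -> 256
    b_h1: object
    W_h2: object  # 256 -> 64
    b_h2: object
    W_o: object  # 64 -> C
    b_o: object

    @classmethod
    def init(cls, n_tasks: int = 1, bam_reduction: int = 16, head_widths=(256, 64), seed: int = 0,
             trainable: bool = True, dtype=np.float64):
        rng = np.random.default_rng(seed)
        mk = (lambda s: Parameter(glorot(rng, s, dtype))) if trainable else (lambda s: glorot(rng, s, dtype))
        zeros = (lambda s: Parameter(np.zeros(s, dtype))) if trainable else (lambda s: np.zeros(s, dtype))
        h1, h2 = head_widths
        r = CONCAT_DIM // bam_reduction
        return cls(
            W_g=mk((GRAPH_DIM, GRAPH_DIM)),
            W_i=mk((IMAGE_DIM, IMAGE_DIM)),
            W_bam1=mk((CONCAT_DIM, r)),
            b_bam1=zeros((r,)),
            W_bam2=mk((r, CONCAT_DIM)),
            b_bam2=zeros((CONCAT_DIM,)),
            W_h1=mk((CONCAT_DIM, h1)),
            b_h1=zeros((h1,)),
            W_h2=mk((h1, h2)),
            b_h2=zeros((h2,)),
            W_o=mk((h2, n_tasks)),
            b_o=zeros((n_tasks,)),
        )

    def parameters(self) -> list:
        return [self.W_g, self.W_i, self.W_bam1, self.b_bam1, self.W_bam2, self.b_bam2,
                self.W_h1, self.b_h1, self.W_h2, self.b_h2, self.W_o, self.b_o]


def align(x_super, latent, params: FusionParams):
    """Map both modalities by their alignment matrices (Eq. dims preserved)."""
    return x_super @ params.W_g, latent @ params.W_i


def fuse(x_graph, x_image, params: FusionParams):
    """Concatenate and apply the channel-attention BAM residual gate."""
    x_cat = _cat([x_graph, x_image], -1)
    hidden = _relu(x_cat @ params.W_bam1 + params.b_bam1)
    gate = _sigmoid(hidden @ params.W_bam2 + params.b_bam2)
    return x_cat * (gate + 1.0)


def predict(x_fused, params: FusionParams):
    """Two rectified linear layers 1024→256→64, then the sigmoid output map."""
    h1 = _relu(x_fused @ params.W_h1 + params.b_h1)
    h2 = _relu(h1 @ params.W_h2 + params.b_h2)
    return _sigmoid(h2 @ params.W_o + params.b_o)


def masked_bce(y_hat, labels: np.ndarray, mask: np.ndarray | None = None, eps: float = CLAMP_EPS):
    """Mean binary cross-entropy over unmasked labels only.

    ``labels`` may contain NaN for missing entries (mask inferred); an
    explicit boolean ``mask`` selects the observed entries. Raises if every
    label is masked.
    """
    labels = np.asarray(labels, dtype=float)
    if mask is None:
        mask = ~np.isnan(labels)
    mask = np.asarray(mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("all labels are masked")
    y = np.where(mask, labels, 0.0)
    m = mask.astype(float)
    if isinstance(y_hat, Tensor):
        p = y_hat.clip(eps, 1.0 - eps)
        ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
        return (ll * Tensor(m)).sum() * (-1.0 / n_obs)
    p = np.clip(y_hat, eps, 1.0 - eps)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-(ll * m).sum() / n_obs)


class MolPropertyModel:
    """Every trainable component of the predictor, end to end.

    Parameters are autodiff :class:`Parameter` tensors; ``get_flat`` /
    ``set_flat`` expose the flat parameter vector the Reptile meta-learner
    interpolates. The frozen image encoder lives outside this class — its
    768-d embedding is an *input* here.
    """

    def __init__(self, n_tasks: int = 1, seed: int = 0, n_iterations: int = 3,
                 bam_reduction: int = 16, head_widths=(256, 64), clamp_eps: float = CLAMP_EPS,
                 dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.n_tasks = n_tasks
        self.n_iterations = n_iterations
        self.clamp_eps = clamp_eps
        self.dtype = dtype
        self.node_W = Parameter(glorot(rng, (hier_graph.ATOM_DIM, GRAPH_DIM), dtype))
        self.node_b = Parameter(np.zeros(GRAPH_DIM, dtype))
        self.edge_W = Parameter(glorot(rng, (hier_graph.BOND_DIM, gptrans.EDGE_DIM), dtype))
        self.edge_b = Parameter(np.zeros(gptrans.EDGE_DIM, dtype))
        self.virtual_embed = Parameter(glorot(rng, (1, gptrans.EDGE_DIM), dtype).ravel())
        self.gpt = GPTransParams.init(seed=int(rng.integers(2**31)), dtype=dtype)
        self.fusion = FusionParams.init(n_tasks=n_tasks, bam_reduction=bam_reduction,
                                        head_widths=head_widths, seed=int(rng.integers(2**31)),
                                        dtype=dtype)

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return ([self.node_W, self.node_b, self.edge_W, self.edge_b, self.virtual_embed]
                + self.gpt.parameters() + self.fusion.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.parameters()])

    def set_flat(self, theta: np.ndarray) -> None:
        off = 0
        for p in self.parameters():
            n = p.data.size
            p.data = theta[off : off + n].reshape(p.data.shape).astype(p.data.dtype)
            off += n
        if off != theta.size:
            raise ValueError("flat parameter vector has wrong length")

    def grad_flat(self) -> np.ndarray:
        return np.concatenate([
            (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
            for p in self.parameters()
        ])

    # -- forward --------------------------------------------------------------
    def graph_embedding(self, g: hier_graph.HierMolGraph) -> Tensor:
        node_latent, edge_latent = hier_graph.project_features(
            Tensor(g.node_raw.astype(self.dtype)), Tensor(g.edge_raw.astype(self.dtype)),
            Tensor(g.virtual_mask.astype(self.dtype)),
            self.node_W, self.node_b, self.edge_W, self.edge_b, self.virtual_embed,
        )
        return gptrans.encode_graph((node_latent, edge_latent), self.gpt, self.n_iterations)

    def forward(self, g: hier_graph.HierMolGraph, image_embedding: np.ndarray) -> Tensor:
        x_super = self.graph_embedding(g)
        x_graph, x_image = align(x_super, Tensor(np.asarray(image_embedding, dtype=self.dtype)), self.fusion)
        x_fused = fuse(x_graph, x_image, self.fusion)
        return predict(x_fused, self.fusion)  # (C,)

    def forward_batch(self, graphs, image_embeddings) -> Tensor:
        outs = [self.forward(g, e).reshape((1, self.n_tasks)) for g, e in zip(graphs, image_embeddings)]
        return concat(outs, axis=0)

    def predict_batch(self, graphs, image_embeddings) -> np.ndarray:
        return self.forward_batch(graphs, image_embeddings).data.copy()


def count_trainable(model: MolPropertyModel) -> int:
    """Number of trainable scalars (the frozen image encoder, not being part
    of the model's parameter set, is excluded by construction)."""
    return int(sum(p.data.size for p in model.parameters()))
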