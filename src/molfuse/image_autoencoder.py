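"""Convolutional self-attention autoencoder over 224×224 molecular depictions.

The encoder downsamples 224→112→56→28 through 3×3 conv / batch-norm / ReLU
blocks with average-pool halvings (channel path 3→64→128→256→1), then a
CNN-style self-attention block with a learnable Gaussian distance prior
summarises the 28×28 map into a 768-d latent:

* Q, K, V come from 3×3 convolutions of the single-channel feature map
  (Q/K carry ``n_qk`` channels so the cosine similarity is taken between
  genuine channel vectors; V stays single-channel so the attended map
  flattens to exactly 784 = 28·28);
* ``I[(i,j),(m,n)]`` is the cosine similarity between the Q vector at (i,j)
  and the K vector at (m,n);
* ``M[(i,j),(m,n)] = exp(-[(i-m)²(2^d/H)² + (j-n)²(2^d/W)²] / (2(θα)²))``
  reweights similarities by pooled-coordinate distance (d pooling layers
  rescale coordinates by 2^d); θ is learnable, α a fixed hyperparameter;
* ``A = I ⊙ M``; the context ``A·V`` is flattened to 784 and mapped by a
  768×784 linear layer to the latent.

The decoder restores 768→784, reshapes to 28×28 and upsamples back to
3×224×224 through mirrored conv blocks. Pretraining minimises mean squared
reconstruction error with plain minibatch gradient descent; afterwards the
encoder is frozen and only ever used to embed depictions.

The module runs in float32. The attention block is resolution-generic so
the same math can be exercised on tiny feature maps.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, avg_pool2d, conv2d, no_grad, upsample2x
from .gptrans import glorot

LATENT_DIM = 768
IMG_SIZE = 224
ATTN_SIZE = 28
N_POOL = 3  # pooling layers ahead of the attention block

_F32 = np.float32


def _kaiming(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_F32)


class BatchNorm:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, _F32))
        self.beta = Parameter(np.zeros(channels, _F32))
        self.running_mean = np.zeros(channels, _F32)
        self.running_var = np.ones(channels, _F32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        c = self.gamma.data.shape[0]
        shape = (1, c, 1, 1) if x.ndim == 4 else (1, c)
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        # fold normalisation and the affine map into one scale/shift pair so
        # only two full-size passes touch the feature map
        scale = self.gamma.reshape(shape) / (var + self.eps) ** 0.5
        shift = self.beta.reshape(shape) - mu * scale
        return x * scale + shift

    def parameters(self):
        return [self.gamma, self.beta]


class ConvBlock:
    """Conv → BatchNorm → ReLU."""

    def __init__(self, rng, c_in: int, c_out: int, k: int = 3, pad: int | None = None):
        self.w = Parameter(_kaiming(rng, (c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out, _F32))
        self.pad = (k // 2) if pad is None else pad
        self.bn = BatchNorm(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(conv2d(x, self.w, self.b, pad=self.pad)).relu()

    def parameters(self):
        return [self.w, self.b] + self.bn.parameters()


def _dist2_grid(h: int, w: int, d: int) -> np.ndarray:
    """Squared pooled-coordinate distances between all pixel pairs,
    ((i-m)(2^d/H))² + ((j-n)(2^d/W))², as an (h·w, h·w) matrix."""
    scale_i, scale_j = (2.0 ** d) / h, (2.0 ** d) / w
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ci, cj = ii.ravel(), jj.ravel()
    di = (ci[:, None] - ci[None, :]) * scale_i
    dj = (cj[:, None] - cj[None, :]) * scale_j
    return (di**2 + dj**2).astype(_F32)


def gaussian_distance_matrix(h: int = ATTN_SIZE, w: int = ATTN_SIZE, d: int = N_POOL,
                             theta: float = 1.0, alpha: float = 1.0) -> np.ndarray:
    """The Gaussian distance prior M (NumPy reference; symmetric, unit
    diagonal). Raises for a degenerate zero width θ·α."""
    if theta * alpha == 0:
        raise ValueError("theta * alpha must be nonzero")
    return np.exp(-_dist2_grid(h, w, d) / (2.0 * (theta * alpha) ** 2))


class ConvAttention:
    """CNN-style self-attention with the Gaussian distance prior."""

    def __init__(self, rng, h: int = ATTN_SIZE, w: int = ATTN_SIZE, d: int = N_POOL,
                 n_qk: int = 16, out_dim: int = LATENT_DIM, alpha: float = 1.0,
                 theta_init: float = 1.0):
        self.h, self.w, self.d = h, w, d
        self.alpha = alpha
        self.E_q = Parameter(_kaiming(rng, (n_qk, 1, 3, 3)))
        self.E_k = Parameter(_kaiming(rng, (n_qk, 1, 3, 3)))
        self.E_v = Parameter(_kaiming(rng, (1, 1, 3, 3)))
        self.theta = Parameter(np.array([theta_init], _F32))
        self.fc_w = Parameter(glorot(rng, (h * w, out_dim), _F32))
        self.fc_b = Parameter(np.zeros(out_dim, _F32))
        self._dist2 = Tensor(_dist2_grid(h, w, d))

    def conv_qkv(self, x: Tensor):
        """3×3 convolutions (zero padding 1) producing the Q, K, V maps."""
        return (conv2d(x, self.E_q, pad=1), conv2d(x, self.E_k, pad=1),
                conv2d(x, self.E_v, pad=1))

    def similarity_map(self, q: Tensor, k: Tensor) -> Tensor:
        """Pairwise cosine similarity between Q and K channel vectors.

        q, k: (B, C, h, w) → I: (B, h·w, h·w); zero-norm vectors get
        similarity 0 (guarded denominator)."""
        b, c = q.shape[0], q.shape[1]
        hw = q.shape[2] * q.shape[3]
        qf = q.reshape((b, c, hw)).transpose((0, 2, 1))  # (B, hw, C)
        kf = k.reshape((b, c, hw)).transpose((0, 2, 1))
        qn = qf * (((qf**2).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5)
        kn = kf * (((kf**2).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5)
        return qn @ kn.transpose((0, 2, 1))

    def distance_matrix(self) -> Tensor:
        """Differentiable M from the current learnable θ."""
        width = self.theta.reshape((1, 1)) * self.alpha
        if float(width.data[0, 0]) == 0.0:
            raise ValueError("theta * alpha must be nonzero")
        return (self._dist2 * (-0.5) / width**2).exp()

    def attend_and_embed(self, i_map: Tensor, m: Tensor, v: Tensor) -> Tensor:
        """A = I ⊙ M; flatten the attended context A·V and map to the latent."""
        b = v.shape[0]
        hw = self.h * self.w
        a = i_map * m
        ctx = a @ v.reshape((b, 1, hw)).transpose((0, 2, 1))  # (B, hw, 1)
        return ctx.reshape((b, hw)) @ self.fc_w + self.fc_b

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.conv_qkv(x)
        i_map = self.similarity_map(q, k)
        return self.attend_and_embed(i_map, self.distance_matrix(), v)

    def parameters(self):
        return [self.E_q, self.E_k, self.E_v, self.theta, self.fc_w, self.fc_b]


class ImageEncoder:
    """224×224×3 depiction → 768-d latent (downsampling stack + attention)."""

    def __init__(self, seed: int = 0, alpha: float = 1.0, theta_init: float = 1.0):
        rng = np.random.default_rng(seed)
        self.conv1 = ConvBlock(rng, 3, 64)
        self.conv2 = ConvBlock(rng, 64, 128)
        self.conv3 = ConvBlock(rng, 128, 256)
        self.pool_bn = BatchNorm(256)
        self.conv4 = ConvBlock(rng, 256, 1)
        self.attn = ConvAttention(rng, alpha=alpha, theta_init=theta_init)
        self.frozen = False

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-2:] != (IMG_SIZE, IMG_SIZE):
            raise ValueError(f"expected {IMG_SIZE}x{IMG_SIZE} input, got {x.shape}")
        y = avg_pool2d(self.conv1(x))          # 64 x 112 x 112
        y = avg_pool2d(self.conv2(y))          # 128 x 56 x 56
        y = self.pool_bn(avg_pool2d(self.conv3(y))).relu()  # 256 x 28 x 28
        y = self.conv4(y)                      # 1 x 28 x 28
        return self.attn(y)                    # (B, 768)

    def parameters(self):
        return (self.conv1.parameters() + self.conv2.parameters() + self.conv3.parameters()
                + self.pool_bn.parameters() + self.conv4.parameters() + self.attn.parameters())

    def set_training(self, mode: bool):
        for bn in (self.conv1.bn, self.conv2.bn, self.conv3.bn, self.pool_bn, self.conv4.bn):
            bn.training = mode

    def freeze(self):
        """Exclude the encoder from any further gradient update."""
        for p in self.parameters():
            p.requires_grad = False
            p.grad = None
        self.set_training(False)
        self.frozen = True

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]


class ImageDecoder:
    """768-d latent → 28×28 map → upsampled 3×224×224 reconstruction."""

    def __init__(self, seed: int = 1):
        rng = np.random.default_rng(seed)
        self.fc_w = Parameter(glorot(rng, (LATENT_DIM, ATTN_SIZE * ATTN_SIZE), _F32))
        self.fc_b = Parameter(np.zeros(ATTN_SIZE * ATTN_SIZE, _F32))
        self.conv1 = ConvBlock(rng, 1, 3)
        self.conv2 = ConvBlock(rng, 3, 3)
        self.conv3 = ConvBlock(rng, 3, 3, k=1, pad=0)

    def __call__(self, latent: Tensor) -> Tensor:
        b = latent.shape[0]
        y = (latent @ self.fc_w + self.fc_b).reshape((b, 1, ATTN_SIZE, ATTN_SIZE))
        y = upsample2x(self.conv1(y))  # 3 x 56 x 56
        y = upsample2x(self.conv2(y))  # 3 x 112 x 112
        y = upsample2x(self.conv3(y))  # 3 x 224 x 224
        return y

    def parameters(self):
        return ([self.fc_w, self.fc_b] + self.conv1.parameters() + self.conv2.parameters()
                + self.conv3.parameters())

    def set_training(self, mode: bool):
        for bn in (self.conv1.bn, self.conv2.bn, self.conv3.bn):
            bn.training = mode


class ImageAutoencoder:
    def __init__(self, seed: int = 0, alpha: float = 1.0, theta_init: float = 1.0):
        self.encoder = ImageEncoder(seed=seed, alpha=alpha, theta_init=theta_init)
        self.decoder = ImageDecoder(seed=seed + 1)

    def reconstruct(self, x: Tensor) -> Tensor:
        return self.decoder(self.encoder(x))

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    def set_training(self, mode: bool):
        self.encoder.set_training(mode)
        self.decoder.set_training(mode)


def _stack_images(images) -> np.ndarray:
    arrs = [im.pixels if hasattr(im, "pixels") else im for im in images]
    return np.stack(arrs).astype(_F32)


def reconstruction_mse(auto: ImageAutoencoder, images, batch_size: int = 4) -> float:
    """Mean squared pixel error of the autoencoder on a set of depictions."""
    px = _stack_images(images)
    se, n = 0.0, 0
    with no_grad():
        for lo in range(0, px.shape[0], batch_size):
            x = px[lo : lo + batch_size]
            out = auto.reconstruct(Tensor(x))
            se += float(((out.data - x) ** 2).sum())
            n += x.size
    return se / n


def pretrain_autoencoder(images, epochs: int = 2, lr: float = 1.0, seed: int = 0,
                         batch_size: int = 8, alpha: float = 1.0, theta_init: float = 1.0,
                         auto: ImageAutoencoder | None = None):
    """Minimise mean squared reconstruction error by plain minibatch gradient
    descent, then freeze the encoder.

    Returns ``(encoder, losses)`` where ``losses`` is the per-step training
    MSE curve. Requires at least 16 images. Deterministic for a fixed seed.
    """
    if len(images) < 16:
        raise ValueError("pretraining requires at least 16 images")
    x_all = _stack_images(images)
    calibration = x_all[: min(16, len(images))]
    rng = np.random.default_rng(seed)
    if auto is None:
        auto = ImageAutoencoder(seed=int(rng.integers(2**31)), alpha=alpha, theta_init=theta_init)
    auto.set_training(True)
    params = auto.parameters()
    losses: list[float] = []
    n = x_all.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            if idx.size < 2:
                continue  # batch norm needs more than one sample
            x = Tensor(x_all[idx])
            out = auto.reconstruct(x)
            loss = ((out - x) ** 2).mean()
            for p in params:
                p.grad = None
            loss.backward()
            for p in params:
                p.data = p.data - _F32(lr) * p.grad
            losses.append(float(loss.data))
    _recalibrate_batchnorm(auto, calibration)
    auto.set_training(False)
    auto.encoder.freeze()
    return auto.encoder, losses


def _all_batchnorms(auto: ImageAutoencoder):
    for blk in (auto.encoder.conv1, auto.encoder.conv2, auto.encoder.conv3,
                auto.encoder.conv4, auto.decoder.conv1, auto.decoder.conv2,
                auto.decoder.conv3):
        yield blk.bn
    yield auto.encoder.pool_bn


def _recalibrate_batchnorm(auto: ImageAutoencoder, x: np.ndarray) -> None:
    """Replace the batch-norm running statistics with the statistics of one
    full calibration pass. After short training runs the momentum-averaged
    running stats still sit near their (0, 1) initialisation, which makes
    the frozen eval-mode encoder wildly miscalibrated; a single
    momentum-1 pass fixes the inference statistics."""
    saved = [bn.momentum for bn in _all_batchnorms(auto)]
    for bn in _all_batchnorms(auto):
        bn.momentum = 1.0
        bn.training = True
    with no_grad():
        auto.reconstruct(Tensor(x))
    for bn, m in zip(_all_batchnorms(auto), saved):
        bn.momentum = m


def encode_image(image, encoder: ImageEncoder) -> np.ndarray:
    """Embed one depiction (or pixel array) with a frozen encoder."""
    px = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    if px.shape != (3, IMG_SIZE, IMG_SIZE):
        raise ValueError(f"expected (3, {IMG_SIZE}, {IMG_SIZE}) pixels, got {px.shape}")
    with no_grad():
        out = encoder(Tensor(px[None].astype(_F32)))
    return out.data[0].copy()


def encode_images(images, encoder: ImageEncoder, batch_size: int = 4) -> np.ndarray:
    px = _stack_images(images)
    with no_grad():
        outs = [encoder(Tensor(px[lo : lo + batch_size])).data
                for lo in range(0, px.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
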