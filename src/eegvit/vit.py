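"""A from-scratch Vision Transformer for binary wave-image classification.

The model follows the standard ViT recipe: the S x S image is cut into
non-overlapping patches, each patch is linearly embedded, a learned class
token is prepended and learned positional embeddings added, and a stack of
pre-norm transformer blocks (multi-head scaled-dot-product self-attention
followed by a GELU MLP, both with residual connections) processes the
sequence.  The class-token output, after a final layer norm, feeds a linear
head; softmax gives the two class probabilities.

Everything — forward pass, backpropagation through layer norm / attention /
GELU, and the Adam optimiser — is implemented directly on NumPy arrays, so
training is exactly reproducible from a seed on any machine.

Two presets are provided: :meth:`ViTConfig.clinical` (224 px, depth 12,
heads 8, batch 64, lr 1e-3, 5 epochs — the full-scale configuration)
and :meth:`ViTConfig.desk` (64 px, depth 2 — small enough to train in
seconds on one CPU, used by the test-bench experiments).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

_LN_EPS = 1e-6
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ViTConfig:
    image_side: int = 224
    patch_side: int = 16
    embed_dim: int = 512
    depth: int = 12
    heads: int = 8
    mlp_ratio: int = 4
    n_classes: int = 2
    batch_size: int = 64
    learning_rate: float = 1e-3
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side % self.patch_side != 0:
            raise ValueError(f"image_side {self.image_side} not divisible by patch_side {self.patch_side}")
        if self.embed_dim % self.heads != 0:
            raise ValueError(f"embed_dim {self.embed_dim} not divisible by heads {self.heads}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")

    @property
    def n_patches(self) -> int:
        return (self.image_side // self.patch_side) ** 2

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @classmethod
    def clinical(cls, **overrides) -> "ViTConfig":
        """Full-scale preset: 224 px images, depth 12, heads 8, batch 64."""
        return cls(**{**dict(image_side=224, patch_side=16, embed_dim=512, depth=12,
                             heads=8, mlp_ratio=4, batch_size=64, learning_rate=1e-3,
                             epochs=5), **overrides})

    @classmethod
    def desk(cls, **overrides) -> "ViTConfig":
        """CPU-friendly preset used throughout the test bench."""
        return cls(**{**dict(image_side=64, patch_side=8, embed_dim=64, depth=2,
                             heads=4, mlp_ratio=2, batch_size=32, learning_rate=1e-3,
                             epochs=5), **overrides})


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def init_params(cfg: ViTConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded initialisation: Glorot-scaled weight matrices, N(0, 0.02)
    class/position embeddings, zero biases, unit LN gains."""
    d, p2 = cfg.embed_dim, cfg.patch_side ** 2

    def xavier(fan_in, fan_out):
        return rng.normal(0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out))

    params: dict[str, np.ndarray] = {
        "patch_w": xavier(p2, d),
        "patch_b": np.zeros(d),
        "cls": rng.normal(0, 0.02, (1, 1, d)),
        "pos": rng.normal(0, 0.02, (1, cfg.n_patches + 1, d)),
        "ln_f_g": np.ones(d), "ln_f_b": np.zeros(d),
        # zero-initialised head: the untrained model starts exactly at
        # chance (loss ln 2) and the first updates shape the classifier
        "head_w": np.zeros((d, cfg.n_classes)),
        "head_b": np.zeros(cfg.n_classes),
    }
    m = cfg.mlp_ratio * d
    for i in range(cfg.depth):
        params.update({
            f"b{i}.ln1_g": np.ones(d), f"b{i}.ln1_b": np.zeros(d),
            f"b{i}.qkv_w": xavier(d, 3 * d), f"b{i}.qkv_b": np.zeros(3 * d),
            f"b{i}.proj_w": xavier(d, d), f"b{i}.proj_b": np.zeros(d),
            f"b{i}.ln2_g": np.ones(d), f"b{i}.ln2_b": np.zeros(d),
            f"b{i}.fc1_w": xavier(d, m), f"b{i}.fc1_b": np.zeros(m),
            f"b{i}.fc2_w": xavier(m, d), f"b{i}.fc2_b": np.zeros(d),
        })
    return params


def count_parameters(cfg: ViTConfig) -> int:
    """Closed-form learnable-parameter count for a configuration."""
    d, p2, c, m = cfg.embed_dim, cfg.patch_side ** 2, cfg.n_classes, cfg.mlp_ratio * cfg.embed_dim
    per_block = (2 * d) + (d * 3 * d + 3 * d) + (d * d + d) + (2 * d) + (d * m + m) + (m * d + d)
    return (p2 * d + d) + d + (cfg.n_patches + 1) * d + cfg.depth * per_block + 2 * d + (d * c + c)


# --------------------------------------------------------------------------
# primitive layers
# --------------------------------------------------------------------------

def patchify(images: np.ndarray, cfg: ViTConfig) -> np.ndarray:
    """(B, S, S) images -> (B, P, p*p) flattened patches in row-major order."""
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 2
    if single:
        images = images[None]
    b, s1, s2 = images.shape
    if (s1, s2) != (cfg.image_side, cfg.image_side):
        raise ValueError(f"image shape {(s1, s2)} does not match cfg.image_side {cfg.image_side}")
    p = cfg.patch_side
    g = cfg.image_side // p
    patches = images.reshape(b, g, p, g, p).transpose(0, 1, 3, 2, 4).reshape(b, g * g, p * p)
    return patches[0] if single else patches


def unpatchify(patches: np.ndarray, cfg: ViTConfig) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    single = patches.ndim == 2
    if single:
        patches = patches[None]
    b = patches.shape[0]
    p = cfg.patch_side
    g = cfg.image_side // p
    images = patches.reshape(b, g, g, p, p).transpose(0, 1, 3, 2, 4).reshape(b, g * p, g * p)
    return images[0] if single else images


def _layernorm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv)


def _layernorm_back(dout, cache, g):
    xhat, inv = cache
    dxhat = dout * g
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    n = xhat.shape[-1]
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True) - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    return 0.5 * (1.0 + erf(x / _SQRT2)) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# --------------------------------------------------------------------------
# forward / backward
# --------------------------------------------------------------------------

def _forward(params, images, cfg, need_cache=False, collect_attention=False):
    b = images.shape[0]
    d, h, dh = cfg.embed_dim, cfg.heads, cfg.head_dim
    if "input_mu" in params:
        # standardisation constants estimated on the training set
        images = (images - params["input_mu"]) / params["input_sd"]
    patches = patchify(images, cfg)                                   # (B,P,p2)
    x = patches @ params["patch_w"] + params["patch_b"]               # (B,P,D)
    x = np.concatenate([np.broadcast_to(params["cls"], (b, 1, d)), x], axis=1)
    x = x + params["pos"]
    t = x.shape[1]
    cache: dict = {"patches": patches}
    attention: list[np.ndarray] = []
    for i in range(cfg.depth):
        pre = f"b{i}."
        x_in = x
        hn, ln1c = _layernorm(x, params[pre + "ln1_g"], params[pre + "ln1_b"])
        qkv = hn @ params[pre + "qkv_w"] + params[pre + "qkv_b"]
        q, k, v = (qkv.reshape(b, t, 3, h, dh).transpose(2, 0, 3, 1, 4))  # each (B,h,T,dh)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        if not np.all(np.isfinite(scores)):
            raise FloatingPointError(f"non-finite attention scores in block {i}")
        attn = _softmax(scores)
        ctx = attn @ v                                                # (B,h,T,dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(b, t, d)
        proj = merged @ params[pre + "proj_w"] + params[pre + "proj_b"]
        x = x_in + proj
        x_mid = x
        hn2, ln2c = _layernorm(x, params[pre + "ln2_g"], params[pre + "ln2_b"])
        z1 = hn2 @ params[pre + "fc1_w"] + params[pre + "fc1_b"]
        a1 = _gelu(z1)
        z2 = a1 @ params[pre + "fc2_w"] + params[pre + "fc2_b"]
        x = x_mid + z2
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"non-finite activations in block {i}")
        if collect_attention:
            attention.append(attn)
        if need_cache:
            cache[pre] = dict(hn=hn, ln1c=ln1c, q=q, k=k, v=v, attn=attn, merged=merged,
                              hn2=hn2, ln2c=ln2c, z1=z1, a1=a1)
    hf, lnfc = _layernorm(x, params["ln_f_g"], params["ln_f_b"])
    logits = hf[:, 0] @ params["head_w"] + params["head_b"]
    if need_cache:
        cache["lnf"] = (hf, lnfc)
        cache["t"] = t
    return logits, cache, attention


def forward(params, images, cfg: ViTConfig, collect_attention: bool = False):
    """Class probabilities for a batch of images (optionally with per-block
    attention weight tensors, shape (B, heads, T, T))."""
    images = _as_batch(images, cfg)
    logits, _, attention = _forward(params, images, cfg, collect_attention=collect_attention)
    probs = _softmax(logits)
    return (probs, attention) if collect_attention else probs


def _backward(params, images, labels, cfg):
    """Mean cross-entropy loss and gradients for one mini-batch."""
    b = images.shape[0]
    d, h, dh = cfg.embed_dim, cfg.heads, cfg.head_dim
    logits, cache, _ = _forward(params, images, cfg, need_cache=True)
    probs = _softmax(logits)
    loss = -np.log(np.clip(probs[np.arange(b), labels], 1e-12, None)).mean()

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    dlogits /= b

    hf, lnfc = cache["lnf"]
    t = cache["t"]
    grads["head_w"] += hf[:, 0].T @ dlogits
    grads["head_b"] += dlogits.sum(0)
    dhf = np.zeros_like(hf)
    dhf[:, 0] = dlogits @ params["head_w"].T
    dx, dg, db = _layernorm_back(dhf, lnfc, params["ln_f_g"])
    grads["ln_f_g"] += dg
    grads["ln_f_b"] += db

    for i in reversed(range(cfg.depth)):
        pre = f"b{i}."
        c = cache[pre]
        # MLP branch
        dz2 = dx  # residual: dx flows to both x_mid and the MLP output
        grads[pre + "fc2_w"] += c["a1"].reshape(-1, c["a1"].shape[-1]).T @ dz2.reshape(-1, d)
        grads[pre + "fc2_b"] += dz2.sum((0, 1))
        da1 = dz2 @ params[pre + "fc2_w"].T
        dz1 = da1 * _gelu_grad(c["z1"])
        grads[pre + "fc1_w"] += c["hn2"].reshape(-1, d).T @ dz1.reshape(-1, dz1.shape[-1])
        grads[pre + "fc1_b"] += dz1.sum((0, 1))
        dhn2 = dz1 @ params[pre + "fc1_w"].T
        dx_mid, dg2, db2 = _layernorm_back(dhn2, c["ln2c"], params[pre + "ln2_g"])
        grads[pre + "ln2_g"] += dg2
        grads[pre + "ln2_b"] += db2
        dx = dx + dx_mid
        # attention branch
        dproj = dx
        grads[pre + "proj_w"] += c["merged"].reshape(-1, d).T @ dproj.reshape(-1, d)
        grads[pre + "proj_b"] += dproj.sum((0, 1))
        dmerged = dproj @ params[pre + "proj_w"].T
        dctx = dmerged.reshape(b, t, h, dh).transpose(0, 2, 1, 3)
        attn, q, k, v = c["attn"], c["q"], c["k"], c["v"]
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack([dq, dk, dv])                                  # (3,B,h,T,dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(b, t, 3 * d)
        grads[pre + "qkv_w"] += c["hn"].reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
        grads[pre + "qkv_b"] += dqkv.sum((0, 1))
        dhn = dqkv @ params[pre + "qkv_w"].T
        dx_in, dg1, db1 = _layernorm_back(dhn, c["ln1c"], params[pre + "ln1_g"])
        grads[pre + "ln1_g"] += dg1
        grads[pre + "ln1_b"] += db1
        dx = dx + dx_in

    grads["pos"] += dx.sum(0, keepdims=True)
    grads["cls"] += dx[:, :1].sum(0, keepdims=True)
    dpatch_embed = dx[:, 1:]
    patches = cache["patches"]
    grads["patch_w"] += patches.reshape(-1, patches.shape[-1]).T @ dpatch_embed.reshape(-1, d)
    grads["patch_b"] += dpatch_embed.sum((0, 1))
    return loss, grads, probs


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class EpochTrace:
    epoch: int
    loss: float
    accuracy: float


def _as_batch(images, cfg) -> np.ndarray:
    """Accept WaveImage lists or raw arrays; return (B, S, S) float64."""
    if isinstance(images, np.ndarray):
        arr = images[None] if images.ndim == 2 else images
    else:
        arr = np.stack([getattr(im, "pixels", im) for im in images])
    arr = np.asarray(arr, dtype=np.float64)
    if arr.shape[1:] != (cfg.image_side, cfg.image_side):
        raise ValueError(f"image batch shape {arr.shape} does not match cfg.image_side {cfg.image_side}")
    return arr


def labels_of(images) -> np.ndarray:
    return np.array([im.label for im in images], dtype=int)


def train(images, labels, cfg: ViTConfig):
    """Train from scratch; returns (params, [EpochTrace...]).

    Adam (beta1 0.9, beta2 0.999, eps 1e-8) on mean cross-entropy over
    shuffled mini-batches of ``cfg.batch_size``.  Initialisation, shuffling
    and therefore the final parameters are fully determined by ``cfg.seed``.
    """
    x = _as_batch(images, cfg)
    y = np.asarray(labels, dtype=int)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{x.shape[0]} images but {y.shape[0]} labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg, rng)
    # input standardisation constants, frozen from the training set
    sd_in = x.std()
    params["input_mu"] = np.array([x.mean()])
    params["input_sd"] = np.array([sd_in if sd_in > 0 else 1.0])
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[EpochTrace] = []
    n = x.shape[0]
    for ep in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads, probs = _backward(params, x[idx], y[idx], cfg)
            losses.append(loss * len(idx))
            correct += int((probs.argmax(1) == y[idx]).sum())
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v2[key] = beta2 * v2[key] + (1 - beta2) * g * g
                params[key] -= lr_t * m[key] / (np.sqrt(v2[key]) + eps)
        trace.append(EpochTrace(ep + 1, float(np.sum(losses) / n), correct / n))
    return params, trace


def predict(params, images, cfg: ViTConfig):
    """Predicted labels, probabilities and tie flags for a list of images.

    Exact probability ties are broken toward the negative (control) class
    and flagged.
    """
    x = _as_batch(images, cfg)
    out_labels, out_probs, out_ties = [], [], []
    for start in range(0, x.shape[0], cfg.batch_size):
        probs = forward(params, x[start:start + cfg.batch_size], cfg)
        ties = probs[:, 0] == probs[:, 1]
        preds = np.where(ties, 0, probs.argmax(1))
        out_labels.append(preds)
        out_probs.append(probs)
        out_ties.append(ties)
    return np.concatenate(out_labels), np.vstack(out_probs), np.concatenate(out_ties)


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def save_model(path, params, cfg: ViTConfig, trace=None) -> None:
    """Parameters to one .npz plus a JSON sidecar with config and trace."""
    path = Path(path)
    np.savez(path, **params)
    sidecar = {"config": asdict(cfg)}
    if trace is not None:
        sidecar["trace"] = [asdict(t) for t in trace]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path):
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as npz:
        params = {k: npz[k] for k in npz.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ViTConfig(**sidecar["config"])
    return params, cfg
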