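"""Single-channel 3D encoder-decoder with a variational reconstruction branch.

The segmenter is a V-net-style convolutional encoder-decoder: a strided-
convolution encoder whose filter count doubles per stage, a mirrored
decoder with additive skip connections, and a sigmoid head producing a
lesion probability map.  A variational branch compresses the bottleneck to
a Gaussian latent code (mu, log-variance), samples it, and decodes a
reconstruction of the input image; its KL and L2 penalties regularize the
shared encoder during training and are unused at inference.

Width, depth and input geometry are configurable: the full-scale
configuration takes a [224, 224, 128] crop with 16 initial filters (depth-3
encoding grid 28 x 28 x 16); tests run a [48, 48, 32] / 4-filter model so a
CPU epoch is fast.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core import BinaryMask, ValidationError, Volume3D

__all__ = ["ModelConfig", "ModelOutput", "VAESegmenter", "build_model",
           "predict_mask", "FULL_SCALE_CONFIG", "TEST_SCALE_CONFIG"]

_VAE_CHANNELS = 8  # fixed narrow width of the reconstruction decoder


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_shape`` must be divisible by ``2**depth`` (the encoder halves
    each axis per stage).  ``latent_dim`` is the length of the variational
    code.  ``seed`` fixes parameter initialization.
    """

    input_shape: tuple[int, int, int] = (224, 224, 128)
    initial_filters: int = 16
    depth: int = 3
    latent_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.initial_filters < 1:
            raise ValidationError("initial_filters must be >= 1")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        f = 2 ** self.depth
        bad = [d for d in self.input_shape if d % f]
        if bad:
            need = [int(np.ceil(d / f) * f) for d in self.input_shape]
            raise ValidationError(
                f"input_shape {tuple(self.input_shape)} not divisible by 2^depth={f}; "
                f"pad to {tuple(need)}")

    @property
    def encoding_shape(self) -> tuple[int, ...]:
        """(channels, x, y, z) of the bottleneck feature grid."""
        f = 2 ** self.depth
        return (self.initial_filters * f,) + tuple(d // f for d in self.input_shape)


FULL_SCALE_CONFIG = ModelConfig((224, 224, 128), 16, 3, 128)
TEST_SCALE_CONFIG = ModelConfig((48, 48, 32), 4, 3, 32)


@dataclass
class ModelOutput:
    seg_prob: np.ndarray            # (X, Y, Z) in [0, 1]
    recon: np.ndarray               # (X, Y, Z)
    mu: np.ndarray                  # (latent_dim,)
    log_var: np.ndarray             # (latent_dim,)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class VAESegmenter:
    """Trainable segmentation model; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))

    # ---- parameters ------------------------------------------------------

    def _add_conv(self, rng, name: str, c_in: int, c_out: int, k: int = 3) -> None:
        self.params[f"{name}.w"] = Tensor(
            _he(rng, (c_out, c_in, k, k, k), c_in * k ** 3), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(c_out), requires_grad=True)

    def _add_linear(self, rng, name: str, n_in: int, n_out: int) -> None:
        self.params[f"{name}.w"] = Tensor(_he(rng, (n_out, n_in), n_in), requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(n_out), requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        f = cfg.initial_filters
        self._add_conv(rng, "stem", 1, f)
        for d in range(1, cfg.depth + 1):
            self._add_conv(rng, f"enc{d}.down", f * 2 ** (d - 1), f * 2 ** d)
            self._add_conv(rng, f"enc{d}.conv", f * 2 ** d, f * 2 ** d)
        for d in range(cfg.depth, 0, -1):
            self._add_conv(rng, f"dec{d}.up", f * 2 ** d, f * 2 ** (d - 1))
            self._add_conv(rng, f"dec{d}.conv", f * 2 ** (d - 1), f * 2 ** (d - 1))
        self._add_conv(rng, "seg_head", f, 1, k=1)

        c_b, bx, by, bz = cfg.encoding_shape
        n_flat = _VAE_CHANNELS * bx * by * bz
        self._add_conv(rng, "vae.squeeze", c_b, _VAE_CHANNELS, k=1)
        self._add_linear(rng, "vae.to_latent", n_flat, 2 * cfg.latent_dim)
        self._add_linear(rng, "vae.from_latent", cfg.latent_dim, n_flat)
        for d in range(cfg.depth):
            self._add_conv(rng, f"vae.dec{d}", _VAE_CHANNELS, _VAE_CHANNELS)
        self._add_conv(rng, "vae.head", _VAE_CHANNELS, 1, k=1)

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise ValidationError(f"state dict mismatch on keys {sorted(missing)}")
        for k, p in self.params.items():
            if p.data.shape != state[k].shape:
                raise ValidationError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return h.hexdigest()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ---- forward ---------------------------------------------------------

    def _conv(self, name: str, x: Tensor, stride: int = 1) -> Tensor:
        return ad.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], stride)

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None,
                train: bool = True) -> dict[str, Tensor]:
        """Graph-building forward pass.

        ``x`` is an (X, Y, Z) volume matching ``config.input_shape``.  In
        training mode the latent code is sampled (reparameterization trick,
        noise drawn from ``rng``); in eval mode the mean code is used, making
        the pass deterministic.  Returns tensors ``seg_prob``, ``recon``,
        ``mu``, ``log_var``.
        """
        cfg = self.config
        if tuple(x.shape) != tuple(cfg.input_shape):
            raise ValidationError(
                f"input shape {x.shape} != configured {tuple(cfg.input_shape)}")
        t = Tensor(x[None])  # add channel axis

        feats = ad.relu(self._conv("stem", t))
        skips = [feats]
        for d in range(1, cfg.depth + 1):
            feats = ad.relu(self._conv(f"enc{d}.down", feats, stride=2))
            feats = ad.relu(self._conv(f"enc{d}.conv", feats))
            skips.append(feats)

        y = skips[-1]
        for d in range(cfg.depth, 0, -1):
            y = ad.relu(self._conv(f"dec{d}.up", ad.upsample2(y)))
            y = y + skips[d - 1]
            y = ad.relu(self._conv(f"dec{d}.conv", y))
        seg_logits = self._conv("seg_head", y)
        seg_prob = ad.sigmoid(seg_logits).reshape(*cfg.input_shape)

        bottleneck = skips[-1]
        v = ad.relu(self._conv("vae.squeeze", bottleneck))
        flat = v.reshape(-1)
        stats = ad.linear(flat, self.params["vae.to_latent.w"], self.params["vae.to_latent.b"])
        n = cfg.latent_dim
        mu_vec = _segment(stats, 0, n)
        lv_vec = _segment(stats, n, 2 * n)
        if train:
            if rng is None:
                raise ValidationError("training forward pass needs an rng for latent sampling")
            eps = rng.standard_normal(n)
        else:
            eps = np.zeros(n)
        z = mu_vec + (lv_vec * 0.5).exp() * Tensor(eps)
        w = ad.relu(ad.linear(z, self.params["vae.from_latent.w"],
                              self.params["vae.from_latent.b"]))
        c_b, bx, by, bz = cfg.encoding_shape
        w = w.reshape(_VAE_CHANNELS, bx, by, bz)
        for d in range(cfg.depth):
            w = ad.relu(self._conv(f"vae.dec{d}", ad.upsample2(w)))
        recon = self._conv("vae.head", w).reshape(*cfg.input_shape)

        return {"seg_prob": seg_prob, "recon": recon, "mu": mu_vec, "log_var": lv_vec}

    def predict(self, x: np.ndarray) -> ModelOutput:
        """Deterministic eval-mode forward pass returning plain arrays."""
        out = self.forward(x, train=False)
        return ModelOutput(out["seg_prob"].data, out["recon"].data,
                           out["mu"].data, out["log_var"].data)

    # ---- persistence -------------------------------------------------------

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        meta = {"config": dataclasses.asdict(self.config),
                "provenance": provenance or {}}
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        np.savez_compressed(str(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["VAESegmenter", dict]:
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["input_shape"] = tuple(cfg_d["input_shape"])
            model = cls(ModelConfig(**cfg_d))
            model.load_state_dict({k[len("param::"):]: data[k]
                                   for k in data.files if k.startswith("param::")})
        return model, meta.get("provenance", {})


def _segment(x: Tensor, lo: int, hi: int) -> Tensor:
    """Differentiable slice of a flat vector."""
    n = x.data.size

    def backward(g):
        full = np.zeros(n)
        full[lo:hi] = g
        x._accum(full)

    return x._make(x.data[lo:hi], (x,), backward)


def build_model(config: ModelConfig) -> VAESegmenter:
    """Construct a model with deterministic seed-derived initialization."""
    return VAESegmenter(config)


def center_pad_or_crop(data: np.ndarray, target: tuple[int, int, int],
                       pad_value: float = 0.0):
    """Center pad/crop a volume to ``target``; returns (out, restore_fn)."""
    out = np.full(target, pad_value, dtype=data.dtype)
    src, dst = [], []
    for n, m in zip(data.shape, target):
        if n >= m:
            off = (n - m) // 2
            src.append(slice(off, off + m))
            dst.append(slice(0, m))
        else:
            off = (m - n) // 2
            src.append(slice(0, n))
            dst.append(slice(off, off + n))
    out[tuple(dst)] = data[tuple(src)]
    native_shape = data.shape

    def restore(arr: np.ndarray, fill=0.0) -> np.ndarray:
        back = np.full(native_shape, fill, dtype=arr.dtype)
        back[tuple(src)] = arr[tuple(dst)]
        return back

    return out, restore


def predict_mask(model: VAESegmenter, volume: Volume3D, threshold: float = 0.5) -> BinaryMask:
    """Binarize the predicted probability map at ``threshold`` (>=).

    The volume is center padded/cropped to the model's input shape and the
    prediction is mapped back to the native geometry.  The variational
    branch plays no role at inference.
    """
    x, restore = center_pad_or_crop(volume.data.astype(np.float64),
                                    tuple(model.config.input_shape))
    out = model.predict(x)
    if not np.all(np.isfinite(out.seg_prob)):
        raise ValidationError("divergence: non-finite network output")
    mask = restore((out.seg_prob >= threshold).astype(np.uint8), fill=0)
    return BinaryMask(mask, volume.spacing, role="lesion")
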