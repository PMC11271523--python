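"""Convolutional variational autoencoder over masked 96x96 nucleus patches.

Pure-NumPy implementation (see :mod:`chromastate._nn`): a 5-layer strided
convolutional encoder, two fully connected heads for the posterior mean and
log-variance ("dispersion"), and a mirrored transposed-convolution decoder.
Training minimizes the summed-square reconstruction error plus the KL
divergence of the diagonal-Gaussian posterior from a standard normal prior,
with reparameterized sampling during training only; embeddings are posterior
means. Deterministic for a fixed seed on a single worker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dense,
    LeakyReLU,
    Sequential,
    get_weights,
    set_weights,
)

IMG = 96


@dataclass
class VAEConfig:
    n_conv_layers: int = 5
    latent_dim: int = 64
    conv_channels: tuple[int, ...] = (8, 16, 32, 64, 128)
    activation_slope: float = 0.01
    batch_size: int = 128
    epochs: int = 20
    kl_weight: float = 1.0
    learning_rate: float = 1e-3
    split_fractions: tuple[float, float, float] = (0.85, 0.05, 0.10)
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if len(self.conv_channels) != self.n_conv_layers:
            raise ValueError("conv_channels length must equal n_conv_layers")
        if IMG % (2**self.n_conv_layers) != 0:
            raise ValueError(
                f"{self.n_conv_layers} stride-2 layers incompatible with {IMG}x{IMG} input"
            )

    @classmethod
    def paper_scale(cls) -> "VAEConfig":
        """Reference configuration at full training scale
        (latent 6000, batch 8000, 310 epochs); not meant for CPU desk use."""
        return cls(
            latent_dim=6000,
            conv_channels=(32, 64, 128, 256, 512),
            batch_size=8000,
            epochs=310,
        )


@dataclass
class LatentTable:
    values: np.ndarray  # (n_cells, latent_dim) posterior means
    index: np.ndarray  # nucleus ids, aligned with rows
    fingerprint: str = ""

    def to_frame(self):
        import pandas as pd

        cols = [f"z{i}" for i in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "nucleus_id", self.index)
        return df


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)
    best_epoch: int = -1


class ConvVAE:
    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.conv_channels
        slope = config.activation_slope
        enc_layers = []
        c_in = 1
        for c_out in ch:
            enc_layers += [Conv2d(c_in, c_out, rng), LeakyReLU(slope)]
            c_in = c_out
        self.encoder = Sequential(*enc_layers)
        self.feat_hw = IMG // (2 ** config.n_conv_layers)
        feat_dim = ch[-1] * self.feat_hw**2
        self.fc_mu = Dense(feat_dim, config.latent_dim, rng)
        self.fc_logvar = Dense(feat_dim, config.latent_dim, rng)
        self.fc_dec = Dense(config.latent_dim, feat_dim, rng)
        dec_layers = [LeakyReLU(slope)]
        rev = list(ch[::-1])
        for i in range(len(rev) - 1):
            dec_layers += [ConvTranspose2d(rev[i], rev[i + 1], rng), LeakyReLU(slope)]
        dec_layers += [ConvTranspose2d(rev[-1], 1, rng)]  # linear output
        self.decoder = Sequential(*dec_layers)
        self._modules = {
            "encoder": self.encoder,
            "fc_mu": self.fc_mu,
            "fc_logvar": self.fc_logvar,
            "fc_dec": self.fc_dec,
            "decoder": self.decoder,
        }

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        out = {}
        for mname, mod in self._modules.items():
            for pname, pg in mod.params().items():
                out[f"{mname}.{pname}"] = pg
        return out

    def get_weights(self):
        return get_weights(self)

    def set_weights(self, weights):
        set_weights(self, weights)

    # -- forward / backward -------------------------------------------------
    def encode_batch(self, x: np.ndarray):
        """x: (n, 96, 96) -> (mu, logvar, feature cache for backward)."""
        h = self.encoder.forward(
            x[:, None].astype(_nn.DTYPE), train=False
        )
        n = h.shape[0]
        hf = h.reshape(n, -1)
        mu = self.fc_mu.forward(hf)
        logvar = np.clip(self.fc_logvar.forward(hf), -8.0, 8.0)
        return mu, logvar, h.shape

    def decode_batch(self, z: np.ndarray) -> np.ndarray:
        n = z.shape[0]
        ch = self.config.conv_channels[-1]
        h = self.fc_dec.forward(z.astype(_nn.DTYPE))
        h = h.reshape(n, ch, self.feat_hw, self.feat_hw)
        out = self.decoder.forward(h)
        return out[:, 0]

    def _step(self, x: np.ndarray, rng: np.random.Generator, opt: Adam):
        cfg = self.config
        n = x.shape[0]
        opt.zero_grad()
        mu, logvar, h_shape = self.encode_batch(x)
        eps = rng.standard_normal(mu.shape).astype(_nn.DTYPE)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        xhat = self.decode_batch(z)

        diff = (xhat - x).astype(np.float64)
        recon = float((diff**2).sum() / n)
        kl = float(
            (-0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))).sum() / n
        )
        loss = recon + cfg.kl_weight * kl
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss (recon={recon}, kl={kl}); "
                "lower the learning rate or check input scaling"
            )

        # backward
        gxhat = (2.0 / n) * diff.astype(_nn.DTYPE)
        gh = self.decoder.backward(gxhat[:, None])
        gz = self.fc_dec.backward(gh.reshape(n, -1))
        gmu = gz + (cfg.kl_weight / n) * mu
        glogvar = gz * eps * (0.5 * std) + (cfg.kl_weight / n) * (
            -0.5 * (1.0 - np.exp(logvar))
        ).astype(_nn.DTYPE)
        ghf = self.fc_mu.backward(gmu) + self.fc_logvar.backward(glogvar)
        self.encoder.backward(ghf.reshape(h_shape))

        self._clip_gradients(cfg.grad_clip)
        opt.step()
        return loss, recon, kl

    def _clip_gradients(self, max_norm: float):
        if max_norm <= 0:
            return
        total = 0.0
        for _, (_, g) in self.params().items():
            total += float((g.astype(np.float64) ** 2).sum())
        norm = np.sqrt(total)
        if norm > max_norm:
            scale = _nn.DTYPE(max_norm / norm)
            for _, (_, g) in self.params().items():
                g *= scale

    def eval_loss(self, x: np.ndarray) -> float:
        """Deterministic loss (z = mu, no sampling)."""
        mu, logvar, _ = self.encode_batch(x)
        xhat = self.decode_batch(mu)
        n = x.shape[0]
        recon = float(((xhat - x) ** 2).sum() / n)
        kl = float((-0.5 * (1.0 + logvar - mu**2 - np.exp(logvar))).sum() / n)
        return recon + self.config.kl_weight * kl


def build_vae(config: VAEConfig) -> ConvVAE:
    return ConvVAE(config)


def split_indices(n: int, fractions, seed: int):
    """Seeded (train, val, test) index split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train_vae(model: ConvVAE, patches: np.ndarray, config: VAEConfig | None = None):
    """Train on (n, 96, 96) masked normalized patches.

    Model selection keeps the weights with the lowest validation loss.
    Returns ``(model, LossHistory)``.
    """
    cfg = config or model.config
    patches = np.asarray(patches, dtype=_nn.DTYPE)
    n = len(patches)
    if n < cfg.batch_size:
        raise ValueError(f"need >= batch_size={cfg.batch_size} patches, got {n}")
    tr, va, _te = split_indices(n, cfg.split_fractions, cfg.seed)
    x_val = patches[va] if len(va) else patches[tr[: min(len(tr), cfg.batch_size)]]

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model, lr=cfg.learning_rate)
    history = LossHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = patches[order[start : start + cfg.batch_size]]
            if len(batch) < 2:
                continue
            loss, _, _ = model._step(batch, rng, opt)
            losses.append(loss)
        val_loss = model.eval_loss(x_val)
        history.train.append(float(np.mean(losses)))
        history.val.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
    model.set_weights(best_weights)
    return model, history


def encode(model: ConvVAE, patches: np.ndarray, index=None, batch_size: int = 256) -> LatentTable:
    """Posterior means for each patch (no sampling; deterministic)."""
    patches = np.asarray(patches, dtype=_nn.DTYPE)
    if patches.ndim != 3 or patches.shape[1:] != (IMG, IMG):
        raise ValueError(f"patches must be (n, {IMG}, {IMG}), got {patches.shape}")
    mus = []
    for start in range(0, len(patches), batch_size):
        mu, _, _ = model.encode_batch(patches[start : start + batch_size])
        mus.append(mu.astype(np.float64))
    values = (
        np.concatenate(mus) if mus else np.zeros((0, model.config.latent_dim))
    )
    if index is None:
        index = np.arange(len(patches))
    fingerprint = f"convvae-l{model.config.latent_dim}-s{model.config.seed}"
    return LatentTable(values=values, index=np.asarray(index), fingerprint=fingerprint)


def save_checkpoint(model: ConvVAE, path) -> None:
    path = Path(path)
    np.savez(path, **{k: v for k, v in model.get_weights().items()})
    sidecar = path.with_suffix(".json")
    cfg = model.config.__dict__.copy()
    cfg["conv_channels"] = list(cfg["conv_channels"])
    cfg["split_fractions"] = list(cfg["split_fractions"])
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> ConvVAE:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    cfg_raw["conv_channels"] = tuple(cfg_raw["conv_channels"])
    cfg_raw["split_fractions"] = tuple(cfg_raw["split_fractions"])
    model = ConvVAE(VAEConfig(**cfg_raw))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.set_weights({k: data[k] for k in data.files})
    return model
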