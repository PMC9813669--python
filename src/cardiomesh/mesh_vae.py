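"""Hierarchical variational mesh autoencoder.

Encoder and decoder are symmetric stacks of Chebyshev graph-convolution
blocks (conv + ReLU) with quadric-error mesh pooling between levels and a
fully connected map between the coarsest-level features and the
16-dimensional latent space.  The objective is the beta-VAE loss

    L_total = L_reconstruction + beta * L_KL,

where the reconstruction term is the per-vertex mean squared coordinate
error in standardized space, the KL term is the closed-form divergence of a
diagonal Gaussian posterior from the standard normal prior, and beta follows
a monotonic linear annealing schedule.

All layers, gradients and the Adam optimizer are implemented here directly
on numpy/scipy arrays; gradient correctness is covered by finite-difference
and dense-spectral-oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sparse

from . import mesh_core
from .errors import ConfigurationError, DimensionError
from .graph_conv import ChebLayer, cheb_basis, scaled_laplacian
from .mesh_core import Mesh, MeshDataset, StandardizationStats, surface_distances
from .mesh_sampling import SamplingHierarchy

LOGVAR_CLIP = 15.0


@dataclass
class VAEConfig:
    latent_dim: int = 16
    cheb_order: int = 5
    n_levels: int = 4
    channels: tuple[int, ...] = (16, 16, 16, 32)
    pool_factor: float = 4.0
    epochs: int = 250
    learning_rate: float = 0.001
    batch_size: int = 8
    beta_start: float = 0.0001
    beta_end: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.cheb_order, self.n_levels, self.epochs, self.batch_size) < 1:
            raise ConfigurationError("latent_dim, cheb_order, n_levels, epochs, batch_size must be positive")
        if self.learning_rate <= 0 or self.beta_start <= 0 or self.beta_end <= 0:
            raise ConfigurationError("learning_rate and beta values must be positive")
        if self.beta_start > self.beta_end:
            raise ConfigurationError("beta_start must be <= beta_end (monotonic annealing)")
        if len(self.channels) != self.n_levels:
            raise ConfigurationError(f"need one channel width per level, got {self.channels}")


@dataclass
class LatentCode:
    """Diagonal-Gaussian posterior of one mesh: mean and log-variance."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.log_var = np.asarray(self.log_var, dtype=np.float64)
        if self.mu.shape != self.log_var.shape:
            raise DimensionError("mu and log_var must have equal shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_var).all()):
            raise ValueError("latent code entries must be finite")


@dataclass
class LossBreakdown:
    total: float
    reconstruction: float
    kl: float
    beta: float


# ---------------------------------------------------------------------------
# Minimal reverse-mode layers
# ---------------------------------------------------------------------------

class _Param:
    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Layer:
    def params(self) -> list[_Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _ChebConv(_Layer):
    """Chebyshev graph convolution with cached polynomial basis."""

    def __init__(self, L_scaled: sparse.spmatrix, order: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.L = L_scaled.tocsr()
        self.order = order
        self.c_in = c_in
        self.c_out = c_out
        ref = ChebLayer.glorot(order, c_in, c_out, rng)
        self.w = _Param(ref.weights)
        self.b = _Param(ref.bias)
        self._basis: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def as_cheb_layer(self) -> ChebLayer:
        return ChebLayer(self.order, self.c_in, self.c_out, self.w.value, self.b.value)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._basis = cheb_basis(self.L, x, self.order)  # (K, B, V, c_in)
        return np.einsum("kbvi,kio->bvo", self._basis, self.w.value) + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        basis = self._basis
        self.w.grad += np.einsum("kbvi,bvo->kio", basis, grad)
        self.b.grad += grad.sum(axis=(0, 1))
        # dX = sum_k T_k(L) (grad W_k^T); one joint recurrence over all k.
        G = np.einsum("bvo,kio->bvki", grad, self.w.value)  # (B, V, K, c_in)
        B_, V, K, C = G.shape
        Gcat = G.reshape(B_, V, K * C)
        basis2 = cheb_basis(self.L, Gcat, self.order)  # (K, B, V, K*c_in)
        basis2 = basis2.reshape(K, B_, V, K, C)
        return sum(basis2[k, :, :, k, :] for k in range(K))


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class _SparseMap(_Layer):
    """Multiply vertex axis by a fixed sparse matrix (pooling / unpooling)."""

    def __init__(self, matrix: sparse.spmatrix):
        self.m = matrix.tocsr()
        self.mt = self.m.T.tocsr()

    def _apply(self, mat: sparse.spmatrix, x: np.ndarray) -> np.ndarray:
        B, V, C = x.shape
        flat = np.moveaxis(x, 0, 1).reshape(V, B * C)
        out = mat @ flat
        return np.moveaxis(out.reshape(mat.shape[0], B, C), 0, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._apply(self.m, x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self._apply(self.mt, grad)


class _Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class _Unflatten(_Layer):
    def __init__(self, n_vertices: int, channels: int):
        self.v = n_vertices
        self.c = channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], self.v, self.c)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(grad.shape[0], self.v * self.c)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = _Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = _Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class _Sequential(_Layer):
    def __init__(self, layers: list[_Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class _Adam:
    def __init__(self, params: list[_Param], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MeshVAEModel:
    """Symmetric hierarchical mesh VAE bound to one sampling hierarchy."""

    def __init__(
        self,
        hierarchy: SamplingHierarchy,
        config: VAEConfig,
        standardization: StandardizationStats,
        phase: str = "unspecified",
    ):
        if hierarchy.n_levels != config.n_levels:
            raise ConfigurationError(
                f"hierarchy has {hierarchy.n_levels} levels but config requests {config.n_levels}"
            )
        self.hierarchy = hierarchy
        self.config = config
        self.standardization = standardization
        self.phase = phase
        self.template = hierarchy.levels[0]
        self.history: pd.DataFrame | None = None

        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        Ls = [scaled_laplacian(L) for L in hierarchy.laplacians]
        ch = config.channels
        K = config.cheb_order
        n_coarse = hierarchy.levels[-1].n_vertices
        coarse_feats = n_coarse * ch[-1]

        enc: list[_Layer] = []
        c_prev = 3
        for lvl in range(config.n_levels):
            enc += [_ChebConv(Ls[lvl], K, c_prev, ch[lvl], rng), _ReLU()]
            c_prev = ch[lvl]
            if lvl < config.n_levels - 1:
                enc.append(_SparseMap(hierarchy.down_transforms[lvl]))
        enc.append(_Flatten())
        head = _Dense(coarse_feats, 2 * config.latent_dim, rng)
        # Start the posterior near-deterministic (sigma ~ e^-3): large initial
        # sampling noise stalls reconstruction learning early in training.
        head.b.value[config.latent_dim :] = -6.0
        enc.append(head)
        self.encoder = _Sequential(enc)

        dec: list[_Layer] = [
            _Dense(config.latent_dim, coarse_feats, rng),
            _Unflatten(n_coarse, ch[-1]),
            _ReLU(),
        ]
        for lvl in range(config.n_levels - 1, 0, -1):
            dec += [_ChebConv(Ls[lvl], K, ch[lvl], ch[lvl - 1], rng), _ReLU(), _SparseMap(hierarchy.up_transforms[lvl - 1])]
        dec.append(_ChebConv(Ls[0], K, ch[0], 3, rng))  # linear output layer
        self.decoder = _Sequential(dec)

    # -- basics ------------------------------------------------------------

    def parameters(self) -> list[_Param]:
        return self.encoder.params() + self.decoder.params()

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def _check_mesh(self, mesh: Mesh) -> None:
        if mesh.n_vertices != self.template.n_vertices:
            raise DimensionError(
                f"mesh has {mesh.n_vertices} vertices, model expects {self.template.n_vertices}"
            )
        if self.phase != "unspecified" and mesh.phase != "unspecified" and mesh.phase != self.phase:
            raise ConfigurationError(f"{mesh.phase} mesh passed to a {self.phase}-phase model")

    # -- inference ---------------------------------------------------------

    def encode_array(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Standardized (B, V, 3) coordinates -> (mu, log_var), each (B, latent)."""
        out = self.encoder.forward(np.asarray(coords, dtype=np.float64))
        mu = out[:, : self.config.latent_dim]
        log_var = np.clip(out[:, self.config.latent_dim :], -LOGVAR_CLIP, LOGVAR_CLIP)
        return mu, log_var

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        """(B, latent) -> standardized (B, V, 3) coordinates."""
        z = np.asarray(z, dtype=np.float64)
        if z.shape[-1] != self.config.latent_dim:
            raise DimensionError(f"z has length {z.shape[-1]}, expected {self.config.latent_dim}")
        return self.decoder.forward(z)


def encode(model: MeshVAEModel, mesh: Mesh) -> LatentCode:
    """Deterministic posterior parameters of one mesh (standardizes internally)."""
    model._check_mesh(mesh)
    std = model.standardization.apply(mesh.vertices)
    mu, log_var = model.encode_array(std[None])
    return LatentCode(mu[0], log_var[0])


def encode_dataset(model: MeshVAEModel, dataset: MeshDataset | list[Mesh]) -> np.ndarray:
    """Posterior means of every mesh, stacked (n, latent)."""
    meshes = dataset.meshes if isinstance(dataset, MeshDataset) else dataset
    coords = np.stack([model.standardization.apply(m.vertices) for m in meshes])
    mu, _ = model.encode_array(coords)
    return mu


def decode(model: MeshVAEModel, z: np.ndarray) -> Mesh:
    """Decode one latent vector to a mesh in mm with template connectivity."""
    coords = model.decode_array(np.asarray(z, dtype=np.float64)[None])[0]
    return Mesh(
        model.standardization.invert(coords),
        model.template.faces.copy(),
        None if model.template.vertex_labels is None else model.template.vertex_labels.copy(),
        model.phase,
    )


def reparameterize(code: LatentCode, rng: np.random.Generator | int) -> np.ndarray:
    """z = mu + exp(log_var / 2) * eps with eps ~ N(0, I)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    eps = rng.standard_normal(code.mu.shape)
    return code.mu + np.exp(0.5 * code.log_var) * eps


def kl_divergence(code: LatentCode) -> float:
    """Closed-form KL of a diagonal Gaussian from the standard normal prior."""
    mu, lv = code.mu, code.log_var
    return float(0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv))


def reconstruction_loss(x: Mesh | np.ndarray, y: Mesh | np.ndarray) -> float:
    """Mean over vertices of the squared coordinate distance between
    corresponded vertices (the training objective, coordinates as given)."""
    xa = x.vertices if isinstance(x, Mesh) else np.asarray(x, dtype=np.float64)
    ya = y.vertices if isinstance(y, Mesh) else np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise DimensionError(f"shape mismatch {xa.shape} vs {ya.shape}")
    return float(((xa - ya) ** 2).sum(axis=-1).mean())


def beta_schedule(epoch: int, config: VAEConfig) -> float:
    """Monotonic linear annealing from beta_start (epoch 0) to beta_end (last epoch)."""
    if config.epochs == 1:
        return config.beta_end
    frac = min(max(epoch / (config.epochs - 1), 0.0), 1.0)
    return config.beta_start + (config.beta_end - config.beta_start) * frac


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    model: MeshVAEModel,
    dataset: MeshDataset,
    config: VAEConfig | None = None,
    checkpoint_path: str | Path | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Optimize the beta-VAE objective on the dataset's training split.

    Weight initialization (done at model build), batch shuffling and the
    reparameterization noise are all driven by ``config.seed``, so the loss
    history is reproducible on one platform.  Raises on non-finite loss with
    the offending epoch/batch.
    """
    cfg = config or model.config
    report = mesh_core.validate_correspondence(dataset)
    if not report.passed:
        raise ConfigurationError(f"dataset failed correspondence validation:\n{report}")
    train_set = dataset.split_subset("train") if dataset.split is not None else dataset
    coords = np.stack([model.standardization.apply(m.vertices) for m in train_set.meshes])
    n = len(coords)
    V = coords.shape[1]
    latent = cfg.latent_dim

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    opt = _Adam(model.parameters(), cfg.learning_rate)
    rows = []
    for epoch in range(cfg.epochs):
        beta = beta_schedule(epoch, cfg)
        order = rng.permutation(n)
        rec_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            X = coords[idx]
            B = len(idx)

            enc_out = model.encoder.forward(X)
            mu = enc_out[:, :latent]
            lv_raw = enc_out[:, latent:]
            clip_mask = np.abs(lv_raw) < LOGVAR_CLIP
            lv = np.clip(lv_raw, -LOGVAR_CLIP, LOGVAR_CLIP)
            eps = rng.standard_normal(mu.shape)
            sigma = np.exp(0.5 * lv)
            z = mu + sigma * eps
            Y = model.decoder.forward(z)

            diff = Y - X
            rec_per = (diff**2).sum(axis=-1).mean(axis=-1)  # (B,)
            kl_per = 0.5 * (mu**2 + np.exp(lv) - 1.0 - lv).sum(axis=-1)
            rec = float(rec_per.mean())
            kl = float(kl_per.mean())
            total = rec + beta * kl
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: rec={rec}, kl={kl}"
                )

            opt.zero_grad()
            dY = 2.0 * diff / (V * B)
            dz = model.decoder.backward(dY)
            dmu = dz + beta * mu / B
            dlv = dz * eps * 0.5 * sigma + beta * 0.5 * (np.exp(lv) - 1.0) / B
            dlv = np.where(clip_mask, dlv, 0.0)
            model.encoder.backward(np.concatenate([dmu, dlv], axis=1))
            opt.step()

            rec_sum += rec
            kl_sum += kl
            n_batches += 1

        rec_m = rec_sum / n_batches
        kl_m = kl_sum / n_batches
        rows.append(
            {"epoch": epoch, "total": rec_m + beta * kl_m, "reconstruction": rec_m, "kl": kl_m, "beta": beta}
        )
        if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
            print(f"epoch {epoch:4d}  total {rows[-1]['total']:.6f}  rec {rec_m:.6f}  kl {kl_m:.4f}  beta {beta:.6f}")

    model.history = pd.DataFrame(rows)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model.history


def evaluate_reconstruction(
    model: MeshVAEModel,
    dataset: MeshDataset,
    split: str | None = "test",
    csv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-subject MSD/HD (mm) between inputs and posterior-mean reconstructions.

    Also reports the clinical metrics of each reconstruction when the
    template carries anatomical labels.  The returned frame ends with a
    summary row of means; SDs are available via ``DataFrame.std``.
    """
    subset = dataset.split_subset(split) if (split is not None and dataset.split is not None) else dataset
    rows = []
    for sid, mesh in zip(subset.subject_ids, subset.meshes):
        code = encode(model, mesh)
        recon = decode(model, code.mu)
        msd, hd = surface_distances(mesh, recon)
        row = {"subject_id": sid, "phase": mesh.phase, "msd_mm": msd, "hd_mm": hd}
        if recon.vertex_labels is not None:
            row.update(mesh_core.clinical_metrics(recon))
        rows.append(row)
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(model: MeshVAEModel, path: str | Path) -> Path:
    """Single-file .npz archive: weights, config, hierarchy, stats, history."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i}"] = p.value
    arrays["std_mean"] = model.standardization.mean
    arrays["std_sd"] = model.standardization.sd
    h = model.hierarchy
    for i, m in enumerate(h.levels):
        arrays[f"lvl{i}_vertices"] = m.vertices
        arrays[f"lvl{i}_faces"] = m.faces
        if m.vertex_labels is not None:
            arrays[f"lvl{i}_labels"] = m.vertex_labels
    for name, mats in (("down", h.down_transforms), ("up", h.up_transforms), ("lap", h.laplacians)):
        for i, mat in enumerate(mats):
            coo = mat.tocoo()
            arrays[f"{name}{i}_row"] = coo.row.astype(np.int64)
            arrays[f"{name}{i}_col"] = coo.col.astype(np.int64)
            arrays[f"{name}{i}_data"] = coo.data.astype(np.float64)
            arrays[f"{name}{i}_shape"] = np.asarray(coo.shape, dtype=np.int64)
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "phase": model.phase,
        "hierarchy_hash": h.content_hash(),
        "level_phases": [m.phase for m in h.levels],
        "history": None if model.history is None else model.history.to_dict(orient="list"),
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> MeshVAEModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ConfigurationError(f"unsupported checkpoint schema {meta['schema']}")
        cfg_dict = meta["config"]
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        config = VAEConfig(**cfg_dict)
        levels = []
        for i in range(config.n_levels):
            labels = npz[f"lvl{i}_labels"] if f"lvl{i}_labels" in npz else None
            levels.append(Mesh(npz[f"lvl{i}_vertices"], npz[f"lvl{i}_faces"], labels, meta["level_phases"][i]))

        def _mats(name: str, count: int) -> list[sparse.csr_matrix]:
            out = []
            for i in range(count):
                shape = tuple(npz[f"{name}{i}_shape"])
                out.append(
                    sparse.csr_matrix(
                        (npz[f"{name}{i}_data"], (npz[f"{name}{i}_row"], npz[f"{name}{i}_col"])), shape=shape
                    )
                )
            return out

        hierarchy = SamplingHierarchy(
            levels,
            _mats("down", config.n_levels - 1),
            _mats("up", config.n_levels - 1),
            _mats("lap", config.n_levels),
        )
        if hierarchy.content_hash() != meta["hierarchy_hash"]:
            raise ConfigurationError("checkpoint hierarchy hash mismatch")
        stats = StandardizationStats(mean=npz["std_mean"], sd=npz["std_sd"])
        model = MeshVAEModel(hierarchy, config, stats, meta["phase"])
        for i, p in enumerate(model.parameters()):
            p.value[...] = npz[f"param_{i}"]
        if meta["history"] is not None:
            model.history = pd.DataFrame(meta["history"])
    return model
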