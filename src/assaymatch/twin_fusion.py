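"""Barlow Twins fusion of molecular fingerprints and assay-text embeddings.

The network has three multilayer perceptrons: a molecule encoder consuming
fingerprints, a text encoder consuming assay embeddings, and a projector
shared by both modalities. For a batch of (molecule, assay) pairs the two
projections are batch-standardized and their d x d cross-correlation matrix

    C = (1/N) * standardize(Za)^T standardize(Zb)

is driven toward the identity by the Barlow Twins objective

    L(C) = sum_i (1 - C_ii)^2 + lambda * sum_{i != j} C_ij^2 ,

aligning each projection dimension across modalities (diagonal -> 1) while
decorrelating distinct dimensions (off-diagonal -> 0), which prevents the
representational collapse that pure alignment objectives suffer from. After
training, the two encoder bottleneck outputs are concatenated into the fused
embedding that feeds the downstream matcher.

The whole model — forward pass, backpropagation through the standardization
and the correlation loss, and the AdamW optimizer (decoupled weight decay) —
is implemented directly in NumPy, which keeps training bitwise-reproducible
from (seed, config, data) on any machine.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    ArchiveError,
    BatchTooSmallError,
    ConfigurationError,
    DimensionError,
    DivergenceError,
)

_EPS_STD = 1e-8
FORMAT_VERSION = 1


@dataclass(frozen=True)
class BTConfig:
    """Hyperparameters of the fusion network.

    ``enc_mol_dims`` / ``enc_text_dims`` list the encoder layer widths after
    the (inferred) input layer; both must end at the same bottleneck width
    because the projector is shared. ``proj_dims`` are the projector widths
    after the bottleneck. ``lambda_offdiag`` is the off-diagonal weight of
    the loss (canonical value 5e-3). ``pairs_used`` selects whether the
    alignment objective sees every labelled pair or only the active ones.
    """

    enc_mol_dims: tuple[int, ...] = (512, 256)
    enc_text_dims: tuple[int, ...] = (512, 256)
    proj_dims: tuple[int, ...] = (512, 512)
    lambda_offdiag: float = 5e-3
    batch_size: int = 256
    max_epochs: int = 25
    patience: int = 5
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    seed: int = 0
    pairs_used: str = "all"  # or "positives_only"

    def __post_init__(self):
        if self.enc_mol_dims[-1] != self.enc_text_dims[-1]:
            raise ConfigurationError(
                "encoder bottlenecks differ "
                f"({self.enc_mol_dims[-1]} vs {self.enc_text_dims[-1]}); "
                "both encoders feed the shared projector"
            )
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2")
        if self.lambda_offdiag <= 0:
            raise ConfigurationError("lambda_offdiag must be > 0")
        if self.pairs_used not in ("all", "positives_only"):
            raise ConfigurationError(
                f"pairs_used must be 'all' or 'positives_only', got {self.pairs_used!r}"
            )


# ---------------------------------------------------------------------------
# Batch standardization and the cross-correlation objective
# ---------------------------------------------------------------------------

def standardize_batch(Z: np.ndarray) -> np.ndarray:
    """Standardize each column to mean 0, population variance 1.

    Uses sigma = sqrt(var + 1e-8), so constant columns map to exactly zero
    instead of dividing by zero.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2:
        raise DimensionError(f"expected an N x d matrix, got shape {Z.shape}")
    if Z.shape[0] < 2:
        raise BatchTooSmallError(f"need N >= 2 rows, got {Z.shape[0]}")
    mu = Z.mean(axis=0)
    sigma = np.sqrt(Z.var(axis=0) + _EPS_STD)
    return (Z - mu) / sigma


def _standardize_backward(Z_hat: np.ndarray, sigma: np.ndarray, dZ_hat: np.ndarray) -> np.ndarray:
    # Backprop of z_hat = (z - mu)/sigma with batch statistics, per column.
    return (
        dZ_hat
        - dZ_hat.mean(axis=0)
        - Z_hat * (dZ_hat * Z_hat).mean(axis=0)
    ) / sigma


def cross_correlation(Za: np.ndarray, Zb: np.ndarray) -> np.ndarray:
    """Batch cross-correlation matrix between two projection matrices.

    Entry (i, j) is the empirical correlation of dimension i of modality A
    with dimension j of modality B over the batch; entries lie in [-1, 1] up
    to the standardization epsilon.
    """
    Za = np.asarray(Za, dtype=np.float64)
    Zb = np.asarray(Zb, dtype=np.float64)
    if Za.shape != Zb.shape:
        raise DimensionError(f"shape mismatch: {Za.shape} vs {Zb.shape}")
    n = Za.shape[0]
    return standardize_batch(Za).T @ standardize_batch(Zb) / n


def bt_loss(C: np.ndarray, lambda_offdiag: float) -> float:
    """Barlow Twins loss: squared diagonal misalignment + weighted redundancy.

    Zero exactly when C is the identity.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError(f"C must be square, got shape {C.shape}")
    diag = np.diag(C)
    on_diag = float(np.sum((1.0 - diag) ** 2))
    off_diag = float(np.sum(C**2) - np.sum(diag**2))
    return on_diag + lambda_offdiag * off_diag


def _bt_loss_grad(C: np.ndarray, lam: float) -> np.ndarray:
    G = 2.0 * lam * C
    np.fill_diagonal(G, -2.0 * (1.0 - np.diag(C)))
    return G


# ---------------------------------------------------------------------------
# Minimal MLP with explicit backward pass
# ---------------------------------------------------------------------------

class _MLP:
    """Fully connected net, ReLU between layers, linear output."""

    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator):
        self.dims = tuple(dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.b.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        A = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            pre = A @ W + b
            if cache is not None:
                cache.append((A, pre))
            A = pre if i == len(self.W) - 1 else np.maximum(pre, 0.0)
        return A

    def backward(self, cache: list, dOut: np.ndarray):
        """Returns (param grads [(dW, db), ...], gradient wrt input)."""
        grads = [None] * len(self.W)
        dA = dOut
        for i in reversed(range(len(self.W))):
            A_prev, pre = cache[i]
            dPre = dA if i == len(self.W) - 1 else dA * (pre > 0.0)
            grads[i] = (A_prev.T @ dPre, dPre.sum(axis=0))
            dA = dPre @ self.W[i].T
        return grads, dA

    def params(self):
        return self.W + self.b

    def set_params(self, params):
        k = len(self.W)
        self.W = [p.copy() for p in params[:k]]
        self.b = [p.copy() for p in params[k:]]


class _AdamW:
    """Adam with decoupled weight decay; decay skips biases."""

    def __init__(self, params, lr, weight_decay, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            if p.ndim > 1:  # decoupled decay on weight matrices only
                p -= self.lr * self.wd * p
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# Model container, training, fusion
# ---------------------------------------------------------------------------

@dataclass
class FusedEmbedding:
    """Joint representation of one (molecule, assay) pair."""

    vector: np.ndarray
    source: str = "encoder_concat"


class BTModel:
    """Trained fusion network: two encoders plus the shared projector."""

    def __init__(self, config: BTConfig, d_mol_in: int, d_text_in: int):
        self.config = config
        self.d_mol_in = d_mol_in
        self.d_text_in = d_text_in
        ss = np.random.SeedSequence(config.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
        self.mol_mlp = _MLP((d_mol_in, *config.enc_mol_dims), rngs[0])
        self.text_mlp = _MLP((d_text_in, *config.enc_text_dims), rngs[1])
        self.proj_mlp = _MLP((config.enc_mol_dims[-1], *config.proj_dims), rngs[2])
        self._shuffle_rng = rngs[3]
        self.training_history: list[dict] = []

    # -- forward surfaces ---------------------------------------------------
    def encode_mol(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.d_mol_in:
            raise DimensionError(
                f"molecule input has {X.shape[1]} features, expected {self.d_mol_in}"
            )
        return self.mol_mlp.forward(X)

    def encode_text(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.d_text_in:
            raise DimensionError(
                f"text input has {X.shape[1]} features, expected {self.d_text_in}"
            )
        return self.text_mlp.forward(X)

    def project(self, H: np.ndarray) -> np.ndarray:
        return self.proj_mlp.forward(np.atleast_2d(np.asarray(H, dtype=np.float64)))

    def fuse_batch(
        self, X_mol: np.ndarray, X_text: np.ndarray, source: str = "encoder_concat"
    ) -> np.ndarray:
        Hm = self.encode_mol(X_mol)
        Ht = self.encode_text(X_text)
        if Hm.shape[0] != Ht.shape[0]:
            raise DimensionError(
                f"row mismatch: {Hm.shape[0]} molecules vs {Ht.shape[0]} texts"
            )
        if source == "projector_concat":
            Hm, Ht = self.project(Hm), self.project(Ht)
        elif source != "encoder_concat":
            raise ConfigurationError(f"unknown fusion source {source!r}")
        return np.hstack([Hm, Ht])

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": FORMAT_VERSION,
            "d_mol_in": self.d_mol_in,
            "d_text_in": self.d_text_in,
            "config": asdict(self.config),
            "training_history": self.training_history,
        }
        (path / "bt_config.json").write_text(json.dumps(meta, indent=1))
        arrays = {}
        for tag, mlp in (("mol", self.mol_mlp), ("text", self.text_mlp), ("proj", self.proj_mlp)):
            for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
                arrays[f"{tag}_W{i}"] = W
                arrays[f"{tag}_b{i}"] = b
        np.savez(path / "bt_weights.npz", **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BTModel":
        path = Path(path)
        try:
            meta = json.loads((path / "bt_config.json").read_text())
        except FileNotFoundError as exc:
            raise ArchiveError(f"no fusion model under {path}") from exc
        if meta.get("format_version") != FORMAT_VERSION:
            raise ArchiveError(
                f"archive format {meta.get('format_version')} != {FORMAT_VERSION}"
            )
        cfg_dict = meta["config"]
        for key in ("enc_mol_dims", "enc_text_dims", "proj_dims"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(BTConfig(**cfg_dict), meta["d_mol_in"], meta["d_text_in"])
        with np.load(path / "bt_weights.npz") as arrays:
            for tag, mlp in (("mol", model.mol_mlp), ("text", model.text_mlp), ("proj", model.proj_mlp)):
                mlp.W = [arrays[f"{tag}_W{i}"].copy() for i in range(len(mlp.W))]
                mlp.b = [arrays[f"{tag}_b{i}"].copy() for i in range(len(mlp.b))]
        model.training_history = meta["training_history"]
        return model

    # -- internals ----------------------------------------------------------
    def _all_params(self):
        return self.mol_mlp.params() + self.text_mlp.params() + self.proj_mlp.params()

    def _snapshot(self):
        return [p.copy() for p in self._all_params()]

    def _restore(self, snap):
        nm = len(self.mol_mlp.params())
        nt = len(self.text_mlp.params())
        self.mol_mlp.set_params(snap[:nm])
        self.text_mlp.set_params(snap[nm : nm + nt])
        self.proj_mlp.set_params(snap[nm + nt :])

    def _batch_loss_and_grads(self, Xm, Xt):
        """One forward/backward pass; returns (loss, grads aligned with _all_params)."""
        lam = self.config.lambda_offdiag
        n = Xm.shape[0]
        cache_m, cache_t, cache_pa, cache_pb = [], [], [], []
        Hm = self.mol_mlp.forward(Xm, cache_m)
        Ht = self.text_mlp.forward(Xt, cache_t)
        Pa = self.proj_mlp.forward(Hm, cache_pa)
        Pb = self.proj_mlp.forward(Ht, cache_pb)

        mu_a, mu_b = Pa.mean(axis=0), Pb.mean(axis=0)
        sig_a = np.sqrt(Pa.var(axis=0) + _EPS_STD)
        sig_b = np.sqrt(Pb.var(axis=0) + _EPS_STD)
        Za = (Pa - mu_a) / sig_a
        Zb = (Pb - mu_b) / sig_b
        C = Za.T @ Zb / n
        loss = bt_loss(C, lam)

        G = _bt_loss_grad(C, lam)
        dZa = Zb @ G.T / n
        dZb = Za @ G / n
        dPa = _standardize_backward(Za, sig_a, dZa)
        dPb = _standardize_backward(Zb, sig_b, dZb)

        gproj_a, dHm = self.proj_mlp.backward(cache_pa, dPa)
        gproj_b, dHt = self.proj_mlp.backward(cache_pb, dPb)
        gmol, _ = self.mol_mlp.backward(cache_m, dHm)
        gtext, _ = self.text_mlp.backward(cache_t, dHt)

        def flatten(pairs):
            return [g for g, _ in pairs] + [g for _, g in pairs]

        gproj = [(ga + gb, ba + bb) for (ga, ba), (gb, bb) in zip(gproj_a, gproj_b)]
        grads = flatten(gmol) + flatten(gtext) + flatten(gproj)
        return loss, grads

    def _epoch_loss(self, Xm, Xt) -> float:
        """Loss without gradient, streamed in batches of the configured size."""
        bs = self.config.batch_size
        total, count = 0.0, 0
        for start in range(0, Xm.shape[0], bs):
            xb_m, xb_t = Xm[start : start + bs], Xt[start : start + bs]
            if xb_m.shape[0] < 2:
                continue
            C = cross_correlation(self.project(self.mol_mlp.forward(xb_m)),
                                  self.project(self.text_mlp.forward(xb_t)))
            total += bt_loss(C, self.config.lambda_offdiag) * xb_m.shape[0]
            count += xb_m.shape[0]
        return total / count


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accepts (X_mol, X_text, y) arrays or a sequence of triples."""
    if isinstance(pairs, tuple) and len(pairs) == 3 and hasattr(pairs[0], "ndim"):
        Xm, Xt, y = pairs
    else:
        mols, texts, labels = [], [], []
        for fp, emb, label in pairs:
            mols.append(np.asarray(getattr(fp, "bits", fp), dtype=np.float64))
            texts.append(np.asarray(getattr(emb, "vector", emb), dtype=np.float64))
            labels.append(label)
        Xm, Xt, y = np.array(mols), np.array(texts), np.array(labels)
    Xm = np.asarray(Xm, dtype=np.float64)
    Xt = np.asarray(Xt, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if not (Xm.shape[0] == Xt.shape[0] == y.shape[0]):
        raise DimensionError(
            f"pair components disagree on length: {Xm.shape[0]}, {Xt.shape[0]}, {y.shape[0]}"
        )
    return Xm, Xt, y


def train_bt(pairs, config: BTConfig, val_pairs=None) -> BTModel:
    """Train the fusion network on labelled (fingerprint, text, label) pairs.

    With ``pairs_used='all'`` every labelled pair enters the alignment
    objective (the default); ``'positives_only'`` restricts it to active
    pairs. Stops after ``max_epochs`` epochs, or earlier when validation loss
    has not improved for ``patience`` epochs (best-epoch weights are kept).
    Given a fixed seed, training is bitwise reproducible.
    """
    Xm, Xt, y = _pairs_to_arrays(pairs)
    if config.pairs_used == "positives_only":
        keep = y == 1
        Xm, Xt = Xm[keep], Xt[keep]
    n = Xm.shape[0]
    if n < 2 * config.batch_size:
        raise ConfigurationError(
            f"need at least 2*batch_size={2 * config.batch_size} usable pairs, got {n}"
        )
    model = BTModel(config, d_mol_in=Xm.shape[1], d_text_in=Xt.shape[1])
    opt = _AdamW(model._all_params(), config.learning_rate, config.weight_decay)

    val = None
    if val_pairs is not None:
        Vm, Vt, _ = _pairs_to_arrays(val_pairs)
        if Vm.shape[1] != Xm.shape[1] or Vt.shape[1] != Xt.shape[1]:
            raise DimensionError("validation pair dimensions differ from training")
        val = (Vm, Vt)

    best_val, best_snap, stale = np.inf, None, 0
    for epoch in range(config.max_epochs):
        perm = model._shuffle_rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if idx.shape[0] < 2:
                continue
            loss, grads = model._batch_loss_and_grads(Xm[idx], Xt[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch + 1)
            opt.step(grads)
            total += loss * idx.shape[0]
            count += idx.shape[0]
        entry = {"epoch": epoch + 1, "train_loss": total / count}
        if val is not None:
            vloss = model._epoch_loss(*val)
            entry["val_loss"] = vloss
            if vloss < best_val - 1e-12:
                best_val, best_snap, stale = vloss, model._snapshot(), 0
            else:
                stale += 1
        model.training_history.append(entry)
        if val is not None and stale >= config.patience:
            break
    if best_snap is not None:
        model._restore(best_snap)
    return model


def fuse(model: BTModel, fp, emb, source: str = "encoder_concat") -> FusedEmbedding:
    """Fused representation of one (molecule, assay) pair.

    Default source concatenates the two encoder bottleneck outputs (the
    information-bottleneck features the matcher trains on); the projector
    outputs are available via ``source='projector_concat'``.
    """
    x_mol = np.asarray(getattr(fp, "bits", fp), dtype=np.float64)
    x_text = np.asarray(getattr(emb, "vector", emb), dtype=np.float64)
    vec = model.fuse_batch(x_mol[None, :], x_text[None, :], source=source)[0]
    return FusedEmbedding(vector=vec, source=source)
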