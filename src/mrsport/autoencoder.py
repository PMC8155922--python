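"""Mirrored deep autoencoder for denoising metabolite matrices.

The network maps a min-max-normalized voxels x 34 matrix X through a
sigmoid encoder phi: X -> F (hidden widths 32, 16, 8 with batch
normalization, then a 6-neuron bottleneck) and a mirrored sigmoid decoder
psi: F -> X, trained with Adam to minimize the mean squared reconstruction
error L(x, x') = ||x - psi(phi(x))||^2.  A light dropout (rate 0.1) acts on
the encoder hidden activations during training only.  The reconstruction
psi(phi(X)) is used as the denoised matrix.

Everything — forward pass, backpropagation (including the batch-norm
backward pass), dropout and Adam — is implemented directly on NumPy arrays,
which keeps training bit-reproducible for a fixed seed on one thread and
fast enough for matrices of a few thousand voxels.

The bottleneck width is selected by retraining over a grid (4..10 by
default) and scoring each denoised matrix by the variance share captured by
its first two principal components; the width maximizing that share wins,
ties going to the smaller network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .core_data import ValidationError

__all__ = [
    "LayerSpec",
    "TrainReport",
    "MetaboliteAutoencoder",
    "sigmoid",
    "init_autoencoder",
    "encode",
    "reconstruct",
    "train_autoencoder",
    "denoise",
    "bottleneck_search",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # running = (1-m)*running + m*batch


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), elementwise; saturates, never overflows."""
    return expit(np.asarray(x, dtype=float))


@dataclass
class LayerSpec:
    """Architecture of the mirrored autoencoder."""

    encoder_widths: tuple[int, ...] = (32, 16, 8)
    bottleneck: int = 6
    dropout: float = 0.1
    batch_norm: bool = True

    def __post_init__(self) -> None:
        w = tuple(self.encoder_widths)
        self.encoder_widths = w
        if len(w) == 0 or any(x <= 0 for x in w):
            raise ValidationError("encoder widths must be positive")
        if any(w[i + 1] >= w[i] for i in range(len(w) - 1)):
            raise ValidationError("encoder widths must be strictly decreasing")
        if not (0 < self.bottleneck < w[-1]):
            raise ValidationError(
                f"bottleneck ({self.bottleneck}) must lie in (0, {w[-1]})")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")

    def widths(self, n_inputs: int) -> list[int]:
        return ([n_inputs] + list(self.encoder_widths) + [self.bottleneck]
                + list(reversed(self.encoder_widths)) + [n_inputs])


@dataclass
class TrainReport:
    """Per-epoch mean squared reconstruction loss on both splits."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epochs: int = 0
    seed: int = 0


class MetaboliteAutoencoder(TransformerMixin, BaseEstimator):
    """scikit-learn style denoising autoencoder.

    Parameters mirror the training recipe: ``encoder_widths``/``bottleneck``
    define the mirrored architecture, ``dropout`` and ``batch_norm`` the
    regularization, ``epochs``/``batch_size``/``learning_rate`` the Adam
    optimization, and ``train_fraction`` the internal train/held-out split
    used for the loss history.  ``transform`` returns the denoised
    (reconstructed) matrix; ``encode`` exposes the latent code.
    """

    def __init__(self, encoder_widths=(32, 16, 8), bottleneck=6, dropout=0.1,
                 batch_norm=True, epochs=500, batch_size=32,
                 learning_rate=1e-3, train_fraction=2.0 / 3.0, random_state=0):
        self.encoder_widths = encoder_widths
        self.bottleneck = bottleneck
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.train_fraction = train_fraction
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    @property
    def layer_spec(self) -> LayerSpec:
        return LayerSpec(tuple(self.encoder_widths), self.bottleneck,
                         self.dropout, self.batch_norm)

    def initialize(self, n_inputs: int = 34) -> "MetaboliteAutoencoder":
        """Draw symmetric scaled-uniform (Glorot) weights, zero biases."""
        spec = self.layer_spec  # validates
        if n_inputs < spec.bottleneck:
            raise ValidationError("n_inputs must be >= bottleneck")
        widths = spec.widths(n_inputs)
        rng = np.random.default_rng(self.random_state)
        self.weights_ = []
        self.biases_ = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights_.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))
        n_enc_hidden = len(spec.encoder_widths)
        # batch norm on encoder hidden layers only
        self.bn_layers_ = ([i for i in range(n_enc_hidden)]
                           if spec.batch_norm else [])
        self.bn_gamma_ = {i: np.ones(widths[i + 1]) for i in self.bn_layers_}
        self.bn_beta_ = {i: np.zeros(widths[i + 1]) for i in self.bn_layers_}
        self.bn_run_mean_ = {i: np.zeros(widths[i + 1]) for i in self.bn_layers_}
        self.bn_run_var_ = {i: np.ones(widths[i + 1]) for i in self.bn_layers_}
        # dropout acts on the encoder hidden activations only: the decoder's
        # role is precise reconstruction, and corrupting its activations
        # measurably blurs small-variance structure out of the output
        n_layers = len(widths) - 1
        self.dropout_layers_ = set(range(n_enc_hidden))
        self.widths_ = widths
        self.n_features_in_ = n_inputs
        self.n_layers_ = n_layers
        self.bottleneck_index_ = n_enc_hidden  # affine layer producing latent
        self.trained_ = False
        return self

    def _ensure_initialized(self, n_inputs: int) -> None:
        if not hasattr(self, "weights_"):
            self.initialize(n_inputs)
        elif self.n_features_in_ != n_inputs:
            raise ValidationError(
                f"model expects {self.n_features_in_} features, got {n_inputs}")

    # -- forward -----------------------------------------------------------

    def _forward_eval(self, X: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Inference-mode forward pass (running BN stats, no dropout)."""
        A = np.asarray(X, dtype=float)
        stop = self.n_layers_ if upto is None else upto
        for l in range(stop):
            Z = A @ self.weights_[l] + self.biases_[l]
            if l in self.bn_layers_:
                Z = ((Z - self.bn_run_mean_[l])
                     / np.sqrt(self.bn_run_var_[l] + _BN_EPS))
                Z = self.bn_gamma_[l] * Z + self.bn_beta_[l]
            A = expit(Z)
        return A

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent representation z (voxels x bottleneck), entries in (0, 1)."""
        X = self._check_matrix(X)
        return self._forward_eval(X, upto=self.bottleneck_index_ + 1)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Full decode(encode(X)); same shape as X, entries in (0, 1)."""
        X = self._check_matrix(X)
        return self._forward_eval(X)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Denoised matrix (the reconstruction), preserving voxel order."""
        import warnings

        if not getattr(self, "trained_", False):
            warnings.warn("autoencoder has not been trained; output is the "
                          "reconstruction of an untrained network", stacklevel=2)
        return self.reconstruct(X)

    def _check_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (voxels x metabolites)")
        if not hasattr(self, "weights_"):
            raise ValidationError("model is not initialized")
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}")
        return X

    # -- training ----------------------------------------------------------

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator):
        caches = []
        A = X
        p = self.dropout
        for l in range(self.n_layers_):
            A_in = A
            Z = A_in @ self.weights_[l] + self.biases_[l]
            cache = {"A_in": A_in}
            if l in self.bn_layers_:
                mu = Z.mean(axis=0)
                var = Z.var(axis=0)
                inv_std = 1.0 / np.sqrt(var + _BN_EPS)
                Zh = (Z - mu) * inv_std
                Z = self.bn_gamma_[l] * Zh + self.bn_beta_[l]
                cache.update(Zh=Zh, inv_std=inv_std)
                self.bn_run_mean_[l] = ((1 - _BN_MOMENTUM) * self.bn_run_mean_[l]
                                        + _BN_MOMENTUM * mu)
                self.bn_run_var_[l] = ((1 - _BN_MOMENTUM) * self.bn_run_var_[l]
                                       + _BN_MOMENTUM * var)
            A = expit(Z)
            cache["A_act"] = A
            if l in self.dropout_layers_ and p > 0:
                mask = (rng.random(A.shape) >= p) / (1.0 - p)
                A = A * mask
                cache["mask"] = mask
            caches.append(cache)
        return A, caches

    def _backward(self, X: np.ndarray, A_out: np.ndarray, caches):
        n_entries = X.size
        grads_W = [None] * self.n_layers_
        grads_b = [None] * self.n_layers_
        grads_g = {}
        grads_be = {}
        dA = 2.0 * (A_out - X) / n_entries
        for l in reversed(range(self.n_layers_)):
            c = caches[l]
            if "mask" in c:
                dA = dA * c["mask"]
            A_act = c["A_act"]
            dZ = dA * A_act * (1.0 - A_act)
            if l in self.bn_layers_:
                Zh, inv_std = c["Zh"], c["inv_std"]
                grads_g[l] = (dZ * Zh).sum(axis=0)
                grads_be[l] = dZ.sum(axis=0)
                dZh = dZ * self.bn_gamma_[l]
                N = Zh.shape[0]
                dZ = (inv_std / N) * (
                    N * dZh - dZh.sum(axis=0) - Zh * (dZh * Zh).sum(axis=0))
            grads_W[l] = c["A_in"].T @ dZ
            grads_b[l] = dZ.sum(axis=0)
            dA = dZ @ self.weights_[l].T
        return grads_W, grads_b, grads_g, grads_be

    def _loss(self, X: np.ndarray) -> float:
        R = self._forward_eval(X)
        return float(np.mean((X - R) ** 2))

    def fit(self, X, y=None, epochs: int | None = None):
        """Train with Adam on a shuffled train/held-out row split.

        Requires X scaled to [0, 1] (see :class:`MinMaxNormalizer`) and at
        least 10 rows.  Deterministic for fixed ``random_state``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 10:
            raise ValidationError("X must be 2-D with >= 10 rows")
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValidationError("X must be normalized to [0, 1] before training")
        self._ensure_initialized(X.shape[1])
        n_epochs = self.epochs if epochs is None else epochs

        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, 1]))
        n = X.shape[0]
        n_train = max(1, int(round(self.train_fraction * n)))
        perm = rng.permutation(n)
        Xtr, Xval = X[perm[:n_train]], X[perm[n_train:]]

        report = TrainReport(epochs=n_epochs, seed=int(self.random_state))
        if n_epochs == 0:
            self.report_ = report
            self.loss_history_ = report
            return self

        # Adam state over the flat parameter list
        params = self._param_refs()
        m = [np.zeros_like(p) for _, _, p in params]
        v = [np.zeros_like(p) for _, _, p in params]
        t = 0
        lr, b1, b2, eps = self.learning_rate, 0.9, 0.999, 1e-8
        bs = max(1, int(self.batch_size))

        for _ in range(n_epochs):
            order = rng.permutation(n_train)
            for start in range(0, n_train, bs):
                batch = Xtr[order[start:start + bs]]
                A_out, caches = self._forward_train(batch, rng)
                gW, gb, gg, gbe = self._backward(batch, A_out, caches)
                grads = self._collect_grads(gW, gb, gg, gbe)
                t += 1
                for i, ((_, _, p), g) in enumerate(zip(params, grads)):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g * g
                    mh = m[i] / (1 - b1**t)
                    vh = v[i] / (1 - b2**t)
                    p -= lr * mh / (np.sqrt(vh) + eps)
            report.train_loss.append(self._loss(Xtr))
            report.val_loss.append(self._loss(Xval) if len(Xval) else float("nan"))

        self.trained_ = True
        self.report_ = report
        self.loss_history_ = report
        return self

    def _param_refs(self):
        refs = []
        for l in range(self.n_layers_):
            refs.append(("W", l, self.weights_[l]))
            refs.append(("b", l, self.biases_[l]))
        for l in self.bn_layers_:
            refs.append(("g", l, self.bn_gamma_[l]))
            refs.append(("be", l, self.bn_beta_[l]))
        return refs

    def _collect_grads(self, gW, gb, gg, gbe):
        grads = []
        for l in range(self.n_layers_):
            grads.append(gW[l])
            grads.append(gb[l])
        for l in self.bn_layers_:
            grads.append(gg[l])
            grads.append(gbe[l])
        return grads

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "params": self.get_params(),
            "widths": self.widths_,
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "bn_layers": list(self.bn_layers_),
            "bn_gamma": {str(k): v.tolist() for k, v in self.bn_gamma_.items()},
            "bn_beta": {str(k): v.tolist() for k, v in self.bn_beta_.items()},
            "bn_run_mean": {str(k): v.tolist() for k, v in self.bn_run_mean_.items()},
            "bn_run_var": {str(k): v.tolist() for k, v in self.bn_run_var_.items()},
            "trained": bool(getattr(self, "trained_", False)),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetaboliteAutoencoder":
        model = cls(**d["params"])
        model.initialize(d["widths"][0])
        model.weights_ = [np.asarray(w, dtype=float) for w in d["weights"]]
        model.biases_ = [np.asarray(b, dtype=float) for b in d["biases"]]
        model.bn_layers_ = list(d["bn_layers"])
        model.bn_gamma_ = {int(k): np.asarray(v) for k, v in d["bn_gamma"].items()}
        model.bn_beta_ = {int(k): np.asarray(v) for k, v in d["bn_beta"].items()}
        model.bn_run_mean_ = {int(k): np.asarray(v) for k, v in d["bn_run_mean"].items()}
        model.bn_run_var_ = {int(k): np.asarray(v) for k, v in d["bn_run_var"].items()}
        model.trained_ = bool(d["trained"])
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def init_autoencoder(spec: LayerSpec = LayerSpec(), n_inputs: int = 34,
                     seed: int = 0) -> MetaboliteAutoencoder:
    model = MetaboliteAutoencoder(
        encoder_widths=spec.encoder_widths, bottleneck=spec.bottleneck,
        dropout=spec.dropout, batch_norm=spec.batch_norm, random_state=seed)
    return model.initialize(n_inputs)


def encode(model: MetaboliteAutoencoder, X: np.ndarray) -> np.ndarray:
    return model.encode(X)


def reconstruct(model: MetaboliteAutoencoder, X: np.ndarray) -> np.ndarray:
    return model.reconstruct(X)


def train_autoencoder(model: MetaboliteAutoencoder, X: np.ndarray,
                      epochs: int = 500, split: float = 2.0 / 3.0,
                      seed: int | None = None):
    """Train ``model`` on X; returns ``(model, TrainReport)``."""
    model.epochs = epochs
    model.train_fraction = split
    if seed is not None:
        model.random_state = seed
    model.fit(X)
    return model, model.report_


def denoise(model: MetaboliteAutoencoder, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


def first_two_eigenvalue_share(X: np.ndarray) -> float:
    """Variance share of the first two principal components of X."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    ev = s**2
    tot = ev.sum()
    return float(ev[:2].sum() / tot) if tot > 0 else 0.0


def bottleneck_search(X: np.ndarray, sizes=range(4, 11), seed: int = 0,
                      epochs: int = 500, **model_kw):
    """Retrain over a bottleneck grid; score by the first-two-PC share.

    Returns ``(best_size, {size: benchmark})``; ties break toward the
    smaller network.  Hidden widths not strictly wider than the candidate
    bottleneck are dropped from the encoder (and its mirror), so the grid
    may exceed the default last hidden width of 8.
    """
    X = np.asarray(X, dtype=float)
    sizes = list(sizes)
    if any(not (1 <= s < X.shape[1]) for s in sizes):
        raise ValidationError("bottleneck sizes must lie in [1, n_inputs)")
    benchmarks: dict[int, float] = {}
    best_size, best_val = None, -np.inf
    for size in sizes:
        widths = tuple(w for w in model_kw.get("encoder_widths", (32, 16, 8))
                       if w > size)
        if not widths:
            raise ValidationError(f"no encoder width exceeds bottleneck {size}")
        model = MetaboliteAutoencoder(
            encoder_widths=widths, bottleneck=size, epochs=epochs,
            random_state=seed,
            **{k: v for k, v in model_kw.items() if k != "encoder_widths"})
        model.fit(X)
        benchmarks[size] = first_two_eigenvalue_share(model.transform(X))
        if benchmarks[size] > best_val:  # strict: ties keep the smaller size
            best_size, best_val = size, benchmarks[size]
    return best_size, benchmarks
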