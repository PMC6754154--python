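"""Tied-weight autoencoder for latent trajectory-pattern discovery.

A patient's fitted biweekly trajectory (a vector ``m`` of ``M = 20`` values,
normalised to zero mean and unit variance) is assumed to be a linear
combination of a small set of latent *basis trajectories*.  The autoencoder
learns those bases: the encoder maps ``m`` to activations
``h = u(W m + b)`` with ``W`` an ``H x M`` matrix whose rows are the basis
trajectories, and the decoder reconstructs ``m_hat = W^T h + b'`` with the
*same* (tied) weights, so there is a single weight matrix throughout
training by construction.  ``h_i`` measures how strongly basis ``W_i`` is
expressed in the patient's curve and is the feature vector used downstream
for subtype clustering.

Training minimises the reconstruction mean squared error (plus an optional
L2 weight penalty) by minibatch stochastic gradient descent with a fixed
shuffling seed, so identical seeds give bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from phqtraj.cohort import ConfigurationError

__all__ = [
    "AutoencoderModel",
    "SgdSettings",
    "ConstantTrajectoryError",
    "TrainingDivergedError",
    "normalize_input",
    "encode",
    "decode",
    "reconstruction_mse",
    "train",
    "cross_validate",
]


class ConstantTrajectoryError(ValueError):
    """A constant trajectory has no shape to normalise; the patient is excluded."""


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


_NONLINEARITIES: Dict[str, Tuple[Callable, Callable]] = {
    "sigmoid": (lambda a: 1.0 / (1.0 + np.exp(-a)), lambda a, h: h * (1.0 - h)),
    "tanh": (np.tanh, lambda a, h: 1.0 - h**2),
    "identity": (lambda a: a, lambda a, h: np.ones_like(a)),
}


@dataclass
class AutoencoderModel:
    """Tied-weight autoencoder parameters.

    The decoder weight is ``W.T`` by definition — only ``W`` is stored, so
    the tied-weight contract cannot drift.
    """

    W: np.ndarray  # (H, M) rows = latent basis trajectories
    b: np.ndarray  # (H,) encoder bias
    b_prime: np.ndarray  # (M,) decoder bias
    u: str = "sigmoid"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.b_prime = np.asarray(self.b_prime, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] < 1 or self.W.shape[1] < 1:
            raise ValueError("W must be a nonempty H x M matrix")
        if self.b.shape != (self.H,) or self.b_prime.shape != (self.M,):
            raise ValueError("bias shapes must be (H,) and (M,)")
        if self.u not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.u!r}")

    @property
    def H(self) -> int:
        return self.W.shape[0]

    @property
    def M(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class SgdSettings:
    """Minibatch SGD hyperparameters (desk-scale, deterministic defaults)."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 500
    l2: float = 1e-4
    sparsity_weight: float = 0.0  # L1 penalty on activations; off by default


def normalize_input(trajectory: Sequence[float]) -> np.ndarray:
    """Normalise one trajectory to zero mean and unit variance (per patient).

    Normalising across the 20 time points makes clustering shape-focused:
    level and amplitude are removed, the temporal profile remains.  Constant
    trajectories raise :class:`ConstantTrajectoryError`.
    """
    x = np.asarray(trajectory, dtype=float)
    sd = float(x.std())
    if sd == 0.0:
        raise ConstantTrajectoryError("constant trajectory cannot be normalised")
    return (x - x.mean()) / sd


def _as_batch(m: np.ndarray, M: int) -> Tuple[np.ndarray, bool]:
    m = np.asarray(m, dtype=float)
    single = m.ndim == 1
    batch = m[None, :] if single else m
    if batch.ndim != 2 or batch.shape[1] != M:
        raise ValueError(f"input must have {M} columns, got shape {m.shape}")
    return batch, single


def encode(model: AutoencoderModel, m: np.ndarray) -> np.ndarray:
    """Activations ``h = u(W m + b)`` (accepts a vector or a row-stacked batch)."""
    batch, single = _as_batch(m, model.M)
    act, _ = _NONLINEARITIES[model.u]
    h = act(batch @ model.W.T + model.b)
    return h[0] if single else h


def decode(model: AutoencoderModel, h: np.ndarray) -> np.ndarray:
    """Reconstruction ``m_hat = W^T h + b'``."""
    batch, single = _as_batch(h, model.H)
    out = batch @ model.W + model.b_prime
    return out[0] if single else out


def reconstruction_mse(model: AutoencoderModel, X: np.ndarray) -> float:
    """Mean squared reconstruction error over all entries of ``X`` (n x M)."""
    X = np.asarray(X, dtype=float)
    return float(np.mean((decode(model, encode(model, X)) - X) ** 2))


def train(
    X: np.ndarray,
    H: int,
    sgd: SgdSettings = SgdSettings(),
    seed: int = 0,
    u: str = "sigmoid",
) -> Tuple[AutoencoderModel, List[float]]:
    """Train a tied-weight autoencoder on row-stacked trajectories ``X`` (n x M).

    Returns the model and the trace of full-dataset reconstruction MSE after
    each epoch.  Identical inputs and seed give a bit-identical model; a
    non-finite loss aborts with :class:`TrainingDivergedError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a nonempty n x M matrix")
    n, M = X.shape
    if H < 1:
        raise ConfigurationError("H must be >= 1")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(2.0 / (H + M))
    W = rng.normal(0.0, scale, size=(H, M))
    b = np.zeros(H)
    b_prime = np.zeros(M)
    if u not in _NONLINEARITIES:
        raise ConfigurationError(f"unknown nonlinearity {u!r}")
    act, dact = _NONLINEARITIES[u]

    trace: List[float] = []
    lr = sgd.learning_rate
    for epoch in range(sgd.epochs):
        order = rng.permutation(n)
        for start in range(0, n, sgd.batch_size):
            idx = order[start : start + sgd.batch_size]
            Xb = X[idx]
            B = Xb.shape[0]
            A = Xb @ W.T + b
            Hh = act(A)
            E = Hh @ W + b_prime - Xb  # reconstruction error
            gout = (2.0 / (B * M)) * E
            dA = (gout @ W.T) * dact(A, Hh)
            if sgd.sparsity_weight > 0.0:
                dA += (sgd.sparsity_weight / (B * H)) * np.sign(Hh) * dact(A, Hh)
            gW = Hh.T @ gout + dA.T @ Xb + 2.0 * sgd.l2 * W
            W -= lr * gW
            b -= lr * dA.sum(axis=0)
            b_prime -= lr * gout.sum(axis=0)
        model = AutoencoderModel(W=W, b=b, b_prime=b_prime, u=u)
        mse = reconstruction_mse(model, X)
        if not np.isfinite(mse):
            raise TrainingDivergedError(epoch + 1)
        trace.append(mse)
    return AutoencoderModel(W=W.copy(), b=b.copy(), b_prime=b_prime.copy(), u=u), trace


def cross_validate(
    X: np.ndarray,
    H_values: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    sgd: SgdSettings = SgdSettings(),
) -> Dict[int, Dict[str, float]]:
    """K-fold cross-validated reconstruction MSE per candidate latent size.

    The rows are randomly split into ``folds`` equal-size subsamples; each is
    used exactly once as the validation set while the model trains on the
    rest.  Returns mean and sd of the validation MSE per ``H``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < folds:
        raise ConfigurationError(f"need >= {folds} rows for {folds}-fold CV, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_idx = np.array_split(order, folds)

    results: Dict[int, Dict[str, float]] = {}
    for H in H_values:
        val_mse = []
        for i, val in enumerate(fold_idx):
            train_rows = np.concatenate([f for j, f in enumerate(fold_idx) if j != i])
            model, _ = train(X[train_rows], H, sgd, seed=(seed + 1000 * (i + 1)) % (2**31))
            val_mse.append(reconstruction_mse(model, X[val]))
        results[int(H)] = {
            "mean_mse": float(np.mean(val_mse)),
            "sd_mse": float(np.std(val_mse)),
            "fold_mse": [float(v) for v in val_mse],
        }
    return results
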