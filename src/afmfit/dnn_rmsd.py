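"""Supervised model-accuracy estimation: a feed-forward network that maps
ten energetic/topographic features of a trajectory frame to the RMSD (in
Angstrom) between that frame's structure and the unknown reference.

Features (in order): E_total, E_local, E_go, E_repulsive, E_stacking,
E_pairing, E_electrostatic, V_AFM, CC_AFM and one engineered feature,
CC_AFM^N * E_total (N = 7), which up-weights frames whose image agreement
is near-perfect.  Size-extensive energies are normalized by the nucleotide
count, stacking/pairing by their interaction counts, and the
theta-weighted terms by their theta factors, so one trained network
transfers across RNAs of different sizes.

The optimized architecture is 10 -> 128 -> 64 -> 16 -> 1 with ELU
activations, ~20% dropout, He-normal initialization, Adam (learning rate
0.001, mini-batch 128) and Huber loss; early stopping monitors the
validation loss restricted to examples with true RMSD <= 10 A, weighting
performance at small RMSD where model ranking matters.  The network and
its training loop are implemented directly on numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .energy_model import ThetaConfig
from .io_formats import EnergyRecord

__all__ = [
    "RnaMeta",
    "FEATURE_NAMES",
    "MLPConfig",
    "ScalerParams",
    "TrainedModel",
    "featurize",
    "fit_scaler",
    "apply_scaler",
    "build_mlp",
    "count_parameters",
    "train",
    "predict_rmsd",
    "huber",
    "mse",
    "save_model",
    "load_model",
    "RmsdEstimator",
]

FEATURE_NAMES = (
    "e_total", "e_local", "e_go", "e_repulsive", "e_stacking",
    "e_pairing", "e_electrostatic", "v_afm", "cc_afm", "ccN_etotal",
)


@dataclass(frozen=True)
class RnaMeta:
    """Per-RNA normalizers for size-independent features."""

    n_nucleotides: int
    n_stacks: int
    n_pairs: int

    def __post_init__(self):
        if min(self.n_nucleotides, self.n_stacks, self.n_pairs) <= 0:
            raise ValueError("RNA meta counts must be positive")


@dataclass
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (128, 64, 16)
    activation: str = "elu"
    dropout: float = 0.20
    learning_rate: float = 0.001
    batch_size: int = 128
    loss: str = "huber"          # or "mse"
    huber_delta: float = 1.0
    max_epochs: int = 300
    patience: int = 20
    val_rmsd_cap: float = 10.0   # early-stopping mask on true RMSD, Angstrom

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.loss not in ("huber", "mse"):
            raise ValueError("loss must be 'huber' or 'mse'")
        if self.huber_delta <= 0:
            raise ValueError("huber delta must be positive")


@dataclass
class ScalerParams:
    """Standard-scaling statistics frozen from the training set.  Every
    later evaluation must reuse these — never refit on new data."""

    mean: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("scaler sigma must be positive for every feature")


@dataclass
class TrainedModel:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    scaler: ScalerParams | None = None
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def featurize(records: Sequence[EnergyRecord], rna_meta: RnaMeta,
              theta: ThetaConfig | None = None, N: int = 7) -> np.ndarray:
    """Build the (m, 10) feature matrix from energy records.

    Per-nucleotide normalization for E_total, E_local, E_go, E_repulsive,
    E_electrostatic, V_AFM; per-interaction for E_stacking / E_pairing;
    theta normalization for V_AFM, E_stacking, E_pairing, E_local.  The
    engineered feature CC^N * E_total uses the normalized E_total.
    """
    theta = theta or ThetaConfig()
    for name in ("theta_afm", "theta_c", "theta_stacking", "theta_pairing"):
        if getattr(theta, name) <= 0:
            raise ValueError(f"{name} must be positive for featurization")
    nt = rna_meta.n_nucleotides
    X = np.empty((len(records), 10))
    for i, r in enumerate(records):
        e_total = r.e_total / nt
        e_local = r.e_local / nt / theta.theta_c
        e_go = r.e_go / nt
        e_rep = r.e_repulsive / nt
        e_stack = r.e_stacking / rna_meta.n_stacks / theta.theta_stacking
        e_pair = r.e_pairing / rna_meta.n_pairs / theta.theta_pairing
        e_elec = r.e_electrostatic / nt
        vafm = r.v_afm / nt / theta.theta_afm
        cc = r.cc_afm
        X[i] = (e_total, e_local, e_go, e_rep, e_stack, e_pair, e_elec,
                vafm, cc, cc**N * e_total)
    return X


def fit_scaler(features: np.ndarray) -> ScalerParams:
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need more than one row to fit a scaler")
    sigma = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sigma == 0)
    if len(bad):
        names = ", ".join(FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                          for i in bad)
        raise ValueError(f"constant feature(s): {names}")
    return ScalerParams(mean=X.mean(axis=0), sigma=sigma)


def apply_scaler(features: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    return (np.asarray(features, dtype=float) - scaler.mean) / scaler.sigma


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def count_parameters(hidden_sizes: Sequence[int], input_dim: int = 10) -> int:
    """Trainable parameter count: sum over layers of in*out + out."""
    dims = [input_dim, *hidden_sizes, 1]
    return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))


def build_mlp(cfg: MLPConfig | None = None, input_dim: int = 10,
              seed: int = 0) -> TrainedModel:
    """He-normal-initialized network (weights N(0, sqrt(2/fan_in)))."""
    cfg = cfg or MLPConfig()
    rng = np.random.default_rng(seed)
    dims = [input_dim, *cfg.hidden_sizes, 1]
    weights, biases = [], []
    for i in range(len(dims) - 1):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                                  size=(dims[i], dims[i + 1])))
        biases.append(np.zeros(dims[i + 1]))
    return TrainedModel(weights=weights, biases=biases, config=cfg)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _forward(model: TrainedModel, X: np.ndarray, rng=None):
    """Forward pass; with an rng, inverted dropout is applied to hidden
    activations and the caches needed for backprop are returned."""
    cfg = model.config
    a = X
    caches = []
    n_layers = len(model.weights)
    for li, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        last = li == n_layers - 1
        h = z if last else _elu(z)
        mask = None
        if rng is not None and not last and cfg.dropout > 0:
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = h * mask
        caches.append((a, z, mask))
        a = h
    return a[:, 0], caches


def huber(pred: np.ndarray, true: np.ndarray, delta: float = 1.0) -> float:
    """Mean-reduced Huber loss: quadratic inside |err| < delta, linear
    (delta*(|err| - delta/2)) outside; continuous at the boundary."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    err = np.asarray(pred, float) - np.asarray(true, float)
    a = np.abs(err)
    per = np.where(a < delta, 0.5 * err * err, delta * (a - 0.5 * delta))
    return float(per.mean())


def mse(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean squared error."""
    err = np.asarray(pred, float) - np.asarray(true, float)
    return float(np.mean(err * err))


def _loss_and_grad(pred, true, cfg: MLPConfig):
    err = pred - true
    m = len(err)
    if cfg.loss == "mse":
        return float(np.mean(err * err)), 2.0 * err / m
    d = cfg.huber_delta
    a = np.abs(err)
    per = np.where(a < d, 0.5 * err * err, d * (a - 0.5 * d))
    return float(per.mean()), np.clip(err, -d, d) / m


def _eval_loss(model: TrainedModel, X, y) -> float:
    pred, _ = _forward(model, X)
    return huber(pred, y, model.config.huber_delta) \
        if model.config.loss == "huber" else mse(pred, y)


def train(model: TrainedModel, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray], seed: int = 0) -> TrainedModel:
    """Mini-batch Adam with early stopping.

    Inputs must already be scaled with the training scaler.  After each
    epoch the validation loss is computed only over examples with true
    RMSD <= the configured cap (10 A); the weights of the best such epoch
    are restored at the end.
    """
    cfg = model.config
    Xtr, ytr = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    Xv, yv = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    vmask = yv <= cfg.val_rmsd_cap
    if not np.any(vmask):
        raise ValueError(
            f"no validation examples with RMSD <= {cfg.val_rmsd_cap} A")
    Xv, yv = Xv[vmask], yv[vmask]

    rng = np.random.default_rng(seed)
    # Adam state
    mW = [np.zeros_like(w) for w in model.weights]
    vW = [np.zeros_like(w) for w in model.weights]
    mB = [np.zeros_like(b) for b in model.biases]
    vB = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    lr = cfg.learning_rate

    best_val = np.inf
    best = None
    bad_epochs = 0
    n = len(ytr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred, caches = _forward(model, Xtr[idx], rng=rng)
            loss, dpred = _loss_and_grad(pred, ytr[idx], cfg)
            ep_loss += loss
            nb += 1
            # backprop
            delta = dpred[:, None]
            grads_W, grads_b = [], []
            for li in range(len(model.weights) - 1, -1, -1):
                a_in, z, mask = caches[li]
                if li != len(model.weights) - 1:
                    if mask is not None:
                        delta = delta * mask
                    delta = delta * _elu_grad(z)
                grads_W.append(a_in.T @ delta)
                grads_b.append(delta.sum(axis=0))
                if li > 0:
                    delta = delta @ model.weights[li].T
            grads_W.reverse()
            grads_b.reverse()
            t += 1
            for li in range(len(model.weights)):
                for g, p_, m_, v_ in ((grads_W[li], model.weights[li], mW, vW),
                                      (grads_b[li], model.biases[li], mB, vB)):
                    m_[li] = beta1 * m_[li] + (1 - beta1) * g
                    v_[li] = beta2 * v_[li] + (1 - beta2) * g * g
                    mhat = m_[li] / (1 - beta1**t)
                    vhat = v_[li] / (1 - beta2**t)
                    p_ -= lr * mhat / (np.sqrt(vhat) + eps)
        val_loss = _eval_loss(model, Xv, yv)
        model.history["train_loss"].append(ep_loss / max(nb, 1))
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best = ([w.copy() for w in model.weights],
                    [b.copy() for b in model.biases])
            model.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    if best is not None:
        model.weights, model.biases = best
    return model


def predict_rmsd(model: TrainedModel, records: Sequence[EnergyRecord],
                 rna_meta: RnaMeta, theta: ThetaConfig | None = None,
                 N: int = 7) -> np.ndarray:
    """Deterministic forward pass (dropout off) using the stored scaler."""
    if model.scaler is None:
        raise ValueError("model has no stored scaler; train it first")
    X = featurize(records, rna_meta, theta, N=N)
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError("feature dimension mismatch")
    pred, _ = _forward(model, apply_scaler(X, model.scaler))
    return pred


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Single-file .npz archive: weights, biases, config, scaler, history."""
    payload = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        payload[f"W{i}"] = w
        payload[f"b{i}"] = b
    if model.scaler is not None:
        payload["scaler_mean"] = model.scaler.mean
        payload["scaler_sigma"] = model.scaler.sigma
    cfg = asdict(model.config)
    cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
    meta = {"config": cfg, "best_epoch": model.best_epoch,
            "n_layers": len(model.weights), "history": model.history}
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(Path(path), **payload)


def load_model(path) -> TrainedModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        cfg = MLPConfig(**cfg_d)
        n = meta["n_layers"]
        weights = [z[f"W{i}"] for i in range(n)]
        biases = [z[f"b{i}"] for i in range(n)]
        scaler = None
        if "scaler_mean" in z:
            scaler = ScalerParams(z["scaler_mean"], z["scaler_sigma"])
    model = TrainedModel(weights=weights, biases=biases, config=cfg,
                         scaler=scaler, history=meta["history"],
                         best_epoch=meta["best_epoch"])
    return model


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class RmsdEstimator(BaseEstimator, RegressorMixin):
    """Feed-forward RMSD regressor on 10-feature matrices.

    ``fit(X, y)`` splits off a validation fraction (default 20%), fits the
    standard scaler on the training part only, trains with Adam + early
    stopping and restores the best-epoch weights.  ``predict`` is a
    deterministic forward pass through the stored scaler and network.
    """

    def __init__(self, hidden_sizes=(128, 64, 16), dropout=0.20,
                 learning_rate=0.001, batch_size=128, loss="huber",
                 huber_delta=1.0, max_epochs=300, patience=20,
                 val_fraction=0.2, val_rmsd_cap=10.0, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.loss = loss
        self.huber_delta = huber_delta
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.val_rmsd_cap = val_rmsd_cap
        self.random_state = random_state

    def _config(self) -> MLPConfig:
        return MLPConfig(hidden_sizes=tuple(self.hidden_sizes),
                         dropout=self.dropout,
                         learning_rate=self.learning_rate,
                         batch_size=self.batch_size, loss=self.loss,
                         huber_delta=self.huber_delta,
                         max_epochs=self.max_epochs, patience=self.patience,
                         val_rmsd_cap=self.val_rmsd_cap)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(y))
        n_val = max(1, int(round(self.val_fraction * len(y))))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        scaler = fit_scaler(X[tr_idx])
        model = build_mlp(self._config(), input_dim=X.shape[1],
                          seed=self.random_state)
        model.scaler = scaler
        train(model,
              (apply_scaler(X[tr_idx], scaler), y[tr_idx]),
              (apply_scaler(X[val_idx], scaler), y[val_idx]),
              seed=self.random_state + 1)
        self.model_ = model
        self.n_features_in_ = X.shape[1]
        self.history_ = model.history
        self.best_epoch_ = model.best_epoch
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        pred, _ = _forward(self.model_, apply_scaler(X, self.model_.scaler))
        return pred
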