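"""Two-hidden-layer perceptron trained with Levenberg-Marquardt backprop.

The network is a multilayer perceptron with tanh hidden layers (10 + 10
units by default), a single logistic output unit, and 0/1 targets.  Let x
be the flattened vector of all weights and biases and e(x) the vector of
per-sample errors e_i = t_i - a_i (target minus output).  Training
minimizes the summed squared error

    F(x) = e(x)^T e(x)

with the Levenberg-Marquardt update

    x_{k+1} = x_k - (J^T J + mu I)^{-1} J^T e = x_k - (H + mu I)^{-1} G,

where J = de/dx is the error Jacobian, H = J^T J approximates the Hessian
and G = J^T e is the gradient of F/2.  The Jacobian rows are obtained by
propagating output sensitivities backward through the layers, the
backpropagation recursion S^m = F'(n^m) (W^{m+1})^T S^{m+1} written in
matrix form over all samples at once.  The damping mu interpolates between
Gauss-Newton (mu -> 0) and a short gradient step (mu large): a candidate
step is accepted only if it decreases F, otherwise mu is increased and the
step retried, so accepted steps never increase the training error.

Model selection / evaluation uses stratified k-fold cross-validation with
per-fold standardization fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

__all__ = [
    "MlpModel",
    "TrainConfig",
    "TrainState",
    "CvResult",
    "init_mlp",
    "lm_update",
    "lmbp_step",
    "train",
    "predict",
    "cross_validate",
]


@dataclass
class MlpModel:
    """Feed-forward perceptron: tanh hidden layers, logistic output."""

    layer_sizes: Sequence[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        sizes = list(self.layer_sizes)
        if len(sizes) < 2 or sizes[-1] != 1:
            raise ValueError("layer_sizes must end in a single output unit")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"inconsistent parameter shapes at layer {l}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite parameters")
        self.layer_sizes = sizes

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def get_params(self) -> np.ndarray:
        return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(self.weights, self.biases)])

    def set_params(self, x: np.ndarray) -> None:
        pos = 0
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            self.weights[l] = x[pos : pos + w.size].reshape(w.shape)
            pos += w.size
            self.biases[l] = x[pos : pos + b.size].copy()
            pos += b.size
        if pos != x.size:
            raise ValueError("parameter vector length mismatch")

    def copy(self) -> "MlpModel":
        return MlpModel(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
        )

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations of every layer (input included) for rows of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_inputs:
            raise ValueError(f"X must have {self.n_inputs} columns, got shape {X.shape}")
        a = X
        acts = [a]
        last = len(self.weights) - 1
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            n = a @ w.T + b
            a = expit(n) if l == last else np.tanh(n)
            acts.append(a)
        return acts

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_sizes": list(self.layer_sizes),
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MlpModel":
        d = json.loads(text)
        return cls(
            d["layer_sizes"],
            [np.array(w, dtype=float) for w in d["weights"]],
            [np.array(b, dtype=float) for b in d["biases"]],
        )


@dataclass
class TrainConfig:
    """Levenberg-Marquardt schedule (the classical Marquardt recipe)."""

    mu0: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 10.0
    mu_max: float = 1e10
    max_epochs: int = 100
    grad_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_increase <= 1 or self.mu_decrease <= 1:
            raise ValueError("mu factors must exceed 1")
        if self.mu0 <= 0 or self.mu_max <= 0 or self.grad_tol <= 0:
            raise ValueError("mu0, mu_max and grad_tol must be positive")


@dataclass
class TrainState:
    mu: float
    epoch: int = 0
    F: float = np.inf
    grad_norm: float = np.inf
    converged: bool = False


def init_mlp(n_inputs: int, seed: int = 0, hidden: Sequence[int] = (10, 10)) -> MlpModel:
    """Fresh model with weights drawn uniformly in [-0.5, 0.5] from ``seed``."""
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = [int(n_inputs), *map(int, hidden), 1]
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        weights.append(rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l])))
        biases.append(rng.uniform(-0.5, 0.5, size=sizes[l + 1]))
    return MlpModel(sizes, weights, biases)


def _error_and_jacobian(model: MlpModel, X: np.ndarray, y: np.ndarray):
    """e = t - a and J = de/dx for every sample, via backward sensitivities."""
    acts = model.forward(X)
    out = acts[-1][:, 0]
    e = np.asarray(y, dtype=float) - out
    m = X.shape[0]
    last = len(model.weights) - 1

    # g[l] (m, n_l) = d out / d n_l, built backwards from the logistic output
    g = [None] * (last + 1)
    g[last] = (out * (1.0 - out))[:, None]
    for l in range(last - 1, -1, -1):
        g[l] = (g[l + 1] @ model.weights[l + 1]) * (1.0 - acts[l + 1] ** 2)

    blocks = []
    for l in range(last + 1):
        a_prev = acts[l]
        jw = g[l][:, :, None] * a_prev[:, None, :]  # (m, n_l, n_{l-1})
        blocks.append(jw.reshape(m, -1))
        blocks.append(g[l])
    J = -np.concatenate(blocks, axis=1)  # de/dx = -d out/d x
    return e, J


def lm_update(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Parameter increment Delta = -(J^T J + mu I)^{-1} J^T e."""
    h = J.T @ J
    g = J.T @ e
    try:
        return -np.linalg.solve(h + mu * np.eye(h.shape[0]), g)
    except np.linalg.LinAlgError as err:
        raise RuntimeError("Levenberg-Marquardt system is singular") from err


def lmbp_step(
    model: MlpModel, X: np.ndarray, y: np.ndarray, state: TrainState, cfg: TrainConfig
) -> tuple[MlpModel, TrainState]:
    """One damped update: accept only steps that decrease F, escalating mu.

    Returns the (possibly unchanged) model and updated state; sets
    ``state.converged`` when the gradient tolerance or mu_max is reached.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must have matching, nonzero sample counts")
    e, J = _error_and_jacobian(model, X, y)
    F = float(e @ e)
    G = J.T @ e
    state.F = F
    state.grad_norm = float(np.abs(G).max()) if G.size else 0.0
    if state.grad_norm < cfg.grad_tol:
        state.converged = True
        return model, state

    x = model.get_params()
    while state.mu <= cfg.mu_max:
        delta = lm_update(J, e, state.mu)
        candidate = model.copy()
        candidate.set_params(x + delta)
        acts = candidate.forward(X)
        e_new = y - acts[-1][:, 0]
        F_new = float(e_new @ e_new)
        if F_new < F:
            state.mu = max(state.mu / cfg.mu_decrease, np.finfo(float).tiny)
            state.F = F_new
            state.epoch += 1
            return candidate, state
        state.mu *= cfg.mu_increase
    state.converged = True  # no descent direction within the damping budget
    return model, state


def train(
    model: MlpModel, X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[MlpModel, list[float]]:
    """Run LM epochs until max_epochs, gradient tolerance or mu exhaustion.

    Returns the trained model and the history of F(x) after each accepted
    step (non-increasing by construction).
    """
    cfg = cfg or TrainConfig()
    state = TrainState(mu=cfg.mu0)
    history: list[float] = []
    for _ in range(cfg.max_epochs):
        model, state = lmbp_step(model, X, y, state, cfg)
        if state.converged:
            break
        history.append(state.F)
    return model, history


def predict(model: MlpModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (score strictly above 0.5) and raw logistic scores."""
    scores = model.forward(np.atleast_2d(np.asarray(X, dtype=float)))[-1][:, 0]
    return (scores > 0.5).astype(int), scores


@dataclass
class CvResult:
    """Cross-validated performance of the MLP on one feature matrix."""

    fold_assignments: np.ndarray
    fold_accuracies: list[float]  # percent
    mean_accuracy: float  # percent
    mse: float
    pooled_accuracy: float = np.nan  # percent, over all held-out predictions


def _standardize(train_X: np.ndarray, test_X: np.ndarray):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train_X - mu) / sd, (test_X - mu) / sd


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    cfg: TrainConfig | None = None,
    standardize: bool = True,
    mode: str = "kfold",
    hidden: Sequence[int] = (10, 10),
) -> CvResult:
    """Stratified k-fold (default) or single stratified 90/10 split.

    Each fold trains a freshly initialized network on the remaining data
    (standardized with training-fold statistics) and scores accuracy on the
    held-out part.  ``mode='single'`` uses one stratified train/validation
    split per repeat — the fast variant used inside subset searches.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cfg = cfg or TrainConfig()
    counts = np.bincount(y, minlength=2)
    if mode == "kfold" and counts.min() < n_folds:
        raise ValueError(f"each class needs >= {n_folds} members, got {counts.tolist()}")

    root = np.random.default_rng(seed)
    fold_acc: list[float] = []
    all_correct = 0
    all_sq = 0.0
    n_pred = 0
    assignments = np.full(len(y), -1, dtype=int)
    for rep in range(repeats):
        split_seed = int(root.integers(2**31))
        if mode == "single":
            splitter = StratifiedShuffleSplit(
                n_splits=1, test_size=1.0 / n_folds, random_state=split_seed
            )
        elif mode == "kfold":
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=split_seed)
        else:
            raise ValueError("mode must be 'kfold' or 'single'")
        for fold, (tr, te) in enumerate(splitter.split(X, y)):
            if rep == 0:
                assignments[te] = fold
            Xtr, Xte = (X[tr], X[te])
            if standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            model = init_mlp(X.shape[1], seed=int(root.integers(2**31)), hidden=hidden)
            model, _ = train(model, Xtr, y[tr], cfg)
            labels, scores = predict(model, Xte)
            fold_acc.append(100.0 * float(np.mean(labels == y[te])))
            all_correct += int(np.sum(labels == y[te]))
            all_sq += float(np.sum((y[te] - scores) ** 2))
            n_pred += len(te)
    return CvResult(
        fold_assignments=assignments,
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        mse=all_sq / n_pred,
        pooled_accuracy=100.0 * all_correct / n_pred,
    )
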