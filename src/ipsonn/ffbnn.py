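"""Per-class feed-forward back-propagation networks (c-FFBNN).

One single-hidden-layer sigmoid network is trained per tissue class in
one-vs-rest fashion; classification fuses the five activations by
argmax (ties broken by the fixed class order WM, GM, CSF, tumor,
edema).  The output activation is the logistic sigmoid of the bias-plus
weighted sum; training minimizes the mean squared error by seeded
stochastic gradient backpropagation, while the signed mean residual
(which can cancel to zero on nonzero errors, hence is tracked but not
optimized) is logged alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .phantom import TISSUE_CLASSES


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class Network:
    """Weights of one 1-hidden-layer network: inputs -> H_d sigmoid units
    -> one sigmoid output with bias ``beta``."""

    w_in: np.ndarray   # (H_d, n_inputs)
    b_hidden: np.ndarray  # (H_d,)
    w_out: np.ndarray  # (H_d,)
    beta: float

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.w_in.shape[0]


def init_network(n_inputs: int, hidden: int = 10, seed: int = 0,
                 init_scale: float = 1.0) -> Network:
    """Seeded Xavier-style initialization."""
    if hidden < 1 or n_inputs < 1:
        raise ValueError("network needs >= 1 input and >= 1 hidden unit")
    rng = np.random.default_rng(seed)
    s1 = init_scale * np.sqrt(1.0 / n_inputs)
    s2 = init_scale * np.sqrt(1.0 / hidden)
    return Network(
        w_in=rng.normal(0.0, s1, size=(hidden, n_inputs)),
        b_hidden=np.zeros(hidden),
        w_out=rng.normal(0.0, s2, size=hidden),
        beta=0.0,
    )


def forward(net: Network, x) -> float:
    """Activation in (0, 1) for one input vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"expected input of length {net.n_inputs}")
    h = _sigmoid(net.w_in @ x + net.b_hidden)
    z = net.beta + net.w_out @ h
    return float(_sigmoid(z))


def gradients(net: Network, x, y: float):
    """Analytic gradients of the per-sample loss 0.5*(a - y)^2."""
    x = np.asarray(x, dtype=np.float64)
    h = _sigmoid(net.w_in @ x + net.b_hidden)
    a = _sigmoid(net.beta + net.w_out @ h)
    delta_out = (a - y) * a * (1.0 - a)
    d_w_out = delta_out * h
    d_beta = delta_out
    delta_h = delta_out * net.w_out * h * (1.0 - h)
    d_w_in = np.outer(delta_h, x)
    d_b_hidden = delta_h
    return d_w_in, d_b_hidden, d_w_out, d_beta


def learning_error(desired: Sequence[float], actual: Sequence[float],
                   H_d: Optional[int] = None) -> float:
    """Signed mean residual L = (1/H_d) * sum(D - Z).

    The divisor defaults to the sequence length.  Opposite-signed
    residuals cancel, so this is a report-only quantity; the trainer's
    stopping rule uses MSE.
    """
    d = np.asarray(desired, dtype=np.float64)
    z = np.asarray(actual, dtype=np.float64)
    if d.shape != z.shape:
        raise ValueError("desired and actual must have equal length")
    if H_d is None:
        H_d = d.size
    return float(np.sum(d - z) / H_d)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.1
    max_epochs: int = 2000
    error_tol: float = 1e-3
    seed: int = 0
    init_scale: float = 1.0
    hidden: int = 10

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def train(net: Network, X: np.ndarray, y: np.ndarray, cfg: TrainingConfig):
    """Seeded per-sample SGD on the squared-error surface.

    Stops at ``max_epochs`` or when the epoch MSE drops to
    ``error_tol``.  Returns ``(net, history)`` where ``history`` is a
    DataFrame with epoch, mse and the signed learning error.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have matching first dimensions")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("training targets contain a single class")

    rng = np.random.default_rng(cfg.seed)
    rows = []
    for epoch in range(cfg.max_epochs):
        for i in rng.permutation(X.shape[0]):
            d_w_in, d_b, d_w_out, d_beta = gradients(net, X[i], y[i])
            net.w_in -= cfg.learning_rate * d_w_in
            net.b_hidden -= cfg.learning_rate * d_b
            net.w_out -= cfg.learning_rate * d_w_out
            net.beta -= cfg.learning_rate * d_beta
        acts = np.array([forward(net, x) for x in X])
        mse = float(np.mean((acts - y) ** 2))
        rows.append({"epoch": epoch, "mse": mse,
                     "signed_error": learning_error(y, acts)})
        if mse <= cfg.error_tol:
            break
    history = pd.DataFrame(rows)
    return net, history


# ---------------------------------------------------------------------------
# one-vs-rest ensemble


@dataclass
class ClassifierEnsemble:
    """One trained network per tissue class plus the shared scaler.

    ``feature_names`` maps class -> the selected feature subset the
    class network consumes; ``scaler_mean``/``scaler_scale`` are the
    z-score parameters fitted on the training table (full 7 columns).
    """

    networks: dict
    feature_names: dict
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    classes: tuple = TISSUE_CLASSES
    history: dict = field(default_factory=dict, repr=False)

    def activations(self, x) -> dict:
        xv = x.as_array() if isinstance(x, FeatureVector) else np.asarray(x, float)
        z = (xv - self.scaler_mean) / self.scaler_scale
        out = {}
        for c in self.classes:
            idx = [FEATURE_NAMES.index(n) for n in self.feature_names[c]]
            out[c] = forward(self.networks[c], z[idx])
        return out


def classify(ensemble: ClassifierEnsemble, x) -> str:
    """Argmax over per-class activations; ties go to the first class in
    the fixed order."""
    missing = [c for c in ensemble.classes if c not in ensemble.networks]
    if missing:
        raise ValueError(f"ensemble is missing networks for {missing}")
    acts = ensemble.activations(x)
    best, best_a = None, -np.inf
    for c in ensemble.classes:
        if acts[c] > best_a:  # strict: earlier class wins ties
            best, best_a = c, acts[c]
    return best


def fit_ensemble(
    feature_table: pd.DataFrame,
    selected: dict,
    cfg: TrainingConfig,
    classes: tuple = TISSUE_CLASSES,
) -> ClassifierEnsemble:
    """Train one one-vs-rest network per class on the feature table.

    ``feature_table`` has a ``tissue`` column plus the 7 feature
    columns; ``selected`` maps class -> feature-name subset (from the
    swarm selector).  Features are z-scored with parameters fitted here
    and stored on the ensemble.
    """
    X_all = feature_table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    mean = X_all.mean(axis=0)
    scale = X_all.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    Z = (X_all - mean) / scale
    tissues = feature_table["tissue"].to_numpy()

    networks, history = {}, {}
    for k, c in enumerate(classes):
        names = list(selected.get(c) or FEATURE_NAMES)
        idx = [FEATURE_NAMES.index(n) for n in names]
        y = (tissues == c).astype(np.float64)
        net = init_network(len(idx), hidden=cfg.hidden,
                           seed=cfg.seed + k, init_scale=cfg.init_scale)
        net, hist = train(net, Z[:, idx], y, cfg)
        networks[c] = net
        history[c] = hist
    return ClassifierEnsemble(
        networks=networks,
        feature_names={c: list(selected.get(c) or FEATURE_NAMES) for c in classes},
        scaler_mean=mean,
        scaler_scale=scale,
        classes=tuple(classes),
        history=history,
    )


# ---------------------------------------------------------------------------
# serialization


def ensemble_to_json(ens: ClassifierEnsemble) -> str:
    payload = {
        "classes": list(ens.classes),
        "scaler_mean": ens.scaler_mean.tolist(),
        "scaler_scale": ens.scaler_scale.tolist(),
        "feature_names": {c: list(v) for c, v in ens.feature_names.items()},
        "networks": {
            c: {
                "w_in": n.w_in.tolist(),
                "b_hidden": n.b_hidden.tolist(),
                "w_out": n.w_out.tolist(),
                "beta": n.beta,
            }
            for c, n in ens.networks.items()
        },
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def ensemble_from_json(text: str) -> ClassifierEnsemble:
    payload = json.loads(text)
    networks = {
        c: Network(
            w_in=np.array(d["w_in"], dtype=np.float64),
            b_hidden=np.array(d["b_hidden"], dtype=np.float64),
            w_out=np.array(d["w_out"], dtype=np.float64),
            beta=float(d["beta"]),
        )
        for c, d in payload["networks"].items()
    }
    return ClassifierEnsemble(
        networks=networks,
        feature_names={c: list(v) for c, v in payload["feature_names"].items()},
        scaler_mean=np.array(payload["scaler_mean"], dtype=np.float64),
        scaler_scale=np.array(payload["scaler_scale"], dtype=np.float64),
        classes=tuple(payload["classes"]),
    )
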