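"""Beat-level classifiers: rule-based VPC and MLP-based APC.

VPC (ventricular premature complex) detection is a two-condition rule on
beat morphology and timing: the QRS must be wide relative to the running
median width, and the beat premature relative to the local mean RR.

APC (atrial premature complex, AAMI class S) detection uses a single-hidden-
layer perceptron trained with backpropagation on the seven interval/
morphology features.  The network is written out explicitly (no ML framework)
so gradients can be verified against finite differences and training is
bitwise reproducible from a seed.  Class order in the pipeline follows the
integrated flow: VPC labels are assigned first and are never overwritten by
the APC stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import MlpConfig, VpcConfig
from .qrs_beats import FEATURE_NAMES, BeatFeatures, BeatSeries

__all__ = ["MlpModel", "TrainReport", "classify_vpc", "train_apc_mlp",
           "mlp_forward", "classify_apc", "loss_and_grad"]


# ---------------------------------------------------------------------------
# Rule-based VPC
# ---------------------------------------------------------------------------

def classify_vpc(features: list[BeatFeatures], beats: BeatSeries,
                 cfg: VpcConfig | None = None) -> BeatSeries:
    """Label beats V when wide AND premature; everything else keeps N.

    Wide: ``qrs_duration > width_factor x`` running median of the QRS widths
    of preceding non-V beats (falling back to the record median early on).
    Premature: ``rr_prev < prematurity_factor x rr_mean_20``.  Beats with
    undefined inputs are never labeled V.
    """
    cfg = cfg or VpcConfig()
    if len(features) != len(beats):
        raise ValueError("features must align with beats")
    durations = np.array([f.qrs_duration for f in features])
    finite = durations[np.isfinite(durations)]
    global_median = float(np.median(finite)) if finite.size else math.nan
    labels: list[str] = []
    normal_widths: list[float] = []
    for k, f in enumerate(features):
        recent = normal_widths[-cfg.median_window:]
        med = float(np.median(recent)) if len(recent) >= 5 else global_median
        is_v = (
            np.isfinite(f.qrs_duration) and np.isfinite(med)
            and np.isfinite(f.rr_prev) and np.isfinite(f.rr_mean_20)
            and f.qrs_duration > cfg.width_factor * med
            and f.rr_prev < cfg.prematurity_factor * f.rr_mean_20
        )
        if is_v:
            labels.append("V")
        else:
            prior = beats.labels[k]
            labels.append(prior if prior not in ("?",) else "N")
            if np.isfinite(f.qrs_duration):
                normal_widths.append(float(f.qrs_duration))
    return BeatSeries(beats.beat_samples.copy(), beats.fs, labels)


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclass
class MlpModel:
    """Single-hidden-layer sigmoid network with stored input normalization."""

    w1: np.ndarray               # (n_in, n_hidden)
    b1: np.ndarray               # (n_hidden,)
    w2: np.ndarray               # (n_hidden,)
    b2: float
    impute: np.ndarray           # training-set medians per feature
    mean: np.ndarray             # z-score statistics
    std: np.ndarray
    classes: tuple[str, str] = ("N", "S")

    @property
    def n_in(self) -> int:
        return self.w1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]

    def save(self, path: str | Path) -> None:
        payload = {
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "impute": self.impute.tolist(), "mean": self.mean.tolist(),
            "std": self.std.tolist(), "classes": list(self.classes),
            "feature_names": list(FEATURE_NAMES),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w1=np.array(d["w1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=float(d["b2"]),
            impute=np.array(d["impute"]), mean=np.array(d["mean"]),
            std=np.array(d["std"]), classes=tuple(d["classes"]),
        )

    def normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float, ndmin=2)
        nan = ~np.isfinite(X)
        X[nan] = np.broadcast_to(self.impute, X.shape)[nan]
        return (X - self.mean) / self.std


@dataclass
class TrainReport:
    split: tuple[float, float, float]
    epochs_run: int
    train_accuracy: float
    val_accuracy: float
    test_accuracy: float
    seed: int
    history: list[float] = field(default_factory=list)  # training loss by epoch


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(params, X):
    w1, b1, w2, b2 = params
    h = _sigmoid(X @ w1 + b1)
    p = _sigmoid(h @ w2 + b2)
    return h, p


def loss_and_grad(params, X: np.ndarray, y: np.ndarray, sample_w: np.ndarray):
    """Weighted cross-entropy loss and its analytic gradients.

    Returns ``(loss, (gw1, gb1, gw2, gb2))``; the gradient is exact for the
    sigmoid-sigmoid architecture and is what training descends on.
    """
    w1, b1, w2, b2 = params
    h, p = _forward(params, X)
    eps = 1e-12
    wsum = sample_w.sum()
    loss = -np.sum(sample_w * (y * np.log(p + eps)
                               + (1 - y) * np.log(1 - p + eps))) / wsum
    # output delta for cross-entropy + sigmoid: (p - y)
    d2 = sample_w * (p - y) / wsum
    gw2 = h.T @ d2
    gb2 = float(d2.sum())
    d1 = np.outer(d2, w2) * h * (1 - h)
    gw1 = X.T @ d1
    gb1 = d1.sum(axis=0)
    return loss, (gw1, gb1, gw2, gb2)


def mlp_forward(model: MlpModel, x: np.ndarray, normalized: bool = False) -> float:
    """Probability that a beat is class S; label S iff >= 0.5."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1 and x.shape[0] != model.n_in:
        raise ValueError(f"expected {model.n_in} features, got {x.shape[0]}")
    X = x.reshape(1, -1) if x.ndim == 1 else x
    if X.shape[1] != model.n_in:
        raise ValueError(f"expected {model.n_in} features, got {X.shape[1]}")
    if not normalized:
        X = model.normalize(X)
    _, p = _forward((model.w1, model.b1, model.w2, model.b2), X)
    return float(p[0]) if x.ndim == 1 else p


def _stratified_split(y: np.ndarray, fracs, rng: np.random.Generator):
    idx_tr, idx_va, idx_te = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fracs[0] * n))
        n_va = int(round(fracs[1] * n))
        idx_tr.append(idx[:n_tr])
        idx_va.append(idx[n_tr : n_tr + n_va])
        idx_te.append(idx[n_tr + n_va :])
    return (np.sort(np.concatenate(idx_tr)), np.sort(np.concatenate(idx_va)),
            np.sort(np.concatenate(idx_te)))


def train_apc_mlp(features: list[BeatFeatures] | np.ndarray,
                  ref_labels: list[str] | np.ndarray,
                  cfg: MlpConfig | None = None,
                  seed: int = 0) -> tuple[MlpModel, TrainReport]:
    """Train the S-vs-rest perceptron with a stratified 60/20/20 split.

    Missing feature values are imputed with training-set medians and all
    features z-scored with training-set statistics (both stored in the
    model).  Full-batch gradient descent with early stopping on validation
    loss; inverse-class-frequency sample weights counter the heavy N/S
    imbalance of real recordings.  Identical seed, data and config give
    bitwise-identical weights.
    """
    cfg = cfg or MlpConfig()
    if abs(sum(cfg.split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(features) and isinstance(features[0], BeatFeatures):
        X = np.array([f.as_array() for f in features])
    else:
        X = np.array(features, dtype=float, ndmin=2)
    y = np.array([1.0 if lab == "S" else 0.0 for lab in ref_labels])
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 beats per class, got N={counts[0]}, S={counts[1]}"
        )
    rng = np.random.default_rng(seed)
    tr, va, te = _stratified_split(y, cfg.split, rng)

    impute = np.nanmedian(np.where(np.isfinite(X[tr]), X[tr], np.nan), axis=0)
    impute = np.where(np.isfinite(impute), impute, 0.0)
    Xi = np.where(np.isfinite(X), X, impute)
    mean = Xi[tr].mean(axis=0)
    std = Xi[tr].std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    Z = (Xi - mean) / std

    n_in = X.shape[1]
    w1 = rng.normal(0.0, 1.0 / math.sqrt(n_in), size=(n_in, cfg.n_hidden))
    b1 = np.zeros(cfg.n_hidden)
    w2 = rng.normal(0.0, 1.0 / math.sqrt(cfg.n_hidden), size=cfg.n_hidden)
    b2 = 0.0

    if cfg.class_weighting:
        cw = len(y) / (2.0 * np.maximum(counts, 1))
        sw = cw[y.astype(int)]
    else:
        sw = np.ones(len(y))

    params = [w1, b1, w2, b2]
    best = [p.copy() if isinstance(p, np.ndarray) else p for p in params]
    best_val = math.inf
    patience_left = cfg.patience
    history: list[float] = []
    epochs = 0
    for epoch in range(cfg.max_epochs):
        loss, grads = loss_and_grad(tuple(params), Z[tr], y[tr], sw[tr])
        history.append(loss)
        for i in range(4):
            params[i] = params[i] - cfg.learning_rate * grads[i]
        val_loss, _ = loss_and_grad(tuple(params), Z[va], y[va], sw[va])
        epochs = epoch + 1
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = [p.copy() if isinstance(p, np.ndarray) else p for p in params]
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model = MlpModel(w1=best[0], b1=best[1], w2=best[2], b2=float(best[3]),
                     impute=impute, mean=mean, std=std)

    def acc(idx):
        if len(idx) == 0:
            return math.nan
        p = mlp_forward(model, Z[idx], normalized=True)
        return float(np.mean((p >= 0.5) == (y[idx] == 1.0)))

    report = TrainReport(split=cfg.split, epochs_run=epochs,
                         train_accuracy=acc(tr), val_accuracy=acc(va),
                         test_accuracy=acc(te), seed=seed, history=history)
    return model, report


def classify_apc(model: MlpModel, features: list[BeatFeatures],
                 beats: BeatSeries) -> BeatSeries:
    """Apply the MLP to beats not already labeled V.

    V labels from the upstream VPC stage are never overwritten; the decision
    threshold is 0.5 with ties going to S.
    """
    if len(features) != len(beats):
        raise ValueError("features must align with beats")
    labels = list(beats.labels)
    if features:
        X = np.array([f.as_array() for f in features])
        p = mlp_forward(model, X)
        for k in range(len(labels)):
            if labels[k] == "V":
                continue
            labels[k] = "S" if p[k] >= 0.5 else "N"
    return BeatSeries(beats.beat_samples.copy(), beats.fs, labels)
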