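r"""Hybrid static-encoder + recurrent-attention conversion predictor.

Architecture
------------
Two branches are fused:

* **Static encoder** — five fully connected ReLU layers over the
  non-time-dependent features (demographics, comorbidities, intervention
  arm, family history, diagnosis class), followed by a logistic head that
  compresses them into a single score in (0, 1).
* **Recurrent core** — a single-layer LSTM unrolled over the scheduled
  visits.  The input at each step concatenates that visit's scale values,
  the static score, and the previous step's conversion outcome (teacher
  forcing: the true 3-month label during training, the model's own
  predicted label at inference).  A scaled dot-product attention block
  queries the current hidden state against all hidden states so far,

  .. math:: \mathrm{attn}(Q,K,V) = \mathrm{softmax}(QK^\top/\sqrt{d})\,V,

  and the attended context is mapped through a logistic head to the
  conversion probability for the next follow-up (step 1 → 3 months,
  step 2 → 6 months).

Training is full-batch Adam on summed per-step binary cross-entropy,
with a step learning-rate decay and epoch selection by highest 6-month
validation AUC.  Everything is seed-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .nn import Adam, Tensor, concat_cols, softmax_rows
from .synthetic import ARMS, CohortTable

__all__ = [
    "StaticEncoderConfig",
    "AttentionConfig",
    "TrainingConfig",
    "ConversionNet",
    "TrainedModel",
    "attention",
    "design_matrices",
    "aligned_labels",
    "train_model",
]


@dataclass(frozen=True)
class StaticEncoderConfig:
    """Five fully connected layers, then a logistic score head."""

    hidden: tuple[int, ...] = (64, 64, 32, 32, 16)

    def __post_init__(self):
        if len(self.hidden) != 5:
            raise ValueError("static encoder has exactly five hidden layers")


@dataclass(frozen=True)
class AttentionConfig:
    d: int

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("attention dimensionality must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    epochs: int = 1000
    batch_size: int = 3600  # >= any realistic cohort, i.e. full-batch
    lr_decay_epochs: tuple[int, ...] = (400, 800)
    lr_decay_factor: float = 0.1
    teacher_forcing: bool = True
    teacher_signal: str = "label"  # 'label' | 'probability'
    val_fraction: float = 0.2
    hidden_size: int = 32
    encoder: StaticEncoderConfig = field(default_factory=StaticEncoderConfig)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.teacher_signal not in ("label", "probability"):
            raise ValueError("teacher_signal must be 'label' or 'probability'")


def attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
              d: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention: softmax(QKᵀ/√d)·V.

    Returns ``(context, weights)``; each weight row is non-negative and
    sums to one.  ``d`` defaults to the key dimensionality.
    """
    Q, K, V = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (Q, K, V))
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    if Q.shape[1] != K.shape[1]:
        raise ValueError("Q and K dimensionality mismatch")
    d = AttentionConfig(d if d is not None else K.shape[1]).d
    scores = Tensor(Q) @ Tensor(K).T * (1.0 / np.sqrt(d))
    weights = softmax_rows(scores)
    context = weights @ Tensor(V)
    return context.value, weights.value


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class ConversionNet:
    """The hybrid network with explicit, inspectable weight tensors."""

    def __init__(self, n_static: int, n_time: int,
                 encoder: StaticEncoderConfig = StaticEncoderConfig(),
                 hidden_size: int = 32, seed: int = 0):
        self.n_static = n_static
        self.n_time = n_time
        self.encoder_cfg = encoder
        self.hidden_size = hidden_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        H = hidden_size
        self.params: dict[str, Tensor] = {}

        widths = [n_static, *encoder.hidden]
        for i in range(5):
            self.params[f"enc_W{i}"] = Tensor(
                _glorot(rng, widths[i], widths[i + 1]), requires_grad=True)
            self.params[f"enc_b{i}"] = Tensor(
                np.zeros((1, widths[i + 1])), requires_grad=True)
        self.params["enc_w_head"] = Tensor(
            _glorot(rng, widths[-1], 1), requires_grad=True)
        self.params["enc_b_head"] = Tensor(np.zeros((1, 1)), requires_grad=True)

        step_in = n_time + 2  # visit scales + static score + previous outcome
        self.params["lstm_W"] = Tensor(
            _glorot(rng, step_in + H, 4 * H), requires_grad=True)
        self.params["lstm_b"] = Tensor(np.zeros((1, 4 * H)), requires_grad=True)
        self.params["out_w"] = Tensor(_glorot(rng, H, 1), requires_grad=True)
        self.params["out_b"] = Tensor(np.zeros((1, 1)), requires_grad=True)

    # -- forward passes ----------------------------------------------------

    def encode_static(self, X: np.ndarray) -> np.ndarray:
        """Static-branch score in (0, 1) for each row of ``X``."""
        return self._encode(Tensor(np.atleast_2d(X))).value

    def _encode(self, x: Tensor) -> Tensor:
        a = x
        for i in range(5):
            a = (a @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]).relu()
        return (a @ self.params["enc_w_head"] + self.params["enc_b_head"]).sigmoid()

    def _attend(self, query: Tensor, keys: list[Tensor]) -> Tensor:
        if len(keys) == 1:
            return keys[0]
        scale = 1.0 / np.sqrt(self.hidden_size)
        scores = concat_cols(
            [(query * k).sum(axis=1, keepdims=True) * scale for k in keys])
        w = softmax_rows(scores)
        ctx = w.slice_cols(0, 1) * keys[0]
        for j in range(1, len(keys)):
            ctx = ctx + w.slice_cols(j, j + 1) * keys[j]
        return ctx

    def _unroll(self, static_X: np.ndarray, seq_X: np.ndarray,
                prev_signals: list[np.ndarray | None]) -> list[Tensor]:
        """Per-step output logits.

        ``seq_X`` is (n, T, n_time); ``prev_signals[t]`` is the (n, 1)
        previous-outcome input for step t, or None to use the model's own
        prediction from step t-1 (gradient-detached).
        """
        n, T, _ = seq_X.shape
        H = self.hidden_size
        score = self._encode(Tensor(static_X))
        h = Tensor(np.zeros((n, H)))
        c = Tensor(np.zeros((n, H)))
        hidden: list[Tensor] = []
        logits: list[Tensor] = []
        for t in range(T):
            if prev_signals[t] is not None:
                prev = Tensor(prev_signals[t])
            elif t == 0:
                prev = Tensor(np.zeros((n, 1)))
            else:
                p_prev = _sigmoid(logits[-1].value)
                if self.teacher_signal_infer == "label":
                    p_prev = (p_prev >= 0.5).astype(float)
                prev = Tensor(p_prev)
            inp = concat_cols([Tensor(seq_X[:, t, :]), score, prev])
            z = concat_cols([inp, h]) @ self.params["lstm_W"] + self.params["lstm_b"]
            i = z.slice_cols(0, H).sigmoid()
            f = z.slice_cols(H, 2 * H).sigmoid()
            g = z.slice_cols(2 * H, 3 * H).tanh()
            o = z.slice_cols(3 * H, 4 * H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hidden.append(h)
            ctx = self._attend(h, hidden)
            logits.append(ctx @ self.params["out_w"] + self.params["out_b"])
        return logits

    teacher_signal_infer = "label"

    def predict(self, static_X: np.ndarray, seq_X: np.ndarray) -> np.ndarray:
        """Per-step conversion probabilities, shape (n, T).

        With the full two-step sequence the columns are the 3- and 6-month
        predictions; with the mid-point withdrawn (T = 1, baseline step
        only) the single column is used as the 6-month prediction.
        """
        seq_X = np.asarray(seq_X, dtype=float)
        if seq_X.ndim != 3 or seq_X.shape[1] == 0:
            raise ValueError("seq_X must be (n, T >= 1, n_time)")
        logits = self._unroll(np.asarray(static_X, dtype=float), seq_X,
                              [None] * seq_X.shape[1])
        return np.column_stack([_sigmoid(z.value[:, 0]) for z in logits])

    # -- weight snapshots --------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.value.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].value = np.array(v, dtype=float)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


@dataclass
class TrainedModel:
    net: ConversionNet
    selected_epoch: int
    history: pd.DataFrame  # epoch, loss, val_auc
    training: TrainingConfig
    feature_names: list[str]

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights as .npz plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.net.get_weights())
        cfg = dict(
            n_static=self.net.n_static, n_time=self.net.n_time,
            hidden_size=self.net.hidden_size, seed=self.net.seed,
            encoder_hidden=list(self.net.encoder_cfg.hidden),
            selected_epoch=self.selected_epoch,
            training=asdict(self.training),
            feature_names=self.feature_names,
        )
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(cfg, indent=1))
        self.history.to_csv(path.with_suffix(path.suffix + ".history.csv"),
                            index=False)


def design_matrices(table: CohortTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Model inputs from a preprocessed cohort table.

    Returns ``(ids, static_X, seq_X, static_names)`` with patients in
    sorted-id order.  Static features: continuous and binary columns as-is,
    intervention arm one-hot, diagnosis as an AD indicator.  ``seq_X`` holds
    the time-dependent scales at the input visits (months 0 and 3); the
    6-month visit is the outcome, never an input.
    """
    stat = table.static_frame().sort_values("id").reset_index(drop=True)
    ids = stat["id"].to_numpy()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in table.schema.static:
        if f.kind == "categorical":
            levels = ARMS if f.name == "arm" else sorted(stat[f.name].dropna().unique())
            for lev in levels:
                cols.append((stat[f.name] == lev).to_numpy(dtype=float))
                names.append(f"{f.name}={lev}")
        else:
            cols.append(stat[f.name].to_numpy(dtype=float))
            names.append(f.name)
    cols.append((stat["diagnosis"] == "AD").to_numpy(dtype=float))
    names.append("diagnosis=AD")
    static_X = np.column_stack(cols)

    input_months = [m for m in table.schema.months[:-1]]
    seq = np.stack(
        [np.column_stack([table.visit_values(f).loc[ids, m].to_numpy(dtype=float)
                          for f in table.schema.time_names])
         for m in input_months], axis=1)
    return ids, static_X, seq, names


def aligned_labels(labels: pd.DataFrame, ids: np.ndarray, month: int) -> np.ndarray:
    """0/1 outcome vector (1 = CI) aligned to ``ids``; NaN where omitted."""
    sub = labels[labels["month"] == month].set_index("id")["label"]
    return np.array([
        (1.0 if sub[pid] == "CI" else 0.0) if pid in sub.index else np.nan
        for pid in ids])


def train_model(
    static_X: np.ndarray,
    seq_X: np.ndarray,
    y3: np.ndarray,
    y6: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
    val_mask: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Train the hybrid network and return the epoch-selected model.

    ``val_mask`` marks the rows held out for epoch selection; when None, a
    stratified (by 6-month label) fraction ``cfg.val_fraction`` is split
    off with the config seed.  Training is full-batch: the configured
    batch size exceeds any realistic cohort.
    """
    static_X = np.asarray(static_X, dtype=float)
    seq_X = np.asarray(seq_X, dtype=float)
    y3 = np.asarray(y3, dtype=float)
    y6 = np.asarray(y6, dtype=float)
    n = static_X.shape[0]
    if val_mask is None:
        idx = np.arange(n)
        _, val_idx = train_test_split(
            idx, test_size=cfg.val_fraction, stratify=y6,
            random_state=cfg.seed % (2**31))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
    tr = ~val_mask
    for name, y in (("3-month", y3[tr]), ("6-month", y6[tr])):
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"single-class {name} training labels: AUC-based epoch "
                "selection is undefined")
    if len(np.unique(y6[val_mask])) < 2:
        raise ValueError("single-class 6-month validation labels")

    net = ConversionNet(static_X.shape[1], seq_X.shape[2],
                        encoder=cfg.encoder, hidden_size=cfg.hidden_size,
                        seed=cfg.seed)
    net.teacher_signal_infer = cfg.teacher_signal
    params = list(net.params.values())
    opt = Adam(params, lr=cfg.learning_rate)

    y3c = y3[tr][:, None]
    y6c = y6[tr][:, None]
    # teacher forcing feeds the true 3-month outcome into the 6-month step
    # during training; at inference the model's own prediction is fed back
    prev = [None, y3c] if cfg.teacher_forcing else [None, None]

    best_auc, best_epoch, best_weights = -np.inf, 1, net.get_weights()
    hist = []
    lr = cfg.learning_rate
    for epoch in range(1, cfg.epochs + 1):
        if epoch in cfg.lr_decay_epochs:
            lr *= cfg.lr_decay_factor
        opt.lr = lr
        opt.zero_grad()
        logits = net._unroll(static_X[tr], seq_X[tr], prev)
        loss = _bce_with_logits(logits[0], y3c) + _bce_with_logits(logits[1], y6c)
        loss.backward()
        opt.step()

        p_val = net.predict(static_X[val_mask], seq_X[val_mask])
        val_auc = roc_auc_score(y6[val_mask], p_val[:, -1])
        hist.append((epoch, float(loss.value), float(val_auc)))
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_weights = net.get_weights()

    net.set_weights(best_weights)
    history = pd.DataFrame(hist, columns=["epoch", "loss", "val_auc"])
    return TrainedModel(net=net, selected_epoch=best_epoch, history=history,
                        training=cfg,
                        feature_names=feature_names or [])


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    # mean over patients of softplus(z) - y*z, the stable form of
    # -[y log p + (1-y) log(1-p)] with p = sigmoid(z)
    return (z.softplus() - Tensor(y) * z).mean()
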