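"""One client's personalized local training round.

A client holds a private shard, a private classifier head and a local
copy of the global adapters. Local training minimizes a class-aware
focal loss over weighted-random-sampled mini-batches; gradients flow
only into the adapters and the head (the backbone stays frozen), and the
only thing a client ever emits is the adapter delta plus scalar logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import Backbone
from .lora import (AdapterState, DeltaUpdate, adapter_parameters,
                   extract_delta, get_adapter_state, set_adapter_state)

EPS_PROB = 1e-8


# ---------------------------------------------------------------------------
# Sampling weights (inverse class frequency)
# ---------------------------------------------------------------------------

def compute_sampling_weights(labels) -> np.ndarray:
    """Per-sample probabilities proportional to 1 / class frequency,
    normalized to sum 1; the expected sampled class mix is uniform over
    the classes present in the shard."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("shard is empty")
    classes, counts = np.unique(labels, return_counts=True)
    freq = dict(zip(classes.tolist(), counts.tolist()))
    w = np.array([1.0 / freq[y] for y in labels.tolist()])
    w /= len(classes)  # sum_j 1/f_{y_j} = (#classes); exact normalization
    assert abs(w.sum() - 1.0) < 1e-9
    return w


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalLossParams:
    """gamma focuses on hard samples; alpha balances class frequency.
    gamma=0, alpha=1 recovers plain cross-entropy."""

    gamma: float = 2.0
    alpha: float = 0.25
    class_weights: tuple[float, ...] | None = None  # optional per-class hook

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")

    def weight_for(self, y: np.ndarray) -> np.ndarray:
        if self.class_weights is None:
            return np.full(len(y), self.alpha)
        return self.alpha * np.asarray(self.class_weights)[y]


def focal_loss(p_true, params: FocalLossParams = FocalLossParams()) -> float:
    """Mean of -alpha * (1 - p)^gamma * log(p) over true-class probabilities."""
    p = np.atleast_1d(np.asarray(p_true, dtype=np.float64))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, EPS_PROB, 1.0)
    return float(np.mean(params.alpha * (1.0 - p) ** params.gamma * (-np.log(p))))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_and_grad(logits: np.ndarray, y: np.ndarray,
                        params: FocalLossParams):
    """Batch focal loss and its gradient with respect to the logits.

    With p = softmax(z) and p_t the true-class probability,
    dL/dp_t = alpha * [gamma (1-p_t)^{gamma-1} log p_t - (1-p_t)^gamma / p_t]
    and dL/dz follows from the softmax Jacobian.
    """
    n = len(y)
    p = softmax(logits.astype(np.float64))
    pt = np.clip(p[np.arange(n), y], EPS_PROB, 1.0)
    a = params.weight_for(y)
    one_m = 1.0 - pt
    loss = float(np.mean(a * one_m**params.gamma * (-np.log(pt))))
    g = params.gamma
    dl_dpt = a * (g * np.where(one_m > 0, one_m, 1.0) ** (g - 1.0)
                  * np.log(pt) * (one_m > 0) - one_m**g / pt)
    # softmax jacobian: dp_t/dz_j = p_t (1{j=t} - p_j)
    dz = dl_dpt[:, None] * pt[:, None] * (-p)
    dz[np.arange(n), y] += dl_dpt * pt
    return loss, (dz / n).astype(np.float32), p.astype(np.float32)


# ---------------------------------------------------------------------------
# Adam (client-side optimizer)
# ---------------------------------------------------------------------------

class Adam:
    """Standard bias-corrected Adam over a list of named Parameters."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for _, p in self.params]
        self.v = [np.zeros_like(p.data) for _, p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (_, p) in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------------
# Client state and local training
# ---------------------------------------------------------------------------

@dataclass
class TrainLog:
    losses: list[float] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)
    steps: int = 0


@dataclass
class ClientState:
    """Private per-client state; the head never leaves this object."""

    client_id: int
    x_train: np.ndarray  # normalized NCHW float32
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    head_weight: np.ndarray | None = None
    head_bias: np.ndarray | None = None
    adam_state: Adam | None = None
    sampler_weights: np.ndarray = None
    lr: float = 1e-4
    batch_size: int = 32
    focal: FocalLossParams = field(default_factory=FocalLossParams)

    def __post_init__(self):
        if self.sampler_weights is None:
            self.sampler_weights = compute_sampling_weights(self.y_train)


def _install_head(model: Backbone, client: ClientState,
                  rng: np.random.Generator) -> None:
    if client.head_weight is None:
        head = nn.Linear(model.feature_dim, model.num_classes, rng=rng)
        client.head_weight = head.weight.data.copy()
        client.head_bias = head.bias.data.copy()
    model.classifier.weight.data = client.head_weight.copy()
    model.classifier.bias.data = client.head_bias.copy()


def _store_head(model: Backbone, client: ClientState) -> None:
    client.head_weight = model.classifier.weight.data.copy()
    client.head_bias = model.classifier.bias.data.copy()


def personalized_forward(client: ClientState, model: Backbone,
                         x: np.ndarray) -> np.ndarray:
    """Class probabilities from the shared frozen backbone + the client's
    adapters-as-loaded + its private head."""
    if x.shape[2] != model.resolution or x.shape[3] != model.resolution:
        raise ValueError(
            f"expected {model.resolution}x{model.resolution} input, got {x.shape[2:]}")
    _install_head(model, client, np.random.default_rng(client.client_id))
    model.eval()
    return softmax(model(x))


def local_train(client: ClientState, model: Backbone,
                global_adapters: AdapterState, epochs: int = 1,
                seed: int = 0) -> tuple[DeltaUpdate, TrainLog]:
    """Run ``epochs`` of weighted-sampled mini-batch focal-loss training on
    the client's shard, updating only adapters and the private head, and
    return the adapter delta against the received global state."""
    set_adapter_state(model, global_adapters)
    rng = np.random.default_rng(seed)
    _install_head(model, client, rng)
    log = TrainLog()
    trainables = list(adapter_parameters(model)) + list(model.head_parameters())
    opt = Adam(trainables, lr=client.lr)
    n = len(client.y_train)
    n_batches = max(1, int(np.ceil(n / client.batch_size)))
    for _ in range(epochs):
        model.train()
        ep_loss, ep_correct, ep_seen = 0.0, 0, 0
        for _b in range(n_batches):
            idx = rng.choice(n, size=min(client.batch_size, n),
                             replace=True, p=client.sampler_weights)
            xb = client.x_train[idx]
            yb = client.y_train[idx]
            logits = model(xb)
            loss, dz, probs = focal_loss_and_grad(logits, yb, client.focal)
            model.zero_grad()
            model.backward(dz)
            opt.step()
            opt.zero_grad()
            ep_loss += loss * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            ep_seen += len(yb)
            log.steps += 1
        log.losses.append(ep_loss / ep_seen)
        log.accuracies.append(ep_correct / ep_seen)
    model.eval()
    _store_head(model, client)
    local_state = get_adapter_state(model, global_adapters.round_tag)
    delta = extract_delta(local_state, global_adapters, client.client_id)
    return delta, log


def evaluate_client(client: ClientState, model: Backbone,
                    global_adapters: AdapterState,
                    batch_size: int = 64):
    """Loss/accuracy plus raw predictions of the personalized model
    (global adapters + private head) on the client's validation shard."""
    set_adapter_state(model, global_adapters)
    probs = []
    for s in range(0, len(client.y_val), batch_size):
        probs.append(personalized_forward(client, model, client.x_val[s:s + batch_size]))
    probs = np.concatenate(probs)
    pt = np.clip(probs[np.arange(len(client.y_val)), client.y_val], EPS_PROB, 1.0)
    loss = focal_loss(pt, client.focal)
    pred = probs.argmax(axis=1)
    acc = float((pred == client.y_val).mean())
    return {"loss": loss, "accuracy": acc, "y_true": client.y_val,
            "y_pred": pred, "scores": probs}


def centralized_train(model: Backbone, x: np.ndarray, y: np.ndarray,
                      epochs: int = 5, lr: float = 1e-3, batch_size: int = 32,
                      focal: FocalLossParams | None = None, seed: int = 0,
                      train_adapters: bool = True) -> TrainLog:
    """Plain (non-federated) training of adapters and head on pooled data;
    used as a centralized baseline and for separability calibration."""
    rng = np.random.default_rng(seed)
    focal = focal or FocalLossParams(gamma=0.0, alpha=1.0)
    trainables = list(model.head_parameters())
    if train_adapters:
        trainables = list(adapter_parameters(model)) + trainables
    opt = Adam(trainables, lr=lr)
    log = TrainLog()
    n = len(y)
    for _ in range(epochs):
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            logits = model(x[idx])
            loss, dz, probs = focal_loss_and_grad(logits, y[idx], focal)
            model.zero_grad()
            model.backward(dz)
            opt.step()
            opt.zero_grad()
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(axis=1) == y[idx]).sum())
            log.steps += 1
        log.losses.append(ep_loss / n)
        log.accuracies.append(ep_correct / n)
    model.eval()
    return log
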