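"""Federated orchestration: broadcast adapters, collect deltas, FedAdam.

Each round the server broadcasts the global adapter state, every selected
client trains locally (adapters + private head) and uploads only its
adapter delta, and the server folds the weighted mean delta into the
global state with a server-side adaptive step,

    g_t = -mean_delta
    m_t = beta1 m_{t-1} + (1 - beta1) g_t
    v_t = beta2 v_{t-1} + (1 - beta2) g_t^2
    theta_{t+1} = theta_t - eta * m_t / sqrt(v_t + eps)

(no bias correction), so the update moves the global adapters toward the
client consensus. Communication is accounted per round in MiB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .backbone import Backbone, build_backbone, calibrate_batchnorm
from .client import (ClientState, FocalLossParams, evaluate_client,
                     local_train)
from .lora import (AdapterState, DeltaUpdate, IncompatibleStateError,
                   LoRAConfig, inject_lora, payload_megabytes)
from .metrics import MetricsReport, classification_metrics, confusion_matrix
from .partition import SplitSpec, dirichlet_partition, stratified_split
from .synthetic import (apply_stain_shift, client_stain_shifts,
                        normalization_stats, to_model_input)

NOT_CONVERGED = -1


@dataclass
class ServerState:
    """Global adapters plus FedAdam moment estimates (zero-initialized)."""

    adapters: AdapterState
    lr: float = 0.01
    eps: float = 1e-8
    round: int = 0
    m: dict | None = None
    v: dict | None = None

    def __post_init__(self):
        if self.m is None:
            self.m = {k: (np.zeros_like(a), np.zeros_like(b))
                      for k, (a, b) in self.adapters.tensors.items()}
        if self.v is None:
            self.v = {k: (np.zeros_like(a), np.zeros_like(b))
                      for k, (a, b) in self.adapters.tensors.items()}


@dataclass(frozen=True)
class FederationConfig:
    """One federated experiment; defaults follow the reference setup
    (10 clients, 20 rounds, E=1, Dirichlet alpha 0.7, FedAdam lr 0.01,
    LoRA r=16/alpha=32/dropout=0.1, focal gamma=2 alpha=0.25, batch 32)."""

    variant: str = "b0"
    num_classes: int = 4
    n_clients: int = 10
    rounds: int = 20
    local_epochs: int = 1
    client_fraction: float = 1.0
    client_lr: float = 1e-4
    batch_size: int = 32
    server_lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.99
    server_eps: float = 1e-8
    dirichlet_alpha: float = 0.7
    min_client_size: int = 20
    client_val_fraction: float = 0.1
    lora: LoRAConfig = field(default_factory=LoRAConfig)
    focal: FocalLossParams = field(default_factory=FocalLossParams)
    split: SplitSpec = field(default_factory=SplitSpec)
    stain_shift: float = 10.0
    weight_by_samples: bool = False
    loss_threshold: float | None = None
    target_accuracy: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 < self.client_fraction <= 1:
            raise ValueError("client_fraction must be in (0, 1]")


@dataclass
class FederationResult:
    """Run history: per-round, per-client validation metrics, communication
    log, convergence round and final per-client reports."""

    config: FederationConfig
    history: pd.DataFrame
    communication: pd.DataFrame
    converged_round: int
    final_reports: dict[int, MetricsReport]
    server: ServerState

    def mean_accuracy_by_round(self) -> pd.Series:
        return self.history.groupby("round")["accuracy"].mean()

    def summary(self) -> str:
        acc = self.mean_accuracy_by_round()
        lines = [
            "Federated run summary",
            "=====================",
            f"variant={self.config.variant}  clients={self.config.n_clients}  "
            f"rounds={self.config.rounds}  lora_rank={self.config.lora.rank}",
            f"adapter payload per client: "
            f"{payload_megabytes(self.server.adapters)} MB",
            f"mean personalized val accuracy: round 1 = {acc.iloc[0]:.3f}, "
            f"round {acc.index[-1]} = {acc.iloc[-1]:.3f}",
            f"converged at round: "
            f"{self.converged_round if self.converged_round != NOT_CONVERGED else 'not converged'}",
            f"total uplink: {self.communication['uplink_mb'].sum():.2f} MB, "
            f"total downlink: {self.communication['downlink_mb'].sum():.2f} MB",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_deltas(deltas: list[DeltaUpdate],
                     weights: np.ndarray | None = None) -> DeltaUpdate:
    """Elementwise weighted mean of client deltas (uniform by default)."""
    if not deltas:
        raise ValueError("need at least one delta")
    keys = list(deltas[0].tensors)
    for d in deltas[1:]:
        if list(d.tensors) != keys:
            raise IncompatibleStateError("delta key sets differ")
    if weights is None:
        weights = np.full(len(deltas), 1.0 / len(deltas))
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be non-negative and sum to 1")
    out = {}
    for k in keys:
        a = sum(w * d.tensors[k][0].astype(np.float64) for w, d in zip(weights, deltas))
        b = sum(w * d.tensors[k][1].astype(np.float64) for w, d in zip(weights, deltas))
        sa, sb = deltas[0].tensors[k]
        if a.shape != sa.shape or b.shape != sb.shape:
            raise IncompatibleStateError(f"delta shape mismatch at {k!r}")
        out[k] = (a.astype(sa.dtype), b.astype(sb.dtype))
    return DeltaUpdate(out, client_id=-1, round_tag=deltas[0].round_tag)


def fedadam_step(state: ServerState, mean_delta: DeltaUpdate,
                 beta1: float = 0.9, beta2: float = 0.99) -> ServerState:
    """One server update with the negated mean delta as pseudo-gradient."""
    if not 0 <= beta1 < 1 or not 0 <= beta2 < 1:
        raise ValueError("beta1, beta2 must be in [0, 1)")
    for k in state.adapters.tensors:
        for i in range(2):
            g = -np.asarray(mean_delta.tensors[k][i], dtype=np.float64)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite delta entries at {k!r}")
            m = beta1 * state.m[k][i] + (1 - beta1) * g
            v = beta2 * state.v[k][i] + (1 - beta2) * g**2
            theta = state.adapters.tensors[k][i] - state.lr * m / np.sqrt(v + state.eps)
            if i == 0:
                state.m[k] = (m, state.m[k][1])
                state.v[k] = (v, state.v[k][1])
                state.adapters.tensors[k] = (theta.astype(np.float32),
                                             state.adapters.tensors[k][1])
            else:
                state.m[k] = (state.m[k][0], m)
                state.v[k] = (state.v[k][0], v)
                state.adapters.tensors[k] = (state.adapters.tensors[k][0],
                                             theta.astype(np.float32))
    state.round += 1
    state.adapters.round_tag = state.round
    return state


def communication_cost_per_round(model_size_mb: float,
                                 clients_per_round: int) -> float:
    """2 x model size x clients per round (down- plus uplink)."""
    if model_size_mb < 0 or clients_per_round < 0:
        raise ValueError("inputs must be non-negative")
    return 2.0 * model_size_mb * clients_per_round


def rounds_to_convergence(history, loss_threshold: float | None = None,
                          target_accuracy: float | None = None) -> int:
    """Smallest 1-based round meeting either criterion, else a sentinel.

    ``history`` is a sequence of (loss, accuracy) per round, or the
    history DataFrame from a run (averaged per round).
    """
    if loss_threshold is None and target_accuracy is None:
        raise ValueError("at least one convergence criterion is required")
    if isinstance(history, pd.DataFrame):
        grouped = history.groupby("round")[["loss", "accuracy"]].mean()
        pairs = list(zip(grouped["loss"], grouped["accuracy"]))
    else:
        pairs = list(history)
    if not pairs:
        raise ValueError("history is empty")
    for r, (loss, acc) in enumerate(pairs, start=1):
        if loss_threshold is not None and loss <= loss_threshold:
            return r
        if target_accuracy is not None and acc >= target_accuracy:
            return r
    return NOT_CONVERGED


# ---------------------------------------------------------------------------
# Full federation
# ---------------------------------------------------------------------------

def run_federation(cfg: FederationConfig, images: np.ndarray,
                   labels: np.ndarray) -> FederationResult:
    """Partition the data, build the frozen backbone + adapters, and run
    the full round loop; returns the complete run history."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(2**31, size=6)

    # splits: global train/test, per-client Dirichlet shards, local val carve
    train_idx, val_idx, test_idx = stratified_split(
        labels, replace(cfg.split, seed=int(seeds[0])))
    pool_idx = np.sort(np.concatenate([train_idx, val_idx]))
    plan = dirichlet_partition(labels[pool_idx], cfg.n_clients,
                               cfg.dirichlet_alpha, seed=int(seeds[1]),
                               min_size=cfg.min_client_size)

    mean, std = normalization_stats(images[pool_idx])
    shifts = client_stain_shifts(cfg.n_clients, cfg.stain_shift, int(seeds[2]))

    model = build_backbone(cfg.variant, cfg.num_classes, seed=int(seeds[3]))
    # the frozen backbone ships with normalization statistics matched to its
    # activations; emulate that with one calibration pass before federation
    calib = master.choice(pool_idx, size=min(64, len(pool_idx)), replace=False)
    calibrate_batchnorm(model, to_model_input(images[calib], mean, std))
    global_state = inject_lora(model, cfg.lora, seed=int(seeds[4]))
    server = ServerState(global_state, lr=cfg.server_lr, eps=cfg.server_eps)

    clients: list[ClientState] = []
    client_rng = np.random.default_rng(int(seeds[5]))
    for k in range(cfg.n_clients):
        shard = pool_idx[plan.client(k)]
        shard_labels = labels[shard]
        tr, va, _ = stratified_split(
            shard_labels,
            SplitSpec(1.0 - cfg.client_val_fraction - 1e-6, cfg.client_val_fraction,
                      1e-6, seed=int(client_rng.integers(2**31)), stratified=False))
        shard_images = apply_stain_shift(images[shard], shifts[k])
        x = to_model_input(shard_images, mean, std)
        clients.append(ClientState(
            client_id=k, x_train=x[tr], y_train=shard_labels[tr],
            x_val=x[va], y_val=shard_labels[va],
            lr=cfg.client_lr, batch_size=cfg.batch_size, focal=cfg.focal))

    hist_rows, comm_rows = [], []
    round_rng = np.random.default_rng(int(master.integers(2**31)))
    n_selected = max(1, int(round(cfg.client_fraction * cfg.n_clients)))
    payload_mb = payload_megabytes(server.adapters)
    final_preds: dict[int, dict] = {}
    for t in range(1, cfg.rounds + 1):
        selected = sorted(round_rng.choice(cfg.n_clients, size=n_selected,
                                           replace=False).tolist())
        broadcast = server.adapters.copy()
        deltas, sizes = [], []
        for k in selected:
            delta, _log = local_train(
                clients[k], model, broadcast, epochs=cfg.local_epochs,
                seed=int(round_rng.integers(2**31)))
            _audit_wire(delta, broadcast)
            deltas.append(delta)
            sizes.append(len(clients[k].y_train))
        weights = None
        if cfg.weight_by_samples:
            weights = np.asarray(sizes, dtype=float)
            weights /= weights.sum()
        mean_delta = aggregate_deltas(deltas, weights)
        server = fedadam_step(server, mean_delta, cfg.beta1, cfg.beta2)

        uplink = sum(payload_megabytes(d) for d in deltas)
        comm_rows.append({"round": t, "uplink_mb": uplink,
                          "downlink_mb": payload_mb * len(selected),
                          "clients": len(selected)})
        for k in range(cfg.n_clients):
            ev = evaluate_client(clients[k], model, server.adapters)
            hist_rows.append({"round": t, "client": k, "loss": ev["loss"],
                              "accuracy": ev["accuracy"],
                              "n_val": len(clients[k].y_val)})
            if t == cfg.rounds:
                final_preds[k] = ev

    history = pd.DataFrame(hist_rows)
    communication = pd.DataFrame(comm_rows)
    if cfg.loss_threshold is not None or cfg.target_accuracy is not None:
        converged = rounds_to_convergence(history, cfg.loss_threshold,
                                          cfg.target_accuracy)
    else:
        converged = NOT_CONVERGED
    reports = {
        k: classification_metrics(confusion_matrix(
            ev["y_true"], ev["y_pred"], cfg.num_classes))
        for k, ev in final_preds.items()
    }
    return FederationResult(cfg, history, communication, converged, reports, server)


def _audit_wire(delta: DeltaUpdate, reference: AdapterState) -> None:
    """Wire-minimality check: a client message carries exactly the adapter
    key set (no head, no backbone arrays)."""
    if list(delta.tensors) != list(reference.tensors):
        raise IncompatibleStateError(
            "client payload does not match the adapter schema")
    for k, (a, b) in delta.tensors.items():
        ra, rb = reference.tensors[k]
        if a.shape != ra.shape or b.shape != rb.shape:
            raise IncompatibleStateError(f"unexpected payload shape at {k!r}")
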