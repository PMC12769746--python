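"""Low-rank adapters (LoRA) on group-1 convolutions of a frozen backbone.

A targeted convolution with flattened kernel W in R^{d x k}
(d = out-channels, k = in-channels * kH * kW) gains a trainable pair
A in R^{d x r}, B in R^{r x k}; the adapted layer computes

    y = conv(W, x) + (alpha / r) * conv(reshape(A @ B), dropout(x))

with W frozen. A is Gaussian-initialized and B starts at zero, so a
freshly injected model is exactly the frozen model. Only the A/B pairs
(and their deltas) ever leave a client.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import nn
from .backbone import Backbone, LayerInventoryEntry, layer_inventory

BYTES_PER_PARAM_ALLOWED = (2, 4, 8)


@dataclass(frozen=True)
class LoRAConfig:
    """Adapter hyper-parameters; ``alpha / rank`` scales the A@B branch."""

    rank: int = 16
    alpha: float = 32.0
    dropout: float = 0.1
    # predicate over inventory entries; default: every groups==1 convolution
    target_rule: Callable[[LayerInventoryEntry], bool] | None = None

    def __post_init__(self):
        if self.rank <= 0:
            raise ValueError("rank must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def scaling(self) -> float:
        return self.alpha / self.rank

    def targets(self, entries: list[LayerInventoryEntry]) -> list[LayerInventoryEntry]:
        rule = self.target_rule or default_target_rule
        return [e for e in entries if rule(e)]

    def fingerprint(self) -> str:
        return hashlib.sha256(
            f"r={self.rank},a={self.alpha},p={self.dropout}".encode()).hexdigest()[:12]


def default_target_rule(entry: LayerInventoryEntry) -> bool:
    """Every convolution with channel-groups 1 (stem, expand, SE, project,
    head-conv); depthwise convolutions and the classifier are excluded."""
    return entry.groups == 1 and entry.role != "classifier"


class LoRAAdapter(nn.Module):
    """The A/B pair attached to one convolution."""

    def __init__(self, d: int, k: int, cfg: LoRAConfig, rng: np.random.Generator):
        super().__init__()
        self.d, self.k, self.rank = d, k, cfg.rank
        self.scaling = cfg.scaling
        self.p = cfg.dropout
        self.A = nn.Parameter(rng.standard_normal((d, cfg.rank)) * 0.02)
        self.B = nn.Parameter(np.zeros((cfg.rank, k)))
        self.rng = np.random.default_rng(rng.integers(2**31))

    @property
    def parameter_count(self) -> int:
        return self.rank * (self.d + self.k)

    def delta_weight(self) -> np.ndarray:
        """scaling * A @ B, in flattened-kernel coordinates (d x k)."""
        return (self.scaling * (self.A.data @ self.B.data)).astype(nn.DTYPE)

    # called from Conv2d.forward with the im2col'd input (N, k, L)
    def forward(self, flat_cols: np.ndarray, training: bool):
        if training and self.p > 0.0:
            mask = (self.rng.random(flat_cols.shape, dtype=np.float32) >= self.p).astype(nn.DTYPE) / (1.0 - self.p)
            dropped = flat_cols * mask
        else:
            mask = None
            dropped = flat_cols
        mid = np.matmul(self.B.data, dropped)          # (N, r, L)
        y = self.scaling * np.matmul(self.A.data, mid)  # (N, d, L)
        cache = (dropped, mid, mask) if training else None
        return y, cache

    def backward(self, dy_flat: np.ndarray, cache):
        dropped, mid, mask = cache
        self.A.add_grad(self.scaling * np.einsum("nol,nrl->or", dy_flat, mid, optimize=True))
        dmid = self.scaling * np.einsum("or,nol->nrl", self.A.data, dy_flat, optimize=True)
        self.B.add_grad(np.einsum("nrl,nkl->rk", dmid, dropped, optimize=True))
        dcols = np.einsum("rk,nrl->nkl", self.B.data, dmid, optimize=True)
        if mask is not None:
            dcols = dcols * mask
        return dcols


@dataclass
class AdapterState:
    """Ordered map layer-name -> (A, B) with the shared scaling; the only
    state the federation ever communicates."""

    tensors: dict[str, tuple[np.ndarray, np.ndarray]]
    scaling: float
    round_tag: int = 0
    config_fingerprint: str = ""

    def copy(self) -> "AdapterState":
        return AdapterState(
            {k: (a.copy(), b.copy()) for k, (a, b) in self.tensors.items()},
            self.scaling, self.round_tag, self.config_fingerprint)

    def parameter_count(self) -> int:
        return sum(a.size + b.size for a, b in self.tensors.values())

    def keys(self):
        return self.tensors.keys()

    def check_compatible(self, other: "AdapterState") -> None:
        if list(self.tensors) != list(other.tensors):
            raise IncompatibleStateError("adapter key sets differ")
        for k, (a, b) in self.tensors.items():
            oa, ob = other.tensors[k]
            if a.shape != oa.shape or b.shape != ob.shape:
                raise IncompatibleStateError(f"shape mismatch at layer {k!r}")


@dataclass
class DeltaUpdate:
    """Per-layer (dA, dB) arrays computed against a reference AdapterState."""

    tensors: dict[str, tuple[np.ndarray, np.ndarray]]
    client_id: int = -1
    round_tag: int = 0

    def parameter_count(self) -> int:
        return sum(a.size + b.size for a, b in self.tensors.values())


class IncompatibleStateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Injection and state movement
# ---------------------------------------------------------------------------

def inject_lora(model: Backbone, cfg: LoRAConfig, seed: int = 0) -> AdapterState:
    """Attach adapters to every targeted convolution (in inventory order)
    and return the initial AdapterState.

    The backbone must already be frozen; adapter parameters are trainable.
    A rank at or above min(d, k) for some small layer (the SE reductions,
    at rank 16) makes the low-rank factorization overcomplete there; this
    is allowed — uniform rank matches the reference accounting — but warned
    about once per injection.
    """
    rng = np.random.default_rng(seed)
    entries = layer_inventory(model)
    targets = cfg.targets(entries)
    if not targets:
        raise ValueError("target rule selected no layers")
    mods = dict(model.named_modules())
    overcomplete = []
    tensors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for e in targets:
        conv = mods[e.name]
        if not isinstance(conv, nn.Conv2d) or conv.groups != 1:
            raise ValueError(f"layer {e.name!r} is not a group-1 convolution")
        d, k = conv.fan_out, conv.fan_in
        if cfg.rank >= min(d, k):
            overcomplete.append(e.name)
        adapter = LoRAAdapter(d, k, cfg, rng)
        conv.adapter = adapter
        tensors[e.name] = (adapter.A.data.copy(), adapter.B.data.copy())
    if overcomplete:
        warnings.warn(
            f"rank {cfg.rank} >= min(d, k) for {len(overcomplete)} layer(s) "
            f"(e.g. {overcomplete[0]}): the factorization is overcomplete there",
            stacklevel=2)
    return AdapterState(tensors, cfg.scaling, 0, cfg.fingerprint())


def get_adapter_state(model: Backbone, round_tag: int = 0) -> AdapterState:
    tensors = {}
    scaling = 1.0
    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv2d) and mod.adapter is not None:
            tensors[name] = (mod.adapter.A.data.copy(), mod.adapter.B.data.copy())
            scaling = mod.adapter.scaling
    return AdapterState(tensors, scaling, round_tag)


def set_adapter_state(model: Backbone, state: AdapterState) -> None:
    mods = dict(model.named_modules())
    for name, (a, b) in state.tensors.items():
        conv = mods.get(name)
        if conv is None or not isinstance(conv, nn.Conv2d) or conv.adapter is None:
            raise IncompatibleStateError(f"model has no adapter at layer {name!r}")
        if conv.adapter.A.data.shape != a.shape or conv.adapter.B.data.shape != b.shape:
            raise IncompatibleStateError(f"shape mismatch at layer {name!r}")
        conv.adapter.A.data = a.copy()
        conv.adapter.B.data = b.copy()


def adapter_parameters(model: Backbone):
    """Named trainable adapter parameters, in inventory order."""
    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv2d) and mod.adapter is not None:
            yield f"{name}.adapter.A", mod.adapter.A
            yield f"{name}.adapter.B", mod.adapter.B


# ---------------------------------------------------------------------------
# Deltas, payloads, merging
# ---------------------------------------------------------------------------

def extract_delta(local: AdapterState, global_ref: AdapterState,
                  client_id: int = -1) -> DeltaUpdate:
    """Elementwise local - global per layer (the uplink payload)."""
    local.check_compatible(global_ref)
    tensors = {
        k: (local.tensors[k][0] - global_ref.tensors[k][0],
            local.tensors[k][1] - global_ref.tensors[k][1])
        for k in local.tensors
    }
    return DeltaUpdate(tensors, client_id, global_ref.round_tag)


def apply_delta(state: AdapterState, delta: DeltaUpdate) -> AdapterState:
    out = state.copy()
    for k, (da, db) in delta.tensors.items():
        a, b = out.tensors[k]
        out.tensors[k] = (a + da, b + db)
    return out


def payload_megabytes(state_or_delta, bytes_per_param: int = 4) -> float:
    """Wire size in MiB (2^20 bytes), rounded to 2 decimals."""
    if bytes_per_param not in BYTES_PER_PARAM_ALLOWED:
        raise ValueError(f"bytes_per_param must be one of {BYTES_PER_PARAM_ALLOWED}")
    if isinstance(state_or_delta, (AdapterState, DeltaUpdate)):
        n = state_or_delta.parameter_count()
    else:
        n = int(state_or_delta)  # raw parameter count
    return round(n * bytes_per_param / 2**20, 2)


def merge_adapters(model: Backbone, state: AdapterState | None = None) -> Backbone:
    """Fold scaling * A @ B into each frozen kernel (deployment form) and
    strip the adapters. Merging an already-merged model is an error."""
    if getattr(model, "_lora_merged", False):
        raise IncompatibleStateError("model adapters were already merged")
    if state is not None:
        set_adapter_state(model, state)
    merged_any = False
    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv2d) and mod.adapter is not None:
            dw = mod.adapter.delta_weight().reshape(mod.weight.data.shape)
            mod.weight.data = mod.weight.data + dw
            mod.adapter = None
            merged_any = True
    if not merged_any:
        raise IncompatibleStateError("model carries no adapters to merge")
    model._lora_merged = True
    return model


# ---------------------------------------------------------------------------
# Wire format
# ---------------------------------------------------------------------------

def save_delta(delta: DeltaUpdate, path, bytes_per_param: int = 4) -> None:
    """npz container: JSON header + ordered (dA, dB) arrays; bit-exact."""
    header = {
        "client_id": delta.client_id,
        "round": delta.round_tag,
        "bytes_per_param": bytes_per_param,
        "layers": list(delta.tensors),
    }
    arrays = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, (k, (a, b)) in enumerate(delta.tensors.items()):
        arrays[f"{i:04d}/A"] = a
        arrays[f"{i:04d}/B"] = b
    np.savez(path, **arrays)


def load_delta(path) -> DeltaUpdate:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        tensors = {
            k: (z[f"{i:04d}/A"].copy(), z[f"{i:04d}/B"].copy())
            for i, k in enumerate(header["layers"])
        }
    return DeltaUpdate(tensors, header["client_id"], header["round"])
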