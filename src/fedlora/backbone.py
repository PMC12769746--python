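"""EfficientNet-style backbones built from an explicit MBConv stage plan.

The B0 and B2 variants follow the published EfficientNet stage plans
(mobile inverted bottleneck blocks with squeeze-and-excite ratio 0.25,
SiLU activations, batch normalization, channel rounding to multiples of 8
and ceil-rounded repeats).  A reduced ``s0`` variant built by the same
machinery is provided for desk-scale federated simulations.  Backbones
are frozen by default except for the affine classifier head, matching a
personalization setup where only adapters and the private head train.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn

VARIANTS = ("b0", "b2", "s0")

#: base (B0) stage plan: expansion, kernel, stride, in_ch, out_ch, repeats
_B0_PLAN = [
    (1, 3, 1, 32, 16, 1),
    (6, 3, 2, 16, 24, 2),
    (6, 5, 2, 24, 40, 2),
    (6, 3, 2, 40, 80, 3),
    (6, 5, 1, 80, 112, 3),
    (6, 5, 2, 112, 192, 4),
    (6, 3, 1, 192, 320, 1),
]

#: per-variant (width multiplier, depth multiplier, input resolution)
_VARIANT_TABLE = {"b0": (1.0, 1.0, 224), "b2": (1.1, 1.2, 260)}

#: reduced simulation variant: same block structure, far fewer channels
_S0_PLAN = [
    (1, 3, 1, 8, 8, 1),
    (4, 3, 2, 8, 16, 1),
    (4, 5, 2, 16, 24, 1),
]
_S0_STEM, _S0_HEAD, _S0_RES = 8, 64, 96


# ---------------------------------------------------------------------------
# Compound scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingSpec:
    """Compound-scaling state: d = alpha^phi, w = beta^phi, r = gamma^phi."""

    phi: float
    alpha_d: float = 1.2
    beta_w: float = 1.1
    gamma_r: float = 1.15
    depth_mult: float = 1.0
    width_mult: float = 1.0
    input_resolution: float = 224.0

    def flops_constraint(self) -> float:
        """alpha * beta^2 * gamma^2, ~2 for the published constants."""
        return self.alpha_d * self.beta_w**2 * self.gamma_r**2


def compound_scale(phi: float, base: ScalingSpec | None = None) -> ScalingSpec:
    """Derive depth/width/resolution multipliers for coefficient ``phi``.

    ``phi = 0`` is the B0 baseline (all multipliers 1, resolution 224).
    """
    if not np.isfinite(phi) or phi < 0:
        raise ValueError(f"phi must be a finite non-negative number, got {phi!r}")
    base = base or ScalingSpec(phi=0.0)
    if min(base.alpha_d, base.beta_w, base.gamma_r) <= 0:
        raise ValueError("scaling constants must be positive")
    return ScalingSpec(
        phi=phi,
        alpha_d=base.alpha_d,
        beta_w=base.beta_w,
        gamma_r=base.gamma_r,
        depth_mult=base.alpha_d**phi,
        width_mult=base.beta_w**phi,
        input_resolution=224.0 * base.gamma_r**phi,
    )


def round_channels(ch: int, mult: float, divisor: int = 8) -> int:
    """Width scaling with rounding to the nearest multiple of ``divisor``,
    never dropping below 90% of the unrounded value."""
    if mult == 1.0:
        return ch
    v = ch * mult
    new = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new < 0.9 * v:
        new += divisor
    return new


def round_repeats(r: int, mult: float) -> int:
    return int(math.ceil(r * mult))


# ---------------------------------------------------------------------------
# Block and model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MBConvBlockSpec:
    """One mobile inverted bottleneck block."""

    expansion: int
    kernel: int
    stride: int
    in_ch: int
    out_ch: int
    se_ratio: float = 0.25

    @property
    def residual(self) -> bool:
        return self.stride == 1 and self.in_ch == self.out_ch

    @property
    def mid_ch(self) -> int:
        return self.in_ch * self.expansion

    @property
    def se_reduced(self) -> int:
        # SE width is derived from the block *input* channels
        return max(1, int(self.in_ch * self.se_ratio))


class MBConvBlock(nn.Module):
    """expand (1x1) -> depthwise -> squeeze-excite -> project (1x1), with a
    skip connection when stride 1 and matching channels."""

    def __init__(self, spec: MBConvBlockSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        mid = spec.mid_ch
        if spec.expansion != 1:
            self.expand = nn.Conv2d(spec.in_ch, mid, 1, rng=rng)
            self.expand_bn = nn.BatchNorm2d(mid)
            self.expand_act = nn.SiLU()
        else:
            self.expand = None
        self.dw = nn.Conv2d(mid, mid, spec.kernel, stride=spec.stride, groups=mid, rng=rng)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.dw_act = nn.SiLU()
        self.se = nn.SqueezeExcite(mid, spec.se_reduced, rng)
        self.project = nn.Conv2d(mid, spec.out_ch, 1, rng=rng)
        self.project_bn = nn.BatchNorm2d(spec.out_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.in_ch:
            raise ValueError(
                f"block expects {self.spec.in_ch} channels, got {x.shape[1]}")
        h = x
        if self.expand is not None:
            h = self.expand_act(self.expand_bn(self.expand(h)))
        h = self.dw_act(self.dw_bn(self.dw(h)))
        h = self.se(h)
        h = self.project_bn(self.project(h))
        if self.spec.residual:
            h = h + x
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.project_bn.backward(dy)
        dh = self.project.backward(dh)
        dh = self.se.backward(dh)
        dh = self.dw.backward(self.dw_bn.backward(self.dw_act.backward(dh)))
        if self.expand is not None:
            dh = self.expand.backward(self.expand_bn.backward(self.expand_act.backward(dh)))
        if self.spec.residual:
            dh = dh + dy
        return dh


class Backbone(nn.Module):
    """Frozen feature extractor (stem -> MBConv stages -> head conv -> pooled
    features) with a trainable affine classifier on top."""

    def __init__(self, variant: str, num_classes: int, stem_ch: int, head_ch: int,
                 block_specs: list[MBConvBlockSpec], resolution: int,
                 seed: int, head_dropout: float = 0.2):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.variant = variant
        self.num_classes = num_classes
        self.resolution = resolution
        self.feature_dim = head_ch
        self.block_specs = block_specs
        self.stem = nn.Conv2d(3, stem_ch, 3, stride=2, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_ch)
        self.stem_act = nn.SiLU()
        self.blocks = [MBConvBlock(s, rng) for s in block_specs]
        self.head = nn.Conv2d(block_specs[-1].out_ch, head_ch, 1, rng=rng)
        self.head_bn = nn.BatchNorm2d(head_ch)
        self.head_act = nn.SiLU()
        self.pool = nn.GlobalAvgPool()
        self.dropout = nn.Dropout(head_dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.classifier = nn.Linear(head_ch, num_classes, rng=rng)

    def features(self, x: np.ndarray) -> np.ndarray:
        h = self.stem_act(self.stem_bn(self.stem(x)))
        for b in self.blocks:
            h = b(h)
        h = self.head_act(self.head_bn(self.head(h)))
        return self.pool(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.classifier(self.dropout(self.features(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.classifier.backward(dy)
        dh = self.dropout.backward(dh)
        dh = self.pool.backward(dh)
        dh = self.head.backward(self.head_bn.backward(self.head_act.backward(dh)))
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        return self.stem.backward(self.stem_bn.backward(self.stem_act.backward(dh)))

    # convenience: only the private classifier head
    def head_parameters(self):
        yield from self.classifier.named_parameters("classifier")


# ---------------------------------------------------------------------------
# Build / inventory / accounting
# ---------------------------------------------------------------------------

def stage_plan(variant: str):
    """(stem_ch, head_ch, block specs, input resolution) for a variant."""
    variant = variant.lower()
    if variant == "s0":
        specs = []
        for e, k, s, ci, co in [(p[0], p[1], p[2], p[3], p[4]) for p in _S0_PLAN]:
            specs.append(MBConvBlockSpec(e, k, s, ci, co))
        return _S0_STEM, _S0_HEAD, specs, _S0_RES
    if variant not in _VARIANT_TABLE:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    wm, dm, res = _VARIANT_TABLE[variant]
    stem = round_channels(32, wm)
    head = round_channels(1280, wm)
    specs: list[MBConvBlockSpec] = []
    for e, k, s, ci, co, r in _B0_PLAN:
        ci, co = round_channels(ci, wm), round_channels(co, wm)
        for b in range(round_repeats(r, dm)):
            specs.append(MBConvBlockSpec(e, k, s if b == 0 else 1,
                                         ci if b == 0 else co, co))
    return stem, head, specs, res


def build_backbone(variant: str, num_classes: int, seed: int = 0,
                   frozen: bool = True) -> Backbone:
    """Construct a backbone; every non-classifier parameter is frozen when
    ``frozen`` (the default), leaving only the affine head trainable."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    stem, head, specs, res = stage_plan(variant)
    model = Backbone(variant.lower(), num_classes, stem, head, specs, res, seed)
    if frozen:
        model.freeze(True)
        for _, p in model.head_parameters():
            p.frozen = False
    model.eval()
    return model


def calibrate_batchnorm(model: Backbone, x: np.ndarray) -> Backbone:
    """Set every batch-norm's running statistics from one forward pass on a
    calibration batch (layerwise, in sequence).

    A deployed frozen backbone carries normalization statistics matched to
    its activations; a freshly random-initialized one does not, and its
    activations shrink layer by layer. Calibration restores unit-scale
    activations; the statistics become part of the frozen shared state and
    never change during federated training.
    """
    was_training = model.training
    model.eval()
    for _, mod in model.named_modules():
        if isinstance(mod, nn.BatchNorm2d):
            mod.calibrating = True
    try:
        model.features(x)
    finally:
        for _, mod in model.named_modules():
            if isinstance(mod, nn.BatchNorm2d):
                mod.calibrating = False
    model.train(was_training)
    return model


@dataclass(frozen=True)
class LayerInventoryEntry:
    """One weight-bearing layer, keyed by its stable module path."""

    name: str
    kernel_shape: tuple[int, int, int, int]  # out, in/groups, kH, kW
    groups: int
    role: str
    has_bias: bool = False

    @property
    def parameter_count(self) -> int:
        n = int(np.prod(self.kernel_shape))
        if self.has_bias:
            n += self.kernel_shape[0]
        return n


_ROLE_BY_SUFFIX = [
    ("se.reduce", "se"), ("se.expand", "se"), ("expand", "expand"),
    ("project", "project"), ("stem", "stem"), ("head", "head-conv"), ("dw", "depthwise"),
]


def _conv_role(name: str) -> str:
    for suffix, role in _ROLE_BY_SUFFIX:
        if name.endswith(suffix):
            return role
    return "conv"


def layer_inventory(model: Backbone) -> list[LayerInventoryEntry]:
    """Every convolution plus the classifier, with kernel shapes and groups."""
    entries: list[LayerInventoryEntry] = []
    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv2d):
            entries.append(LayerInventoryEntry(
                name=name,
                kernel_shape=tuple(mod.weight.data.shape),
                groups=mod.groups,
                role=_conv_role(name),
                has_bias=mod.bias is not None,
            ))
        elif isinstance(mod, nn.Linear):
            o, i = mod.weight.data.shape
            entries.append(LayerInventoryEntry(name, (o, i, 1, 1), 1, "classifier", True))
    names = [e.name for e in entries]
    assert len(names) == len(set(names)), "inventory identifiers must be unique"
    return entries


def count_parameters(model: nn.Module, trainable_only: bool = False) -> int:
    """Exact parameter count (batch-norm running statistics are buffers and
    are not counted)."""
    return sum(p.size for p in model.parameters()
               if not (trainable_only and p.frozen))


def accounting_report(model: Backbone) -> dict:
    """JSON-ready accounting: totals and a per-role breakdown."""
    by_role: dict[str, int] = {}
    for e in layer_inventory(model):
        by_role[e.role] = by_role.get(e.role, 0) + e.parameter_count
    bn = sum(p.size for name, p in model.named_parameters() if "_bn" in name or "bn." in name)
    if bn:
        by_role["batchnorm"] = bn
    adapters = sum(p.size for name, p in model.named_parameters() if ".adapter." in name)
    if adapters:
        by_role["lora-adapter"] = adapters
    total = count_parameters(model)
    trainable = count_parameters(model, trainable_only=True)
    return {
        "variant": model.variant,
        "num_classes": model.num_classes,
        "total": total,
        "trainable": trainable,
        "frozen": total - trainable,
        "by_role": by_role,
    }


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Backbone, path) -> None:
    """Flat name->array container (npz) with a JSON metadata entry;
    round-trips bit-exactly."""
    arrays = {f"param/{n}": p.data for n, p in model.named_parameters()}
    for name, mod in model.named_modules():
        if isinstance(mod, nn.BatchNorm2d):
            arrays[f"buffer/{name}.running_mean"] = mod.running_mean
            arrays[f"buffer/{name}.running_var"] = mod.running_var
    meta = {"variant": model.variant, "num_classes": model.num_classes}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Backbone:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = build_backbone(meta["variant"], meta["num_classes"])
        params = dict(model.named_parameters())
        for key in z.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                params[name].data = z[key].copy()
            elif key.startswith("buffer/"):
                name = key[len("buffer/"):]
                mod_name, attr = name.rsplit(".", 1)
                mod = dict(model.named_modules())[mod_name]
                setattr(mod, attr, z[key].copy())
    return model


def closed_form_count(entries: list[LayerInventoryEntry],
                      bn_channels: list[int] | None = None) -> int:
    """Independent accounting oracle: sum of per-layer closed forms
    (kernel products + biases), plus 2 params per batch-norm channel."""
    total = sum(e.parameter_count for e in entries)
    if bn_channels:
        total += 2 * sum(bn_channels)
    return total
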