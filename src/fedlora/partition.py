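"""Non-IID client partitioning and stratified splits.

Label-skew partitioning: for each class, a proportion vector over the K
clients is drawn from Dirichlet(alpha * 1_K) and the class's samples are
allocated by largest-remainder rounding. Small alpha concentrates a
class on few clients; large alpha approaches a uniform spread. The
train/validation/test split is stratified per class with the same
largest-remainder rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PartitionInfeasibleError(RuntimeError):
    pass


class StratificationError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions; the defaults give a 72/8/20 split
    realized as a global 80/20 train/test cut followed by a validation
    carve-out of one tenth of the training side."""

    train: float = 0.72
    validation: float = 0.08
    test: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        fr = (self.train, self.validation, self.test)
        if not all(0 < f < 1 for f in fr):
            raise ValueError("fractions must be in (0, 1)")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class PartitionPlan:
    """Disjoint, exhaustive assignment of sample indices to K clients."""

    n_clients: int
    alpha: float
    seed: int
    client_indices: dict[int, np.ndarray]

    def client(self, i: int) -> np.ndarray:
        return self.client_indices[i]

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "alpha": self.alpha,
            "n_clients": self.n_clients,
            "clients": {str(k): v.tolist() for k, v in self.client_indices.items()},
        }


def _largest_remainder(n: int, proportions: np.ndarray) -> np.ndarray:
    """Integer allocation of n items to bins, exactly conserving n."""
    raw = proportions * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def dirichlet_partition(labels, n_clients: int, alpha: float, seed: int = 0,
                        min_size: int = 20, max_retries: int = 100) -> PartitionPlan:
    """Partition sample indices across clients with per-class Dirichlet
    label skew; resamples (bounded) until every client holds at least
    ``min_size`` samples."""
    labels = np.asarray(labels)
    n = len(labels)
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n < min_size * n_clients:
        raise PartitionInfeasibleError(
            f"{n} samples cannot give {n_clients} clients >= {min_size} each")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    for _ in range(max_retries):
        assignment: list[list[int]] = [[] for _ in range(n_clients)]
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            if n_clients == 1:
                counts = np.array([len(idx)])
            else:
                p = rng.dirichlet(np.full(n_clients, alpha))
                counts = _largest_remainder(len(idx), p)
            start = 0
            for k, cnt in enumerate(counts):
                assignment[k].extend(idx[start:start + cnt].tolist())
                start += cnt
        sizes = np.array([len(a) for a in assignment])
        if sizes.min() >= min_size:
            client_indices = {
                k: np.sort(np.array(a, dtype=int)) for k, a in enumerate(assignment)
            }
            plan = PartitionPlan(n_clients, alpha, seed, client_indices)
            _check_exact_cover(plan, n)
            return plan
    raise PartitionInfeasibleError(
        f"no partition with min_size={min_size} found in {max_retries} draws")


def _check_exact_cover(plan: PartitionPlan, n: int) -> None:
    all_idx = np.concatenate(list(plan.client_indices.values()))
    if len(all_idx) != n or len(np.unique(all_idx)) != n:
        raise AssertionError("partition is not an exact cover")  # pragma: no cover


def stratified_split(labels, spec: SplitSpec):
    """Per-class largest-remainder allocation into (train, validation, test)
    index arrays; disjoint, exhaustive and deterministic given the seed."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    fractions = np.array([spec.train, spec.validation, spec.test])
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
        for idx in groups:
            if len(idx) < 3:
                raise StratificationError(
                    f"class with {len(idx)} samples cannot be split three ways")
    else:
        groups = [np.arange(len(labels))]
    for idx in groups:
        idx = idx.copy()
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for j, cnt in enumerate(counts):
            parts[j].extend(idx[start:start + cnt].tolist())
            start += cnt
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def distribution_table(plan: PartitionPlan, labels,
                       class_names: list[str] | None = None,
                       val_indices: dict[int, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-client class counts and percentages (one row per client and
    split), mirroring a client-wise distribution report."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    names = class_names or [str(c) for c in classes]
    rows = []
    for k in sorted(plan.client_indices):
        splits = {"train": plan.client_indices[k]}
        if val_indices is not None and k in val_indices:
            splits["validation"] = val_indices[k]
        for split, idx in splits.items():
            lab = labels[idx]
            total = len(lab)
            row = {"client": k, "split": split, "total": total}
            for c, nm in zip(classes, names):
                cnt = int((lab == c).sum())
                row[f"{nm}_count"] = cnt
                row[f"{nm}_pct"] = 100.0 * cnt / total if total else 0.0
            rows.append(row)
    df = pd.DataFrame(rows)
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    assert np.allclose(df[df["total"] > 0][pct_cols].sum(axis=1), 100.0, atol=0.1)
    return df
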