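"""Quantity-skewed non-IID partitioning of a sample pool across clients.

Each client k is assigned a preset nonnegative weight w_k.  Weights are
normalised to ratios, per-client counts are the floored proportional shares
c_k = floor(w̃_k · n), the remainder is handed back one sample at a time to
the earliest clients, a minimum-count floor m_min is enforced, and any
surplus the floor created is removed one sample per client cycling from
client 1 while skipping clients already at the floor — so the total is
conserved exactly and no client ever drops below m_min.  Index assignment
is a seeded Fisher–Yates shuffle (numpy PCG64) sliced contiguously.

The defaults (K = 10 with weights [0.30, 0.20, 0.15, 0.10, 0.08, 0.06,
0.04, 0.03, 0.02, 0.02], m_min = 10, seed 1234) reproduce a heavily
quantity-skewed federation: the largest client holds 15× the smallest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CLIENT_WEIGHTS",
    "DEFAULT_M_MIN",
    "DEFAULT_SEED",
    "InvalidWeightsError",
    "InfeasiblePartitionError",
    "PartitionPlan",
    "normalize_weights",
    "allocate_counts",
    "assign_indices",
    "make_partition",
]

DEFAULT_CLIENT_WEIGHTS: tuple[float, ...] = (
    0.30, 0.20, 0.15, 0.10, 0.08, 0.06, 0.04, 0.03, 0.02, 0.02,
)
DEFAULT_M_MIN = 10
DEFAULT_SEED = 1234


class InvalidWeightsError(ValueError):
    """Weight vector is empty, contains negatives, or sums to zero."""


class InfeasiblePartitionError(ValueError):
    """n < K·m_min: every allocation would violate the minimum-count floor."""


@dataclass
class PartitionPlan:
    """Per-client counts and disjoint index lists covering 0..n−1."""

    counts: list[int]
    indices: list[np.ndarray]
    n: int
    m_min: int
    seed: int

    def __post_init__(self) -> None:
        self.indices = [np.asarray(ix, dtype=np.int64) for ix in self.indices]

    @property
    def n_clients(self) -> int:
        return len(self.counts)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "counts": [int(c) for c in self.counts],
            "indices": [ix.tolist() for ix in self.indices],
            "n": int(self.n),
            "m_min": int(self.m_min),
            "seed": int(self.seed),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PartitionPlan":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            counts=list(d["counts"]),
            indices=[np.asarray(ix, dtype=np.int64) for ix in d["indices"]],
            n=d["n"],
            m_min=d["m_min"],
            seed=d["seed"],
        )


def normalize_weights(w: Sequence[float]) -> np.ndarray:
    """Normalise preset client weights to allocation ratios summing to 1."""
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or w.size == 0:
        raise InvalidWeightsError("weight vector must be a nonempty 1-D sequence")
    if np.any(w < 0):
        raise InvalidWeightsError("client weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise InvalidWeightsError("client weights must not all be zero")
    return w / total


def allocate_counts(ratios: Sequence[float], n: int, m_min: int = DEFAULT_M_MIN) -> list[int]:
    """Proportional counts with exact total conservation and a per-client floor.

    Floored shares first; the rounding deficit is returned one sample at a
    time to the earliest clients; clients below ``m_min`` are lifted to it;
    the surplus that lifting created is then removed one sample per client
    cycling from client 1, skipping clients already at the floor.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    k = ratios.size
    if m_min < 0:
        raise ValueError("m_min must be nonnegative")
    if n < k * m_min:
        raise InfeasiblePartitionError(
            f"cannot give {k} clients at least {m_min} samples each from n={n}"
        )
    counts = np.floor(ratios * n).astype(np.int64)
    # hand the flooring deficit back to the earliest clients, one each
    deficit = n - int(counts.sum())
    i = 0
    while deficit > 0:
        counts[i % k] += 1
        deficit -= 1
        i += 1
    # lift small clients to the floor, then drain the surplus cycling from
    # client 1 and never touching a client already at the floor
    counts = np.maximum(counts, m_min)
    surplus = int(counts.sum()) - n
    i = 0
    while surplus > 0:
        j = i % k
        if counts[j] > m_min:
            counts[j] -= 1
            surplus -= 1
        i += 1
    return [int(c) for c in counts]


def assign_indices(counts: Sequence[int], n: int, seed: int = DEFAULT_SEED) -> PartitionPlan:
    """Seeded shuffle of 0..n−1 sliced contiguously by ``counts``."""
    counts = [int(c) for c in counts]
    if sum(counts) != n:
        raise ValueError(f"counts sum to {sum(counts)}, expected n={n}")
    rng = np.random.Generator(np.random.PCG64(seed))
    shuffled = rng.permutation(n)
    indices = []
    offset = 0
    for c in counts:
        indices.append(shuffled[offset : offset + c].copy())
        offset += c
    return PartitionPlan(counts=counts, indices=indices, n=n, m_min=0, seed=seed)


def make_partition(
    w: Sequence[float] = DEFAULT_CLIENT_WEIGHTS,
    n: int = 300,
    m_min: int = DEFAULT_M_MIN,
    seed: int = DEFAULT_SEED,
) -> PartitionPlan:
    """Full pipeline: normalise → allocate → shuffle-and-slice."""
    ratios = normalize_weights(w)
    counts = allocate_counts(ratios, n, m_min)
    plan = assign_indices(counts, n, seed)
    plan.m_min = m_min
    return plan
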