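"""Gradient harmonization: conflict-aware server-side aggregation (FedGH).

Under non-IID clients, two local updates can point in opposing directions
(negative inner product); plain averaging then attenuates or reverses the
intended global step.  The harmonization pipeline implemented here:

1. convert each client's post-training parameters into a gradient
   g_k = (w_k − w_t)/η  at the server learning rate η;
2. test each gradient against a partner chosen from the others and, when
   their inner product is negative, project the gradient onto the
   orthogonal complement of the partner (the PCGrad correction) — at most
   one projection per gradient, partners are always the *original*
   uncorrected gradients, and the processing order is a seeded shuffle;
3. form the consensus ("ideal") direction d = mean of corrected gradients,
   score each client by β_k = max(0, ⟨g_k′, d⟩)·n_k and normalise to
   aggregation weights α_k (falling back to equal weights when every score
   vanishes, e.g. perfect cancellation);
4. aggregate g_global = Σ α_k g_k′ and step w_{t+1} = w_t + η·g_global.

The degree of inter-client disagreement is quantified by the conflict
objective Σ_{i<j} 1[⟨g_i,g_j⟩<0]·|⟨g_i,g_j⟩|, which harmonization reduces
in expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .params import ParamVector

__all__ = [
    "GradientSet",
    "AggregationState",
    "ConflictReport",
    "params_to_gradient",
    "pcgrad_project",
    "pairwise_difference",
    "conflict_objective",
    "harmonize",
    "ideal_direction",
    "reconstruction_weights",
    "aggregate",
    "global_update",
]

PairingMode = Literal["random_pair", "scan_first_conflict"]
WeightMode = Literal["hybrid", "sample_size", "inner_product"]


@dataclass
class GradientSet:
    """Client gradients plus bookkeeping of which were projected.

    ``corrected`` equals ``gradients`` entry-wise wherever the projection
    did not fire; ``pair_choices[k]`` records the partner index used for
    gradient k (None when no projection was applied).
    """

    gradients: list[np.ndarray]
    eta: float = 1.0
    corrected: list[np.ndarray] = field(default_factory=list)
    projected_flags: list[bool] = field(default_factory=list)
    pair_choices: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gradients = [np.asarray(g, dtype=np.float64).ravel() for g in self.gradients]
        dims = {g.size for g in self.gradients}
        if len(dims) > 1:
            raise ValueError("all gradients must share one dimension")
        if not self.corrected:
            self.corrected = [g.copy() for g in self.gradients]
        if not self.projected_flags:
            self.projected_flags = [False] * len(self.gradients)
        if not self.pair_choices:
            self.pair_choices = [None] * len(self.gradients)

    @property
    def n_clients(self) -> int:
        return len(self.gradients)

    @property
    def n_projections(self) -> int:
        return int(sum(self.projected_flags))


@dataclass
class AggregationState:
    """Ideal direction, raw scores, simplex weights and the global gradient."""

    ideal: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    g_global: np.ndarray
    fallback_used: bool


@dataclass
class ConflictReport:
    """Pairwise-conflict summary of a gradient set."""

    objective: float
    n_conflicting_pairs: int
    pair_differences: np.ndarray | None = None


def params_to_gradient(w_k: ParamVector, w_t: ParamVector, eta: float) -> np.ndarray:
    """Client pseudo-gradient g_k = (w_k − w_t)/η."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    w_k.check_same_layout(w_t)
    return (w_k.values - w_t.values) / eta


def pcgrad_project(g_k: np.ndarray, g_j: np.ndarray) -> np.ndarray:
    """Remove from g_k its component along a conflicting partner g_j.

    Fires only when ⟨g_k, g_j⟩ < 0 (strict; exact ties never project);
    then returns g_k − (⟨g_k,g_j⟩/‖g_j‖²)·g_j, which is orthogonal to g_j
    and never longer than g_k.  Otherwise returns g_k unchanged.
    """
    g_k = np.asarray(g_k, dtype=np.float64)
    g_j = np.asarray(g_j, dtype=np.float64)
    if g_k.shape != g_j.shape:
        raise ValueError("gradient dimensions differ")
    inner = float(g_k @ g_j)
    if inner >= 0.0:
        return g_k.copy()
    sq = float(g_j @ g_j)
    if sq == 0.0:
        warnings.warn("zero partner gradient in projection branch; skipping", stacklevel=2)
        return g_k.copy()
    return g_k - (inner / sq) * g_j


def pairwise_difference(g_i: np.ndarray, g_j: np.ndarray) -> np.ndarray:
    """Gradient-difference vector Δ_ij = g_i − g_j (antisymmetric)."""
    g_i = np.asarray(g_i, dtype=np.float64)
    g_j = np.asarray(g_j, dtype=np.float64)
    if g_i.shape != g_j.shape:
        raise ValueError("gradient dimensions differ")
    return g_i - g_j


def conflict_objective(
    gradients: "GradientSet | Sequence[np.ndarray]",
    keep_differences: bool = False,
) -> ConflictReport:
    """Σ over unordered pairs of |⟨g_i,g_j⟩| restricted to conflicting pairs."""
    gs = gradients.gradients if isinstance(gradients, GradientSet) else \
        [np.asarray(g, dtype=np.float64).ravel() for g in gradients]
    k = len(gs)
    objective = 0.0
    n_conflicts = 0
    if k >= 2:
        mat = np.stack(gs)
        inner = mat @ mat.T
        iu = np.triu_indices(k, 1)
        vals = inner[iu]
        mask = vals < 0
        n_conflicts = int(mask.sum())
        objective = float(np.abs(vals[mask]).sum())
    diffs = None
    if keep_differences and k >= 1:
        mat = np.stack(gs)
        diffs = mat[:, None, :] - mat[None, :, :]
    return ConflictReport(objective=objective, n_conflicting_pairs=n_conflicts,
                          pair_differences=diffs)


def harmonize(
    gradient_set: GradientSet,
    rng: np.random.Generator,
    mode: PairingMode = "random_pair",
) -> GradientSet:
    """Apply at-most-one PCGrad correction to each gradient.

    The set is processed in a seeded shuffled order.  In ``random_pair``
    mode each gradient is tested against exactly one uniformly chosen other
    gradient; in ``scan_first_conflict`` mode it is tested against the
    others in shuffled order and corrected against the first conflicting
    partner found.  Partners are always the original, uncorrected
    gradients, so the result is independent of processing order in the
    scan mode and depends only on the drawn partners in the random mode.
    """
    k = gradient_set.n_clients
    if k < 2:
        return gradient_set
    originals = gradient_set.gradients
    corrected = [g.copy() for g in originals]
    flags = [False] * k
    partners: list[int | None] = [None] * k

    order = rng.permutation(k)
    for idx in order:
        others = [j for j in range(k) if j != idx]
        if mode == "random_pair":
            j = int(others[rng.integers(len(others))])
            if float(originals[idx] @ originals[j]) < 0.0:
                corrected[idx] = pcgrad_project(originals[idx], originals[j])
                flags[idx] = True
                partners[idx] = j
        elif mode == "scan_first_conflict":
            for j in rng.permutation(others):
                j = int(j)
                if float(originals[idx] @ originals[j]) < 0.0:
                    corrected[idx] = pcgrad_project(originals[idx], originals[j])
                    flags[idx] = True
                    partners[idx] = j
                    break
        else:
            raise ValueError(f"unknown pairing mode: {mode!r}")

    return GradientSet(
        gradients=[g.copy() for g in originals],
        eta=gradient_set.eta,
        corrected=corrected,
        projected_flags=flags,
        pair_choices=partners,
    )


def ideal_direction(corrected: Sequence[np.ndarray]) -> np.ndarray:
    """Consensus direction: unweighted mean of the corrected gradients."""
    mat = np.stack([np.asarray(g, dtype=np.float64).ravel() for g in corrected])
    return mat.mean(axis=0)


def reconstruction_weights(
    corrected: Sequence[np.ndarray],
    ideal: np.ndarray,
    sample_counts: Sequence[float],
    mode: WeightMode = "hybrid",
) -> AggregationState:
    """Score clients against the ideal direction and normalise to the simplex.

    ``hybrid`` (default) multiplies the clipped alignment ⟨g_k′, d⟩₊ by the
    client sample count n_k; ``sample_size`` uses n_k alone (the classical
    dataset-size weighting); ``inner_product`` uses the alignment alone.
    All-zero scores (e.g. d = 0 under perfect cancellation) trigger the
    equal-weight fallback.
    """
    mat = np.stack([np.asarray(g, dtype=np.float64).ravel() for g in corrected])
    n = np.asarray(sample_counts, dtype=np.float64)
    if np.any(n < 0) or (n.size and n.sum() <= 0):
        raise ValueError("sample counts must be nonnegative and not all zero")
    k = mat.shape[0]
    align = np.maximum(0.0, mat @ np.asarray(ideal, dtype=np.float64))
    if mode == "hybrid":
        beta = align * n
    elif mode == "sample_size":
        beta = n.copy()
    elif mode == "inner_product":
        beta = align
    else:
        raise ValueError(f"unknown weight mode: {mode!r}")
    total = float(beta.sum())
    if total > 0:
        alpha = beta / total
        fallback = False
    else:
        alpha = np.full(k, 1.0 / k)
        fallback = True
    g_global = alpha @ mat
    return AggregationState(ideal=np.asarray(ideal, dtype=np.float64), beta=beta,
                            alpha=alpha, g_global=g_global, fallback_used=fallback)


def aggregate(corrected: Sequence[np.ndarray], alpha: Sequence[float]) -> np.ndarray:
    """Weighted sum Σ α_k g_k′ of the corrected gradients."""
    mat = np.stack([np.asarray(g, dtype=np.float64).ravel() for g in corrected])
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.size != mat.shape[0]:
        raise ValueError("weight/gradient count mismatch")
    return alpha @ mat


def global_update(w_t: ParamVector, g_global: np.ndarray, eta: float) -> ParamVector:
    """Server step w_{t+1} = w_t + η·g_global."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    g_global = np.asarray(g_global, dtype=np.float64).ravel()
    if g_global.size != len(w_t):
        raise ValueError("gradient/parameter dimension mismatch")
    return ParamVector(w_t.values + eta * g_global, w_t.layout)
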