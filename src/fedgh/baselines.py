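"""Server-side aggregation strategies compared against gradient harmonization.

All strategies implement one plug-in contract:

    aggregate(updates, global_params, rng, round_index) -> (new_global, ConflictReport)

plus an optional local-training hook ``local_penalty`` that returns a
parameter-space gradient added to the client's task gradient (used by the
proximal and dynamic-regularization strategies).  The conflict report is
telemetry: every strategy measures the pairwise-conflict objective of the
raw client gradients, but only the harmonizing strategy acts on it.

Implemented strategies:

* ``fedavg``  — sample-size-weighted parameter averaging.
* ``fedprox`` — FedAvg aggregation; locally, a proximal term
  (mu/2)·‖w − w_global‖² constrains client drift.
* ``fedbn``   — parameters whose names match the normalization patterns
  are excluded from averaging (each client keeps its own; the server copy
  is frozen); everything else averages as FedAvg.
* ``feddyn``  — locally, a linear correction −⟨h, w⟩ plus a quadratic
  anchor (alpha/2)·‖w − w_global‖²; the server keeps a running mean of the
  h-corrections and adds it to the averaged model.
* ``fedaw``   — weights α_k ∝ n_k·q_k with data quality q_k = 1/(local
  validation loss + eps), or q_k = 1 in sample-size mode.
* ``fedgh``   — the gradient-harmonization pipeline from
  :mod:`fedgh.harmonize`.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import harmonize as gh
from .harmonize import ConflictReport, GradientSet, conflict_objective
from .params import ClientUpdate, ParamVector

__all__ = [
    "BaselineConfig",
    "Aggregator", "FedAvg", "FedProx", "FedBN", "FedDyn", "FedAW", "FedGH",
    "fedavg_aggregate", "fedprox_local_loss", "fedbn_aggregate",
    "feddyn_local_loss", "fedaw_aggregate",
    "make_aggregator", "AGGREGATORS",
]


@dataclass
class BaselineConfig:
    """Knobs for the comparison strategies."""

    prox_mu: float = 0.01
    dyn_alpha: float = 0.01
    bn_param_names: tuple[str, ...] = ("*norm*", "*bn*")
    aw_quality: str = "inv_val_loss"  # or "sample_size"
    aw_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.prox_mu < 0 or self.dyn_alpha < 0:
            raise ValueError("prox_mu and dyn_alpha must be nonnegative")


# ---------------------------------------------------------------------------
# functional forms


def fedavg_aggregate(updates: Sequence[ClientUpdate]) -> ParamVector:
    """Elementwise Σ_k (n_k/Σn)·w_k."""
    if not updates:
        raise ValueError("need at least one client update")
    n = np.array([u.n_samples for u in updates], dtype=np.float64)
    total = n.sum()
    if total <= 0:
        raise ValueError("zero total sample count")
    ref = updates[0].params
    for u in updates[1:]:
        u.params.check_same_layout(ref)
    mat = np.stack([u.params.values for u in updates])
    return ParamVector((n / total) @ mat, ref.layout)


def fedprox_local_loss(task_loss: float, w_local: np.ndarray, w_global: np.ndarray,
                       mu: float) -> float:
    """task_loss + (mu/2)·‖w_local − w_global‖²."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    d = np.asarray(w_local, dtype=np.float64) - np.asarray(w_global, dtype=np.float64)
    return float(task_loss + 0.5 * mu * (d @ d))


def fedbn_aggregate(updates: Sequence[ClientUpdate], global_params: ParamVector,
                    bn_param_names: Sequence[str]) -> ParamVector:
    """FedAvg on non-normalization slices; normalization slices keep the
    previous global values (clients keep their own copies locally)."""
    avg = fedavg_aggregate(updates)
    layout = global_params.layout
    matched = [name for name in layout.names
               if any(fnmatch.fnmatch(name, pat) for pat in bn_param_names)]
    if not matched:
        warnings.warn("no parameter names match the normalization patterns; "
                      "aggregation degenerates to FedAvg", stacklevel=2)
        return avg
    out = avg.values.copy()
    for name in matched:
        sl = layout.slice_of(name)
        out[sl] = global_params.values[sl]
    return ParamVector(out, layout)


def feddyn_local_loss(task_loss: float, w_local: np.ndarray, w_global: np.ndarray,
                      h_state: np.ndarray, alpha: float) -> float:
    """task_loss − ⟨h, w_local⟩ + (alpha/2)·‖w_local − w_global‖²."""
    w_local = np.asarray(w_local, dtype=np.float64)
    d = w_local - np.asarray(w_global, dtype=np.float64)
    return float(task_loss - h_state @ w_local + 0.5 * alpha * (d @ d))


def fedaw_aggregate(updates: Sequence[ClientUpdate],
                    quality_scores: Sequence[float]) -> ParamVector:
    """Quality-and-size weighted averaging: α_k ∝ n_k·q_k on the simplex."""
    q = np.asarray(quality_scores, dtype=np.float64)
    if np.any(q < 0):
        raise ValueError("quality scores must be nonnegative")
    n = np.array([u.n_samples for u in updates], dtype=np.float64)
    beta = n * q
    total = beta.sum()
    if total <= 0:
        warnings.warn("all quality scores are zero; falling back to equal weights",
                      stacklevel=2)
        alpha = np.full(len(updates), 1.0 / len(updates))
    else:
        alpha = beta / total
    ref = updates[0].params
    mat = np.stack([u.params.values for u in updates])
    return ParamVector(alpha @ mat, ref.layout)


# ---------------------------------------------------------------------------
# plug-in classes


def _raw_gradient_report(updates: Sequence[ClientUpdate], global_params: ParamVector,
                         eta: float) -> ConflictReport:
    grads = [gh.params_to_gradient(u.params, global_params, eta) for u in updates]
    return conflict_objective(grads)


class Aggregator:
    """Plug-in contract shared by all six strategies."""

    name = "base"

    def __init__(self, config: BaselineConfig | None = None, eta: float = 1e-3) -> None:
        self.config = config or BaselineConfig()
        self.eta = eta

    def local_penalty(self, client_id: int, w_global: np.ndarray):
        """Optional parameter-space gradient hook for local training."""
        return None

    def after_local_training(self, update: ClientUpdate, w_global: ParamVector) -> None:
        """Optional per-client state update after local training."""

    def aggregate(self, updates: Sequence[ClientUpdate], global_params: ParamVector,
                  rng: np.random.Generator, round_index: int = 0
                  ) -> tuple[ParamVector, ConflictReport]:
        raise NotImplementedError


class FedAvg(Aggregator):
    name = "fedavg"

    def aggregate(self, updates, global_params, rng, round_index=0):
        report = _raw_gradient_report(updates, global_params, self.eta)
        return fedavg_aggregate(updates), report


class FedProx(FedAvg):
    name = "fedprox"

    def local_penalty(self, client_id, w_global):
        mu = self.config.prox_mu
        return lambda w: mu * (w - w_global)


class FedBN(Aggregator):
    name = "fedbn"

    def aggregate(self, updates, global_params, rng, round_index=0):
        report = _raw_gradient_report(updates, global_params, self.eta)
        new = fedbn_aggregate(updates, global_params, self.config.bn_param_names)
        return new, report


class FedDyn(Aggregator):
    """Dynamic regularization: per-client linear corrections h_k and a
    server-side running mean of the corrections."""

    name = "feddyn"

    def __init__(self, config=None, eta=1e-3):
        super().__init__(config, eta)
        self._h: dict[int, np.ndarray] = {}
        self._h_server: np.ndarray | None = None

    def local_penalty(self, client_id, w_global):
        alpha = self.config.dyn_alpha
        h = self._h.get(client_id)

        def grad(w):
            g = alpha * (w - w_global)
            if h is not None:
                g = g - h
            return g

        return grad

    def after_local_training(self, update, w_global):
        alpha = self.config.dyn_alpha
        delta = update.params.values - w_global.values
        h = self._h.get(update.client_id)
        self._h[update.client_id] = (h if h is not None else 0.0) - alpha * delta

    def aggregate(self, updates, global_params, rng, round_index=0):
        report = _raw_gradient_report(updates, global_params, self.eta)
        avg = fedavg_aggregate(updates)
        alpha = self.config.dyn_alpha
        if alpha > 0:
            # correct with the running mean accumulated over *previous*
            # rounds, then fold this round's mean delta into the state
            hs = self._h_server if self._h_server is not None else np.zeros(len(avg))
            new = ParamVector(avg.values - hs / alpha, avg.layout)
            mean_delta = np.mean(
                [u.params.values - global_params.values for u in updates], axis=0)
            self._h_server = hs - alpha * mean_delta
        else:
            new = avg
        return new, report


class FedAW(Aggregator):
    name = "fedaw"

    def aggregate(self, updates, global_params, rng, round_index=0):
        report = _raw_gradient_report(updates, global_params, self.eta)
        if self.config.aw_quality == "inv_val_loss":
            q = [1.0 / (u.val_loss + self.config.aw_eps) if u.val_loss is not None else 1.0
                 for u in updates]
        else:
            q = [1.0] * len(updates)
        return fedaw_aggregate(updates, q), report


class FedGH(Aggregator):
    """Gradient harmonization: PCGrad correction + ideal-direction weights."""

    name = "fedgh"

    def __init__(self, config=None, eta=1e-3, pairing_mode="random_pair",
                 weight_mode="hybrid"):
        super().__init__(config, eta)
        self.pairing_mode = pairing_mode
        self.weight_mode = weight_mode
        self.last_state: gh.AggregationState | None = None
        self.last_n_projections = 0

    def aggregate(self, updates, global_params, rng, round_index=0):
        grads = [gh.params_to_gradient(u.params, global_params, self.eta)
                 for u in updates]
        gset = GradientSet(gradients=grads, eta=self.eta)
        report = conflict_objective(gset)
        corrected_set = gh.harmonize(gset, rng, mode=self.pairing_mode)
        d = gh.ideal_direction(corrected_set.corrected)
        # alignment weighting is part of the conflict-resolution machinery:
        # in a conflict-free round the strategy degenerates gracefully to
        # dataset-size weighting (and hence to plain parameter averaging)
        weight_mode = self.weight_mode
        if weight_mode == "hybrid" and report.n_conflicting_pairs == 0:
            weight_mode = "sample_size"
        state = gh.reconstruction_weights(
            corrected_set.corrected, d, [u.n_samples for u in updates],
            mode=weight_mode)
        new = gh.global_update(global_params, state.g_global, self.eta)
        self.last_state = state
        self.last_n_projections = corrected_set.n_projections
        return new, report


AGGREGATORS: dict[str, type[Aggregator]] = {
    cls.name: cls for cls in (FedAvg, FedProx, FedBN, FedDyn, FedAW, FedGH)
}


def make_aggregator(name: str, config: BaselineConfig | None = None,
                    eta: float = 1e-3, **kwargs) -> Aggregator:
    try:
        cls = AGGREGATORS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown aggregator {name!r}; choose from {sorted(AGGREGATORS)}")
    return cls(config, eta, **kwargs)
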