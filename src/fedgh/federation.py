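"""Synchronous federated-training orchestration.

One communication round: the server broadcasts the current global
parameters, a uniform random subset of clients (without replacement)
trains locally for a fixed number of epochs, the configured aggregation
strategy combines the updates, and the new global model is evaluated on
the held-out test set.  A master seed derives independent per-round,
per-client and per-aggregator child seeds, so a (config, seed) pair fully
determines every round record.

The reference protocol is 10 clients, 5 sampled per round, 5 local
epochs, batch size 32, server learning rate 1e-3 over 100 rounds; the
desk-scale defaults used by the test suite shrink the round count and the
model, not the protocol structure.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .baselines import Aggregator, BaselineConfig, make_aggregator
from .evaluation import PCKConfig, detection_accuracy, paired_t_test, pck
from .nn import masked_mse
from .params import ClientUpdate, ParamVector
from .pose import PoseNet, PoseNetConfig, TINY, decode_heatmaps, local_train, \
    render_target_heatmaps
from .scenes import ClientProfile, FederatedDataset, PoseSample, conflict_profiles, \
    iid_profiles, make_federated_dataset, make_profiles

__all__ = [
    "FederationConfig", "RoundRecord", "Client", "prepare_clients",
    "run_round", "run_training", "TrainingResult", "records_to_frame",
    "compare_strategies",
]


@dataclass
class FederationConfig:
    """Everything needed to reproduce a federated run."""

    n_clients: int = 10
    clients_per_round: int = 5
    local_epochs: int = 5
    rounds: int = 100
    server_lr: float = 1e-3
    server_optimizer: str = "plain"   # direct gradient step; or "adam"
    batch_size: int = 32
    aggregator: str = "fedgh"
    seed: int = 0
    client_optimizer: str = "adam"
    client_lr: float = 1e-3
    # dataset
    n_samples: int = 300
    divergence: float = 1.0
    image_size: int = 64
    client_weights: tuple[float, ...] | None = None
    m_min: int = 10
    partition_seed: int = 1234
    # strategy knobs
    prox_mu: float = 0.01
    dyn_alpha: float = 0.01
    aw_quality: str = "inv_val_loss"
    pairing_mode: str = "random_pair"
    weight_mode: str = "hybrid"
    eval_every: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.clients_per_round <= self.n_clients:
            raise ValueError("clients_per_round must lie in [1, n_clients]")
        if self.rounds < 0:
            raise ValueError("rounds must be nonnegative")
        if self.server_lr <= 0:
            raise ValueError("server learning rate must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FederationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "client_weights" in data and data["client_weights"] is not None:
            data["client_weights"] = tuple(data["client_weights"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["client_weights"] is not None:
            d["client_weights"] = list(d["client_weights"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class RoundRecord:
    """Per-round telemetry and test metrics."""

    round: int
    sampled_clients: list[int]
    n_samples: list[int]
    conflict_objective: float
    n_conflicting_pairs: int
    n_projections: int
    fallback_used: bool
    mean_train_loss: float
    detection_accuracy: float
    pck_per_joint: list[float]
    mean_pck: float

    def to_row(self) -> dict:
        row = {
            "round": self.round,
            "sampled_clients": ";".join(map(str, self.sampled_clients)),
            "conflict_objective": self.conflict_objective,
            "n_conflicting_pairs": self.n_conflicting_pairs,
            "n_projections": self.n_projections,
            "fallback_used": int(self.fallback_used),
            "mean_train_loss": self.mean_train_loss,
            "detection_accuracy": self.detection_accuracy,
            "mean_pck": self.mean_pck,
        }
        for j, v in enumerate(self.pck_per_joint):
            row[f"pck_joint{j}"] = v
        return row


def records_to_frame(records: Sequence[RoundRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


class Client:
    """A client's tensors, rendered once from its scene shard."""

    def __init__(self, client_id: int, train: Sequence[PoseSample],
                 val: Sequence[PoseSample], pose_config: PoseNetConfig) -> None:
        self.client_id = client_id
        self.images, self.targets, self.masks = _stack_samples(train, pose_config)
        if val:
            self.val_images, self.val_targets, self.val_masks = _stack_samples(val, pose_config)
        else:
            self.val_images = None
        self.n_samples = len(train)


def _stack_samples(samples: Sequence[PoseSample], pose_config: PoseNetConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples])[:, None, :, :].astype(np.float32)
    maps, masks = zip(*(render_target_heatmaps(s.keypoints, pose_config)
                        for s in samples))
    return images, np.stack(maps), np.stack(masks)


def prepare_clients(dataset: FederatedDataset, pose_config: PoseNetConfig) -> list[Client]:
    return [Client(cd.client_id, cd.train, cd.val, pose_config)
            for cd in dataset.clients]


class _ServerAdam:
    """Server-side Adam treating −g_global as a pseudo-gradient."""

    def __init__(self, lr: float) -> None:
        from .nn import Adam
        self._adam = Adam(lr=lr)

    def step(self, w_t: ParamVector, proposed: ParamVector) -> ParamVector:
        pseudo_grad = -(proposed.values - w_t.values)
        params = {"w": w_t.values.copy()}
        self._adam.step(params, {"w": pseudo_grad.astype(np.float32)})
        return ParamVector(params["w"], w_t.layout)


def _evaluate(model: PoseNet, global_params: ParamVector, test: Sequence[PoseSample],
              pose_config: PoseNetConfig, pck_config: PCKConfig) -> tuple[float, np.ndarray, float]:
    model.set_params(global_params)
    images = np.stack([s.image for s in test])[:, None, :, :].astype(np.float32)
    gt = np.stack([s.keypoints for s in test])
    norms = np.stack([s.norm_lengths for s in test])
    preds = []
    for start in range(0, len(test), 64):
        preds.append(model.forward(images[start : start + 64]))
    heatmaps = np.concatenate(preds)
    coords, _ = decode_heatmaps(heatmaps, pose_config)
    acc = detection_accuracy(coords, gt, norms, config=pck_config)
    report = pck(coords, gt, norms, pck_config)
    return acc, report.per_joint, report.mean


def run_round(
    global_params: ParamVector,
    clients: Sequence[Client],
    aggregator: Aggregator,
    model: PoseNet,
    config: FederationConfig,
    round_index: int,
    test: Sequence[PoseSample] | None = None,
    pck_config: PCKConfig = PCKConfig(),
) -> tuple[ParamVector, RoundRecord]:
    """One broadcast → local-train → aggregate → evaluate cycle."""
    master = config.seed
    sample_rng = np.random.default_rng([master, round_index, 900_001])
    chosen = sorted(sample_rng.choice(len(clients), size=config.clients_per_round,
                                      replace=False).tolist())
    updates: list[ClientUpdate] = []
    losses = []
    for cid in chosen:
        client = clients[cid]
        model.set_params(global_params)
        penalty = aggregator.local_penalty(cid, global_params.values)
        rng = np.random.default_rng([master, round_index, cid])
        update, epoch_losses = local_train(
            model, client.images, client.targets, client.masks,
            epochs=config.local_epochs, rng=rng,
            optimizer=config.client_optimizer, lr=config.client_lr,
            batch_size=config.batch_size, client_id=cid, penalty=penalty,
        )
        if client.val_images is not None:
            pred = model.forward(client.val_images)
            update.val_loss, _ = masked_mse(pred, client.val_targets, client.val_masks)
        aggregator.after_local_training(update, global_params)
        losses.append(epoch_losses[-1])
        updates.append(update)

    agg_rng = np.random.default_rng([master, round_index, 900_002])
    try:
        new_global, report = aggregator.aggregate(updates, global_params, agg_rng,
                                                  round_index)
    except Exception:
        # a failed aggregation aborts the round; the global model is kept
        import logging
        logging.getLogger(__name__).exception("aggregation failed; round aborted")
        new_global = global_params
        from .harmonize import ConflictReport
        report = ConflictReport(objective=float("nan"), n_conflicting_pairs=-1)

    fallback = bool(getattr(aggregator, "last_state", None) and
                    aggregator.last_state.fallback_used)
    n_proj = int(getattr(aggregator, "last_n_projections", 0))

    if test:
        acc, per_joint, mean_pck = _evaluate(model, new_global, test,
                                             model.config, pck_config)
    else:
        acc, per_joint, mean_pck = float("nan"), np.full(model.config.n_keypoints, np.nan), float("nan")

    record = RoundRecord(
        round=round_index,
        sampled_clients=chosen,
        n_samples=[u.n_samples for u in updates],
        conflict_objective=report.objective,
        n_conflicting_pairs=report.n_conflicting_pairs,
        n_projections=n_proj,
        fallback_used=fallback,
        mean_train_loss=float(np.mean(losses)) if losses else float("nan"),
        detection_accuracy=acc,
        pck_per_joint=[float(v) for v in np.atleast_1d(per_joint)],
        mean_pck=mean_pck,
    )
    return new_global, record


@dataclass
class TrainingResult:
    records: list[RoundRecord]
    final_params: ParamVector
    config: FederationConfig
    model: PoseNet

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def run_training(
    config: FederationConfig,
    dataset: FederatedDataset | None = None,
    pose_config: PoseNetConfig = TINY,
    out_dir: str | Path | None = None,
) -> TrainingResult:
    """Full federated run: dataset → rounds → metrics CSV (+ checkpoint)."""
    if dataset is None:
        profiles = make_profiles(config.n_clients, config.divergence,
                                 weights=config.client_weights)
        dataset = make_federated_dataset(
            config.n_samples, profiles, seed=config.partition_seed,
            image_size=config.image_size, m_min=config.m_min)
    if len(dataset.clients) != config.n_clients:
        raise ValueError("dataset client count does not match config")

    clients = prepare_clients(dataset, pose_config)
    model = PoseNet(pose_config, seed=config.seed)
    global_params = model.get_params()
    baseline_cfg = BaselineConfig(prox_mu=config.prox_mu, dyn_alpha=config.dyn_alpha,
                                  aw_quality=config.aw_quality)
    kwargs = {}
    if config.aggregator.lower() == "fedgh":
        kwargs = {"pairing_mode": config.pairing_mode, "weight_mode": config.weight_mode}
    aggregator = make_aggregator(config.aggregator, baseline_cfg,
                                 eta=config.server_lr, **kwargs)
    server_adam = _ServerAdam(config.server_lr) if config.server_optimizer == "adam" else None

    records: list[RoundRecord] = []
    for t in range(config.rounds):
        evaluate_now = (t + 1) % config.eval_every == 0 or t == config.rounds - 1
        proposed, record = run_round(
            global_params, clients, aggregator, model, config, t,
            test=dataset.test if evaluate_now else None)
        if server_adam is not None:
            proposed = server_adam.step(global_params, proposed)
        global_params = proposed
        records.append(record)

    result = TrainingResult(records=records, final_params=global_params,
                            config=config, model=model)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.frame.to_csv(out / "metrics.csv", index=False)
        np.savetxt(out / "final_params.txt", global_params.values)
        config.to_yaml(out / "config.yaml")
    return result


def compare_strategies(
    config: FederationConfig,
    aggregators: Sequence[str] = ("fedavg", "fedprox", "fedbn", "feddyn", "fedaw", "fedgh"),
    seeds: Sequence[int] = (0, 1, 2),
    dataset: FederatedDataset | None = None,
    pose_config: PoseNetConfig = TINY,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[pd.DataFrame]]]:
    """Run every strategy over the seeds on a common dataset.

    Returns (summary, t-test table, per-strategy per-seed round frames).
    The summary lists each strategy's max and final mean PCK (median over
    seeds); the t-test table pairs the harmonizing strategy's per-round
    mean-PCK series against each baseline's, per seed.
    """
    if dataset is None:
        profiles = make_profiles(config.n_clients, config.divergence,
                                 weights=config.client_weights)
        dataset = make_federated_dataset(
            config.n_samples, profiles, seed=config.partition_seed,
            image_size=config.image_size, m_min=config.m_min)

    frames: dict[str, list[pd.DataFrame]] = {}
    for name in aggregators:
        frames[name] = []
        for seed in seeds:
            cfg = replace(config, aggregator=name, seed=seed)
            res = run_training(cfg, dataset=dataset, pose_config=pose_config)
            frames[name].append(res.frame)

    rows = []
    for name in aggregators:
        finals = [f["mean_pck"].iloc[-1] for f in frames[name]]
        maxes = [f["mean_pck"].max() for f in frames[name]]
        rows.append({"aggregator": name,
                     "median_final_mean_pck": float(np.median(finals)),
                     "median_max_mean_pck": float(np.median(maxes))})
    summary = pd.DataFrame(rows)

    trows = []
    if "fedgh" in frames:
        for name in aggregators:
            if name == "fedgh":
                continue
            for i, seed in enumerate(seeds):
                a = frames["fedgh"][i]["mean_pck"].to_numpy()
                b = frames[name][i]["mean_pck"].to_numpy()
                keep = ~(np.isnan(a) | np.isnan(b))
                if keep.sum() >= 2:
                    res = paired_t_test(a[keep], b[keep])
                    trows.append({"baseline": name, "seed": seed,
                                  "t": res.t, "p": res.p, "df": res.df})
    ttests = pd.DataFrame(trows)
    return summary, ttests, frames
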