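"""Simulated federated training: partitioning, sampling, weight averaging.

The protocol: the dataset is split into ``n_clients`` equally sized
disjoint subsets.  Each communication round, ``clients_per_round``
clients are drawn uniformly without replacement; every selected client
starts from the current global weights, trains ``local_epochs`` epochs on
its own subset only, and the new global weights are the per-parameter
unweighted mean of the selected clients' weights (subsets are equal-sized
by construction, so this coincides with example-count weighting).  The
average covers generator and discriminator parameters of all four
networks.  Optimizer state is local to each client and reset at every
synchronisation.

All randomness derives from ``FedConfig.seed`` through a fixed
SeedSequence layout (see the ``*_seed``/``*_rng`` helpers), so a run is
reproducible and a single-client, single-round federation is
step-for-step identical to centralized training with the same derived
seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import gan, signals
from .gan import (CycleGan, CycleGanTrainer, DiscriminatorSpec, GeneratorSpec,
                  LossBreakdown, LossWeights, TrainOptions, WeightSet)

__all__ = [
    "FedConfig",
    "RoundRecord",
    "AggregationError",
    "partition_dataset",
    "select_clients",
    "aggregate_weights",
    "run_federated_training",
    "init_seed",
    "client_rng",
]

logger = logging.getLogger(__name__)


class AggregationError(ValueError):
    """Weight sets passed to aggregation are incompatible."""


@dataclass(frozen=True)
class FedConfig:
    """Federation hyperparameters.

    Defaults are the reference protocol: 20 clients, 6 sampled per round,
    10 communication rounds, 5 local epochs, batch size 32.
    """

    n_clients: int = 20
    clients_per_round: int = 6
    n_rounds: int = 10
    local_epochs: int = 5
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.n_clients < 1 or self.n_rounds < 1 or self.local_epochs < 1 \
                or self.batch_size < 1:
            raise ValueError("all federation counts must be >= 1")
        if not (1 <= self.clients_per_round <= self.n_clients):
            raise ValueError(
                f"clients_per_round must be in [1, n_clients], got "
                f"{self.clients_per_round} with n_clients={self.n_clients}"
            )


@dataclass
class RoundRecord:
    """History of one communication round."""

    round: int
    selected: list[int]
    client_losses: dict[int, list[LossBreakdown]]

    @property
    def mean_losses(self) -> LossBreakdown:
        all_steps = [s for steps in self.client_losses.values() for s in steps]
        return LossBreakdown(
            adv_p2a=float(np.mean([s.adv_p2a for s in all_steps])),
            adv_a2p=float(np.mean([s.adv_a2p for s in all_steps])),
            cycle=float(np.mean([s.cycle for s in all_steps])),
            identity=float(np.mean([s.identity for s in all_steps])),
            total=float(np.mean([s.total for s in all_steps])),
        )


# --- deterministic seed layout -------------------------------------------

def init_seed(seed: int) -> int:
    """Seed for global model initialization."""
    return int(np.random.SeedSequence([seed, 0]).generate_state(1)[0] % (2 ** 31))


def _partition_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1]))


def selection_rng(seed: int, round_idx: int) -> np.random.Generator:
    """Client-sampling RNG for one communication round."""
    return np.random.default_rng(np.random.SeedSequence([seed, 2, round_idx]))


def client_rng(seed: int, round_idx: int, client: int) -> np.random.Generator:
    """Batch-shuffling RNG for one client in one round."""
    return np.random.default_rng(np.random.SeedSequence([seed, 3, round_idx, client]))


# --- protocol operations --------------------------------------------------

def partition_dataset(n_items: int, n_clients: int, seed: int) -> list[np.ndarray]:
    """Shuffle-split item indices into ``n_clients`` equal disjoint subsets.

    At most ``n_clients - 1`` remainder items are dropped (with a warning)
    so subsets are exactly equal-sized.
    """
    if n_clients < 1:
        raise ValueError(f"n_clients must be >= 1, got {n_clients}")
    if n_items < n_clients:
        raise ValueError(f"dataset of {n_items} items cannot feed {n_clients} clients")
    per = n_items // n_clients
    dropped = n_items - per * n_clients
    if dropped:
        logger.warning("dropping %d remainder item(s) to equalize %d client subsets",
                       dropped, n_clients)
    perm = _partition_rng(seed).permutation(n_items)[: per * n_clients]
    return [perm[k * per : (k + 1) * per] for k in range(n_clients)]


def select_clients(n_clients: int, clients_per_round: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of distinct client indices for one round."""
    if clients_per_round > n_clients:
        raise ValueError(
            f"cannot select {clients_per_round} of {n_clients} clients"
        )
    return np.sort(rng.choice(n_clients, size=clients_per_round, replace=False))


def aggregate_weights(client_weights: Sequence[WeightSet]) -> WeightSet:
    """Per-parameter elementwise unweighted mean of client weight sets."""
    if len(client_weights) == 0:
        raise ValueError("cannot aggregate an empty collection of weight sets")
    names = set(client_weights[0])
    for w in client_weights[1:]:
        if set(w) != names:
            raise AggregationError(
                f"parameter name mismatch: {sorted(names ^ set(w))}"
            )
    out: WeightSet = {}
    for name in client_weights[0]:
        shapes = {w[name].shape for w in client_weights}
        if len(shapes) != 1:
            raise AggregationError(f"shape mismatch for parameter {name!r}: {shapes}")
        acc = np.zeros_like(client_weights[0][name], dtype=np.float64)
        for w in client_weights:
            acc += w[name]
        out[name] = (acc / len(client_weights)).astype(client_weights[0][name].dtype)
    return out


def run_federated_training(
    dataset: Sequence,
    fed: FedConfig,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
    loss_weights: LossWeights = LossWeights(),
    options: TrainOptions = TrainOptions(),
    checkpoint_dir=None,
    start_round: int = 0,
    initial_weights: WeightSet | None = None,
) -> tuple[WeightSet, list[RoundRecord]]:
    """Run the full federated protocol on a paired segment dataset.

    ``dataset`` is a sequence of :class:`~pulsefed.simulate.SegmentPair`;
    each client only ever touches the items of its own subset (access is
    by per-item indexing, so a logging wrapper around ``dataset`` can
    verify isolation).  Returns the trained global weight set and the
    per-round history.

    Because every per-round RNG is derived from ``fed.seed`` and the
    round index, passing ``start_round`` together with the
    ``initial_weights`` checkpointed after round ``start_round - 1``
    resumes a run on a trajectory identical to the uninterrupted one.
    """
    fed.validate()
    subsets = partition_dataset(len(dataset), fed.n_clients, fed.seed)
    # normalize each client's subset once, up front
    client_data: list[tuple[np.ndarray, np.ndarray]] = []
    for idx in subsets:
        pairs = [dataset[int(i)] for i in idx]
        client_data.append(signals.normalize_pairs(pairs))

    if initial_weights is None:
        global_model = CycleGan(gen_spec, disc_spec, seed=init_seed(fed.seed))
        global_weights = global_model.get_weights()
    else:
        global_weights = {k: v.copy() for k, v in initial_weights.items()}
    history: list[RoundRecord] = []

    for r in range(start_round, fed.n_rounds):
        selected = select_clients(fed.n_clients, fed.clients_per_round,
                                  selection_rng(fed.seed, r))
        client_weights: list[WeightSet] = []
        client_losses: dict[int, list[LossBreakdown]] = {}
        for c in selected:
            c = int(c)
            model = CycleGan(gen_spec, disc_spec, seed=0)
            model.set_weights(global_weights)          # synchronise
            trainer = CycleGanTrainer(model, loss_weights, options)
            ppg, abp = client_data[c]
            try:
                steps = gan.train_loop(ppg, abp, trainer, fed.local_epochs,
                                       fed.batch_size, client_rng(fed.seed, r, c))
            except gan.TrainingDivergenceError as exc:
                raise gan.TrainingDivergenceError(
                    f"divergence in round {r}, client {c}: {exc}", exc.breakdown
                ) from exc
            client_weights.append(model.get_weights())
            client_losses[c] = steps
        global_weights = aggregate_weights(client_weights)
        record = RoundRecord(round=r, selected=[int(c) for c in selected],
                             client_losses=client_losses)
        history.append(record)
        mean = record.mean_losses
        logger.info("round %d/%d clients=%s cycle=%.4f identity=%.4f total=%.4f",
                    r + 1, fed.n_rounds, record.selected, mean.cycle,
                    mean.identity, mean.total)
        if checkpoint_dir is not None:
            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            gan.save_weights(ckpt / f"global_round{r:03d}.npz", global_weights)

    return global_weights, history


def history_manifest(history: Sequence[RoundRecord], fed: FedConfig) -> pd.DataFrame:
    """Round-level run manifest (selected clients, mean losses) as a table."""
    rows = []
    for rec in history:
        mean = rec.mean_losses
        rows.append({
            "round": rec.round,
            "selected_clients": " ".join(map(str, rec.selected)),
            "seed": fed.seed,
            **{k: v for k, v in mean.as_dict().items()},
        })
    return pd.DataFrame(rows)
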