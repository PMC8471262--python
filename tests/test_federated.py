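"""Federated protocol: partitioning, sampling, aggregation, equivalences."""

import numpy as np
import pytest

from pulsefed import federated, gan, signals
from pulsefed.federated import (AggregationError, FedConfig, aggregate_weights,
                                partition_dataset, run_federated_training,
                                select_clients)


def test_partition_equal_disjoint_complete():
    subsets = partition_dataset(100, 20, seed=0)
    assert len(subsets) == 20
    assert all(len(s) == 5 for s in subsets)
    flat = np.concatenate(subsets)
    assert len(set(flat.tolist())) == 100  # pairwise disjoint, full coverage


def test_partition_single_client_gets_everything():
    (subset,) = partition_dataset(10, 1, seed=0)
    assert sorted(subset.tolist()) == list(range(10))


def test_partition_drops_at_most_nclients_minus_one():
    subsets = partition_dataset(103, 20, seed=1)
    assert all(len(s) == 5 for s in subsets)
    assert 103 - sum(len(s) for s in subsets) == 3


def test_partition_rejects_too_small_dataset():
    with pytest.raises(ValueError):
        partition_dataset(5, 20, seed=0)


def test_select_clients_distinct_and_reproducible():
    picked = select_clients(20, 6, np.random.default_rng(0))
    assert len(picked) == 6 == len(set(picked.tolist()))
    assert all(0 <= c < 20 for c in picked)
    assert np.array_equal(picked, select_clients(20, 6, np.random.default_rng(0)))
    assert sorted(select_clients(5, 5, np.random.default_rng(0)).tolist()) == [0, 1, 2, 3, 4]
    with pytest.raises(ValueError):
        select_clients(4, 6, np.random.default_rng(0))


def _random_weightset(rng, shapes=None):
    shapes = shapes or {"a": (3, 4), "b": (5,), "c": (2, 2, 2)}
    return {k: rng.normal(size=s).astype(np.float32) for k, s in shapes.items()}


def test_aggregate_mean_of_identical_is_identity(rng):
    w = _random_weightset(rng)
    agg = aggregate_weights([w, {k: v.copy() for k, v in w.items()}, w])
    for k in w:
        np.testing.assert_allclose(agg[k], w[k], atol=1e-7)


def test_aggregate_matches_elementwise_loop_oracle(rng):
    sets = [_random_weightset(rng) for _ in range(6)]
    agg = aggregate_weights(sets)
    for k in sets[0]:
        oracle = np.zeros(sets[0][k].shape, dtype=np.float64)
        for idx in np.ndindex(*oracle.shape):
            vals = [float(w[k][idx]) for w in sets]
            oracle[idx] = sum(vals) / len(vals)
        np.testing.assert_allclose(agg[k], oracle, atol=1e-6)
    two = aggregate_weights([{"p": np.zeros(3)}, {"p": np.full(3, 2.0)}])
    np.testing.assert_allclose(two["p"], 1.0)


def test_aggregate_rejects_incompatible_sets(rng):
    with pytest.raises(ValueError):
        aggregate_weights([])
    a = _random_weightset(rng)
    b = _random_weightset(rng, {"a": (3, 4), "b": (6,), "c": (2, 2, 2)})
    with pytest.raises(AggregationError) as err:
        aggregate_weights([a, b])
    assert "b" in str(err.value)
    c = _random_weightset(rng, {"a": (3, 4), "x": (5,), "c": (2, 2, 2)})
    with pytest.raises(AggregationError):
        aggregate_weights([a, c])


def test_aggregation_idempotent_on_global_weights(small_gen_spec, small_disc_spec):
    model = gan.CycleGan(small_gen_spec, small_disc_spec, seed=0)
    w = model.get_weights()
    for _ in range(3):
        w = aggregate_weights([w])
    original = model.get_weights()
    assert all(np.array_equal(w[k], original[k]) for k in w)


class _AccessLoggingDataset(list):
    def __init__(self, items):
        super().__init__(items)
        self.accessed: list[int] = []

    def __getitem__(self, i):
        self.accessed.append(int(i))
        return super().__getitem__(i)


def test_client_data_isolation(small_gen_spec, small_disc_spec, small_pairs):
    # every item access during a federated run must belong to the partition;
    # dropped remainder items are never touched
    dataset = _AccessLoggingDataset(small_pairs[:22])  # 22 items, 4 clients -> 2 dropped
    fed = FedConfig(n_clients=4, clients_per_round=2, n_rounds=1, local_epochs=1,
                    batch_size=4, seed=0)
    run_federated_training(dataset, fed, small_gen_spec, small_disc_spec)
    subsets = partition_dataset(22, 4, seed=0)
    allowed = {int(i) for s in subsets for i in s}
    assert set(dataset.accessed) == allowed
    assert len(allowed) == 20


def test_history_records_rounds_and_clients(small_gen_spec, small_disc_spec,
                                            small_pairs):
    fed = FedConfig(n_clients=4, clients_per_round=3, n_rounds=2, local_epochs=1,
                    batch_size=4, seed=1)
    weights, history = run_federated_training(small_pairs, fed, small_gen_spec,
                                              small_disc_spec)
    assert len(history) == 2
    for rec in history:
        assert len(rec.selected) == 3
        assert set(rec.client_losses) == set(rec.selected)
    manifest = federated.history_manifest(history, fed)
    assert list(manifest["round"]) == [0, 1]


def test_degenerate_federation_equals_centralized(small_gen_spec, small_disc_spec,
                                                  small_pairs):
    # one client, one round == plain centralized training, step for step
    fed = FedConfig(n_clients=1, clients_per_round=1, n_rounds=1, local_epochs=3,
                    batch_size=8, seed=5)
    fed_weights, history = run_federated_training(small_pairs, fed, small_gen_spec,
                                                  small_disc_spec)
    # replicate centrally with the same derived seeds
    subset = partition_dataset(len(small_pairs), 1, fed.seed)[0]
    pairs = [small_pairs[int(i)] for i in subset]
    ppg, abp = signals.normalize_pairs(pairs)
    model = gan.CycleGan(small_gen_spec, small_disc_spec,
                         seed=federated.init_seed(fed.seed))
    trainer = gan.CycleGanTrainer(model)
    steps = gan.train_loop(ppg, abp, trainer, fed.local_epochs, fed.batch_size,
                           federated.client_rng(fed.seed, 0, 0))
    central = model.get_weights()
    assert [s.total for s in history[0].client_losses[0]] == [s.total for s in steps]
    assert all(np.array_equal(fed_weights[k], central[k]) for k in fed_weights)


def test_federated_run_reproducible(small_gen_spec, small_disc_spec, small_pairs):
    fed = FedConfig(n_clients=3, clients_per_round=2, n_rounds=2, local_epochs=1,
                    batch_size=8, seed=9)
    w1, h1 = run_federated_training(small_pairs, fed, small_gen_spec, small_disc_spec)
    w2, h2 = run_federated_training(small_pairs, fed, small_gen_spec, small_disc_spec)
    assert [r.selected for r in h1] == [r.selected for r in h2]
    assert all(np.array_equal(w1[k], w2[k]) for k in w1)


def test_fed_config_validation():
    with pytest.raises(ValueError):
        FedConfig(n_clients=4, clients_per_round=6).validate()
    with pytest.raises(ValueError):
        FedConfig(n_rounds=0).validate()
    FedConfig().validate()  # reference protocol values are valid
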