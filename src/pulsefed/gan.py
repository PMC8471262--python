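"""Cycle-consistent GAN for PPG <-> ABP waveform translation.

Two sequence generators (``p2a``: PPG -> ABP, ``a2p``: ABP -> PPG), each a
two-layer stacked LSTM with 50 hidden units per layer and a per-timestep
fully connected output head operating on length-1000 segments.  Two
discriminators (``d_a`` judging ABP segments, ``d_p`` judging PPG), each a
4-layer 1-D CNN (ReLU + max pooling) with a fully connected sigmoid head.

The training objective is the least-squares CycleGAN composition

    total = adv(p2a, d_a) + adv(a2p, d_p) + lambda_c * L_cyc + lambda_i * L_id

with mean-squared-error adversarial terms (real label 1, fake label 0),
L1 cycle-consistency loss and L1 identity loss, weighted lambda_c = 10 and
lambda_i = 5.  Segments are expected min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .nn import F32

WeightSet = dict[str, np.ndarray]


class GanConfigError(ValueError):
    """A generator/discriminator/loss specification violates its invariants."""


class TrainingDivergenceError(RuntimeError):
    """A training step produced a non-finite loss; carries the breakdown."""

    def __init__(self, message: str, breakdown: "LossBreakdown"):
        super().__init__(message)
        self.breakdown = breakdown


@dataclass(frozen=True)
class GeneratorSpec:
    """Stacked-LSTM sequence generator architecture."""

    num_layers: int = 2
    hidden_units: int = 50
    input_len: int = 1000
    output_len: int = 1000

    def validate(self) -> None:
        if self.input_len != self.output_len:
            raise GanConfigError(
                "input_len must equal output_len (identity loss needs "
                f"same-domain shapes); got {self.input_len} != {self.output_len}"
            )
        if self.num_layers < 1 or self.hidden_units < 1 or self.input_len < 1:
            raise GanConfigError("num_layers, hidden_units and input_len must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """4-layer 1-D CNN discriminator architecture.

    Channel widths and kernel size are package defaults; any 4-layer 1-D
    conv stack with ReLU, max pooling and a sigmoid dense head fits the
    architecture family.
    """

    input_len: int = 1000
    channels: tuple[int, ...] = (16, 32, 64, 64)
    kernel: int = 5

    def validate(self) -> None:
        if len(self.channels) != 4:
            raise GanConfigError(f"discriminator needs 4 conv layers, got {len(self.channels)}")
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise GanConfigError("kernel must be odd and positive")
        if self.input_len // 2 ** len(self.channels) < 1:
            raise GanConfigError("input_len too short for 4 pooling stages")


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the cycle (lambda_c) and identity (lambda_i) terms."""

    lambda_c: float = 10.0
    lambda_i: float = 5.0

    def validate(self) -> None:
        if self.lambda_c < 0 or self.lambda_i < 0:
            raise GanConfigError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    """Per-step loss components; ``total`` is the weighted Eq-style composition."""

    adv_p2a: float
    adv_a2p: float
    cycle: float
    identity: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "adv_p2a": self.adv_p2a,
            "adv_a2p": self.adv_a2p,
            "cycle": self.cycle,
            "identity": self.identity,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def adversarial_loss(scores: np.ndarray, target_label: float) -> float:
    """Least-squares adversarial loss: mean (score - target)^2."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("adversarial_loss: empty score set")
    if not np.all(np.isfinite(scores)):
        raise ValueError("adversarial_loss: non-finite scores")
    return float(np.mean((scores - target_label) ** 2))


def cycle_loss(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """L1 cycle-consistency loss: mean |x - x_reconstructed|."""
    x = np.asarray(x, dtype=np.float64)
    xr = np.asarray(x_reconstructed, dtype=np.float64)
    if x.shape != xr.shape:
        raise ValueError(f"cycle_loss: shape mismatch {x.shape} vs {xr.shape}")
    return float(np.mean(np.abs(x - xr)))


def identity_loss(x: np.ndarray, g_same_domain_output: np.ndarray) -> float:
    """L1 identity loss (same form as cycle loss, target-domain input)."""
    return cycle_loss(x, g_same_domain_output)


def total_generator_loss(adv_p2a: float, adv_a2p: float, cycle: float,
                         identity: float, weights: LossWeights) -> LossBreakdown:
    """Compose the weighted generator objective and return the breakdown."""
    weights.validate()
    parts = np.array([adv_p2a, adv_a2p, cycle, identity], dtype=np.float64)
    if not np.all(np.isfinite(parts)):
        raise ValueError("total_generator_loss: non-finite component")
    total = adv_p2a + adv_a2p + weights.lambda_c * cycle + weights.lambda_i * identity
    return LossBreakdown(adv_p2a, adv_a2p, cycle, identity, float(total))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class Generator:
    """Two-layer stacked LSTM + per-timestep dense head; (B, L) -> (B, L)."""

    def __init__(self, spec: GeneratorSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        H = spec.hidden_units
        self.layers = []
        d = 1
        for _ in range(spec.num_layers):
            self.layers.append(nn.LSTM(d, H, rng))
            d = H
        self.head = nn.TimeDense(H, 1, rng)

    def forward(self, x: np.ndarray, need_cache: bool = True):
        if x.ndim != 2 or x.shape[1] != self.spec.input_len:
            raise GanConfigError(
                f"generator expects (batch, {self.spec.input_len}), got {x.shape}"
            )
        # internal layout is time-major (T, B, D)
        h = np.ascontiguousarray(np.asarray(x, dtype=F32).T)[:, :, None]
        caches = []
        for layer in self.layers:
            h, c = layer.forward(h)
            caches.append(c)
        y, c = self.head.forward(h)
        caches.append(c)
        out = np.ascontiguousarray(y[:, :, 0].T)
        return (out, caches) if need_cache else (out, None)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, need_cache=False)[0]

    def backward(self, dy: np.ndarray, caches) -> tuple[np.ndarray, WeightSet]:
        grads: WeightSet = {}
        d = np.ascontiguousarray(np.asarray(dy, dtype=F32).T)[:, :, None]
        d, g = self.head.backward(d, caches[-1])
        for k, v in g.items():
            grads[f"head.{k}"] = v
        for i in range(len(self.layers) - 1, -1, -1):
            d, g = self.layers[i].backward(d, caches[i])
            for k, v in g.items():
                grads[f"lstm{i}.{k}"] = v
        return np.ascontiguousarray(d[:, :, 0].T), grads

    @property
    def params(self) -> WeightSet:
        out: WeightSet = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"lstm{i}.{k}"] = v
        for k, v in self.head.params.items():
            out[f"head.{k}"] = v
        return out

    def set_params(self, weights: WeightSet) -> None:
        own = self.params
        for k, v in own.items():
            v[...] = weights[k]


class Discriminator:
    """4x (conv1d -> ReLU -> maxpool) + dense sigmoid head; (B, L) -> (B,) in (0,1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs = []
        c_in = 1
        L = spec.input_len
        for c_out in spec.channels:
            self.convs.append(nn.Conv1d(c_in, c_out, spec.kernel, rng))
            c_in = c_out
            L //= 2
        self.flat_dim = c_in * L
        self.head = nn.Dense(self.flat_dim, 1, rng)
        self.relu = nn.ReLU()
        self.pool = nn.MaxPool1d()

    def forward(self, x: np.ndarray, need_cache: bool = True):
        if x.ndim != 2 or x.shape[1] != self.spec.input_len:
            raise GanConfigError(
                f"discriminator expects (batch, {self.spec.input_len}), got {x.shape}"
            )
        h = np.ascontiguousarray(x, dtype=F32)[:, None, :]
        caches = []
        for conv in self.convs:
            h, c1 = conv.forward(h)
            h, c2 = self.relu.forward(h)
            h, c3 = self.pool.forward(h)
            caches.append((c1, c2, c3))
        B = h.shape[0]
        flat = h.reshape(B, self.flat_dim)
        logit, c4 = self.head.forward(flat)
        score = nn._sigmoid(logit[:, 0])
        caches.append((c4, score, h.shape))
        return (score, caches) if need_cache else (score, None)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, need_cache=False)[0]

    def backward(self, dscore: np.ndarray, caches,
                 need_param_grads: bool = True) -> tuple[np.ndarray, WeightSet]:
        c4, score, conv_shape = caches[-1]
        dlogit = (dscore * score * (1.0 - score)).astype(F32)[:, None]
        grads: WeightSet = {}
        d, g = self.head.backward(dlogit, c4, need_param_grads)
        for k, v in g.items():
            grads[f"head.{k}"] = v
        d = d.reshape(conv_shape)
        for i in range(len(self.convs) - 1, -1, -1):
            c1, c2, c3 = caches[i]
            d, _ = self.pool.backward(d, c3)
            d, _ = self.relu.backward(d, c2)
            d, g = self.convs[i].backward(d, c1, need_param_grads)
            for k, v in g.items():
                grads[f"conv{i}.{k}"] = v
        return d[:, 0, :], grads

    @property
    def params(self) -> WeightSet:
        out: WeightSet = {}
        for i, conv in enumerate(self.convs):
            for k, v in conv.params.items():
                out[f"conv{i}.{k}"] = v
        for k, v in self.head.params.items():
            out[f"head.{k}"] = v
        return out

    def set_params(self, weights: WeightSet) -> None:
        own = self.params
        for k, v in own.items():
            v[...] = weights[k]


def build_generator(spec: GeneratorSpec, seed: int) -> Generator:
    return Generator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> Discriminator:
    return Discriminator(spec, seed)


# ---------------------------------------------------------------------------
# the coupled 4-network model and its training step
# ---------------------------------------------------------------------------

@dataclass
class TrainOptions:
    """Optimizer settings (package defaults sized for desk-scale runs)."""

    lr: float = 2e-3
    beta1: float = 0.5
    beta2: float = 0.999


class CycleGan:
    """Container for the four coupled networks with flat weight export."""

    def __init__(self, gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec, seed: int):
        ss = np.random.SeedSequence(seed)
        s = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]
        self.p2a = Generator(gen_spec, s[0])
        self.a2p = Generator(gen_spec, s[1])
        self.d_a = Discriminator(disc_spec, s[2])
        self.d_p = Discriminator(disc_spec, s[3])
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec

    _PARTS = ("p2a", "a2p", "d_a", "d_p")

    def get_weights(self) -> WeightSet:
        out: WeightSet = {}
        for part in self._PARTS:
            for k, v in getattr(self, part).params.items():
                out[f"{part}.{k}"] = v.copy()
        return out

    def set_weights(self, weights: WeightSet) -> None:
        for part in self._PARTS:
            net = getattr(self, part)
            net.set_params({k[len(part) + 1:]: v for k, v in weights.items()
                            if k.startswith(part + ".")})


class CycleGanTrainer:
    """One generator update and one discriminator update per batch.

    Both updates are computed from the generator weights at batch start:
    the generator outputs produced for the generator objective are reused
    (detached) as the fake samples in the discriminator objective.
    """

    def __init__(self, model: CycleGan, weights: LossWeights = LossWeights(),
                 options: TrainOptions = TrainOptions()):
        weights.validate()
        self.model = model
        self.weights = weights
        self.opt_g = nn.Adam(options.lr, options.beta1, options.beta2)
        self.opt_d = nn.Adam(options.lr, options.beta1, options.beta2)

    def step(self, ppg: np.ndarray, abp: np.ndarray) -> LossBreakdown:
        return train_step(ppg, abp, self.model, self.opt_g, self.opt_d, self.weights)


def _merge_grads(*grad_dicts: WeightSet) -> WeightSet:
    out: WeightSet = {}
    for g in grad_dicts:
        for k, v in g.items():
            if k in out:
                out[k] = out[k] + v
            else:
                out[k] = v
    return out


def train_step(ppg: np.ndarray, abp: np.ndarray, model: CycleGan,
               opt_g: nn.Adam, opt_d: nn.Adam,
               weights: LossWeights) -> LossBreakdown:
    """One coupled optimization step on a batch of paired normalized segments.

    Raises :class:`TrainingDivergenceError` if any loss component is
    non-finite.
    """
    if ppg.ndim != 2 or ppg.shape != abp.shape or ppg.shape[0] < 1:
        raise ValueError(f"batch shapes must match and be non-empty: {ppg.shape} vs {abp.shape}")
    B, T = ppg.shape
    ppg = np.ascontiguousarray(ppg, dtype=F32)
    abp = np.ascontiguousarray(abp, dtype=F32)
    lam_c, lam_i = weights.lambda_c, weights.lambda_i

    # ---- generator forwards (translation + identity merged per network) ----
    pa_in = np.concatenate([ppg, abp], axis=0)       # rows [:B] translate, [B:] identity
    fa_all, cache_p2a = model.p2a.forward(pa_in)
    fake_a, idt_a = fa_all[:B], fa_all[B:]
    ap_in = np.concatenate([abp, ppg], axis=0)
    fp_all, cache_a2p = model.a2p.forward(ap_in)
    fake_p, idt_p = fp_all[:B], fp_all[B:]
    rec_p, cache_a2p_rec = model.a2p.forward(fake_a)
    rec_a, cache_p2a_rec = model.p2a.forward(fake_p)

    s_fake_a, cache_da_fake = model.d_a.forward(fake_a)
    s_fake_p, cache_dp_fake = model.d_p.forward(fake_p)

    adv_p2a = float(np.mean((s_fake_a - 1.0) ** 2))
    adv_a2p = float(np.mean((s_fake_p - 1.0) ** 2))
    cyc = float(np.mean(np.abs(ppg - rec_p)) + np.mean(np.abs(abp - rec_a)))
    idt = float(np.mean(np.abs(abp - idt_a)) + np.mean(np.abs(ppg - idt_p)))
    total = adv_p2a + adv_a2p + lam_c * cyc + lam_i * idt
    breakdown = LossBreakdown(adv_p2a, adv_a2p, cyc, idt, total)
    if not np.isfinite(breakdown.total):
        raise TrainingDivergenceError("non-finite generator loss", breakdown)

    # ---- generator backward ----
    n_el = F32(B * T)
    d_rec_p = (lam_c / n_el) * np.sign(rec_p - ppg).astype(F32)
    d_fake_a_cyc, g_a2p_rec = model.a2p.backward(d_rec_p, cache_a2p_rec)
    d_rec_a = (lam_c / n_el) * np.sign(rec_a - abp).astype(F32)
    d_fake_p_cyc, g_p2a_rec = model.p2a.backward(d_rec_a, cache_p2a_rec)

    d_s_fake_a = (2.0 / B) * (s_fake_a - 1.0)
    d_fake_a_adv, _ = model.d_a.backward(d_s_fake_a, cache_da_fake,
                                         need_param_grads=False)
    d_s_fake_p = (2.0 / B) * (s_fake_p - 1.0)
    d_fake_p_adv, _ = model.d_p.backward(d_s_fake_p, cache_dp_fake,
                                         need_param_grads=False)

    d_fa_all = np.empty_like(fa_all)
    d_fa_all[:B] = d_fake_a_cyc + d_fake_a_adv
    d_fa_all[B:] = (lam_i / n_el) * np.sign(idt_a - abp).astype(F32)
    _, g_p2a_main = model.p2a.backward(d_fa_all, cache_p2a)

    d_fp_all = np.empty_like(fp_all)
    d_fp_all[:B] = d_fake_p_cyc + d_fake_p_adv
    d_fp_all[B:] = (lam_i / n_el) * np.sign(idt_p - ppg).astype(F32)
    _, g_a2p_main = model.a2p.backward(d_fp_all, cache_a2p)

    g_p2a = _merge_grads(g_p2a_main, g_p2a_rec)
    g_a2p = _merge_grads(g_a2p_main, g_a2p_rec)
    gen_grads = {f"p2a.{k}": v for k, v in g_p2a.items()}
    gen_grads.update({f"a2p.{k}": v for k, v in g_a2p.items()})
    gen_params = {f"p2a.{k}": v for k, v in model.p2a.params.items()}
    gen_params.update({f"a2p.{k}": v for k, v in model.a2p.params.items()})
    opt_g.step(gen_params, gen_grads)

    # ---- discriminator update (fakes detached; caches reused) ----
    s_real_a, cache_da_real = model.d_a.forward(abp)
    s_real_p, cache_dp_real = model.d_p.forward(ppg)
    d_loss = 0.5 * float(np.mean((s_real_a - 1.0) ** 2) + np.mean(s_fake_a ** 2)
                         + np.mean((s_real_p - 1.0) ** 2) + np.mean(s_fake_p ** 2))
    if not np.isfinite(d_loss):
        raise TrainingDivergenceError("non-finite discriminator loss", breakdown)

    _, g_da_real = model.d_a.backward((1.0 / B) * (s_real_a - 1.0), cache_da_real)
    _, g_da_fake = model.d_a.backward((1.0 / B) * s_fake_a, cache_da_fake)
    _, g_dp_real = model.d_p.backward((1.0 / B) * (s_real_p - 1.0), cache_dp_real)
    _, g_dp_fake = model.d_p.backward((1.0 / B) * s_fake_p, cache_dp_fake)
    g_da = _merge_grads(g_da_real, g_da_fake)
    g_dp = _merge_grads(g_dp_real, g_dp_fake)
    disc_grads = {f"d_a.{k}": v for k, v in g_da.items()}
    disc_grads.update({f"d_p.{k}": v for k, v in g_dp.items()})
    disc_params = {f"d_a.{k}": v for k, v in model.d_a.params.items()}
    disc_params.update({f"d_p.{k}": v for k, v in model.d_p.params.items()})
    opt_d.step(disc_params, disc_grads)

    return breakdown


def train_loop(ppg: np.ndarray, abp: np.ndarray, trainer: CycleGanTrainer,
               epochs: int, batch_size: int,
               rng: np.random.Generator) -> list[LossBreakdown]:
    """Shuffled mini-batch epochs over a (N, L) paired dataset.

    The trailing partial batch is kept.  Returns one loss breakdown per
    optimization step in order.
    """
    N = ppg.shape[0]
    history: list[LossBreakdown] = []
    for _ in range(epochs):
        perm = rng.permutation(N)
        for start in range(0, N, batch_size):
            idx = perm[start : start + batch_size]
            history.append(trainer.step(ppg[idx], abp[idx]))
    return history


def translate(generator: Generator, segments: np.ndarray,
              batch_size: int = 64) -> np.ndarray:
    """Run a generator over (N, L) normalized segments in inference batches."""
    outs = [generator(segments[i : i + batch_size])
            for i in range(0, segments.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def save_weights(path, weights: WeightSet) -> None:
    np.savez(path, **weights)


def load_weights(path) -> WeightSet:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
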