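"""Contrastive-divergence and mean-field training for masked Boltzmann machines.

Single-pair networks (RBMs) are fit with k-step contrastive divergence:
the positive statistics come from the data with ``p(h|v)``, the negative
statistics from a k-step alternating Gibbs reconstruction started at the
data.  Two-hidden-layer networks (DBMs) are built by greedy layer-wise
pretraining of two RBMs, merged by averaging the shared layer's biases,
then trained jointly with mean-field variational inference for the
positive phase and persistent Markov chains for the negative phase.

Pruning masks are respected everywhere: a masked weight entry never
receives an update and stays exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core_bm import BoltzmannNet, conditional_on, gibbs_sweep, init_rbm
from .synthetic_data import BinaryDataset, ConnectivityMask

__all__ = [
    "TrainConfig",
    "MeanFieldResult",
    "cd_update",
    "train_rbm",
    "pretrain_stack",
    "mean_field_infer",
    "pcd_train",
    "data_driven_visible_bias",
]


@dataclass
class TrainConfig:
    """Hyper-parameters for CD/PCD training.

    The learning rate decays logarithmically from ``lr_start`` to
    ``lr_end`` over the epochs; momentum starts at ``momentum_initial``
    and switches to ``momentum`` at ``momentum_switch_epoch``.  With
    ``batch_size=1`` updates are applied after every training instance.
    """

    k: int = 1
    epochs: int = 2
    lr_start: float = 0.1
    lr_end: float = 0.01
    momentum: float = 0.9
    momentum_initial: float | None = None
    momentum_switch_epoch: int = 0
    batch_size: int = 1
    weight_init_sd: float = 0.1
    bias_init: float | str = 0.0
    weight_norm_cap: float | None = None
    n_persistent_chains: int = 100
    mf_damping: float = 0.8
    mf_tol: float = 1e-4
    mf_max_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lr_start < 0 or self.lr_end < 0:
            raise ValueError("learning rates must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.mf_damping <= 1:
            raise ValueError("mf_damping must lie in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        if self.epochs <= 1 or self.lr_start == 0:
            return self.lr_start
        frac = epoch / (self.epochs - 1)
        return float(self.lr_start * (self.lr_end / self.lr_start) ** frac)

    def momentum_at(self, epoch: int) -> float:
        if self.momentum_initial is not None and epoch < self.momentum_switch_epoch:
            return self.momentum_initial
        return self.momentum


def data_driven_visible_bias(data: BinaryDataset, clip: float = 1e-3) -> np.ndarray:
    """log-odds initial visible biases, log[p_i / (1 - p_i)] from pixel rates."""
    p = np.clip(data.patterns.mean(axis=0), clip, 1 - clip)
    return np.log(p / (1 - p))


# -- contrastive divergence (single RBM pair) ----------------------------------


def _cd_gradients(net, v, k, rng):
    """CD-k gradient estimates for one batch (mean over rows of v)."""
    w = net.effective_weights(0)
    bv, bh = net.biases
    ph_data = expit(bh + v @ w)
    h = (rng.random(ph_data.shape) < ph_data).astype(float)
    vk = v
    for _ in range(k):
        pv = expit(bv + h @ w.T)
        vk = (rng.random(pv.shape) < pv).astype(float)
        ph = expit(bh + vk @ w)
        h = (rng.random(ph.shape) < ph).astype(float)
    n = v.shape[0]
    g_w = (v.T @ ph_data - vk.T @ ph) / n
    g_bv = (v - vk).mean(axis=0)
    g_bh = (ph_data - ph).mean(axis=0)
    return g_w, g_bv, g_bh


def cd_update(
    net: BoltzmannNet,
    batch: np.ndarray | BinaryDataset,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
    velocity: dict | None = None,
    lr: float | None = None,
    momentum: float | None = None,
) -> BoltzmannNet:
    """One k-step contrastive-divergence parameter update (in place).

    The weight gradient is ⟨v h⟩ under the data minus ⟨v h⟩ under the
    k-step Gibbs reconstruction; bias gradients are the analogous rate
    differences.  Masked entries receive no update.
    """
    if net.n_pairs != 1:
        raise ValueError("cd_update applies to a single RBM pair")
    v = np.asarray(batch.patterns if isinstance(batch, BinaryDataset) else batch, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] != net.layer_sizes[0]:
        raise ValueError("batch width does not match visible layer")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lr = cfg.lr_start if lr is None else lr
    momentum = cfg.momentum if momentum is None else momentum
    g_w, g_bv, g_bh = _cd_gradients(net, v, cfg.k, rng)
    if velocity is None:
        velocity = {"w": np.zeros_like(net.weights[0]),
                    "bv": np.zeros_like(net.biases[0]),
                    "bh": np.zeros_like(net.biases[1])}
    velocity["w"] = momentum * velocity["w"] + lr * g_w
    velocity["bv"] = momentum * velocity["bv"] + lr * g_bv
    velocity["bh"] = momentum * velocity["bh"] + lr * g_bh
    net.weights[0] += velocity["w"] * net.masks[0]
    net.biases[0] += velocity["bv"]
    net.biases[1] += velocity["bh"]
    net.apply_masks()
    _cap_norms(net, cfg.weight_norm_cap)
    return net


def _cap_norms(net: BoltzmannNet, cap: float | None) -> None:
    """Rescale any weight matrix whose spectral norm exceeds the cap."""
    if cap is None:
        return
    for w in net.weights:
        s = np.linalg.norm(w, 2)
        if s > cap:
            w *= cap / s


def train_rbm(
    net: BoltzmannNet,
    data: BinaryDataset,
    cfg: TrainConfig,
    shuffle: bool = True,
) -> list[dict]:
    """Fit an RBM with CD-k over epochs; returns a per-epoch log.

    Updates are applied per mini-batch (``batch_size=1`` means after each
    training instance); the learning-rate and momentum schedules follow
    the config.  Deterministic given (seed, config, data).
    """
    rng = np.random.default_rng([cfg.seed, 0x7472])
    velocity = {"w": np.zeros_like(net.weights[0]),
                "bv": np.zeros_like(net.biases[0]),
                "bh": np.zeros_like(net.biases[1])}
    log = []
    x = data.patterns.astype(float)
    for epoch in range(cfg.epochs):
        lr, mom = cfg.lr_at(epoch), cfg.momentum_at(epoch)
        order = rng.permutation(len(x)) if shuffle else np.arange(len(x))
        recon_err = 0.0
        for start in range(0, len(x), cfg.batch_size):
            v = x[order[start : start + cfg.batch_size]]
            cd_update(net, v, cfg, rng=rng, velocity=velocity, lr=lr, momentum=mom)
        # one-step reconstruction error, logged per epoch
        w = net.effective_weights(0)
        ph = expit(net.biases[1] + x @ w)
        pv = expit(net.biases[0] + ph @ w.T)
        recon_err = float(np.mean((x - pv) ** 2))
        hidden_act = float(ph.mean())
        log.append({"epoch": epoch, "lr": lr, "momentum": mom,
                    "recon_mse": recon_err, "mean_hidden_activation": hidden_act})
    net.history.append({"stage": "train_rbm", "epochs": cfg.epochs, "seed": cfg.seed})
    return log


# -- DBM construction ----------------------------------------------------------


def pretrain_stack(
    data: BinaryDataset,
    hidden_sizes: tuple[int, int],
    cfgs: tuple[TrainConfig, TrainConfig],
    mask1: ConnectivityMask | None = None,
    seed: int | None = None,
) -> BoltzmannNet:
    """Greedy layer-wise pretraining of a two-hidden-layer network.

    RBM-1 (optionally with a receptive-field mask) is trained on the data;
    its hidden layer is then sampled once per training instance with the
    visible layer clamped, and those binary vectors train RBM-2.  The two
    RBMs are stacked into a DBM, with the shared layer's biases merged by
    averaging.
    """
    n_h1, n_h2 = hidden_sizes
    cfg1, cfg2 = cfgs
    seed = cfg1.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0x737461])

    def bias_value(cfg, d):
        if cfg.bias_init == "data":
            return data_driven_visible_bias(d)
        return float(cfg.bias_init)

    rbm1 = init_rbm(
        data.n_units, n_h1, weight_sd=cfg1.weight_init_sd,
        bias_v=bias_value(cfg1, data), bias_h=-2.0,
        mask=None if mask1 is None else mask1.mask, seed=rng,
    )
    train_rbm(rbm1, data, cfg1)

    w1 = rbm1.effective_weights(0)
    ph1 = expit(rbm1.biases[1] + data.patterns.astype(float) @ w1)
    h1_samples = (rng.random(ph1.shape) < ph1).astype(np.uint8)
    data2 = BinaryDataset(h1_samples)

    rbm2 = init_rbm(n_h1, n_h2, weight_sd=cfg2.weight_init_sd,
                    bias_v=bias_value(cfg2, data2), bias_h=-2.0, seed=rng)
    train_rbm(rbm2, data2, cfg2)

    merged_bias = 0.5 * (rbm1.biases[1] + rbm2.biases[0])
    dbm = BoltzmannNet(
        [rbm1.weights[0].copy(), rbm2.weights[0].copy()],
        [rbm1.biases[0].copy(), merged_bias, rbm2.biases[1].copy()],
        [rbm1.masks[0].copy(), rbm2.masks[0].copy()],
    )
    dbm.history.append({"stage": "pretrain_stack", "hidden_sizes": list(hidden_sizes)})
    return dbm


@dataclass
class MeanFieldResult:
    """Fixed-point layer means for clamped visible data."""

    means: list[np.ndarray]
    converged: bool
    n_iter: int


def mean_field_infer(
    net: BoltzmannNet,
    v: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    damping: float = 1.0,
) -> MeanFieldResult:
    """Damped fixed-point iteration for hidden-layer means given clamped v.

    Iterates mu^l <- (1-d) mu^l + d sigma(b^l + masked input from the
    adjacent layers' means) until the largest absolute change is below
    ``tol``.  The fixed point itself does not depend on the damping, only
    the approach to it.  Non-convergence is flagged, not raised.
    """
    if net.n_layers < 2:
        raise ValueError("need at least one hidden layer")
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    mus: list[np.ndarray] = [v] + [
        np.broadcast_to(expit(b), (v.shape[0], b.size)).copy()
        for b in net.biases[1:]
    ]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for l in range(1, net.n_layers):
            new = conditional_on(net, l, mus)
            step = damping * (new - mus[l])
            delta = max(delta, float(np.abs(step).max()))
            mus[l] = mus[l] + step
        if delta < tol:
            converged = True
            break
    return MeanFieldResult(mus, converged, it)


def pcd_train(
    net: BoltzmannNet,
    data: BinaryDataset,
    cfg: TrainConfig,
    shuffle: bool = True,
) -> list[dict]:
    """Joint DBM training: mean-field positive phase, persistent negative phase.

    Negative statistics come from ``n_persistent_chains`` free-running
    Gibbs chains that persist across parameter updates (one sweep per
    update).  After every update each weight matrix's spectral norm is
    clipped to ``weight_norm_cap``.  Works for RBMs too (the mean-field
    positive phase is then exact in one step).
    """
    rng = np.random.default_rng([cfg.seed, 0x706364])
    chains = [
        (rng.random((cfg.n_persistent_chains, n)) < 0.5).astype(float)
        for n in net.layer_sizes
    ]
    velocity_w = [np.zeros_like(w) for w in net.weights]
    velocity_b = [np.zeros_like(b) for b in net.biases]
    x = data.patterns.astype(float)
    log = []
    for epoch in range(cfg.epochs):
        lr, mom = cfg.lr_at(epoch), cfg.momentum_at(epoch)
        order = rng.permutation(len(x)) if shuffle else np.arange(len(x))
        for start in range(0, len(x), cfg.batch_size):
            v = x[order[start : start + cfg.batch_size]]
            mf = mean_field_infer(net, v, tol=cfg.mf_tol,
                                  max_iter=cfg.mf_max_iter, damping=cfg.mf_damping)
            gibbs_sweep(net, chains, rng)
            nb = v.shape[0]
            nc = cfg.n_persistent_chains
            for l in range(net.n_pairs):
                pos = mf.means[l].T @ mf.means[l + 1] / nb
                neg = chains[l].T @ chains[l + 1] / nc
                velocity_w[l] = mom * velocity_w[l] + lr * (pos - neg)
                net.weights[l] += velocity_w[l] * net.masks[l]
            for l in range(net.n_layers):
                gb = mf.means[l].mean(axis=0) - chains[l].mean(axis=0)
                velocity_b[l] = mom * velocity_b[l] + lr * gb
                net.biases[l] += velocity_b[l]
            net.apply_masks()
            _cap_norms(net, cfg.weight_norm_cap)
        mf_all = mean_field_infer(net, x[: min(len(x), 1000)], tol=cfg.mf_tol,
                                  max_iter=cfg.mf_max_iter, damping=cfg.mf_damping)
        log.append({
            "epoch": epoch, "lr": lr, "momentum": mom,
            "mean_hidden_activation": [float(m.mean()) for m in mf_all.means[1:]],
        })
    net.history.append({"stage": "pcd_train", "epochs": cfg.epochs, "seed": cfg.seed})
    return log
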