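"""Bernoulli restricted and deep Boltzmann machines with prunable masked weights.

A :class:`BoltzmannNet` holds an ordered stack of binary layers (visible
layer first, up to two hidden layers) with symmetric weights between
consecutive layers.  Every weight matrix carries a congruent binary mask:
pruning a synapse means zeroing its mask entry, the stored value is kept
until the unit is structurally removed.  The energy of a joint state
``(v, h^1, h^2)`` is

    E = - sum_l b^l . s^l  -  sum_l s^l . (W^l * M^l) . s^{l+1}

and the model distribution is the Boltzmann distribution
``p(s) = exp(-E(s)) / Z`` at unit temperature.  Tiny networks (<= 24 units
in total) can be enumerated exactly, which serves as the oracle for the
sampling and Fisher-information code.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "BoltzmannNet",
    "NetworkState",
    "init_rbm",
    "init_dbm",
    "energy",
    "conditional_on",
    "gibbs_chain",
    "gibbs_sweep",
    "sample_clamped_hidden",
    "exact_distribution",
    "exact_marginal_visible",
    "enumerate_states",
    "save_net",
    "load_net",
]

#: hard cap for exhaustive enumeration (2**24 joint states)
MAX_ENUM_UNITS = 24


@dataclass
class BoltzmannNet:
    """Layered Boltzmann machine parameters with per-weight binary masks.

    Parameters
    ----------
    weights
        ``weights[l]`` has shape ``(n_l, n_{l+1})`` and couples layer ``l``
        to layer ``l + 1``.
    biases
        ``biases[l]`` has shape ``(n_l,)``.
    masks
        Binary (uint8) arrays congruent to ``weights``.  Masked-out entries
        of the stored weights are forced to exactly zero.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    masks: list[np.ndarray] = field(default=None)  # type: ignore[assignment]
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        if self.masks is None:
            self.masks = [np.ones_like(w, dtype=np.uint8) for w in self.weights]
        else:
            self.masks = [np.asarray(m, dtype=np.uint8) for m in self.masks]
        if len(self.weights) != len(self.biases) - 1:
            raise ValueError("need exactly one weight matrix per consecutive layer pair")
        if not 1 <= len(self.weights) <= 2:
            raise ValueError("supported depth: one or two hidden layers")
        for l, (w, m) in enumerate(zip(self.weights, self.masks)):
            if w.shape != m.shape:
                raise ValueError(f"mask {l} not congruent with weight matrix {l}")
            if w.shape != (self.biases[l].size, self.biases[l + 1].size):
                raise ValueError(f"weight matrix {l} inconsistent with layer sizes")
        self.apply_masks()

    # -- structural properties -------------------------------------------------

    @property
    def layer_sizes(self) -> list[int]:
        return [b.size for b in self.biases]

    @property
    def n_layers(self) -> int:
        return len(self.biases)

    @property
    def n_units(self) -> int:
        return int(sum(self.layer_sizes))

    @property
    def n_pairs(self) -> int:
        return len(self.weights)

    def n_live_weights(self, pair: int | None = None) -> int:
        """Number of unpruned weights, in one layer pair or in total."""
        if pair is not None:
            return int(self.masks[pair].sum())
        return int(sum(int(m.sum()) for m in self.masks))

    def effective_weights(self, pair: int) -> np.ndarray:
        return self.weights[pair] * self.masks[pair]

    def apply_masks(self) -> None:
        """Force masked-out weight entries to exactly zero (idempotent)."""
        for w, m in zip(self.weights, self.masks):
            w *= m

    def copy(self) -> "BoltzmannNet":
        return BoltzmannNet(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            [m.copy() for m in self.masks],
            history=[dict(h) for h in self.history],
        )

    def check_state(self, state: "NetworkState") -> None:
        if len(state) != self.n_layers:
            raise ValueError("state has wrong number of layers")
        for s, n in zip(state, self.layer_sizes):
            if np.shape(s)[-1] != n:
                raise ValueError("state layer width mismatch")


#: a joint configuration: one {0,1} vector per layer (leading axes allowed
#: for batches of parallel chains)
NetworkState = list


def init_rbm(
    n_v: int,
    n_h: int,
    weight_sd: float = 0.1,
    bias_v: float | np.ndarray = 0.0,
    bias_h: float | np.ndarray = 0.0,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> BoltzmannNet:
    """Gaussian-initialised single-pair network (one visible, one hidden layer)."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, weight_sd, size=(n_v, n_h))
    bv = np.broadcast_to(np.asarray(bias_v, dtype=float), (n_v,)).copy()
    bh = np.broadcast_to(np.asarray(bias_h, dtype=float), (n_h,)).copy()
    masks = None if mask is None else [np.asarray(mask, dtype=np.uint8)]
    return BoltzmannNet([w], [bv, bh], masks)


def init_dbm(
    sizes: list[int],
    weight_sd: float = 0.1,
    biases: list[float] | None = None,
    masks: list[np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> BoltzmannNet:
    """Gaussian-initialised two-hidden-layer network."""
    rng = np.random.default_rng(seed)
    ws = [rng.normal(0.0, weight_sd, size=(a, b)) for a, b in zip(sizes, sizes[1:])]
    bvals = biases if biases is not None else [0.0] * len(sizes)
    bs = [np.full(n, float(b)) for n, b in zip(sizes, bvals)]
    return BoltzmannNet(ws, bs, masks)


# -- energies and conditionals -------------------------------------------------


def energy(net: BoltzmannNet, state: NetworkState) -> float | np.ndarray:
    """Energy of a joint configuration (vectorised over leading axes).

    All-zero states have energy zero for any parameters; lower energy means
    higher probability.
    """
    net.check_state(state)
    layers = [np.asarray(s, dtype=float) for s in state]
    e = 0.0
    for b, s in zip(net.biases, layers):
        e = e - s @ b
    for l in range(net.n_pairs):
        w = net.effective_weights(l)
        e = e - np.sum((layers[l] @ w) * layers[l + 1], axis=-1)
    return e


def conditional_on(
    net: BoltzmannNet, layer_index: int, neighbor_states: NetworkState
) -> np.ndarray:
    """On-probabilities of one layer given the states of its neighbours.

    ``neighbor_states`` is a full per-layer state list; only the layers
    adjacent to ``layer_index`` are read.  The middle layer of a DBM
    receives summed input from both sides.
    """
    if not 0 <= layer_index < net.n_layers:
        raise ValueError("layer index out of range")
    field_ = net.biases[layer_index].astype(float)
    touched = False
    if layer_index > 0:
        below = neighbor_states[layer_index - 1]
        if below is None:
            raise ValueError("missing neighbour state below")
        field_ = field_ + np.asarray(below, dtype=float) @ net.effective_weights(layer_index - 1)
        touched = True
    if layer_index < net.n_layers - 1:
        above = neighbor_states[layer_index + 1]
        if above is None:
            raise ValueError("missing neighbour state above")
        field_ = field_ + np.asarray(above, dtype=float) @ net.effective_weights(layer_index).T
        touched = True
    if not touched:
        raise ValueError("layer has no neighbours")
    return expit(field_)


def gibbs_sweep(
    net: BoltzmannNet,
    states: NetworkState,
    rng: np.random.Generator,
    clamped: tuple[int, ...] = (),
) -> NetworkState:
    """One in-place alternating-layer Gibbs update.

    Even-indexed layers are resampled first, then odd-indexed layers; for a
    DBM this updates v and h^2 given h^1, then h^1 given both.  Layers in
    ``clamped`` are left untouched.
    """
    order = [l for l in range(net.n_layers) if l % 2 == 0] + [
        l for l in range(net.n_layers) if l % 2 == 1
    ]
    for l in order:
        if l in clamped:
            continue
        p = conditional_on(net, l, states)
        states[l] = (rng.random(np.shape(states[l])) < p).astype(float)
    return states


def _random_states(net, rng, n_chains=None):
    shape = (lambda n: (n,)) if n_chains is None else (lambda n: (n_chains, n))
    return [(rng.random(shape(n)) < 0.5).astype(float) for n in net.layer_sizes]


def gibbs_chain(
    net: BoltzmannNet,
    init_state: NetworkState | None = None,
    n_steps: int = 1,
    thin: int = 200,
    seed: int | np.random.Generator = 0,
    n_chains: int | None = None,
) -> list[NetworkState]:
    """Run alternating Gibbs sampling and return every ``thin``-th state.

    ``n_steps`` counts *stored* samples; ``thin`` full sweeps separate
    consecutive stored states (the default of 200 decorrelates layer
    states).  With ``n_chains`` set, that many chains evolve in parallel
    and each stored state has a leading chain axis.  Deterministic given
    the seed.
    """
    if n_steps < 1 or thin < 1:
        raise ValueError("n_steps and thin must be >= 1")
    rng = np.random.default_rng(seed)
    if init_state is None:
        states = _random_states(net, rng, n_chains)
    else:
        states = [np.array(s, dtype=float) for s in init_state]
    net.check_state(states)
    out = []
    for _ in range(n_steps):
        for _ in range(thin):
            gibbs_sweep(net, states, rng)
        out.append([s.copy() for s in states])
    return out


def sample_clamped_hidden(
    net: BoltzmannNet,
    visible: np.ndarray,
    n_sweeps: int = 10,
    seed: int | np.random.Generator = 0,
) -> NetworkState:
    """Sample hidden layers with the visible layer clamped to data rows.

    Runs ``n_sweeps`` Gibbs sweeps over the hidden layers only, vectorised
    across the rows of ``visible``; for an RBM one sweep is an exact sample
    from ``p(h | v)``.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(visible, dtype=float)
    states = [v] + [
        (rng.random(v.shape[:-1] + (n,)) < 0.5).astype(float)
        for n in net.layer_sizes[1:]
    ]
    n_sweeps = 1 if net.n_layers == 2 else n_sweeps
    for _ in range(n_sweeps):
        gibbs_sweep(net, states, rng, clamped=(0,))
    return states


# -- exact enumeration (the oracle) -------------------------------------------


def enumerate_states(n_units: int) -> np.ndarray:
    """All 2**n binary vectors; row ``i`` encodes ``i`` with unit k = bit k."""
    if n_units > MAX_ENUM_UNITS:
        raise ValueError(f"enumeration limited to {MAX_ENUM_UNITS} units")
    idx = np.arange(2**n_units, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n_units)) & 1).astype(np.float64)


def _joint_energy_table(net: BoltzmannNet) -> tuple[np.ndarray, list[np.ndarray]]:
    n = net.n_units
    if n > MAX_ENUM_UNITS:
        raise ValueError(
            f"exact enumeration refused: {n} units exceeds the {MAX_ENUM_UNITS}-unit guard"
        )
    s = enumerate_states(n)
    splits = np.cumsum(net.layer_sizes)[:-1]
    layers = np.split(s, splits, axis=1)
    e = np.zeros(s.shape[0])
    for b, sl in zip(net.biases, layers):
        e -= sl @ b
    for l in range(net.n_pairs):
        e -= np.sum((layers[l] @ net.effective_weights(l)) * layers[l + 1], axis=1)
    return e, layers


def exact_distribution(net: BoltzmannNet) -> np.ndarray:
    """Exact joint probability of every configuration of a tiny network.

    Entry ``i`` is the probability of the joint state whose concatenated
    unit vector encodes ``i`` in binary (unit k = bit k, visible units in
    the low bits).  Sums to one.
    """
    e, _ = _joint_energy_table(net)
    logp = -e - logsumexp(-e)
    return np.exp(logp)


def exact_marginal_visible(net: BoltzmannNet) -> np.ndarray:
    """Exact marginal p(v), summing the joint table over all hidden states."""
    p = exact_distribution(net)
    n_v = net.layer_sizes[0]
    vis_idx = np.arange(p.size, dtype=np.int64) & ((1 << n_v) - 1)
    return np.bincount(vis_idx, weights=p, minlength=2**n_v)


# -- checkpoint archive --------------------------------------------------------


def save_net(net: BoltzmannNet, path) -> None:
    """Write a checkpoint archive (npz): sizes, weights, biases, masks, history."""
    arrays = {"layer_sizes": np.asarray(net.layer_sizes)}
    for l, (w, m) in enumerate(zip(net.weights, net.masks)):
        arrays[f"weights_{l}"] = w
        arrays[f"masks_{l}"] = m
    for l, b in enumerate(net.biases):
        arrays[f"biases_{l}"] = b
    arrays["history_json"] = np.frombuffer(
        json.dumps(net.history).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_net(path) -> BoltzmannNet:
    """Load a checkpoint archive written by :func:`save_net` (bit-exact)."""
    with np.load(path if not isinstance(path, io.IOBase) else path) as z:
        sizes = z["layer_sizes"]
        n_pairs = len(sizes) - 1
        weights = [z[f"weights_{l}"] for l in range(n_pairs)]
        masks = [z[f"masks_{l}"] for l in range(n_pairs)]
        biases = [z[f"biases_{l}"] for l in range(len(sizes))]
        history = json.loads(bytes(z["history_json"]).decode()) if "history_json" in z else []
    return BoltzmannNet(weights, biases, masks, history=history)
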