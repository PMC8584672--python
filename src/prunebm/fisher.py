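"""Local and exact estimates of parameter importance via Fisher information.

For a Boltzmann machine the Fisher information matrix (FIM) is the
covariance, under the model distribution, of the per-parameter energy
gradients: ``v_i h_j`` for a weight, ``v_i`` or ``h_j`` for a bias.  Its
diagonal is locally available to a synapse — for a weight it reduces to

    F_ww = <v h> (1 - <v h>)

because the units are binary ("variance" estimate).  A further mean-field
step removes the need to track coincidences at all: the pre-post
coincidence is approximated from the synaptic weight and the two mean
firing rates alone ("heuristic" estimate),

    <v h>  ~=  <v><h> / (<v> + (1 - <v>) exp(-w (1 - <h>))).

Tiny networks are handled exactly by state enumeration, which is the
oracle every sampled estimate is tested against.  Eigenvector importance
(the magnitude each parameter receives in the FIM's leading eigenvector)
is provided for the full-matrix criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_bm import BoltzmannNet, _joint_energy_table, exact_distribution, gibbs_sweep, \
    sample_clamped_hidden
from .synthetic_data import BinaryDataset

__all__ = [
    "ActivityStats",
    "ImportanceEstimate",
    "collect_stats",
    "exact_activity_stats",
    "fim_exact",
    "fim_param_labels",
    "fim_diag_variance",
    "heuristic_coincidence",
    "heuristic_importance",
    "importance_table",
    "leading_eigen_importance",
    "eigen_importance",
]

RATE_CLIP = 1e-6  # log-odds of a rate are undefined at exactly {0, 1}

CRITERIA = (
    "variance_fi",
    "heuristic_fi",
    "first_eigenvector",
    "weight_magnitude",
    "anti_fi",
    "random_weight",
    "random_unit",
)


@dataclass
class ActivityStats:
    """Sampled firing rates and pre-post coincidences for one layer pair."""

    mean_pre: np.ndarray
    mean_post: np.ndarray
    coincidence: np.ndarray
    n_samples: int
    source: str  # {gibbs | clamped | exact}
    low_sample_warning: bool = False

    def __post_init__(self) -> None:
        for a in (self.mean_pre, self.mean_post, self.coincidence):
            if np.any((a < -1e-12) | (a > 1 + 1e-12)):
                raise ValueError("activity statistics must lie in [0, 1]")
        if self.coincidence.shape != (self.mean_pre.size, self.mean_post.size):
            raise ValueError("coincidence shape mismatch")


@dataclass
class ImportanceEstimate:
    """Per-parameter importance for one weight matrix (plus optional biases).

    ``values`` is congruent with the layer pair's weight matrix; masked
    (pruned) entries are NaN and are never consulted.  FI-based criteria
    produce non-negative values.
    """

    values: np.ndarray
    criterion: str
    layer_pair: int
    bias_pre: np.ndarray | None = None
    bias_post: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        live = self.values[~np.isnan(self.values)]
        if not np.isfinite(live).all():
            raise ValueError("importance values must be finite")
        if self.criterion in ("variance_fi", "heuristic_fi", "first_eigenvector") and (
            live < -1e-12
        ).any():
            raise ValueError("FI-based importances must be non-negative")


# -- activity statistics -------------------------------------------------------


def _pair_stats(sums, co_sums, n, source, warn):
    out = []
    for l, co in enumerate(co_sums):
        out.append(
            ActivityStats(
                mean_pre=sums[l] / n,
                mean_post=sums[l + 1] / n,
                coincidence=co / n,
                n_samples=n,
                source=source,
                low_sample_warning=warn,
            )
        )
    return out


def collect_stats(
    net: BoltzmannNet,
    mode: str = "free",
    data: BinaryDataset | np.ndarray | None = None,
    n_samples: int | None = None,
    thin: int = 200,
    seed: int = 0,
    n_chains: int = 100,
    burn_in: int | None = None,
    estimator: str = "sample",
) -> list[ActivityStats]:
    """Layer means and pairwise coincidences from Gibbs samples.

    ``free`` mode runs ``n_chains`` parallel free chains, storing one
    thinned state per chain every ``thin`` sweeps until at least
    ``n_samples`` stored layer states are accumulated.  ``clamped`` mode
    clamps the visible layer to each data row and either samples the
    hidden layers once per instance (``estimator='sample'``, exact for an
    RBM) or uses the conditional hidden probabilities in place of spikes
    (``estimator='expectation'``, a Rao-Blackwellised estimate with far
    lower variance at the same instance count).  Returns one
    :class:`ActivityStats` per layer pair; fewer than 100 samples sets a
    warning flag.
    """
    rng = np.random.default_rng([seed, 0x7374])
    if mode == "clamped":
        if data is None:
            raise ValueError("clamped mode needs a dataset")
        v = np.asarray(
            data.patterns if isinstance(data, BinaryDataset) else data, dtype=float
        )
        n = v.shape[0]
        if estimator == "expectation":
            from .training import mean_field_infer

            mf = mean_field_infer(net, v, damping=1.0, max_iter=100, tol=1e-10)
            states = mf.means
        else:
            states = sample_clamped_hidden(net, v, seed=rng)
        sums = [s.sum(axis=0) for s in states]
        co = [states[l].T @ states[l + 1] for l in range(net.n_pairs)]
        return _pair_stats(sums, co, n, "clamped", n < 100)
    if mode != "free":
        raise ValueError("mode must be 'free' or 'clamped'")

    if n_samples is None:
        n_samples = 10_000
    n_chains = min(n_chains, n_samples)
    n_store = -(-n_samples // n_chains)  # stored steps per chain
    states = [(rng.random((n_chains, n)) < 0.5).astype(float) for n in net.layer_sizes]
    burn = 2 * thin if burn_in is None else burn_in
    for _ in range(burn):
        gibbs_sweep(net, states, rng)
    sums = [np.zeros(n) for n in net.layer_sizes]
    co = [np.zeros(w.shape) for w in net.weights]
    for _ in range(n_store):
        for _ in range(thin):
            gibbs_sweep(net, states, rng)
        for l, s in enumerate(states):
            sums[l] += s.sum(axis=0)
        for l in range(net.n_pairs):
            co[l] += states[l].T @ states[l + 1]
    n = n_store * n_chains
    return _pair_stats(sums, co, n, "gibbs", n < 100)


def exact_activity_stats(net: BoltzmannNet) -> list[ActivityStats]:
    """Exact means and coincidences from the enumerated joint distribution."""
    p = exact_distribution(net)
    _, layers = _joint_energy_table(net)
    means = [p @ sl for sl in layers]
    out = []
    for l in range(net.n_pairs):
        co = (layers[l] * p[:, None]).T @ layers[l + 1]
        out.append(
            ActivityStats(means[l], means[l + 1], co, n_samples=p.size, source="exact")
        )
    return out


# -- exact FIM (oracle) --------------------------------------------------------


def _gradient_statistics(net: BoltzmannNet):
    """Per-state energy-gradient statistics, one column per live parameter."""
    _, layers = _joint_energy_table(net)
    n_states = layers[0].shape[0]
    cols, labels = [], []
    for l in range(net.n_pairs):
        live = np.argwhere(net.masks[l] == 1)
        prod = layers[l][:, live[:, 0]] * layers[l + 1][:, live[:, 1]]
        cols.append(prod)
        labels += [("w", l, int(i), int(j)) for i, j in live]
    for l in range(net.n_layers):
        cols.append(layers[l])
        labels += [("b", l, int(i)) for i in range(net.layer_sizes[l])]
    return np.concatenate(cols, axis=1), labels


def fim_exact(net: BoltzmannNet) -> np.ndarray:
    """Exact Fisher information matrix by state enumeration.

    Rows/columns run over live weights (per layer pair, row-major) followed
    by biases layer by layer; see :func:`fim_param_labels` for the order.
    Symmetric and positive semi-definite up to numerical error.
    """
    p = exact_distribution(net)
    g, _ = _gradient_statistics(net)
    mean = p @ g
    f = (g * p[:, None]).T @ g - np.outer(mean, mean)
    return 0.5 * (f + f.T)


def fim_param_labels(net: BoltzmannNet) -> list[tuple]:
    """Parameter labels aligned with :func:`fim_exact` rows: ('w', pair, i, j) or ('b', layer, i)."""
    _, labels = _gradient_statistics(net)
    return labels


# -- local diagonal estimates --------------------------------------------------


def fim_diag_variance(
    stats: ActivityStats,
    mask: np.ndarray | None = None,
    layer_pair: int = 0,
) -> ImportanceEstimate:
    """Variance estimate of the FIM diagonal from coincidence statistics.

    Weight importance is ``c (1 - c)`` with ``c = <v h>``; bias importance
    is the firing-rate variance ``m (1 - m)``.  A silent or saturated unit
    therefore renders all its synapses zero-importance.
    """
    c = np.clip(stats.coincidence, 0.0, 1.0)
    values = c * (1.0 - c)
    if mask is not None:
        if mask.shape != values.shape:
            raise ValueError("mask shape does not match statistics")
        values = np.where(mask == 1, values, np.nan)
    mp, mq = np.clip(stats.mean_pre, 0, 1), np.clip(stats.mean_post, 0, 1)
    return ImportanceEstimate(
        values, "variance_fi", layer_pair,
        bias_pre=mp * (1 - mp), bias_post=mq * (1 - mq),
    )


def heuristic_coincidence(
    w: np.ndarray | float, mean_v: np.ndarray | float, mean_h: np.ndarray | float
) -> np.ndarray:
    """Mean-field approximation of <v h> from the weight and the mean rates.

    Broadcasts: ``w`` of shape (n_v, n_h) against rates of shape (n_v,)
    and (n_h,).  At ``w = 0`` it returns exactly ``<v><h>``; rates at the
    boundary {0, 1} are clipped before the implicit log-odds inversion, so
    the analytic limit ``<v><h>`` is returned instead of raising.
    """
    w = np.asarray(w, dtype=float)
    mv = np.clip(np.asarray(mean_v, dtype=float), RATE_CLIP, 1 - RATE_CLIP)
    mh = np.clip(np.asarray(mean_h, dtype=float), RATE_CLIP, 1 - RATE_CLIP)
    if w.ndim == 2:
        mv = mv[:, None]
        mh = mh[None, :]
    denom = mv + (1.0 - mv) * np.exp(-w * (1.0 - mh))
    return mv * mh / denom


def heuristic_importance(
    net: BoltzmannNet,
    stats: ActivityStats,
    layer_pair: int = 0,
) -> ImportanceEstimate:
    """Heuristic FI: plug the mean-field coincidence into c(1-c).

    Uses only each synapse's own weight and the two units' mean rates —
    the fully local criterion.
    """
    c = np.clip(
        heuristic_coincidence(
            net.effective_weights(layer_pair), stats.mean_pre, stats.mean_post
        ),
        0.0,
        1.0,
    )
    values = np.where(net.masks[layer_pair] == 1, c * (1 - c), np.nan)
    return ImportanceEstimate(values, "heuristic_fi", layer_pair)


# -- eigenvector importance ----------------------------------------------------


def importance_table(estimates: list[ImportanceEstimate]):
    """Flatten importance estimates to a tidy table (layer_pair, i, j, criterion, value)."""
    import pandas as pd

    rows = []
    for est in estimates:
        live = np.argwhere(~np.isnan(est.values))
        for i, j in live:
            rows.append({
                "layer_pair": est.layer_pair, "i": int(i), "j": int(j),
                "criterion": est.criterion, "value": float(est.values[i, j]),
            })
    return pd.DataFrame(rows)


def leading_eigen_importance(f: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Leading-eigenvector magnitudes of a (symmetric) FIM.

    Returns ``|u|`` per parameter plus the top two eigenvalues.  For a
    rank-1 matrix ``lambda u u^T`` the squared magnitudes are proportional
    to the diagonal, which is what justifies the diagonal as a proxy.
    """
    f = np.asarray(f, dtype=float)
    if f.shape[0] != f.shape[1] or not np.allclose(f, f.T, atol=1e-8):
        raise ValueError("FIM must be symmetric")
    evals, evecs = np.linalg.eigh(f)
    lam0, lam1 = float(evals[-1]), float(evals[-2]) if f.shape[0] > 1 else 0.0
    return np.abs(evecs[:, -1]), (lam0, lam1)


def eigen_importance(net: BoltzmannNet) -> list[ImportanceEstimate]:
    """Full-FIM eigenvector criterion mapped back onto the weight matrices.

    Only feasible for enumerable networks; each live weight receives the
    magnitude of its entry in the leading eigenvector.
    """
    f = fim_exact(net)
    u, _ = leading_eigen_importance(f)
    labels = fim_param_labels(net)
    out = []
    for l in range(net.n_pairs):
        values = np.full(net.weights[l].shape, np.nan)
        for mag, lab in zip(u, labels):
            if lab[0] == "w" and lab[1] == l:
                values[lab[2], lab[3]] = mag
        out.append(ImportanceEstimate(values, "first_eigenvector", l))
    return out
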