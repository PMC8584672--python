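"""Generative and encoding performance of (pruned) Boltzmann machines.

Generative fit is assessed on the visible-pattern level: the empirical
distribution of free-running model samples is compared to the empirical
data distribution with KL(data || model) and with the mean squared error
between matched log-probabilities.  Encoding quality is the held-out
accuracy of a multinomial logistic classifier trained on sampled
final-hidden-layer states (the classifier is an instrument, not part of
the model).  Generated-pattern quality is the mean confidence a
raw-data classifier assigns to its winning class, and diversity is the
entropy of the winning-class histogram (nats; at most ln n_classes,
about 2.30 nats for ten balanced classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as shannon_entropy
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .core_bm import BoltzmannNet, exact_marginal_visible, gibbs_chain
from .synthetic_data import BinaryDataset
from .training import mean_field_infer

__all__ = [
    "EvalReport",
    "empirical_distribution",
    "patterns_to_codes",
    "kl_data_model",
    "logprob_match_mse",
    "default_epsilon",
    "sample_visible",
    "generative_fit",
    "encoding_quality",
    "train_reference_classifier",
    "generative_scores",
    "activation_monitor",
]

MAX_TABULATE_UNITS = 24


@dataclass
class EvalReport:
    """Bundle of evaluation metrics for one model state."""

    kl_data_model: float | None = None
    logprob_mse: float | None = None
    encoding_accuracy: float | None = None
    raw_baseline_accuracy: float | None = None
    quality_score: float | None = None
    diversity_entropy: float | None = None
    mean_hidden_activation: list[float] | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# -- pattern distributions -----------------------------------------------------


def patterns_to_codes(patterns: np.ndarray) -> np.ndarray:
    """Encode binary rows as integers (unit k = bit k)."""
    patterns = np.asarray(patterns)
    if patterns.shape[1] > MAX_TABULATE_UNITS:
        raise ValueError(f"tabulation limited to {MAX_TABULATE_UNITS} units")
    weights = (1 << np.arange(patterns.shape[1])).astype(np.int64)
    return patterns.astype(np.int64) @ weights


def empirical_distribution(patterns: np.ndarray) -> pd.Series:
    """Normalised frequency of each distinct binary pattern.

    Indexed by the integer code of the pattern; sums to one.
    """
    codes = patterns_to_codes(patterns)
    counts = pd.Series(codes).value_counts(sort=False)
    return counts / counts.sum()


def default_epsilon(n_model_samples: int) -> float:
    """Probability floor for patterns the model never produced.

    Laplace-style smoothing scaled to the sample size: one tenth of a
    single-sample probability.
    """
    return 1.0 / (10.0 * max(1, n_model_samples))


def _aligned(p: pd.Series, q: pd.Series, epsilon: float):
    support = p.index.union(q.index)
    qv = q.reindex(support, fill_value=0.0).to_numpy(dtype=float)
    qv = np.maximum(qv, epsilon)
    qv /= qv.sum()
    pv = p.reindex(support, fill_value=0.0).to_numpy(dtype=float)
    return pv, qv


def kl_data_model(data_dist: pd.Series, model_dist: pd.Series, epsilon: float = 1e-6) -> float:
    """KL(data || model) in nats over the union pattern support.

    Model probabilities are floored at ``epsilon`` and renormalised before
    the divergence is taken, so patterns the model never generated
    contribute a large but finite penalty.  Non-negative; zero iff the
    distributions agree on the tabulated support.
    """
    pv, qv = _aligned(data_dist, model_dist, epsilon)
    nz = pv > 0
    return float(np.sum(pv[nz] * np.log(pv[nz] / qv[nz])))


def logprob_match_mse(
    data_dist: pd.Series, model_dist: pd.Series, epsilon: float = 1e-6
) -> float:
    """Mean squared log-probability mismatch over data-observed patterns.

    For each pattern seen in the data, the squared difference between its
    data log-probability and its (epsilon-floored) model log-probability;
    a pattern the model misses contributes ``(log p - log eps)^2``.
    """
    qv = model_dist.reindex(data_dist.index, fill_value=0.0).to_numpy(dtype=float)
    qv = np.maximum(qv, epsilon)
    pv = data_dist.to_numpy(dtype=float)
    return float(np.mean((np.log(pv) - np.log(qv)) ** 2))


# -- model sampling ------------------------------------------------------------


def sample_visible(
    net: BoltzmannNet,
    n_samples: int,
    thin: int = 200,
    seed: int = 0,
    n_chains: int = 100,
) -> np.ndarray:
    """Visible patterns from free-running thinned Gibbs chains."""
    n_chains = min(n_chains, n_samples)
    n_store = -(-n_samples // n_chains)
    stored = gibbs_chain(net, n_steps=n_store, thin=thin, seed=seed, n_chains=n_chains)
    vis = np.concatenate([s[0] for s in stored], axis=0)[:n_samples]
    return vis.astype(np.uint8)


def generative_fit(
    net: BoltzmannNet,
    data: BinaryDataset,
    n_samples: int | None = None,
    thin: int = 20,
    seed: int = 0,
    exact: bool = False,
    epsilon: float | None = None,
) -> dict:
    """KL(data || model) and log-probability MSE for one model.

    With ``exact=True`` (enumerable networks) the exact visible marginal
    replaces sampling; otherwise the model side is the empirical
    distribution of ``n_samples`` generated patterns (default: as many as
    there are training instances).
    """
    p = empirical_distribution(data.patterns)
    if exact:
        pv = exact_marginal_visible(net)
        q = pd.Series(pv, index=np.arange(pv.size))
        q = q[q > 0]
        n_model = data.n_samples
    else:
        n_model = n_samples or data.n_samples
        q = empirical_distribution(sample_visible(net, n_model, thin=thin, seed=seed))
    eps = default_epsilon(n_model) if epsilon is None else epsilon
    return {
        "kl_data_model": kl_data_model(p, q, eps),
        "logprob_mse": logprob_match_mse(p, q, eps),
    }


# -- classifier-based metrics --------------------------------------------------


def _fit_classifier(x, y, seed, max_iter=500):
    clf = LogisticRegression(max_iter=max_iter, C=1.0, random_state=seed)
    clf.fit(x, y)
    return clf


def train_reference_classifier(data: BinaryDataset, seed: int = 0) -> LogisticRegression:
    """Multinomial logistic classifier on the raw labeled patterns."""
    if data.labels is None:
        raise ValueError("reference classifier needs labels")
    return _fit_classifier(data.patterns, data.labels, seed)


def encoding_quality(
    net: BoltzmannNet,
    data: BinaryDataset,
    seed: int = 0,
    test_size: float = 0.2,
    return_baseline: bool = False,
):
    """Held-out accuracy of a classifier on final-hidden-layer encodings.

    Hidden states are sampled once per instance with the visible layer
    clamped; a multinomial logistic classifier is trained on a stratified
    80/20 split of the encodings.  With ``return_baseline`` the same
    protocol is applied to the raw patterns for comparison.
    """
    if data.labels is None:
        raise ValueError("encoding quality needs labels")
    if np.unique(data.labels).size < 2:
        raise ValueError("need at least two classes")
    from .core_bm import sample_clamped_hidden

    states = sample_clamped_hidden(net, data.patterns.astype(float), seed=seed)
    enc = states[-1]
    idx_tr, idx_te = train_test_split(
        np.arange(data.n_samples), test_size=test_size,
        stratify=data.labels, random_state=seed,
    )
    clf = _fit_classifier(enc[idx_tr], data.labels[idx_tr], seed)
    acc = float(clf.score(enc[idx_te], data.labels[idx_te]))
    if not return_baseline:
        return acc
    base = _fit_classifier(data.patterns[idx_tr], data.labels[idx_tr], seed)
    base_acc = float(base.score(data.patterns[idx_te], data.labels[idx_te]))
    return acc, base_acc


def generative_scores(
    net: BoltzmannNet,
    reference_classifier: LogisticRegression,
    n_samples: int = 1000,
    thin: int = 20,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Quality and diversity of generated patterns under a raw-data classifier.

    Quality is the mean winning-class probability over generated samples;
    diversity is the Shannon entropy (nats) of the winning-class
    histogram, at most ``ln n_classes``.  Returns (quality, diversity,
    low_sample_warning).
    """
    n_classes = len(reference_classifier.classes_)
    warn = n_samples < n_classes
    samples = sample_visible(net, n_samples, thin=thin, seed=seed)
    proba = reference_classifier.predict_proba(samples)
    quality = float(proba.max(axis=1).mean())
    hist = np.bincount(proba.argmax(axis=1), minlength=n_classes).astype(float)
    diversity = float(shannon_entropy(hist / hist.sum()))
    return quality, diversity, warn


def activation_monitor(net: BoltzmannNet, data: BinaryDataset | np.ndarray) -> list[np.ndarray]:
    """Mean stimulus-evoked firing probability of each remaining hidden unit.

    Mean-field activations with the visible layer clamped to the data,
    averaged over instances; one vector per hidden layer.  Rising mean
    activation across pruning iterations is a candidate stop signal.
    """
    v = np.asarray(
        data.patterns if isinstance(data, BinaryDataset) else data, dtype=float
    )
    mf = mean_field_infer(net, v, damping=1.0, max_iter=100, tol=1e-8)
    return [m.mean(axis=0) for m in mf.means[1:]]
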