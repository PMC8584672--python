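"""Iterative prune–retrain loop and the individual pruning criteria.

Pruning is mask editing: weights whose estimated importance falls below a
pre-specified percentile of the live weights in their layer pair are fixed
to zero.  Hidden units whose incoming weights are all pruned — or, in
multi-layer networks, whose outgoing weights are all pruned — are removed
from the network entirely (the cascade repeats until stable, so deleting
one unit may strand and delete another).  Visible units left without live
weights are flagged as disconnected but kept, preserving data indexing.

Seven criteria are supported: variance FI, heuristic FI, leading
FIM-eigenvector magnitude, absolute weight magnitude, Anti-FI (removes the
*most* important weights by the variance estimate), random weights, and
random whole-unit removal at a matched weight budget.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_bm import BoltzmannNet
from .fisher import (
    CRITERIA,
    ImportanceEstimate,
    collect_stats,
    eigen_importance,
    fim_diag_variance,
    heuristic_importance,
)
from .synthetic_data import BinaryDataset
from .training import TrainConfig, pcd_train, train_rbm

__all__ = [
    "PruneConfig",
    "PruneRunReport",
    "threshold_prune",
    "zero_importance_prune",
    "remove_dead_units",
    "match_unit_budget",
    "compute_importance",
    "prune_loop",
]


@dataclass
class PruneConfig:
    """Settings for the iterative prune–retrain loop.

    ``percentile`` may be a single value or one per layer pair (deeper
    layer pairs are often pruned more aggressively).  When
    ``zero_importance_override`` is set and more zero-importance live
    weights exist than the percentile would remove, all of them are
    removed instead.
    """

    criterion: str = "variance_fi"
    percentile: float | tuple[float, ...] = 50.0
    n_iterations: int = 3
    retrain_epochs: int = 2
    zero_importance_override: bool = True
    seed: int = 0
    #: activity-statistics protocol: "clamped" (stimulus-evoked, all pairs),
    #: "free" (model distribution), or "mixed" (clamped for the data-facing
    #: pair, free for deeper pairs)
    stat_mode: str = "clamped"
    stat_estimator: str = "expectation"  # "sample" or "expectation" (clamped only)
    stat_samples: int | None = None
    stat_thin: int = 20

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for p in np.atleast_1d(np.asarray(self.percentile, dtype=float)):
            if not 0 <= p <= 100:
                raise ValueError("percentile must lie in [0, 100]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def percentile_for(self, pair: int, n_pairs: int) -> float:
        p = np.atleast_1d(np.asarray(self.percentile, dtype=float))
        if p.size == 1:
            return float(p[0])
        if p.size != n_pairs:
            raise ValueError("need one percentile per layer pair")
        return float(p[pair])


@dataclass
class PruneRunReport:
    """Per-iteration bookkeeping of a prune–retrain run."""

    criterion: str
    seed: int
    records: list[dict] = field(default_factory=list)
    stopped_early: bool = False

    def append(self, rec: dict) -> None:
        if self.records:
            prev = self.records[-1]
            if rec["n_weights_total"] > prev["n_weights_total"]:
                raise ValueError("remaining weight count must be non-increasing")
        self.records.append(rec)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            flat = {k: v for k, v in r.items() if not isinstance(v, (list, dict))}
            for k, v in r.items():
                if isinstance(v, list):
                    for i, x in enumerate(v):
                        flat[f"{k}_{i}"] = x
                elif isinstance(v, dict):
                    for kk, vv in v.items():
                        flat[f"{k}_{kk}"] = vv
            rows.append(flat)
        df = pd.DataFrame(rows)
        df.insert(0, "criterion", self.criterion)
        df.insert(1, "seed", self.seed)
        return df

    def save(self, csv_path=None, json_path=None) -> None:
        if csv_path is not None:
            self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as f:
                json.dump(
                    {"criterion": self.criterion, "seed": self.seed,
                     "stopped_early": self.stopped_early, "records": self.records},
                    f, indent=1, default=float,
                )


# -- mask edits ----------------------------------------------------------------


def _live_values(mask, importance):
    vals = importance.values if isinstance(importance, ImportanceEstimate) else importance
    vals = np.asarray(vals, dtype=float)
    if vals.shape != mask.shape:
        raise ValueError("importance shape does not match mask")
    live = mask == 1
    if np.isnan(vals[live]).any():
        raise ValueError("importance missing for live weights")
    return vals, live


def threshold_prune(
    mask: np.ndarray, importance, percentile: float
) -> np.ndarray:
    """Remove the lowest-importance fraction of live weights.

    Exactly ``floor((100 - percentile)/100 * n_live)`` entries survive
    (iterated halving of an odd count therefore rounds down, e.g.
    910 -> 455 -> 227 -> 113); removals are taken in ascending order of
    (importance, row, column) — the index tie-break makes runs
    deterministic when importances tie.  Survivors keep their stored
    values.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    mask = np.asarray(mask, dtype=np.uint8)
    vals, live = _live_values(mask, importance)
    rows, cols = np.nonzero(live)
    n_remove = rows.size - math.floor((100.0 - percentile) / 100.0 * rows.size)
    if n_remove == 0:
        return mask.copy()
    order = np.lexsort((cols, rows, vals[rows, cols]))
    new = mask.copy()
    new[rows[order[:n_remove]], cols[order[:n_remove]]] = 0
    return new


def zero_importance_prune(mask: np.ndarray, importance, percentile: float) -> np.ndarray:
    """Remove all zero-importance live weights when they outnumber the percentile.

    If the fraction of live weights with exactly zero importance exceeds
    ``percentile/100``, every one of them is removed (possibly more than
    the percentile count); otherwise this falls back to
    :func:`threshold_prune`.
    """
    mask = np.asarray(mask, dtype=np.uint8)
    vals, live = _live_values(mask, importance)
    zero = live & (vals == 0.0)
    n_live = int(live.sum())
    if n_live and zero.sum() / n_live > percentile / 100.0:
        new = mask.copy()
        new[zero] = 0
        return new
    return threshold_prune(mask, importance, percentile)


def remove_dead_units(net: BoltzmannNet) -> tuple[BoltzmannNet, dict]:
    """Delete hidden units stranded by pruning; cascade to a fixpoint.

    A hidden unit dies when all weights on either adjacent side are
    masked; its remaining weights on the other side are dropped with it,
    so the total number of deleted weights can exceed what the percentile
    specified.  Visible units with no live weights are only reported as
    disconnected (data columns keep their meaning).
    """
    net = net.copy()
    removed = [0] * net.n_layers
    changed = True
    while changed:
        changed = False
        for l in range(1, net.n_layers):
            incoming = net.masks[l - 1]  # (n_{l-1}, n_l)
            dead = incoming.sum(axis=0) == 0
            if l < net.n_layers - 1:
                dead = dead | (net.masks[l].sum(axis=1) == 0)
            if dead.any():
                keep = ~dead
                net.biases[l] = net.biases[l][keep]
                net.weights[l - 1] = net.weights[l - 1][:, keep]
                net.masks[l - 1] = net.masks[l - 1][:, keep]
                if l < net.n_layers - 1:
                    net.weights[l] = net.weights[l][keep, :]
                    net.masks[l] = net.masks[l][keep, :]
                removed[l] += int(dead.sum())
                changed = True
    disconnected_visible = np.nonzero(net.masks[0].sum(axis=1) == 0)[0]
    report = {
        "removed_per_layer": removed,
        "disconnected_visible": disconnected_visible.tolist(),
    }
    return net, report


def match_unit_budget(n_units: int, fan_per_unit: float, weight_budget: int) -> int:
    """Smallest unit count whose total fan reaches a weight budget.

    ``ceil(weight_budget / fan_per_unit)``, capped at ``n_units``; used by
    the random-unit control to delete whole units while keeping a weight
    count comparable to the synaptic criteria.
    """
    if n_units <= 0 or fan_per_unit <= 0 or weight_budget < 0:
        raise ValueError("all inputs must be positive")
    return min(n_units, math.ceil(weight_budget / fan_per_unit))


# -- criteria ------------------------------------------------------------------


def compute_importance(
    net: BoltzmannNet,
    criterion: str,
    stats: list | None = None,
    rng: np.random.Generator | None = None,
) -> list[ImportanceEstimate]:
    """Per-layer-pair importance estimates under the requested criterion.

    ``stats`` (one :class:`~prunebm.fisher.ActivityStats` per pair) is
    required for the FI-based criteria; the eigenvector criterion
    enumerates the network exactly.  Anti-FI shares the variance-FI values
    — the ranking is inverted at pruning time.
    """
    if criterion in ("variance_fi", "anti_fi", "heuristic_fi") and stats is None:
        raise ValueError(f"criterion {criterion!r} needs activity statistics")
    out = []
    if criterion == "first_eigenvector":
        return eigen_importance(net)
    for l in range(net.n_pairs):
        mask = net.masks[l]
        if criterion in ("variance_fi", "anti_fi"):
            est = fim_diag_variance(stats[l], mask=mask, layer_pair=l)
            est = ImportanceEstimate(est.values, criterion, l,
                                     bias_pre=est.bias_pre, bias_post=est.bias_post)
        elif criterion == "heuristic_fi":
            est = heuristic_importance(net, stats[l], layer_pair=l)
        elif criterion == "weight_magnitude":
            vals = np.where(mask == 1, np.abs(net.effective_weights(l)), np.nan)
            est = ImportanceEstimate(vals, criterion, l)
        elif criterion == "random_weight":
            if rng is None:
                raise ValueError("random_weight needs a generator")
            vals = np.where(mask == 1, rng.random(mask.shape), np.nan)
            est = ImportanceEstimate(vals, criterion, l)
        else:
            raise ValueError(f"criterion {criterion!r} has no per-weight importance")
        out.append(est)
    return out


def _random_unit_masks(net, cfg, rng):
    """Random-unit control: drop whole hidden units at a matched weight budget."""
    new_masks = [m.copy() for m in net.masks]
    for l in range(1, net.n_layers):
        pair = l - 1  # incoming pair governs this layer's budget
        mask = new_masks[pair]
        live = int(mask.sum())
        p = cfg.percentile_for(pair, net.n_pairs)
        budget = live - math.floor(p / 100.0 * live)
        n_units = mask.shape[1]
        connected = np.nonzero(mask.sum(axis=0) > 0)[0]
        if connected.size == 0:
            continue
        fan = live / connected.size
        n_keep = match_unit_budget(connected.size, fan, budget)
        keep = rng.choice(connected, size=n_keep, replace=False)
        drop = np.setdiff1d(connected, keep)
        mask[:, drop] = 0
        if l < net.n_layers - 1:
            new_masks[pair + 1][drop, :] = 0
    return new_masks


# -- the loop ------------------------------------------------------------------


def prune_loop(
    net: BoltzmannNet,
    data: BinaryDataset,
    prune_cfg: PruneConfig,
    train_cfg: TrainConfig,
    evaluate=None,
) -> tuple[BoltzmannNet, PruneRunReport]:
    """Iteratively estimate importance, prune, drop dead units, and retrain.

    Each iteration: collect activity statistics (if the criterion needs
    them), edit the masks at the configured percentile (with the
    zero-importance override for FI criteria, or the random-unit path),
    remove stranded units, evaluate, retrain for ``retrain_epochs`` with
    unaltered surviving parameter values, and evaluate again.  Returns the
    pruned network and a :class:`PruneRunReport`; the loop stops early if
    the network becomes fully disconnected.
    """
    rng = np.random.default_rng([prune_cfg.seed, 0x7072])
    report = PruneRunReport(criterion=prune_cfg.criterion, seed=prune_cfg.seed)
    net = net.copy()
    stat_samples = prune_cfg.stat_samples or data.n_samples
    for it in range(prune_cfg.n_iterations):
        criterion = prune_cfg.criterion
        if criterion in ("variance_fi", "anti_fi", "heuristic_fi"):
            mode = prune_cfg.stat_mode
            if mode == "mixed":
                stats = collect_stats(
                    net, mode="free", data=data, n_samples=stat_samples,
                    thin=prune_cfg.stat_thin, seed=int(rng.integers(2**31)),
                )
                stats[0] = collect_stats(
                    net, mode="clamped", data=data,
                    estimator=prune_cfg.stat_estimator,
                    seed=int(rng.integers(2**31)),
                )[0]
            else:
                stats = collect_stats(
                    net, mode=mode, data=data, n_samples=stat_samples,
                    thin=prune_cfg.stat_thin, estimator=prune_cfg.stat_estimator,
                    seed=int(rng.integers(2**31)),
                )
        else:
            stats = None

        if criterion == "random_unit":
            new_masks = _random_unit_masks(net, prune_cfg, rng)
        else:
            ests = compute_importance(net, criterion, stats=stats, rng=rng)
            new_masks = []
            for l, est in enumerate(ests):
                p = prune_cfg.percentile_for(l, net.n_pairs)
                vals = est.values
                if criterion == "anti_fi":
                    vals = np.where(np.isnan(vals), np.nan, -vals)
                    new_masks.append(threshold_prune(net.masks[l], vals, p))
                elif criterion in ("variance_fi", "heuristic_fi", "first_eigenvector") \
                        and prune_cfg.zero_importance_override:
                    new_masks.append(zero_importance_prune(net.masks[l], vals, p))
                else:
                    new_masks.append(threshold_prune(net.masks[l], vals, p))
        for l, m in enumerate(new_masks):
            if np.any(m > net.masks[l]):
                raise AssertionError("a pruned weight can never return")
            net.masks[l] = m
        net.apply_masks()
        net, cascade = remove_dead_units(net)

        rec = {
            "iteration": it,
            "n_weights": [net.n_live_weights(l) for l in range(net.n_pairs)],
            "n_weights_total": net.n_live_weights(),
            "n_units": net.layer_sizes,
            "n_disconnected_visible": len(cascade["disconnected_visible"]),
            "disconnected_visible": cascade["disconnected_visible"],
            "removed_units": cascade["removed_per_layer"],
        }
        if net.n_live_weights() == 0 or min(net.layer_sizes[1:]) == 0:
            rec["metrics_before_retrain"] = {}
            rec["metrics_after_retrain"] = {}
            report.append(rec)
            report.stopped_early = True
            break
        if evaluate is not None:
            rec["metrics_before_retrain"] = evaluate(net)
        retrain_cfg = _with_epochs(train_cfg, prune_cfg.retrain_epochs,
                                   seed=int(rng.integers(2**31)))
        if net.n_pairs == 1:
            train_rbm(net, data, retrain_cfg)
        else:
            pcd_train(net, data, retrain_cfg)
        if evaluate is not None:
            rec["metrics_after_retrain"] = evaluate(net)
        report.append(rec)
    net.history.append({
        "stage": "prune_loop", "criterion": prune_cfg.criterion,
        "iterations": len(report.records), "seed": prune_cfg.seed,
    })
    return net, report


def _with_epochs(cfg: TrainConfig, epochs: int, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, epochs=epochs, seed=seed)
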