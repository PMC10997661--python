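"""Cross-validated training with early stopping and model-ranking summaries.

Models train for at most ``epochs`` epochs and stop early when the
validation metric has not improved for ``patience`` consecutive epochs; the
best-validation weights are restored before test evaluation.  The held-out
test set is fixed across folds, so fold test metrics are comparable and
their mean is the reported performance (AUROC for classification, RMSE for
regression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .graphs import build_graphs
from .network import (Adam, GraphScheme, MMGXNetwork, ModelConfig,
                      batch_molecules)

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """The requested metric is undefined on the given targets."""


@dataclass
class TrainConfig:
    epochs: int = 300
    patience: int = 30
    min_improvement: float = 1e-5
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 64


@dataclass
class FoldResult:
    fold_index: int
    best_validation_metric: float
    test_metric: float
    network: MMGXNetwork
    test_predictions: pd.DataFrame  # columns: id, target, prediction
    epochs_run: int
    target_mean: float = 0.0
    target_std: float = 1.0


def evaluate(predictions, targets, task):
    """AUROC for classification, RMSE for regression."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if task == "classification":
        if len(np.unique(targets)) < 2:
            raise MetricError("AUROC undefined on single-class targets")
        return float(roc_auc_score(targets, predictions))
    return float(np.sqrt(np.mean((predictions - targets) ** 2)))


def _metric_better(candidate, best, task, tol):
    if task == "classification":  # higher is better
        return candidate > best + tol
    return candidate < best - tol


def _predict(network, graph_dicts, scheme, batch_size=256):
    preds = []
    for start in range(0, len(graph_dicts), batch_size):
        batch = batch_molecules(graph_dicts[start:start + batch_size], scheme)
        preds.append(network.forward(batch).prediction)
    return np.concatenate(preds) if preds else np.zeros(0)


def train_fold(scheme, records_by_id, graphs_by_id, fold, fold_index, test_ids,
               model_config: ModelConfig, train_config: TrainConfig, seed=0):
    """Train one CV fold; returns restored-best-weights results on the test set."""
    if isinstance(scheme, str):
        scheme = GraphScheme.parse(scheme)
    train_ids, val_ids = fold
    task = model_config.task
    net = MMGXNetwork(scheme, model_config, seed=seed)
    opt = Adam(net.parameters(), lr=train_config.lr,
               weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(seed)

    def targets_of(ids):
        return np.array([records_by_id[i].target for i in ids], dtype=float)

    y_train = targets_of(train_ids)
    mu, sigma = 0.0, 1.0
    if task == "regression":
        mu = float(y_train.mean())
        sigma = float(y_train.std()) or 1.0

    def graph_list(ids):
        return [graphs_by_id[i] for i in ids]

    val_graphs, test_graphs = graph_list(val_ids), graph_list(test_ids)
    y_val, y_test = targets_of(val_ids), targets_of(test_ids)

    best_metric = -np.inf if task == "classification" else np.inf
    best_state, bad_epochs, epochs_run = None, 0, 0
    order = np.arange(len(train_ids))
    for epoch in range(train_config.epochs):
        epochs_run = epoch + 1
        rng.shuffle(order)
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch_ids = [train_ids[i] for i in idx]
            batch = batch_molecules(graph_list(batch_ids), scheme)
            y = targets_of(batch_ids)
            if task == "regression":
                y = (y - mu) / sigma
            out = net.forward(batch, rng=rng, training=True)
            loss = net.loss(out, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss in fold {fold_index} epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_pred = _predict(net, val_graphs, scheme)
        if task == "regression":
            val_pred = val_pred * sigma + mu
        val_metric = evaluate(val_pred, y_val, task)
        if best_state is None or _metric_better(val_metric, best_metric, task,
                                               train_config.min_improvement):
            best_metric, best_state, bad_epochs = val_metric, net.state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_config.patience:
                logger.info("fold %d early stop at epoch %d", fold_index, epoch + 1)
                break
    net.load_state(best_state)
    test_pred = _predict(net, test_graphs, scheme)
    if task == "regression":
        test_pred = test_pred * sigma + mu
    test_metric = evaluate(test_pred, y_test, task)
    return FoldResult(
        fold_index=fold_index,
        best_validation_metric=float(best_metric),
        test_metric=test_metric,
        network=net,
        test_predictions=pd.DataFrame(
            {"id": test_ids, "target": y_test, "prediction": test_pred}),
        epochs_run=epochs_run,
        target_mean=mu,
        target_std=sigma,
    )


def build_graph_cache(records, scheme) -> dict:
    """Pre-build every representation a scheme needs, keyed by record id."""
    if isinstance(scheme, str):
        scheme = GraphScheme.parse(scheme)
    reps = scheme.representations
    if scheme.uses_initial_pooling:
        reps = tuple(dict.fromkeys(("A",) + reps))
    return {r.id: build_graphs(r, reps) for r in records}


def train_cv(records, split, scheme, model_config, train_config=None, seed=0,
             graphs_by_id=None):
    """Train every fold of a split; fold seeds are seed + fold index."""
    if isinstance(scheme, str):
        scheme = GraphScheme.parse(scheme)
    train_config = train_config or TrainConfig()
    records_by_id = {r.id: r for r in records}
    if graphs_by_id is None:
        graphs_by_id = build_graph_cache(records, scheme)
    results = []
    for k, fold in enumerate(split.train_folds):
        results.append(
            train_fold(scheme, records_by_id, graphs_by_id, fold, k,
                       split.test_ids, model_config, train_config,
                       seed=seed + k)
        )
    return results


@dataclass
class RankingSummary:
    """Across-dataset model comparison: average rank and average z-score."""

    table: pd.DataFrame  # index: model, columns: AvgRank, AvgZScore
    per_dataset_ranks: pd.DataFrame
    per_dataset_zscores: pd.DataFrame


def summarize_model_ranking(metrics: pd.DataFrame, higher_is_better=True,
                            population_std=False) -> RankingSummary:
    """AvgRank and AvgZScore over a (model x dataset) metric table.

    Per dataset, models are ranked 1 = best (ties get the mean rank) and
    z-scored against the across-model mean using the sample standard
    deviation (so two models at 0.9/0.8 score +-0.7071); the z-score sign
    is flipped for lower-is-better metrics so that larger always means
    better.  Both are then averaged over datasets.
    """
    if isinstance(higher_is_better, bool):
        higher_is_better = {c: higher_is_better for c in metrics.columns}
    ranks, zscores = {}, {}
    for dataset in metrics.columns:
        col = metrics[dataset].astype(float)
        sign = 1.0 if higher_is_better[dataset] else -1.0
        ranks[dataset] = rankdata(-sign * col.values, method="average")
        std = col.values.std(ddof=0 if population_std else 1)
        if std == 0 or not np.isfinite(std):
            zscores[dataset] = np.zeros(len(col))
        else:
            zscores[dataset] = sign * (col.values - col.values.mean()) / std
    rank_df = pd.DataFrame(ranks, index=metrics.index)
    z_df = pd.DataFrame(zscores, index=metrics.index)
    table = pd.DataFrame(
        {"AvgRank": rank_df.mean(axis=1), "AvgZScore": z_df.mean(axis=1)})
    return RankingSummary(table=table, per_dataset_ranks=rank_df,
                          per_dataset_zscores=z_df)
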