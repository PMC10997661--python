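"""High-level Model/Results interface tying the pipeline together.

``MMGX`` is constructed from molecule records (or a DataFrame / CSV), a
graph scheme, and hyperparameters; ``fit`` runs the cross-validated
training and returns an ``MMGXResults`` carrying the per-fold estimates,
test metrics, and the interpretation stack (single-prediction attention,
node-features view, potential substructures, attention evaluation against
ground-truth masks).

Example
-------
>>> from mmgx import MMGX
>>> from mmgx.synthlogics import generate_dataset
>>> records, masks = generate_dataset("3MR", 500, seed=0)
>>> model = MMGX(records, scheme="A+J", embedding_dim=48)
>>> results = model.fit(seed=0, epochs=20, n_folds=2)
>>> print(results.summary())           # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interpret, molio, substructures, synthlogics, training
from .network import GraphScheme, ModelConfig
from .training import TrainConfig


class MMGX:
    """A multiple-graph-representation model for one molecular dataset."""

    def __init__(self, records, scheme="A", task="classification",
                 test_fraction=0.2, **model_kwargs):
        self.records = list(records)
        self.scheme = GraphScheme.parse(scheme) if isinstance(scheme, str) else scheme
        self.task = task
        self.test_fraction = test_fraction
        self.model_config = ModelConfig(task=task, **model_kwargs)
        self._graph_cache = None

    @classmethod
    def from_dataframe(cls, df, scheme="A", task="classification",
                       smiles_col="smiles", target_col="target", id_col="id",
                       **kwargs):
        records = molio.records_from_frame(df, task=task, smiles_col=smiles_col,
                                           target_col=target_col, id_col=id_col)
        return cls(records, scheme=scheme, task=task, **kwargs)

    @classmethod
    def from_csv(cls, path, scheme="A", task="classification", **kwargs):
        return cls.from_dataframe(pd.read_csv(path), scheme=scheme, task=task,
                                  **kwargs)

    @property
    def graph_cache(self):
        if self._graph_cache is None:
            self._graph_cache = training.build_graph_cache(self.records, self.scheme)
        return self._graph_cache

    def fit(self, seed=0, n_folds=5, split=None, **train_kwargs) -> "MMGXResults":
        """Cross-validated training; returns the fitted results object."""
        if split is None:
            split = molio.make_splits(self.records, self.test_fraction,
                                      n_folds, seed)
        train_config = TrainConfig(**train_kwargs)
        fold_results = training.train_cv(
            self.records, split, self.scheme, self.model_config, train_config,
            seed=seed, graphs_by_id=self.graph_cache)
        return MMGXResults(self, split, fold_results, seed)


class MMGXResults:
    """Fitted cross-validation results with interpretation methods."""

    def __init__(self, model: MMGX, split, fold_results, seed):
        self.model = model
        self.split = split
        self.fold_results = fold_results
        self.seed = seed

    # -- estimates ---------------------------------------------------------
    @property
    def networks(self):
        return [fr.network for fr in self.fold_results]

    @property
    def metric_name(self):
        return "AUROC" if self.model.task == "classification" else "RMSE"

    @property
    def test_metrics(self):
        return np.array([fr.test_metric for fr in self.fold_results])

    @property
    def test_metric_mean(self):
        return float(self.test_metrics.mean())

    @property
    def test_metric_std(self):
        return float(self.test_metrics.std(ddof=0))

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"fold": fr.fold_index, "epochs": fr.epochs_run,
             f"val_{self.metric_name}": fr.best_validation_metric,
             f"test_{self.metric_name}": fr.test_metric}
            for fr in self.fold_results
        ])

    def summary(self) -> str:
        lines = [
            "MMGX cross-validation results",
            "=" * 46,
            f"scheme:       {self.model.scheme.label}",
            f"task:         {self.model.task}",
            f"molecules:    {len(self.model.records)}",
            f"folds:        {len(self.fold_results)}   seed: {self.seed}",
            f"embedding:    {self.model.model_config.embedding_dim}",
            "-" * 46,
            self.fold_table().to_string(index=False),
            "-" * 46,
            (f"test {self.metric_name}: {self.test_metric_mean:.4f} "
             f"(std {self.test_metric_std:.4f})"),
        ]
        return "\n".join(lines)

    # -- prediction & attention -------------------------------------------
    def _graphs_for(self, smiles_or_record):
        from .graphs import build_graphs
        if hasattr(smiles_or_record, "id") and smiles_or_record.id in self.model.graph_cache:
            return self.model.graph_cache[smiles_or_record.id]
        reps = self.model.scheme.representations
        if self.model.scheme.uses_initial_pooling:
            reps = tuple(dict.fromkeys(("A",) + reps))
        return build_graphs(smiles_or_record, reps)

    def predict(self, smiles) -> float:
        """Fold-averaged prediction for one molecule."""
        return self.attention(smiles).prediction

    def attention(self, smiles) -> interpret.AttentionResult:
        """Fold-averaged attention (raw, per-graph, mapped, combined)."""
        return interpret.fold_average_attention(self.networks,
                                                self._graphs_for(smiles))

    def single_prediction_view(self, record, out_prefix):
        res = self.attention(record)
        return interpret.single_prediction_view(record, res, out_prefix)

    def node_features_view(self, prediction_filter=None, plot_path=None):
        return interpret.node_features_view(
            self.model.records, self.networks, self.model.graph_cache,
            prediction_filter=prediction_filter, plot_path=plot_path)

    def attention_correlation(self, rep_pair=None):
        return interpret.attention_correlation(
            self.model.records, self.networks, self.model.graph_cache,
            rep_pair=rep_pair)

    # -- substructures -----------------------------------------------------
    def potential_substructures(self, config=None, prediction_filter=None
                                ) -> pd.DataFrame:
        """Potential-substructures view over (by default) predicted positives."""
        if prediction_filter is None:
            prediction_filter = lambda p: p >= 0.5
        molecules = []
        for rec in self.model.records:
            res = self.attention(rec)
            if prediction_filter(res.prediction):
                molecules.append((rec.id, rec.smiles, res.combined))
        return substructures.potential_substructures_view(molecules, config)

    # -- attention evaluation against ground truth -------------------------
    def evaluate_interpretation(self, masks_by_id):
        """Mean AttAUROC/AttACC over true positives, per fold and summarized."""
        return synthlogics.evaluate_interpretation(
            self.model.records, masks_by_id, self.networks,
            self.model.graph_cache)
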