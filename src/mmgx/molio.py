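"""Dataset input, sanitization, deduplication, and split construction.

Molecules arrive as SMILES in a CSV (or DataFrame).  Records that cannot be
parsed, have no bond, or consist of a single heavy atom are dropped.
Duplicate structures (same canonical SMILES) with agreeing targets collapse
to one record; duplicates with conflicting targets are removed entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: targets closer than this (regression) are considered the same measurement
REGRESSION_CONFLICT_TOL = 1e-9


class ConfigurationError(ValueError):
    """Bad column names, task labels, or other run-configuration problems."""


class DataError(ValueError):
    """The data itself cannot support the requested operation."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with a canonical SMILES and a single task target."""

    id: str
    smiles: str
    target: float

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass
class DatasetSplit:
    """Held-out test ids plus cross-validation (train, validation) id folds."""

    train_folds: list  # list of (train_ids, validation_ids) tuples
    test_ids: list
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.train_folds)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "test_ids": list(self.test_ids),
                    "folds": [
                        {"train_ids": list(tr), "validation_ids": list(va)}
                        for tr, va in self.train_folds
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "DatasetSplit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            train_folds=[(f["train_ids"], f["validation_ids"]) for f in d["folds"]],
            test_ids=d["test_ids"],
            seed=d["seed"],
        )


def sanitize_smiles(smiles: str):
    """Canonical SMILES for a usable molecule, or None if it must be dropped.

    Dropped: unparseable SMILES, molecules with no bond, single-atom
    molecules.  Multi-fragment SMILES (salts) are kept but logged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if mol.GetNumAtoms() < 2 or mol.GetNumBonds() < 1:
        return None
    if len(Chem.GetMolFrags(mol)) > 1:
        logger.info("multi-fragment SMILES kept as-is: %s", smiles)
    return Chem.MolToSmiles(mol)


def remove_conflicts(records, task="classification"):
    """Collapse duplicate canonical SMILES; drop groups with conflicting targets."""
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.smiles, []).append(rec)
    out, n_conflict = [], 0
    for smiles, group in groups.items():
        targets = [g.target for g in group]
        if task == "regression":
            conflict = max(targets) - min(targets) > REGRESSION_CONFLICT_TOL
        else:
            conflict = len(set(targets)) > 1
        if conflict:
            n_conflict += 1
            continue
        out.append(group[0])
    if n_conflict:
        logger.info("removed %d conflicting duplicate groups", n_conflict)
    return out


def records_from_frame(df, task="classification", smiles_col="smiles",
                       target_col="target", id_col="id"):
    """Build sanitized, conflict-free records from a DataFrame."""
    if task not in ("classification", "regression"):
        raise ConfigurationError(f"unknown task {task!r}")
    for col in (smiles_col, target_col):
        if col not in df.columns:
            raise ConfigurationError(f"missing required column {col!r}")
    records, n_dropped = [], 0
    for i, row in df.iterrows():
        canon = sanitize_smiles(str(row[smiles_col]))
        if canon is None:
            n_dropped += 1
            continue
        rid = str(row[id_col]) if id_col in df.columns else f"mol{i}"
        records.append(MoleculeRecord(id=rid, smiles=canon, target=float(row[target_col])))
    if n_dropped:
        logger.info("dropped %d unusable molecules", n_dropped)
    records = remove_conflicts(records, task=task)
    if not records:
        raise DataError("no usable molecules after sanitization")
    return records


def load_dataset(path, task="classification", smiles_col="smiles",
                 target_col="target", id_col="id"):
    """Read a CSV of (smiles, target[, id]) into sanitized MoleculeRecords."""
    return records_from_frame(pd.read_csv(path), task=task, smiles_col=smiles_col,
                              target_col=target_col, id_col=id_col)


def write_dataset(records, path) -> None:
    pd.DataFrame(
        {"id": [r.id for r in records],
         "smiles": [r.smiles for r in records],
         "target": [r.target for r in records]}
    ).to_csv(path, index=False)


def make_splits(records, test_fraction=0.2, n_folds=5, seed=0) -> DatasetSplit:
    """Random 8:2-style test split plus n-fold CV partition of the remainder.

    Deterministic for a given seed.  Not stratified.  The test set is fixed;
    validation sets across folds are pairwise disjoint and partition the
    non-test ids.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie in (0, 1)")
    if n_folds < 2:
        raise ConfigurationError("n_folds must be at least 2")
    ids = [r.id for r in records]
    if len(ids) < n_folds + 1:
        raise DataError(f"dataset of {len(ids)} records cannot support {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    n_test = min(max(n_test, 1), len(ids) - n_folds)
    test_ids = [ids[i] for i in order[:n_test]]
    rest = [ids[i] for i in order[n_test:]]
    fold_chunks = np.array_split(np.arange(len(rest)), n_folds)
    train_folds = []
    for chunk in fold_chunks:
        val = [rest[i] for i in chunk]
        val_set = set(val)
        train = [r for r in rest if r not in val_set]
        train_folds.append((train, val))
    return DatasetSplit(train_folds=train_folds, test_ids=test_ids, seed=seed)
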