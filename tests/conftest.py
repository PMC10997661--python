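import numpy as np
import pandas as pd
import pytest

from mmgx import MMGX
from mmgx.molio import MoleculeRecord, records_from_frame
from mmgx.synthlogics import generate_dataset


@pytest.fixture(scope="session")
def aspirin_record():
    return MoleculeRecord(id="aspirin", smiles="CC(=O)OC1=CC=CC=C1C(=O)O", target=1.0)


@pytest.fixture(scope="session")
def toy_records():
    """100 small labelled molecules (label = contains oxygen)."""
    smiles = [
        "CCO", "CCC", "CCCC", "CCCO", "CC(C)O", "CC(C)C", "CCOC", "CCCCC",
        "c1ccccc1", "c1ccccc1O", "c1ccccc1C", "CC(=O)C", "CCN", "CCCN",
        "CC(=O)O", "CCCCCC", "C1CCCCC1", "C1CCCCC1O", "CC(C)(C)C", "COC",
    ] * 5
    rows = [{"id": f"m{i}", "smiles": s + "C" * (i // 20), "target": float("O" in s)}
            for i, s in enumerate(smiles)]
    return records_from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_3mr():
    """A small generated 3MR dataset shared across tests."""
    records, masks = generate_dataset("3MR", 240, seed=11)
    return records, masks


@pytest.fixture(scope="session")
def fitted_3mr(tiny_3mr):
    """A quickly trained A+J model on the tiny 3MR set (2 folds, few epochs)."""
    records, masks = tiny_3mr
    model = MMGX(records, scheme="A+J", embedding_dim=32)
    results = model.fit(seed=3, n_folds=2, epochs=12, patience=12)
    return results, masks
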