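"""Synthetic binding-logic benchmarks with atom-level ground truth.

A logic is a boolean expression over SMARTS substructure leaves combined
with AND / OR / NOT.  A molecule is labelled positive iff the expression
matches, and for positives the atoms matched by the *positively required*
leaves form the ground-truth importance masks.  Because a leaf can match in
several places, a molecule can have several alternative ground truths; when
scoring attention against them, the maximum metric over alternatives is
recorded.

Five built-in logics are provided (the SMARTS are the community-standard
benchmark definitions):

========  ==========================================================
Logic6    ``[FX1]`` AND ``[CX3]=O``
Logic7    ``[R0;D2,D1][R0;D2][R0;D2,D1]`` AND ``[CX3]=O``
Logic9    ``[NX3;H2]`` AND ``[OD2](C)C`` AND benzene-type aromatic ring
Logic14   (``[OD2](C)C`` OR NOT ``[OX2H]``) AND ``[CX3]=O``
          AND NOT ``[CX2]#[CX2]``
3MR       any three-membered ring, ``*1**1``
========  ==========================================================

Attention-evaluation metrics:

* **AttAUROC** — AUROC of the atom attention vector as a scorer of mask
  membership, maximised over alternative masks.
* **AttACC** — fraction of atoms whose thresholded attention (>= 0.5 means
  important) equals the mask label, maximised over alternative masks.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.metrics import roc_auc_score

from .molio import MoleculeRecord, remove_conflicts

logger = logging.getLogger(__name__)

#: combinatorial ground-truth alternatives are capped per molecule
MAX_MASK_ALTERNATIVES = 32


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# logic expression trees
# ---------------------------------------------------------------------------

class LogicExpr:
    def evaluate(self, mol) -> bool:
        raise NotImplementedError

    def ground_truths(self, mol):
        """Alternative atom-index masks supporting a positive label."""
        raise NotImplementedError


@dataclass(frozen=True)
class Pattern(LogicExpr):
    smarts: str

    def _query(self):
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ConfigurationError(f"invalid SMARTS {self.smarts!r}")
        return q

    def evaluate(self, mol):
        return mol.HasSubstructMatch(self._query())

    def ground_truths(self, mol):
        matches = mol.GetSubstructMatches(self._query())
        return [frozenset(m) for m in matches[:MAX_MASK_ALTERNATIVES]]


@dataclass(frozen=True)
class And(LogicExpr):
    children: tuple

    def evaluate(self, mol):
        return all(c.evaluate(mol) for c in self.children)

    def ground_truths(self, mol):
        # NOT children are absence constraints: no atoms to highlight
        positive = [c for c in self.children if not isinstance(c, Not)]
        alternatives = [frozenset()]
        for child in positive:
            child_masks = child.ground_truths(mol) or [frozenset()]
            alternatives = [a | b for a, b in
                            itertools.product(alternatives, child_masks)]
            alternatives = list(dict.fromkeys(alternatives))[:MAX_MASK_ALTERNATIVES]
        return [a for a in alternatives if a] or []


@dataclass(frozen=True)
class Or(LogicExpr):
    children: tuple

    def evaluate(self, mol):
        return any(c.evaluate(mol) for c in self.children)

    def ground_truths(self, mol):
        masks = []
        for child in self.children:
            if isinstance(child, Not):
                continue
            if child.evaluate(mol):
                masks.extend(child.ground_truths(mol))
        return list(dict.fromkeys(masks))[:MAX_MASK_ALTERNATIVES]


@dataclass(frozen=True)
class Not(LogicExpr):
    child: LogicExpr

    def evaluate(self, mol):
        return not self.child.evaluate(mol)

    def ground_truths(self, mol):
        return []


@dataclass(frozen=True)
class LogicSpec:
    """A named synthetic task: boolean SMARTS expression plus ground truth."""

    name: str
    expression: LogicExpr

    def evaluate(self, mol):
        return evaluate_logic(self, mol)


@dataclass
class GroundTruthMask:
    """Per-molecule label and alternative ground-truth atom sets."""

    label: int
    masks: list  # list of frozenset(atom indices); empty for negatives


def builtin_logics():
    """The five built-in synthetic binding logics."""
    carbonyl = Pattern("[CX3]=O")
    return [
        LogicSpec("Logic6", And((Pattern("[FX1]"), carbonyl))),
        LogicSpec("Logic7", And((Pattern("[R0;D2,D1][R0;D2][R0;D2,D1]"), carbonyl))),
        LogicSpec("Logic9", And((
            Pattern("[NX3;H2]"), Pattern("[OD2](C)C"),
            Pattern("[cX3]1[cX3H][cX3H][cX3H][cX3H][cX3H]1")))),
        LogicSpec("Logic14", And((
            Or((Pattern("[OD2](C)C"), Not(Pattern("[OX2H]")))),
            carbonyl,
            Not(Pattern("[CX2]#[CX2]"))))),
        LogicSpec("3MR", Pattern("*1**1")),
    ]


def get_logic(name: str) -> LogicSpec:
    for spec in builtin_logics():
        if spec.name.lower() == name.lower():
            return spec
    names = ", ".join(s.name for s in builtin_logics())
    raise ConfigurationError(f"unknown logic {name!r}; built-ins are: {names}")


def evaluate_logic(spec: LogicSpec, mol) -> GroundTruthMask:
    """Label a molecule under a logic and collect its ground-truth masks."""
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    if mol is None:
        raise ValueError("invalid molecule")
    if not spec.expression.evaluate(mol):
        return GroundTruthMask(label=0, masks=[])
    masks = spec.expression.ground_truths(mol)
    return GroundTruthMask(label=1, masks=masks)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

# fragment grammar: scaffolds plus substituents; the pool deliberately
# contains the pieces the built-in logics test for (fluorine, carbonyls,
# ethers, amines, alkynes, hydroxyls, aromatic and small rings) so both
# classes are reachable for every logic.
SCAFFOLDS = ["C" * n for n in range(3, 9)] + [
    "c1ccccc1", "C1CCCCC1", "C1CCCC1", "c1ccncc1",
]
SUBSTITUENTS = [
    "C", "CC", "CCC", "F", "Cl", "Br", "O", "OC", "OCC", "N", "NC",
    "C=O", "C(C)=O", "C(=O)O", "C(=O)OC", "C(=O)N", "C#C", "C#N",
    "C1CC1", "C1CO1", "c1ccccc1", "C1CCCCC1", "S", "SC", "C=C",
]
# per-logic groups of substituents, one group per positively-required leaf;
# positives force-attach one draw from every group, negatives avoid them all
LOGIC_HINT_GROUPS = {
    "Logic6": [["F"], ["C(C)=O", "C=O", "C(=O)OC"]],
    "Logic7": [["CCC", "CCCC"], ["C(C)=O", "C=O"]],
    "Logic9": [["N"], ["OC", "OCC"], ["c1ccccc1"]],
    "Logic14": [["OC", "OCC"], ["C(C)=O", "C=O", "C(=O)OC"]],
    "3MR": [["C1CC1", "C1CO1"]],
}


def _attach(mol, frag_smiles, rng, max_heavy):
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None or mol.GetNumAtoms() + frag.GetNumAtoms() > max_heavy:
        return mol
    attach_at = int(rng.integers(mol.GetNumAtoms()))
    offset = mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(attach_at, offset, Chem.BondType.SINGLE)
    try:
        test = combined.GetMol()
        Chem.SanitizeMol(test)
    except Exception:
        return mol
    return Chem.RWMol(test)


def _random_molecule(rng, want_positive, hint_groups, max_heavy=25):
    """Assemble a scaffold with random substituents; returns canonical SMILES."""
    scaffold = Chem.MolFromSmiles(SCAFFOLDS[rng.integers(len(SCAFFOLDS))])
    mol = Chem.RWMol(scaffold)
    avoid = {s for group in hint_groups for s in group}
    if want_positive:
        for group in hint_groups:
            mol = _attach(mol, group[rng.integers(len(group))], rng, max_heavy)
    n_subs = int(rng.integers(0, 3))
    for _ in range(n_subs):
        frag_smiles = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
        if not want_positive and frag_smiles in avoid:
            continue  # bias negatives away from trigger pieces
        mol = _attach(mol, frag_smiles, rng, max_heavy)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if out.GetNumAtoms() < 2 or out.GetNumBonds() < 1:
        return None
    return Chem.MolToSmiles(out)


def generate_dataset(spec, n_molecules, seed=0, max_retries=300,
                     min_heavy=8, max_heavy=25):
    """Generate a ~class-balanced dataset for a logic with ground truths.

    Molecules are assembled from a fragment grammar (alkyl chains, rings,
    and the logic's own trigger pieces, inserted or withheld to steer the
    label); labels and masks come from :func:`evaluate_logic` so generator
    and evaluator cannot disagree.  Deterministic per seed.

    Returns ``(records, masks_by_id)``.
    """
    if isinstance(spec, str):
        spec = get_logic(spec)
    if n_molecules < 100:
        raise ValueError("generate at least 100 molecules")
    rng = np.random.default_rng(seed)
    hints = LOGIC_HINT_GROUPS.get(spec.name, [])
    records, masks, seen = [], {}, set()
    failures = 0
    for i in range(n_molecules):
        want_positive = bool(i % 2)  # alternate target classes
        got = None
        for _ in range(max_retries):
            smiles = _random_molecule(rng, want_positive, hints, max_heavy)
            if smiles is None or smiles in seen:
                continue
            mol = Chem.MolFromSmiles(smiles)
            if mol.GetNumAtoms() < min_heavy:
                continue
            gt = evaluate_logic(spec, mol)
            if gt.label == int(want_positive) and (gt.label == 0 or gt.masks):
                got = (smiles, gt)
                break
        if got is None:  # fall back: accept whatever class comes out
            failures += 1
            for _ in range(max_retries):
                smiles = _random_molecule(rng, want_positive, hints, max_heavy)
                if smiles is not None and smiles not in seen:
                    gt = evaluate_logic(spec, Chem.MolFromSmiles(smiles))
                    if gt.label == 0 or gt.masks:
                        got = (smiles, gt)
                        break
        if got is None:
            continue
        smiles, gt = got
        seen.add(smiles)
        rid = f"{spec.name}_{i}"
        records.append(MoleculeRecord(id=rid, smiles=smiles, target=float(gt.label)))
        masks[rid] = gt
    records = remove_conflicts(records)
    masks = {r.id: masks[r.id] for r in records}
    pos_rate = np.mean([r.target for r in records]) if records else 0.0
    if not 0.45 <= pos_rate <= 0.55:
        warnings.warn(f"class balance {pos_rate:.2f} outside 45-55% for {spec.name}")
    logger.info("%s: %d molecules, %.1f%% positive, %d steering failures",
                spec.name, len(records), 100 * pos_rate, failures)
    return records, masks


def write_generated(records, masks, csv_path, masks_path):
    pd.DataFrame({"id": [r.id for r in records],
                  "smiles": [r.smiles for r in records],
                  "target": [int(r.target) for r in records]}).to_csv(csv_path, index=False)
    with open(masks_path, "w") as fh:
        json.dump({rid: {"label": m.label, "masks": [sorted(s) for s in m.masks]}
                   for rid, m in masks.items()}, fh)


def read_masks(path):
    with open(path) as fh:
        raw = json.load(fh)
    return {rid: GroundTruthMask(label=d["label"],
                                 masks=[frozenset(m) for m in d["masks"]])
            for rid, d in raw.items()}


# ---------------------------------------------------------------------------
# attention-evaluation metrics
# ---------------------------------------------------------------------------

def attention_auroc(attention, masks):
    """Max over masks of AUROC(attention as scorer of mask membership).

    Masks covering no atom or every atom leave AUROC undefined and are
    skipped; returns None if no mask is scorable.
    """
    attention = np.asarray(attention, dtype=float)
    best = None
    for mask in masks:
        y = np.zeros(len(attention))
        y[sorted(mask)] = 1.0
        if y.sum() == 0 or y.sum() == len(y):
            continue
        score = roc_auc_score(y, attention)
        best = score if best is None else max(best, score)
    return best


def attention_acc(attention, masks):
    """Max over masks of the thresholded attention accuracy.

    An atom is predicted important when its attention weight is >= 0.5; the
    accuracy is the fraction of atoms whose predicted importance equals the
    mask label.
    """
    attention = np.asarray(attention, dtype=float)
    if attention.size == 0:
        raise ValueError("empty attention vector")
    pred = (attention >= 0.5).astype(float)
    best = None
    for mask in masks:
        y = np.zeros(len(attention))
        y[sorted(mask)] = 1.0
        acc = float(np.mean(pred == y))
        best = acc if best is None else max(best, acc)
    return best


def evaluate_interpretation(records, masks_by_id, fold_networks, graphs_by_id,
                            threshold=0.5):
    """Mean AttAUROC/AttACC over true-positive predictions, per fold.

    For each fold model, only molecules that are labelled positive *and*
    predicted positive by that fold are scored, on the fold's own combined
    atom-level attention; fold means are then averaged, and the standard
    deviation across folds is reported.
    """
    from .interpret import attention_for_molecule

    per_fold = []
    for net in fold_networks:
        aurocs, accs = [], []
        for rec in records:
            gt = masks_by_id[rec.id]
            if gt.label != 1 or not gt.masks:
                continue
            res = attention_for_molecule(net, graphs_by_id[rec.id], label=rec.target)
            if res.prediction < threshold:
                continue
            auroc = attention_auroc(res.combined, gt.masks)
            acc = attention_acc(res.combined, gt.masks)
            if auroc is not None:
                aurocs.append(auroc)
            if acc is not None:
                accs.append(acc)
        if not aurocs:
            raise ValueError("a fold produced no scorable true positives")
        per_fold.append({"AttAUROC": float(np.mean(aurocs)),
                         "AttACC": float(np.mean(accs)),
                         "n_true_positive": len(aurocs)})
    df = pd.DataFrame(per_fold)
    summary = {
        "AttAUROC_mean": float(df["AttAUROC"].mean()),
        "AttAUROC_std": float(df["AttAUROC"].std(ddof=0)),
        "AttACC_mean": float(df["AttACC"].mean()),
        "AttACC_std": float(df["AttACC"].std(ddof=0)),
    }
    return df, summary
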