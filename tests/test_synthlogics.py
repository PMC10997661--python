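import numpy as np
import pytest
from rdkit import Chem

from mmgx.synthlogics import (And, ConfigurationError, LogicSpec, Not, Or,
                              Pattern, attention_acc, attention_auroc,
                              builtin_logics, evaluate_logic, generate_dataset,
                              get_logic, read_masks, write_generated)


class TestBuiltinLogics:
    def test_five_builtins(self):
        assert len(builtin_logics()) == 5
        assert [s.name for s in builtin_logics()] == [
            "Logic6", "Logic7", "Logic9", "Logic14", "3MR"]

    @pytest.mark.parametrize("logic,smiles,label", [
        ("Logic6", "CC(=O)F", 1),        # fluorine + carbonyl
        ("Logic6", "CC(=O)C", 0),        # carbonyl, no F
        ("Logic6", "CCF", 0),            # F, no carbonyl
        ("Logic7", "CCCCC(C)=O", 1),     # unbranched chain + carbonyl
        ("Logic9", "NCc1ccccc1", 0),     # amine + benzene but no ether
        ("Logic9", "NCCOCc1ccccc1", 1),
        ("Logic14", "C#CC(C)=O", 0),     # alkyne NOT-clause vetoes
        ("Logic14", "CCC(C)=O", 1),      # carbonyl, no OH, no alkyne
        ("Logic14", "OCC(C)=O", 0),      # hydroxyl without ether vetoes
        ("3MR", "C1CC1", 1),
        ("3MR", "c1ccccc1", 0),
    ])
    def test_labels(self, logic, smiles, label):
        assert evaluate_logic(get_logic(logic), smiles).label == label

    def test_unknown_logic_lists_builtins(self):
        with pytest.raises(ConfigurationError, match="Logic6"):
            get_logic("Logic99")


class TestGroundTruths:
    def test_cyclopropane_mask(self):
        gt = evaluate_logic(get_logic("3MR"), "C1CC1")
        assert gt.masks == [frozenset({0, 1, 2})]

    def test_negative_has_no_mask(self):
        assert evaluate_logic(get_logic("3MR"), "c1ccccc1").masks == []

    def test_two_carbonyls_give_multiple_alternatives(self):
        gt = evaluate_logic(get_logic("Logic7"), "O=C(C)CCCCC(C)=O")
        assert gt.label == 1
        assert len(gt.masks) >= 2

    def test_not_leaves_contribute_no_atoms(self):
        gt = evaluate_logic(get_logic("Logic14"), "CCC(C)=O")
        carbonyl = Chem.MolFromSmiles("CCC(C)=O").GetSubstructMatches(
            Chem.MolFromSmarts("[CX3]=O"))
        assert gt.label == 1
        # every mask is exactly a carbonyl match (no atoms from NOT clauses)
        assert all(m == frozenset(carbonyl[0]) for m in gt.masks)

    def test_agrees_with_independent_leaf_enumeration(self):
        # brute-force evaluator: evaluate every leaf independently with raw
        # RDKit matching and recombine through plain python logic
        spec = get_logic("Logic14")
        records, _ = generate_dataset("Logic14", 120, seed=31)
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            ether = mol.HasSubstructMatch(Chem.MolFromSmarts("[OD2](C)C"))
            oh = mol.HasSubstructMatch(Chem.MolFromSmarts("[OX2H]"))
            co = mol.HasSubstructMatch(Chem.MolFromSmarts("[CX3]=O"))
            alkyne = mol.HasSubstructMatch(Chem.MolFromSmarts("[CX2]#[CX2]"))
            expected = (ether or not oh) and co and not alkyne
            assert evaluate_logic(spec, mol).label == int(expected), rec.smiles


class TestGenerator:
    def test_deterministic_per_seed(self):
        a, am = generate_dataset("3MR", 120, seed=5)
        b, bm = generate_dataset("3MR", 120, seed=5)
        assert [r.smiles for r in a] == [r.smiles for r in b]
        assert all(am[r.id].masks == bm[r.id].masks for r in a)

    def test_labels_self_consistent(self, tiny_3mr):
        records, masks = tiny_3mr
        spec = get_logic("3MR")
        for rec in records[:80]:
            gt = evaluate_logic(spec, rec.smiles)
            assert gt.label == int(rec.target)
            assert masks[rec.id].label == gt.label

    def test_class_balance(self, tiny_3mr):
        records, _ = tiny_3mr
        rate = np.mean([r.target for r in records])
        assert 0.45 <= rate <= 0.55

    def test_roundtrip_files(self, tmp_path, tiny_3mr):
        records, masks = tiny_3mr
        write_generated(records, masks, tmp_path / "d.csv", tmp_path / "m.json")
        loaded = read_masks(tmp_path / "m.json")
        assert loaded.keys() == masks.keys()
        some_pos = next(r.id for r in records if r.target == 1)
        assert loaded[some_pos].masks == masks[some_pos].masks


def brute_force_auroc(scores, labels):
    """O(N^2) pairwise concordance."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    pairs = [(a > b) + 0.5 * (a == b) for a in pos for b in neg]
    return float(np.mean(pairs))


class TestAttentionMetrics:
    def test_oracle_attention_scores_one(self):
        att = np.array([1.0, 1.0, 0.0, 0.0])
        assert attention_auroc(att, [frozenset({0, 1})]) == 1.0
        assert attention_acc(att, [frozenset({0, 1})]) == 1.0

    def test_uniform_attention_auroc_half(self):
        assert attention_auroc(np.full(6, 0.3), [frozenset({1, 2})]) == 0.5

    def test_five_atom_worked_example(self):
        att = [0.9, 0.8, 0.1, 0.7, 0.2]
        assert attention_auroc(att, [frozenset({0, 1, 3})]) == 1.0

    def test_acc_threshold_rule(self):
        # all weights 0.6 -> every atom predicted important; mask {0} of 4
        assert attention_acc([0.6] * 4, [frozenset({0})]) == 0.25

    def test_acc_worked_example(self):
        assert attention_acc([0.9, 0.1, 0.2, 0.8], [frozenset({0, 3})]) == 1.0

    def test_max_over_masks(self):
        att = [0.9, 0.9, 0.1]
        masks = [frozenset({0}), frozenset({0, 1})]
        assert attention_acc(att, masks) == 1.0

    def test_degenerate_masks_skipped(self):
        att = [0.4, 0.6, 0.8]
        assert attention_auroc(att, [frozenset({0, 1, 2})]) is None

    def test_empty_attention_rejected(self):
        with pytest.raises(ValueError):
            attention_acc([], [frozenset({0})])

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = rng.integers(4, 15)
            att = rng.random(n)
            k = rng.integers(1, n)
            mask = frozenset(rng.choice(n, size=k, replace=False).tolist())
            y = np.array([1.0 if i in mask else 0.0 for i in range(n)])
            expected_auroc = brute_force_auroc(att, y)
            assert attention_auroc(att, [mask]) == pytest.approx(
                expected_auroc, abs=1e-9)
            expected_acc = np.mean((att >= 0.5).astype(float) == y)
            assert attention_acc(att, [mask]) == pytest.approx(
                expected_acc, abs=1e-9)


class TestEvaluateInterpretation:
    def test_true_positive_filter_and_fold_summary(self, fitted_3mr):
        results, masks = fitted_3mr
        per_fold, summary = results.evaluate_interpretation(masks)
        assert len(per_fold) == len(results.networks)
        assert 0 <= summary["AttAUROC_mean"] <= 1
        assert 0 <= summary["AttACC_mean"] <= 1
        assert (per_fold["n_true_positive"] > 0).all()

    def test_random_attention_near_chance(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(500):
            n = 20
            att = rng.random(n)
            mask = frozenset(rng.choice(n, size=6, replace=False).tolist())
            vals.append(attention_auroc(att, [mask]))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)
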