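import numpy as np
import pytest
from rdkit import Chem

from mmgx.substructures import (ExtractionConfig, FragmentOccurrence,
                                FragmentRecord, collect_fragment_records,
                                detect_important_fragments, fragment_molecule,
                                potential_substructures_view, score_fragment,
                                select_potential_substructures)


def occ(m_frag, m_mol, mol_id="m", important=True):
    return FragmentOccurrence(molecule_id=mol_id, atoms=frozenset([0, 1, 2]),
                              m_frag=m_frag, m_mol=m_mol, important=important)


class TestFragmentation:
    def test_cyclopropane_whole_ring_only(self):
        frags = fragment_molecule("C1CC1")
        assert len(frags) == 1
        assert frags[0][1] == frozenset([0, 1, 2])

    def test_ethane_below_size_floor(self):
        assert fragment_molecule("CC") == []

    def test_aspirin_fragments_obey_constraints(self):
        mol = Chem.MolFromSmiles("CC(=O)OC1=CC=CC=C1C(=O)O")
        ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
        frags = fragment_molecule(mol)
        assert len(frags) > 3
        for smiles, atoms in frags:
            assert 3 <= len(atoms) <= 20
            # rings are never broken: a fragment either contains the whole
            # benzene ring or none of it
            overlap = atoms & ring_atoms
            assert overlap in (set(), ring_atoms), smiles

    def test_fragmenters_are_subsets_of_grinder(self):
        mol = Chem.MolFromSmiles("CCOC(=O)c1ccccc1NC(C)=O")
        grinder = {a for _, a in fragment_molecule(mol, ("grinder",))}
        for name in ("brics", "recap"):
            sub = {a for _, a in fragment_molecule(mol, (name,))}
            assert sub <= grinder

    def test_unknown_fragmenter_rejected(self):
        with pytest.raises(ValueError):
            fragment_molecule("CCCC", ("magic",))


class TestImportanceDetection:
    def test_uniform_attention_flags_nothing(self):
        mol = Chem.MolFromSmiles("CCCCCC")
        frags = fragment_molecule(mol)
        flags = detect_important_fragments(np.full(6, 0.4), frags, p_f=75)
        assert not any(flags)

    def test_concentrated_attention_flags_the_hot_fragment(self):
        # attention (1,1,1,0,...,0): with 3 of 12 atoms hot, the 75th
        # percentile falls below 1 and the hot ring's median exceeds it
        mol = Chem.MolFromSmiles("C1CC1CCCCCCCCC")
        att = np.zeros(mol.GetNumAtoms())
        att[:3] = 1.0  # the ring
        frags = fragment_molecule(mol)
        flags = detect_important_fragments(att, frags, p_f=75)
        ring = frozenset([0, 1, 2])
        flagged = {atoms for (_, atoms), f in zip(frags, flags) if f}
        assert ring in flagged

    def test_flags_match_per_fragment_brute_force(self):
        rng = np.random.default_rng(2)
        mol = Chem.MolFromSmiles("CCOC(=O)CC(N)c1ccccc1")
        att = rng.random(mol.GetNumAtoms())
        frags = fragment_molecule(mol)
        flags = detect_important_fragments(att, frags, p_f=60)
        cutoff = np.percentile(att, 60)
        for (_, atoms), flag in zip(frags, flags):
            assert flag == (np.median(att[sorted(atoms)]) > cutoff)


class TestScore:
    def test_worked_example(self):
        assert score_fragment([occ(0.8, 0.5), occ(0.6, 0.5)]) == pytest.approx(0.2)

    def test_zero_difference(self):
        assert score_fragment([occ(0.5, 0.5), occ(0.3, 0.3)]) == 0.0

    def test_single_occurrence(self):
        assert score_fragment([occ(0.9, 0.4)]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_fragment([])


def _record(smiles, occurrences):
    r = FragmentRecord(smiles=smiles)
    r.occurrences = occurrences
    return r


class TestSelection:
    def test_zero_score_excluded(self):
        recs = {
            "CCC": _record("CCC", [occ(0.5, 0.5, f"m{i}") for i in range(5)]),
            "CCO": _record("CCO", [occ(0.9, 0.4, f"m{i}") for i in range(5)]),
        }
        table = select_potential_substructures(recs, ExtractionConfig(p_s=10))
        assert "CCC" not in set(table["fragment"])
        assert "CCO" in set(table["fragment"])

    def test_low_support_excluded_by_percentile(self):
        recs = {f"frag{i}": _record(f"frag{i}", [occ(0.9, 0.1, f"m{j}")
                                                 for j in range(10)])
                for i in range(9)}
        recs["rare"] = _record("rare", [occ(0.9, 0.1, "m0")])
        table = select_potential_substructures(recs, ExtractionConfig(p_s=70))
        assert "rare" not in set(table["fragment"])

    def test_importance_percentage_rule(self):
        half = [occ(0.9, 0.1, f"m{i}", important=(i < 2)) for i in range(5)]
        recs = {"CCN": _record("CCN", half)}
        table = select_potential_substructures(recs, ExtractionConfig(p_s=10))
        assert len(table) == 0  # 40% < 50%

    def test_redundant_subfragment_pruned(self):
        big = [occ(0.9, 0.1, f"m{i}") for i in range(5)]
        small = [occ(0.8, 0.1, f"m{i}") for i in range(5)]
        recs = {"CCCO": _record("CCCO", big), "CCO": _record("CCO", small)}
        table = select_potential_substructures(recs, ExtractionConfig(p_s=10))
        assert set(table["fragment"]) == {"CCCO"}

    def test_raising_support_percentile_never_enlarges_kept_set(self):
        # monotone before redundancy pruning: a higher P_s only raises the
        # support cutoff (pruning itself may resurrect subfragments)
        rng = np.random.default_rng(4)
        mols = []
        for i, smi in enumerate(["CCOC(=O)CC", "CCOC(=O)CN", "CCCCOC(C)=O",
                                 "c1ccccc1CC(N)=O", "C1CC1CC(=O)OC"]):
            mol = Chem.MolFromSmiles(smi)
            mols.append((f"m{i}", mol, rng.random(mol.GetNumAtoms())))
        records = collect_fragment_records(mols, ExtractionConfig(p_f=60))
        loose = select_potential_substructures(
            records, ExtractionConfig(p_f=60, p_s=30), prune_redundant=False)
        tight = select_potential_substructures(
            records, ExtractionConfig(p_f=60, p_s=90), prune_redundant=False)
        assert set(tight["fragment"]) <= set(loose["fragment"])

    def test_raising_pf_never_adds_importance_flags(self):
        rng = np.random.default_rng(6)
        mol = Chem.MolFromSmiles("CCOC(=O)c1ccccc1NC(C)=O")
        att = rng.random(mol.GetNumAtoms())
        frags = fragment_molecule(mol)
        low = detect_important_fragments(att, frags, p_f=60)
        high = detect_important_fragments(att, frags, p_f=85)
        assert all(not h or l for l, h in zip(low, high))

    def test_statistics_invariant_to_processing_order(self):
        rng = np.random.default_rng(9)
        mols = []
        for i, smi in enumerate(["CCOC(=O)CC", "CCCCN", "c1ccccc1CCO"]):
            mol = Chem.MolFromSmiles(smi)
            mols.append((f"m{i}", mol, rng.random(mol.GetNumAtoms())))
        a = collect_fragment_records(mols)
        b = collect_fragment_records(list(reversed(mols)))
        assert set(a) == set(b)
        for smiles in a:
            assert a[smiles].score == pytest.approx(b[smiles].score)
            assert a[smiles].n_compounds == b[smiles].n_compounds

    def test_selected_fragments_reverify_all_conditions(self):
        rng = np.random.default_rng(1)
        mols = []
        for i, smi in enumerate(["CCOC(=O)CC", "CCOC(=O)CN", "CCCCOC(C)=O",
                                 "c1ccccc1CC(N)=O"]):
            mol = Chem.MolFromSmiles(smi)
            att = rng.random(mol.GetNumAtoms())
            mols.append((f"m{i}", mol, att))
        cfg = ExtractionConfig(p_f=60, p_s=50)
        records = collect_fragment_records(mols, cfg)
        table = select_potential_substructures(records, cfg)
        support = np.array([r.n_important_compounds for r in records.values()])
        cutoff = np.percentile(support, cfg.p_s)
        for _, row in table.iterrows():
            rec = records[row["fragment"]]
            assert rec.important_percentage >= 50
            assert rec.n_important_compounds >= cutoff
            assert rec.score > 0
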