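"""Potential-substructures view: fragmentation, importance, scoring, selection.

Molecules are fragmented by cutting acyclic single bonds — rings are never
broken — and every connected piece of 3–20 heavy atoms is a candidate
fragment.  Three cut-bond generators are available:

* ``brics``   — cut bonds proposed by the BRICS rules (RDKit);
* ``recap``   — cut bonds matching the RECAP cleavage-bond patterns;
* ``grinder`` — every acyclic single bond (exhaustive enumeration).

Each generator enumerates subsets of up to ``max_cuts`` simultaneous cuts.

A fragment occurrence is *important* when the median attention over its
atoms strictly exceeds the ``P_f`` percentile of the whole molecule's atom
attentions.  Per fragment type the importance score is

    Score_frag = mean over occurrences of (M_frag - M_mol)

with ``M_frag`` the mean attention of the fragment's atoms and ``M_mol``
the mean attention of all atoms of the molecule.  A fragment is selected as
a potential substructure when its important-occurrence percentage is >= 50%,
its important-compound count reaches the ``P_s`` percentile among all
fragments, and its score is positive; substructure-redundant survivors are
then pruned.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS

logger = logging.getLogger(__name__)

MIN_FRAGMENT_ATOMS = 3
MAX_FRAGMENT_ATOMS = 20

# RECAP cleavage-bond SMARTS; the cleaved bond is the one between the FIRST
# TWO mapped atoms of each pattern, so every pattern starts with that pair
RECAP_BOND_SMARTS = [
    "[C;!$(C=[O,N,S])]!@[N;!$(N=*)]",        # amine C-N
    "[NX3]!@[CX3]=[OX1]",                    # amide N-C(=O)
    "[OX2]!@[CX3]=[OX1]",                    # ester O-C(=O)
    "[OX2]!@[c]",                            # aromatic ether
    "[OX2;!$(O[CX3]=[OX1])]!@[C;!$(C=*)]",   # aliphatic ether
    "[c]!@[c]",                              # biaryl
    "[NX3]!@[c]",                            # aromatic N - aliphatic N side
    "[NX3]!@[SX4](=[OX1])=[OX1]",            # sulfonamide
    "[CX4]!@[CX3]=[CX3]",                    # allylic C-C
]


@dataclass
class FragmentOccurrence:
    molecule_id: str
    atoms: frozenset
    m_frag: float      # mean attention over fragment atoms
    m_mol: float       # mean attention over all molecule atoms
    important: bool


@dataclass
class FragmentRecord:
    smiles: str
    occurrences: list = field(default_factory=list)

    @property
    def n_compounds(self) -> int:
        return len({o.molecule_id for o in self.occurrences})

    @property
    def n_important_compounds(self) -> int:
        return len({o.molecule_id for o in self.occurrences if o.important})

    @property
    def important_percentage(self) -> float:
        return 100.0 * self.n_important_compounds / self.n_compounds

    @property
    def score(self) -> float:
        return score_fragment(self.occurrences)


@dataclass
class ExtractionConfig:
    """Thresholds of the selection rules.

    ``p_f``: percentile of molecule attentions a fragment's median must
    exceed to count as important (default 75).  ``p_s``: percentile of
    important-compound counts a fragment must reach (default 70).  The 50%
    important-percentage rule is fixed.
    """

    p_f: float = 75.0
    p_s: float = 70.0
    min_important_pct: float = 50.0
    fragmenters: tuple = ("brics", "recap", "grinder")
    max_cuts: int = 2

    def __post_init__(self):
        if not (0 < self.p_f < 100 and 0 < self.p_s < 100):
            raise ValueError("percentiles must lie in (0, 100)")


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def _acyclic_single_bonds(mol):
    return [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if not b.IsInRing() and b.GetBondType() == Chem.BondType.SINGLE
    ]


def _brics_bonds(mol):
    return [tuple(map(int, pair)) for pair, _ in BRICS.FindBRICSBonds(mol)]


def _recap_bonds(mol):
    bonds = set()
    for smarts in RECAP_BOND_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            i, j = match[0], match[1]
            bond = mol.GetBondBetweenAtoms(i, j)
            if (bond is not None and not bond.IsInRing()
                    and bond.GetBondType() == Chem.BondType.SINGLE):
                bonds.add((min(i, j), max(i, j)))
    return sorted(bonds)


CUT_GENERATORS = {
    "brics": _brics_bonds,
    "recap": _recap_bonds,
    "grinder": _acyclic_single_bonds,
}


def _components_after_cuts(mol, cut_bonds):
    n = mol.GetNumAtoms()
    cut = {frozenset(b) for b in cut_bonds}
    adj = [[] for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if frozenset((i, j)) not in cut:
            adj[i].append(j)
            adj[j].append(i)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            stack.extend(adj[a])
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def fragment_molecule(mol, fragmenters=("brics", "recap", "grinder"),
                      max_cuts=2):
    """All candidate (fragment SMILES, atom set) pairs for one molecule.

    Only acyclic single bonds are ever cut, so rings stay intact; connected
    pieces of 3–20 heavy atoms survive.  Fragments are deduplicated by atom
    set across fragmenters.
    """
    if isinstance(mol, str):
        mol = Chem.MolFromSmiles(mol)
    seen_atom_sets = set()
    out = []
    for name in fragmenters:
        try:
            bonds = CUT_GENERATORS[name](mol)
        except KeyError:
            raise ValueError(f"unknown fragmenter {name!r}") from None
        for k in range(1, min(max_cuts, len(bonds)) + 1):
            for subset in itertools.combinations(bonds, k):
                for comp in _components_after_cuts(mol, subset):
                    if not (MIN_FRAGMENT_ATOMS <= len(comp) <= MAX_FRAGMENT_ATOMS):
                        continue
                    if comp in seen_atom_sets:
                        continue
                    seen_atom_sets.add(comp)
                    smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(comp),
                                                      canonical=True)
                    out.append((smiles, comp))
    # a whole small molecule is its own candidate (e.g. cyclopropane)
    whole = frozenset(range(mol.GetNumAtoms()))
    if (MIN_FRAGMENT_ATOMS <= len(whole) <= MAX_FRAGMENT_ATOMS
            and whole not in seen_atom_sets):
        out.append((Chem.MolToSmiles(mol), whole))
    return out


# ---------------------------------------------------------------------------
# importance, statistics, scoring
# ---------------------------------------------------------------------------

def detect_important_fragments(attention, fragments, p_f=75.0):
    """Importance flags: median fragment attention > P_f molecule percentile."""
    attention = np.asarray(attention, dtype=float)
    cutoff = np.percentile(attention, p_f)
    return [bool(np.median(attention[sorted(atoms)]) > cutoff)
            for _, atoms in fragments]


def score_fragment(occurrences) -> float:
    """Mean over occurrences of (fragment mean attention - molecule mean)."""
    if not occurrences:
        raise ValueError("score undefined for an empty occurrence list")
    return float(np.mean([o.m_frag - o.m_mol for o in occurrences]))


def collect_fragment_records(molecules, config: ExtractionConfig = None):
    """Fragment statistics over (molecule id, mol, attention vector) triples."""
    config = config or ExtractionConfig()
    records: dict = {}
    for mol_id, mol, attention in sorted(molecules, key=lambda t: t[0]):
        if isinstance(mol, str):
            mol = Chem.MolFromSmiles(mol)
        attention = np.asarray(attention, dtype=float)
        frags = fragment_molecule(mol, config.fragmenters, config.max_cuts)
        flags = detect_important_fragments(attention, frags, config.p_f)
        m_mol = float(attention.mean())
        for (smiles, atoms), important in zip(frags, flags):
            rec = records.setdefault(smiles, FragmentRecord(smiles=smiles))
            rec.occurrences.append(FragmentOccurrence(
                molecule_id=mol_id, atoms=atoms,
                m_frag=float(attention[sorted(atoms)].mean()),
                m_mol=m_mol, important=important))
    return records


def _is_substructure(small_smiles, big_smiles):
    small = Chem.MolFromSmiles(small_smiles)
    big = Chem.MolFromSmiles(big_smiles)
    if small is None or big is None:
        return False
    return big.HasSubstructMatch(small)


def select_potential_substructures(records, config: ExtractionConfig = None,
                                   prune_redundant=True) -> pd.DataFrame:
    """Apply the three selection rules and prune redundant survivors.

    Redundancy: a kept fragment that is a substructure of another kept
    fragment with an equal-or-higher score is dropped.  Note the support
    cutoff is a *relative* percentile and pruning depends on the surviving
    set, so only the pre-pruning rules are monotone in ``p_s``.
    """
    config = config or ExtractionConfig()
    records = list(records.values()) if isinstance(records, dict) else list(records)
    if not records:
        warnings.warn("no fragments to select from")
        return _empty_table()
    support = np.array([r.n_important_compounds for r in records], dtype=float)
    support_cutoff = np.percentile(support, config.p_s)
    kept = [
        r for r in records
        if r.important_percentage >= config.min_important_pct
        and r.n_important_compounds >= support_cutoff
        and r.score > 0.0
    ]
    kept.sort(key=lambda r: (-r.score, r.smiles))
    if not prune_redundant:
        return pd.DataFrame([
            {"fragment": r.smiles, "n_compounds": r.n_compounds,
             "n_important_compounds": r.n_important_compounds,
             "important_percentage": r.important_percentage, "score": r.score}
            for r in kept
        ]) if kept else _empty_table()
    pruned = []
    for r in kept:
        redundant = any(
            other.smiles != r.smiles
            and other.score >= r.score
            and _is_substructure(r.smiles, other.smiles)
            for other in kept
        )
        if not redundant:
            pruned.append(r)
    if not pruned:
        warnings.warn("no fragment passed all selection conditions")
        return _empty_table()
    return pd.DataFrame([
        {"fragment": r.smiles, "n_compounds": r.n_compounds,
         "n_important_compounds": r.n_important_compounds,
         "important_percentage": r.important_percentage, "score": r.score}
        for r in pruned
    ])


def _empty_table():
    return pd.DataFrame(columns=["fragment", "n_compounds",
                                 "n_important_compounds",
                                 "important_percentage", "score"])


def potential_substructures_view(molecules, config: ExtractionConfig = None
                                 ) -> pd.DataFrame:
    """End-to-end: fragment, flag, score, and select over a molecule set."""
    config = config or ExtractionConfig()
    return select_potential_substructures(
        collect_fragment_records(molecules, config), config)
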