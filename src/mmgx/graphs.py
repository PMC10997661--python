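"""The four molecular graph representations and their reduction maps.

Every representation is produced by a reduction that contracts subgraphs of
the atom-level graph into nodes and records, for each node, the set of
source atom indices it covers (``atom_map``).  That map is what later lets
attention weights on reduced nodes be redistributed back onto atoms.

Representations
---------------
``A``  atom graph: heavy atoms as nodes, bonds as edges.
``P``  pharmacophore graph (ErG-style): nodes typed by six pharmacophoric
       properties (donor, acceptor, positive, negative, hydrophobic,
       aromatic); ring systems collapse to one node per ring, carbon chains
       of length >= 3 collapse to hydrophobic nodes, atoms with no type
       become untyped linker nodes so topology survives.
``J``  junction-tree graph: rings, non-ring bonds, and junction atoms
       (shared by >= 3 clusters) as nodes; a maximum spanning tree over the
       cluster adjacency guarantees the result is acyclic.
``F``  functional-group graph: greedy non-overlapping matching of a
       predefined SMARTS vocabulary (largest first), then rings, then
       leftover bonds as atom-pair nodes; every atom is covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

REPRESENTATIONS = ("A", "P", "J", "F")

# ---------------------------------------------------------------------------
# feature vocabularies
# ---------------------------------------------------------------------------

ATOM_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "other"]
ATOM_DEGREES = list(range(6))
ATOM_HYBRIDIZATIONS = ["SP", "SP2", "SP3", "SP3D", "SP3D2", "other"]
BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]

PHARMACOPHORE_TYPES = ["donor", "acceptor", "positive", "negative", "hydrophobic", "aromatic"]

# ErG-style SMARTS definitions; the source reduction only names the six
# property classes, so the exact patterns are a package choice and may be
# overridden via build_pharmacophore_graph(..., smarts=...).
PHARMACOPHORE_SMARTS = {
    "donor": "[$([N;!H0]),$([O;!H0]),$([n;!H0])]",
    "acceptor": "[$([O;X1]),$([O;X2]),$([N;X1]),$([N;X2]),$([n;X2]),$([N;X3;!$([N+]);!$(N~[O])])]",
    "positive": "[$([+,+2,+3]),$([NX3;H2;+0;!$(NC=O);!$(N~[!#6])])]",
    "negative": "[$([-,-2,-3]),$([OX2H1][CX3]=[OX1]),$([OX2H1][SX4](=O)=O)]",
}

# Functional-group vocabulary for the F graph: (name, SMARTS).  Matching is
# greedy non-overlapping, largest match first, ties broken by list order.
FUNCTIONAL_GROUPS = [
    ("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3]"),
    ("sulfonate", "[SX4](=[OX1])(=[OX1])[OX2]"),
    ("sulfone", "[SX4](=[OX1])(=[OX1])"),
    ("sulfoxide", "[SX3](=[OX1])"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("amide", "[CX3](=[OX1])[NX3]"),
    ("carboxylic_acid", "[CX3](=[OX1])[OX2H1]"),
    ("ester", "[CX3](=[OX1])[OX2H0]"),
    ("anhydride", "[CX3](=[OX1])[OX2][CX3](=[OX1])"),
    ("acyl_halide", "[CX3](=[OX1])[F,Cl,Br,I]"),
    ("aldehyde", "[CX3H1](=[OX1])"),
    ("ketone", "[CX3](=[OX1])[#6]"),
    ("nitro", "[NX3](=[OX1])(=[OX1])"),
    ("nitro_charged", "[NX3+](=[OX1])[OX1-]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("azo", "[NX2]=[NX2]"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
    ("nitrile", "[CX2]#[NX1]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("thiocyanate", "[SX2][CX2]#[NX1]"),
    ("imine", "[CX3]=[NX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("amidine", "[CX3](=[NX2])[NX3]"),
    ("hydrazine", "[NX3][NX3]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("hydroxyl", "[OX2H]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("amine", "[NX3;!$(N=O);!$(NC=O);!$(NS=O)]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("alkene", "[CX3]=[CX3]"),
    ("halide_F", "[F]"),
    ("halide_Cl", "[Cl]"),
    ("halide_Br", "[Br]"),
    ("halide_I", "[I]"),
    ("phosphate", "[PX4](=[OX1])"),
]


@dataclass
class FeatureVocabulary:
    """Ordered node (and edge) feature slot names for one representation."""

    representation: str
    node_features: list
    edge_features: list = field(default_factory=list)

    @property
    def node_dim(self) -> int:
        return len(self.node_features)

    @property
    def edge_dim(self) -> int:
        return len(self.edge_features)


def _one_hot_names(prefix, values):
    return [f"{prefix}={v}" for v in values]


ATOM_VOCAB = FeatureVocabulary(
    "A",
    node_features=(
        _one_hot_names("element", ATOM_ELEMENTS)
        + _one_hot_names("degree", ATOM_DEGREES)
        + ["formal_charge"]
        + ["aromatic"]
        + _one_hot_names("hybridization", ATOM_HYBRIDIZATIONS)
        + ["num_h"]
        + ["in_ring"]
    ),
    edge_features=(
        _one_hot_names("bond", BOND_TYPES) + ["conjugated", "in_ring"]
    ),
)

PHARM_VOCAB = FeatureVocabulary(
    "P", node_features=PHARMACOPHORE_TYPES + ["is_ring", "n_atoms"]
)

JT_VOCAB = FeatureVocabulary(
    "J", node_features=["kind=ring", "kind=bond", "kind=junction", "n_atoms", "aromatic"]
)

FG_VOCAB = FeatureVocabulary(
    "F",
    node_features=(
        [f"group={name}" for name, _ in FUNCTIONAL_GROUPS]
        + ["group=ring", "group=atom_pair", "n_atoms", "aromatic"]
    ),
)

VOCABULARIES = {"A": ATOM_VOCAB, "P": PHARM_VOCAB, "J": JT_VOCAB, "F": FG_VOCAB}


@dataclass
class MolecularGraph:
    """One reduced (or atom-level) graph of a molecule.

    ``atom_map[i]`` is the frozenset of heavy-atom indices that node ``i``
    covers in the source atom-level graph.
    """

    representation: str
    node_features: np.ndarray          # (n_nodes, node_dim)
    edges: list                        # [(i, j), ...] undirected, i < j
    atom_map: list                     # [frozenset(atom indices), ...]
    n_atoms: int
    edge_features: np.ndarray | None = None  # (n_edges, edge_dim) for A

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def to_json_dict(self) -> dict:
        return {
            "representation": self.representation,
            "node_features": self.node_features.tolist(),
            "edges": [list(e) for e in self.edges],
            "atom_map": [sorted(s) for s in self.atom_map],
            "n_atoms": self.n_atoms,
            "edge_features": None if self.edge_features is None else self.edge_features.tolist(),
            "feature_names": VOCABULARIES[self.representation].node_features,
        }


def _mol_from_record(record):
    mol = record.mol() if hasattr(record, "mol") else Chem.MolFromSmiles(record)
    if mol is None:
        raise ValueError("record does not contain a parseable molecule")
    return mol


def _one_hot(value, values):
    v = np.zeros(len(values))
    v[values.index(value) if value in values else len(values) - 1] = 1.0
    return v


# ---------------------------------------------------------------------------
# Atom graph
# ---------------------------------------------------------------------------

def atom_features(atom) -> np.ndarray:
    return np.concatenate([
        _one_hot(atom.GetSymbol(), ATOM_ELEMENTS),
        _one_hot(min(atom.GetDegree(), 5), ATOM_DEGREES),
        [float(atom.GetFormalCharge())],
        [float(atom.GetIsAromatic())],
        _one_hot(str(atom.GetHybridization()), ATOM_HYBRIDIZATIONS),
        [float(atom.GetTotalNumHs())],
        [float(atom.IsInRing())],
    ])


def bond_features(bond) -> np.ndarray:
    return np.concatenate([
        _one_hot(str(bond.GetBondType()), BOND_TYPES),
        [float(bond.GetIsConjugated())],
        [float(bond.IsInRing())],
    ])


def build_atom_graph(record) -> MolecularGraph:
    """Heavy atoms as nodes, bonds as edges; atom_map[i] = {i}."""
    mol = _mol_from_record(record)
    nodes = np.array([atom_features(a) for a in mol.GetAtoms()])
    edges, efeat = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeat.append(bond_features(bond))
    efeat = np.array(efeat) if efeat else np.zeros((0, ATOM_VOCAB.edge_dim))
    return MolecularGraph(
        "A", nodes, edges, [frozenset([i]) for i in range(mol.GetNumAtoms())],
        mol.GetNumAtoms(), efeat,
    )


# ---------------------------------------------------------------------------
# shared reduction helpers
# ---------------------------------------------------------------------------

def _cluster_edges(mol, clusters):
    """Edges between clusters that share an atom or are joined by a bond."""
    atom2clusters: dict = {}
    for ci, atoms in enumerate(clusters):
        for a in atoms:
            atom2clusters.setdefault(a, set()).add(ci)
    edges = set()
    for a, owners in atom2clusters.items():
        for ci in owners:
            for cj in owners:
                if ci < cj:
                    edges.add((ci, cj))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for ci in atom2clusters.get(i, ()):
            for cj in atom2clusters.get(j, ()):
                if ci != cj:
                    edges.add((min(ci, cj), max(ci, cj)))
    return sorted(edges)


def _sorted_clusters(clusters):
    """Deterministic node order: by smallest atom index, then size, then content."""
    return sorted(clusters, key=lambda s: (min(s), len(s), sorted(s)))


# ---------------------------------------------------------------------------
# Pharmacophore (ErG-style) graph
# ---------------------------------------------------------------------------

def _pharmacophore_atom_types(mol, smarts=None):
    smarts = smarts or PHARMACOPHORE_SMARTS
    types = {name: set() for name in PHARMACOPHORE_TYPES}
    for name, pattern in smarts.items():
        patt = Chem.MolFromSmarts(pattern)
        for match in mol.GetSubstructMatches(patt):
            types[name].update(match)
    return types


def build_pharmacophore_graph(record, smarts=None) -> MolecularGraph:
    """ErG-style reduction onto six pharmacophoric node types.

    Ring systems collapse to one node per SSSR ring (aromatic rings typed
    aromatic, carbocyclic aliphatic rings hydrophobic); acyclic carbon
    chains of length >= 3 with no other type collapse to one hydrophobic
    node; every other acyclic atom becomes its own (possibly untyped
    "linker") node.  Edges follow bonds/shared atoms between node atom sets.
    """
    mol = _mol_from_record(record)
    types = _pharmacophore_atom_types(mol, smarts)
    ring_info = mol.GetRingInfo()
    rings = [frozenset(r) for r in ring_info.AtomRings()]
    in_ring = set().union(*rings) if rings else set()

    clusters, cluster_bits = [], []
    for ring in _sorted_clusters(rings):
        bits = np.zeros(6)
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            bits[PHARMACOPHORE_TYPES.index("aromatic")] = 1.0
        elif all(mol.GetAtomWithIdx(a).GetSymbol() == "C" for a in ring):
            bits[PHARMACOPHORE_TYPES.index("hydrophobic")] = 1.0
        for name in ("donor", "acceptor", "positive", "negative"):
            if any(a in types[name] for a in ring):
                bits[PHARMACOPHORE_TYPES.index(name)] = 1.0
        clusters.append(frozenset(ring))
        cluster_bits.append(bits)

    # hydrophobic chains: maximal acyclic all-carbon, otherwise-untyped runs
    typed = set().union(*(types[n] for n in ("donor", "acceptor", "positive", "negative")))
    chain_atoms = {
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetIdx() not in in_ring and a.GetSymbol() == "C" and a.GetIdx() not in typed
    }
    sub = nx.Graph()
    sub.add_nodes_from(chain_atoms)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in chain_atoms and j in chain_atoms:
            sub.add_edge(i, j)
    collapsed = set()
    for comp in sorted(nx.connected_components(sub), key=min):
        if len(comp) >= 3:
            bits = np.zeros(6)
            bits[PHARMACOPHORE_TYPES.index("hydrophobic")] = 1.0
            clusters.append(frozenset(comp))
            cluster_bits.append(bits)
            collapsed |= comp

    # remaining acyclic atoms: one node each (typed or untyped linker)
    for atom in mol.GetAtoms():
        a = atom.GetIdx()
        if a in in_ring or a in collapsed:
            continue
        bits = np.zeros(6)
        for name in PHARMACOPHORE_TYPES[:4]:
            if a in types[name]:
                bits[PHARMACOPHORE_TYPES.index(name)] = 1.0
        clusters.append(frozenset([a]))
        cluster_bits.append(bits)

    if not clusters:  # no assignable feature at all: one fallback node
        clusters = [frozenset(range(mol.GetNumAtoms()))]
        cluster_bits = [np.zeros(6)]

    order = sorted(range(len(clusters)), key=lambda i: (min(clusters[i]), len(clusters[i])))
    clusters = [clusters[i] for i in order]
    cluster_bits = [cluster_bits[i] for i in order]
    ring_set = set(rings)
    feats = np.array([
        np.concatenate([bits, [float(c in ring_set)], [float(len(c))]])
        for bits, c in zip(cluster_bits, clusters)
    ])
    return MolecularGraph("P", feats, _cluster_edges(mol, clusters), clusters,
                          mol.GetNumAtoms())


# ---------------------------------------------------------------------------
# JunctionTree graph
# ---------------------------------------------------------------------------

def build_junctiontree_graph(record) -> MolecularGraph:
    """Rings, non-ring bonds, and junction atoms as nodes of an acyclic tree.

    Clusters sharing atoms are linked with weight = shared-atom count and a
    maximum spanning tree is taken per component, which removes any loop
    among clusters while preferring the strongest overlaps.
    """
    mol = _mol_from_record(record)
    rings = [frozenset(r) for r in Chem.GetSymmSSSR(mol)]
    clusters = list(_sorted_clusters(rings))
    kinds = ["ring"] * len(clusters)
    for bond in mol.GetBonds():
        if not bond.IsInRing():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            clusters.append(frozenset([i, j]))
            kinds.append("bond")
    # junction atoms: present in >= 3 clusters
    counts: dict = {}
    for c in clusters:
        for a in c:
            counts[a] = counts.get(a, 0) + 1
    for a in sorted(a for a, n in counts.items() if n >= 3):
        clusters.append(frozenset([a]))
        kinds.append("junction")

    order = sorted(range(len(clusters)),
                   key=lambda i: (min(clusters[i]), -len(clusters[i]), kinds[i]))
    clusters = [clusters[i] for i in order]
    kinds = [kinds[i] for i in order]

    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    for ci in range(len(clusters)):
        for cj in range(ci + 1, len(clusters)):
            shared = len(clusters[ci] & clusters[cj])
            if shared:
                g.add_edge(ci, cj, weight=shared)
    tree = nx.maximum_spanning_tree(g, weight="weight")
    edges = sorted((min(i, j), max(i, j)) for i, j in tree.edges)

    feats = np.array([
        np.concatenate([
            _one_hot(k, ["ring", "bond", "junction"]),
            [float(len(c))],
            [float(all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in c))],
        ])
        for k, c in zip(kinds, clusters)
    ])
    return MolecularGraph("J", feats, edges, clusters, mol.GetNumAtoms())


# ---------------------------------------------------------------------------
# FunctionalGroup graph
# ---------------------------------------------------------------------------

def build_functionalgroup_graph(record, vocabulary=None) -> MolecularGraph:
    """Predefined functional groups, then rings, then atom pairs, as nodes."""
    mol = _mol_from_record(record)
    vocabulary = vocabulary if vocabulary is not None else FUNCTIONAL_GROUPS
    n_groups = len(vocabulary)
    matches = []
    for gi, (name, pattern) in enumerate(vocabulary):
        patt = Chem.MolFromSmarts(pattern)
        for match in mol.GetSubstructMatches(patt):
            matches.append((len(match), -gi, frozenset(match), gi))
    # largest first; ties broken by vocabulary order
    matches.sort(key=lambda t: (-t[0], -t[1], sorted(t[2])))
    assigned: set = set()
    clusters, identities = [], []
    for _, _, atoms, gi in matches:
        if atoms & assigned:
            continue
        clusters.append(atoms)
        identities.append(gi)
        assigned |= atoms

    for ring in _sorted_clusters([frozenset(r) for r in Chem.GetSymmSSSR(mol)]):
        if not (ring & assigned):
            clusters.append(frozenset(ring))
            identities.append(n_groups)  # generic ring slot
            assigned |= ring

    # remaining bonds as atom-pair nodes (covers every leftover atom)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in assigned and j in assigned:
            continue
        clusters.append(frozenset([i, j]))
        identities.append(n_groups + 1)  # atom-pair slot
        assigned |= {i, j}
    for atom in mol.GetAtoms():  # isolated leftover atoms in salt fragments
        if atom.GetIdx() not in assigned:
            clusters.append(frozenset([atom.GetIdx()]))
            identities.append(n_groups + 1)
            assigned.add(atom.GetIdx())

    order = sorted(range(len(clusters)), key=lambda i: (min(clusters[i]), -len(clusters[i])))
    clusters = [clusters[i] for i in order]
    identities = [identities[i] for i in order]
    feats = np.zeros((len(clusters), FG_VOCAB.node_dim))
    for ni, (c, gi) in enumerate(zip(clusters, identities)):
        feats[ni, gi] = 1.0
        feats[ni, n_groups + 2] = float(len(c))
        feats[ni, n_groups + 3] = float(all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in c))
    return MolecularGraph("F", feats, _cluster_edges(mol, clusters), clusters,
                          mol.GetNumAtoms())


BUILDERS = {
    "A": build_atom_graph,
    "P": build_pharmacophore_graph,
    "J": build_junctiontree_graph,
    "F": build_functionalgroup_graph,
}


def build_graphs(record, representations=REPRESENTATIONS) -> dict:
    """All requested representations for one molecule, keyed by label."""
    return {rep: BUILDERS[rep](record) for rep in representations}


def reduction_statistics(records, representations=REPRESENTATIONS) -> pd.DataFrame:
    """Mean/median node counts per representation over a dataset.

    Reduced representations shrink node counts relative to the atom graph;
    the functional-group graph typically shrinks the most and the
    pharmacophore graph the least.
    """
    counts = {rep: [] for rep in representations}
    for rec in records:
        for rep in representations:
            counts[rep].append(BUILDERS[rep](rec).n_nodes)
    return pd.DataFrame(
        {
            "representation": list(representations),
            "mean_nodes": [float(np.mean(counts[r])) for r in representations],
            "median_nodes": [float(np.median(counts[r])) for r in representations],
        }
    ).set_index("representation")
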