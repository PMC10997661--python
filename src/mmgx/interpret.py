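"""Attention post-processing and the three interpretation views.

Raw virtual-link attention weights per graph are (1) min-max normalized on
that graph's nodes, (2) redistributed onto atoms via each node's
``atom_map`` — atoms covered by several nodes receive the *sum* of those
nodes' weights — and re-normalized, then (3) combined across the
representations of a scheme by the elementwise *maximum*, emphasising
whatever any representation found important.  A constant vector has no
contrast and normalizes to 0.5 everywhere (neutral importance).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .network import GraphScheme, batch_molecules

logger = logging.getLogger(__name__)


@dataclass
class AttentionResult:
    """Attention for one molecule under one scheme (possibly fold-averaged)."""

    raw: dict            # rep -> raw node attention (softmax weights)
    per_graph: dict      # rep -> min-max normalized node attention
    mapped: dict         # rep -> atom-level normalized vector
    combined: np.ndarray  # atom-level combined vector in [0, 1]
    prediction: float
    label: float | None = None


def minmax_normalize(weights) -> np.ndarray:
    """(w - min) / (max - min); a constant vector maps to all 0.5."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo, hi = w.min(), w.max()
    if hi - lo < 1e-300:
        return np.full_like(w, 0.5)
    return (w - lo) / (hi - lo)


def map_to_atoms(graph, node_attention) -> np.ndarray:
    """Redistribute node attention onto atoms (summing overlaps), renormalize."""
    node_attention = np.asarray(node_attention, dtype=float)
    if node_attention.shape[0] != graph.n_nodes:
        raise ValueError("attention length does not match node count")
    atom = np.zeros(graph.n_atoms)
    for w, atoms in zip(node_attention, graph.atom_map):
        for a in atoms:
            atom[a] += w
    return minmax_normalize(atom)


def combine_graphs(mapped_vectors) -> np.ndarray:
    """Elementwise maximum across atom-level vectors from several graphs."""
    vs = [np.asarray(v, dtype=float) for v in mapped_vectors]
    if len({v.shape for v in vs}) > 1:
        raise ValueError("mapped vectors must have equal length")
    return np.maximum.reduce(vs)


def attention_for_molecule(network, graph_dict, label=None) -> AttentionResult:
    """Run one molecule through a trained network and post-process attention."""
    scheme = network.scheme
    batch = batch_molecules([graph_dict], scheme)
    out = network.forward(batch)
    raw, per_graph, mapped = {}, {}, {}
    for rep in scheme.representations:
        w, _ = out.attention[rep]
        raw[rep] = w
        per_graph[rep] = minmax_normalize(w)
        mapped[rep] = map_to_atoms(graph_dict[rep], per_graph[rep])
    combined = combine_graphs([mapped[rep] for rep in scheme.representations])
    return AttentionResult(raw=raw, per_graph=per_graph, mapped=mapped,
                           combined=combined, prediction=float(out.prediction[0]),
                           label=label)


def fold_average_attention(networks, graph_dict, label=None) -> AttentionResult:
    """Mean of per-fold results (each fold normalized on its own) per view."""
    results = [attention_for_molecule(n, graph_dict, label) for n in networks]
    reps = networks[0].scheme.representations
    return AttentionResult(
        raw={r: np.mean([x.raw[r] for x in results], axis=0) for r in reps},
        per_graph={r: np.mean([x.per_graph[r] for x in results], axis=0) for r in reps},
        mapped={r: np.mean([x.mapped[r] for x in results], axis=0) for r in reps},
        combined=np.mean([x.combined for x in results], axis=0),
        prediction=float(np.mean([x.prediction for x in results])),
        label=label,
    )


# ---------------------------------------------------------------------------
# single prediction view
# ---------------------------------------------------------------------------

def single_prediction_view(record, result: AttentionResult, out_prefix):
    """Depict the molecule with green atom highlights scaled by attention.

    Writes ``<prefix>.png`` (best effort) and ``<prefix>.json`` (always).
    Returns the JSON payload.
    """
    payload = {
        "id": getattr(record, "id", None),
        "smiles": getattr(record, "smiles", str(record)),
        "prediction": result.prediction,
        "combined_attention": [float(x) for x in result.combined],
        "mapped_attention": {r: [float(x) for x in v] for r, v in result.mapped.items()},
    }
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    try:
        from rdkit import Chem
        from rdkit.Chem.Draw import rdMolDraw2D

        mol = Chem.MolFromSmiles(payload["smiles"])
        drawer = rdMolDraw2D.MolDraw2DCairo(420, 360)
        colors = {i: (1.0 - 0.85 * w, 1.0, 1.0 - 0.85 * w)
                  for i, w in enumerate(result.combined)}
        rdMolDraw2D.PrepareAndDrawMolecule(
            drawer, mol, highlightAtoms=list(range(mol.GetNumAtoms())),
            highlightAtomColors=colors)
        drawer.FinishDrawing()
        with open(f"{out_prefix}.png", "wb") as fh:
            fh.write(drawer.GetDrawingText())
    except Exception as exc:  # depiction is best-effort; numbers always land
        warnings.warn(f"depiction failed ({exc}); numeric output written")
    return payload


# ---------------------------------------------------------------------------
# node features view
# ---------------------------------------------------------------------------

@dataclass
class NodeFeatureSummary:
    table: pd.DataFrame  # columns: representation, feature, mean_attention, count


def node_features_view(records, networks, graphs_by_id, prediction_filter=None,
                       plot_path=None) -> NodeFeatureSummary:
    """Mean per-graph attention and occurrence count of every node feature.

    A node contributes its (min-max normalized, per-graph) attention to each
    of its active feature slots — multi-hot nodes count toward several
    features.  ``prediction_filter`` optionally restricts the dataset to
    molecules whose fold-averaged prediction passes the predicate.
    """
    from .graphs import VOCABULARIES

    scheme = networks[0].scheme
    acc: dict = {}
    n_used = 0
    for rec in records:
        gd = graphs_by_id[rec.id]
        res = fold_average_attention(networks, gd, label=rec.target)
        if prediction_filter is not None and not prediction_filter(res.prediction):
            continue
        n_used += 1
        for rep in scheme.representations:
            names = VOCABULARIES[rep].node_features
            feats = gd[rep].node_features
            for node_idx in range(feats.shape[0]):
                w = res.per_graph[rep][node_idx]
                for slot, name in enumerate(names):
                    if feats[node_idx, slot] > 0:
                        key = (rep, name)
                        tot, cnt = acc.get(key, (0.0, 0))
                        acc[key] = (tot + w, cnt + 1)
    if not acc:
        raise ValueError("no molecules pass the prediction filter")
    rows = [
        {"representation": rep, "feature": name,
         "mean_attention": tot / cnt, "count": cnt}
        for (rep, name), (tot, cnt) in sorted(acc.items())
    ]
    table = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        for rep, sub in table.groupby("representation"):
            ax.scatter(sub["count"], sub["mean_attention"], label=rep, alpha=0.7)
        ax.set_xlabel("number of feature nodes")
        ax.set_ylabel("mean attention weight")
        ax.legend()
        fig.savefig(plot_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    logger.info("node features view over %d molecules", n_used)
    return NodeFeatureSummary(table=table)


# ---------------------------------------------------------------------------
# attention correlation across representations
# ---------------------------------------------------------------------------

def attention_correlation(records, networks, graphs_by_id, rep_pair=None):
    """Per-molecule Spearman correlation between two mapped attention vectors.

    Molecules with fewer than 3 atoms are skipped.  Returns a DataFrame of
    per-molecule correlations plus summary statistics.
    """
    scheme = networks[0].scheme
    if len(scheme.representations) < 2:
        raise ValueError("attention correlation needs a scheme with >= 2 graphs")
    r1, r2 = rep_pair or scheme.representations[:2]
    rows = []
    for rec in records:
        gd = graphs_by_id[rec.id]
        if gd[r1].n_atoms < 3:
            continue
        res = fold_average_attention(networks, gd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(res.mapped[r1], res.mapped[r2]).statistic
        if np.isfinite(rho):
            rows.append({"id": rec.id, "correlation": float(rho)})
    df = pd.DataFrame(rows)
    summary = {
        "mean": float(df["correlation"].mean()) if len(df) else float("nan"),
        "median": float(df["correlation"].median()) if len(df) else float("nan"),
        "n": len(df),
    }
    return df, summary
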