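"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code with the
package: exhaustive common-connected-subgraph enumeration for MCS checks,
and closed-form confusion-count / rank / covariance formulas for metrics.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism as iso
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for a in mol.GetAtoms():
        g.add_node(a.GetIdx(), el=a.GetSymbol())
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), bo=b.GetBondTypeAsDouble())
    return g


def max_common_connected_atoms(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Atom count of the largest common connected subgraph.

    Enumerates every connected node subset of molecule A, every connected
    spanning edge subset of its induced subgraph, and tests embeddability
    into molecule B by subgraph monomorphism with element and bond-order
    labels.  Falls back to 1 when the molecules share an element but no
    bonded substructure, and 0 when they share no element at all.
    """
    ga, gb = mol_graph(mol_a), mol_graph(mol_b)
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    nm = iso.categorical_node_match("el", None)
    em = iso.categorical_edge_match("bo", None)
    b_elements = {}
    for _, data in gb.nodes(data=True):
        b_elements[data["el"]] = b_elements.get(data["el"], 0) + 1
    nodes = sorted(ga.nodes)
    for k in range(min(len(nodes), gb.number_of_nodes()), 1, -1):
        for subset in itertools.combinations(nodes, k):
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            counts = {}
            for v in subset:
                el = ga.nodes[v]["el"]
                counts[el] = counts.get(el, 0) + 1
            if any(b_elements.get(el, 0) < c for el, c in counts.items()):
                continue
            edges = list(sub.edges)
            for mask in range(2 ** len(edges)):
                chosen = [edges[i] for i in range(len(edges)) if mask >> i & 1]
                if len(chosen) < k - 1:
                    continue
                h = nx.Graph()
                h.add_nodes_from((v, ga.nodes[v]) for v in subset)
                h.add_edges_from((u, v, ga.edges[u, v]) for u, v in chosen)
                if not nx.is_connected(h):
                    continue
                if iso.GraphMatcher(
                    gb, h, node_match=nm, edge_match=em
                ).subgraph_is_monomorphic():
                    return k
    a_elements = {d["el"] for _, d in ga.nodes(data=True)}
    return 1 if a_elements & set(b_elements) else 0


def count_substructure_embeddings(mol: Chem.Mol, pattern: Chem.Mol) -> int:
    """Distinct atom-set embeddings of a pattern graph into a molecule."""
    gm = iso.GraphMatcher(
        mol_graph(mol),
        mol_graph(pattern),
        node_match=iso.categorical_node_match("el", None),
        edge_match=iso.categorical_edge_match("bo", None),
    )
    return len({frozenset(m) for m in gm.subgraph_monomorphisms_iter()})


def random_small_molecule(rng: np.random.Generator, max_atoms: int = 8) -> Chem.Mol:
    """A random small aliphatic C/N/O molecule (tree plus optional ring bond)."""
    elements = ["C", "C", "C", "O", "N"]
    while True:
        n = int(rng.integers(2, max_atoms + 1))
        rw = Chem.RWMol()
        for _ in range(n):
            rw.AddAtom(Chem.Atom(elements[int(rng.integers(len(elements)))]))
        for i in range(1, n):
            j = int(rng.integers(i))
            order = Chem.BondType.DOUBLE if rng.random() < 0.15 else Chem.BondType.SINGLE
            rw.AddBond(i, j, order)
        if n >= 5 and rng.random() < 0.25:
            a, b = (int(v) for v in rng.choice(n, size=2, replace=False))
            if rw.GetBondBetweenAtoms(a, b) is None:
                rw.AddBond(a, b, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        if any(b.GetIsAromatic() for b in mol.GetBonds()):
            continue
        return mol


# ---------------------------------------------------------------------------
# metric formulas from pooled confusion counts


def confusion_counts(true: np.ndarray, pred: np.ndarray) -> tuple[int, int, int, int]:
    t = np.asarray(true).ravel().astype(bool)
    p = np.asarray(pred).ravel().astype(bool)
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    tn = int((~t & ~p).sum())
    return tp, fp, fn, tn


def brute_micro_f1(true, pred) -> float:
    tp, fp, fn, _ = confusion_counts(true, pred)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def brute_micro_mcc(true, pred) -> float:
    tp, fp, fn, tn = confusion_counts(true, pred)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def brute_rocauc(true, scores) -> float:
    """Rank-based AUC with midranks for ties."""
    t = np.asarray(true).ravel().astype(bool)
    s = np.asarray(scores, dtype=float).ravel()
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    return (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def brute_pearson(a, b) -> float:
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
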