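"""Markov clustering of protein similarity graphs and EC-number transfer.

Protein families are built by MCL on the all-versus-all similarity graph
of environmental proteins combined with EC-labelled reference proteins:
edges above an e-value cutoff (default 1e-40) are discarded, remaining
edges are weighted by bit score, and the column-stochastic transition
matrix is iterated with expansion (matrix squaring) and inflation
(entrywise power, default 1.2) until convergence.  Each EC number seen
in a cluster is transferred to the cluster's unlabelled members when it
accounts for more than 1% of the cluster's EC label instances.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np


@dataclass
class ProteinCluster:
    """One Markov cluster with its EC label multiset and transferred ECs."""

    cluster_id: int
    members: list[str]
    ec_counts: Counter = field(default_factory=Counter)
    transferred_ecs: set[str] = field(default_factory=set)


def build_graph(
    edges: Iterable[tuple[str, str, float, float]],
    e_value_cutoff: float = 1e-40,
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Similarity graph from (query, subject, e_value, bit_score) rows.

    Edges with e-value above the cutoff are dropped; surviving edges are
    weighted by bit score.  A self-loop equal to each node's maximum
    incident weight (1.0 for isolated nodes) is added, the standard MCL
    guard against random-walk parity artifacts.
    """
    g = nx.Graph()
    g.add_nodes_from(extra_nodes)
    for q, s, e_value, bit in edges:
        if bit < 0:
            raise ValueError(f"negative bit score on edge {q}-{s}")
        g.add_nodes_from((q, s))  # endpoints stay even if the edge is filtered
        if e_value > e_value_cutoff:
            continue
        if q == s:
            g.add_node(q)
            continue
        if g.has_edge(q, s):
            g[q][s]["weight"] = max(g[q][s]["weight"], bit)
        else:
            g.add_edge(q, s, weight=bit)
    for node in g.nodes:
        incident = [
            d["weight"] for _, nbr, d in g.edges(node, data=True) if nbr != node
        ]
        g.add_edge(node, node, weight=max(incident) if incident else 1.0)
    return g


def _stochastic_matrix(g: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    m = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    col_sums = m.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    return m / col_sums


def mcl_iterate(
    matrix: np.ndarray,
    inflation: float = 1.2,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Run the MCL expansion/inflation loop on a column-stochastic matrix.

    Entries below ``prune`` are zeroed after each inflation (set
    ``prune=0`` for the exact iteration).  Returns the converged matrix
    and a convergence flag.
    """
    m = np.asarray(matrix, dtype=float)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        if prune > 0:
            inflated[inflated < prune] = 0.0
        col_sums = inflated.sum(axis=0)
        col_sums[col_sums == 0] = 1.0
        inflated = inflated / col_sums
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    return m, converged


def clusters_from_matrix(matrix: np.ndarray, nodes: Sequence[str]) -> list[list[str]]:
    """Read clusters off a converged MCL matrix.

    Attractor rows (nonzero entries) define cluster seeds; attractor
    systems sharing any column are merged, and every node joins the
    cluster of its largest steady-state entry (ties to the lowest row
    index).  Clusters are returned sorted by their smallest member id.
    """
    n = len(nodes)
    support = matrix > 1e-9
    attractors = [i for i in range(n) if support[i, i]]
    if not attractors:  # fallback: treat rows with any support as attractors
        attractors = [i for i in range(n) if support[i].any()]
    # union attractors that serve a common column
    parent = {i: i for i in attractors}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(n):
        rows = [i for i in attractors if support[i, j]]
        for a, b in zip(rows, rows[1:]):
            parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for j in range(n):
        col = matrix[:, j]
        candidates = [i for i in attractors if support[i, j]]
        if candidates:
            best = max(candidates, key=lambda i: (col[i], -i))
        else:
            best = int(np.argmax(col))
            if best not in parent:
                parent[best] = best
        groups.setdefault(find(best), []).append(j)

    named = sorted(
        (sorted(nodes[j] for j in members) for members in groups.values()),
        key=lambda ms: ms[0],
    )
    return [list(ms) for ms in named]


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 1.2,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
    ec_labels: Mapping[str, Sequence[str]] | None = None,
) -> list[ProteinCluster]:
    """Markov clustering of a similarity graph into protein families."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty similarity graph")
    nodes = sorted(g.nodes)
    m = _stochastic_matrix(g, nodes)
    converged_m, ok = mcl_iterate(m, inflation, prune, max_iter, tol)
    if not ok:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")
    out = []
    for cid, members in enumerate(clusters_from_matrix(converged_m, nodes)):
        counts: Counter = Counter()
        if ec_labels:
            for member in members:
                counts.update(ec_labels.get(member, ()))
        out.append(ProteinCluster(cluster_id=cid, members=members, ec_counts=counts))
    return out


def transfer_ec(cluster: ProteinCluster, min_frac: float = 0.01) -> set[str]:
    """ECs transferred to a cluster's unlabelled members.

    An EC number is transferred when its count exceeds ``min_frac`` of
    all EC label instances in the cluster (strict inequality).  Clusters
    with no labelled members transfer nothing.
    """
    total = sum(cluster.ec_counts.values())
    if total == 0:
        cluster.transferred_ecs = set()
        return set()
    transferred = {
        ec for ec, count in cluster.ec_counts.items() if count / total > min_frac
    }
    cluster.transferred_ecs = transferred
    return transferred


def transfer_all(
    clusters: Sequence[ProteinCluster],
    ec_labels: Mapping[str, Sequence[str]],
    min_frac: float = 0.01,
) -> dict[str, set[str]]:
    """EC sets acquired by every unlabelled protein across clusters."""
    out: dict[str, set[str]] = {}
    for cluster in clusters:
        ecs = transfer_ec(cluster, min_frac)
        if not ecs:
            continue
        for member in cluster.members:
            if member not in ec_labels:
                out[member] = set(ecs)
    return out
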