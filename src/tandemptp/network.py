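"""Residue interaction networks from contact matrices.

Nodes are residues (annotated with motif id, butterfly region and FIR
group where available); edges join residue pairs whose time-averaged
contact holds, excluding trivial sequence neighbours. "Clusters" of the
20-FIR subnetwork are its connected components — a reproducible stand-in
for the visual hubs of a force-directed layout; a modularity-based
community mode is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from tandemptp.annotations import FIRSet, MotifAnnotation
from tandemptp.contacts import ContactMatrix

__all__ = [
    "build_network",
    "extract_fir_subnetwork",
    "find_clusters",
    "classify_regions",
    "compare_networks",
    "NetworkComparison",
    "export_graph",
    "import_graph",
]


def build_network(
    cm: ContactMatrix,
    motifs: MotifAnnotation | None = None,
    firs: FIRSet | None = None,
    min_seq_sep: int = 2,
    adjacency_mode: str = "mean",
) -> nx.Graph:
    """Build the residue interaction network of a contact matrix.

    Every residue becomes a node; adjacency (mean distance below the
    cutoff by default) becomes an edge weighted by the mean distance.
    Pairs closer than ``min_seq_sep`` in sequence (same chain) are
    excluded — backbone neighbours are trivially in contact and would
    drown out the functional interactions.
    """
    adj = cm.adjacency(mode=adjacency_mode)
    if not np.array_equal(adj, adj.T):
        raise ValueError("contact matrix adjacency must be symmetric")
    n = cm.n_residues
    motif_of = motifs.motif_of() if motifs is not None else {}
    group_of = firs.group_of() if firs is not None else {}
    for r in group_of:
        if not 0 <= r < n:
            raise ValueError(f"FIR residue {r} outside matrix range 0..{n - 1}")

    g = nx.Graph()
    g.graph.update(
        cutoff=cm.cutoff, window=list(cm.window), reducer=cm.reducer,
        adjacency_mode=adjacency_mode, min_seq_sep=min_seq_sep,
    )
    res = cm.residues
    chains = res["chain"].to_numpy()
    for i in range(n):
        attrs = {"chain": str(chains[i]), "res_id": int(res["res_id"].iloc[i])}
        if i in motif_of:
            attrs["motif"] = int(motif_of[i])
        if i in group_of:
            attrs["fir_group"] = group_of[i]
        g.add_node(i, **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            if chains[i] == chains[j] and abs(i - j) < min_seq_sep:
                continue
            g.add_edge(i, j, weight=float(cm.mean_distance[i, j]))
    return g


def extract_fir_subnetwork(net: nx.Graph, firs: FIRSet) -> nx.Graph:
    """Induced subgraph on the FIR residues (FIR nodes without contacts
    are kept as isolated nodes)."""
    residues = firs.residues
    missing = [r for r in residues if r not in net]
    if missing:
        raise ValueError(f"FIR residues not in network: {missing}")
    sub = net.subgraph(residues).copy()
    group_of = firs.group_of()
    for r in residues:
        sub.nodes[r]["fir_group"] = group_of[r]
    return sub


def find_clusters(subnet: nx.Graph, method: str = "components") -> pd.DataFrame:
    """Cluster the FIR subnetwork.

    ``method="components"`` (default) uses connected components;
    ``method="modularity"`` uses greedy modularity communities. Returns a
    table with one row per residue: cluster id (ordered by size then
    smallest member), FIR group, and the set of groups sharing the
    cluster.
    """
    if method == "components":
        raw = list(nx.connected_components(subnet))
    elif method == "modularity":
        raw = [set(c) for c in nx.community.greedy_modularity_communities(subnet)]
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    raw.sort(key=lambda c: (-len(c), min(c)))
    rows = []
    for cid, members in enumerate(raw):
        groups = sorted(
            {subnet.nodes[m].get("fir_group", "unassigned") for m in members}
        )
        for m in sorted(members):
            rows.append(
                {
                    "residue": m,
                    "cluster": cid,
                    "fir_group": subnet.nodes[m].get("fir_group", "unassigned"),
                    "cluster_groups": ",".join(groups),
                    "cluster_size": len(members),
                }
            )
    return pd.DataFrame(rows)


def classify_regions(net: nx.Graph, motifs: MotifAnnotation | None = None) -> dict:
    """Label every edge with its butterfly region.

    Precedence head > tail > body-wings: an edge touching motif 1 is
    ``head``; otherwise an edge touching motifs 8-10 is ``tail``; an edge
    with both endpoints in motifs 2-7 is ``body-wings``; anything else
    (unannotated endpoints) is ``unassigned``.
    """
    motif_of = motifs.motif_of() if motifs is not None else None

    def motif_at(node):
        if motif_of is not None:
            return motif_of.get(node)
        return net.nodes[node].get("motif")

    labels = {}
    for u, v in net.edges:
        mu, mv = motif_at(u), motif_at(v)
        ms = {m for m in (mu, mv) if m is not None}
        if 1 in ms:
            label = "head"
        elif ms & {8, 9, 10}:
            label = "tail"
        elif mu is not None and mv is not None and ms <= set(range(2, 8)):
            label = "body-wings"
        else:
            label = "unassigned"
        labels[(u, v)] = label
    return labels


@dataclass
class NetworkComparison:
    """Edge-set difference between two networks under a node mapping.
    ``only_in_a``/``only_in_b``/``shared`` partition the union of the
    mapped edge sets; ``region_counts`` tallies the differing edges per
    butterfly region."""

    only_in_a: set
    only_in_b: set
    shared: set
    region_counts: pd.DataFrame


def compare_networks(
    a: nx.Graph,
    b: nx.Graph,
    node_mapping: dict | None = None,
    motifs: MotifAnnotation | None = None,
) -> NetworkComparison:
    """Diff two residue networks (e.g. the D1 domain simulated alone
    versus within the D1D2 tandem).

    ``node_mapping`` maps a-nodes to b-nodes (a bijection; identity by
    default). Edges are compared in a-coordinates; differing edges are
    tallied per butterfly region using a's motif annotations.
    """
    if node_mapping is None:
        node_mapping = {n: n for n in a.nodes}
    if len(set(node_mapping.values())) != len(node_mapping):
        raise ValueError("node mapping must be a bijection")
    unmapped = [n for n in a.nodes if n not in node_mapping and a.degree[n] > 0]
    if unmapped:
        raise ValueError(f"unmapped nodes with edges: {unmapped}")
    inverse = {v: k for k, v in node_mapping.items()}
    unmapped_b = [n for n in b.nodes if n not in inverse and b.degree[n] > 0]
    if unmapped_b:
        raise ValueError(f"unmapped nodes with edges in second network: {unmapped_b}")

    edges_a = {frozenset(e) for e in a.edges}
    edges_b = {
        frozenset((inverse[u], inverse[v])) for u, v in b.edges
    }
    only_a = edges_a - edges_b
    only_b = edges_b - edges_a
    shared = edges_a & edges_b

    region_labels = classify_regions(a, motifs)
    region_of = {frozenset(e): lab for e, lab in region_labels.items()}
    # edges present only in b may be absent from a; classify via a's node motifs
    def classify_pair(pair):
        if pair in region_of:
            return region_of[pair]
        tmp = nx.Graph()
        u, v = tuple(pair)
        tmp.add_node(u, **a.nodes[u])
        tmp.add_node(v, **a.nodes[v])
        tmp.add_edge(u, v)
        return classify_regions(tmp, motifs)[(u, v)]

    counts: dict[str, dict[str, int]] = {}
    for name, edges in (("only_in_a", only_a), ("only_in_b", only_b)):
        for e in edges:
            lab = classify_pair(e)
            counts.setdefault(lab, {"only_in_a": 0, "only_in_b": 0})[name] += 1
    table = (
        pd.DataFrame.from_dict(counts, orient="index")
        .rename_axis("region")
        .reset_index()
        .sort_values("region")
        .reset_index(drop=True)
    )
    return NetworkComparison(
        only_in_a=only_a, only_in_b=only_b, shared=shared, region_counts=table
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_graph(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network to disk.

    GraphML round-trips nodes, edges and annotations losslessly; SIF is a
    lossy Cytoscape-compatible edge list (node ids and a fixed ``contact``
    interaction type only).
    """
    if format == "graphml":
        clean = nx.Graph(**{k: v for k, v in net.graph.items() if v is not None})
        for n, attrs in net.nodes(data=True):
            clean.add_node(n, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in net.edges(data=True):
            clean.add_edge(u, v, **{k: w for k, w in attrs.items() if w is not None})
        for k, v in list(clean.graph.items()):
            if isinstance(v, (list, tuple)):
                clean.graph[k] = ",".join(str(x) for x in v)
        nx.write_graphml(clean, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            written = set()
            for u, v in net.edges:
                fh.write(f"{u}\tcontact\t{v}\n")
                written.update((u, v))
            for n in net.nodes:
                if n not in written:
                    fh.write(f"{n}\n")
    else:
        raise ValueError(f"unsupported export format {format!r}")


def import_graph(path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_graph` (GraphML only;
    node ids restored as integers)."""
    if format != "graphml":
        raise ValueError(f"unsupported import format {format!r}")
    return nx.read_graphml(str(path), node_type=int)
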