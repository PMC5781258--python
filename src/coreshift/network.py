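"""Per-treatment co-occurrence graphs, hub subnetworks, and cross-treatment merging.

Each treatment's significant-edge list becomes an undirected weighted
graph; the hub subnetwork keeps the most-connected nodes (degree ties at
the boundary all included) plus their immediate neighbors, as an induced
subgraph.  Merging the per-treatment hub subnetworks partitions OTUs by
the set of treatments whose subnetwork contains them — treatment-specific
classes at one extreme and the all-treatment "central" class at the other.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


def edges_to_graph(edges: pd.DataFrame, treatment: str | None = None,
                   taxonomy: dict[str, str] | None = None) -> nx.Graph:
    """Build an undirected graph from an (otu_a, otu_b, rho, p) edge list."""
    g = nx.Graph(treatment=treatment)
    for row in edges.itertuples(index=False):
        if row.otu_a == row.otu_b:
            continue
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho), p=float(row.p))
    if taxonomy:
        nx.set_node_attributes(
            g, {n: taxonomy.get(n, "") for n in g.nodes}, "taxonomy")
    return g


def hub_subnetwork(net: nx.Graph, top_n: int = 20) -> nx.Graph:
    """Induced subgraph on the `top_n` most connected nodes and their neighbors.

    Nodes tied with the top_n-th degree are all included (logged), so the
    selection is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = sorted(dict(net.degree()).items(), key=lambda kv: (-kv[1], kv[0]))
    if len(degrees) <= top_n:
        hubs = [n for n, _ in degrees]
    else:
        cutoff = degrees[top_n - 1][1]
        hubs = [n for n, d in degrees if d >= cutoff]
        if len(hubs) > top_n:
            logger.info("hub_subnetwork: degree tie at rank %d includes %d nodes",
                        top_n, len(hubs))
    keep = set(hubs)
    for h in hubs:
        keep.update(net.neighbors(h))
    return net.subgraph(keep).copy()


def merge_subnetworks(subnets: dict[str, nx.Graph],
                      ) -> tuple[nx.Graph, pd.DataFrame]:
    """Union of per-treatment subnetworks with node-membership classes.

    Returns the merged graph (each edge keeps per-treatment rho values
    under ``rho_<treatment>``) and a per-node frame with the treatment
    membership set, its size, and a class label: ``<t>-only`` for
    single-treatment nodes, ``core`` for nodes present in every
    treatment's subnetwork, and ``shared-k`` otherwise.  Classes
    partition the merged node set and the result is independent of the
    order of `subnets`.
    """
    if len(subnets) < 2:
        raise ValueError("need at least 2 treatments to merge")
    names = sorted(subnets)
    merged = nx.Graph()
    membership: dict[str, set[str]] = {}
    for t in names:
        g = subnets[t]
        for n, attrs in g.nodes(data=True):
            membership.setdefault(n, set()).add(t)
            if n not in merged:
                merged.add_node(n, **attrs)
        for u, v, attrs in g.edges(data=True):
            if not merged.has_edge(u, v):
                merged.add_edge(u, v, treatments=set())
            merged[u][v]["treatments"].add(t)
            merged[u][v][f"rho_{t}"] = attrs.get("rho")
    rows = []
    for n in sorted(membership):
        mem = membership[n]
        if len(mem) == len(names):
            cls = "core"
        elif len(mem) == 1:
            cls = f"{next(iter(mem))}-only"
        else:
            cls = f"shared-{len(mem)}"
        rows.append({"otu": n, "treatments": ",".join(sorted(mem)),
                     "n_treatments": len(mem), "class": cls})
    partition = pd.DataFrame(rows).set_index("otu")
    assert len(partition) == merged.number_of_nodes()
    assert partition.groupby("class").size().sum() == merged.number_of_nodes()
    return merged, partition


def membership_classes(partition: pd.DataFrame) -> dict[str, set[str]]:
    """Map class label -> OTU id set from a merge partition."""
    return {cls: set(sub.index) for cls, sub in partition.groupby("class")}


_PROTEO_CLASSES = ("Alphaproteobacteria", "Betaproteobacteria",
                   "Gammaproteobacteria", "Deltaproteobacteria")


def _rank_token(lineage: str, prefix: str) -> str | None:
    for part in lineage.split(";"):
        part = part.strip()
        if part.lower().startswith(prefix):
            name = part[len(prefix):].strip()
            return name or None
    return None


def taxonomy_composition(nodes, taxonomy: dict[str, str], rank: str = "phylum",
                         split_proteobacteria: bool = False) -> dict[str, float]:
    """Fraction of a node set per taxon at `rank` ('phylum' or 'class').

    Unresolvable lineages count as ``unclassified``.  With
    ``split_proteobacteria``, phylum-level Proteobacteria are reported at
    class level (Alpha/Beta/Gamma/Delta) instead.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node set")
    prefix = {"phylum": "p__", "class": "c__"}.get(rank)
    if prefix is None:
        raise ValueError("rank must be 'phylum' or 'class'")
    counts: dict[str, int] = {}
    for n in nodes:
        lineage = taxonomy.get(n, "")
        label = _rank_token(lineage, prefix) or "unclassified"
        if (split_proteobacteria and rank == "phylum"
                and label == "Proteobacteria"):
            cls = _rank_token(lineage, "c__")
            if cls in _PROTEO_CLASSES:
                label = cls
        counts[label] = counts.get(label, 0) + 1
    total = len(nodes)
    return {k: v / total for k, v in sorted(counts.items())}
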