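"""Feature co-occurrence network over the top pro-groups.

Every feature appearing in a top pro-group is a node; two features are
connected when they co-occur in the same pro-group, so each pro-group
induces a clique.  A node's weight is the mean of the average scores of
the pro-groups containing it and its size is the feature's total
cross-iteration appearance count.  Communities come from greedy
(fast-greedy) modularity maximization: starting from singleton
communities, the merge with the largest modularity gain is applied until
no merge increases modularity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .aggregate import RankSummary


def infer_feature_kind(feature_id: str) -> str:
    """Heuristic layer assignment from conventional id prefixes.

    CpG probe ids start with ``cg``; miRNA ids contain ``mir``/``miR``;
    everything else is treated as a gene.  Pass an explicit kind mapping
    to :func:`build_feature_network` when ids do not follow convention.
    """
    if feature_id.lower().startswith("cg"):
        return "CpG"
    if "mir" in feature_id.lower():
        return "miRNA"
    return "mRNA"


@dataclass
class FeatureNetwork:
    graph: nx.Graph                      # node attrs: kind, weight, size, community
    communities: list[set[str]]
    modularity: float


def build_feature_network(
    summaries: list[RankSummary],
    kinds: dict[str, str] | None = None,
) -> FeatureNetwork:
    """Build the (unweighted-edge) co-occurrence graph from summary rows.

    Only features with recorded appearance counts participate.  The
    community partition is left trivial (each node alone) until
    :func:`detect_communities` runs.
    """
    rows = [s for s in summaries if s.feature_counts]
    if not rows:
        raise ValueError("no summary row carries any features")
    g = nx.Graph()
    weight_terms: dict[str, list[float]] = {}
    size: dict[str, int] = {}
    for s in rows:
        feats = sorted(s.feature_counts)
        for f in feats:
            weight_terms.setdefault(f, []).append(s.average_score)
            size[f] = size.get(f, 0) + s.feature_counts[f]
        for i, a in enumerate(feats):
            for b in feats[i + 1:]:
                g.add_edge(a, b)
    for f in sorted(weight_terms):
        kind = (kinds or {}).get(f, infer_feature_kind(f))
        g.add_node(f, kind=kind,
                   weight=sum(weight_terms[f]) / len(weight_terms[f]),
                   size=size[f], community=-1)
    # rebuild with sorted node insertion for deterministic iteration order
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    h.add_edges_from(sorted(tuple(sorted(e)) for e in g.edges))
    return FeatureNetwork(h, [{n} for n in sorted(h.nodes)], 0.0)


def detect_communities(network: FeatureNetwork) -> FeatureNetwork:
    """Partition nodes by greedy modularity maximization.

    Uses the agglomerative Clauset-Newman-Moore scheme.  An edgeless
    graph degenerates to singleton communities with Q = 0.  Community
    ids are assigned in order of each community's smallest node id, so
    the labeling is deterministic.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        comms = [{n} for n in sorted(g.nodes)]
        q = 0.0
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
        q = nx.community.modularity(g, comms)
    comms.sort(key=lambda c: min(c))
    for cid, c in enumerate(comms):
        for n in c:
            g.nodes[n]["community"] = cid
    return FeatureNetwork(g, comms, float(q))


def export_network(network: FeatureNetwork, out_dir: str | Path, stem: str = "network") -> dict[str, Path]:
    """Write GraphML (node attributes: kind, weight, size, community) and
    an edge-list CSV with deterministic (sorted) ordering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graphml = out_dir / f"{stem}.graphml"
    edges_csv = out_dir / f"{stem}_edges.csv"
    nx.write_graphml(network.graph, graphml)
    with open(edges_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target"])
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            w.writerow([a, b])
    return {"graphml": graphml, "edges": edges_csv}


def plot_network(network: FeatureNetwork, path: str | Path) -> None:
    """Static layout plot colored by community, sized by frequency."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = network.graph
    pos = nx.spring_layout(g, seed=0)
    comm = [g.nodes[n]["community"] for n in g.nodes]
    sizes = [60 + 40 * g.nodes[n]["size"] for n in g.nodes]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(g, pos, ax=ax, node_color=comm, node_size=sizes,
                     cmap="tab10", font_size=6, edge_color="lightgray")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
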