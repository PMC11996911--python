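"""Signed OTU co-occurrence networks and topology metrics.

Edges are significant pairwise Spearman correlations (|rho| above a
threshold, BH-corrected q below a ceiling) between OTUs that pass a
prevalence/abundance filter. Topology reports node/edge counts, signed
edge fractions, unweighted average local clustering, density, and a
seeded Louvain modularity on absolute edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CommunityTable, ValidationError

logger = logging.getLogger("ecoassembly")

METRIC_COLUMNS = ["n_nodes", "n_edges", "positive_fraction",
                  "negative_fraction", "avg_clustering", "density",
                  "modularity", "n_modules"]


def filter_otus(table: CommunityTable, min_prevalence: float = 0.2,
                min_mean_relabund: float = 0.0) -> CommunityTable:
    """Keep OTUs present in >= ``min_prevalence`` of samples with mean
    relative abundance >= ``min_mean_relabund``."""
    for v in (min_prevalence, min_mean_relabund):
        if not 0 <= v <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    prev = (table.df > 0).mean(axis=0)
    mean_ra = table.relative_abundance().mean(axis=0)
    keep = table.df.columns[(prev >= min_prevalence)
                            & (mean_ra >= min_mean_relabund)]
    if len(keep) == 0:
        raise ValidationError(
            "no OTU passes the filters; relax min_prevalence or "
            "min_mean_relabund")
    return CommunityTable(table.df[keep])


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame
    #: node annotation (mean relative abundance; phylum when known)
    nodes: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def build_network(table: CommunityTable, rho_min: float = 0.6,
                  q_max: float = 0.05, method: str = "spearman",
                  taxonomy: pd.DataFrame | None = None,
                  seed: int = 0) -> CooccurrenceNetwork:
    """Build the signed co-occurrence network.

    All pairwise Spearman correlations among OTU abundance vectors;
    edges kept where |rho| >= rho_min and BH q <= q_max. Constant OTU
    vectors are skipped. Isolated nodes are dropped from the graph.
    """
    if method != "spearman":
        raise ValueError("only spearman correlations are supported")
    n, m = table.shape
    if n < 5:
        raise ValidationError("need >= 5 samples to estimate correlations")
    if m < 3:
        raise ValidationError("need >= 3 OTUs after filtering")
    x = table.counts.astype(float)
    const = np.ptp(x, axis=0) == 0
    if const.any():
        logger.warning("build_network: %d constant OTU vector(s) skipped",
                       int(const.sum()))
    rho, p = sps.spearmanr(x)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu = np.triu_indices(m, k=1)
    valid = ~(const[iu[0]] | const[iu[1]])
    pv = p[iu][valid]
    qv = sps.false_discovery_control(pv, method="bh") if len(pv) else pv
    rv = rho[iu][valid]
    keep = (np.abs(rv) >= rho_min) & (qv <= q_max)

    ii = iu[0][valid][keep]
    jj = iu[1][valid][keep]
    otus = table.otu_ids
    edges = pd.DataFrame({
        "u": [otus[i] for i in ii],
        "v": [otus[j] for j in jj],
        "rho": rv[keep], "q": qv[keep],
        "sign": np.sign(rv[keep]).astype(int)})

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.u, row.v, rho=row.rho, q=row.q, sign=row.sign,
                   weight=abs(row.rho))

    mean_ra = table.relative_abundance().mean(axis=0)
    node_ids = sorted(g.nodes)
    nodes = pd.DataFrame({"otu_id": node_ids,
                          "mean_relabund": [mean_ra[o] for o in node_ids]})
    if taxonomy is not None and "phylum" in taxonomy.columns:
        nodes["phylum"] = [taxonomy["phylum"].get(o, "unclassified")
                           for o in node_ids]
    nodes = nodes.set_index("otu_id")
    net = CooccurrenceNetwork(graph=g, edges=edges, nodes=nodes)
    net.metrics = network_metrics(net, seed=seed)
    return net


def network_metrics(net: CooccurrenceNetwork | nx.Graph,
                    seed: int = 0) -> dict:
    """Topology metric bundle for a signed network."""
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        logger.warning("network_metrics: empty graph")
        return dict.fromkeys(METRIC_COLUMNS, 0.0) | {"n_nodes": 0,
                                                     "n_edges": 0,
                                                     "n_modules": 0}
    signs = np.array([d.get("sign", 1) for _, _, d in g.edges(data=True)])
    pos_frac = float((signs > 0).mean()) if e else 0.0
    neg_frac = float((signs < 0).mean()) if e else 0.0
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_clust = nx.average_clustering(g) if n else 0.0
    if e:
        comms = nx.community.louvain_communities(g, weight="weight",
                                                 seed=seed)
        # deterministic tie-break: order modules by their lowest node id
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        q = nx.community.modularity(g, comms, weight="weight")
    else:
        comms, q = [sorted(g.nodes)], 0.0
    return {"n_nodes": n, "n_edges": e,
            "positive_fraction": pos_frac, "negative_fraction": neg_frac,
            "avg_clustering": float(avg_clust), "density": float(density),
            "modularity": float(q), "n_modules": len(comms)}


def module_assignment(net: CooccurrenceNetwork, seed: int = 0) -> pd.Series:
    """OTU -> module id from the seeded Louvain partition."""
    comms = nx.community.louvain_communities(net.graph, weight="weight",
                                             seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    out = {}
    for k, c in enumerate(comms):
        for node in c:
            out[node] = k
    return pd.Series(out, name="module")


def compare_networks(nets: dict[str, CooccurrenceNetwork | dict]) -> pd.DataFrame:
    """Long-format metric table across groups."""
    if len(nets) < 2:
        raise ValueError("need >= 2 networks to compare")
    rows = []
    for name, net in nets.items():
        metrics = net if isinstance(net, dict) else net.metrics
        for metric in METRIC_COLUMNS:
            rows.append({"group": name, "metric": metric,
                         "value": metrics[metric]})
    return pd.DataFrame(rows)


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))
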