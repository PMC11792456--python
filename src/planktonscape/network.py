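"""Co-occurrence networks: construction, topology, modules, and Zi-Pi roles.

Edges are Spearman correlations between OTU abundance profiles passing both
an effect-size threshold (|rho| >= 0.6 by default) and a Benjamini-Hochberg
FDR cut (adjusted p < 0.05) applied across all tested pairs. Topology
follows the usual community-ecology panel: node/edge counts, average degree
2E/N, density 2E/(N(N-1)), diameter and average path length on the largest
connected component, mean local clustering, Newman modularity of the module
partition, and the positive/negative edge split. Node importance uses the
within-module degree z-score Zi and among-module connectivity
Pi = 1 - sum_s (k_is/k_i)^2 with the conventional thresholds Zi = 2.5,
Pi = 0.62; connectors, module hubs, and network hubs are the key species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import OTUTable

__all__ = [
    "filter_otus_for_network",
    "correlation_edges",
    "build_network",
    "NetworkTopology",
    "topology_metrics",
    "detect_modules",
    "NodeRole",
    "zi_pi",
    "key_species",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def filter_otus_for_network(
    table: OTUTable, min_prevalence: float = 1 / 3, min_mean_abund: float = 1e-4
) -> OTUTable:
    """Keep OTUs present in >= ``min_prevalence`` of samples with mean relative
    abundance >= ``min_mean_abund``."""
    if not (0 <= min_prevalence <= 1) or not (0 <= min_mean_abund <= 1):
        raise ValueError("thresholds must be in [0, 1]")
    rel = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=1)
    mean_abund = rel.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_abund >= min_mean_abund)
    if not keep.any():
        raise ValueError(
            "no OTUs survive the network filter; lower min_prevalence/min_mean_abund"
        )
    idx = np.where(keep)[0]
    otu_ids = [table.otu_ids[i] for i in idx]
    taxonomy = (
        {o: table.taxonomy[o] for o in otu_ids if o in table.taxonomy}
        if table.taxonomy
        else None
    )
    return OTUTable(
        otu_ids=otu_ids,
        sample_ids=list(table.sample_ids),
        counts=table.counts[idx],
        taxonomy=taxonomy,
    )


def correlation_edges(
    table: OTUTable,
    method: str = "spearman",
    min_abs_r: float = 0.6,
    alpha: float = 0.05,
    p_adjust: str = "BH",
) -> pd.DataFrame:
    """All-pairs OTU correlations with FDR control; returns the retained edges.

    Columns: otu_a, otu_b, rho, p_value, p_adjusted, sign.
    """
    if table.n_samples < 5:
        raise ValueError("need at least 5 samples for correlation inference")
    x = table.relative_abundance()
    keep = []
    for i, otu in enumerate(table.otu_ids):
        if np.all(x[i] == x[i][0]):
            warnings.warn(f"constant OTU vector skipped: {otu}", stacklevel=2)
        else:
            keep.append(i)
    if len(keep) < 2:
        return _empty_edges()
    sub = x[keep]
    ids = [table.otu_ids[i] for i in keep]
    if method == "spearman":
        data = np.apply_along_axis(stats.rankdata, 1, sub)
    elif method == "pearson":
        data = sub
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    rho = np.corrcoef(data)
    n = table.n_samples
    iu = np.triu_indices(len(ids), 1)
    r = np.clip(rho[iu], -1.0, 1.0)
    # t-distribution p-values for the correlation coefficient
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    if p_adjust == "BH":
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    elif p_adjust == "none":
        p_adj = p
    else:
        raise ValueError("p_adjust must be 'BH' or 'none'")
    mask = (np.abs(r) >= min_abs_r) & (p_adj <= alpha)
    edges = pd.DataFrame({
        "otu_a": [ids[i] for i in iu[0][mask]],
        "otu_b": [ids[j] for j in iu[1][mask]],
        "rho": r[mask],
        "p_value": p[mask],
        "p_adjusted": p_adj[mask],
    })
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    return edges


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p_value", "p_adjusted", "sign"])


def build_network(table: OTUTable, edges: pd.DataFrame) -> nx.Graph:
    """Signed weighted undirected graph over the OTUs appearing in the edge list."""
    g = nx.Graph()
    mean_abund = dict(zip(table.otu_ids, table.relative_abundance().mean(axis=1)))
    nodes = sorted(set(edges["otu_a"]) | set(edges["otu_b"]))
    for o in nodes:
        attrs = {"mean_abundance": float(mean_abund.get(o, 0.0))}
        if table.taxonomy and o in table.taxonomy:
            attrs["phylum"] = table.taxonomy[o].get("phylum", "")
        g.add_node(o, **attrs)
    for row in edges.itertuples(index=False):
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho), sign=row.sign,
                   weight=abs(float(row.rho)), p_adjusted=float(row.p_adjusted))
    return g


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    diameter: float | None
    density: float
    modularity: float | None
    average_clustering: float
    average_path_length: float | None
    pct_positive: float
    pct_negative: float


def topology_metrics(graph: nx.Graph, partition: dict | None = None, seed: int = 0) -> NetworkTopology:
    """The standard topology panel; path metrics use the largest connected component."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = graph.number_of_edges()
    avg_degree = 2 * e / n
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(graph) if e else 0.0
    if e:
        lcc = graph.subgraph(max(nx.connected_components(graph), key=len))
        diameter = float(nx.diameter(lcc))
        apl = float(nx.average_shortest_path_length(lcc))
    else:
        diameter = apl = None
    signs = [d.get("sign", "positive") for _, _, d in graph.edges(data=True)]
    pos = signs.count("positive")
    pct_pos = 100.0 * pos / e if e else 0.0
    pct_neg = 100.0 - pct_pos if e else 0.0
    if partition is None and e:
        partition = detect_modules(graph, seed=seed)
    if partition is not None and e:
        communities = _partition_to_communities(partition)
        q = float(nx.community.modularity(graph, communities))
    else:
        q = None
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=avg_degree,
        diameter=diameter,
        density=density,
        modularity=q,
        average_clustering=float(clustering),
        average_path_length=apl,
        pct_positive=pct_pos,
        pct_negative=pct_neg,
    )


def _partition_to_communities(partition: dict) -> list[set]:
    mods: dict = {}
    for node, m in partition.items():
        mods.setdefault(m, set()).add(node)
    return list(mods.values())


def detect_modules(graph: nx.Graph, seed: int = 0, method: str = "louvain") -> dict:
    """Node -> module id by Louvain modularity maximization (deterministic under seed)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if method != "louvain":
        raise ValueError("only 'louvain' is implemented")
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(graph.nodes())}
    communities = nx.community.louvain_communities(graph, seed=seed, weight=None)
    partition = {}
    for m, nodes in enumerate(sorted(communities, key=lambda s: (-len(s), sorted(s)[0]))):
        for node in nodes:
            partition[node] = m
    return partition


@dataclass
class NodeRole:
    otu_id: str
    module_id: int
    zi: float
    pi: float
    role: str
    degree: int
    boundary: bool = False


def zi_pi(graph: nx.Graph, partition: dict) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi standardizes a node's within-module degree against its module's mean
    and sd (sd = 0 gives Zi = 0). Pi = 1 - sum_s (k_is / k_i)^2 over modules
    s. Roles: module hub (Zi > 2.5, Pi < 0.62), network hub (both high),
    connector (Zi < 2.5, Pi > 0.62), else peripheral; exact threshold hits
    fall to the lower category and are flagged.
    """
    missing = set(graph.nodes()) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    within_degree = {}
    for node in graph.nodes():
        m = partition[node]
        within_degree[node] = sum(1 for nb in graph.neighbors(node) if partition[nb] == m)
    module_stats = {}
    for m in set(partition.values()):
        vals = np.array([within_degree[v] for v in graph.nodes() if partition[v] == m], dtype=float)
        module_stats[m] = (vals.mean(), vals.std(ddof=0))
    roles = []
    for node in graph.nodes():
        m = partition[node]
        k = graph.degree(node)
        mean, sd = module_stats[m]
        zi = float((within_degree[node] - mean) / sd) if sd > 0 else 0.0
        if k == 0:
            pi = 0.0
        else:
            per_module: dict = {}
            for nb in graph.neighbors(node):
                per_module[partition[nb]] = per_module.get(partition[nb], 0) + 1
            pi = float(1.0 - sum((c / k) ** 2 for c in per_module.values()))
        hub = zi > ZI_THRESHOLD
        conn = pi > PI_THRESHOLD
        if hub and conn:
            role = "network hub"
        elif hub:
            role = "module hub"
        elif conn:
            role = "connector"
        else:
            role = "peripheral"
        boundary = zi == ZI_THRESHOLD or pi == PI_THRESHOLD
        roles.append(NodeRole(otu_id=node, module_id=m, zi=zi, pi=pi, role=role,
                              degree=k, boundary=boundary))
    return roles


def key_species(roles: list[NodeRole], table: OTUTable | None = None) -> pd.DataFrame:
    """Non-peripheral nodes (connectors + hubs) ranked by Pi then Zi, with
    abundance and taxonomy annotation when an OTU table is provided."""
    rows = []
    mean_abund = {}
    if table is not None:
        mean_abund = dict(zip(table.otu_ids, table.relative_abundance().mean(axis=1)))
    for r in roles:
        if r.role == "peripheral":
            continue
        row = {
            "otu_id": r.otu_id,
            "role": r.role,
            "zi": r.zi,
            "pi": r.pi,
            "module_id": r.module_id,
            "degree": r.degree,
            "mean_abundance": mean_abund.get(r.otu_id, np.nan),
        }
        if table is not None and table.taxonomy and r.otu_id in table.taxonomy:
            row["phylum"] = table.taxonomy[r.otu_id].get("phylum", "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "otu_id", "role", "zi", "pi", "module_id", "degree", "mean_abundance", "phylum",
    ] if rows and "phylum" in rows[0] else [
        "otu_id", "role", "zi", "pi", "module_id", "degree", "mean_abundance",
    ])
    if len(df):
        df = df.sort_values(["pi", "zi"], ascending=False).reset_index(drop=True)
    return df
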