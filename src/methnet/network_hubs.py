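"""PPI graph construction, centralities, hub clustering and cluster mapping.

Centralities follow the unweighted shortest-path definitions; betweenness
defaults to unnormalized raw pair counts (star center K_{1,n-1} scores
(n-1)(n-2)/2).  K-means hub clustering is evaluated by bootstrap Jaccard
stability (clusterboot-style) and a MANOVA Pillai-trace test; hierarchical
clustering of methylation signal uses Ward linkage on 1 - Pearson
correlation with ordinary bootstrap cluster support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import PathwayDB, PPIEdgeTable

__all__ = [
    "HubClustering",
    "ClusterNetworkMapping",
    "build_graph",
    "centralities",
    "kmeans_hub_clusters",
    "hypergeom_enrichment",
    "ward_signal_clusters",
    "map_clusters_to_network",
]

DEFAULT_FEATURES = ("betweenness", "degree", "closeness", "clustering_coefficient")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def build_graph(edge_table: PPIEdgeTable, score_threshold: float = 0.4,
                min_degree: int = 0) -> nx.Graph:
    """Build the undirected PPI graph, dropping edges below ``score_threshold``
    and (optionally) iteratively removing nodes below ``min_degree`` until
    the filter is stable."""
    df = edge_table.edges
    df = df[df["combined_score"] >= score_threshold]
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b,
                       combined_score=row.combined_score, coexpression=row.coexpression)
    if min_degree > 0:
        while True:
            drop = [v for v, d in graph.degree() if d < min_degree]
            if not drop:
                break
            graph.remove_nodes_from(drop)
    if graph.number_of_nodes() == 0:
        warnings.warn("graph is empty after filtering", stacklevel=2)
    graph.graph["score_threshold"] = score_threshold
    graph.graph["min_degree"] = min_degree
    return graph


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------


def _bfs_counts(graph: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances D and path counts S via BFS."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = [[idx[u] for u in graph.neighbors(v)] for v in nodes]
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if np.isinf(dist[s, u]):
                        dist[s, u] = d + 1
                        nxt.append(u)
                    if dist[s, u] == d + 1:
                        sigma[s, u] += sigma[s, v]
            frontier = nxt
            d += 1
    return dist, sigma


def centralities(graph: nx.Graph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Per-node centralities: degree, betweenness, closeness,
    clustering_coefficient, avg_shortest_path, stress, radiality.

    Path-based metrics are computed within connected components; singleton
    components score 0 on them by convention.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    out = pd.DataFrame(index=nodes, dtype=float)
    out["degree"] = [graph.degree(v) for v in nodes]
    bet = nx.betweenness_centrality(graph, normalized=normalized_betweenness)
    out["betweenness"] = [bet[v] for v in nodes]
    out["clustering_coefficient"] = [nx.clustering(graph, v) for v in nodes]

    closeness = {}
    avg_sp = {}
    stress = {}
    radiality = {}
    for comp in nx.connected_components(graph):
        comp_nodes = sorted(comp)
        nc = len(comp_nodes)
        if nc == 1:
            v = comp_nodes[0]
            closeness[v] = avg_sp[v] = stress[v] = radiality[v] = 0.0
            continue
        sub = graph.subgraph(comp_nodes)
        dist, sigma = _bfs_counts(sub, comp_nodes)
        diam = dist.max()
        for i, v in enumerate(comp_nodes):
            total = dist[i].sum()
            closeness[v] = (nc - 1) / total
            avg_sp[v] = total / (nc - 1)
            radiality[v] = (diam + 1 - dist[i]).sum() - (diam + 1) # exclude self term
            radiality[v] /= nc - 1
        # stress: number of shortest s-t paths passing through v (s != v != t),
        # each unordered pair counted once
        for k, v in enumerate(comp_nodes):
            on_path = dist[:, k][:, None] + dist[k, :][None, :] == dist
            contrib = sigma[:, k][:, None] * sigma[k, :][None, :] * on_path
            contrib[k, :] = 0.0
            contrib[:, k] = 0.0
            np.fill_diagonal(contrib, 0.0)
            stress[v] = contrib.sum() / 2.0
    out["closeness"] = [closeness[v] for v in nodes]
    out["avg_shortest_path"] = [avg_sp[v] for v in nodes]
    out["stress"] = [stress[v] for v in nodes]
    out["radiality"] = [radiality[v] for v in nodes]
    return out


# ---------------------------------------------------------------------------
# K-means hub clustering with bootstrap Jaccard stability + MANOVA
# ---------------------------------------------------------------------------


@dataclass
class HubClustering:
    k: int
    labels: pd.Series
    jaccard: np.ndarray  # mean Jaccard per original cluster
    stable: np.ndarray  # jaccard >= 0.75
    pillai: float
    manova_p: float
    pairwise_f: pd.DataFrame
    degenerate: bool = False


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _pillai_manova(x: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pillai trace and its F-approximation p-value."""
    groups = np.unique(labels)
    g, p = len(groups), x.shape[1]
    n = x.shape[0]
    grand = x.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for lab in groups:
        sub = x[labels == lab]
        d = (sub.mean(axis=0) - grand)[:, None]
        B += len(sub) * (d @ d.T)
        centered = sub - sub.mean(axis=0)
        W += centered.T @ centered
    eigvals = np.real(np.linalg.eigvals(np.linalg.pinv(W + B) @ B))
    eigvals = np.clip(eigvals, 0.0, 1.0)
    pillai = float(eigvals.sum())  # trace((W+B)^-1 B) = sum lambda/(1+lambda)
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if df2 <= 0 or s - pillai <= 1e-12:
        return pillai, 0.0 if s - pillai <= 1e-12 else 1.0
    f_stat = (df2 / df1) * pillai / (s - pillai)
    return pillai, float(stats.f.sf(f_stat, df1, df2))


def _pairwise_hotelling(x: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    groups = np.unique(labels)
    p = x.shape[1]
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa, xb = x[labels == a], x[labels == b]
            na, nb = len(xa), len(xb)
            d = xa.mean(axis=0) - xb.mean(axis=0)
            ca = xa - xa.mean(axis=0)
            cb = xb - xb.mean(axis=0)
            pooled = (ca.T @ ca + cb.T @ cb) / max(na + nb - 2, 1)
            t2 = (na * nb / (na + nb)) * float(d @ np.linalg.pinv(pooled) @ d)
            df2 = na + nb - p - 1
            if df2 <= 0:
                rows.append((a, b, np.nan, np.nan))
                continue
            f_stat = t2 * df2 / (p * (na + nb - 2))
            rows.append((a, b, f_stat, float(stats.f.sf(f_stat, p, df2))))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "f_stat", "p_value"])


def kmeans_hub_clusters(centrality_table: pd.DataFrame, k: int = 3,
                        features: tuple[str, ...] = DEFAULT_FEATURES,
                        seed: int = 0, n_boot: int = 100,
                        stability_threshold: float = 0.75) -> HubClustering:
    """K-means on standardized centrality features with clusterboot-style
    bootstrap Jaccard stability and MANOVA validation."""
    n = len(centrality_table)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes ({n})")
    x = centrality_table.loc[:, list(features)].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        warnings.warn("identical feature rows; clustering is degenerate", stacklevel=2)
        labels = pd.Series(np.zeros(n, dtype=int), index=centrality_table.index)
        return HubClustering(k=k, labels=labels, jaccard=np.full(k, np.nan),
                             stable=np.zeros(k, dtype=bool), pillai=np.nan,
                             manova_p=np.nan, pairwise_f=pd.DataFrame(), degenerate=True)
    z = _zscore(x)
    km = KMeans(n_clusters=k, n_init=50, random_state=seed)
    labels = km.fit_predict(z)

    rng = np.random.default_rng(seed)
    jac_sums = np.zeros(k)
    jac_counts = np.zeros(k)
    orig_members = [set(np.flatnonzero(labels == c)) for c in range(k)]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        kb = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        boot_labels = kb.fit_predict(z[idx])
        label_of = {}
        for pos, node in enumerate(idx):
            label_of.setdefault(node, boot_labels[pos])
        boot_members = [set(node for node in uniq if label_of[node] == c) for c in range(k)]
        sampled = set(uniq.tolist())
        for c in range(k):
            a = orig_members[c] & sampled
            if not a:
                continue
            best = max((len(a & b) / len(a | b)) for b in boot_members if b) if any(boot_members) else 0.0
            jac_sums[c] += best
            jac_counts[c] += 1
    jaccard = np.where(jac_counts > 0, jac_sums / np.maximum(jac_counts, 1), np.nan)
    pillai, manova_p = _pillai_manova(z, labels)
    pairwise = _pairwise_hotelling(z, labels)
    return HubClustering(
        k=k, labels=pd.Series(labels, index=centrality_table.index),
        jaccard=jaccard, stable=jaccard >= stability_threshold,
        pillai=pillai, manova_p=manova_p, pairwise_f=pairwise,
    )


# ---------------------------------------------------------------------------
# hypergeometric pathway enrichment
# ---------------------------------------------------------------------------


def hypergeom_enrichment(gene_set: set[str], pathway_db: PathwayDB,
                         background: set[str], min_genes: int = 2) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_set`` in each pathway.

    BH adjustment is applied across all pathways tested; pathways with
    overlap < min_genes are excluded from the report afterwards.
    """
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    m = len(background)
    n_draw = len(gene_set)
    rows = []
    for pid in sorted(pathway_db.sets):
        members = pathway_db.sets[pid] & background
        k = len(gene_set & members)
        p = stats.hypergeom.sf(k - 1, m, len(members), n_draw) if members else 1.0
        rows.append((pid, k, len(members), float(p)))
    df = pd.DataFrame(rows, columns=["pathway_id", "n_genes_in_set", "pathway_size", "p_value"])
    df["fdr_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df[df["n_genes_in_set"] >= min_genes].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Ward clustering of methylation signal
# ---------------------------------------------------------------------------


def ward_signal_clusters(gene_by_individual_signal: pd.DataFrame, n_clusters: int = 3,
                         n_boot: int = 100, seed: int = 0) -> tuple[pd.Series, pd.Series]:
    """Hierarchical (Ward) clustering of genes on the 1 - corr dissimilarity
    of their methylation signal across individuals.

    Returns (labels per gene, bootstrap support per cluster label), where
    support is the fraction of resampled-individual trees reproducing the
    exact cluster membership.  Constant signal rows are dropped with warning.
    """
    df = gene_by_individual_signal
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise ValueError("need >= 3 genes and >= 3 individuals")
    sds = df.std(axis=1)
    if (sds == 0).any():
        dropped = list(df.index[sds == 0])
        warnings.warn(f"dropping constant-signal genes: {dropped}", stacklevel=2)
        df = df[sds > 0]
        if df.shape[0] < 3:
            raise ValueError("fewer than 3 genes with non-constant signal")

    def _cut(frame: pd.DataFrame) -> np.ndarray:
        corr = np.corrcoef(frame.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(diss, checks=False), method="ward")
        return fcluster(z, n_clusters, criterion="maxclust")

    labels = _cut(df)
    members = {c: frozenset(df.index[labels == c]) for c in np.unique(labels)}
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in members}
    n_ind = df.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_ind, size=n_ind)
        boot = df.iloc[:, cols]
        if (boot.std(axis=1) == 0).any():
            boot = boot + rng.normal(0, 1e-9, size=boot.shape)
        blab = _cut(boot)
        bsets = {frozenset(df.index[blab == c]) for c in np.unique(blab)}
        for c, s in members.items():
            if s in bsets:
                hits[c] += 1
    support = pd.Series({c: hits[c] / n_boot for c in members})
    return pd.Series(labels, index=df.index), support


# ---------------------------------------------------------------------------
# cluster -> network mapping with random-subset null
# ---------------------------------------------------------------------------


@dataclass
class ClusterNetworkMapping:
    cluster: str
    fraction: float
    null_fractions: np.ndarray
    empirical_p: float


def _preservation_fraction(gene_set: set[str], graph: nx.Graph, min_degree: int) -> float:
    """Fraction of the gene set surviving in the largest connected component of
    its induced subgraph after iterative min-degree pruning."""
    sub = graph.subgraph(n for n in gene_set if n in graph).copy()
    if min_degree > 0:
        while True:
            drop = [v for v, d in sub.degree() if d < min_degree]
            if not drop:
                break
            sub.remove_nodes_from(drop)
    if sub.number_of_nodes() == 0:
        return 0.0
    main = max(nx.connected_components(sub), key=len)
    return len(main) / len(gene_set)


def map_clusters_to_network(clusters: dict[str, set[str]], edge_table: PPIEdgeTable,
                            score_threshold: float = 0.7, min_degree: int = 3,
                            n_random: int = 1000, seed: int = 0,
                            universe: set[str] | None = None) -> list[ClusterNetworkMapping]:
    """Observed preservation fraction per cluster vs a null of same-size
    uniform gene subsets drawn from ``universe`` (default: all graph nodes)."""
    graph = build_graph(edge_table, score_threshold=score_threshold, min_degree=0)
    if universe is None:
        universe = set(graph.nodes)
    universe_list = sorted(universe)
    rng = np.random.default_rng(seed)
    out = []
    for name in sorted(clusters):
        gene_set = set(clusters[name])
        if len(gene_set) > len(universe_list):
            raise ValueError(f"cluster {name!r} larger than sampling universe")
        observed = _preservation_fraction(gene_set, graph, min_degree)
        null = np.empty(n_random)
        for i in range(n_random):
            subset = set(rng.choice(universe_list, size=len(gene_set), replace=False))
            null[i] = _preservation_fraction(subset, graph, min_degree)
        emp_p = float(np.mean(null >= observed))
        out.append(ClusterNetworkMapping(cluster=name, fraction=observed,
                                         null_fractions=null, empirical_p=emp_p))
    return out
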