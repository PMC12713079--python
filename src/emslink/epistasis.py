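"""Gene-level pairwise epistasis scan and interaction-network analysis.

Epistasis here is a non-additive joint effect of two genes on a trait,
detected on the 0/1 gene-presence encoding: for each eligible gene pair the
full interaction model ::

    y = b0 + b1 * g_i + b2 * g_j + b3 * g_i*g_j + e

is fitted by OLS and the two-sided t-test on the interaction coefficient
``b3`` is reported.  Genes need a minimum number of carrier lines to be
eligible, and pairs whose interaction column is constant or collinear with
the marginals are skipped.

The most significant pairs per trait are assembled into an undirected
network (trait labels kept on edges, parallel edges merged for topology);
degree and shortest-path betweenness describe its hubs, and an iterative
node-removal simulation probes how fast connectivity (average degree)
decays when hubs, flagged candidate genes, or random nodes are deleted.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def pairwise_epistasis(
    binary: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    min_carriers: int = 5,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Interaction t-test for every eligible gene pair.

    ``binary`` is a genes x lines 0/1 presence matrix.  Eligible genes
    carry at least ``min_carriers`` carrier lines among the phenotyped,
    non-wild-type lines.  Returns a DataFrame with columns (gene_i,
    gene_j, stat, p, n) where gene_i < gene_j lexicographically and
    ``stat`` is the t statistic of the interaction coefficient.
    """
    is_wt = phenotypes["is_wt"] if "is_wt" in phenotypes.columns else pd.Series(
        False, index=phenotypes.index
    )
    pheno = phenotypes.loc[~is_wt].set_index("line_id")[trait].astype(float).dropna()
    lines = binary.columns.intersection(pheno.index)
    B = binary[lines].to_numpy(dtype=float)
    y = pheno[lines].to_numpy()
    n = len(lines)

    carriers = B.sum(axis=1)
    eligible = np.flatnonzero(carriers >= min_carriers)
    genes = binary.index.to_numpy()
    if len(eligible) < 2:
        raise ValueError("fewer than 2 genes meet the carrier floor")

    if pairs is None:
        pair_iter = itertools.combinations(eligible, 2)
    else:
        pos = {g: i for i, g in enumerate(genes)}
        pair_iter = ((pos[a], pos[b]) for a, b in pairs)

    rows = []
    n_skipped = 0
    ones = np.ones(n)
    for i, j in pair_iter:
        gi, gj = B[i], B[j]
        inter = gi * gj
        if inter.std() == 0:
            n_skipped += 1
            continue
        X = np.column_stack([ones, gi, gj, inter])
        stat_p = _interaction_t(X, y)
        if stat_p is None:
            n_skipped += 1
            continue
        t_stat, p = stat_p
        a, b = sorted((str(genes[i]), str(genes[j])))
        rows.append((a, b, t_stat, p, n))

    if n_skipped:
        logger.info("pairwise_epistasis: %d degenerate pairs skipped", n_skipped)
    out = pd.DataFrame(rows, columns=["gene_i", "gene_j", "stat", "p", "n"])
    out.insert(2, "trait", trait)
    if out.empty:
        warnings.warn("all gene pairs were skipped; no epistasis statistics computed")
    return out


def _interaction_t(X: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """t statistic and p-value of the last coefficient of an OLS fit.

    Returns None for rank-deficient designs or saturated fits with no
    residual degrees of freedom.
    """
    n, k = X.shape
    if n <= k:
        return None
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        return None
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    var = sigma2 * xtx_inv[-1, -1]
    if var <= 0:
        # perfect fit: infinite t, p -> 0
        return (np.inf if beta[-1] > 0 else -np.inf), 0.0
    t_stat = float(beta[-1] / np.sqrt(var))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n - k))
    return t_stat, p


def top_edges(edges: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """The n smallest-p edges, ties broken by lexicographic pair id."""
    if n > len(edges):
        warnings.warn(f"requested {n} edges but only {len(edges)} available")
    ranked = edges.sort_values(["p", "gene_i", "gene_j"], kind="mergesort")
    return ranked.head(n).reset_index(drop=True)


def build_network(edges: pd.DataFrame,
                  candidates: set[str] | None = None) -> nx.Graph:
    """Undirected gene network from a (possibly multi-trait) edge table.

    Parallel edges from different traits are merged; each edge keeps the
    list of traits supporting it and its smallest p.  Nodes carry a
    ``candidate`` flag.
    """
    G = nx.Graph()
    for row in edges.itertuples(index=False):
        u, v = row.gene_i, row.gene_j
        if G.has_edge(u, v):
            G[u][v]["traits"].append(row.trait)
            G[u][v]["p"] = min(G[u][v]["p"], row.p)
        else:
            G.add_edge(u, v, traits=[row.trait], p=row.p)
    candidates = candidates or set()
    for node in G.nodes:
        G.nodes[node]["candidate"] = node in candidates
    return G


def network_metrics(G: nx.Graph) -> tuple[pd.DataFrame, float]:
    """Per-node degree and betweenness, plus the global average degree."""
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree", "betweenness"]), 0.0
    degree = dict(G.degree())
    betweenness = nx.betweenness_centrality(G, normalized=True)
    table = pd.DataFrame(
        {"degree": pd.Series(degree), "betweenness": pd.Series(betweenness)}
    ).sort_index()
    table.index.name = "gene_id"
    avg_degree = 2.0 * G.number_of_edges() / G.number_of_nodes()
    return table, avg_degree


def average_degree(G: nx.Graph) -> float:
    if G.number_of_nodes() == 0:
        return 0.0
    return 2.0 * G.number_of_edges() / G.number_of_nodes()


def node_removal_simulation(
    G: nx.Graph,
    strategy: str = "hub",
    steps: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Average-degree trajectory under iterative node deletion.

    Strategies: ``hub`` removes the current highest-degree node (ties
    broken lexicographically), ``candidate`` removes a random
    candidate-flagged node, ``random`` removes a uniformly random node.
    Returns ``steps + 1`` values including the intact network at step 0.
    """
    if steps is None:
        steps = G.number_of_nodes()
    if steps > G.number_of_nodes():
        raise ValueError("steps exceeds node count")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    H = G.copy()
    trajectory = [average_degree(H)]
    for _ in range(steps):
        if strategy == "hub":
            node = min(H.nodes, key=lambda u: (-H.degree(u), str(u)))
        elif strategy == "random":
            node = sorted(H.nodes)[rng.integers(len(H))]
        elif strategy == "candidate":
            flagged = sorted(u for u in H.nodes if H.nodes[u].get("candidate"))
            if not flagged:
                raise ValueError("no candidate-flagged nodes remain")
            node = flagged[rng.integers(len(flagged))]
        else:
            raise ValueError("strategy must be 'hub', 'candidate' or 'random'")
        H.remove_node(node)
        trajectory.append(average_degree(H))
    return np.asarray(trajectory)


def write_graphml(G: nx.Graph, path: str) -> None:
    """GraphML export with degree/betweenness/candidate node attributes."""
    H = G.copy()
    metrics, _ = network_metrics(H)
    for node in H.nodes:
        H.nodes[node]["degree"] = int(metrics.loc[node, "degree"])
        H.nodes[node]["betweenness"] = float(metrics.loc[node, "betweenness"])
        H.nodes[node]["candidate"] = bool(H.nodes[node].get("candidate", False))
    for u, v in H.edges:
        H[u][v]["traits"] = ",".join(H[u][v].get("traits", []))
    nx.write_graphml(H, path)
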