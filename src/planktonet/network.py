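"""Correlation-based co-occurrence networks and their topology.

Edges connect features whose (Spearman, by default) correlation of
log-transformed relative abundances passes both an effect-size threshold
|r| >= r_min and a Benjamini-Hochberg FDR cutoff q <= q_max.  Threshold
selection is explicit and recorded in the graph attributes rather than
scanned (no random-matrix-theory step); zeros are replaced by a 0.01
pseudo-abundance on the percent scale before the log, following the usual
molecular-ecological-network preprocessing.

Modules come from deterministic greedy modularity maximization; node roles
follow the Guimera-Amaral plane: within-module degree z-score Zi >= 2.5
marks module hubs, participation coefficient Pi >= 0.62 marks connectors,
both together network hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import relative_abundance

logger = logging.getLogger("planktonet")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# construction


def correlation_matrix(x: np.ndarray, method: str = "spearman"):
    """Pairwise feature correlations and two-sided p-values (columns of x)."""
    n, k = x.shape
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ xc) / n / np.outer(sd, sd)
    r = np.clip(r, -1.0, 1.0)
    r[:, sd == 0] = np.nan        # constant feature: correlation undefined
    r[sd == 0, :] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def build_network(table: pd.DataFrame, prevalence_min: float = 0.5,
                  method: str = "spearman", r_min: float = 0.6,
                  q_max: float = 0.05, pseudo: float = 0.01,
                  keep_isolated: bool = False) -> nx.Graph:
    """Build the signed co-occurrence network.

    Features present in fewer than ``prevalence_min`` of samples are
    dropped; correlations are computed on log10 percent relative abundance
    with zeros replaced by ``pseudo``; edges require |r| >= r_min and
    BH-adjusted p <= q_max.  Nodes without any edge are dropped unless
    ``keep_isolated``.
    """
    if len(table) < 10:
        logger.warning("build_network on %d samples (<10): correlations "
                       "will be noisy", len(table))
    prev = (table > 0).mean(axis=0)
    full_rel = relative_abundance(table)
    sub = full_rel.loc[:, prev >= prevalence_min]
    if sub.shape[1] < 2:
        raise ValueError("fewer than 2 features pass the prevalence filter")
    rel = sub.to_numpy() * 100.0
    x = np.log10(np.where(rel > 0, rel, pseudo))
    r, p = correlation_matrix(x, method=method)

    feats = list(sub.columns)
    iu, ju = np.triu_indices(len(feats), k=1)
    rv, pv = r[iu, ju], p[iu, ju]
    ok = np.isfinite(rv) & np.isfinite(pv)
    q = np.full_like(pv, np.nan)
    if ok.any():
        q[ok] = multipletests(pv[ok], method="fdr_bh")[1]
    edge_mask = ok & (np.abs(rv) >= r_min) & (q <= q_max)

    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(feats)
    for a, b, rr, qq in zip(iu[edge_mask], ju[edge_mask],
                            rv[edge_mask], q[edge_mask]):
        g.add_edge(feats[a], feats[b], r=float(rr), q=float(qq),
                   weight=float(abs(rr)),
                   sign="positive" if rr > 0 else "negative")
    g.graph.update(method=method, r_min=r_min, q_max=q_max,
                   prevalence_min=prevalence_min, pseudo=pseudo,
                   n_tested_pairs=int(ok.sum()))
    if g.number_of_nodes() == 0:
        logger.warning("build_network produced an empty network")
    return g


# ---------------------------------------------------------------------------
# modules and metrics


def detect_modules(network: nx.Graph, seed: int = 0):
    """Greedy modularity partition (deterministic); returns
    ``(labels, Q)`` and stores labels in the node attribute ``module``.
    Isolated nodes become singleton modules."""
    if network.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless network")
    comms = greedy_modularity_communities(network)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    labels = {node: i for i, c in enumerate(comms) for node in c}
    q = modularity(network, [set(c) for c in comms])
    nx.set_node_attributes(network, labels, "module")
    return labels, float(q)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_path_length: float
    modularity: float
    n_modules: int
    powerlaw_gamma: float
    powerlaw_r2: float
    powerlaw_p: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _mean_shortest_path(g: nx.Graph) -> float:
    """Mean shortest-path length over all reachable (unordered) pairs."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += k * (k - 1)
    return total / pairs if pairs else np.nan


def topology_summary(network: nx.Graph, seed: int = 0) -> TopologySummary:
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    modules = nx.get_node_attributes(network, "module")
    if not modules and network.number_of_edges() > 0:
        modules, q = detect_modules(network, seed=seed)
    elif modules:
        groups: dict[int, set] = {}
        for node, mod in modules.items():
            groups.setdefault(mod, set()).add(node)
        q = float(modularity(network, list(groups.values()))) \
            if network.number_of_edges() else np.nan
    else:
        q = np.nan
    degs = [d for _, d in network.degree()]
    pl = powerlaw_fit(degs)
    return TopologySummary(
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        avg_degree=float(np.mean(degs)) if degs else 0.0,
        avg_clustering=float(nx.average_clustering(network))
        if network.number_of_nodes() else np.nan,
        avg_path_length=_mean_shortest_path(network),
        modularity=q,
        n_modules=len(set(modules.values())) if modules else 0,
        powerlaw_gamma=pl.gamma, powerlaw_r2=pl.r2, powerlaw_p=pl.p)


def node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness, Zi, Pi and topological role per node
    (requires a module partition; computes one if absent)."""
    modules = nx.get_node_attributes(network, "module")
    if not modules:
        modules, _ = detect_modules(network)
    btw = nx.betweenness_centrality(network, normalized=True)
    rows = {}
    # within-module degree per node, then z-score within each module
    within = {}
    for node in network.nodes:
        within[node] = sum(1 for nb in network.neighbors(node)
                           if modules[nb] == modules[node])
    by_module: dict[int, list] = {}
    for node, mod in modules.items():
        by_module.setdefault(mod, []).append(node)
    zi = {}
    for mod, members in by_module.items():
        vals = np.array([within[m] for m in members], float)
        sd = vals.std(ddof=0)
        for m in members:
            zi[m] = (within[m] - vals.mean()) / sd if sd > 0 else 0.0
    for node in network.nodes:
        k = network.degree(node)
        if k == 0:
            pi = 0.0
        else:
            km: dict[int, int] = {}
            for nb in network.neighbors(node):
                km[modules[nb]] = km.get(modules[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in km.values())
        z = zi[node]
        if z >= ZI_THRESHOLD and pi >= PI_THRESHOLD:
            role = "network hub"
        elif z >= ZI_THRESHOLD:
            role = "module hub"
        elif pi >= PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows[node] = {"degree": k, "betweenness": btw[node],
                      "module": modules[node], "zi": z, "pi": pi,
                      "role": role}
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PowerlawFit:
    gamma: float
    r2: float
    p: float
    assessable: bool


def powerlaw_fit(degrees) -> PowerlawFit:
    """Least-squares fit of log frequency vs log degree, P(k) ~ k^-gamma.
    Needs >= 5 distinct positive degrees to be assessable."""
    degrees = np.asarray([d for d in degrees if d > 0])
    if degrees.size == 0:
        return PowerlawFit(np.nan, np.nan, np.nan, False)
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 5:
        return PowerlawFit(np.nan, np.nan, np.nan, False)
    freq = counts / counts.sum()
    res = stats.linregress(np.log(ks), np.log(freq))
    return PowerlawFit(gamma=float(-res.slope), r2=float(res.rvalue ** 2),
                       p=float(res.pvalue), assessable=True)
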