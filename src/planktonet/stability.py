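"""Network stability: removal robustness, vulnerability, fragmentation.

Robustness is the proportion of taxa remaining after a removal scheme plus
secondary extinction of nodes the removal leaves without any surviving
partner.  Vulnerability of a node is the relative drop in global efficiency
when it is removed; network vulnerability is the maximum over nodes.
Fragmentation after consecutive removal of the highest-betweenness nodes is
the complement of the fraction of remaining node pairs still connected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("planktonet")


@dataclass
class RobustnessResult:
    mean: float
    sd: float
    values: np.ndarray = field(repr=False)
    scheme: str = "random"
    seed: int | None = None


def robustness_after_removal(network: nx.Graph, removed,
                             cascade: bool = True) -> float:
    """Fraction of original taxa surviving the removal of ``removed`` plus,
    when ``cascade``, the secondary extinction of nodes left isolated."""
    n = network.number_of_nodes()
    removed = set(removed)
    sub = network.subgraph([v for v in network.nodes if v not in removed])
    if cascade:
        survivors = sum(1 for _, d in sub.degree() if d > 0)
    else:
        survivors = sub.number_of_nodes()
    return survivors / n


def robustness_random(network: nx.Graph, remove_fraction: float = 0.5,
                      reps: int = 100, seed: int = 0,
                      cascade: bool = True) -> RobustnessResult:
    """Robustness under uniform random removal of
    ``floor(remove_fraction * n)`` nodes, repeated ``reps`` times."""
    if not (0.0 < remove_fraction < 1.0):
        raise ValueError("remove_fraction must be in (0, 1)")
    if network.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    nodes = sorted(network.nodes)
    k = math.floor(remove_fraction * len(nodes))
    rng = np.random.default_rng(seed)
    vals = np.array([
        robustness_after_removal(
            network, [nodes[i] for i in
                      rng.choice(len(nodes), size=k, replace=False)],
            cascade=cascade)
        for _ in range(reps)])
    return RobustnessResult(float(vals.mean()), float(vals.std(ddof=1))
                            if reps > 1 else 0.0, vals, "random", seed)


def robustness_targeted(network: nx.Graph, metrics: pd.DataFrame,
                        reps: int = 100, seed: int = 0,
                        cascade: bool = True) -> RobustnessResult:
    """Robustness when half the module hubs (Zi >= 2.5, including network
    hubs) are removed; with no hubs the network is untouched (robustness 1,
    warning logged)."""
    hubs = sorted(metrics.index[metrics["role"].isin(
        ["module hub", "network hub"])])
    if not hubs:
        logger.warning("robustness_targeted: no module hubs; nothing removed")
        return RobustnessResult(1.0, 0.0, np.ones(reps), "targeted", seed)
    k = math.ceil(len(hubs) / 2)
    rng = np.random.default_rng(seed)
    vals = np.array([
        robustness_after_removal(
            network, [hubs[i] for i in
                      rng.choice(len(hubs), size=k, replace=False)],
            cascade=cascade)
        for _ in range(reps)])
    return RobustnessResult(float(vals.mean()), float(vals.std(ddof=1))
                            if reps > 1 else 0.0, vals, "targeted", seed)


def vulnerability(network: nx.Graph):
    """Per-node vulnerability V_i = (E - E_-i) / E with E the global
    efficiency (mean inverse shortest-path over ordered pairs, unreachable
    pairs contributing 0); returns ``(per_node, max)``.  V_i can be
    negative when removing a peripheral node raises mean efficiency."""
    if network.number_of_nodes() < 3:
        raise ValueError("need >= 3 nodes")
    e_full = nx.global_efficiency(network)
    if e_full == 0:
        raise ValueError("network has no connected pair")
    vals = {}
    for node in network.nodes:
        sub = network.subgraph([v for v in network.nodes if v != node])
        vals[node] = (e_full - nx.global_efficiency(sub)) / e_full
    per_node = pd.Series(vals, name="vulnerability").sort_index()
    return per_node, float(per_node.max())


def fragmentation(network: nx.Graph) -> float:
    """F = 1 - sum_k s_k (s_k - 1) / (N (N - 1)) over component sizes; 0
    for a connected network, 1 when no pair remains connected."""
    n = network.number_of_nodes()
    if n < 2:
        return 1.0
    paired = sum(len(c) * (len(c) - 1) for c in nx.connected_components(network))
    return 1.0 - paired / (n * (n - 1))


def fragmentation_series(network: nx.Graph, n_steps: int = 10) -> pd.DataFrame:
    """Consecutively remove the current highest-betweenness node (ties:
    higher degree, then lexicographic id), recording the fragmentation F
    and largest-component share after each removal.  Step 0 is the intact
    network."""
    if n_steps >= network.number_of_nodes():
        raise ValueError("n_steps must be < number of nodes")
    g = network.copy()
    n0 = g.number_of_nodes()
    rows = [{"step": 0, "removed": None, "fragmentation": fragmentation(g),
             "largest_component_frac":
                 max(len(c) for c in nx.connected_components(g)) / n0}]
    for step in range(1, n_steps + 1):
        if g.number_of_nodes() == 0:
            logger.warning("fragmentation_series exhausted at step %d", step)
            break
        btw = nx.betweenness_centrality(g, normalized=True)
        target = min(g.nodes,
                     key=lambda v: (-btw[v], -g.degree(v), str(v)))
        g.remove_node(target)
        nr = g.number_of_nodes()
        rows.append({
            "step": step, "removed": target, "fragmentation": fragmentation(g),
            "largest_component_frac":
                (max(len(c) for c in nx.connected_components(g)) / nr)
                if nr else 0.0})
    return pd.DataFrame(rows)


@dataclass
class StabilityResult:
    robustness_random: RobustnessResult
    robustness_targeted: RobustnessResult
    vulnerability: float
    fragmentation_series: pd.DataFrame = field(repr=False)
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "robustness_random_mean": self.robustness_random.mean,
            "robustness_random_sd": self.robustness_random.sd,
            "robustness_targeted_mean": self.robustness_targeted.mean,
            "robustness_targeted_sd": self.robustness_targeted.sd,
            "vulnerability": self.vulnerability,
            "final_fragmentation":
                float(self.fragmentation_series["fragmentation"].iloc[-1]),
            "seed": self.seed,
        }


def stability_analysis(network: nx.Graph, metrics: pd.DataFrame,
                       remove_fraction: float = 0.5, reps: int = 100,
                       n_steps: int = 10, seed: int = 0) -> StabilityResult:
    """Run the full stability battery on one network."""
    rr = robustness_random(network, remove_fraction, reps, seed)
    rt = robustness_targeted(network, metrics, reps, seed + 1)
    _, vmax = vulnerability(network)
    steps = min(n_steps, network.number_of_nodes() - 1)
    if steps < n_steps:
        logger.warning("fragmentation series shortened to %d steps", steps)
    frag = fragmentation_series(network, steps)
    return StabilityResult(rr, rt, vmax, frag, seed)
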