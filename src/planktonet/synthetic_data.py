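"""Synthetic plankton communities with known assembly ground truth.

The generator emulates the structure of a cross-kingdom coastal amplicon
survey — a few dozen stations along a latitude/nutrient gradient, two
"kingdom" count tables with strongly skewed abundance distributions, and a
shared random phylogeny — under three assembly regimes:

neutral
    Each local community is a Dirichlet-multinomial draw around a fixed
    source pool ``p`` with concentration ``N*m`` (Sloan's immigration
    parameter): per-taxon relative abundance is marginally
    ``Beta(N*m*p_i, N*m*(1-p_i))``, counts are a multinomial of size ``N``.
selection
    Each taxon has a Gaussian niche response on the environmental gradient,
    with optima evolved by Brownian motion along the tree so that niches are
    phylogenetically conserved (a prerequisite for betaNTI to detect
    selection).  The per-sample source pool is re-weighted by the niche
    kernel before the same Dirichlet-multinomial draw; ``selection_strength
    = 0`` reproduces the neutral generator bit for bit.
mixed
    Per-sample interpolation between the neutral and selection pools with a
    recorded weight.

All generators are deterministic given ``seed`` (independent substreams for
tree, pool, optima, metadata and counts, so regimes sharing a seed share
their pool and phylogeny).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass
class SyntheticDataset:
    """A simulated (table, tree, metadata) triple plus its ground truth."""

    table: pd.DataFrame          # samples x features, integer counts
    tree: TreeNode
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phylogeny


def simulate_tree(n_taxa: int, seed: int, scale: float = 1.0) -> TreeNode:
    """Random ultrametric tree from the Kingman coalescent.

    With ``k`` lineages the waiting time to the next (uniformly chosen)
    merge is exponential with mean ``scale * 2 / (k (k - 1))``; branch
    lengths are the inter-event intervals.  The shared root-to-tip depth is
    the coalescent tree height, with closed form
    ``mean = 2 scale (1 - 1/n)`` and
    ``variance = scale^2 * sum_{k=2..n} (2 / (k (k-1)))^2``
    used by the generator tests.  Coalescent trees carry deep clade
    structure (high variance of pairwise distances), which the selection
    generator relies on for phylogenetically conserved niches.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([seed, 11])
    width = len(str(n_taxa))
    nodes = [TreeNode(name=f"t{i + 1:0{width}d}") for i in range(n_taxa)]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale * 2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent = TreeNode(children=[a, b])
        nodes[j] = parent
        heights[j] = t
        del nodes[i], heights[i]
    root = nodes[0]
    root.length = None
    return root


def brownian_optima(tree: TreeNode, seed: int, sigma: float = 1.0) -> pd.Series:
    """Evolve a continuous trait by Brownian motion along the tree, then
    map tip values to [0, 1] by rank (niche optima on the gradient).

    The rank transform spreads optima evenly over the gradient at every
    seed — a min-max rescale collapses whenever one outlier tip stretches
    the range — while preserving the trait ordering, so related tips keep
    similar optima (the phylogenetic conservatism betaNTI relies on).
    """
    rng = np.random.default_rng([seed, 13])
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma * np.sqrt(max(node.length or 0.0, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    tips = [t for t in tree.tips()]
    x = np.array([values[id(t)] for t in tips])
    if len(x) > 1:
        x = x.argsort().argsort() / (len(x) - 1.0)
    else:
        x = np.array([0.5])
    return pd.Series(x, index=[t.name for t in tips])


# ---------------------------------------------------------------------------
# source pool and metadata


def stick_breaking_pool(n_taxa: int, seed: int, theta: float = 20.0,
                        discount: float = 0.6) -> np.ndarray:
    """Skewed source-pool proportions via Pitman-Yor stick breaking.

    ``discount > 0`` produces a power-law (log-series-like) tail instead of
    the geometric tail of plain GEM(theta); the defaults yield a handful of
    taxa above 1% and a long rare tail in which most taxa still carry a few
    reads per survey, matching coastal amplicon data.
    """
    rng = np.random.default_rng([seed, 12])
    if not (0.0 <= discount < 1.0):
        raise ValueError("discount must be in [0, 1)")
    v = rng.beta(1.0 - discount, theta + discount * np.arange(1, n_taxa + 1))
    stick = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    p = v * stick
    p = np.sort(p)[::-1]
    return p / p.sum()


def gradient_metadata(n_samples: int, seed: int) -> pd.DataFrame:
    """Station metadata along a coastal latitude gradient (32-39.5 degN).

    Temperature declines and inorganic nutrients rise with latitude, with
    station-level noise; chl a tracks nutrients.  Values are in the usual
    field units (degC, psu, mg/L, umol/L).
    """
    rng = np.random.default_rng([seed, 14])
    lat = np.linspace(32.0, 39.5, n_samples)
    g = (lat - lat.min()) / (lat.max() - lat.min())
    lon = 120.0 + 4.5 * g + rng.normal(0, 0.4, n_samples)
    meta = pd.DataFrame({
        "latitude": lat,
        "longitude": lon,
        "temperature": 27.0 - 6.0 * g + rng.normal(0, 0.5, n_samples),
        "salinity": 31.0 + 1.5 * g + rng.normal(0, 0.3, n_samples),
        "DO": 6.5 + 1.2 * g + rng.normal(0, 0.2, n_samples),
        "chl_a": np.exp(0.2 + 1.0 * g + rng.normal(0, 0.3, n_samples)),
        "nitrate": 2.0 + 6.0 * g + rng.normal(0, 0.5, n_samples),
        "nitrite": 0.2 + 0.5 * g + rng.normal(0, 0.05, n_samples),
        "ammonia": 0.5 + 1.0 * g + rng.normal(0, 0.1, n_samples),
        "DIP": 0.1 + 0.5 * g + rng.normal(0, 0.03, n_samples),
        "silicate": 3.0 + 8.0 * g + rng.normal(0, 0.8, n_samples),
    }, index=[f"S{i + 1:02d}" for i in range(n_samples)])
    meta["total_N"] = meta["nitrate"] + meta["nitrite"] + meta["ammonia"] \
        + rng.normal(0, 0.2, n_samples)
    meta["inorganic_N"] = meta["nitrate"] + meta["nitrite"] + meta["ammonia"]
    return meta


# ---------------------------------------------------------------------------
# community simulation


def _simulate(n_samples, n_taxa, N, m, selection_strength, seed, *,
              theta=20.0, discount=0.6, niche_sigma=0.3, patchiness=1.0,
              n_factors=8, overdispersion=1.0, conserved_niches=True,
              mix_weight=None, tree=None, metadata=None, pool=None,
              mode=None):
    if not (0.0 < m <= 1.0):
        raise ValueError("m must be in (0, 1]")
    if N < 100:
        raise ValueError("N must be >= 100")
    if selection_strength < 0:
        raise ValueError("selection_strength must be >= 0")

    if tree is None:
        tree = simulate_tree(n_taxa, seed)
    tip_names = [t.name for t in tree.tips()]
    if pool is None:
        pool = stick_breaking_pool(n_taxa, seed, theta=theta,
                                   discount=discount)
        # assign abundances to tips at random: the sorted pool must not
        # track the tree's tip-traversal order (phylogenetic artifact)
        pool = pool[np.random.default_rng([seed, 18]).permutation(n_taxa)]
    if metadata is None:
        metadata = gradient_metadata(n_samples, seed)
    lat = metadata["latitude"].to_numpy()
    g = (lat - lat.min()) / (lat.max() - lat.min()) if n_samples > 1 \
        else np.array([0.5])
    # latitude-independent habitat structure (water-mass patchiness):
    # phylogenetically conserved habitat groups whose members bloom and
    # fade together across stations, independently between groups — this
    # is what gives co-occurrence networks their modular block structure
    rng_axis = np.random.default_rng([seed, 16])
    factor_activity = rng_axis.normal(0.0, 1.0, (n_samples, n_factors))

    optima = brownian_optima(tree, seed)
    habitat_trait = brownian_optima(tree, seed + 101)
    opt = optima.loc[tip_names].to_numpy()
    trait2 = habitat_trait.loc[tip_names].to_numpy()
    # conserved discrete habitat groups: quantile bins of a second
    # Brownian trait, so group membership follows clades
    quantiles = np.quantile(trait2, np.linspace(0, 1, n_factors + 1)[1:-1])
    group = np.searchsorted(quantiles, trait2)
    if not conserved_niches:
        # decouple niches from the phylogeny: same niche structure (and
        # hence co-occurrence), but betaNTI sees no phylogenetic signal
        shuffle = np.random.default_rng([seed, 17]).permutation(n_taxa)
        opt = opt[shuffle]
        group = group[shuffle]

    rng = np.random.default_rng([seed, 15])
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for s in range(n_samples):
        if selection_strength > 0:
            # idiosyncratic lognormal bloom noise keeps taxa from being
            # perfectly coupled through the shared gradient
            eps = rng.normal(0.0, 1.0, n_taxa)
            log_kernel = (-selection_strength * (g[s] - opt) ** 2
                          / (2.0 * niche_sigma ** 2)
                          + patchiness * factor_activity[s, group]
                          + overdispersion * eps)
            # geometric interpolation: the mix weight scales the kernel on
            # the log scale, so w=0 is exactly neutral and w=1 full selection
            w = 1.0 if mix_weight is None else mix_weight
            p_eff = pool * np.exp(w * log_kernel)
            p_eff = p_eff / p_eff.sum()
        else:
            p_eff = pool
        alpha = N * m * p_eff
        gamma = rng.gamma(np.maximum(alpha, 1e-12))
        rel = gamma / gamma.sum()
        counts[s] = rng.multinomial(N, rel)

    table = pd.DataFrame(counts, index=metadata.index, columns=tip_names)
    truth = {
        "assembly_mode": mode or ("neutral" if selection_strength == 0
                                  else "selection"),
        "m": m, "N": N, "Nm": N * m,
        "selection_strength": selection_strength,
        "niche_sigma": niche_sigma,
        "patchiness": patchiness,
        "n_factors": n_factors,
        "overdispersion": overdispersion,
        "conserved_niches": conserved_niches,
        "mix_weight": mix_weight,
        "seed": seed,
        "pool": pool,
        "gradient": g,
        "optima": optima.to_dict(),
        "habitat_group": dict(zip(tip_names, group.tolist())),
    }
    return SyntheticDataset(table=table, tree=tree, metadata=metadata,
                            truth=truth)


def simulate_neutral_dataset(n_samples, n_taxa, N, m, seed, *, theta=20.0,
                             tree=None, metadata=None, pool=None):
    """Sloan neutral local communities around a shared source pool."""
    return _simulate(n_samples, n_taxa, N, m, 0.0, seed, theta=theta,
                     tree=tree, metadata=metadata, pool=pool, mode="neutral")


def simulate_selection_dataset(n_samples, n_taxa, N, selection_strength, seed,
                               *, m=0.5, theta=20.0, niche_sigma=0.3,
                               patchiness=1.0, n_factors=8,
                               overdispersion=1.0, conserved_niches=True,
                               tree=None, metadata=None, pool=None):
    """Gaussian niche selection along the gradient plus conserved habitat
    groups; ``selection_strength=0`` degenerates to neutral."""
    return _simulate(n_samples, n_taxa, N, m, selection_strength, seed,
                     theta=theta, niche_sigma=niche_sigma,
                     patchiness=patchiness, n_factors=n_factors,
                     overdispersion=overdispersion,
                     conserved_niches=conserved_niches, tree=tree,
                     metadata=metadata, pool=pool,
                     mode="neutral" if selection_strength == 0 else "selection")


def simulate_mixed_dataset(n_samples, n_taxa, N, selection_strength, weight,
                           seed, *, m=0.5, theta=20.0, niche_sigma=0.3,
                           patchiness=1.0, n_factors=8, overdispersion=1.0,
                           conserved_niches=True,
                           tree=None, metadata=None, pool=None):
    """Interpolate the neutral and selection pools with ``weight`` in [0,1]."""
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must be in [0, 1]")
    return _simulate(n_samples, n_taxa, N, m, selection_strength, seed,
                     theta=theta, niche_sigma=niche_sigma,
                     patchiness=patchiness, n_factors=n_factors,
                     overdispersion=overdispersion,
                     conserved_niches=conserved_niches,
                     mix_weight=weight, tree=tree, metadata=metadata,
                     pool=pool, mode="mixed")


def simulate_cross_kingdom_fixture(seed, *, n_samples=38,
                                   n_taxa=(1945, 1818), N=44800):
    """Two kingdom tables over one station grid, mirroring a 38-station
    cross-kingdom survey: ~1,945-taxon mostly-neutral community and a
    ~1,818-taxon community under strong gradient selection.

    Returns ``(neutral_ds, selection_ds)`` sharing one metadata table.
    """
    metadata = gradient_metadata(n_samples, seed)
    # "mostly neutral" kingdom: weak, phylogenetically unconserved patchy
    # blooms — modular co-occurrence but near-null betaNTI and a good
    # neutral-model fit.  Selection kingdom: conserved niches on the
    # latitude gradient plus conserved habitat groups.
    neutral = simulate_mixed_dataset(
        n_samples, n_taxa[0], N, selection_strength=4.0, weight=0.35,
        seed=seed * 2 + 1, m=0.05, niche_sigma=0.4, patchiness=2.5,
        n_factors=10, overdispersion=1.0, conserved_niches=False,
        metadata=metadata)
    selection = simulate_selection_dataset(
        n_samples, n_taxa[1], N, selection_strength=4.0, seed=seed * 2 + 2,
        m=0.05, niche_sigma=0.4, patchiness=1.2, n_factors=10,
        overdispersion=1.0, metadata=metadata)
    neutral.table.columns = [f"P_{c}" for c in neutral.table.columns]
    for tip in neutral.tree.tips():
        tip.name = f"P_{tip.name}"
    selection.table.columns = [f"E_{c}" for c in selection.table.columns]
    for tip in selection.tree.tips():
        tip.name = f"E_{tip.name}"
    return neutral, selection
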