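"""Alpha diversity, distance matrices, Mantel tests and niche breadth.

Conventions: Shannon H in nats; Pielou J = H/ln S (undefined, NaN, when
S = 1); Faith PD includes the path from a sample's tips to the tree root.
Mantel tests are one-sided (permuted r >= observed), Spearman by default,
with rows and columns of the second matrix permuted jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio.diversity.alpha import faith_pd

from .preprocess import relative_abundance

logger = logging.getLogger("planktonet")


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(table: pd.DataFrame, tree=None) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Pielou evenness and, when a
    tree is given, Faith's phylogenetic diversity."""
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty sample in table")
    rel = relative_abundance(table).to_numpy()
    richness = (table.to_numpy() > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    pielou = np.where(richness > 1, shannon / np.log(
        np.where(richness > 1, richness, 2)), np.nan)
    out = pd.DataFrame({
        "richness": richness, "shannon": shannon, "pielou": pielou,
    }, index=table.index)
    if tree is not None:
        taxa = list(table.columns)
        out["faith_pd"] = [
            faith_pd(row, taxa=taxa, tree=tree)
            for row in table.to_numpy()
        ]
    return out


# ---------------------------------------------------------------------------
# distance matrices


def bray_curtis_matrix(table: pd.DataFrame, on: str = "counts") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, on raw counts (default) or on
    per-sample proportions (``on="proportions"``)."""
    if len(table) < 2:
        raise ValueError("need >= 2 samples")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("zero-sum sample")
    x = table.to_numpy(dtype=float)
    if on == "proportions":
        x = x / x.sum(axis=1, keepdims=True)
    elif on != "counts":
        raise ValueError(f"unknown basis {on!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def geographic_distance_matrix(metadata: pd.DataFrame,
                               method: str = "euclidean") -> pd.DataFrame:
    """Pairwise station distances from (longitude, latitude), Euclidean in
    degrees by default or great-circle km (haversine)."""
    for col in ("latitude", "longitude"):
        if col not in metadata.columns or metadata[col].isna().any():
            raise ValueError(f"missing coordinates in column {col!r}")
    lon = metadata["longitude"].to_numpy(float)
    lat = metadata["latitude"].to_numpy(float)
    if method == "euclidean":
        d = squareform(pdist(np.column_stack([lon, lat])))
    elif method == "haversine":
        R = 6371.0
        la, lo = np.radians(lat), np.radians(lon)
        dla = la[:, None] - la[None, :]
        dlo = lo[:, None] - lo[None, :]
        a = np.sin(dla / 2) ** 2 \
            + np.cos(la)[:, None] * np.cos(la)[None, :] * np.sin(dlo / 2) ** 2
        d = 2 * R * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(d, index=metadata.index, columns=metadata.index)


def env_distance_matrix(metadata: pd.DataFrame, column: str,
                        standardize: bool = True) -> pd.DataFrame:
    """Single-variable Euclidean distance matrix (z-scored by default),
    dropping samples with missing values (count logged)."""
    v = metadata[column]
    if v.isna().any():
        logger.info("env_distance_matrix dropped %d samples missing %r",
                    int(v.isna().sum()), column)
        v = v.dropna()
    x = v.to_numpy(float)
    if standardize:
        sd = x.std(ddof=0)
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    d = np.abs(x[:, None] - x[None, :])
    return pd.DataFrame(d, index=v.index, columns=v.index)


# ---------------------------------------------------------------------------
# Mantel test


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    n: int


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float), list(d.index)
    d = np.asarray(d, dtype=float)
    return d, list(range(len(d)))


def mantel_test(d1, d2, n_perm: int = 999, method: str = "spearman",
                seed: int = 0) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    r is the (rank) correlation of the strict lower triangles; the null
    distribution permutes rows and columns of ``d2`` jointly; the one-sided
    p-value is ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    m1, ids1 = _as_square(d1)
    m2, ids2 = _as_square(d2)
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if set(ids1) != set(ids2):
            raise ValueError("sample sets of the two matrices differ")
        m2 = d2.loc[ids1, ids1].to_numpy(dtype=float)
    elif m1.shape != m2.shape:
        raise ValueError("matrix size mismatch")
    n = m1.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    x = m1[iu, ju]
    y = m2[iu, ju]
    if method == "spearman":
        x = rankdata(x)
        # attach entry ranks to the matrix so permuted triangles stay ranks
        ym = np.zeros_like(m2)
        ym[iu, ju] = rankdata(y)
        ym = ym + ym.T
        m2, y = ym, ym[iu, ju]
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xm = x - x.mean()
    ym = y - y.mean()
    xs = np.sqrt((xm ** 2).sum())
    ys = np.sqrt((ym ** 2).sum())
    if xs == 0 or ys == 0:
        logger.warning("mantel_test: constant distance matrix, r undefined")
        return MantelResult(np.nan, np.nan, n_perm, method, n)
    r_obs = float(xm @ ym / (xs * ys))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    vals = m2[perms[:, iu], perms[:, ju]]          # (n_perm, n_pairs)
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = xs * np.sqrt((vc ** 2).sum(axis=1))
    r_perm = (vc @ xm) / np.where(denom > 0, denom, np.inf)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, method, n)


def mantel_table(dist: pd.DataFrame, metadata: pd.DataFrame,
                 variables: list[str], n_perm: int = 999,
                 method: str = "spearman", seed: int = 0) -> pd.DataFrame:
    """Mantel r/p of a community distance matrix against geographic distance
    and single-variable (z-scored Euclidean) environmental distances."""
    rows = []
    if {"latitude", "longitude"}.issubset(metadata.columns):
        geo = geographic_distance_matrix(metadata)
        res = mantel_test(dist, geo, n_perm=n_perm, method=method, seed=seed)
        rows.append({"variable": "geographic_distance", "r": res.r, "p": res.p})
    for i, var in enumerate(variables):
        env = env_distance_matrix(metadata, var)
        common = [s for s in dist.index if s in env.index]
        res = mantel_test(dist.loc[common, common], env.loc[common, common],
                          n_perm=n_perm, method=method, seed=seed + i + 1)
        rows.append({"variable": var, "r": res.r, "p": res.p})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# niche breadth


def levins_niche_breadth(table: pd.DataFrame,
                         labels: pd.Series | None = None):
    """Levins niche breadth B_j = 1 / sum_i P_ij^2 where P_ij is feature
    j's proportional use of sample i (abundance-based, as in spaa's
    ``niche.width(..., method="levins")``).

    Returns ``(per_feature_B, summary)``; the summary holds mean B per
    abundance class when labels are supplied, plus the overall mean.
    """
    totals = table.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(
            f"features with zero total: {table.columns[totals == 0].tolist()[:10]}")
    P = table.div(totals, axis=1).to_numpy(float)
    B = pd.Series(1.0 / (P ** 2).sum(axis=0), index=table.columns, name="B")
    summary = {"all": float(B.mean())}
    if labels is not None:
        for cls in ("abundant", "rare", "moderate"):
            feats = labels.index[labels == cls].intersection(B.index)
            if len(feats):
                summary[cls] = float(B.loc[feats].mean())
    return B, summary
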