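"""Community assembly inference.

Implements the standard null-model toolkit for partitioning deterministic
and stochastic assembly:

* Sloan neutral community model (NCM) — fits the immigration parameter m to
  the occupancy-frequency vs mean-relative-abundance relationship.  Under
  the model, a taxon of mean relative abundance p is detected (above the
  limit d = 1/N) in a fraction ``1 - I_d(N m p, N m (1-p))`` of samples,
  where I is the regularized incomplete beta function.
* SES MNTD / betaMNTD / betaNTI — within- and between-sample nearest-taxon
  phylogenetic structure, standardized against a tip-label-shuffle null
  (picante's "taxa.labels" convention).
* Raup-Crick on Bray-Curtis (RCbray) — null communities preserve each
  sample's richness and total; taxa colonize with probability proportional
  to occupancy and individuals fill in proportionally to pool abundance.
* Per-pair process classification: |betaNTI| > 2 -> selection (sign gives
  homogeneous vs variable); otherwise RCbray > 0.95 -> dispersal
  limitation, < -0.95 -> homogenizing dispersal, else drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .preprocess import relative_abundance

logger = logging.getLogger("planktonet")

PROCESSES = ["homogeneous selection", "variable selection",
             "dispersal limitation", "homogenizing dispersal", "drift"]


# ---------------------------------------------------------------------------
# Sloan neutral community model


@dataclass
class NCMFit:
    m: float
    N: float
    Nm: float
    r2: float
    freq: pd.DataFrame        # p, observed, predicted, lower, upper
    detection_limit: float
    at_bound: bool = False

    def summary(self) -> dict:
        return {"m": self.m, "N": self.N, "Nm": self.Nm, "r2": self.r2,
                "detection_limit": self.detection_limit,
                "at_bound": self.at_bound}


def fit_ncm(table: pd.DataFrame, detection_limit: float | None = None) -> NCMFit:
    """Fit the Sloan neutral model to occupancy frequencies.

    N is taken as the mean sample total (the rarefaction depth on a
    rarefied table); the single free parameter m is fitted by bounded
    least squares on observed vs predicted occurrence frequency, and
    R^2 = 1 - SSE/SST measures the fit.  95% prediction bounds are Wilson
    intervals around the predicted frequencies.

    The default detection limit is d = ln(2)/N, the relative abundance at
    which the probability of drawing at least one read among N is 1/2 —
    the step-function threshold that best matches the binomial detection
    process.  (The common d = 1/N convention overstates Nm by ~25% on
    communities simulated from the model itself; pass
    ``detection_limit=1/N`` to reproduce it.)
    """
    n_samples = len(table)
    if n_samples < 3:
        raise ValueError("need >= 3 samples to fit the neutral model")
    counts = table.to_numpy(float)
    N = float(counts.sum(axis=1).mean())
    d = detection_limit if detection_limit is not None else float(np.log(2)) / N
    rel = counts / counts.sum(axis=1, keepdims=True)
    p = rel.mean(axis=0)
    obs = (counts > 0).mean(axis=0)
    keep = p > 0
    p, obs = p[keep], obs[keep]
    taxa = table.columns[keep]

    def predicted(m: float) -> np.ndarray:
        return beta_dist.sf(d, N * m * p, N * m * (1.0 - p))

    def sse(logit_m: float) -> float:
        m = 1.0 / (1.0 + np.exp(-logit_m))
        return float(((obs - predicted(m)) ** 2).sum())

    res = minimize_scalar(sse, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError("neutral-model fit did not converge")
    m = float(1.0 / (1.0 + np.exp(-res.x)))
    at_bound = abs(res.x) > 13.0
    if at_bound:
        logger.warning("fit_ncm: m at parameter bound (m=%.3g)", m)
    pred = predicted(m)
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - float(((obs - pred) ** 2).sum()) / sst if sst > 0 else np.nan
    lower, upper = proportion_confint(np.round(pred * n_samples), n_samples,
                                      alpha=0.05, method="wilson")
    freq = pd.DataFrame({"p": p, "observed": obs, "predicted": pred,
                         "lower": lower, "upper": upper}, index=taxa)
    return NCMFit(m=m, N=N, Nm=N * m, r2=r2, freq=freq, detection_limit=d,
                  at_bound=at_bound)


# ---------------------------------------------------------------------------
# phylogenetic null models


def cophenetic_matrix(tree, feature_ids) -> np.ndarray:
    """Tip-to-tip patristic distances ordered like ``feature_ids``."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(f) for f in feature_ids]
    return dm.data[np.ix_(idx, idx)]


def _mntd_sample(D_sub: np.ndarray, w: np.ndarray | None) -> float:
    """MNTD of one community given its cophenetic submatrix; ``w`` are
    relative abundances for the weighted variant (None = unweighted)."""
    s = D_sub.shape[0]
    if s < 2:
        return np.nan
    masked = D_sub + np.where(np.eye(s, dtype=bool), np.inf, 0.0)
    nearest = masked.min(axis=1)
    if w is None:
        return float(nearest.mean())
    return float((w * nearest).sum() / w.sum())


def ses_mntd(table: pd.DataFrame, tree, n_null: int = 999,
             weighted: bool = False, seed: int = 0) -> pd.DataFrame:
    """Standardized effect size of MNTD per sample against a tip-shuffle
    null; SES < 0 indicates phylogenetic clustering.  Samples whose null
    has zero spread (e.g. a community spanning every tip) get NaN."""
    D = cophenetic_matrix(tree, table.columns)
    S = D.shape[0]
    counts = table.to_numpy(float)
    rng = np.random.default_rng(seed)
    present = [np.flatnonzero(row > 0) for row in counts]
    weights = [counts[i, idx] for i, idx in enumerate(present)] \
        if weighted else [None] * len(counts)
    obs = np.array([
        _mntd_sample(D[np.ix_(idx, idx)], weights[i])
        for i, idx in enumerate(present)])
    null = np.empty((n_null, len(counts)))
    for rep in range(n_null):
        perm = rng.permutation(S)
        for i, idx in enumerate(present):
            pidx = perm[idx]
            null[rep, i] = _mntd_sample(D[np.ix_(pidx, pidx)], weights[i])
    mean_null = null.mean(axis=0)
    sd_null = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd_null > 1e-12, (obs - mean_null) / sd_null, np.nan)
    flagged = int((sd_null <= 1e-12).sum())
    if flagged:
        logger.warning("ses_mntd: %d samples with degenerate null", flagged)
    return pd.DataFrame({"mntd": obs, "mean_null": mean_null,
                         "sd_null": sd_null, "ses": ses}, index=table.index)


def _beta_mntd_from(D: np.ndarray, counts: np.ndarray,
                    weighted: bool) -> np.ndarray:
    """All-pairs betaMNTD given a cophenetic matrix and a count matrix.

    betaMNTD(k,l) = 0.5 * [ sum_i w_ik min_{j in l} d(i,j)
                          + sum_j w_jl min_{i in k} d(i,j) ].
    Vectorized: M[l] holds, for every taxon, its distance to the nearest
    member of sample l, so the double sum is a matrix product.
    """
    n, S = counts.shape
    pres = counts > 0
    if not pres.any(axis=1).all():
        raise ValueError("empty community")
    if weighted:
        W = counts / counts.sum(axis=1, keepdims=True)
    else:
        W = pres / pres.sum(axis=1, keepdims=True)
    M = np.empty((n, S))
    for l in range(n):
        M[l] = D[:, pres[l]].min(axis=1)
    A = W @ M.T                      # A[k,l] = sum_i w_ik * M[l,i]
    return 0.5 * (A + A.T)


def beta_mntd(table: pd.DataFrame, tree, weighted: bool = True) -> pd.DataFrame:
    """Pairwise between-sample mean nearest-taxon distance (abundance-
    weighted by default)."""
    if len(table) < 2:
        raise ValueError("need >= 2 samples")
    D = cophenetic_matrix(tree, table.columns)
    B = _beta_mntd_from(D, table.to_numpy(float), weighted)
    return pd.DataFrame(B, index=table.index, columns=table.index)


def beta_nti(table: pd.DataFrame, tree, n_null: int = 999,
             weighted: bool = True, seed: int = 0) -> pd.DataFrame:
    """betaNTI: standardized effect size of betaMNTD against the tip-label
    shuffle null (one shuffle applied to the whole tree per replicate)."""
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    D = cophenetic_matrix(tree, table.columns)
    counts = table.to_numpy(float)
    n, S = counts.shape
    obs = _beta_mntd_from(D, counts, weighted)
    rng = np.random.default_rng(seed)
    pres = counts > 0
    W = counts / counts.sum(axis=1, keepdims=True) if weighted \
        else pres / pres.sum(axis=1, keepdims=True)
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_null):
        perm = rng.permutation(S)
        M = np.empty((n, S))
        for l in range(n):
            M[l] = D[:, perm[pres[l]]].min(axis=1)[perm]
        A = W @ M.T
        B = 0.5 * (A + A.T)
        acc += B
        acc2 += B * B
    mean_null = acc / n_null
    var = (acc2 - n_null * mean_null ** 2) / (n_null - 1)
    sd_null = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        nti = np.where(sd_null > 1e-12, (obs - mean_null) / sd_null, np.nan)
    np.fill_diagonal(nti, np.nan)
    return pd.DataFrame(nti, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)


def _bray_curtis_condensed(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist
    return pdist(x, metric="braycurtis")


def null_communities(richness, totals, occupancy, pool_p,
                     rng: np.random.Generator) -> np.ndarray:
    """One stochastic-colonization null assembly per sample: ``richness[i]``
    taxa drawn without replacement with probability proportional to
    ``occupancy`` (Gumbel top-k), one individual each, remainder of
    ``totals[i]`` filled multinomially by ``pool_p``."""
    S = len(pool_p)
    log_occ = np.log(np.where(occupancy > 0, occupancy, np.nan))
    null = np.zeros((len(richness), S))
    for i in range(len(richness)):
        keys = np.where(np.isnan(log_occ), -np.inf,
                        log_occ + rng.gumbel(size=S))
        chosen = np.argpartition(-keys, richness[i] - 1)[:richness[i]]
        fill = pool_p[chosen]
        null[i, chosen] = 1.0 + rng.multinomial(totals[i] - richness[i],
                                                fill / fill.sum())
    return null


def raup_crick_bray(table: pd.DataFrame, n_null: int = 999, seed: int = 0,
                    occupancy=None, pool_weights=None) -> pd.DataFrame:
    """RCbray in [-1, 1]: the (rescaled) probability that a null Bray-Curtis
    drawn under stochastic colonization is below the observed one.

    Null communities preserve each sample's richness and total count; taxa
    colonize with probability proportional to their occupancy (weighted
    sampling without replacement via Gumbel top-k) and each receives one
    individual before the remainder is filled multinomially in proportion
    to pool-wide relative abundance.  ``occupancy`` and ``pool_weights``
    default to the table's own occupancy and total counts but can be given
    explicitly (e.g. from a regional reference table).
    """
    counts = table.to_numpy(np.int64)
    n, S = counts.shape
    if S < 2:
        raise ValueError("degenerate single-taxon pool")
    occ = (np.asarray(occupancy, float) if occupancy is not None
           else (counts > 0).sum(axis=0).astype(float))
    pool = (np.asarray(pool_weights, float) if pool_weights is not None
            else counts.sum(axis=0).astype(float))
    pool_p = pool / pool.sum()
    obs_bc = _bray_curtis_condensed(counts.astype(float))

    rng = np.random.default_rng(seed)
    less = np.zeros_like(obs_bc)
    equal = np.zeros_like(obs_bc)
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    for _ in range(n_null):
        null = null_communities(richness, totals, occ, pool_p, rng)
        bc = _bray_curtis_condensed(null)
        less += bc < obs_bc - 1e-12
        equal += np.abs(bc - obs_bc) <= 1e-12
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    out = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = rc
    out[ju, iu] = rc
    return pd.DataFrame(out, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# process classification


@dataclass
class AssemblyResult:
    pairs: pd.DataFrame                       # sample_i, sample_j, bnti, rc, process
    fractions: dict
    excluded_pairs: int = 0
    seed: int | None = None
    ses_mntd: pd.DataFrame | None = field(default=None, repr=False)
    bnti: pd.DataFrame | None = field(default=None, repr=False)
    rc: pd.DataFrame | None = field(default=None, repr=False)


def classify_assembly(bnti: pd.DataFrame, rc: pd.DataFrame | None,
                      bnti_threshold: float = 2.0,
                      rc_threshold: float = 0.95) -> AssemblyResult:
    """Label every sample pair with its dominant assembly process and
    report the fraction of pairs per process (fractions sum to 1 over the
    non-degenerate pairs; NaN-betaNTI pairs are excluded with a logged
    count)."""
    ids = list(bnti.index)
    rows = []
    excluded = 0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            v = bnti.iloc[a, b]
            if np.isnan(v):
                excluded += 1
                continue
            if v < -bnti_threshold:
                proc = "homogeneous selection"
                r = np.nan if rc is None else rc.iloc[a, b]
            elif v > bnti_threshold:
                proc = "variable selection"
                r = np.nan if rc is None else rc.iloc[a, b]
            else:
                if rc is None or np.isnan(rc.iloc[a, b]):
                    raise ValueError(
                        f"RCbray required for stochastic pair "
                        f"({ids[a]}, {ids[b]})")
                r = rc.iloc[a, b]
                if r > rc_threshold:
                    proc = "dispersal limitation"
                elif r < -rc_threshold:
                    proc = "homogenizing dispersal"
                else:
                    proc = "drift"
            rows.append({"sample_i": ids[a], "sample_j": ids[b],
                         "bnti": v, "rc": r, "process": proc})
    if excluded:
        logger.warning("classify_assembly excluded %d degenerate pairs",
                       excluded)
    pairs = pd.DataFrame(rows,
                         columns=["sample_i", "sample_j", "bnti", "rc",
                                  "process"])
    n_pairs = len(pairs)
    fractions = {proc: (float((pairs["process"] == proc).sum()) / n_pairs
                        if n_pairs else np.nan)
                 for proc in PROCESSES}
    return AssemblyResult(pairs=pairs, fractions=fractions,
                          excluded_pairs=excluded, bnti=bnti, rc=rc)
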