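"""Feature filtering, rarefaction and abundant/rare partitioning.

The abundance-class rules follow the standard rare-biosphere cutoffs:

* abundant — relative abundance > 1% in at least 10% of samples, OR a
  summed relative abundance > 20%;
* rare — summed relative abundance < 0.5%;
* moderate — everything else.

"Summed relative abundance" is, by default, the sum over samples of the
per-sample relative abundances (``sum_convention="total"``); under this
convention a taxon abundant by the occupancy rule can never also satisfy
the rare rule (>1% in >=10% of n samples forces a sum >= 0.001*n, which is
>= 0.5% whenever n >= 5).  ``sum_convention="mean"`` divides the sum by the
number of samples, for comparability with studies that use mean relative
abundance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("planktonet")


def filter_features(table: pd.DataFrame, min_samples: int = 2,
                    min_total: int = 5) -> pd.DataFrame:
    """Drop features seen in fewer than ``min_samples`` samples or with a
    total count below ``min_total`` (thresholds are 'less than' exclusions,
    so a feature in exactly 2 samples with total exactly 5 is kept)."""
    if table.empty:
        raise ValueError("empty table")
    occ = (table > 0).sum(axis=0)
    tot = table.sum(axis=0)
    keep = (occ >= min_samples) & (tot >= min_total)
    if not keep.any():
        raise ValueError("all features removed by filter")
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_features removed %d of %d features",
                    removed, table.shape[1])
    return table.loc[:, keep]


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric); samples below ``depth`` are dropped with
    a warning."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    if (~keep).any():
        logger.warning("rarefy dropped %d samples below depth %d",
                       int((~keep).sum()), depth)
    sub = table.loc[keep]
    rng = np.random.default_rng(seed)
    out = np.empty(sub.shape, dtype=np.int64)
    for i, row in enumerate(sub.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    totals = table.sum(axis=1)
    if (totals == 0).any():
        bad = table.index[totals == 0].tolist()
        raise ValueError(f"zero-sum samples: {bad}")
    return table.div(totals, axis=0)


def classify_abundance_groups(table: pd.DataFrame, *,
                              abundant_rel: float = 0.01,
                              abundant_occ: float = 0.10,
                              abundant_sum: float = 0.20,
                              rare_sum: float = 0.005,
                              sum_convention: str = "total") -> pd.Series:
    """Label every feature abundant / rare / moderate.

    Returns a Series (index = feature ids, values in
    ``{"abundant", "rare", "moderate"}``).  Raises if any feature satisfies
    both the abundant and the rare rule, which cannot happen under the
    default summation convention.
    """
    if table.empty:
        raise ValueError("empty table")
    if sum_convention not in ("total", "mean"):
        raise ValueError(f"unknown sum_convention {sum_convention!r}")
    rel = relative_abundance(table)
    n = len(rel)
    summed = rel.sum(axis=0)
    if sum_convention == "mean":
        summed = summed / n
    occ_hits = (rel > abundant_rel).sum(axis=0)
    abundant = (occ_hits >= abundant_occ * n) | (summed > abundant_sum)
    rare = summed < rare_sum
    both = abundant & rare
    if both.any():
        raise ValueError(
            "features satisfy both abundant and rare rules under "
            f"sum_convention={sum_convention!r}: "
            f"{table.columns[both].tolist()[:10]}")
    labels = pd.Series("moderate", index=table.columns, name="class")
    labels[abundant] = "abundant"
    labels[rare] = "rare"
    return labels


def subcommunity(table: pd.DataFrame, labels: pd.Series,
                 which: str) -> pd.DataFrame:
    """Column-subset of the full table for one abundance class (counts are
    not re-rarefied)."""
    if which == "all":
        return table
    keep = labels.index[labels == which]
    return table.loc[:, keep]
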