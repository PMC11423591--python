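"""Input/output, validation and run configuration.

The pipeline's canonical in-memory containers are deliberately plain:

* abundance table — :class:`pandas.DataFrame` of non-negative integers,
  samples as rows, features (ASVs) as columns;
* phylogeny — :class:`skbio.TreeNode`, rooted, with branch lengths, tip
  names matching the table's feature ids;
* sample metadata — :class:`pandas.DataFrame` indexed by sample id with
  coordinate and environmental columns.

``load_dataset`` reads the three files, validates their cross-references
(every table feature must be a tree tip; every table sample must have
metadata) and normalizes ordering so downstream stages never have to align
ids themselves.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

logger = logging.getLogger("planktonet")

#: environmental columns recognised in metadata files (order preserved in output)
METADATA_ENV_COLUMNS = [
    "temperature", "salinity", "DO", "chl_a", "total_N", "inorganic_N",
    "nitrite", "nitrate", "ammonia", "DIP", "silicate",
]


@dataclass
class RunConfig:
    """Run-wide parameters; the seed is recorded in every output artifact."""

    rarefaction_depth: int | None = None
    orientation: str = "samples_rows"          # or "features_rows"
    abundant_rel: float = 0.01                 # >1% relative abundance ...
    abundant_occ: float = 0.10                 # ... in >=10% of samples
    abundant_sum: float = 0.20                 # or summed abundance >20%
    rare_sum: float = 0.005                    # summed abundance <0.5%
    sum_convention: str = "total"              # "total" or "mean"
    n_null: int = 999
    correlation_method: str = "spearman"
    r_min: float = 0.6
    q_max: float = 0.05
    prevalence_min: float = 0.5
    remove_fraction: float = 0.5
    robustness_reps: int = 100
    fragmentation_steps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1 or self.robustness_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.orientation not in ("samples_rows", "features_rows"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# loading


def read_abundance_table(path, orientation: str = "samples_rows") -> pd.DataFrame:
    """Read a TSV count table and return it samples x features.

    ``orientation`` names what the rows of the file are; amplicon TSV
    dialects use both layouts.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "features_rows":
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("abundance table contains non-numeric entries")
    if (counts < 0).any():
        raise ValueError("abundance table contains negative counts")
    df = df.astype(np.int64)
    empty = df.sum(axis=1) == 0
    if empty.any():
        raise ValueError(
            f"samples with zero total counts: {df.index[empty].tolist()}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    meta.index = meta.index.astype(str)
    return meta


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def load_dataset(table_path, tree_path, metadata_path,
                 orientation: str = "samples_rows"):
    """Load and cross-validate the (table, tree, metadata) triple.

    Tree tips absent from the table are pruned (warning logged); table
    features absent from the tree are a hard error.  Metadata row order is
    normalized to the table's sample order.
    """
    table = read_abundance_table(table_path, orientation=orientation)
    tree = read_tree(tree_path)
    meta = read_metadata(metadata_path)

    tips = {t.name for t in tree.tips()}
    missing = [f for f in table.columns if f not in tips]
    if missing:
        raise ValueError(
            f"features absent from tree: {missing[:20]}"
            + (" ..." if len(missing) > 20 else ""))
    extra = tips - set(table.columns)
    if extra:
        tree = tree.shear(set(table.columns))
        tree.prune()
        logger.warning("pruned %d tree tips absent from table", len(extra))

    no_meta = [s for s in table.index if s not in meta.index]
    if no_meta:
        raise ValueError(f"samples without metadata: {no_meta}")
    meta = meta.loc[table.index]
    return table, tree, meta


# ---------------------------------------------------------------------------
# writing


def write_abundance_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_network(network: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-occurrence network; graphml round-trips all attributes."""
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty network")
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge_list_tsv":
        rows = []
        for u, v, attrs in network.edges(data=True):
            rows.append({
                "source": u, "target": v,
                "r": attrs.get("r", np.nan),
                "sign": attrs.get("sign", ""),
                "q": attrs.get("q", np.nan),
            })
        pd.DataFrame(rows, columns=["source", "target", "r", "sign", "q"]
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_list_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target),
                       r=float(row.r), sign=str(row.sign), q=float(row.q))
        return g
    raise ValueError(f"unknown network format {format!r}")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
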