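import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from planktonet import simulate_neutral_dataset


@pytest.fixture
def toy_tree() -> TreeNode:
    """Six tips, hand-set branch lengths."""
    return TreeNode.read(io.StringIO(
        "(((a:1,b:1):1,(c:1,d:2):1):1,(e:1,f:1):2):0;"))


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        [[5, 3, 0, 0, 1, 0],
         [0, 2, 4, 1, 0, 0],
         [1, 0, 0, 0, 6, 2]],
        index=["s1", "s2", "s3"],
        columns=["a", "b", "c", "d", "e", "f"])


@pytest.fixture
def toy_metadata(toy_table) -> pd.DataFrame:
    return pd.DataFrame({
        "latitude": [32.0, 35.0, 39.0],
        "longitude": [120.0, 122.0, 124.0],
        "temperature": [26.0, 24.0, 21.0],
        "salinity": [31.0, 31.5, 32.0],
    }, index=toy_table.index)


@pytest.fixture
def neutral_dataset():
    """Small neutral community used across modules (fixed seed)."""
    return simulate_neutral_dataset(15, 120, 2000, 0.2, seed=71)


@pytest.fixture
def dataset_on_disk(tmp_path, toy_table, toy_tree, toy_metadata):
    table_path = tmp_path / "table.tsv"
    tree_path = tmp_path / "tree.nwk"
    meta_path = tmp_path / "metadata.tsv"
    toy_table.to_csv(table_path, sep="\t")
    toy_tree.write(str(tree_path))
    toy_metadata.to_csv(meta_path, sep="\t")
    return table_path, tree_path, meta_path


def brute_force_beta_mntd(counts: np.ndarray, D: np.ndarray,
                          weighted: bool) -> np.ndarray:
    """Literal double-loop betaMNTD, independent of the vectorized path."""
    n = len(counts)
    out = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            ik = np.flatnonzero(counts[k] > 0)
            il = np.flatnonzero(counts[l] > 0)
            if weighted:
                wk = counts[k, ik] / counts[k].sum()
                wl = counts[l, il] / counts[l].sum()
            else:
                wk = np.full(len(ik), 1.0 / len(ik))
                wl = np.full(len(il), 1.0 / len(il))
            t1 = sum(wk[x] * D[ik[x], il].min() for x in range(len(ik)))
            t2 = sum(wl[y] * D[il[y], ik].min() for y in range(len(il)))
            out[k, l] = 0.5 * (t1 + t2)
    return out
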