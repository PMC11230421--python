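"""Evolutionary rate covariation (ERC) between gene trees.

Two genes whose products function together should show correlated
accelerations and decelerations of their substitution rates across the
same species tree.  For each gene pair the two trees are pruned to their
shared taxa, branch lengths are rescaled to total 1, and matched branches
(by leaf-set bipartition) are compared by Pearson correlation.  An
empirical one-sided p-value comes from shuffling one tree's scaled branch
lengths (add-one correction, so p is never 0), and the normalized tree
distance sum|delta|/2 summarizes overall discordance in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .phylo import (
    Phylogeny,
    ScaledBranchVector,
    TreeError,
    prune_to_shared_taxa,
    rescale_to_unit_length,
)


@dataclass
class ERCResult:
    gene_a: str
    gene_b: str
    n_shared_taxa: int
    pearson_r: float
    perm_p: float
    ntd: float
    flagged: bool = False  # zero-variance branch vector: r undefined


def normalized_tree_distance(v1: ScaledBranchVector, v2: ScaledBranchVector) -> float:
    """Half the summed absolute differences of matched scaled branch lengths."""
    if v1.branch_ids != v2.branch_ids:
        raise TreeError("branch correspondence mismatch between scaled vectors")
    return float(np.abs(v1.lengths - v2.lengths).sum() / 2.0)


def _match_vectors(t1: Phylogeny, t2: Phylogeny):
    p1, p2 = prune_to_shared_taxa(t1, t2)
    v1 = rescale_to_unit_length(p1)
    v2 = rescale_to_unit_length(p2)
    if v1.branch_ids != v2.branch_ids:
        raise TreeError(
            "pruned trees induce different bipartition sets; "
            "branch correspondence is undefined"
        )
    return v1, v2, len(p1.leaf_labels())


def pairwise_erc(
    t1: Phylogeny,
    t2: Phylogeny,
    n_perm: int = 1000,
    seed: int = 0,
    gene_a: str = "a",
    gene_b: str = "b",
) -> ERCResult:
    """ERC for one tree pair: r, permutation p-value and tree distance."""
    v1, v2, n_shared = _match_vectors(t1, t2)
    x, y = v1.lengths, v2.lengths
    ntd = normalized_tree_distance(v1, v2)
    if x.std() <= 1e-10 or y.std() <= 1e-10:  # constant branch vector
        return ERCResult(gene_a, gene_b, n_shared, np.nan, np.nan, ntd, flagged=True)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = (xc[None, :] * yc[perms]).mean(axis=1)
    p = (1.0 + np.count_nonzero(r_perm >= r_obs)) / (n_perm + 1.0)
    return ERCResult(gene_a, gene_b, n_shared, r_obs, float(p), ntd)


def erc_matrix(
    trees: dict[str, Phylogeny],
    n_perm: int = 1000,
    seed: int = 0,
    categories: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """All-pairs ERC table plus a summary.

    Pairs with insufficient taxon overlap are skipped and counted.  The
    summary reports the fraction of evaluable pairs with perm_p < alpha
    and, when gene categories are supplied, per-category-pair NTD medians.
    """
    if len(trees) < 2:
        raise TreeError("ERC needs at least 2 gene trees")
    genes = sorted(trees)
    rows, skipped = [], 0
    rng = np.random.default_rng(seed)
    for ga, gb in combinations(genes, 2):
        pair_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = pairwise_erc(
                trees[ga], trees[gb], n_perm=n_perm, seed=pair_seed,
                gene_a=ga, gene_b=gb,
            )
        except TreeError:
            skipped += 1
            continue
        rows.append(res.__dict__)
    table = pd.DataFrame(rows)
    evaluable = table[~table["flagged"]] if len(table) else table
    summary = {
        "n_pairs": len(table),
        "n_skipped": skipped,
        "frac_significant": (
            float((evaluable["perm_p"] < alpha).mean()) if len(evaluable) else np.nan
        ),
    }
    if categories and len(table):
        def cat_pair(row):
            a, b = categories.get(row.gene_a, "?"), categories.get(row.gene_b, "?")
            return "-".join(sorted([a, b]))

        table["category_pair"] = table.apply(cat_pair, axis=1)
        summary["ntd_median_by_category"] = (
            table.groupby("category_pair")["ntd"].median().to_dict()
        )
    return table, summary
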