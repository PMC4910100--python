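"""Sample dendrogram from Spearman correlations (UPGMA on 1 - rho).

Correlations are computed on log2(RPKM + 1) by default for variance
stabilization; a raw-value mode is available.  The UPGMA implementation is
deliberately hand-rolled so the merge order is fully deterministic: ties in
merge height are broken by the lexicographically smallest member label of the
candidate pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_quant import ExpressionMatrix

__all__ = ["CorrelationMatrix", "TreeNode", "spearman_matrix", "average_linkage_tree"]


@dataclass
class CorrelationMatrix:
    """Symmetric sample x sample Spearman rho grid with unit diagonal."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.table.to_numpy()
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def distance(self) -> pd.DataFrame:
        return 1.0 - self.table


@dataclass
class TreeNode:
    """Binary merge-tree node; leaves carry labels, internal nodes heights."""

    label: str
    height: float = 0.0
    children: tuple["TreeNode", "TreeNode"] | tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves]


def spearman_matrix(
    rpkm: ExpressionMatrix,
    gene_subset=None,
    log_transform: bool = True,
) -> CorrelationMatrix:
    """Pairwise Spearman rho across samples over a gene subset.

    Constant columns have undefined rho; those entries are recorded as 0 with
    a warning.
    """
    vals = rpkm.values
    if gene_subset is not None:
        vals = vals.loc[sorted(gene_subset)]
    if len(vals) < 3:
        raise ValueError("need at least 3 genes to correlate samples")
    x = np.log2(vals.to_numpy(dtype=float) + 1.0) if log_transform else vals.to_numpy(dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        import warnings

        warnings.warn("constant sample column: undefined rho recorded as 0", stacklevel=2)
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(pd.DataFrame(rho, index=vals.columns, columns=vals.columns))


def average_linkage_tree(corr: CorrelationMatrix) -> TreeNode:
    """UPGMA on distance 1 - rho with a deterministic lexicographic tie-break.

    At every step the pair with minimal average distance merges; among ties
    (within 1e-12) the pair whose sorted member labels compare smallest wins.
    Heights are half the merge distance, giving an ultrametric tree.
    """
    dist = corr.distance()
    labels = list(dist.index)
    if len(labels) == 1:
        return TreeNode(labels[0])
    # active clusters: key -> (node, size, sorted leaf labels)
    clusters: dict[int, tuple[TreeNode, int, tuple[str, ...]]] = {
        i: (TreeNode(lab), 1, (lab,)) for i, lab in enumerate(labels)
    }
    d = {
        (i, j): float(dist.iloc[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_key = len(labels)
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a_i, a in enumerate(keys):
            for b in keys[a_i + 1 :]:
                dd = d[(a, b) if a < b else (b, a)]
                tag = tuple(sorted(clusters[a][2] + clusters[b][2]))
                cand = (dd, tag, a, b)
                if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and tag < best[1]
                ):
                    best = cand
        dd, _, a, b = best
        na, nb = clusters[a][1], clusters[b][1]
        node = TreeNode(
            label="",
            height=dd / 2.0,
            children=(clusters[a][0], clusters[b][0]),
        )
        merged_labels = tuple(sorted(clusters[a][2] + clusters[b][2]))
        for other in keys:
            if other in (a, b):
                continue
            da = d[(a, other) if a < other else (other, a)]
            db = d[(b, other) if b < other else (other, b)]
            d[(other, next_key) if other < next_key else (next_key, other)] = (
                na * da + nb * db
            ) / (na + nb)
        del clusters[a], clusters[b]
        clusters[next_key] = (node, na + nb, merged_labels)
        next_key += 1
    (_, (root, _, _)), = clusters.items()
    return root
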