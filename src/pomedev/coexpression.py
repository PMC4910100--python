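"""Weighted co-expression network: soft-thresholded correlation adjacency,
topological overlap (TOM), and average-linkage module detection.

Construction follows the standard weighted network recipe: Pearson
correlation on log2(RPKM+1), raised elementwise to a soft power beta
(unsigned |cor|^beta, or signed ((1+cor)/2)^beta), then TOM similarity

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with k_i the connectivity sum_{u != i} a_iu.  Modules come from a static cut
of the average-linkage tree on 1 - TOM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionNetwork",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "export_edges",
    "build_network",
]


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    adjacency: np.ndarray
    tom: np.ndarray
    modules: np.ndarray  # per-gene integer label, 0 = unassigned

    def module_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, "module": self.modules})


def adjacency(
    expr: pd.DataFrame, beta: float = 6.0, signed: bool = False, log_transform: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Soft-thresholded correlation adjacency on genes x samples expression.

    Zero-variance genes are excluded (returned as the second element).
    Requires at least 4 samples.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples for a stable correlation network")
    x = np.log2(expr.to_numpy(dtype=float) + 1.0) if log_transform else expr.to_numpy(dtype=float)
    variable = x.var(axis=1) > 0
    dropped = list(expr.index[~variable])
    if dropped:
        import warnings

        warnings.warn(f"excluding {len(dropped)} zero-variance genes", stacklevel=2)
    x = x[variable]
    genes = list(expr.index[variable])
    cor = np.corrcoef(x)
    cor = np.clip(np.atleast_2d(cor), -1.0, 1.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=genes, columns=genes), dropped


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; symmetric, unit diagonal, entries in [0,1]."""
    a = np.asarray(adj, dtype=float)
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    shared = a_off @ a_off  # sum over u != i,j since the diagonal is zeroed
    k = a_off.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a_off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a_off) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom: np.ndarray, cut_height: float = 0.75, min_size: int = 5) -> np.ndarray:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` get label 0 (unassigned); surviving
    modules are renumbered 1.. by decreasing size (ties by first member).
    """
    n = tom.shape[0]
    if n == 1:
        return np.array([1 if min_size <= 1 else 0])
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = []
    for lab in np.unique(raw):
        members = np.nonzero(raw == lab)[0]
        if len(members) >= min_size:
            sizes.append((len(members), members[0], members))
    sizes.sort(key=lambda s: (-s[0], s[1]))
    for new, (_, _, members) in enumerate(sizes, start=1):
        labels[members] = new
    return labels


def export_edges(genes: list[str], tom: np.ndarray, min_weight: float = 0.1) -> pd.DataFrame:
    """Edge table (gene_i, gene_j, weight) with TOM weight >= min_weight, i < j."""
    rows = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            if tom[i, j] >= min_weight:
                rows.append((genes[i], genes[j], float(tom[i, j])))
    return pd.DataFrame(rows, columns=["gene_i", "gene_j", "weight"])


def build_network(
    expr: pd.DataFrame,
    beta: float = 6.0,
    signed: bool = False,
    cut_height: float = 0.75,
    min_size: int = 5,
    log_transform: bool = True,
) -> CoexpressionNetwork:
    adj, _ = adjacency(expr, beta=beta, signed=signed, log_transform=log_transform)
    tom = tom_similarity(adj.to_numpy())
    modules = detect_modules(tom, cut_height=cut_height, min_size=min_size)
    return CoexpressionNetwork(list(adj.index), adj.to_numpy(), tom, modules)
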