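"""Hypergeometric over-representation test of a gene set against an
annotation table (GO-slim, pathway, or any gene -> term mapping)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["EnrichmentResult", "hypergeom_upper", "enrich", "read_annotation"]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # set genes carrying the term
    K: int  # universe genes carrying the term
    n: int  # set size
    N: int  # universe size
    p_value: float
    p_adjusted: float


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def read_annotation(path) -> dict[str, set[str]]:
    """Gene -> set of terms from a two/three-column TSV (gene, term[, name])."""
    df = pd.read_csv(path, sep="\t", header=0)
    gene_col, term_col = df.columns[0], df.columns[1]
    out: dict[str, set[str]] = {}
    for g, t in zip(df[gene_col], df[term_col]):
        out.setdefault(str(g), set()).add(str(t))
    return out


def enrich(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    correction: str = "none",
) -> list[EnrichmentResult]:
    """One upper-tail hypergeometric result per term present in the universe.

    Results are sorted by raw p ascending.  ``correction`` is "none"
    (default), "bonferroni", or "bh" (Benjamini-Hochberg).
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    if correction not in {"none", "bonferroni", "bh"}:
        raise ValueError(f"unknown correction {correction!r}")
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in annotation.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    N, n = len(universe), len(gene_set)
    raw = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & gene_set)
        raw.append((term, k, K, hypergeom_upper(k, K, n, N)))
    m = len(raw)
    raw.sort(key=lambda r: (r[3], r[0]))
    adjusted = [p for *_, p in raw]
    if correction == "bonferroni":
        adjusted = [min(1.0, p * m) for p in adjusted]
    elif correction == "bh":
        adj, running = [], 1.0
        for rank in range(m, 0, -1):
            running = min(running, raw[rank - 1][3] * m / rank)
            adj.append(running)
        adjusted = adj[::-1]
    return [
        EnrichmentResult(term, k, K, n, N, p, p_adj)
        for (term, k, K, p), p_adj in zip(raw, adjusted)
    ]
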