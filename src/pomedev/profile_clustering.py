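"""Model-profile clustering of short expression time series.

The method follows the short time-series clustering idea of STEM: enumerate
every discretized template of T time points that starts at 0 and changes by
at most ``c`` units between consecutive points, pick ``m`` maximally distinct
templates by greedy max-min selection under distance 1 - Pearson, assign each
gene to its best-correlated template, and judge whether a template attracted
more genes than chance by permuting each gene's time points.

Profiles are numbered 0-based in the order the greedy selection emits them.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelProfile",
    "ProfileAssignment",
    "ClusterSignificance",
    "enumerate_candidates",
    "enumerate_and_select_profiles",
    "assign_genes",
    "cluster_significance",
    "cross_cultivar_overlap",
]


@dataclass(frozen=True)
class ModelProfile:
    profile_id: int
    template: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.template[0] != 0:
            raise ValueError("templates start at 0")


@dataclass(frozen=True)
class ProfileAssignment:
    gene_id: str
    cultivar: str
    profile_id: int
    correlation: float


@dataclass(frozen=True)
class ClusterSignificance:
    profile_id: int
    observed: int
    expected: float
    p_value: float
    p_bonferroni: float


def _standardize(rows: np.ndarray) -> np.ndarray:
    """Rows to zero mean, unit norm (for Pearson via dot product)."""
    x = rows - rows.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return x / norm


def enumerate_candidates(T: int = 7, c: int = 2) -> np.ndarray:
    """All non-flat templates: first element 0, successive diffs in [-c, c].

    Returned in lexicographic order of the template vector; the all-flat
    template is excluded.  Shape ((2c+1)^(T-1) - 1, T).
    """
    diffs = np.array(list(itertools.product(range(-c, c + 1), repeat=T - 1)))
    templates = np.hstack([np.zeros((len(diffs), 1), dtype=int), np.cumsum(diffs, axis=1)])
    keep = ~(templates == 0).all(axis=1)
    templates = templates[keep]
    order = np.lexsort(templates.T[::-1])
    return templates[order]


def enumerate_and_select_profiles(
    T: int = 7, c: int = 2, m: int = 20, seed: int | None = None
) -> list[ModelProfile]:
    """Greedy max-min selection of m mutually distinct templates.

    Seed is accepted for interface symmetry; the procedure is deterministic.
    Start from the pair at maximum 1 - Pearson distance (ties: lexicographic
    template order), then repeatedly add the candidate whose minimum distance
    to the chosen set is largest.  Results are memoized per (T, c, m).
    """
    return list(_select_profiles_cached(T, c, m))


@functools.lru_cache(maxsize=16)
def _select_profiles_cached(T: int, c: int, m: int) -> tuple[ModelProfile, ...]:
    cand = enumerate_candidates(T, c)
    n = len(cand)
    if m > n:
        raise ValueError(f"m={m} exceeds the {n} distinct non-flat candidates")
    Z = _standardize(cand.astype(float))
    # global minimum correlation (= maximum distance) by blocked scan
    block = 2048
    min_corr = np.inf
    for i0 in range(0, n, block):
        C = Z[i0 : i0 + block] @ Z.T
        for r in range(C.shape[0]):  # only pairs j > i
            row = C[r, i0 + r + 1 :]
            if row.size:
                min_corr = min(min_corr, row.min())
    # first (i, j) pair attaining it, in lexicographic pair order
    first_pair = None
    for i0 in range(0, n, block):
        C = Z[i0 : i0 + block] @ Z.T
        for r in range(C.shape[0]):
            js = np.nonzero(C[r, i0 + r + 1 :] <= min_corr + 1e-12)[0]
            if js.size:
                first_pair = (i0 + r, i0 + r + 1 + js[0])
                break
        if first_pair:
            break
    chosen = list(first_pair)
    min_dist = 1.0 - np.maximum(Z @ Z[chosen[0]], Z @ Z[chosen[1]])
    min_dist[chosen] = -np.inf
    while len(chosen) < m:
        nxt = int(np.argmax(min_dist))  # argmax takes the first (lexicographic) tie
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, 1.0 - Z @ Z[nxt])
        min_dist[nxt] = -np.inf
    return tuple(ModelProfile(k, tuple(int(v) for v in cand[i])) for k, i in enumerate(chosen))


def transform_series(series: pd.DataFrame) -> pd.DataFrame:
    """log2(RPKM+1) re-expressed as change from stage 1."""
    x = np.log2(series.to_numpy(dtype=float) + 1.0)
    x = x - x[:, [0]]
    return pd.DataFrame(x, index=series.index, columns=series.columns)


def _assign_matrix(x: np.ndarray, Zt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(best profile index, correlation) per row; zero-variance rows -> -1."""
    var = x.var(axis=1) > 0
    Xs = _standardize(x)
    corr = Xs @ Zt.T
    best = corr.argmax(axis=1)
    best_corr = corr[np.arange(len(x)), best]
    best[~var] = -1
    return best, best_corr


def assign_genes(
    series: pd.DataFrame,
    profiles: list[ModelProfile],
    cultivar: str = "",
    pre_transformed: bool = False,
) -> tuple[list[ProfileAssignment], list[str]]:
    """Assign every gene to its best-correlated profile.

    ``series`` is genes x stages RPKM (or, with ``pre_transformed``, already
    log2/anchored values).  Ties go to the lowest profile_id; genes with zero
    variance are returned separately as unassignable.
    """
    x = series if pre_transformed else transform_series(series)
    Zt = _standardize(np.array([p.template for p in profiles], dtype=float))
    best, corr = _assign_matrix(x.to_numpy(dtype=float), Zt)
    out, flat = [], []
    for g, b, r in zip(series.index, best, corr):
        if b < 0:
            flat.append(g)
        else:
            out.append(ProfileAssignment(g, cultivar, int(b), float(r)))
    return out, flat


def cluster_significance(
    series: pd.DataFrame,
    profiles: list[ModelProfile],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pre_transformed: bool = False,
) -> list[ClusterSignificance]:
    """Permutation significance of per-profile gene counts for one cultivar.

    Each gene's time points are permuted ``n_perm`` times and re-assigned;
    the expected count per profile is the mean over permutations, and the
    p-value is the binomial upper tail P(X >= observed) at success
    probability expected/total, Bonferroni-corrected over the m profiles.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is low for stable expected counts", stacklevel=2)
    x = (series if pre_transformed else transform_series(series)).to_numpy(dtype=float)
    Zt = _standardize(np.array([p.template for p in profiles], dtype=float))
    usable = x.var(axis=1) > 0
    x = x[usable]
    total = len(x)
    m = len(profiles)
    obs_best, _ = _assign_matrix(x, Zt)
    observed = np.bincount(obs_best, minlength=m)
    rng = np.random.default_rng(seed)
    perm_counts = np.zeros(m, dtype=float)
    idx = np.tile(np.arange(x.shape[1]), (total, 1))
    for _ in range(n_perm):
        perm = rng.permuted(idx, axis=1)
        xp = np.take_along_axis(x, perm, axis=1)
        keep = xp.var(axis=1) > 0
        b, _ = _assign_matrix(xp[keep], Zt)
        perm_counts += np.bincount(b, minlength=m)
    expected = perm_counts / n_perm
    out = []
    for k in range(m):
        p_succ = min(1.0, expected[k] / total) if total else 1.0
        p = float(stats.binom.sf(observed[k] - 1, total, p_succ)) if total else 1.0
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        out.append(
            ClusterSignificance(
                profile_id=k,
                observed=int(observed[k]),
                expected=float(expected[k]),
                p_value=p,
                p_bonferroni=min(1.0, p * m),
            )
        )
    return out


def cross_cultivar_overlap(
    assignments: dict[str, list[ProfileAssignment]], profile_id: int
) -> dict[frozenset, int]:
    """Exact Venn tally of one profile's membership across cultivars.

    Returns counts for every non-empty cultivar subset (2^k - 1 entries):
    the number of genes assigned to ``profile_id`` in exactly that subset.
    """
    members = {
        cv: {a.gene_id for a in asg if a.profile_id == profile_id}
        for cv, asg in assignments.items()
    }
    cultivars = sorted(members)
    tally: dict[frozenset, int] = {}
    for r in range(1, len(cultivars) + 1):
        for combo in itertools.combinations(cultivars, r):
            tally[frozenset(combo)] = 0
    for gene in set().union(*members.values()):
        key = frozenset(cv for cv in cultivars if gene in members[cv])
        tally[key] += 1
    return tally
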