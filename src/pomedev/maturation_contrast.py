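"""Maturity -> senescence (stage 6 -> 7) up/down contrasts.

Genes are classed up/down by log2 fold change with a pseudocount, proportions
are taken over genes expressed in either stage, and the post-ripening vs
non-post-ripening difference in up-proportions is tested with Welch's
unequal-variance two-sample t-test (Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_quant import ExpressionMatrix

__all__ = [
    "MaturationContrast",
    "GroupTest",
    "log2_fold_change",
    "classify_updown",
    "welch_t_test",
    "exclusive_gene_sets",
]


@dataclass
class MaturationContrast:
    cultivar: str
    up: set[str]
    down: set[str]
    unchanged: set[str]

    def __post_init__(self) -> None:
        if (self.up & self.down) or (self.up & self.unchanged) or (self.down & self.unchanged):
            raise ValueError("up/down/unchanged must be disjoint")

    @property
    def denominator(self) -> int:
        return len(self.up) + len(self.down) + len(self.unchanged)

    @property
    def up_proportion(self) -> float:
        """Percent of considered genes that are up-regulated."""
        return 100.0 * len(self.up) / self.denominator

    @property
    def down_proportion(self) -> float:
        return 100.0 * len(self.down) / self.denominator


@dataclass
class GroupTest:
    group_a: list[float]
    group_b: list[float]
    t_statistic: float
    df: float
    p_value: float


def log2_fold_change(
    rpkm6: pd.Series, rpkm7: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((stage7 + pc) / (stage6 + pc))."""
    return np.log2((rpkm7 + pseudocount) / (rpkm6 + pseudocount))


def classify_updown(
    rpkm: ExpressionMatrix,
    cultivar: str,
    threshold: float = 1.0,
    pseudocount: float = 1.0,
    min_expr: float = 0.0,
) -> MaturationContrast:
    """Partition genes expressed in stage 6 or 7 into up/down/unchanged.

    Up: fc >= threshold; down: fc <= -threshold; the denominator is genes
    with RPKM > ``min_expr`` in at least one of the two stages.
    """
    series = rpkm.cultivar_series(cultivar)
    if 6 not in series.columns or 7 not in series.columns:
        raise ValueError(f"{cultivar}: stages 6 and 7 are both required")
    s6, s7 = series[6], series[7]
    considered = (s6 > min_expr) | (s7 > min_expr)
    if not considered.any():
        raise ValueError(f"{cultivar}: no gene expressed in stage 6 or 7")
    fc = log2_fold_change(s6[considered], s7[considered], pseudocount)
    up = set(fc.index[(fc >= threshold) & (fc > 0)])
    down = set(fc.index[(fc <= -threshold) & (fc < 0)])
    unchanged = set(fc.index) - up - down  # at threshold 0 this is exactly fc == 0
    return MaturationContrast(cultivar, up, down, unchanged)


def welch_t_test(group_a, group_b, equal_var: bool = False) -> GroupTest:
    """Two-sample t-test, unequal-variance (Welch) by default.

    Degrees of freedom follow Welch-Satterthwaite; two groups with zero
    variance yield t=0 (or +/-inf) with the df formula kept finite.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = res.df if hasattr(res, "df") else len(a) + len(b) - 2
    return GroupTest(
        group_a=list(a),
        group_b=list(b),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )


def group_up_proportion_test(
    contrasts: dict[str, MaturationContrast],
    maturity_groups: dict[str, str],
    equal_var: bool = False,
) -> GroupTest:
    """Welch test of up-proportions: post-ripening vs non-post-ripening."""
    post = [c.up_proportion for cv, c in contrasts.items() if maturity_groups[cv] == "post_ripening"]
    non = [c.up_proportion for cv, c in contrasts.items() if maturity_groups[cv] == "non_post_ripening"]
    return welch_t_test(post, non, equal_var=equal_var)


def exclusive_gene_sets(
    contrasts: dict[str, MaturationContrast],
    maturity_groups: dict[str, str],
    mode: str = "all",
) -> dict[str, set[str]]:
    """Group-exclusive regulated genes.

    ``only_up_in_post``: genes up-regulated in every post-ripening cultivar
    (mode="all"; mode="any" relaxes to at least one) and up-regulated in no
    non-post-ripening cultivar.  ``only_down_in_non`` is the dual for
    down-regulation.
    """
    if mode not in {"all", "any"}:
        raise ValueError("mode must be 'all' or 'any'")
    post = [cv for cv in contrasts if maturity_groups[cv] == "post_ripening"]
    non = [cv for cv in contrasts if maturity_groups[cv] == "non_post_ripening"]

    def combine(sets, how):
        sets = list(sets)
        if not sets:
            return set()
        return set.intersection(*sets) if how == "all" else set.union(*sets)

    only_up_in_post = combine((contrasts[cv].up for cv in post), mode) - set().union(
        *(contrasts[cv].up for cv in non)
    )
    only_down_in_non = combine((contrasts[cv].down for cv in non), mode) - set().union(
        *(contrasts[cv].down for cv in post)
    )
    return {"only_up_in_post": only_up_in_post, "only_down_in_non": only_down_in_non}
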