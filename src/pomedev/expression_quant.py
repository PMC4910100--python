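"""RPKM quantification and the expression-presence filter.

RPKM (reads per kilobase of exon model per million mapped reads) normalizes a
raw read count by gene length and sequencing depth:

    rpkm[g, s] = 1e9 * count[g, s] / (length_bp[g] * total_mapped[s])

Gene length is the union of exon lengths of the transcript with the largest
exon span when a gene has several mRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import GeneModel, SampleSheet

__all__ = ["ExpressionMatrix", "compute_rpkm", "presence_filter", "mapping_summary", "gene_lengths"]


@dataclass
class ExpressionMatrix:
    """Gene x sample value grid plus the metadata RPKM needs.

    ``mode`` is ``"counts"`` (non-negative integers) or ``"rpkm"``
    (non-negative reals).  ``lengths`` is per-gene exon-model length in bp;
    ``totals`` is per-sample total mapped reads.
    """

    values: pd.DataFrame
    sample_sheet: SampleSheet
    mode: str = "counts"
    lengths: pd.Series | None = None
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"counts", "rpkm"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("every gene needs a positive length")
        if self.totals is not None:
            self.totals = self.totals.reindex(self.values.columns)
            if self.totals.isna().any() or (self.totals <= 0).any():
                raise ValueError("every sample needs a positive mapped-read total")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def cultivar_series(self, cultivar: str) -> pd.DataFrame:
        """Stage-ordered (genes x stages) slice for one cultivar."""
        sub = self.sample_sheet.samples_for(cultivar)
        out = self.values[list(sub["sample_id"])]
        out.columns = list(sub["stage"])
        return out


def gene_lengths(models: list[GeneModel]) -> pd.Series:
    """Exon-union length of the longest mRNA per gene, in bp."""
    best: dict[str, int] = {}
    for m in models:
        best[m.gene_id] = max(best.get(m.gene_id, 0), m.exon_length)
    return pd.Series(best, name="length_bp")


def compute_rpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts -> RPKM; totals default to per-sample column sums."""
    if counts.mode != "counts":
        raise ValueError("compute_rpkm expects a counts-mode matrix")
    if counts.lengths is None:
        raise ValueError("per-gene lengths are required for RPKM")
    totals = counts.totals
    if totals is None:
        totals = counts.values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("a sample with zero mapped reads has no RPKM")
    L = counts.lengths.to_numpy(dtype=float)[:, None]
    N = totals.to_numpy(dtype=float)[None, :]
    rpkm = 1e9 * counts.values.to_numpy(dtype=float) / (L * N)
    return ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=counts.genes, columns=counts.samples),
        sample_sheet=counts.sample_sheet,
        mode="rpkm",
        lengths=counts.lengths,
        totals=totals,
    )


def presence_filter(
    rpkm: ExpressionMatrix,
    cultivar: str,
    min_stages: int = 5,
    min_rpkm: float = 0.0,
) -> set[str]:
    """Genes expressed (> ``min_rpkm``) in at least ``min_stages`` of the
    cultivar's stages.  ``min_rpkm`` 0 means strict positivity."""
    series = rpkm.cultivar_series(cultivar)
    expressed = (series > min_rpkm) if min_rpkm == 0 else (series >= min_rpkm)
    keep = expressed.sum(axis=1) >= min_stages
    return set(series.index[keep])


def presence_filter_global(
    rpkm: ExpressionMatrix, min_samples: int = 5, min_rpkm: float = 0.0
) -> set[str]:
    """Alternative reading: at least ``min_samples`` across all samples."""
    expressed = (rpkm.values > min_rpkm) if min_rpkm == 0 else (rpkm.values >= min_rpkm)
    keep = expressed.sum(axis=1) >= min_samples
    return set(rpkm.genes[keep])


def mapping_summary(counts: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample tally: genes with any reads, and total mapped reads."""
    if counts.mode != "counts":
        raise ValueError("mapping_summary expects a counts-mode matrix")
    return pd.DataFrame(
        {
            "n_mapping_genes": (counts.values > 0).sum(axis=0),
            "total_reads": counts.values.sum(axis=0),
        }
    )
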