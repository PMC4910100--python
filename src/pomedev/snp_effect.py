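"""Transcript-aware classification of SNPs into 12 effectiveness categories.

Every single-nucleotide substitution is placed in gene context and assigned
one of:

====  =======================================================================
code  meaning
====  =======================================================================
 1    upstream region, within 2 kb 5' of the transcription start
 2    downstream region, within 2 kb 3' of the transcription end
 3    splice boundary: one of the 2 intronic bases flanking an exon junction
 4    intron interior (more than 2 bp from both junctions)
 5    initiation codon, function-changing (alt codon is not an initiator)
 6    termination codon, function-changing (alt codon is no longer a stop)
 7    exonic, synonymous (amino acid unchanged)
 8    exonic, premature stop codon introduced
 9    exonic, nonsynonymous (amino acid changed, no stop)
10    termination codon, silent (alt codon is still a stop)
11    initiation codon, silent (alt codon still encodes the ATG initiator;
      reachable only for transcripts annotated with a non-ATG start)
12    reference genome base is 'N' (trumps every other context)
 0    intergenic: farther than 2 kb from any gene
====  =======================================================================

Exonic positions outside the CDS (UTRs) carry no category of their own and
are flagged ``unclassified_utr`` (code -1).

Upstream/downstream are strand-aware and truncated at chromosome ends; they
are not trimmed where they overlap a neighboring gene — the neighbor's own
context wins by precedence.  When a variant hits several transcripts, one
record per transcript context is produced; summaries keep one primary record
per variant by the precedence N > codon classes > splice > intron > upstream
> downstream > intergenic, ties broken by lexicographic gene then mRNA id.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats_io import GeneModel, GenomeSequence, Variant

__all__ = [
    "EffectRecord",
    "TranscriptIndex",
    "CLASS_NAMES",
    "build_transcript_index",
    "classify_variant",
    "classify_variants",
    "primary_records",
    "effect_summary",
    "go_effect_crosstab",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
FLANK_BP = 2000  # upstream/downstream window
SPLICE_BP = 2  # intronic bases at each junction taking class 3

CLASS_NAMES = {
    0: "intergenic",
    1: "upstream_2kb",
    2: "downstream_2kb",
    3: "splice_boundary",
    4: "intron",
    5: "start_codon_changed",
    6: "stop_codon_changed",
    7: "synonymous",
    8: "premature_stop",
    9: "nonsynonymous",
    10: "stop_codon_silent",
    11: "start_codon_silent",
    12: "genome_n",
    -1: "unclassified_utr",
}

CODON_CLASSES = frozenset({5, 6, 7, 8, 9, 10, 11})

# precedence rank: smaller wins when one primary record is chosen per variant
_RANK = {12: 0, **{c: 1 for c in CODON_CLASSES}, -1: 2, 3: 3, 4: 4, 1: 5, 2: 6, 0: 7}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class EffectRecord:
    variant: Variant
    gene_id: str | None
    mrna_id: str | None
    effect_class: int
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    cds_position: int | None = None  # 0-based offset in the spliced CDS

    @property
    def effect_name(self) -> str:
        return CLASS_NAMES[self.effect_class]


class _TranscriptContext:
    """Pre-computed geometry and spliced CDS for one mRNA."""

    __slots__ = (
        "model", "cds_seq", "pos_to_offset", "splice_positions",
        "intron_intervals", "exon_intervals", "cds_positions",
        "upstream", "downstream", "flagged_start_stop",
    )

    def __init__(self, model: GeneModel, genome: GenomeSequence):
        self.model = model
        chrom_seq = genome.records[model.chrom]
        L = len(chrom_seq)
        self.exon_intervals = model.exons
        self.intron_intervals = model.introns
        self.splice_positions = set()
        for s, e in self.intron_intervals:
            n = e - s + 1
            for k in range(min(SPLICE_BP, n)):
                self.splice_positions.add(s + k)
                self.splice_positions.add(e - k)
        span_s, span_e = model.span
        if model.strand == "+":
            self.upstream = (max(1, span_s - FLANK_BP), span_s - 1)
            self.downstream = (span_e + 1, min(L, span_e + FLANK_BP))
        else:
            self.upstream = (span_e + 1, min(L, span_e + FLANK_BP))
            self.downstream = (max(1, span_s - FLANK_BP), span_s - 1)
        # spliced CDS in coding-strand orientation + genomic pos -> offset
        genomic_positions: list[int] = []
        for s, e in model.cds:
            genomic_positions.extend(range(s, e + 1))
        plus_seq = "".join(chrom_seq[p - 1] for p in genomic_positions)
        if model.strand == "-":
            genomic_positions.reverse()
            self.cds_seq = plus_seq.translate(_COMPLEMENT)[::-1]
        else:
            self.cds_seq = plus_seq
        self.pos_to_offset = {p: i for i, p in enumerate(genomic_positions)}
        self.cds_positions = set(genomic_positions)
        starts_atg = self.cds_seq[model.phase : model.phase + 3] == "ATG"
        ends_stop = self.cds_seq[-3:] in STOP_CODONS if len(self.cds_seq) >= 3 else False
        self.flagged_start_stop = not (starts_atg and ends_stop)


class TranscriptIndex:
    """Per-chromosome interval lookup over transcript contexts."""

    def __init__(self, contexts: list[_TranscriptContext]):
        self.contexts = contexts
        self.trees: dict[str, IntervalTree] = {}
        for i, ctx in enumerate(contexts):
            lo = min(ctx.upstream[0], ctx.model.span[0], ctx.downstream[0])
            hi = max(ctx.upstream[1], ctx.model.span[1], ctx.downstream[1])
            self.trees.setdefault(ctx.model.chrom, IntervalTree()).addi(lo, hi + 1, i)

    def overlapping(self, chrom: str, pos: int) -> list[_TranscriptContext]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = [self.contexts[iv.data] for iv in tree.at(pos)]
        return sorted(hits, key=lambda c: (c.model.gene_id, c.model.mrna_id))


def build_transcript_index(models: list[GeneModel], genome: GenomeSequence) -> TranscriptIndex:
    return TranscriptIndex([_TranscriptContext(m, genome) for m in models])


def _in(iv: tuple[int, int], pos: int) -> bool:
    return iv[0] <= pos <= iv[1]


def _classify_codon(ctx: _TranscriptContext, variant: Variant) -> EffectRecord:
    model = ctx.model
    offset = ctx.pos_to_offset[variant.pos]
    eff = offset - model.phase
    n_codons = (len(ctx.cds_seq) - model.phase) // 3
    if eff < 0 or model.non_coding_frame:
        return EffectRecord(variant, model.gene_id, model.mrna_id, -1)
    codon_i, within = divmod(eff, 3)
    start = model.phase + codon_i * 3
    ref_codon = ctx.cds_seq[start : start + 3]
    alt_base = variant.alt_allele
    if model.strand == "-":
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate()) if "N" not in ref_codon else "X"
    alt_aa = str(Seq(alt_codon).translate()) if "N" not in alt_codon else "X"
    if codon_i == 0:
        cls = 11 if alt_codon == "ATG" else 5
    elif codon_i == n_codons - 1:
        cls = 10 if alt_codon in STOP_CODONS else 6
    elif alt_codon in STOP_CODONS:
        cls = 8
    elif ref_aa == alt_aa:
        cls = 7
    else:
        cls = 9
    return EffectRecord(
        variant, model.gene_id, model.mrna_id, cls,
        ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa, cds_position=offset,
    )


def classify_variant(
    variant: Variant, index: TranscriptIndex, genome: GenomeSequence
) -> list[EffectRecord]:
    """One record per overlapping transcript context (or a single intergenic
    / genome-N record).  REF must match the genome."""
    gbase = genome.base(variant.chrom, variant.pos)
    if gbase != variant.ref_allele:
        raise ValueError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"variant {variant.ref_allele} vs genome {gbase}"
        )
    if gbase == "N":
        return [EffectRecord(variant, None, None, 12)]
    records = []
    for ctx in index.overlapping(variant.chrom, variant.pos):
        model = ctx.model
        pos = variant.pos
        if pos in ctx.cds_positions:
            records.append(_classify_codon(ctx, variant))
        elif any(_in(iv, pos) for iv in ctx.exon_intervals):
            records.append(EffectRecord(variant, model.gene_id, model.mrna_id, -1))
        elif any(_in(iv, pos) for iv in ctx.intron_intervals):
            cls = 3 if pos in ctx.splice_positions else 4
            records.append(EffectRecord(variant, model.gene_id, model.mrna_id, cls))
        elif _in(ctx.upstream, pos):
            records.append(EffectRecord(variant, model.gene_id, model.mrna_id, 1))
        elif _in(ctx.downstream, pos):
            records.append(EffectRecord(variant, model.gene_id, model.mrna_id, 2))
    if not records:
        records.append(EffectRecord(variant, None, None, 0))
    return records


def classify_variants(
    variants: list[Variant], index: TranscriptIndex, genome: GenomeSequence
) -> list[list[EffectRecord]]:
    return [classify_variant(v, index, genome) for v in variants]


def primary_records(record_lists: list[list[EffectRecord]]) -> list[EffectRecord]:
    """One record per variant by precedence; ties by (gene_id, mrna_id)."""
    out = []
    for records in record_lists:
        out.append(
            min(records, key=lambda r: (_RANK[r.effect_class], r.gene_id or "", r.mrna_id or ""))
        )
    return out


def effect_summary(primaries: list[EffectRecord]) -> pd.DataFrame:
    """Class x cultivar count table over primary records."""
    codes = [12] + sorted(c for c in CLASS_NAMES if c not in (12,))
    cultivars = sorted({r.variant.sample_id for r in primaries})
    table = pd.DataFrame(0, index=[CLASS_NAMES[c] for c in codes], columns=cultivars)
    for r in primaries:
        table.loc[r.effect_name, r.variant.sample_id] += 1
    return table


def go_effect_crosstab(
    records: list[EffectRecord],
    annotation: dict[str, set[str]],
    classes: frozenset = frozenset({5, 6, 9, 8}),
) -> pd.DataFrame:
    """Term x class table: distinct genes with >= 1 variant of that class.

    A gene annotated with several terms contributes once to every term row.
    """
    genes_by = {c: set() for c in classes}
    for r in records:
        if r.effect_class in classes and r.gene_id is not None:
            genes_by[r.effect_class].add(r.gene_id)
    terms = sorted({t for genes in genes_by.values() for g in genes for t in annotation.get(g, ())})
    cols = [CLASS_NAMES[c] for c in sorted(classes)]
    table = pd.DataFrame(0, index=terms, columns=cols)
    for c in sorted(classes):
        for g in genes_by[c]:
            for t in annotation.get(g, ()):
                table.loc[t, CLASS_NAMES[c]] += 1
    return table
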