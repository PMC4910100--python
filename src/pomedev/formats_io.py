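"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive throughout the package, matching
both GFF3 and VCF so no conversion happens at module boundaries.  Only
single-nucleotide substitutions are consumed from VCF input; indels and
symbolic alleles are counted and skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gffutils
import pysam
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "Variant",
    "SampleSheet",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_vcf",
    "read_count_matrix",
    "write_count_matrix",
    "write_newick",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """Chromosome id -> uppercase nucleotide string over {A,C,G,T,N}."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.records.items():
            if not seq:
                raise FormatError(f"empty sequence for {cid!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"non-IUPAC characters in {cid!r}: {sorted(bad)}")

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.records[chrom][pos - 1]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequence) and self.records == other.records


@dataclass
class GeneModel:
    """Strand-aware multi-exon transcript model.

    ``exons`` and ``cds`` are lists of ``(start, end)`` 1-based inclusive
    intervals stored in ascending genomic order regardless of strand.
    """

    gene_id: str
    mrna_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    phase: int = 0
    non_coding_frame: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.mrna_id}: strand must be + or -")
        for name in ("exons", "cds"):
            ivs = sorted(tuple(iv) for iv in getattr(self, name))
            for s, e in ivs:
                if s > e:
                    raise FormatError(f"{self.mrna_id}: inverted {name} interval {s}-{e}")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise FormatError(f"{self.mrna_id}: overlapping {name} intervals")
            setattr(self, name, ivs)
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise FormatError(f"{self.mrna_id}: CDS {s}-{e} outside every exon")
        if (self.cds_length - self.phase) % 3 != 0:
            self.non_coding_frame = True

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, ascending genomic order."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


@dataclass(frozen=True)
class Variant:
    """One single-nucleotide substitution observed in one cultivar."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise FormatError("only single-nucleotide substitutions are supported")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.chrom}:{self.pos} ref equals alt")


@dataclass
class SampleSheet:
    """Sample metadata: cultivar, developmental stage 1-7, maturity group."""

    table: pd.DataFrame  # columns: sample_id, cultivar, stage, maturity_group

    REQUIRED = ("sample_id", "cultivar", "stage", "maturity_group")
    GROUPS = frozenset({"post_ripening", "non_post_ripening"})

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns {sorted(missing)}")
        t = self.table
        if t.duplicated(["cultivar", "stage"]).any():
            raise FormatError("duplicate (cultivar, stage) pairs in sample sheet")
        if not t["stage"].between(1, 7).all():
            raise FormatError("stages must lie in 1..7")
        bad = set(t["maturity_group"]) - self.GROUPS
        if bad:
            raise FormatError(f"unknown maturity groups {sorted(bad)}")

    @property
    def cultivars(self) -> list[str]:
        return list(dict.fromkeys(self.table["cultivar"]))

    def samples_for(self, cultivar: str) -> pd.DataFrame:
        sub = self.table[self.table["cultivar"] == cultivar]
        if sub.empty:
            raise KeyError(f"cultivar {cultivar!r} not in sample sheet")
        return sub.sort_values("stage")

    def maturity_group(self, cultivar: str) -> str:
        return str(self.samples_for(cultivar)["maturity_group"].iloc[0])

    @classmethod
    def read(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"stage": int}))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA into a :class:`GenomeSequence`, uppercasing sequence."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.records.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneModel]:
    """One :class:`GeneModel` per mRNA; invalid models are dropped with a warning.

    Models whose CDS length (after phase) is not a multiple of 3 are kept but
    flagged ``non_coding_frame`` so codon-level analyses can exclude them.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds_feats = list(db.children(mrna, featuretype="CDS"))
        cds = [(f.start, f.end) for f in cds_feats]
        if not exons:
            exons = list(cds)
        first = min(cds_feats, key=lambda f: f.start) if mrna.strand == "+" else (
            max(cds_feats, key=lambda f: f.end) if cds_feats else None
        )
        phase = 0
        if first is not None and first.frame not in (None, "."):
            phase = int(first.frame)
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    mrna_id=mrna.id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                    phase=phase,
                )
            )
        except FormatError as exc:
            import warnings

            warnings.warn(f"rejected model {mrna.id}: {exc}", stacklevel=2)
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Serialize gene models (gene/mRNA/exon/CDS rows with Parent links)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for gene_id, ms in by_gene.items():
            start = min(m.span[0] for m in ms)
            end = max(m.span[1] for m in ms)
            m0 = ms[0]
            fh.write(
                f"{m0.chrom}\tpomedev\tgene\t{start}\t{end}\t.\t{m0.strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for m in ms:
                s, e = m.span
                fh.write(
                    f"{m.chrom}\tpomedev\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.mrna_id};Parent={gene_id}\n"
                )
                for i, (es, ee) in enumerate(m.exons, 1):
                    fh.write(
                        f"{m.chrom}\tpomedev\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                        f"ID={m.mrna_id}.exon{i};Parent={m.mrna_id}\n"
                    )
                # CDS phase: bases to skip before the first complete codon,
                # accumulated along the coding strand.
                cds = m.cds if m.strand == "+" else m.cds[::-1]
                phase = m.phase
                phased = {}
                for cs, ce in cds:
                    phased[(cs, ce)] = phase
                    phase = (3 - ((ce - cs + 1 - phase) % 3)) % 3
                for i, (cs, ce) in enumerate(m.cds, 1):
                    fh.write(
                        f"{m.chrom}\tpomedev\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t"
                        f"{phased[(cs, ce)]}\tID={m.mrna_id}.cds{i};Parent={m.mrna_id}\n"
                    )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample_id: str, genome: GenomeSequence | None = None):
    """Read SNVs for one cultivar from a VCF 4.x file.

    Multi-allelic rows are split into one :class:`Variant` per ALT; non-SNV
    rows are skipped and tallied.  Returns ``(variants, n_skipped)``.  If a
    genome is supplied, REF alleles are checked against it.
    """
    variants: list[Variant] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGTN":
                    skipped += 1
                    continue
                if genome is not None:
                    gbase = genome.base(rec.chrom, rec.pos)
                    if gbase != rec.ref:
                        raise FormatError(
                            f"REF mismatch at {rec.chrom}:{rec.pos}: "
                            f"VCF {rec.ref} vs genome {gbase}"
                        )
                variants.append(Variant(rec.chrom, rec.pos, rec.ref, alt, sample_id))
    return variants, skipped


def write_vcf(variants: list[Variant], genome: GenomeSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, seq in genome.records.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_allele)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Count matrices


def read_count_matrix(path, sample_sheet: SampleSheet) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    known = set(sample_sheet.table["sample_id"])
    extra = set(df.columns) - known
    if extra:
        raise FormatError(f"samples not in sample sheet: {sorted(extra)}")
    if df.isna().any().any():
        raise FormatError("missing cells in count matrix")
    if (df.to_numpy() < 0).any():
        raise FormatError("negative counts in matrix")
    if not (df.to_numpy() == df.to_numpy().astype(int)).all():
        raise FormatError("non-integer counts in matrix")
    return df.astype(int)


def write_count_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Newick

_UNQUOTED = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(label: str) -> str:
    if _UNQUOTED.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree) -> str:
    """Serialize a merge tree (see :mod:`pomedev.sample_tree`) to Newick text.

    Branch lengths are parent height minus child height (leaves at height 0).
    """

    def render(node, parent_height) -> str:
        if node.is_leaf:
            body = _newick_label(node.label)
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:g}"

    return render(tree, None) + ";"
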