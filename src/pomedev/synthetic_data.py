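"""Synthetic genomes, gene models, planted variants and count matrices.

Every downstream stage of the pipeline can be exercised against known truth:
variants are planted with their effect class verified by direct sequence
inspection at planting time, and count matrices carry planted time-course
profiles and a planted maturity-group difference in stage 6 -> 7
up-regulation (defaults 0.44 post-ripening vs 0.24 non-post-ripening,
a magnitude typical of ripening-after-harvest vs eat-at-harvest pome fruit).

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .expression_quant import ExpressionMatrix, gene_lengths
from .formats_io import GeneModel, GenomeSequence, SampleSheet, Variant

__all__ = [
    "VariantTruth",
    "CountsTruth",
    "UnplantableClassError",
    "generate_genome",
    "generate_gene_models",
    "plant_variants",
    "simulate_counts",
    "generate_annotation",
    "make_sample_sheet",
    "reverse_complement_fixture",
    "PROFILE_TEMPLATES",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# planted log2-space time-course shapes over the 7 stages
PROFILE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "flat": (0, 0, 0, 0, 0, 0, 0),
    "steady_decrease": (0, -1, -2, -3, -4, -5, -6),
    "steady_increase": (0, 1, 2, 3, 4, 5, 6),
    "late_peak": (0, 0, 1, 2, 4, 2, 0),
    "early_peak": (0, 3, 4, 2, 0, -1, -2),
}

# default cultivars mirroring a 2 post-ripening / 3 non-post-ripening design
DEFAULT_CULTIVARS = {
    "NG": "post_ripening",
    "RC": "post_ripening",
    "HS": "non_post_ripening",
    "YL": "non_post_ripening",
    "KRLXL": "non_post_ripening",
}


class UnplantableClassError(RuntimeError):
    """A requested effect class has no (or not enough) eligible sites."""


@dataclass(frozen=True)
class VariantTruth:
    variant: Variant
    intended_class: int  # 0 (intergenic) or 1..12
    gene_id: str | None


@dataclass
class CountsTruth:
    profile_label: dict[str, str]  # gene -> template name
    maturation_direction: dict[str, dict[str, str]]  # cultivar -> gene -> up/down/none
    enriched_term: str | None = None
    enriched_genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# genome & gene models


def generate_genome(
    n_chrom: int = 2,
    chrom_length: int = 120_000,
    n_fraction: float = 0.005,
    seed: int = 0,
) -> GenomeSequence:
    """Random chromosomes with a fraction of positions masked 'N'."""
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if not 0 <= n_fraction < 0.05:
        raise ValueError("n_fraction must lie in [0, 0.05)")
    rng = np.random.default_rng(seed)
    records = {}
    for i in range(n_chrom):
        seq = rng.choice(_BASES, size=chrom_length)
        if n_fraction > 0:
            n_sites = rng.random(chrom_length) < n_fraction
            seq[n_sites] = "N"
        records[f"chr{i + 1}"] = "".join(seq)
    return GenomeSequence(records)


def _random_cds(rng, n_codons: int, start_codon: str = "ATG") -> str:
    """Clean ORF: start codon, non-stop internal codons, one stop."""
    internal = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return start_codon + "".join(internal) + stop


def generate_gene_models(
    genome: GenomeSequence,
    n_genes: int = 40,
    exons_per_gene: tuple[int, int] = (1, 4),
    intergenic_gap: int = 4500,
    seed: int = 0,
    n_noncanonical_start: int = 0,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Place non-overlapping multi-exon genes and write their coding bases.

    Returns a new genome (with ORF bases written in) plus the models.  About
    half the genes land on the minus strand.  ``n_noncanonical_start`` genes
    get a GTG initiation codon instead of ATG (they are the only context in
    which a silent initiation-codon substitution is reachable).
    """
    if intergenic_gap < 4001:
        raise ValueError("intergenic_gap must be >= 4001 so 2 kb flanks never overlap")
    rng = np.random.default_rng(seed)
    chroms = {cid: list(seq) for cid, seq in genome.records.items()}
    chrom_ids = list(chroms)
    per_chrom = [n_genes // len(chrom_ids)] * len(chrom_ids)
    for i in range(n_genes % len(chrom_ids)):
        per_chrom[i] += 1
    models: list[GeneModel] = []
    gene_counter = 0
    noncanonical_left = n_noncanonical_start
    for cid, n_here in zip(chrom_ids, per_chrom):
        seq = chroms[cid]
        cursor = intergenic_gap // 2 + 2000
        for _ in range(n_here):
            n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
            exon_lens = [int(rng.integers(10, 50)) * 3 for _ in range(n_exons)]
            if sum(exon_lens) < 12:
                exon_lens[0] += 12
            intron_lens = [int(rng.integers(80, 200)) for _ in range(n_exons - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if cursor + span + 2000 + intergenic_gap // 2 > len(seq):
                raise ValueError(f"{cid}: genome too short for {n_here} genes at this spacing")
            exons = []
            p = cursor
            for k in range(n_exons):
                exons.append((p, p + exon_lens[k] - 1))
                p += exon_lens[k]
                if k < n_exons - 1:
                    p += intron_lens[k]
            strand = "+" if rng.random() < 0.5 else "-"
            start_codon = "ATG"
            if noncanonical_left > 0:
                start_codon = "GTG"
                noncanonical_left -= 1
            cds_seq = _random_cds(rng, sum(exon_lens) // 3, start_codon)
            positions = [pos for s, e in exons for pos in range(s, e + 1)]
            coding_order = positions if strand == "+" else positions[::-1]
            for i, pos in enumerate(coding_order):
                base = cds_seq[i]
                seq[pos - 1] = base if strand == "+" else base.translate(_COMPLEMENT)
            # keep intron bases defined (no N) so splice/intron planting is clean
            for s, e in zip(exons, exons[1:]):
                for pos in range(s[1] + 1, e[0]):
                    if seq[pos - 1] == "N":
                        seq[pos - 1] = str(rng.choice(_BASES))
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            models.append(
                GeneModel(
                    gene_id=gid,
                    mrna_id=f"{gid}.m1",
                    chrom=cid,
                    strand=strand,
                    exons=exons,
                    cds=list(exons),
                )
            )
            cursor = exons[-1][1] + 1 + intergenic_gap
    new_genome = GenomeSequence({cid: "".join(s) for cid, s in chroms.items()})
    return new_genome, models


# ---------------------------------------------------------------------------
# variant planting


def _codon_sites(genome: GenomeSequence, model: GeneModel):
    """Yield (genomic_pos, codon_index, within, ref_codon, alt_plus_strand, alt_codon)
    for every possible single-base codon substitution of the model."""
    chrom_seq = genome.records[model.chrom]
    positions = [pos for s, e in model.cds for pos in range(s, e + 1)]
    coding_order = positions if model.strand == "+" else positions[::-1]
    plus = "".join(chrom_seq[p - 1] for p in positions)
    cds_seq = plus if model.strand == "+" else plus.translate(_COMPLEMENT)[::-1]
    n_codons = len(cds_seq) // 3
    for offset, pos in enumerate(coding_order):
        codon_i, within = divmod(offset, 3)
        codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        if "N" in codon:
            continue
        for alt in "ACGT":
            if alt == codon[within]:
                continue
            alt_codon = codon[:within] + alt + codon[within + 1 :]
            alt_plus = alt if model.strand == "+" else alt.translate(_COMPLEMENT)
            yield pos, codon_i, within, n_codons, codon, alt_plus, alt_codon


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def plant_variants(
    genome: GenomeSequence,
    models: list[GeneModel],
    class_spec: dict[int, int],
    seed: int = 0,
    sample_id: str = "synthetic",
) -> tuple[list[Variant], list[VariantTruth]]:
    """Plant the requested number of variants per effect class (0..12).

    Each site's context is verified by direct sequence inspection while the
    candidate list is built; REF always equals the genome base.  Distinct
    genomic positions are used across all planted variants so each variant
    has one unambiguous primary context.  A class with too few eligible
    sites raises :class:`UnplantableClassError` naming the class.
    """
    rng = np.random.default_rng(seed)
    by_chrom_gene_span: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        by_chrom_gene_span.setdefault(m.chrom, []).append(m.span)

    def in_any_span(chrom, pos, pad=0):
        return any(s - pad <= pos <= e + pad for s, e in by_chrom_gene_span.get(chrom, ()))

    # candidate (chrom, pos, ref, alt, gene_id) per class
    candidates: dict[int, list[tuple]] = {c: [] for c in class_spec}

    def non_n_alt(ref):
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(rng.integers(3))]

    for m in models:
        chrom_seq = genome.records[m.chrom]
        L = len(chrom_seq)
        span_s, span_e = m.span
        up = (max(1, span_s - 2000), span_s - 1) if m.strand == "+" else (span_e + 1, min(L, span_e + 2000))
        down = (span_e + 1, min(L, span_e + 2000)) if m.strand == "+" else (max(1, span_s - 2000), span_s - 1)
        if 1 in candidates:
            for pos in range(up[0], up[1] + 1):
                ref = chrom_seq[pos - 1]
                if ref != "N" and not in_any_span(m.chrom, pos):
                    candidates[1].append((m.chrom, pos, ref, None, m.gene_id))
        if 2 in candidates:
            for pos in range(down[0], down[1] + 1):
                ref = chrom_seq[pos - 1]
                if ref != "N" and not in_any_span(m.chrom, pos):
                    candidates[2].append((m.chrom, pos, ref, None, m.gene_id))
        for s, e in m.introns:
            for pos in range(s, e + 1):
                ref = chrom_seq[pos - 1]
                if ref == "N":
                    continue
                near = min(pos - s, e - pos) < 2
                cls = 3 if near else 4
                if cls in candidates:
                    candidates[cls].append((m.chrom, pos, ref, None, m.gene_id))
        wanted_codon = {c for c in (5, 6, 7, 8, 9, 10, 11) if c in candidates}
        if wanted_codon:
            for pos, ci, within, n_codons, codon, alt_plus, alt_codon in _codon_sites(genome, m):
                if ci == 0:
                    cls = 11 if alt_codon == "ATG" else 5
                elif ci == n_codons - 1:
                    cls = 10 if alt_codon in _STOPS else 6
                elif alt_codon in _STOPS:
                    cls = 8
                elif _aa(alt_codon) == _aa(codon):
                    cls = 7
                else:
                    cls = 9
                if cls in wanted_codon:
                    ref = chrom_seq[pos - 1]
                    candidates[cls].append((m.chrom, pos, ref, alt_plus, m.gene_id))

    if 12 in candidates:
        for cid, seq in genome.records.items():
            for pos, base in enumerate(seq, start=1):
                if base == "N":
                    candidates[12].append((cid, pos, "N", None, None))
    if 0 in candidates:
        for cid, seq in genome.records.items():
            for pos in range(1, len(seq) + 1, 7):  # stride keeps the list tractable
                if seq[pos - 1] != "N" and not in_any_span(cid, pos, pad=2000):
                    candidates[0].append((cid, pos, seq[pos - 1], None, None))

    used: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    truths: list[VariantTruth] = []
    # scarce classes first so abundant ones cannot exhaust their positions
    for cls in sorted(class_spec, key=lambda c: (len(candidates[c]), c)):
        want = class_spec[cls]
        pool = candidates[cls]
        order = rng.permutation(len(pool))
        planted = 0
        for idx in order:
            if planted == want:
                break
            chrom, pos, ref, alt, gene_id = pool[idx]
            if (chrom, pos) in used:
                continue
            if alt is None:
                alt = non_n_alt(ref) if ref != "N" else str(rng.choice(_BASES))
            assert genome.base(chrom, pos) == ref
            used.add((chrom, pos))
            v = Variant(chrom, pos, ref, alt, sample_id)
            variants.append(v)
            truths.append(VariantTruth(v, cls, gene_id))
            planted += 1
        if planted < want:
            raise UnplantableClassError(
                f"class {cls}: only {planted} of {want} requested sites available"
            )
    return variants, truths


# ---------------------------------------------------------------------------
# counts


def make_sample_sheet(cultivars: dict[str, str] | None = None) -> SampleSheet:
    """7-stage sample sheet; default 5 cultivars (2 post-, 3 non-post-ripening)."""
    cultivars = cultivars or DEFAULT_CULTIVARS
    rows = [
        {"sample_id": f"{cv}{stage}", "cultivar": cv, "stage": stage, "maturity_group": grp}
        for cv, grp in cultivars.items()
        for stage in range(1, 8)
    ]
    return SampleSheet(pd.DataFrame(rows))


def simulate_counts(
    models: list[GeneModel],
    sample_sheet: SampleSheet,
    profile_spec: dict[str, float] | None = None,
    maturation_spec: dict[str, float] | None = None,
    down_fraction: float = 0.2,
    noise: float = 0.05,
    base_log2: tuple[float, float] = (8.0, 11.0),
    maturation_log2fc: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CountsTruth]:
    """Negative-binomial counts around planted time-course templates.

    ``profile_spec`` maps template names (:data:`PROFILE_TEMPLATES`) to gene
    fractions (default all flat).  ``maturation_spec`` maps maturity group to
    the fraction of genes up-regulated from stage 6 to 7 (default
    {post_ripening: 0.44, non_post_ripening: 0.24}); a further
    ``down_fraction`` of genes is down-regulated in every cultivar and the
    rest keep their stage-6 mean.  ``noise`` is the negative-binomial
    dispersion (variance = mu + noise * mu^2); 0 gives deterministic rounded
    means.  Library sizes are planted per sample and recorded as totals.
    """
    profile_spec = profile_spec or {"flat": 1.0}
    if maturation_spec is None:
        maturation_spec = {"post_ripening": 0.44, "non_post_ripening": 0.24}
    for frac in list(profile_spec.values()) + list(maturation_spec.values()) + [down_fraction]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    if sum(profile_spec.values()) > 1.0 + 1e-9:
        raise ValueError("profile fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    genes = [m.gene_id for m in models]
    n = len(genes)
    lengths = gene_lengths(models).reindex(genes)

    labels = np.array(["flat"] * n, dtype=object)
    start = 0
    order = rng.permutation(n)
    for name, frac in profile_spec.items():
        if name not in PROFILE_TEMPLATES:
            raise ValueError(f"unknown profile template {name!r}")
        k = int(round(frac * n))
        labels[order[start : start + k]] = name
        start += k

    mu0 = rng.uniform(*base_log2, size=n)
    stage_log2 = np.array([PROFILE_TEMPLATES[l] for l in labels], dtype=float)
    base_mean = 2.0 ** (mu0[:, None] + stage_log2)  # genes x 7, in count units

    table = sample_sheet.table
    sheet_cultivars = list(dict.fromkeys(table["cultivar"]))
    values = {}
    maturation_direction: dict[str, dict[str, str]] = {}
    for cv in sheet_cultivars:
        group = sample_sheet.maturity_group(cv)
        mean = base_mean.copy()
        up_frac = maturation_spec.get(group, 0.0)
        # independent per-gene draws: the realized up-fraction varies between
        # cultivars with binomial spread, as real cultivars differ
        u = rng.random(n)
        up_idx = np.nonzero(u < up_frac)[0]
        down_idx = np.nonzero((u >= up_frac) & (u < up_frac + down_fraction))[0]
        # only selected genes get their stage-7 mean re-anchored to stage 6;
        # the rest keep the template's own stage-7 value
        mean[up_idx, 6] = mean[up_idx, 5] * 2.0**maturation_log2fc
        mean[down_idx, 6] = mean[down_idx, 5] / 2.0**maturation_log2fc
        direction = {g: "none" for g in genes}
        for i in up_idx:
            direction[genes[i]] = "up"
        for i in down_idx:
            direction[genes[i]] = "down"
        maturation_direction[cv] = direction
        for stage in range(1, 8):
            mu = mean[:, stage - 1]
            if noise == 0:
                counts = np.rint(mu).astype(int)
            else:
                size = 1.0 / noise
                p = size / (size + mu)
                counts = rng.negative_binomial(size, p)
            values[f"{cv}{stage}"] = counts
    sample_ids = list(table["sample_id"])
    df = pd.DataFrame(values, index=genes)[sample_ids]
    totals = pd.Series(1_000_000.0, index=sample_ids)
    em = ExpressionMatrix(
        values=df, sample_sheet=sample_sheet, mode="counts", lengths=lengths, totals=totals
    )
    truth = CountsTruth(
        profile_label=dict(zip(genes, labels)),
        maturation_direction=maturation_direction,
    )
    return em, truth


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    models: list[GeneModel],
    n_terms: int = 20,
    enrichment_spec: tuple[str, set[str], float] | None = None,
    background_p: float = 0.15,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene -> term table, optionally with one planted enriched term.

    ``enrichment_spec`` = (term, gene_subset, odds_ratio): inside the subset
    the term's carriage probability is raised so that the odds ratio against
    the background probability equals the requested value.
    """
    rng = np.random.default_rng(seed)
    genes = [m.gene_id for m in models]
    terms = [f"T{i:03d}" for i in range(n_terms)]
    out: dict[str, set[str]] = {g: set() for g in genes}
    for t in terms:
        carriers = rng.random(len(genes)) < background_p
        for g, c in zip(genes, carriers):
            if c:
                out[g].add(t)
    if enrichment_spec is not None:
        term, subset, odds_ratio = enrichment_spec
        odds0 = background_p / (1 - background_p)
        odds1 = odds0 * odds_ratio
        p1 = odds1 / (1 + odds1)
        for g in genes:
            out[g].discard(term)
            p = p1 if g in subset else background_p
            if rng.random() < p:
                out[g].add(term)
    return out


def write_annotation(annotation: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm\n")
        for g in sorted(annotation):
            for t in sorted(annotation[g]):
                fh.write(f"{g}\t{t}\n")


# ---------------------------------------------------------------------------
# strand-symmetry transform


def reverse_complement_fixture(
    genome: GenomeSequence,
    models: list[GeneModel],
    variants: list[Variant],
) -> tuple[GenomeSequence, list[GeneModel], list[Variant]]:
    """Mirror an entire fixture: reverse-complement every chromosome and
    remap all annotations and variants onto the flipped coordinates."""
    lengths = {cid: len(seq) for cid, seq in genome.records.items()}
    new_genome = GenomeSequence(
        {cid: seq.translate(_COMPLEMENT)[::-1] for cid, seq in genome.records.items()}
    )

    def flip_iv(cid, iv):
        L = lengths[cid]
        return (L - iv[1] + 1, L - iv[0] + 1)

    new_models = [
        GeneModel(
            gene_id=m.gene_id,
            mrna_id=m.mrna_id,
            chrom=m.chrom,
            strand="-" if m.strand == "+" else "+",
            exons=[flip_iv(m.chrom, iv) for iv in m.exons],
            cds=[flip_iv(m.chrom, iv) for iv in m.cds],
            phase=m.phase,
        )
        for m in models
    ]
    new_variants = [
        Variant(
            v.chrom,
            lengths[v.chrom] - v.pos + 1,
            v.ref_allele.translate(_COMPLEMENT),
            v.alt_allele.translate(_COMPLEMENT),
            v.sample_id,
        )
        for v in variants
    ]
    return new_genome, new_models, new_variants
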