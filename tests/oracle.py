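"""Independent brute-force oracle for SNP effect classification.

Deliberately naive: it rebuilds the whole mutant chromosome, re-extracts the
spliced CDS of every transcript, translates reference and mutant proteins
with Biopython and derives the class from the comparison.  It shares no code
with :mod:`pomedev.snp_effect`.
"""

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _spliced_cds(chrom_seq: str, model) -> str:
    parts = [chrom_seq[s - 1 : e] for s, e in model.cds]
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _region_of(model, pos):
    """Naive scan of the model geometry for a genomic position."""
    for s, e in model.cds:
        if s <= pos <= e:
            return "cds"
    for s, e in model.exons:
        if s <= pos <= e:
            return "utr"
    span_s, span_e = model.exons[0][0], model.exons[-1][1]
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if e1 < pos < s2:
            dist = min(pos - (e1 + 1), (s2 - 1) - pos)
            return "splice" if dist < 2 else "intron"
    if model.strand == "+":
        if span_s - 2000 <= pos < span_s:
            return "upstream"
        if span_e < pos <= span_e + 2000:
            return "downstream"
    else:
        if span_e < pos <= span_e + 2000:
            return "upstream"
        if span_s - 2000 <= pos < span_s:
            return "downstream"
    return None


def classify_oracle(variant, models, genome):
    """Primary effect class for one variant, by exhaustive reconstruction."""
    chrom_seq = genome.records[variant.chrom]
    assert chrom_seq[variant.pos - 1] == variant.ref_allele
    if variant.ref_allele == "N":
        return 12
    mutant = chrom_seq[: variant.pos - 1] + variant.alt_allele + chrom_seq[variant.pos :]
    classes = []
    for model in models:
        if model.chrom != variant.chrom:
            continue
        region = _region_of(model, variant.pos)
        if region is None:
            continue
        if region == "cds":
            ref_cds = _spliced_cds(chrom_seq, model)
            alt_cds = _spliced_cds(mutant, model)
            diff = [i for i in range(len(ref_cds)) if ref_cds[i] != alt_cds[i]]
            assert len(diff) == 1
            codon_i = diff[0] // 3
            n_codons = len(ref_cds) // 3
            ref_codon = ref_cds[codon_i * 3 : codon_i * 3 + 3]
            alt_codon = alt_cds[codon_i * 3 : codon_i * 3 + 3]
            if codon_i == 0:
                cls = 11 if alt_codon == "ATG" else 5
            elif codon_i == n_codons - 1:
                cls = 10 if alt_codon in STOPS else 6
            else:
                ref_prot = str(Seq(ref_cds).translate())
                alt_prot = str(Seq(alt_cds).translate())
                if "*" in alt_prot[1:-1]:
                    cls = 8
                elif ref_prot == alt_prot:
                    cls = 7
                else:
                    cls = 9
            classes.append((cls, model.gene_id))
        else:
            code = {"utr": -1, "splice": 3, "intron": 4, "upstream": 1, "downstream": 2}[region]
            classes.append((code, model.gene_id))
    if not classes:
        return 0
    rank = {12: 0, 5: 1, 6: 1, 7: 1, 8: 1, 9: 1, 10: 1, 11: 1, -1: 2, 3: 3, 4: 4, 1: 5, 2: 6}
    classes.sort(key=lambda t: (rank[t[0]], t[1]))
    return classes[0][0]
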