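import numpy as np
import pytest

from graftscope.io_formats import GeneModel, VariantRecord, reverse_complement
from graftscope.variant_annotation import (
    GeneIndex,
    annotate_variants,
    assign_region,
    classify_indel,
    coding_effect,
    functional_class,
    impact_tier,
    substitution_class,
)

# Independent oracle: the standard genetic code frozen as a literal, written
# in the canonical TCAG ordering (never derived from the implementation).
_B = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_B)
    for j, b2 in enumerate(_B)
    for k, b3 in enumerate(_B)
}


def oracle_effect(ref_codon, alt_codon):
    aa_ref, aa_alt = CODON_TABLE[ref_codon], CODON_TABLE[alt_codon]
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*":
        return "stop_lost"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 50.0, 30, "homozygous")


# ---------------------------------------------------------------------------
# substitution_class
# ---------------------------------------------------------------------------


def test_transition_pair():
    assert substitution_class("A", "G") == "transition"


def test_transversion_pair():
    assert substitution_class("C", "G") == "transversion"


def test_all_ordered_pairs():
    classes = [
        substitution_class(a, b) for a in "ACGT" for b in "ACGT" if a != b
    ]
    assert classes.count("transition") == 4
    assert classes.count("transversion") == 8


def test_identical_bases_error():
    with pytest.raises(ValueError):
        substitution_class("A", "A")


# ---------------------------------------------------------------------------
# assign_region
# ---------------------------------------------------------------------------


@pytest.fixture
def simple_gene():
    return GeneModel(
        gene_id="g1",
        transcript_id="t1",
        chrom="c1",
        strand="+",
        exons=[(101, 160), (201, 260)],
        cds=[(121, 160, 0), (201, 240, 2)],
        utr5=[(101, 120)],
        utr3=[(241, 260)],
    )


def test_assign_region_cds(simple_gene):
    idx = GeneIndex([simple_gene])
    region, gene_id, model = assign_region(snp("c1", 130, "A", "G"), idx)
    assert (region, gene_id) == ("CDS", "g1")
    assert model is simple_gene


def test_assign_region_intergenic(simple_gene):
    idx = GeneIndex([simple_gene])
    assert assign_region(snp("c1", 50, "A", "G"), idx)[0] == "intergenic"
    assert assign_region(snp("c2", 130, "A", "G"), idx)[0] == "intergenic"


def test_assign_region_intron_and_utr(simple_gene):
    idx = GeneIndex([simple_gene])
    assert assign_region(snp("c1", 180, "A", "G"), idx)[0] == "intron"
    assert assign_region(snp("c1", 110, "A", "G"), idx)[0] == "UTR"
    assert assign_region(snp("c1", 250, "A", "G"), idx)[0] == "UTR"


def test_assign_region_cds_precedence_over_overlap(simple_gene):
    # second transcript whose intron covers the first's CDS: CDS must win
    other = GeneModel(
        gene_id="g2",
        transcript_id="t2",
        chrom="c1",
        strand="+",
        exons=[(90, 100), (170, 190)],
        cds=[(90, 100, 0), (170, 175, 0)],
    )
    idx = GeneIndex([simple_gene, other])
    region, gene_id, _ = assign_region(snp("c1", 130, "A", "G"), idx)
    assert (region, gene_id) == ("CDS", "g1")


def test_assign_region_matches_linear_scan_oracle(small_sim):
    idx = GeneIndex(small_sim.genes)
    rng = np.random.default_rng(0)
    length = len(small_sim.genome["chr1"])
    rank = {"CDS": 0, "UTR": 1, "intron": 2}
    for pos in rng.integers(1, length + 1, 1000):
        v = snp("chr1", int(pos), "A", "G")
        got = assign_region(v, idx)[0]
        # oracle: scan every model linearly, take best-ranked region
        regions = [
            r
            for m in small_sim.genes
            if m.chrom == "chr1" and (r := m.region_of(int(pos))) is not None
        ]
        expected = min(regions, key=lambda r: rank[r]) if regions else "intergenic"
        assert got == expected


# ---------------------------------------------------------------------------
# coding_effect
# ---------------------------------------------------------------------------


def make_coding_gene(coding, chrom="c1", strand="+", flank=0):
    """Single-exon gene whose CDS is exactly ``coding`` (genome on demand)."""
    n = len(coding)
    if strand == "+":
        genome = {chrom: "C" * flank + coding + "C" * flank}
    else:
        genome = {chrom: "C" * flank + reverse_complement(coding) + "C" * flank}
    start, end = flank + 1, flank + n
    gene = GeneModel(
        gene_id="g",
        transcript_id="t",
        chrom=chrom,
        strand=strand,
        exons=[(start, end)],
        cds=[(start, end, 0)],
    )
    return gene, genome


def test_coding_effect_synonymous():
    gene, genome = make_coding_gene("ATGGCTTAA")  # M A *
    v = snp("c1", 6, "T", "C")  # GCT -> GCC, both Ala
    assert coding_effect(v, gene, genome) == "synonymous"


def test_coding_effect_nonsense():
    gene, genome = make_coding_gene("ATGTGGTAA")  # M W *
    v = snp("c1", 6, "G", "A")  # TGG -> TGA
    assert coding_effect(v, gene, genome) == "nonsense"


def test_coding_effect_start_lost():
    gene, genome = make_coding_gene("ATGGCTTAA")
    v = snp("c1", 2, "T", "C")  # ATG -> ACG
    assert coding_effect(v, gene, genome) == "start_lost"


def test_coding_effect_stop_lost():
    gene, genome = make_coding_gene("ATGGCTTAA")
    v = snp("c1", 7, "T", "C")  # TAA -> CAA
    assert coding_effect(v, gene, genome) == "stop_lost"


def test_coding_effect_outside_cds_errors():
    gene, genome = make_coding_gene("ATGGCTTAA", flank=5)
    with pytest.raises(ValueError):
        coding_effect(snp("c1", 2, "C", "G"), gene, genome)


def test_coding_effect_reference_mismatch_errors():
    gene, genome = make_coding_gene("ATGGCTTAA")
    with pytest.raises(ValueError, match="mismatch"):
        coding_effect(snp("c1", 6, "A", "C"), gene, genome)


def test_exhaustive_codon_oracle():
    """All 576 single-base codon changes vs the frozen translation table."""
    checked = 0
    for codon in CODON_TABLE:
        coding = "ATG" + codon + "TAA"  # mutate the middle codon
        gene, genome = make_coding_gene(coding)
        for within in range(3):
            pos = 4 + within
            ref = codon[within]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mutated = codon[:within] + alt + codon[within + 1 :]
                got = coding_effect(snp("c1", pos, ref, alt), gene, genome)
                assert got == oracle_effect(codon, mutated), (codon, pos, alt)
                checked += 1
    assert checked == 576


def test_strand_symmetry():
    """Mirrored minus-strand gene gives identical effects at mirrored sites."""
    coding = "ATGGCTTGGTAA"
    gene_f, genome_f = make_coding_gene(coding, strand="+")
    gene_r, genome_r = make_coding_gene(coding, strand="-")
    n = len(coding)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for pos in range(1, n + 1):
        ref = coding[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            fwd = coding_effect(snp("c1", pos, ref, alt), gene_f, genome_f)
            rev = coding_effect(
                snp("c1", n - pos + 1, comp[ref], comp[alt]), gene_r, genome_r
            )
            assert fwd == rev, (pos, ref, alt)


# ---------------------------------------------------------------------------
# InDels, impact, functional class
# ---------------------------------------------------------------------------


def test_classify_indel():
    deletion = VariantRecord("c1", 5, "AT", "A", 50, 30, "homozygous")
    assert classify_indel(deletion, "CDS") == "frameshift"
    ins3 = VariantRecord("c1", 5, "A", "AGGG", 50, 30, "homozygous")
    assert classify_indel(ins3, "CDS") == "inframe_indel"
    ins2 = VariantRecord("c1", 5, "A", "AGG", 50, 30, "homozygous")
    assert classify_indel(ins2, "intron") == "noncoding"


@pytest.mark.parametrize(
    "effect,region,expected",
    [
        ("nonsense", "CDS", "high"),
        ("start_lost", "CDS", "high"),
        ("stop_lost", "CDS", "high"),
        ("frameshift", "CDS", "high"),
        ("missense", "CDS", "moderate"),
        ("inframe_indel", "CDS", "moderate"),
        ("synonymous", "CDS", "low"),
        ("noncoding", "intron", "modifier"),
        ("noncoding", "UTR", "modifier"),
        ("noncoding", "intergenic", "modifier"),
    ],
)
def test_impact_tier(effect, region, expected):
    assert impact_tier(effect, region) == expected


def test_functional_class_mapping():
    assert functional_class("missense") == "missense"
    assert functional_class("nonsense") == "nonsense"
    assert functional_class("synonymous") == "silent"
    assert functional_class("noncoding") == "none"
    assert functional_class("frameshift") == "none"


# ---------------------------------------------------------------------------
# Partition invariants on simulated data
# ---------------------------------------------------------------------------


def test_annotation_partition_invariants(small_sim):
    calls = annotate_variants(
        small_sim.rootstock_variants, small_sim.genes, small_sim.genome
    )
    assert len(calls) == len(small_sim.rootstock_variants)
    for c in calls:
        assert c.region in ("CDS", "UTR", "intron", "intergenic")
        assert c.impact in ("high", "moderate", "low", "modifier")
        if c.region == "intergenic":
            assert c.impact == "modifier"
            assert c.functional_class == "none"
    # functional classes partition classified CDS SNPs
    cds_snps = [
        c for c in calls if c.region == "CDS" and len(c.ref) == len(c.alt) == 1
    ]
    n_classified = sum(
        1 for c in cds_snps if c.functional_class in ("missense", "nonsense", "silent")
    )
    n_terminal_loss = sum(
        1 for c in cds_snps if c.effect in ("start_lost", "stop_lost")
    )
    assert n_classified + n_terminal_loss == len(cds_snps)


def test_heterozygous_annotated_like_homozygous(small_sim):
    idx = GeneIndex(small_sim.genes)
    v_hom = next(v for v in small_sim.rootstock_variants if v.is_snp)
    v_het = VariantRecord(
        v_hom.chrom, v_hom.pos, v_hom.ref, v_hom.alt, v_hom.qual, v_hom.depth,
        "heterozygous",
    )
    (a,) = annotate_variants([v_hom], idx, small_sim.genome)
    (b,) = annotate_variants([v_het], idx, small_sim.genome)
    assert (a.region, a.effect, a.impact) == (b.region, b.effect, b.impact)
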