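"""SnpEff-style consequence engine.

Assigns each variant a region (CDS/UTR/intron/intergenic), a codon-level
effect, an impact tier, and a functional class.  Region precedence across
overlapping transcripts is CDS > UTR > intron so every variant receives
exactly one call.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_formats import GeneModel, VariantRecord, reverse_complement

TRANSITIONS = {frozenset("AG"), frozenset("CT")}

REGIONS = ("CDS", "UTR", "intron", "intergenic")
EFFECTS = (
    "synonymous",
    "missense",
    "nonsense",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe_indel",
    "noncoding",
)
_HIGH = {"nonsense", "start_lost", "stop_lost", "frameshift"}

_FUNCTIONAL = {"missense": "missense", "nonsense": "nonsense", "synonymous": "silent"}

_REGION_RANK = {"CDS": 0, "UTR": 1, "intron": 2}


@dataclass(frozen=True)
class ConsequenceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    region: str
    effect: str
    impact: str
    functional_class: str
    gene_id: str | None = None
    in_terminal_codon: bool = False
    low_confidence: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def substitution_class(ref: str, alt: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' for the other pairs."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError(f"identical bases {ref}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-nucleotide pair ({ref},{alt})")
    return "transition" if frozenset((ref, alt)) in TRANSITIONS else "transversion"


class GeneIndex:
    """Chromosome-bucketed gene lookup with a sorted-start bisect scan."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for chrom, gl in self._by_chrom.items():
            gl.sort(key=lambda g: g.span)
            self._starts[chrom] = [g.span[0] for g in gl]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        gl = self._by_chrom.get(chrom, [])
        starts = self._starts.get(chrom, [])
        hi = bisect_right(starts, pos)
        return [g for g in gl[:hi] if g.span[1] >= pos]

    def genes(self) -> list[GeneModel]:
        return [g for gl in self._by_chrom.values() for g in gl]


def assign_region(
    variant: VariantRecord, index: GeneIndex
) -> tuple[str, str | None, GeneModel | None]:
    """Region and owning gene for a variant position.

    Returns ``(region, gene_id, model)``; intergenic positions get
    ``("intergenic", None, None)``.
    """
    best: tuple[int, str, GeneModel] | None = None
    for g in index.overlapping(variant.chrom, variant.pos):
        region = g.region_of(variant.pos)
        if region is None:
            continue
        rank = _REGION_RANK[region]
        if best is None or rank < best[0]:
            best = (rank, region, g)
    if best is None:
        return ("intergenic", None, None)
    return (best[1], best[2].gene_id, best[2])


def _translate(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def coding_effect(
    variant: VariantRecord, gene: GeneModel, genome: dict[str, str]
) -> str:
    """Codon-level effect of a SNP inside the CDS of ``gene``.

    The variant base is complemented for minus-strand genes and the codon is
    read from the coding strand; translation uses the standard genetic code.
    """
    if not variant.is_snp:
        raise ValueError("coding_effect applies to SNPs; use classify_indel")
    offset = gene.coding_offset(variant.pos)  # raises if outside CDS
    coding = gene.coding_sequence(genome)
    codon_i, within = divmod(offset, 3)
    ref_codon = coding[codon_i * 3 : codon_i * 3 + 3]
    if len(ref_codon) < 3:
        return "noncoding"  # truncated terminal codon on low-confidence models
    alt_base = (
        variant.alt.upper()
        if gene.strand == "+"
        else reverse_complement(variant.alt.upper())
    )
    ref_base = (
        variant.ref.upper()
        if gene.strand == "+"
        else reverse_complement(variant.ref.upper())
    )
    if ref_codon[within] != ref_base:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"codon has {ref_codon[within]}, variant ref is {ref_base}"
        )
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    aa_ref = _translate(ref_codon)
    aa_alt = _translate(alt_codon)
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*":
        return "stop_lost"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def classify_indel(variant: VariantRecord, region: str) -> str:
    """Frameshift vs in-frame inside CDS; noncoding elsewhere."""
    if not variant.is_indel:
        raise ValueError("classify_indel applies to InDels")
    if region == "CDS":
        return "frameshift" if variant.indel_length % 3 != 0 else "inframe_indel"
    return "noncoding"


def impact_tier(effect: str, region: str) -> str:
    """SnpEff-convention impact: high/moderate/low/modifier."""
    if effect in _HIGH:
        return "high"
    if effect in ("missense", "inframe_indel"):
        return "moderate"
    if effect == "synonymous":
        return "low"
    return "modifier"  # intron, UTR, intergenic, noncoding


def functional_class(effect: str) -> str:
    return _FUNCTIONAL.get(effect, "none")


def _in_terminal_codon(variant: VariantRecord, gene: GeneModel) -> bool:
    """True when a CDS SNP falls in the first or last codon of the transcript."""
    try:
        offset = gene.coding_offset(variant.pos)
    except ValueError:
        return False
    n = gene.cds_length
    return offset < 3 or offset >= n - 3


def annotate_variant(
    variant: VariantRecord, index: GeneIndex, genome: dict[str, str]
) -> ConsequenceCall:
    region, gene_id, model = assign_region(variant, index)
    low_conf = bool(model and model.low_confidence)
    terminal = False
    if variant.is_indel:
        effect = classify_indel(variant, region)
    elif region == "CDS" and model is not None:
        effect = coding_effect(variant, model, genome)
        terminal = _in_terminal_codon(variant, model)
    else:
        effect = "noncoding"
    return ConsequenceCall(
        chrom=variant.chrom,
        pos=variant.pos,
        ref=variant.ref,
        alt=variant.alt,
        region=region,
        effect=effect,
        impact=impact_tier(effect, region),
        functional_class=functional_class(effect),
        gene_id=gene_id,
        in_terminal_codon=terminal,
        low_confidence=low_conf,
    )


def annotate_variants(
    variants: Sequence[VariantRecord],
    genes: Iterable[GeneModel],
    genome: dict[str, str],
) -> list[ConsequenceCall]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [annotate_variant(v, index, genome) for v in variants]
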