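"""Graft-mobile transcript detection from diagnostic SNPs.

Pipeline: merge replicate RNA pileups, call a homozygous consensus genotype
per site, keep loci where scion and rootstock are homozygous for different
alleles (diagnostic loci), test each locus for donor-allele reads in the
receptor's RNA above threshold (with a pre-graft-control conflict check),
and aggregate supported loci to gene-level mobility calls with direction.

Only SNP loci participate; InDels are never considered.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import BASES, HOMOZYGOUS, SiteCounts, VariantRecord
from .variant_annotation import GeneIndex

logger = logging.getLogger(__name__)

SCION_TO_ROOTSTOCK = "scion_to_rootstock"
ROOTSTOCK_TO_SCION = "rootstock_to_scion"
BIDIRECTIONAL = "bidirectional"

NOT_HOMOZYGOUS = "not_homozygous"


@dataclass(frozen=True)
class MobilityConfig:
    min_reads: int = 5  # dominant-allele reads, inclusive
    hom_freq: float = 0.95  # dominant-allele frequency, strict ">"
    donor_fraction: float = 0.05  # donor-allele share in receptor, strict ">"
    max_alleles: int = 2
    min_support_snps: int = 1
    # "allele present" floor used for the two-allele and control checks
    noise_min_reads: int = 2
    noise_min_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.donor_fraction < self.hom_freq <= 1):
            raise ValueError("need 0 < donor_fraction < hom_freq <= 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.max_alleles != 2:
            raise ValueError("max_alleles must be exactly 2")


@dataclass(frozen=True)
class DiagnosticLocus:
    """A position homozygous for different alleles in scion vs rootstock."""

    chrom: str
    pos: int
    scion_allele: str
    rootstock_allele: str
    scion_reads: int = 0
    scion_fraction: float = 1.0
    rootstock_reads: int = 0
    rootstock_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.scion_allele == self.rootstock_allele:
            raise ValueError(f"alleles identical at {self.chrom}:{self.pos}")

    def donor_allele(self, direction: str) -> str:
        return (
            self.scion_allele
            if direction == SCION_TO_ROOTSTOCK
            else self.rootstock_allele
        )

    def receptor_allele(self, direction: str) -> str:
        return (
            self.rootstock_allele
            if direction == SCION_TO_ROOTSTOCK
            else self.scion_allele
        )


@dataclass
class SupportedLocus:
    locus: DiagnosticLocus
    direction: str
    donor_reads: int
    donor_fraction: float


@dataclass
class MobileGeneCall:
    gene_id: str
    tissue: str
    direction: str
    supporting: list[SupportedLocus] = field(default_factory=list)

    @property
    def n_support_snps(self) -> int:
        return len(self.supporting)

    @property
    def best_donor_fraction(self) -> float:
        return max(s.donor_fraction for s in self.supporting)


# ---------------------------------------------------------------------------
# Pileup-level operations
# ---------------------------------------------------------------------------


def merge_replicates(
    replicates: Sequence[Sequence[SiteCounts]],
) -> list[SiteCounts]:
    """Element-wise sum of base counts across replicate pileups."""
    acc: dict[tuple[str, int], list[int]] = {}
    for rep in replicates:
        for site in rep:
            key = (site.chrom, site.pos)
            if key in acc:
                cur = acc[key]
                for i, c in enumerate(site.as_tuple()):
                    cur[i] += c
            else:
                acc[key] = list(site.as_tuple())
    return [
        SiteCounts(chrom, pos, *counts)
        for (chrom, pos), counts in sorted(acc.items())
    ]


def consensus_genotype(site: SiteCounts, cfg: MobilityConfig) -> str:
    """Homozygous allele call, or ``"not_homozygous"``.

    Requires the dominant allele to have at least ``min_reads`` supporting
    reads and a frequency strictly greater than ``hom_freq``; ties for the
    dominant allele are conservatively not homozygous.
    """
    depth = site.depth
    if depth == 0:
        return NOT_HOMOZYGOUS
    counts = site.as_tuple()
    best = max(counts)
    if counts.count(best) > 1:
        return NOT_HOMOZYGOUS
    if best < cfg.min_reads or best / depth <= cfg.hom_freq:
        return NOT_HOMOZYGOUS
    return BASES[counts.index(best)]


def find_diagnostic_loci(
    scion_sites: Sequence[SiteCounts],
    rootstock_sites: Sequence[SiteCounts],
    cfg: MobilityConfig | None = None,
) -> list[DiagnosticLocus]:
    """Loci where both merged partners are homozygous for different alleles."""
    cfg = cfg or MobilityConfig()
    rs_by_pos = {(s.chrom, s.pos): s for s in rootstock_sites}
    loci: list[DiagnosticLocus] = []
    for sc in scion_sites:
        rs = rs_by_pos.get((sc.chrom, sc.pos))
        if rs is None:
            continue
        a_sc = consensus_genotype(sc, cfg)
        a_rs = consensus_genotype(rs, cfg)
        if NOT_HOMOZYGOUS in (a_sc, a_rs) or a_sc == a_rs:
            continue
        loci.append(
            DiagnosticLocus(
                chrom=sc.chrom,
                pos=sc.pos,
                scion_allele=a_sc,
                rootstock_allele=a_rs,
                scion_reads=sc.count(a_sc),
                scion_fraction=sc.count(a_sc) / sc.depth,
                rootstock_reads=rs.count(a_rs),
                rootstock_fraction=rs.count(a_rs) / rs.depth,
            )
        )
    return loci


def diagnostic_loci_from_variants(
    variants_scion: Sequence[VariantRecord],
    variants_rootstock: Sequence[VariantRecord],
    genome: Mapping[str, str],
) -> list[DiagnosticLocus]:
    """Diagnostic loci from genomic variant calls instead of RNA consensus.

    A partner absent from its VCF at a position is homozygous reference; a
    heterozygous call disqualifies the locus.  Only SNPs are considered.
    """

    def snp_map(
        variants: Sequence[VariantRecord],
    ) -> dict[tuple[str, int], VariantRecord]:
        return {(v.chrom, v.pos): v for v in variants if v.is_snp}

    sc_map = snp_map(variants_scion)
    rs_map = snp_map(variants_rootstock)
    loci: list[DiagnosticLocus] = []
    for key in sorted(sc_map.keys() | rs_map.keys()):
        chrom, pos = key
        ref = genome[chrom][pos - 1].upper()
        alleles: list[str] = []
        depths: list[int] = []
        ok = True
        for vmap in (sc_map, rs_map):
            v = vmap.get(key)
            if v is None:
                alleles.append(ref)
                depths.append(0)
            elif v.zygosity == HOMOZYGOUS:
                alleles.append(v.alt)
                depths.append(v.depth)
            else:
                ok = False
                break
        if not ok or alleles[0] == alleles[1]:
            continue
        loci.append(
            DiagnosticLocus(
                chrom=chrom,
                pos=pos,
                scion_allele=alleles[0],
                rootstock_allele=alleles[1],
                scion_reads=depths[0],
                rootstock_reads=depths[1],
            )
        )
    return loci


def _allele_present(site: SiteCounts, base: str, cfg: MobilityConfig) -> bool:
    n = site.count(base)
    return (
        n >= cfg.noise_min_reads
        and site.depth > 0
        and n / site.depth >= cfg.noise_min_fraction
    )


def detect_mobility(
    locus: DiagnosticLocus,
    receptor_site: SiteCounts | None,
    control_sites: Iterable[SiteCounts],
    cfg: MobilityConfig,
    direction: str,
) -> SupportedLocus | None:
    """Test one diagnostic locus for donor transcripts in the receptor.

    Supported iff (a) the donor allele exceeds ``donor_fraction`` of receptor
    depth, (b) exactly the donor and receptor alleles are present above the
    noise floor, and (c) the donor allele is absent above the noise floor in
    every pre-graft control site supplied for the receptor (conflict-free).
    """
    if receptor_site is None or receptor_site.depth == 0:
        return None
    donor = locus.donor_allele(direction)
    receptor = locus.receptor_allele(direction)
    donor_n = receptor_site.count(donor)
    frac = donor_n / receptor_site.depth
    if frac <= cfg.donor_fraction:
        return None
    present = {b for b in BASES if _allele_present(receptor_site, b, cfg)}
    if present != {donor, receptor}:
        return None
    for ctrl in control_sites:
        if (ctrl.chrom, ctrl.pos) != (locus.chrom, locus.pos):
            continue
        if _allele_present(ctrl, donor, cfg):
            return None
    return SupportedLocus(locus, direction, donor_n, frac)


# ---------------------------------------------------------------------------
# Gene-level aggregation
# ---------------------------------------------------------------------------


def aggregate_genes(
    supported: Sequence[SupportedLocus],
    genes: GeneIndex,
    cfg: MobilityConfig,
    tissue: str,
) -> tuple[list[MobileGeneCall], dict[str, int]]:
    """Gene-level mobility calls and direction tallies for one tissue.

    Directional tallies count every gene supported in that direction, so a
    bidirectional gene appears in both; the union applies inclusion-
    exclusion.  Loci outside every transcript span are dropped (logged).
    """
    per_gene: dict[str, dict[str, list[SupportedLocus]]] = defaultdict(
        lambda: defaultdict(list)
    )
    dropped = 0
    for sup in supported:
        hits = [
            g
            for g in genes.overlapping(sup.locus.chrom, sup.locus.pos)
            if g.contains(sup.locus.pos)
        ]
        if not hits:
            dropped += 1
            continue
        for g in hits:
            per_gene[g.gene_id][sup.direction].append(sup)
    if dropped:
        logger.info("dropped %d supported loci outside every gene", dropped)

    calls: list[MobileGeneCall] = []
    n_s2r = n_r2s = n_bidir = 0
    for gene_id in sorted(per_gene):
        dirs = {
            d: ls
            for d, ls in per_gene[gene_id].items()
            if len(ls) >= cfg.min_support_snps
        }
        if not dirs:
            continue
        if SCION_TO_ROOTSTOCK in dirs:
            n_s2r += 1
        if ROOTSTOCK_TO_SCION in dirs:
            n_r2s += 1
        if len(dirs) == 2:
            n_bidir += 1
            direction = BIDIRECTIONAL
        else:
            direction = next(iter(dirs))
        supporting = [s for ls in dirs.values() for s in ls]
        calls.append(MobileGeneCall(gene_id, tissue, direction, supporting))
    tallies = {
        SCION_TO_ROOTSTOCK: n_s2r,
        ROOTSTOCK_TO_SCION: n_r2s,
        BIDIRECTIONAL: n_bidir,
        "union": n_s2r + n_r2s - n_bidir,
        "dropped_loci": dropped,
    }
    return calls, tallies


def call_mobile_genes(
    loci: Sequence[DiagnosticLocus],
    scion_rna: Sequence[SiteCounts],
    rootstock_rna: Sequence[SiteCounts],
    scion_control: Sequence[SiteCounts],
    rootstock_control: Sequence[SiteCounts],
    genes: GeneIndex,
    cfg: MobilityConfig | None = None,
    tissue: str = "leaf",
) -> tuple[list[MobileGeneCall], dict[str, int]]:
    """End-to-end mobility calling for one tissue from merged pileups."""
    cfg = cfg or MobilityConfig()
    sc_by_pos = {(s.chrom, s.pos): s for s in scion_rna}
    rs_by_pos = {(s.chrom, s.pos): s for s in rootstock_rna}
    sc_ctrl = {(s.chrom, s.pos): s for s in scion_control}
    rs_ctrl = {(s.chrom, s.pos): s for s in rootstock_control}
    supported: list[SupportedLocus] = []
    for locus in loci:
        key = (locus.chrom, locus.pos)
        # scion -> rootstock: look for scion allele in rootstock RNA
        sup = detect_mobility(
            locus,
            rs_by_pos.get(key),
            [rs_ctrl[key]] if key in rs_ctrl else [],
            cfg,
            SCION_TO_ROOTSTOCK,
        )
        if sup:
            supported.append(sup)
        sup = detect_mobility(
            locus,
            sc_by_pos.get(key),
            [sc_ctrl[key]] if key in sc_ctrl else [],
            cfg,
            ROOTSTOCK_TO_SCION,
        )
        if sup:
            supported.append(sup)
    return aggregate_genes(supported, genes, cfg, tissue)
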