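"""Synthetic reference, genotypes, and graft RNA pileups with a truth table.

The generator emulates the statistical structure the pipeline must handle:
two genotypes with asymmetric SNP density and heterozygosity (one highly
homozygous, one ~98% heterozygous), a configurable transition/transversion
ratio, mononucleotide-dominant InDels capped at 40 bp, and RNA pileups in
which planted mobile genes contribute donor-allele reads to the recipient
graft partner.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    BASES,
    HETEROZYGOUS,
    HOMOZYGOUS,
    GeneModel,
    SiteCounts,
    VariantRecord,
    reverse_complement,
)
from .mobile_detection import (
    BIDIRECTIONAL,
    ROOTSTOCK_TO_SCION,
    SCION_TO_ROOTSTOCK,
    DiagnosticLocus,
)

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

SCION = "scion"
ROOTSTOCK = "rootstock"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 200_000
    n_genes_per_chrom: int = 40
    # genotype structure (rootstock ~ homozygous, scion ~ heterozygous)
    snp_density_rootstock: float = 12.0  # per kb
    snp_density_scion: float = 8.0
    het_fraction_rootstock: float = 0.32
    het_fraction_scion: float = 0.98
    ts_tv: float = 1.75
    indel_density: float = 1.5  # per kb
    indel_geom_p: float = 0.55  # geometric length parameter
    indel_max_len: int = 40
    variant_mean_depth: float = 30.0
    # RNA model
    rna_depth: float = 60.0  # mean per replicate per site
    n_replicates: int = 3
    error_rate: float = 0.005
    donor_fraction: float = 0.10
    tissues: tuple[str, ...] = ("leaf", "stem")
    # mobility truth
    mobile_fraction: float = 0.25
    direction_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    min_diag_loci_per_mobile: int = 3

    def __post_init__(self) -> None:
        for f in (
            self.het_fraction_rootstock,
            self.het_fraction_scion,
            self.error_rate,
            self.donor_fraction,
            self.mobile_fraction,
        ):
            if not 0 <= f <= 1:
                raise ValueError(f"fraction {f} outside [0, 1]")
        if self.snp_density_rootstock <= 0 or self.snp_density_scion <= 0:
            raise ValueError("SNP densities must be positive")
        if self.indel_max_len > 40:
            raise ValueError("InDel length cap is 40")


@dataclass
class SimulationTruth:
    """Ground truth planted by the simulator, for recovery scoring."""

    diagnostic_loci: list[DiagnosticLocus] = field(default_factory=list)
    mobile_genes: dict[str, str] = field(default_factory=dict)  # gene -> direction
    diag_loci_by_gene: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "diagnostic_loci": [
                [l.chrom, l.pos, l.scion_allele, l.rootstock_allele]
                for l in self.diagnostic_loci
            ],
            "mobile_genes": self.mobile_genes,
            "diag_loci_by_gene": {
                g: [[c, p] for c, p in loci]
                for g, loci in self.diag_loci_by_gene.items()
            },
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)


@dataclass
class SimulationResult:
    genome: dict[str, str]
    genes: list[GeneModel]
    scion_variants: list[VariantRecord]
    rootstock_variants: list[VariantRecord]
    pileups: dict[str, list[SiteCounts]]
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, n)])


def _make_gene_pieces(
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """Transcript-order pieces as (sequence, kind, phase); phase only for CDS."""
    n_codons = int(rng.integers(60, 121))
    cds = (
        "ATG"
        + "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons)
        )
        + _STOPS[rng.integers(0, 3)]
    )
    utr5 = _random_seq(rng, int(rng.integers(20, 61)))
    utr3 = _random_seq(rng, int(rng.integers(20, 61)))
    n_introns = int(rng.integers(1, 3))
    cuts = sorted(rng.choice(np.arange(1, len(cds)), n_introns, replace=False))
    pieces: list[tuple[str, str, int]] = [(utr5, "utr5", 0)]
    prev = 0
    cum = 0
    for cut in [*cuts, len(cds)]:
        seg = cds[prev:cut]
        phase = (3 - cum % 3) % 3
        pieces.append((seg, "cds", phase))
        cum += len(seg)
        prev = cut
        if cut < len(cds):
            pieces.append((_random_seq(rng, int(rng.integers(60, 151))), "intron", 0))
    pieces.append((utr3, "utr3", 0))
    return pieces


def _gene_from_pieces(
    pieces: list[tuple[str, str, int]],
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
) -> tuple[GeneModel, str]:
    """Map transcript-order pieces onto genome coordinates at ``start``."""
    seq = "".join(p[0] for p in pieces)
    total = len(seq)
    if strand == "-":
        seq = reverse_complement(seq)
    intervals: list[tuple[int, int, str, int]] = []
    off = 0
    for piece, kind, phase in pieces:
        a, b = off, off + len(piece)  # transcript-order half-open offsets
        if strand == "+":
            gs, ge = start + a, start + b - 1
        else:
            gs, ge = start + total - b, start + total - a - 1
        intervals.append((gs, ge, kind, phase))
        off = b
    intervals.sort()
    cds = [(s, e, ph) for s, e, kind, ph in intervals if kind == "cds"]
    utr5 = [(s, e) for s, e, kind, _ in intervals if kind == "utr5"]
    utr3 = [(s, e) for s, e, kind, _ in intervals if kind == "utr3"]
    # merge contiguous non-intron stretches into exons
    exons: list[tuple[int, int]] = []
    for s, e, kind, _ in intervals:
        if kind == "intron":
            continue
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    model = GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )
    return model, seq


def simulate_reference(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with non-overlapping multi-exon genes (valid ORFs)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        background = list(_random_seq(rng, cfg.chrom_length))
        all_pieces = [_make_gene_pieces(rng) for _ in range(cfg.n_genes_per_chrom)]
        lengths = [sum(len(p[0]) for p in pieces) for pieces in all_pieces]
        n = cfg.n_genes_per_chrom
        free = cfg.chrom_length - sum(lengths) - (n + 1)  # 1 bp minimum gaps
        if free < 0:
            raise RuntimeError(
                "gene placement failed; lower n_genes_per_chrom or "
                "raise chrom_length"
            )
        # split the leftover space over the n+1 inter-gene gaps
        gaps = rng.multinomial(free, [1.0 / (n + 1)] * (n + 1)) + 1
        cursor = 1
        for gi, (pieces, glen) in enumerate(zip(all_pieces, lengths)):
            start = cursor + int(gaps[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene_{chrom}_{gi + 1:03d}"
            model, seq = _gene_from_pieces(pieces, gene_id, chrom, start, strand)
            background[start - 1 : start - 1 + glen] = list(seq)
            models.append(model)
            cursor = start + glen
        genome[chrom] = "".join(background)
    return genome, models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chrom}\tsim\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, (es, ee) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tsim\texon\t{es}\t{ee}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            for i, (cs, ce, ph) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t{ph}\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )
            for kind, ivs in (("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
                for i, (us, ue) in enumerate(ivs, 1):
                    fh.write(
                        f"{m.chrom}\tsim\t{kind}\t{us}\t{ue}\t.\t{m.strand}\t.\t"
                        f"ID={m.transcript_id}.{kind}{i};Parent={m.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_genotype(
    genome: dict[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    snp_density: float,
    het_fraction: float,
) -> list[VariantRecord]:
    """Plant SNPs and InDels on the reference at the requested density.

    The alt base of each SNP is the transition partner with probability
    TsTv/(TsTv+1), otherwise one of the two transversions uniformly.  InDel
    lengths are geometric, truncated at the 40 bp cap, so mononucleotide
    events dominate.
    """
    p_ts = cfg.ts_tv / (cfg.ts_tv + 1.0)
    records: list[VariantRecord] = []
    for chrom, seq in genome.items():
        length = len(seq)
        n_snps = int(round(snp_density * length / 1000.0))
        n_indels = int(round(cfg.indel_density * length / 1000.0))
        # leave headroom at the chromosome end for deletions
        usable = length - cfg.indel_max_len - 1
        all_pos = rng.choice(usable, size=n_snps + n_indels, replace=False) + 1
        snp_pos = np.sort(all_pos[:n_snps])
        indel_pos = np.sort(all_pos[n_snps:])
        for pos in snp_pos:
            ref = seq[pos - 1]
            if rng.random() < p_ts:
                alt = _TRANSITION[ref]
            else:
                choices = [b for b in BASES if b != ref and b != _TRANSITION[ref]]
                alt = choices[rng.integers(0, 2)]
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    qual=float(np.round(rng.uniform(35, 60), 1)),
                    depth=max(1, int(rng.poisson(cfg.variant_mean_depth))),
                    zygosity=(
                        HETEROZYGOUS if rng.random() < het_fraction else HOMOZYGOUS
                    ),
                )
            )
        for pos in indel_pos:
            ilen = min(int(rng.geometric(cfg.indel_geom_p)), cfg.indel_max_len)
            anchor = seq[pos - 1]
            if rng.random() < 0.5:  # insertion
                ref, alt = anchor, anchor + _random_seq(rng, ilen)
            else:  # deletion
                ref, alt = seq[pos - 1 : pos + ilen], anchor
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    qual=float(np.round(rng.uniform(35, 60), 1)),
                    depth=max(1, int(rng.poisson(cfg.variant_mean_depth))),
                    zygosity=(
                        HETEROZYGOUS if rng.random() < het_fraction else HOMOZYGOUS
                    ),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


# ---------------------------------------------------------------------------
# Graft RNA pileups
# ---------------------------------------------------------------------------


def _genotype_alleles(
    variants: Sequence[VariantRecord],
) -> dict[tuple[str, int], tuple[str, str]]:
    """SNP genotype per position: hom-alt -> (alt, alt), het -> (ref, alt)."""
    out: dict[tuple[str, int], tuple[str, str]] = {}
    for v in variants:
        if not v.is_snp:
            continue
        out[(v.chrom, v.pos)] = (
            (v.alt, v.alt) if v.zygosity == HOMOZYGOUS else (v.ref, v.alt)
        )
    return out


def _planted_diagnostics(
    exonic: list[tuple[str, int]],
    genome: dict[str, str],
    scion_gt: dict[tuple[str, int], tuple[str, str]],
    rootstock_gt: dict[tuple[str, int], tuple[str, str]],
) -> list[tuple[str, int, str, str]]:
    """(chrom, pos, scion allele, rootstock allele) at divergent hom sites."""
    out = []
    for chrom, pos in exonic:
        ref = genome[chrom][pos - 1]
        sc = scion_gt.get((chrom, pos), (ref, ref))
        rs = rootstock_gt.get((chrom, pos), (ref, ref))
        if sc[0] != sc[1] or rs[0] != rs[1] or sc[0] == rs[0]:
            continue
        out.append((chrom, pos, sc[0], rs[0]))
    return out


def _apply_errors(
    counts: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each read to one of the 3 other bases with prob ``error_rate``."""
    if error_rate <= 0:
        return counts
    out = counts.copy()
    for b in range(4):
        errs = rng.binomial(counts[:, b], error_rate)
        out[:, b] -= errs
        others = [o for o in range(4) if o != b]
        e1 = rng.binomial(errs, 1 / 3)
        e2 = rng.binomial(errs - e1, 1 / 2)
        out[:, others[0]] += e1
        out[:, others[1]] += e2
        out[:, others[2]] += errs - e1 - e2
    return out


def simulate_graft_pileups(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    scion_variants: Sequence[VariantRecord],
    rootstock_variants: Sequence[VariantRecord],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[SiteCounts]], SimulationTruth]:
    """Per-library exonic base counts plus the planted mobility truth table.

    Libraries are named ``{tissue}_{partner}_rep{i}`` for grafted material and
    ``control_{partner}_rep{i}`` for the pre-graft controls (which carry no
    donor reads).  Mobile genes receive donor-allele reads at
    ``donor_fraction`` of site depth in the designated recipient partner.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    gene_sites: list[tuple[str, int, int]] = []  # (chrom, pos, gene index)
    for gi, g in enumerate(genes):
        for es, ee in g.exons:
            for pos in range(es, ee + 1):
                gene_sites.append((g.chrom, pos, gi))

    exonic = [(c, p) for c, p, _ in gene_sites]
    scion_gt = _genotype_alleles(scion_variants)
    rootstock_gt = _genotype_alleles(rootstock_variants)
    diagnostics = _planted_diagnostics(exonic, genome, scion_gt, rootstock_gt)
    diag_set = {(c, p) for c, p, _, _ in diagnostics}
    diag_by_gene: dict[str, list[tuple[str, int]]] = {}
    for chrom, pos, gi in gene_sites:
        if (chrom, pos) in diag_set:
            diag_by_gene.setdefault(genes[gi].gene_id, []).append((chrom, pos))

    eligible = [
        g.gene_id
        for g in genes
        if len(diag_by_gene.get(g.gene_id, [])) >= cfg.min_diag_loci_per_mobile
    ]
    n_mobile = int(round(cfg.mobile_fraction * len(genes)))
    if n_mobile > len(eligible):
        raise RuntimeError(
            f"only {len(eligible)} genes have >= {cfg.min_diag_loci_per_mobile} "
            f"exonic diagnostic loci but {n_mobile} mobile genes requested; "
            "raise SNP density or lower mobile_fraction"
        )
    chosen = sorted(
        rng.choice(np.array(sorted(eligible)), size=n_mobile, replace=False)
    )
    dirs = rng.choice(
        [SCION_TO_ROOTSTOCK, ROOTSTOCK_TO_SCION, BIDIRECTIONAL],
        size=n_mobile,
        p=list(cfg.direction_probs),
    )
    mobile: dict[str, str] = {g: d for g, d in zip(chosen, dirs)}

    truth = SimulationTruth(
        diagnostic_loci=[
            DiagnosticLocus(c, p, sa, ra) for c, p, sa, ra in diagnostics
        ],
        mobile_genes=mobile,
        diag_loci_by_gene=diag_by_gene,
    )

    n_sites = len(gene_sites)
    site_chrom = [c for c, _, _ in gene_sites]
    site_pos = np.array([p for _, p, _ in gene_sites])
    ref_bases = [genome[c][p - 1] for c, p, _ in gene_sites]

    def allele_arrays(
        gt: dict[tuple[str, int], tuple[str, str]]
    ) -> tuple[np.ndarray, np.ndarray]:
        a1 = np.empty(n_sites, dtype=np.int8)
        a2 = np.empty(n_sites, dtype=np.int8)
        for i, (c, p, _) in enumerate(gene_sites):
            x, y = gt.get((c, p), (ref_bases[i], ref_bases[i]))
            a1[i] = _BASE_IDX[x]
            a2[i] = _BASE_IDX[y]
        return a1, a2

    partner_alleles = {
        SCION: allele_arrays(scion_gt),
        ROOTSTOCK: allele_arrays(rootstock_gt),
    }
    gene_dir = np.array(
        [mobile.get(genes[gi].gene_id, "") for _, _, gi in gene_sites]
    )
    receives = {
        # donor reads appear in the *recipient* partner's graft libraries
        ROOTSTOCK: np.isin(gene_dir, [SCION_TO_ROOTSTOCK, BIDIRECTIONAL]),
        SCION: np.isin(gene_dir, [ROOTSTOCK_TO_SCION, BIDIRECTIONAL]),
    }
    donor_of = {ROOTSTOCK: SCION, SCION: ROOTSTOCK}

    def make_library(partner: str, with_donor: bool) -> list[SiteCounts]:
        counts = np.zeros((n_sites, 4), dtype=np.int64)
        depth = rng.poisson(cfg.rna_depth, n_sites)
        donor_n = np.zeros(n_sites, dtype=np.int64)
        if with_donor:
            mask = receives[partner]
            donor_n[mask] = rng.binomial(depth[mask], cfg.donor_fraction)
        rec_n = depth - donor_n
        a1, a2 = partner_alleles[partner]
        het = a1 != a2
        n1 = np.where(het, rng.binomial(rec_n, 0.5), rec_n)
        n2 = rec_n - n1
        np.add.at(counts, (np.arange(n_sites), a1), n1)
        np.add.at(counts, (np.arange(n_sites), a2), n2)
        d1, d2 = partner_alleles[donor_of[partner]]
        dhet = d1 != d2
        m1 = np.where(dhet, rng.binomial(donor_n, 0.5), donor_n)
        np.add.at(counts, (np.arange(n_sites), d1), m1)
        np.add.at(counts, (np.arange(n_sites), d2), donor_n - m1)
        counts = _apply_errors(counts, cfg.error_rate, rng)
        return [
            SiteCounts(site_chrom[i], int(site_pos[i]), *map(int, counts[i]))
            for i in range(n_sites)
        ]

    pileups: dict[str, list[SiteCounts]] = {}
    for tissue in cfg.tissues:
        for partner in (SCION, ROOTSTOCK):
            for rep in range(1, cfg.n_replicates + 1):
                pileups[f"{tissue}_{partner}_rep{rep}"] = make_library(
                    partner, with_donor=True
                )
    for partner in (SCION, ROOTSTOCK):
        for rep in range(1, cfg.n_replicates + 1):
            pileups[f"control_{partner}_rep{rep}"] = make_library(
                partner, with_donor=False
            )
    return pileups, truth


def write_pileup(
    sites: Sequence[SiteCounts], genome: dict[str, str], path: str | Path
) -> None:
    """Emit samtools-mpileup-style text (ref matches rendered as '.')."""
    with open(path, "w") as fh:
        for s in sites:
            ref = genome[s.chrom][s.pos - 1]
            bases = []
            for b in BASES:
                n = s.count(b)
                bases.append(("." if b == ref else b) * n)
            bases_s = "".join(bases)
            fh.write(
                f"{s.chrom}\t{s.pos}\t{ref}\t{s.depth}\t{bases_s}\t"
                f"{'I' * s.depth}\n"
            )


def simulate_all(cfg: SimulationConfig) -> SimulationResult:
    """Run the full generator: reference, two genotypes, graft pileups."""
    rng = np.random.default_rng(cfg.seed)
    genome, genes = simulate_reference(cfg, rng)
    rootstock = simulate_genotype(
        genome, cfg, rng, cfg.snp_density_rootstock, cfg.het_fraction_rootstock
    )
    scion = simulate_genotype(
        genome, cfg, rng, cfg.snp_density_scion, cfg.het_fraction_scion
    )
    pileups, truth = simulate_graft_pileups(genome, genes, scion, rootstock, cfg, rng)
    return SimulationResult(genome, genes, scion, rootstock, pileups, truth)
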