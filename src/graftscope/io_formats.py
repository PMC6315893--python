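"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 1-based inclusive (VCF/GFF3 native); no half-open
conversions are exposed to callers.  InDels are stored VCF-style with an
anchor base (``ref="AT", alt="A"`` is a 1 bp deletion).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
from Bio import SeqIO

BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending location."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (SNP or InDel) against the reference."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    zygosity: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.zygosity not in (HOMOZYGOUS, HETEROZYGOUS):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        """Anchored length difference; 0 for SNPs."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) < len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """Stranded transcript structure for consequence calls.

    Intervals are 1-based inclusive ``(start, end)`` tuples, sorted by start
    and non-overlapping within the transcript.  ``cds`` carries GFF3 phase.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    low_confidence: bool = False  # CDS length not divisible by 3

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for ivs in (self.exons, [(s, e) for s, e, _ in self.cds]):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping intervals in {self.transcript_id}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e

    def region_of(self, pos: int) -> str | None:
        """Sub-region at ``pos``: CDS, UTR, intron, or None outside the span."""
        if not self.contains(pos):
            return None
        for s, e, _ in self.cds:
            if s <= pos <= e:
                return "CDS"
        for s, e in self.exons:
            if s <= pos <= e:
                return "UTR"
        return "intron"

    def coding_offset(self, pos: int) -> int:
        """0-based offset of ``pos`` within the coding sequence (5'->3')."""
        intervals = self.cds if self.strand == "+" else list(reversed(self.cds))
        off = 0
        for s, e, _ in intervals:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        raise ValueError(f"{pos} not in CDS of {self.transcript_id}")

    def coding_sequence(self, genome: dict[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = [chrom_seq[s - 1 : e] for s, e, _ in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()


@dataclass(frozen=True)
class SiteCounts:
    """Per-position A/C/G/T read counts from an RNA pileup."""

    chrom: str
    pos: int
    count_a: int = 0
    count_c: int = 0
    count_g: int = 0
    count_t: int = 0

    @property
    def depth(self) -> int:
        return self.count_a + self.count_c + self.count_g + self.count_t

    def count(self, base: str) -> int:
        return {
            "A": self.count_a,
            "C": self.count_c,
            "G": self.count_g,
            "T": self.count_t,
        }[base.upper()]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.count_a, self.count_c, self.count_g, self.count_t)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_SPLIT = re.compile(r"[/|]")


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Parse a VCF 4.x file into one record per (row, alt allele).

    Zygosity comes from the first sample's GT field; depth from the sample DP
    (falling back to INFO DP).  Records are returned sorted by (chrom, pos).
    Only the first sample of multi-sample files is consulted.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"line {lineno}: expected >= 10 VCF columns, got {len(fields)}"
                )
            chrom, pos_s, _, ref, alt_s, qual_s = fields[0:6]
            fmt, sample = fields[8], fields[9]
            try:
                pos = int(pos_s)
                qual = float(qual_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            fmt_keys = fmt.split(":")
            sample_vals = sample.split(":")
            if "GT" not in fmt_keys:
                raise FormatError(f"line {lineno}: missing GT in FORMAT")
            gt = sample_vals[fmt_keys.index("GT")]
            alleles = _GT_SPLIT.split(gt)
            if "." in alleles:
                raise FormatError(f"line {lineno}: missing genotype call {gt!r}")
            depth = _extract_depth(fmt_keys, sample_vals, fields[7], lineno)
            zygosity = HOMOZYGOUS if len(set(alleles)) == 1 else HETEROZYGOUS
            for alt in alt_s.split(","):
                if alt in (".", "*"):
                    continue
                try:
                    records.append(
                        VariantRecord(chrom, pos, ref, alt, qual, depth, zygosity)
                    )
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def _extract_depth(
    fmt_keys: list[str], sample_vals: list[str], info: str, lineno: int
) -> int:
    if "DP" in fmt_keys and len(sample_vals) > fmt_keys.index("DP"):
        raw = sample_vals[fmt_keys.index("DP")]
    else:
        m = re.search(r"(?:^|;)DP=(\d+)", info)
        if not m:
            raise FormatError(f"line {lineno}: no DP in sample or INFO")
        raw = m.group(1)
    try:
        return int(raw)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: bad DP {raw!r}") from exc


def write_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal single-sample VCF (GT:DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n"
        )
        for r in records:
            gt = "1/1" if r.zygosity == HOMOZYGOUS else "0/1"
            qual = f"{r.qual:g}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\tPASS\t.\t"
                f"GT:DP\t{gt}:{r.depth}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _subtract_intervals(
    exons: Sequence[tuple[int, int]], cds: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Exon minus CDS, as sorted 1-based inclusive intervals."""
    out: list[tuple[int, int]] = []
    for es, ee in exons:
        cuts = [(max(es, s), min(ee, e)) for s, e in cds if s <= ee and e >= es]
        cur = es
        for s, e in sorted(cuts):
            if s > cur:
                out.append((cur, s - 1))
            cur = max(cur, e + 1)
        if cur <= ee:
            out.append((cur, ee))
    return out


def read_gff3(path: str | Path, fasta: str | Path | dict[str, str]) -> list[GeneModel]:
    """Load one GeneModel per mRNA from a GFF3 file.

    UTRs are taken from five_prime_UTR/three_prime_UTR features when present,
    otherwise inferred as exon minus CDS split by position relative to the CDS.
    A CDS whose total length is not a multiple of 3 flags the model
    low-confidence rather than failing.
    """
    genome = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [
            (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
            for f in db.children(mrna, featuretype="CDS")
        ]
        if not cds:
            continue
        if mrna.seqid not in genome:
            raise FormatError(
                f"CDS of {mrna.id} references absent chromosome {mrna.seqid!r}"
            )
        utr5 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="five_prime_UTR")
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="three_prime_UTR")
        ]
        if not exons:
            exons = sorted(
                [(s, e) for s, e, _ in cds] + utr5 + utr3
            ) or [(min(s for s, _, _ in cds), max(e for _, e, _ in cds))]
        if not utr5 and not utr3:
            leftover = _subtract_intervals(sorted(exons), [(s, e) for s, e, _ in cds])
            cds_start = min(s for s, _, _ in cds)
            cds_end = max(e for _, e, _ in cds)
            left = [iv for iv in leftover if iv[1] < cds_start]
            right = [iv for iv in leftover if iv[0] > cds_end]
            utr5, utr3 = (left, right) if mrna.strand == "+" else (right, left)
        total = sum(e - s + 1 for s, e, _ in cds)
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=sorted(exons),
                cds=sorted(cds),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
                low_confidence=(total % 3 != 0),
            )
        )
    return models


# ---------------------------------------------------------------------------
# samtools mpileup text
# ---------------------------------------------------------------------------


def _parse_pileup_bases(bases: str, ref: str, where: str) -> dict[str, int]:
    counts = {b: 0 for b in BASES}
    ref = ref.upper()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # read start: skip mapping-quality char too
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"{where}: indel block without length after {c!r}")
            i = j + int(bases[i + 1 : j])
        else:
            u = c.upper()
            if c in ".,":
                if ref in counts:
                    counts[ref] += 1
            elif u in counts:
                counts[u] += 1
            # '*', 'N', '<', '>' carry no base information
            i += 1
    return counts


def read_pileup(path: str | Path) -> list[SiteCounts]:
    """Parse samtools mpileup text into per-site A/C/G/T counts.

    '.'/',' resolve to the reference base; indel blocks, read-start and
    read-end markers are skipped; counts are strand-collapsed.
    """
    sites: list[SiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected >= 4 pileup columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            bases = fields[4] if len(fields) > 4 else ""
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            counts = _parse_pileup_bases(bases, ref, f"line {lineno} ({chrom}:{pos})")
            sites.append(
                SiteCounts(
                    chrom,
                    pos,
                    count_a=counts["A"],
                    count_c=counts["C"],
                    count_g=counts["G"],
                    count_t=counts["T"],
                )
            )
    return sites


def write_site_counts_tsv(sites: Iterable[SiteCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tA\tC\tG\tT\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.count_a}\t{s.count_c}\t{s.count_g}\t{s.count_t}\n"
            )


def iter_by_chrom(
    records: Sequence[VariantRecord],
) -> Iterator[tuple[str, list[VariantRecord]]]:
    """Group sorted records by chromosome, preserving order."""
    from itertools import groupby

    for chrom, group in groupby(records, key=lambda r: r.chrom):
        yield chrom, list(group)
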