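"""Two-genotype variant partitioning and summary statistics.

Everything downstream reports ratios and percentages at two decimals with
half-away-from-zero rounding, matching the conventional printed style of
variant-survey tables.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .io_formats import HETEROZYGOUS, HOMOZYGOUS, VariantRecord
from .variant_annotation import ConsequenceCall, substitution_class

INDEL_LENGTH_CAP = 40


def round2(x: float) -> float:
    """Round to two decimals, half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percentage(part: int, total: int) -> float:
    """``part`` as a 2-decimal percentage of ``total``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round2(100.0 * part / total)


# ---------------------------------------------------------------------------
# Specific / common partition
# ---------------------------------------------------------------------------


@dataclass
class PartitionResult:
    """Exact-key partition of two variant sets: common, specific-A, specific-B."""

    common: list[VariantRecord]
    specific_a: list[VariantRecord]
    specific_b: list[VariantRecord]

    def counts(self) -> dict[str, int]:
        def split(recs: Sequence[VariantRecord]) -> dict[str, int]:
            snp = sum(1 for r in recs if r.is_snp)
            return {"snp": snp, "indel": len(recs) - snp, "total": len(recs)}

        return {
            "common": split(self.common),
            "specific_a": split(self.specific_a),
            "specific_b": split(self.specific_b),
        }


def partition(
    variants_a: Sequence[VariantRecord], variants_b: Sequence[VariantRecord]
) -> PartitionResult:
    """Split by exact (chrom, pos, ref, alt) identity; duplicates are errors."""
    keys_a = _keyed(variants_a, "A")
    keys_b = _keyed(variants_b, "B")
    common_keys = keys_a.keys() & keys_b.keys()
    return PartitionResult(
        common=[keys_a[k] for k in sorted(common_keys)],
        specific_a=[keys_a[k] for k in sorted(keys_a.keys() - common_keys)],
        specific_b=[keys_b[k] for k in sorted(keys_b.keys() - common_keys)],
    )


def _keyed(
    variants: Sequence[VariantRecord], label: str
) -> dict[tuple[str, int, str, str], VariantRecord]:
    out: dict[tuple[str, int, str, str], VariantRecord] = {}
    for v in variants:
        if v.key in out:
            raise ValueError(f"duplicate key {v.key} in input {label}")
        out[v.key] = v
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class VariantSummary:
    n_snps: int = 0
    n_indels: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    n_heterozygous: int = 0
    n_homozygous: int = 0
    pct_heterozygous: float | None = None
    pct_homozygous: float | None = None
    n_transitions: int = 0
    n_transversions: int = 0
    ts_tv_ratio: float | None = None
    n_genic: int = 0
    n_intergenic: int = 0
    pct_genic: float | None = None
    region_counts: dict[str, int] = field(default_factory=dict)
    effect_counts: dict[str, int] = field(default_factory=dict)
    impact_counts: dict[str, int] = field(default_factory=dict)
    functional_class_counts: dict[str, int] = field(default_factory=dict)
    n_terminal_codon: int = 0
    missense_silent_ratio: float | None = None
    indel_length_hist: dict[int, int] = field(default_factory=dict)
    per_chrom_counts: dict[str, int] = field(default_factory=dict)
    per_chrom_density: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def zygosity_percentages(n_het: int, n_hom: int) -> tuple[float, float]:
    """Heterozygous/homozygous shares of a SNP set, 2-decimal percentages."""
    total = n_het + n_hom
    return percentage(n_het, total), percentage(n_hom, total)


def ts_tv_ratio(n_ts: int, n_tv: int) -> float:
    """Transition/transversion count ratio at 2 decimals."""
    if n_tv <= 0:
        raise ValueError("transversion count must be positive")
    return round2(n_ts / n_tv)


def functional_class_ratio(n_missense: int, n_silent: int) -> float | None:
    """Missense/silent ratio at 2 decimals; None when silent is zero."""
    if n_silent == 0:
        return None
    return round2(n_missense / n_silent)


def union_with_overlap(count_a: int, count_b: int, count_both: int) -> int:
    """Inclusion-exclusion union of two overlapping gene sets."""
    if count_both > min(count_a, count_b) or min(count_a, count_b, count_both) < 0:
        raise ValueError(
            f"overlap {count_both} exceeds a set size ({count_a}, {count_b})"
        )
    return count_a + count_b - count_both


def indel_length_spectrum(
    indels: Iterable[VariantRecord],
) -> tuple[dict[int, int], dict[int, float]]:
    """Histogram of anchored InDel lengths plus 2-decimal percent fractions.

    Lengths above the 40 bp cap are binned at 40 with a warning.
    """
    hist: Counter[int] = Counter()
    for v in indels:
        if not v.is_indel:
            continue
        length = v.indel_length
        if length > INDEL_LENGTH_CAP:
            warnings.warn(
                f"InDel length {length} exceeds {INDEL_LENGTH_CAP}; binned as 40+",
                stacklevel=2,
            )
            length = INDEL_LENGTH_CAP
        hist[length] += 1
    total = sum(hist.values())
    fractions = {
        length: percentage(n, total) for length, n in sorted(hist.items())
    }
    return dict(sorted(hist.items())), fractions


def summarize(
    variants: Sequence[VariantRecord],
    annotations: Sequence[ConsequenceCall] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> VariantSummary:
    """Populate every summary field derivable from the inputs.

    Densities are variants per 100 kb and require ``chrom_lengths``; a
    chromosome with variants but no length is an error for the density
    fields only.
    """
    s = VariantSummary()
    snps = [v for v in variants if v.is_snp]
    indels = [v for v in variants if v.is_indel]
    s.n_snps = len(snps)
    s.n_indels = len(indels)
    s.n_insertions = sum(1 for v in indels if v.is_insertion)
    s.n_deletions = sum(1 for v in indels if v.is_deletion)
    s.n_heterozygous = sum(1 for v in snps if v.zygosity == HETEROZYGOUS)
    s.n_homozygous = sum(1 for v in snps if v.zygosity == HOMOZYGOUS)
    if s.n_snps:
        s.pct_heterozygous, s.pct_homozygous = zygosity_percentages(
            s.n_heterozygous, s.n_homozygous
        )
        classes = Counter(substitution_class(v.ref, v.alt) for v in snps)
        s.n_transitions = classes["transition"]
        s.n_transversions = classes["transversion"]
        if s.n_transversions:
            s.ts_tv_ratio = ts_tv_ratio(s.n_transitions, s.n_transversions)
    s.indel_length_hist, _ = (
        indel_length_spectrum(indels) if indels else ({}, {})
    )

    if annotations is not None:
        by_key = {a.key: a for a in annotations}
        calls = [by_key[v.key] for v in variants if v.key in by_key]
        if len(calls) != len(variants):
            missing = len(variants) - len(calls)
            raise ValueError(f"{missing} variants lack annotations")
        s.n_genic = sum(1 for a in calls if a.region != "intergenic")
        s.n_intergenic = len(calls) - s.n_genic
        if variants:
            s.pct_genic = percentage(s.n_genic, len(variants))
        s.region_counts = dict(
            Counter(a.region for a in calls if a.region != "intergenic")
        )
        s.effect_counts = dict(Counter(a.effect for a in calls))
        s.impact_counts = dict(Counter(a.impact for a in calls))
        s.functional_class_counts = dict(
            Counter(a.functional_class for a in calls)
        )
        s.n_terminal_codon = sum(1 for a in calls if a.in_terminal_codon)
        s.missense_silent_ratio = functional_class_ratio(
            s.functional_class_counts.get("missense", 0),
            s.functional_class_counts.get("silent", 0),
        )

    chrom_counts = Counter(v.chrom for v in variants)
    s.per_chrom_counts = dict(sorted(chrom_counts.items()))
    if chrom_lengths is not None:
        for chrom, n in s.per_chrom_counts.items():
            if chrom not in chrom_lengths:
                raise ValueError(f"missing chromosome length for {chrom!r}")
            s.per_chrom_density[chrom] = round2(n / (chrom_lengths[chrom] / 100_000))
    return s
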