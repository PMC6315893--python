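"""Post-calling variant filters: quality, relative coverage, SNP density.

Filters run in the order quality -> coverage -> density, with the mean depth
computed on the unfiltered input.  The density rule applies to SNPs only;
InDels pass it untouched but are still subject to quality and coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import VariantRecord


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 30.0
    coverage_low_factor: float = 0.5
    coverage_high_factor: float = 2.0
    density_window: int = 10
    density_max_snps: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.coverage_low_factor < self.coverage_high_factor):
            raise ValueError("need 0 < coverage_low_factor < coverage_high_factor")
        if self.density_window < 1 or self.density_max_snps < 1:
            raise ValueError("density_window and density_max_snps must be >= 1")


@dataclass
class FilterTally:
    removed_quality: int = 0
    removed_coverage: int = 0
    removed_density: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "removed_quality": self.removed_quality,
            "removed_coverage": self.removed_coverage,
            "removed_density": self.removed_density,
            "retained": self.retained,
        }


def mean_depth(records: Sequence[VariantRecord]) -> float:
    """Arithmetic mean of per-variant depths (proxy for mapped-read coverage)."""
    if not records:
        raise ValueError("cannot compute mean depth of empty record set")
    return sum(r.depth for r in records) / len(records)


def filter_quality(
    records: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Drop records with qual below the threshold (qual == threshold survives)."""
    return [r for r in records if r.qual >= cfg.min_qual]


def filter_coverage(
    records: Sequence[VariantRecord], mean: float, cfg: FilterConfig
) -> list[VariantRecord]:
    """Keep records whose depth lies in [low_factor*mean, high_factor*mean]."""
    if mean <= 0:
        raise ValueError("mean depth must be positive")
    lo = cfg.coverage_low_factor * mean
    hi = cfg.coverage_high_factor * mean
    return [r for r in records if lo <= r.depth <= hi]


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError(
                f"records not sorted: {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def filter_density(
    records: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Remove every SNP lying in any dense window; InDels pass through.

    A window is any run of ``density_window`` consecutive bases on one
    chromosome; it is dense when it contains more than ``density_max_snps``
    SNPs.  Every SNP of a dense window is removed (whole-cluster semantics),
    which makes the result independent of evaluation order.
    """
    _check_sorted(records)
    w = cfg.density_window
    doomed: set[int] = set()
    # Group SNP indices per chromosome; anchoring candidate windows at SNP
    # positions is exhaustive: any dense window shifted right to its first
    # SNP contains a superset of its SNPs.
    by_chrom: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        if r.is_snp:
            by_chrom.setdefault(r.chrom, []).append(idx)
    for idxs in by_chrom.values():
        positions = [records[i].pos for i in idxs]
        j = 0
        for i in range(len(positions)):
            if j < i:
                j = i
            while j < len(positions) and positions[j] <= positions[i] + w - 1:
                j += 1
            if j - i > cfg.density_max_snps:
                doomed.update(idxs[i:j])
    return [r for idx, r in enumerate(records) if idx not in doomed]


def apply_filters(
    records: Sequence[VariantRecord],
    cfg: FilterConfig | None = None,
    mean: float | None = None,
) -> tuple[list[VariantRecord], FilterTally]:
    """Quality -> coverage -> density, with a per-stage removal tally.

    The coverage filter uses ``mean`` when given; otherwise the mean depth of
    the *input* records, computed before any removal.  Re-applying with the
    same mean is idempotent; recomputing the mean on already-filtered records
    would shift the coverage bounds.
    """
    cfg = cfg or FilterConfig()
    tally = FilterTally()
    if not records:
        return [], tally
    if mean is None:
        mean = mean_depth(records)
    after_qual = filter_quality(records, cfg)
    tally.removed_quality = len(records) - len(after_qual)
    after_cov = filter_coverage(after_qual, mean, cfg)
    tally.removed_coverage = len(after_qual) - len(after_cov)
    after_dens = filter_density(after_cov, cfg)
    tally.removed_density = len(after_cov) - len(after_dens)
    tally.retained = len(after_dens)
    return after_dens, tally
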