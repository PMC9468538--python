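"""Hotspot distribution over five equal-length bins per chromosome.

Each chromosome is cut into ``n_bins`` (default 5) segments of equal length on
the chosen scale — genetic (cM) or physical (Mb) — and every hotspot is placed
once, by the midpoint of its CI on that scale.  Comparing the two
distributions exposes the recombination landscape: positions uniform on the
genetic map pile up in the telomeric physical bins because recombination is
suppressed around the centromere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .hotspots import Hotspot
from .io_model import ValidationError

__all__ = ["BinDistribution", "assign_bin", "bin_distribution", "chi_square_uniform"]


@dataclass(frozen=True)
class BinDistribution:
    """Pooled hotspot counts per bin index (1-based) on one scale."""

    scale: str  # "genetic" | "physical"
    counts: Mapping[int, int]
    percentages: Mapping[int, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def assign_bin(position: float, chrom_length: float, n_bins: int = 5) -> int:
    """1-based index of the equal-length bin containing ``position``.

    A position exactly at the chromosome length falls in the last bin.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if not (0.0 <= position <= chrom_length):
        raise ValidationError(
            f"position {position} outside chromosome [0, {chrom_length}]"
        )
    return min(int(math.floor(n_bins * position / chrom_length)) + 1, n_bins)


def bin_distribution(
    hotspots: Sequence[Hotspot],
    lengths: Mapping[str, float],
    scale: str,
    n_bins: int = 5,
    reference: str = "Svevo",
) -> BinDistribution:
    """Place every hotspot by CI midpoint and pool counts across chromosomes.

    ``lengths`` maps chromosome to its total length on the requested scale
    (cM for genetic, Mb for physical).  For the physical scale the hotspot
    must already carry a physical CI for ``reference``.
    """
    if scale not in ("genetic", "physical"):
        raise ValidationError(f"unknown scale {scale!r}")
    counts = {b: 0 for b in range(1, n_bins + 1)}
    for h in hotspots:
        if h.chromosome not in lengths:
            raise ValidationError(f"no {scale} length for {h.chromosome}")
        if scale == "genetic":
            mid = (h.ci_start_cM + h.ci_end_cM) / 2.0
        else:
            if reference not in h.physical_ci_Mb:
                raise ValidationError(
                    f"hotspot {h.hotspot_id}: no physical CI on {reference}"
                )
            lo, hi = h.physical_ci_Mb[reference]
            mid = (lo + hi) / 2.0
        length = lengths[h.chromosome]
        mid = min(max(mid, 0.0), length)  # clamp extrapolated midpoints
        counts[assign_bin(mid, length, n_bins)] += 1
    total = sum(counts.values())
    percentages = {
        b: (100.0 * c / total if total else 0.0) for b, c in counts.items()
    }
    return BinDistribution(scale=scale, counts=counts, percentages=percentages)


def chi_square_uniform(dist: BinDistribution) -> tuple[float, float]:
    """Chi-square goodness of fit of the pooled counts against uniformity.

    Test helper only; the pipeline reports descriptive counts, not p-values.
    """
    from scipy.stats import chisquare

    observed = [dist.counts[b] for b in sorted(dist.counts)]
    stat, p = chisquare(observed)
    return float(stat), float(p)
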