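"""QTL-hotspot calling from projected MTAs: the statistical core.

Each MTA's 95% confidence interval of width CI is read as a Gaussian
positional uncertainty with standard deviation s = CI/3.92 (3.92 = 2 x 1.96),
so s^2 = (CI/3.92)^2.  The per-cM *overview index* u of a 1-cM bin [k, k+1)
is the total Gaussian probability mass the MTAs on that chromosome place in
the bin:

    u_k = sum_i [ Phi((k+1 - mu_i)/s_i) - Phi((k - mu_i)/s_i) ]

where mu_i is the projected position and Phi the standard normal CDF.  Mass
falling beyond the chromosome ends is truncated, not renormalized, so each MTA
contributes at most 1 in total and the genome-wide mean of u approximates
N_MTA / total map length.

Hotspots are contiguous supra-threshold runs around local maxima of u, merged
across small gaps; the high threshold is five times the empirical genome-wide
mean.  "Breeding" hotspots additionally need a narrow physical interval
(< 20 Mb on the primary assembly) and enough well-supported effect: mean PVE
>= 0.04 with >= 5 member MTAs, or mean PVE > 0.1 with 3-4 members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .io_model import GeneticMap, ValidationError
from .projection import ProjectedMTA, genetic_to_physical
from .io_model import AnchorTable

__all__ = [
    "CI_TO_SD",
    "StandardizedMTA",
    "OverviewProfile",
    "Peak",
    "Hotspot",
    "standardize",
    "overview_index",
    "mean_threshold",
    "high_threshold",
    "detect_peaks",
    "merge_peaks",
    "attach_physical",
    "select_breeding",
]

CI_TO_SD = 3.92  # 95% CI width -> Gaussian sd (2 * 1.96)


@dataclass(frozen=True)
class StandardizedMTA:
    """A projected MTA with its Gaussian positional sd s = CI/3.92."""

    mta: ProjectedMTA
    s: float
    s_squared: float

    @property
    def position_cM(self) -> float:
        return self.mta.position_cM

    @property
    def chromosome(self) -> str:
        return self.mta.chromosome


@dataclass(frozen=True)
class OverviewProfile:
    """Overview-index values on the 1-cM grid of one chromosome.

    Bin k is [k, k+1) cM, 0-based, left edge at 0; the grid covers
    ceil(chromosome length) bins.
    """

    chromosome: str
    u: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.u)

    def __post_init__(self) -> None:
        if np.any(self.u < -1e-12):
            raise ValidationError(f"{self.chromosome}: negative overview index")


@dataclass(frozen=True)
class Peak:
    """A local maximum of u above threshold, with its supra-threshold run."""

    chromosome: str
    bin: int
    u: float
    run_start: int
    run_end: int  # inclusive bin index


@dataclass(frozen=True)
class Hotspot:
    """A merged supra-threshold region with its member MTAs."""

    hotspot_id: int
    chromosome: str
    ci_start_cM: float
    ci_end_cM: float
    member_ids: tuple[str, ...]
    traits: tuple[str, ...]
    pve_mean: float | None
    physical_ci_Mb: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    is_breeding: bool = False

    @property
    def n_mta(self) -> int:
        return len(self.member_ids)

    def physical_width_Mb(self, reference: str) -> float:
        lo, hi = self.physical_ci_Mb[reference]
        return abs(hi - lo)


def standardize(mta: ProjectedMTA) -> StandardizedMTA:
    """Convert the CI width to the Gaussian sd (s = CI/3.92, s^2 its square)."""
    if mta.ci_cM is None or mta.ci_cM <= 0:
        raise ValidationError(
            f"{mta.mta_id}: CI must be present and positive before standardization"
        )
    s = mta.ci_cM / CI_TO_SD
    return StandardizedMTA(mta=mta, s=s, s_squared=s * s)


def overview_index(
    mtas: Sequence[StandardizedMTA], gmap: GeneticMap
) -> dict[str, OverviewProfile]:
    """Per-cM overview index on every chromosome of the map.

    Every chromosome in ``gmap`` gets a profile (zero where it carries no MTA);
    an MTA on a chromosome missing from the map is an error.
    """
    by_chrom: dict[str, list[StandardizedMTA]] = {}
    for m in mtas:
        if m.chromosome not in gmap.chrom_lengths_cM:
            raise ValidationError(
                f"{m.mta.mta_id}: chromosome {m.chromosome} absent from map"
            )
        by_chrom.setdefault(m.chromosome, []).append(m)

    profiles: dict[str, OverviewProfile] = {}
    for chrom, length in gmap.chrom_lengths_cM.items():
        n_bins = int(np.ceil(length))
        members = by_chrom.get(chrom, [])
        if not members:
            profiles[chrom] = OverviewProfile(chrom, np.zeros(n_bins))
            continue
        edges = np.arange(n_bins + 1, dtype=float)
        mu = np.array([m.position_cM for m in members])[:, None]
        s = np.array([m.s for m in members])[:, None]
        cdf = norm.cdf((edges[None, :] - mu) / s)
        profiles[chrom] = OverviewProfile(chrom, np.diff(cdf, axis=1).sum(axis=0))
    return profiles


def mean_threshold(profiles: Mapping[str, OverviewProfile]) -> float:
    """Arithmetic mean of u over every bin of every chromosome."""
    if not profiles:
        raise ValidationError("no profiles to average")
    total = sum(float(p.u.sum()) for p in profiles.values())
    n = sum(p.n_bins for p in profiles.values())
    if n == 0:
        raise ValidationError("profiles have no bins")
    return total / n


def high_threshold(mean: float, factor: float = 5.0) -> float:
    """The stringent threshold: ``factor`` (default 5) times the mean."""
    return factor * mean


def detect_peaks(profile: OverviewProfile, threshold: float) -> list[Peak]:
    """Local maxima of u restricted to bins with u >= threshold.

    A plateau of equal values yields a single peak at its leftmost bin.  Each
    peak carries the contiguous supra-threshold run containing it, so one run
    may host several peaks.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    u = profile.u
    above = u >= threshold
    peaks: list[Peak] = []
    i = 0
    n = len(u)
    while i < n:
        if not above[i]:
            i += 1
            continue
        run_start = i
        while i < n and above[i]:
            i += 1
        run_end = i - 1
        j = run_start
        while j <= run_end:
            k = j
            while k < run_end and u[k + 1] == u[j]:
                k += 1  # span the plateau
            left_ok = j == run_start or u[j - 1] < u[j]
            right_ok = k == run_end or u[k + 1] < u[j]
            if left_ok and right_ok:
                peaks.append(
                    Peak(profile.chromosome, j, float(u[j]), run_start, run_end)
                )
            j = k + 1
    return peaks


_CHROM_ORDER = {c: i for i, c in enumerate(
    f"{n}{g}" for n in range(1, 8) for g in ("A", "B")
)}


def merge_peaks(
    peaks: Sequence[Peak],
    mtas: Sequence[StandardizedMTA],
    merge_gap_cM: float = 2.0,
    start_id: int = 1,
) -> list[Hotspot]:
    """Merge peaks into hotspots and assign member MTAs.

    Supra-threshold runs on the same chromosome that touch, overlap, or are
    separated by at most ``merge_gap_cM`` empty bins are merged.  The hotspot's
    genetic CI is [min run start, max run end + 1) in cM; members are the MTAs
    whose symmetric CI interval (mu +/- CI/2) overlaps it.  Hotspot ids are
    sequential genome-wide, left-to-right within chromosomes ordered 1A..7B.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chromosome, []).append((p.run_start, p.run_end))

    hotspots: list[Hotspot] = []
    next_id = start_id
    for chrom in sorted(by_chrom, key=lambda c: _CHROM_ORDER.get(c, 99)):
        runs = sorted(set(by_chrom[chrom]))
        merged: list[list[int]] = []
        for start, end in runs:
            if merged and start - (merged[-1][1] + 1) <= merge_gap_cM:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        for start, end in merged:
            ci_start, ci_end = float(start), float(end + 1)
            members = [
                m
                for m in mtas
                if m.chromosome == chrom
                and m.mta.ci_interval[0] < ci_end
                and m.mta.ci_interval[1] > ci_start
            ]
            members.sort(key=lambda m: (m.position_cM, m.mta.mta_id))
            pves = [m.mta.pve for m in members if m.mta.pve is not None]
            hotspots.append(
                Hotspot(
                    hotspot_id=next_id,
                    chromosome=chrom,
                    ci_start_cM=ci_start,
                    ci_end_cM=ci_end,
                    member_ids=tuple(m.mta.mta_id for m in members),
                    traits=tuple(sorted({m.mta.trait_code for m in members})),
                    pve_mean=(sum(pves) / len(pves)) if pves else None,
                )
            )
            next_id += 1
    return hotspots


def attach_physical(
    hotspot: Hotspot, anchor_tables: Iterable[AnchorTable]
) -> Hotspot:
    """Add physical CIs (Mb) for each reference via cM->Mb interpolation."""
    physical = dict(hotspot.physical_ci_Mb)
    for table in anchor_tables:
        lo, _ = genetic_to_physical(hotspot.ci_start_cM, table, hotspot.chromosome)
        hi, _ = genetic_to_physical(hotspot.ci_end_cM, table, hotspot.chromosome)
        physical[table.reference_name] = (min(lo, hi), max(lo, hi))
    return replace(hotspot, physical_ci_Mb=physical)


def select_breeding(
    hotspot: Hotspot,
    primary_reference: str = "Svevo",
    max_width_Mb: float = 20.0,
    pve_large: float = 0.04,
    pve_small: float = 0.1,
    min_mta_large: int = 5,
    min_mta_small: int = 3,
) -> Hotspot:
    """Flag a hotspot as a breeding QTL.

    Selected iff the physical CI on the primary assembly is narrower than
    ``max_width_Mb`` and either >= 5 members with mean PVE >= 0.04, or 3-4
    members with mean PVE > 0.1.  Hotspots with < 3 members, or with no member
    reporting a PVE, are never selected.
    """
    if primary_reference not in hotspot.physical_ci_Mb:
        raise ValidationError(
            f"hotspot {hotspot.hotspot_id}: no physical CI on {primary_reference}"
        )
    width = hotspot.physical_width_Mb(primary_reference)
    pve = hotspot.pve_mean
    if pve is None or width >= max_width_Mb:
        return replace(hotspot, is_breeding=False)
    n = hotspot.n_mta
    selected = (n >= min_mta_large and pve >= pve_large) or (
        min_mta_small <= n < min_mta_large and pve > pve_small
    )
    return replace(hotspot, is_breeding=selected)
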