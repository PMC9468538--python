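"""Homothetic projection of MTAs onto the consensus genetic map.

A position on a source map is re-expressed in consensus coordinates by linear
rescaling between the nearest flanking markers shared by both maps; outside the
shared-marker span the nearest interval's ratio is extended and the record is
flagged rather than dropped.  Markers that exist by name on the consensus map
are placed by direct lookup (identity projection) — the dominant case when the
source studies used the same SNP panels as the consensus map.

Missing confidence intervals are imputed from the per-chromosome LD-decay
distance before projection; the CI width is rescaled by the same local cM ratio
as the position, placed symmetrically about the projected position, and clamped
to the chromosome.

The same piecewise-linear machinery converts consensus cM to physical Mb
through anchor tables for the Svevo and Chinese Spring assemblies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .io_model import (
    AnchorTable,
    GeneticMap,
    LDDecayTable,
    MTARecord,
    ValidationError,
    normalize_chromosome,
)

__all__ = [
    "ProjectedMTA",
    "ProjectionError",
    "impute_ci",
    "project_position",
    "project_ci",
    "project_database",
    "genetic_to_physical",
]


class ProjectionError(ValueError):
    """Projection is impossible with the available shared markers/anchors."""


CI_SOURCES = ("original", "ld_decay")
PROJECTION_FLAGS = ("anchored", "extrapolated", "identity")


@dataclass(frozen=True)
class ProjectedMTA:
    """An MTA in consensus coordinates with a guaranteed CI.

    ``ci_source`` records whether the CI came from the original study or from
    the LD-decay surrogate; ``projection_flag`` how the position was obtained;
    ``clamped`` whether either CI endpoint hit a chromosome boundary.
    """

    mta_id: str
    study_id: str
    trait_code: str
    chromosome: str
    position_cM: float
    ci_cM: float
    ci_source: str
    projection_flag: str
    pve: float | None = None
    marker_id: str | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.ci_cM <= 0:
            raise ValidationError(f"{self.mta_id}: projected CI must be positive")
        if self.ci_source not in CI_SOURCES:
            raise ValidationError(f"{self.mta_id}: bad ci_source {self.ci_source!r}")
        if self.projection_flag not in PROJECTION_FLAGS:
            raise ValidationError(
                f"{self.mta_id}: bad projection_flag {self.projection_flag!r}"
            )

    @property
    def ci_interval(self) -> tuple[float, float]:
        """Symmetric CI interval (start, end) in consensus cM."""
        half = self.ci_cM / 2.0
        return (self.position_cM - half, self.position_cM + half)


def impute_ci(record: MTARecord, ld: LDDecayTable) -> tuple[MTARecord, str]:
    """Fill a missing CI from the chromosome's LD-decay distance.

    Returns the (possibly updated) record and the CI source tag.  Records that
    already carry a CI are returned unchanged with source ``original``.
    """
    if record.ci_cM is not None:
        return record, "original"
    if record.chromosome not in ld:
        raise ProjectionError(
            f"{record.mta_id}: no LD-decay entry for chromosome {record.chromosome}"
        )
    return replace(record, ci_cM=ld[record.chromosome]), "ld_decay"


def _flanking_interval(
    p: float, anchors: Sequence[tuple[float, float]]
) -> tuple[tuple[float, float], tuple[float, float], str]:
    """Pick the anchor interval used for position ``p``: the flanking pair when
    ``p`` is inside the span, else the nearest terminal interval (extrapolated)."""
    if len(anchors) < 2:
        raise ProjectionError("need at least 2 shared markers/anchors")
    xs = [a[0] for a in anchors]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ProjectionError("source positions must be strictly increasing")
    if p < xs[0]:
        return anchors[0], anchors[1], "extrapolated"
    if p > xs[-1]:
        return anchors[-2], anchors[-1], "extrapolated"
    for left, right in zip(anchors, anchors[1:]):
        if left[0] <= p <= right[0]:
            return left, right, "anchored"
    raise ProjectionError(f"position {p} not bracketed")  # pragma: no cover


def project_position(
    p: float, shared_markers: Sequence[tuple[float, float]]
) -> tuple[float, str, float]:
    """Project a source-map position through shared markers.

    ``shared_markers`` are (source cM, consensus cM) pairs sorted by source
    position.  Returns (consensus position, flag, local ratio); the ratio is
    the cM scaling factor of the interval used, which also rescales CI widths.
    """
    (s1, c1), (s2, c2), flag = _flanking_interval(p, shared_markers)
    if s2 == s1:
        raise ProjectionError("zero-length source interval")
    ratio = (c2 - c1) / (s2 - s1)
    return c1 + (p - s1) * ratio, flag, ratio


def project_ci(
    ci_cM: float, ratio: float, position_cM: float, chrom_length_cM: float
) -> tuple[float, float, bool]:
    """Rescale a CI width by the local projection ratio and clamp it.

    The projected CI is placed symmetrically about the projected position and
    clamped to [0, chromosome length]; clamping shrinks the width and sets the
    flag.  Returns (width, start, clamped).
    """
    width = ci_cM * abs(ratio)
    lo = position_cM - width / 2.0
    hi = position_cM + width / 2.0
    clamped = False
    if lo < 0.0:
        lo, clamped = 0.0, True
    if hi > chrom_length_cM:
        hi, clamped = chrom_length_cM, True
    if hi <= lo:  # degenerate after clamping; keep a sliver around the position
        return max(width, 1e-9), lo, clamped
    return hi - lo, lo, clamped


def project_database(
    mtas: Sequence[MTARecord],
    source_map: GeneticMap | None,
    consensus: GeneticMap,
    ld: LDDecayTable,
) -> list[ProjectedMTA]:
    """Project a full MTA database onto the consensus map.

    Each record is CI-imputed, then placed by (in order of preference) direct
    marker lookup on the consensus map, homothetic rescaling through the
    markers shared between ``source_map`` and ``consensus`` on its chromosome,
    or identity when no source map is supplied (positions already consensus).
    """
    shared_cache: dict[str, list[tuple[float, float]]] = {}
    projected: list[ProjectedMTA] = []
    for record in mtas:
        record, ci_source = impute_ci(record, ld)
        chrom = record.chromosome
        length = consensus.chrom_lengths_cM.get(chrom)
        if length is None:
            raise ProjectionError(f"{record.mta_id}: {chrom} absent from consensus map")

        if record.marker_id is not None and record.marker_id in consensus.positions:
            mchrom, cm = consensus.positions[record.marker_id]
            if mchrom != chrom:
                raise ValidationError(
                    f"{record.mta_id}: marker {record.marker_id} maps to {mchrom}, "
                    f"record says {chrom}"
                )
            pos, flag, ratio = cm, "identity", 1.0
        elif source_map is None:
            pos, flag, ratio = record.position_cM, "identity", 1.0
        else:
            if chrom not in shared_cache:
                shared = []
                for marker, (c, s_cm) in source_map.positions.items():
                    if c == chrom and marker in consensus.positions:
                        cc, c_cm = consensus.positions[marker]
                        if cc == chrom:
                            shared.append((s_cm, c_cm))
                shared_cache[chrom] = sorted(shared)
            anchors = shared_cache[chrom]
            if len(anchors) < 2:
                raise ProjectionError(
                    f"{record.mta_id}: < 2 shared markers on {chrom}"
                )
            pos, flag, ratio = project_position(record.position_cM, anchors)

        clamp_pos = False
        if pos < 0.0:
            pos, clamp_pos = 0.0, True
        elif pos > length:
            pos, clamp_pos = length, True
        assert record.ci_cM is not None
        width, _, clamp_ci = project_ci(record.ci_cM, ratio, pos, length)
        projected.append(
            ProjectedMTA(
                mta_id=record.mta_id,
                study_id=record.study_id,
                trait_code=record.trait_code,
                chromosome=chrom,
                position_cM=pos,
                ci_cM=width,
                ci_source=ci_source,
                projection_flag=flag,
                pve=record.pve,
                marker_id=record.marker_id,
                clamped=clamp_pos or clamp_ci,
            )
        )
    return projected


def genetic_to_physical(
    x_cM: float, anchors: AnchorTable, chromosome: str
) -> tuple[float, str]:
    """Interpolate consensus cM to physical Mb through an anchor table.

    Piecewise-linear between flanking anchors; outside the anchor span the
    nearest interval is extended and the result flagged ``extrapolated``.
    Non-monotone Mb between the chosen anchors (real maps contain inversions)
    triggers a warning but is still interpolated.
    """
    chrom = normalize_chromosome(chromosome)
    pts = anchors.anchors.get(chrom)
    if pts is None or len(pts) < 2:
        raise ProjectionError(
            f"no usable anchors for {chrom} on {anchors.reference_name}"
        )
    (c1, m1), (c2, m2), flag = _flanking_interval(x_cM, pts)
    if m2 < m1:
        warnings.warn(
            f"{anchors.reference_name}/{chrom}: non-monotone Mb anchors "
            f"({m1} -> {m2}); interpolating anyway",
            stacklevel=2,
        )
    return m1 + (x_cM - c1) * (m2 - m1) / (c2 - c1), flag
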