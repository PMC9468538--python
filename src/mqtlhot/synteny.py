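"""Ortho-MQTL calling from marker-vs-genome alignments.

Marker sequences of the breeding hotspots are aligned (externally, e.g. with
bwa-mem) against other grass genomes at three stringency rounds; this module
consumes the resulting SAM files.  Hits are filtered by aligned-length
fraction (> 60% of the marker length) and mapping quality (MAPQ > 10, i.e. the
posterior probability of a wrong placement below 10%); per marker and genome
the best surviving hit is kept, preferring higher-stringency rounds, and
markers with ties across distinct loci are dropped as ambiguous.  Clusters of
a hotspot's markers on one target chromosome (single linkage within
``max_gap_bp``) become ortho-MQTL regions; gene models overlapping a region
are looked up in the genome's GFF3 annotation.

Internal coordinates are 0-based half-open; SAM input (1-based) is converted
at the boundary and BED output stays 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam

from .hotspots import Hotspot

__all__ = [
    "STRINGENCY_ORDER",
    "AlignmentHit",
    "OrthoRegion",
    "GeneModel",
    "read_sam_hits",
    "filter_hits",
    "merge_rounds",
    "call_ortho_regions",
    "load_gff",
    "genes_in_interval",
    "ortho_marker_counts",
]

STRINGENCY_ORDER: tuple[str, ...] = ("high", "medium", "low")


@dataclass(frozen=True)
class AlignmentHit:
    """One marker-vs-genome alignment (0-based half-open target interval)."""

    marker_id: str
    target_genome: str
    target_chromosome: str
    target_start: int
    target_end: int
    marker_length: int
    aligned_length: int
    mapping_quality: int
    stringency_round: str
    is_secondary: bool = False

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError(f"{self.marker_id}: empty target interval")
        if self.aligned_length > self.marker_length:
            raise ValueError(f"{self.marker_id}: aligned length exceeds marker length")
        if self.stringency_round not in STRINGENCY_ORDER:
            raise ValueError(f"{self.marker_id}: unknown round {self.stringency_round!r}")

    @property
    def length_fraction(self) -> float:
        return self.aligned_length / self.marker_length


@dataclass(frozen=True)
class OrthoRegion:
    """A syntenic interval on a target genome supporting one hotspot."""

    hotspot_id: int
    target_genome: str
    target_chromosome: str
    start: int
    end: int
    supporting_marker_ids: tuple[str, ...]

    @property
    def n_markers(self) -> int:
        return len(self.supporting_marker_ids)


@dataclass(frozen=True)
class GeneModel:
    """A gene span from a GFF3 annotation (0-based half-open)."""

    gene_id: str
    genome: str
    chromosome: str
    start: int
    end: int
    strand: str
    description: str = ""


def read_sam_hits(
    path: str | Path, target_genome: str, stringency_round: str
) -> list[AlignmentHit]:
    """Parse mapped records of one SAM file into :class:`AlignmentHit` objects.

    The marker length is the full read length inferred from the CIGAR
    (clipped bases included); the aligned length is the aligned portion of the
    read.  Unmapped records are skipped; zero-length markers are dropped with
    a warning.
    """
    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            marker_length = aln.infer_read_length() or 0
            if marker_length <= 0:
                warnings.warn(
                    f"{path}: marker {aln.query_name} has zero length; dropped",
                    stacklevel=2,
                )
                continue
            hits.append(
                AlignmentHit(
                    marker_id=aln.query_name,
                    target_genome=target_genome,
                    target_chromosome=aln.reference_name,
                    target_start=aln.reference_start,
                    target_end=aln.reference_end,
                    marker_length=marker_length,
                    aligned_length=aln.query_alignment_length,
                    mapping_quality=aln.mapping_quality,
                    stringency_round=stringency_round,
                    is_secondary=aln.is_secondary or aln.is_supplementary,
                )
            )
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_len_frac: float = 0.60,
    min_mapq: int = 10,
) -> list[AlignmentHit]:
    """Keep hits with length fraction strictly > ``min_len_frac`` and MAPQ
    strictly > ``min_mapq``.  Idempotent."""
    return [
        h
        for h in hits
        if h.length_fraction > min_len_frac and h.mapping_quality > min_mapq
    ]


def merge_rounds(hits: Iterable[AlignmentHit]) -> dict[tuple[str, str], AlignmentHit]:
    """Reduce filtered hits to at most one per (marker, genome).

    The highest-stringency round with any surviving hit wins; within that
    round only primary hits compete and the unique highest-MAPQ one is kept.
    If the top MAPQ is shared by hits at distinct loci the marker is ambiguous
    for that genome and dropped.  Duplicate reports of the same locus are
    collapsed silently.
    """
    grouped: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault((h.marker_id, h.target_genome), []).append(h)

    merged: dict[tuple[str, str], AlignmentHit] = {}
    for key, group in grouped.items():
        for rnd in STRINGENCY_ORDER:
            candidates = [
                h for h in group if h.stringency_round == rnd and not h.is_secondary
            ]
            if not candidates:
                continue
            top = max(h.mapping_quality for h in candidates)
            best = [h for h in candidates if h.mapping_quality == top]
            loci = {(h.target_chromosome, h.target_start, h.target_end) for h in best}
            if len(loci) == 1:
                merged[key] = best[0]
            # len(loci) > 1: ambiguous -> marker dropped for this genome
            break
    return merged


def call_ortho_regions(
    hotspot: Hotspot,
    merged_hits: Mapping[tuple[str, str], AlignmentHit],
    min_markers: int = 2,
    max_gap_bp: int = 5_000_000,
    marker_of_member: Mapping[str, str] | None = None,
) -> list[OrthoRegion]:
    """Cluster the hotspot's marker hits into syntenic regions per genome.

    ``marker_of_member`` translates member MTA ids to the marker sequence names
    used in the alignments; without it the member ids are used verbatim.
    Only markers that are members of the hotspot contribute.  Hits on the same
    target chromosome are clustered by single linkage: consecutive intervals
    (sorted by start) whose gap is at most ``max_gap_bp`` join one cluster;
    clusters with at least ``min_markers`` distinct markers become regions.
    A hotspot with no aligned markers yields an empty list.
    """
    translate = marker_of_member or {}
    members = {translate.get(m, m) for m in hotspot.member_ids}
    by_target: dict[tuple[str, str], list[AlignmentHit]] = {}
    for (marker, genome), hit in merged_hits.items():
        if marker in members:
            by_target.setdefault((genome, hit.target_chromosome), []).append(hit)

    regions: list[OrthoRegion] = []
    for (genome, chrom), hits in sorted(by_target.items()):
        hits.sort(key=lambda h: (h.target_start, h.target_end, h.marker_id))
        cluster: list[AlignmentHit] = []

        def flush() -> None:
            markers = tuple(sorted({h.marker_id for h in cluster}))
            if len(markers) >= min_markers:
                regions.append(
                    OrthoRegion(
                        hotspot_id=hotspot.hotspot_id,
                        target_genome=genome,
                        target_chromosome=chrom,
                        start=min(h.target_start for h in cluster),
                        end=max(h.target_end for h in cluster),
                        supporting_marker_ids=markers,
                    )
                )

        for h in hits:
            if cluster and h.target_start - max(c.target_end for c in cluster) > max_gap_bp:
                flush()
                cluster = []
            cluster.append(h)
        if cluster:
            flush()
    return regions


def load_gff(path: str | Path, genome: str) -> gffutils.FeatureDB:
    """Build an in-memory feature database from a GFF3 file."""
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def genes_in_interval(
    db: gffutils.FeatureDB,
    genome: str,
    chromosome: str,
    start: int,
    end: int,
    featuretype: str = "gene",
) -> list[GeneModel]:
    """Genes whose span intersects [start, end) (0-based half-open), by start.

    An unknown chromosome returns an empty list with a warning rather than
    failing, since annotations routinely omit scaffolds.
    """
    known = {f.seqid for f in db.all_features()}
    if chromosome not in known:
        warnings.warn(f"chromosome {chromosome!r} absent from annotation", stacklevel=2)
        return []
    genes: list[GeneModel] = []
    # gffutils region queries are 1-based inclusive; convert and post-filter
    # to enforce half-open overlap semantics exactly.
    for feat in db.region(seqid=chromosome, start=start + 1, end=end, featuretype=featuretype):
        g_start, g_end = feat.start - 1, feat.end  # to 0-based half-open
        if g_start < end and g_end > start:
            desc = feat.attributes.get("description", [""])[0]
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    genome=genome,
                    chromosome=chromosome,
                    start=g_start,
                    end=g_end,
                    strand=feat.strand or ".",
                    description=desc,
                )
            )
    genes.sort(key=lambda g: (g.start, g.gene_id))
    return genes


def ortho_marker_counts(regions: Sequence[OrthoRegion]) -> dict[str, int]:
    """Distinct ortho markers per target genome, plus the consistent total.

    A marker supporting several regions of one genome counts once for that
    genome; the ``total`` key is the sum over genomes and is checked against
    direct enumeration as an internal consistency guard.
    """
    per_genome: dict[str, set[str]] = {}
    for r in regions:
        per_genome.setdefault(r.target_genome, set()).update(r.supporting_marker_ids)
    counts = {g: len(markers) for g, markers in sorted(per_genome.items())}
    total = sum(counts.values())
    direct = sum(len(m) for m in per_genome.values())
    assert total == direct, "per-genome ortho-marker counts do not add up"
    counts["total"] = total
    return counts
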