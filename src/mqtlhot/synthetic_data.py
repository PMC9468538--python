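"""Ground-truth-annotated synthetic inputs for the whole pipeline.

The generator emulates a 10-study, 395-MTA durum wheat meta-GWAS database on a
14-chromosome consensus map of 2,630 cM:

* MTA positions are a mixture of planted Gaussian hotspot clusters and a
  uniform background; the planted clusters are the recoverable ground truth.
* CI widths follow a log-normal fitted exactly to the calibration quantiles
  (83% <= 5 cM, 97% <= 10 cM; implied mean 3.24 cM), truncated to the observed
  0.1-43 cM range; a 203/395 share of records has the CI masked as missing.
* PVE values follow a Beta fitted exactly to 79% < 0.1 and 95% < 0.2.
* Trait codes are drawn with YPC at 24%, the rest uniform.
* Anchor tables encode a tanh cM->Mb curve (recombination suppressed around
  the centromere), so genetically uniform positions become physically
  telomere-enriched (~83% of uniform genetic mass lands in the outer fifths).
* Synteny fixtures plant ortho regions in Brachypodium/rice/maize SAM files at
  three stringency rounds, with decoy hits that must fail each filter.

Identical seeds produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .hotspots import Hotspot
from .io_model import (
    AnchorTable,
    GeneticMap,
    LDDecayTable,
    MTARecord,
    Study,
    write_anchor_table,
    write_genetic_map,
    write_ld_decay,
    write_mta,
    write_studies,
)

__all__ = [
    "CHROM_LENGTHS_CM",
    "CHROM_LENGTHS_MB_SVEVO",
    "CHROM_LENGTHS_MB_CS",
    "GeneratorConfig",
    "GroundTruth",
    "generate_database",
    "generate_synteny_fixture",
]

# Consensus-map genetic lengths (cM); total 2,630.
CHROM_LENGTHS_CM: dict[str, float] = {
    "1A": 160.0, "1B": 180.0, "2A": 190.0, "2B": 210.0,
    "3A": 200.0, "3B": 220.0, "4A": 170.0, "4B": 130.0,
    "5A": 200.0, "5B": 210.0, "6A": 160.0, "6B": 180.0,
    "7A": 230.0, "7B": 190.0,
}

# Physical lengths (Mb) of the two reference assemblies.
CHROM_LENGTHS_MB_SVEVO: dict[str, float] = {
    "1A": 594.0, "1B": 700.0, "2A": 784.0, "2B": 813.0,
    "3A": 754.0, "3B": 853.0, "4A": 755.0, "4B": 677.0,
    "5A": 713.0, "5B": 715.0, "6A": 622.0, "6B": 733.0,
    "7A": 744.0, "7B": 763.0,
}
CHROM_LENGTHS_MB_CS = {c: round(l * 1.03, 1) for c, l in CHROM_LENGTHS_MB_SVEVO.items()}

# CI ~ LogNormal(mu, sigma): fitted exactly to P(<=5)=0.83, P(<=10)=0.97.
CI_LOGNORM_MU = 0.8956922651805777
CI_LOGNORM_SIGMA = 0.7480314808153726
# PVE ~ Beta(a, b): fitted exactly to P(<0.1)=0.79, P(<0.2)=0.95.
PVE_BETA_A = 0.7295949828604231
PVE_BETA_B = 11.094919624895802

_STUDY_SIZES = (104, 230, 124, 93, 172, 243, 79, 192, 192, 169)
_STUDY_MTA = (19, 7, 6, 20, 14, 163, 44, 20, 80, 22)

_OTHER_TRAITS = (
    "GPC", "GS", "TW", "AX", "BG", "CLOSS", "Color", "CWT", "dif", "FIRM",
    "GLUT", "MIXO", "PPO", "SASH", "SEXT", "SPROT", "SV", "TEXT", "VIT", "WG",
    "WTS", "Gli", "Glu", "IP", "TPT", "a*", "b*", "L*", "GL", "GW", "DEE",
    "DOE", "DOTE", "PLOSS", "PRLOSS", "HMW", "LMW",
)

_GENOME_CHROMS = {
    "bd": [f"bd{i}" for i in range(1, 6)],
    "os": [f"os{i}" for i in range(1, 13)],
    "zm": [f"zm{i}" for i in range(1, 11)],
}
_GENOME_CHROM_LEN_BP = 50_000_000
_GENOME_REGION_PROB = {"bd": 0.9, "os": 0.6, "zm": 0.15}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic database."""

    seed: int
    n_studies: int = 10
    n_mta: int = 395
    chrom_lengths_cM: Mapping[str, float] = field(
        default_factory=lambda: dict(CHROM_LENGTHS_CM)
    )
    chrom_lengths_Mb: Mapping[str, float] = field(
        default_factory=lambda: dict(CHROM_LENGTHS_MB_SVEVO)
    )
    n_planted_hotspots: int = 25
    hotspot_sd_cM: float = 1.5
    fraction_background: float = 0.05
    fraction_ci_missing: float = 203 / 395
    ci_lognorm_mu: float = CI_LOGNORM_MU
    ci_lognorm_sigma: float = CI_LOGNORM_SIGMA
    ci_range_cM: tuple[float, float] = (0.1, 43.0)
    pve_beta_a: float = PVE_BETA_A
    pve_beta_b: float = PVE_BETA_B
    ypc_frequency: float = 0.24
    telomere_skew: float = 8.0  # tanh steepness of the cM->Mb anchor curve
    n_anchors_per_chrom: int = 21
    cluster_margin_cM: float = 10.0
    cluster_min_separation_cM: float = 20.0
    # synteny planting
    markers_per_region_frac: float = 0.6
    n_length_decoys: int = 3
    n_mapq_decoys: int = 3
    n_ambiguous_decoys: int = 2
    marker_length_bp: int = 100

    def __post_init__(self) -> None:
        for name in ("fraction_background", "fraction_ci_missing", "ypc_frequency",
                     "markers_per_region_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_mta < 1 or self.n_studies < 1 or self.n_planted_hotspots < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class PlantedCluster:
    chromosome: str
    center_cM: float
    sd_cM: float
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class PlantedRegion:
    hotspot_id: int
    genome: str
    chromosome: str
    start: int
    end: int
    marker_ids: tuple[str, ...]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    clusters: tuple[PlantedCluster, ...] = ()
    background_ids: tuple[str, ...] = ()
    regions: tuple[PlantedRegion, ...] = ()
    ambiguous_markers: tuple[str, ...] = ()
    length_decoy_markers: tuple[str, ...] = ()
    mapq_decoy_markers: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clusters": [
                {
                    "chromosome": c.chromosome,
                    "center_cM": c.center_cM,
                    "sd_cM": c.sd_cM,
                    "member_ids": list(c.member_ids),
                }
                for c in self.clusters
            ],
            "background_ids": list(self.background_ids),
            "regions": [
                {
                    "hotspot_id": r.hotspot_id,
                    "genome": r.genome,
                    "chromosome": r.chromosome,
                    "start": r.start,
                    "end": r.end,
                    "marker_ids": list(r.marker_ids),
                }
                for r in self.regions
            ],
            "ambiguous_markers": list(self.ambiguous_markers),
            "length_decoy_markers": list(self.length_decoy_markers),
            "mapq_decoy_markers": list(self.mapq_decoy_markers),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _tanh_physical_fraction(g: np.ndarray, k: float) -> np.ndarray:
    """Map genetic fraction (0..1) to physical fraction through a tanh curve.

    Slope is maximal mid-chromosome: a small genetic interval around the
    centromere covers a large physical span, so uniform genetic positions
    concentrate physically near the telomeres.
    """
    return 0.5 * (1.0 + np.tanh(k * (g - 0.5)) / math.tanh(k / 2.0))


def _plant_centers(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> list[tuple[str, float]]:
    """Spread cluster centers over chromosomes proportional to genetic length,
    keeping a margin from the ends and a minimum mutual separation."""
    chroms = sorted(cfg.chrom_lengths_cM)
    lengths = np.array([cfg.chrom_lengths_cM[c] for c in chroms])
    # largest-remainder apportionment of clusters to chromosomes
    quota = cfg.n_planted_hotspots * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts))
    for i in order[: cfg.n_planted_hotspots - counts.sum()]:
        counts[i] += 1
    centers: list[tuple[str, float]] = []
    for chrom, n in zip(chroms, counts):
        length = cfg.chrom_lengths_cM[chrom]
        placed: list[float] = []
        attempts = 0
        while len(placed) < n and attempts < 1000:
            c = rng.uniform(cfg.cluster_margin_cM, length - cfg.cluster_margin_cM)
            if all(abs(c - p) >= cfg.cluster_min_separation_cM for p in placed):
                placed.append(c)
            attempts += 1
        if len(placed) < n:
            raise ValueError(
                f"cannot place {n} separated clusters on {chrom} "
                f"(length {length} cM, separation {cfg.cluster_min_separation_cM})"
            )
        centers.extend((chrom, c) for c in sorted(placed))
    return centers


def generate_database(
    cfg: GeneratorConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete synthetic input directory; return file paths + truth.

    Files: studies.tsv, mta.tsv, map.tsv, ld_decay.tsv, anchors_Svevo.tsv,
    anchors_CS.tsv, ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # --- studies ------------------------------------------------------------
    if cfg.n_studies == 10:
        sizes = list(_STUDY_SIZES)
        proportions = np.array(_STUDY_MTA, dtype=float)
    else:
        sizes = list(rng.integers(80, 250, size=cfg.n_studies))
        proportions = rng.dirichlet(np.ones(cfg.n_studies)) * cfg.n_mta
    quota = cfg.n_mta * proportions / proportions.sum()
    study_counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - study_counts))
    for i in order[: cfg.n_mta - study_counts.sum()]:
        study_counts[i] += 1

    study_ids = [f"S{i + 1:02d}" for i in range(cfg.n_studies)]
    study_of_mta = np.repeat(np.arange(cfg.n_studies), study_counts)
    rng.shuffle(study_of_mta)

    # --- traits -------------------------------------------------------------
    other = np.array(_OTHER_TRAITS)
    traits = np.where(
        rng.random(cfg.n_mta) < cfg.ypc_frequency,
        "YPC",
        other[rng.integers(0, len(other), size=cfg.n_mta)],
    )

    # --- positions: planted clusters + uniform background -------------------
    chroms = sorted(cfg.chrom_lengths_cM)
    lengths = np.array([cfg.chrom_lengths_cM[c] for c in chroms])
    centers = _plant_centers(rng, cfg)
    n_background = int(round(cfg.fraction_background * cfg.n_mta))
    n_clustered = cfg.n_mta - n_background
    cluster_of = rng.integers(0, len(centers), size=n_clustered)

    mta_ids = [f"mta{i + 1:04d}" for i in range(cfg.n_mta)]
    marker_ids = [f"snp{i + 1:04d}" for i in range(cfg.n_mta)]
    positions: list[tuple[str, float]] = []
    for ci in cluster_of:
        chrom, center = centers[ci]
        length = cfg.chrom_lengths_cM[chrom]
        pos = float(np.clip(rng.normal(center, cfg.hotspot_sd_cM), 0.0, length))
        positions.append((chrom, pos))
    bg_chrom_idx = rng.choice(
        len(chroms), size=n_background, p=lengths / lengths.sum()
    )
    for idx in bg_chrom_idx:
        positions.append((chroms[idx], float(rng.uniform(0.0, lengths[idx]))))

    member_ids: dict[int, list[str]] = {i: [] for i in range(len(centers))}
    for i, ci in enumerate(cluster_of):
        member_ids[ci].append(mta_ids[i])
    background_ids = tuple(mta_ids[n_clustered:])

    # --- CI and PVE ---------------------------------------------------------
    ci = np.exp(rng.normal(cfg.ci_lognorm_mu, cfg.ci_lognorm_sigma, size=cfg.n_mta))
    ci = np.clip(ci, cfg.ci_range_cM[0], cfg.ci_range_cM[1])
    n_missing = int(round(cfg.fraction_ci_missing * cfg.n_mta))
    missing = np.zeros(cfg.n_mta, dtype=bool)
    missing[rng.permutation(cfg.n_mta)[:n_missing]] = True
    pve = rng.beta(cfg.pve_beta_a, cfg.pve_beta_b, size=cfg.n_mta)
    pve = np.clip(pve, 1e-4, 1.0)

    records = [
        MTARecord(
            mta_id=mta_ids[i],
            study_id=study_ids[study_of_mta[i]],
            trait_code=str(traits[i]),
            chromosome=positions[i][0],
            position_cM=round(positions[i][1], 4),
            ci_cM=None if missing[i] else round(float(ci[i]), 4),
            pve=round(float(pve[i]), 4),
            marker_id=marker_ids[i],
        )
        for i in range(cfg.n_mta)
    ]

    # --- studies table (declared counts = realized counts) -------------------
    realized = {sid: 0 for sid in study_ids}
    study_traits: dict[str, set[str]] = {sid: set() for sid in study_ids}
    for r in records:
        realized[r.study_id] += 1
        study_traits[r.study_id].add(r.trait_code)
    studies = [
        Study(
            study_id=sid,
            panel=f"synthetic panel {sid}",
            size=int(sizes[i]),
            trait_codes=frozenset(study_traits[sid] or {"YPC"}),
            n_mta_declared=realized[sid],
        )
        for i, sid in enumerate(study_ids)
    ]

    # --- consensus map: MTA markers by name + scaffold every 5 cM ------------
    map_positions: dict[str, tuple[str, float]] = {}
    for r in records:
        assert r.marker_id is not None
        map_positions[r.marker_id] = (r.chromosome, r.position_cM)
    for chrom in chroms:
        length = cfg.chrom_lengths_cM[chrom]
        for j, cm in enumerate(np.arange(0.0, length + 1e-9, 5.0)):
            map_positions[f"scaf_{chrom}_{j:03d}"] = (chrom, float(min(cm, length)))
    gmap = GeneticMap(
        name="consensus",
        positions=map_positions,
        chrom_lengths_cM=dict(cfg.chrom_lengths_cM),
    )

    # --- LD decay: plausible per-chromosome distances -------------------------
    ld = LDDecayTable(
        decay_cM={c: round(float(d), 3) for c, d in zip(chroms, rng.uniform(2.0, 5.0, len(chroms)))}
    )

    # --- anchors: tanh cM->Mb curve ------------------------------------------
    def anchor_table(name: str, phys_lengths: Mapping[str, float], k: float) -> AnchorTable:
        anchors = {}
        for chrom in chroms:
            g = np.linspace(0.0, 1.0, cfg.n_anchors_per_chrom)
            p = _tanh_physical_fraction(g, k)
            cm = g * cfg.chrom_lengths_cM[chrom]
            mb = np.maximum(p * phys_lengths[chrom], 1e-3)
            anchors[chrom] = tuple(
                (round(float(a), 4), round(float(b), 4)) for a, b in zip(cm, mb)
            )
        return AnchorTable(reference_name=name, anchors=anchors)

    svevo = anchor_table("Svevo", cfg.chrom_lengths_Mb, cfg.telomere_skew)
    cs = anchor_table("CS", CHROM_LENGTHS_MB_CS, cfg.telomere_skew)

    paths = {
        "studies": outdir / "studies.tsv",
        "mta": outdir / "mta.tsv",
        "map": outdir / "map.tsv",
        "ld_decay": outdir / "ld_decay.tsv",
        "anchors_Svevo": outdir / "anchors_Svevo.tsv",
        "anchors_CS": outdir / "anchors_CS.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_studies(studies, paths["studies"])
    write_mta(records, paths["mta"])
    write_genetic_map(gmap, paths["map"])
    write_ld_decay(ld, paths["ld_decay"])
    write_anchor_table(svevo, paths["anchors_Svevo"])
    write_anchor_table(cs, paths["anchors_CS"])

    truth = GroundTruth(
        clusters=tuple(
            PlantedCluster(
                chromosome=chrom,
                center_cM=round(center, 4),
                sd_cM=cfg.hotspot_sd_cM,
                member_ids=tuple(member_ids[i]),
            )
            for i, (chrom, center) in enumerate(centers)
        ),
        background_ids=background_ids,
    )
    truth.to_json(paths["ground_truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# synteny fixtures
# ---------------------------------------------------------------------------


def _sam_header(genome: str) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": _GENOME_CHROM_LEN_BP} for c in _GENOME_CHROMS[genome]
            ],
        }
    )


def _make_segment(
    header: pysam.AlignmentHeader,
    marker: str,
    chrom_index: int,
    start: int,
    aligned: int,
    total: int,
    mapq: int,
    secondary: bool = False,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header=header)
    seg.query_name = marker
    seg.query_sequence = "A" * total
    seg.flag = 256 if secondary else 0
    seg.reference_id = chrom_index
    seg.reference_start = start
    seg.mapping_quality = mapq
    clip = total - aligned
    seg.cigarstring = f"{aligned}M{clip}S" if clip else f"{aligned}M"
    return seg


def generate_synteny_fixture(
    cfg: GeneratorConfig,
    hotspots: Sequence[Hotspot],
    outdir: str | Path,
    marker_of_member: Mapping[str, str] | None = None,
) -> tuple[dict[str, Path], GroundTruth]:
    """Plant ortho regions for the given hotspots and write SAM + GFF3 files.

    ``marker_of_member`` translates member MTA ids to marker sequence names
    (reads are named by marker); member ids are used verbatim without it.

    Per hotspot, a region is planted on each target genome with the configured
    probability; a fraction of the hotspot's member markers receive good hits
    in that region, assigned mostly to the high-stringency round.  Decoy hits
    are added that must be removed by each filter: aligned fraction exactly at
    the 0.60 boundary, MAPQ exactly 10, and equal-MAPQ double hits at distinct
    loci (ambiguous markers).  Gene models are planted inside each region.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 101)
    L = cfg.marker_length_bp

    sam_records: dict[tuple[str, str], list[pysam.AlignedSegment]] = {
        (g, rnd): [] for g in _GENOME_CHROMS for rnd in ("high", "medium", "low")
    }
    headers = {g: _sam_header(g) for g in _GENOME_CHROMS}
    regions: list[PlantedRegion] = []

    translate = marker_of_member or {}
    all_members: list[str] = []
    for h in hotspots:
        members = [translate.get(m, m) for m in h.member_ids]
        all_members.extend(members)
        for genome, prob in _GENOME_REGION_PROB.items():
            if rng.random() >= prob:
                continue
            chrom_idx = int(rng.integers(0, len(_GENOME_CHROMS[genome])))
            chrom = _GENOME_CHROMS[genome][chrom_idx]
            base = int(rng.integers(1_000_000, 40_000_000))
            n_sup = max(2, int(round(cfg.markers_per_region_frac * len(members))))
            n_sup = min(n_sup, len(members))
            if n_sup < 2:
                continue
            chosen = sorted(rng.choice(members, size=n_sup, replace=False))
            starts = sorted(
                int(base + o)
                for o in rng.integers(0, 2_000_000, size=n_sup)
            )
            ends = []
            for marker, start in zip(chosen, starts):
                aligned = int(rng.integers(int(0.7 * L), L + 1))
                mapq = int(rng.integers(30, 61))
                rnd = str(rng.choice(["high", "high", "high", "medium", "low"]))
                sam_records[(genome, rnd)].append(
                    _make_segment(headers[genome], marker, chrom_idx, start, aligned, L, mapq)
                )
                # a stale lower-stringency placement elsewhere: must lose the merge
                if rnd == "high" and rng.random() < 0.2:
                    sam_records[(genome, "low")].append(
                        _make_segment(
                            headers[genome], marker, chrom_idx,
                            start + 10_000_000, aligned, L, mapq,
                        )
                    )
                ends.append(start + aligned)
            regions.append(
                PlantedRegion(
                    hotspot_id=h.hotspot_id,
                    genome=genome,
                    chromosome=chrom,
                    start=min(starts),
                    end=max(ends),
                    marker_ids=tuple(chosen),
                )
            )

    # --- decoys --------------------------------------------------------------
    def fresh_markers(n: int, tag: str) -> list[str]:
        return [f"decoy_{tag}_{i:02d}" for i in range(n)]

    len_decoys = fresh_markers(cfg.n_length_decoys, "len")
    mapq_decoys = fresh_markers(cfg.n_mapq_decoys, "mapq")
    ambiguous = fresh_markers(cfg.n_ambiguous_decoys, "amb")
    for marker in len_decoys:  # aligned fraction exactly 0.60: strict > drops it
        sam_records[("bd", "high")].append(
            _make_segment(headers["bd"], marker, 0, int(rng.integers(0, 4e7)),
                          int(0.6 * L), L, 50)
        )
    for marker in mapq_decoys:  # MAPQ exactly 10: strict > drops it
        sam_records[("bd", "high")].append(
            _make_segment(headers["bd"], marker, 0, int(rng.integers(0, 4e7)),
                          L, L, 10)
        )
    for marker in ambiguous:  # equal-MAPQ hits at two loci: ambiguous, dropped
        start = int(rng.integers(0, 4e7))
        for chrom_idx in (0, 1):
            sam_records[("bd", "high")].append(
                _make_segment(headers["bd"], marker, chrom_idx, start, L, L, 42)
            )

    paths: dict[str, Path] = {}
    for (genome, rnd), segments in sorted(sam_records.items()):
        path = outdir / f"{genome}_{rnd}.sam"
        with pysam.AlignmentFile(str(path), "w", header=headers[genome]) as out:
            for seg in segments:
                out.write(seg)
        paths[f"sam_{genome}_{rnd}"] = path

    # --- GFF3 with genes planted inside each region ---------------------------
    gene_truth: dict[str, list[str]] = {}
    for genome in _GENOME_CHROMS:
        lines = ["##gff-version 3"]
        for chrom in _GENOME_CHROMS[genome]:
            lines.append(f"##sequence-region {chrom} 1 {_GENOME_CHROM_LEN_BP}")
        n_gene = 0
        for region in regions:
            if region.genome != genome:
                continue
            span = max(region.end - region.start, 4000)
            for _ in range(2):
                g_start = int(rng.integers(region.start, region.start + span - 2000))
                g_end = g_start + int(rng.integers(1000, 2000))
                n_gene += 1
                gid = f"{genome}_gene{n_gene:03d}"
                strand = "+" if rng.random() < 0.5 else "-"
                lines.append(
                    f"{region.chromosome}\tsynthetic\tgene\t{g_start + 1}\t{g_end}\t.\t"
                    f"{strand}\t.\tID={gid};description=planted in ortho region"
                )
                gene_truth.setdefault(f"{region.genome}:{region.chromosome}", []).append(gid)
        for chrom in _GENOME_CHROMS[genome]:  # background genes outside regions
            g_start = 45_000_000
            n_gene += 1
            lines.append(
                f"{chrom}\tsynthetic\tgene\t{g_start + 1}\t{g_start + 1500}\t.\t+\t.\t"
                f"ID={genome}_gene{n_gene:03d};description=background gene"
            )
        path = outdir / f"{genome}.gff3"
        path.write_text("\n".join(lines) + "\n")
        paths[f"gff_{genome}"] = path

    truth = GroundTruth(
        regions=tuple(regions),
        ambiguous_markers=tuple(ambiguous),
        length_decoy_markers=tuple(len_decoys),
        mapq_decoy_markers=tuple(mapq_decoys),
    )
    truth.to_json(outdir / "synteny_ground_truth.json")
    paths["ground_truth"] = outdir / "synteny_ground_truth.json"
    return paths, truth
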