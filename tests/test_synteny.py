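"""Alignment filtering, round merging, ortho-region calling, gene lookup."""

import pytest

from mqtlhot.hotspots import Hotspot
from mqtlhot.synteny import (
    AlignmentHit,
    call_ortho_regions,
    filter_hits,
    genes_in_interval,
    load_gff,
    merge_rounds,
    ortho_marker_counts,
    read_sam_hits,
)
from mqtlhot.synthetic_data import GeneratorConfig, generate_synteny_fixture


def hit(marker="mk1", genome="bd", chrom="bd1", start=1000, aligned=80, length=100,
        mapq=40, rnd="high", secondary=False):
    return AlignmentHit(
        marker_id=marker, target_genome=genome, target_chromosome=chrom,
        target_start=start, target_end=start + aligned, marker_length=length,
        aligned_length=aligned, mapping_quality=mapq, stringency_round=rnd,
        is_secondary=secondary,
    )


class TestFilterHits:
    def test_good_hit_kept(self):
        assert filter_hits([hit(aligned=75, mapq=30)]) == [hit(aligned=75, mapq=30)]

    def test_length_fraction_exactly_at_the_boundary_is_dropped(self):
        assert filter_hits([hit(aligned=60, length=100, mapq=30)]) == []

    def test_mapq_exactly_at_the_boundary_is_dropped(self):
        assert filter_hits([hit(aligned=90, mapq=10)]) == []

    def test_idempotent(self):
        hits = [hit(aligned=75), hit(aligned=60), hit(mapq=10)]
        once = filter_hits(hits)
        assert filter_hits(once) == once


class TestMergeRounds:
    def test_higher_stringency_round_wins(self):
        h_high = hit(rnd="high", mapq=20, start=1000)
        h_low = hit(rnd="low", mapq=60, start=9000)
        merged = merge_rounds([h_low, h_high])
        assert merged[("mk1", "bd")] == h_high

    def test_highest_mapq_wins_within_a_round(self):
        a = hit(rnd="low", mapq=40, start=1000)
        b = hit(rnd="low", mapq=12, start=9000)
        assert merge_rounds([a, b])[("mk1", "bd")] == a

    def test_equal_mapq_at_distinct_loci_is_ambiguous(self):
        a = hit(rnd="high", mapq=42, chrom="bd1")
        b = hit(rnd="high", mapq=42, chrom="bd2")
        assert merge_rounds([a, b]) == {}

    def test_duplicate_reports_of_same_locus_collapse(self):
        a = hit(rnd="high", mapq=42)
        assert merge_rounds([a, a])[("mk1", "bd")] == a

    def test_secondary_hits_do_not_compete(self):
        primary = hit(rnd="high", mapq=30, start=1000)
        secondary = hit(rnd="high", mapq=50, start=9000, secondary=True)
        assert merge_rounds([primary, secondary])[("mk1", "bd")] == primary

    def test_at_most_one_hit_per_marker_genome(self):
        hits = [hit(rnd=r, mapq=q, start=s)
                for r, q, s in [("high", 30, 0), ("medium", 50, 5000), ("low", 60, 9000)]]
        merged = merge_rounds(hits)
        assert list(merged) == [("mk1", "bd")]


def hotspot_with(members, hid=1):
    return Hotspot(
        hotspot_id=hid, chromosome="4B", ci_start_cM=59.0, ci_end_cM=60.0,
        member_ids=tuple(members), traits=("YPC",), pve_mean=0.11,
    )


class TestCallOrthoRegions:
    def merged(self, specs):
        return {
            (m, g): hit(marker=m, genome=g, chrom=c, start=s)
            for m, g, c, s in specs
        }

    def test_clustered_markers_become_one_region(self):
        merged = self.merged(
            [("a", "bd", "bd1", 100_000), ("b", "bd", "bd1", 400_000),
             ("c", "bd", "bd1", 900_000)]
        )
        (region,) = call_ortho_regions(hotspot_with(["a", "b", "c"]), merged)
        assert region.n_markers == 3 and region.target_chromosome == "bd1"
        assert region.start == 100_000 and region.end == 900_080

    def test_single_marker_makes_no_region(self):
        merged = self.merged([("a", "os", "os5", 100_000)])
        assert call_ortho_regions(hotspot_with(["a", "b"]), merged) == []

    def test_non_member_hits_are_ignored(self):
        merged = self.merged(
            [("a", "bd", "bd1", 100_000), ("z", "bd", "bd1", 200_000)]
        )
        assert call_ortho_regions(hotspot_with(["a", "b"]), merged) == []

    def test_distant_hits_split_into_clusters(self):
        merged = self.merged(
            [("a", "bd", "bd1", 0), ("b", "bd", "bd1", 100),
             ("c", "bd", "bd1", 20_000_000), ("d", "bd", "bd1", 20_000_100)]
        )
        regions = call_ortho_regions(hotspot_with(["a", "b", "c", "d"]), merged)
        assert len(regions) == 2

    def test_region_count_monotone_in_min_markers(self):
        merged = self.merged(
            [("a", "bd", "bd1", 0), ("b", "bd", "bd1", 100),
             ("c", "os", "os3", 0), ("d", "os", "os3", 50),
             ("e", "os", "os3", 90)]
        )
        h = hotspot_with(["a", "b", "c", "d", "e"])
        counts = [len(call_ortho_regions(h, merged, min_markers=k)) for k in (1, 2, 3, 4)]
        assert counts == sorted(counts, reverse=True)

    def test_marker_translation(self):
        merged = self.merged(
            [("snp1", "bd", "bd1", 0), ("snp2", "bd", "bd1", 100)]
        )
        h = hotspot_with(["mta1", "mta2"])
        assert call_ortho_regions(h, merged) == []
        (region,) = call_ortho_regions(
            h, merged, marker_of_member={"mta1": "snp1", "mta2": "snp2"}
        )
        assert region.supporting_marker_ids == ("snp1", "snp2")


@pytest.fixture(scope="module")
def fixture(tmp_path_factory):
    cfg = GeneratorConfig(seed=31)
    hotspots = [
        hotspot_with([f"h{j}_m{i}" for i in range(8)], hid=j) for j in range(1, 6)
    ]
    outdir = tmp_path_factory.mktemp("syn")
    paths, truth = generate_synteny_fixture(cfg, hotspots, outdir)
    hits = []
    for g in ("bd", "os", "zm"):
        for rnd in ("high", "medium", "low"):
            hits.extend(read_sam_hits(paths[f"sam_{g}_{rnd}"], g, rnd))
    return cfg, hotspots, paths, truth, hits


class TestPlantedFixture:

    def test_planted_regions_recovered_exactly(self, fixture):
        cfg, hotspots, paths, truth, hits = fixture
        merged = merge_rounds(filter_hits(hits))
        called = {
            (r.hotspot_id, r.target_genome, r.target_chromosome)
            for h in hotspots
            for r in call_ortho_regions(h, merged)
        }
        planted = {(r.hotspot_id, r.genome, r.chromosome) for r in truth.regions}
        assert called == planted

    def test_boundary_decoys_never_survive_filtering(self, fixture):
        *_, truth, hits = fixture
        surviving = {h.marker_id for h in filter_hits(hits)}
        assert surviving.isdisjoint(truth.length_decoy_markers)
        assert surviving.isdisjoint(truth.mapq_decoy_markers)

    def test_ambiguous_markers_dropped_at_merge(self, fixture):
        *_, truth, hits = fixture
        merged = merge_rounds(filter_hits(hits))
        merged_markers = {marker for marker, _ in merged}
        assert merged_markers.isdisjoint(truth.ambiguous_markers)

    def test_region_markers_are_hotspot_members(self, fixture):
        cfg, hotspots, paths, truth, hits = fixture
        merged = merge_rounds(filter_hits(hits))
        for h in hotspots:
            for region in call_ortho_regions(h, merged):
                assert set(region.supporting_marker_ids) <= set(h.member_ids)

    def test_ortho_marker_counts_add_up(self, fixture):
        cfg, hotspots, paths, truth, hits = fixture
        merged = merge_rounds(filter_hits(hits))
        regions = [r for h in hotspots for r in call_ortho_regions(h, merged)]
        counts = ortho_marker_counts(regions)
        assert counts["total"] == sum(v for k, v in counts.items() if k != "total")


GFF_TOY = """##gff-version 3
##sequence-region bd1 1 1000000
bd1\ttoy\tgene\t101\t200\t.\t+\t.\tID=g1;description=first
bd1\ttoy\tgene\t301\t400\t.\t-\t.\tID=g2;description=second
bd1\ttoy\tgene\t351\t500\t.\t+\t.\tID=g3;description=third
bd1\ttoy\tgene\t800\t900\t.\t+\t.\tID=g4
bd1\ttoy\tgene\t950\t990\t.\t+\t.\tID=g5
"""


@pytest.fixture(scope="module")
def db(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text(GFF_TOY)
    return load_gff(path, "bd")


class TestGenesInInterval:

    def test_overlapping_gene_returned(self, db):
        genes = genes_in_interval(db, "bd", "bd1", 150, 300)
        assert [g.gene_id for g in genes] == ["g1"]
        assert genes[0].start == 100 and genes[0].end == 200  # 0-based half-open

    def test_half_open_boundary_excluded(self, db):
        assert genes_in_interval(db, "bd", "bd1", 200, 300) == []

    def test_query_covering_two_genes(self, db):
        genes = genes_in_interval(db, "bd", "bd1", 310, 360)
        assert [g.gene_id for g in genes] == ["g2", "g3"]

    def test_unknown_chromosome_warns_and_returns_empty(self, db):
        with pytest.warns(UserWarning, match="absent"):
            assert genes_in_interval(db, "bd", "bd99", 0, 100) == []


def test_alignment_hit_invariants():
    with pytest.raises(ValueError):
        hit(aligned=120, length=100)
    with pytest.raises(ValueError):
        AlignmentHit("m", "bd", "bd1", 10, 10, 100, 50, 30, "high")
    with pytest.raises(ValueError):
        hit(rnd="ultra")
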