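"""CI standardization, the overview index, peak detection and hotspot calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from mqtlhot.hotspots import (
    Hotspot,
    OverviewProfile,
    detect_peaks,
    high_threshold,
    mean_threshold,
    merge_peaks,
    overview_index,
    select_breeding,
    standardize,
)
from mqtlhot.io_model import GeneticMap, ValidationError
from mqtlhot.projection import ProjectedMTA
from mqtlhot.synthetic_data import GeneratorConfig, generate_database
from mqtlhot import (
    load_genetic_map,
    load_ld_decay,
    load_mta,
    project_database,
)


def pmta(mta_id="m1", chrom="1A", pos=50.0, ci=3.92, pve=None):
    return ProjectedMTA(
        mta_id=mta_id, study_id="s1", trait_code="YPC", chromosome=chrom,
        position_cM=pos, ci_cM=ci, ci_source="original", projection_flag="identity",
        pve=pve,
    )


def bare_map(lengths):
    return GeneticMap("consensus", {}, lengths)


class TestStandardize:
    def test_unit_ci(self):
        s = standardize(pmta(ci=3.92))
        assert s.s == pytest.approx(1.0) and s.s_squared == pytest.approx(1.0)

    def test_s_squared_is_the_square(self):
        assert standardize(pmta(ci=7.84)).s_squared == pytest.approx(4.0)

    def test_zero_ci_is_rejected(self):
        with pytest.raises(Exception):
            standardize(pmta(ci=0.0))


class TestOverviewIndex:
    def test_point_mass_lands_in_one_bin(self):
        profile = overview_index(
            [standardize(pmta(pos=50.5, ci=1e-6))], bare_map({"1A": 100.0})
        )["1A"]
        assert profile.u[50] == pytest.approx(1.0)
        assert profile.u.sum() == pytest.approx(1.0)

    def test_interior_mta_conserves_unit_mass(self):
        profile = overview_index(
            [standardize(pmta(pos=50.0, ci=3.92))], bare_map({"1A": 100.0})
        )["1A"]
        assert profile.u.sum() == pytest.approx(1.0, abs=1e-6)

    def test_against_fine_grid_integration_oracle(self):
        # brute-force oracle: integrate each Gaussian pdf over every bin on a
        # fine grid and compare bin by bin
        rng = np.random.default_rng(5)
        mtas = [
            standardize(pmta(mta_id=f"m{i}", pos=float(p), ci=float(c)))
            for i, (p, c) in enumerate(
                zip(rng.uniform(10, 90, 5), rng.uniform(0.5, 8, 5))
            )
        ]
        profile = overview_index(mtas, bare_map({"1A": 100.0}))["1A"]
        grid = np.linspace(0, 100, 100 * 400 + 1)
        dense = np.zeros_like(grid)
        for m in mtas:
            dense += norm.pdf(grid, loc=m.position_cM, scale=m.s)
        oracle = np.add.reduceat(
            (dense[:-1] + dense[1:]) / 2 * np.diff(grid), np.arange(0, 100 * 400, 400)
        )
        np.testing.assert_allclose(profile.u, oracle, atol=1e-5)

    def test_mean_approximates_density(self):
        # N interior MTAs on a length-L map: mean u ~= N / L
        rng = np.random.default_rng(7)
        mtas = [
            standardize(pmta(mta_id=f"m{i}", pos=float(p), ci=2.0))
            for i, p in enumerate(rng.uniform(20, 180, 40))
        ]
        profiles = overview_index(mtas, bare_map({"1A": 200.0}))
        assert mean_threshold(profiles) == pytest.approx(40 / 200.0, rel=1e-3)

    def test_mta_off_the_map_is_an_error(self):
        with pytest.raises(ValidationError):
            overview_index([standardize(pmta(chrom="2B"))], bare_map({"1A": 100.0}))

    def test_unmapped_chromosomes_get_zero_profiles(self):
        profiles = overview_index(
            [standardize(pmta())], bare_map({"1A": 100.0, "1B": 50.0})
        )
        assert profiles["1B"].u.sum() == 0.0 and profiles["1B"].n_bins == 50


class TestThresholds:
    def test_uniform_profile_mean_and_high(self):
        profiles = {
            "1A": OverviewProfile("1A", np.full(100, 0.3)),
            "1B": OverviewProfile("1B", np.full(60, 0.3)),
        }
        mean = mean_threshold(profiles)
        assert mean == pytest.approx(0.3)
        assert high_threshold(mean) == pytest.approx(1.5)
        assert high_threshold(mean) / mean == pytest.approx(5.0)

    def test_empty_profiles_error(self):
        with pytest.raises(ValidationError):
            mean_threshold({})

    def test_ci_rescaling_leaves_interior_mean_unchanged(self):
        rng = np.random.default_rng(3)
        positions = rng.uniform(30, 170, 30)
        mk = lambda ci: overview_index(
            [standardize(pmta(mta_id=f"m{i}", pos=float(p), ci=ci))
             for i, p in enumerate(positions)],
            bare_map({"1A": 200.0}),
        )
        assert mean_threshold(mk(2.0)) == pytest.approx(
            mean_threshold(mk(4.0)), abs=1e-6
        )


class TestDetectPeaks:
    def prof(self, u):
        return OverviewProfile("1A", np.asarray(u, dtype=float))

    def test_single_spike(self):
        peaks = detect_peaks(self.prof([0, 0, 1, 0, 0]), 0.5)
        assert [(p.bin, p.run_start, p.run_end) for p in peaks] == [(2, 2, 2)]

    def test_plateau_counts_once_at_leftmost_bin(self):
        peaks = detect_peaks(self.prof([0, 1, 1, 1, 0]), 0.5)
        assert [(p.bin, p.run_start, p.run_end) for p in peaks] == [(1, 1, 3)]

    def test_two_separated_gaussians_give_two_peaks(self):
        edges = np.arange(101.0)
        cdf = norm.cdf
        u = (cdf(edges[1:], 35, 1) - cdf(edges[:-1], 35, 1)) + (
            cdf(edges[1:], 65, 1) - cdf(edges[:-1], 65, 1)
        )
        peaks = detect_peaks(self.prof(u), 0.2)
        assert len(peaks) == 2 and {p.bin for p in peaks} <= {34, 35, 64, 65}

    def test_one_run_can_hold_two_peaks(self):
        peaks = detect_peaks(self.prof([0, 1, 0.8, 1.2, 0]), 0.5)
        assert [p.bin for p in peaks] == [1, 3]
        assert all((p.run_start, p.run_end) == (1, 3) for p in peaks)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            detect_peaks(self.prof([1.0]), 0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 3), min_size=5, max_size=60), st.data())
    def test_peak_count_monotone_in_threshold(self, u, data):
        lo = data.draw(st.floats(0.05, 2.0))
        hi = data.draw(st.floats(lo, 3.0))
        prof = self.prof(u)
        assert len(detect_peaks(prof, hi)) <= len(detect_peaks(prof, lo))


class TestMergePeaks:
    def test_adjacent_runs_merge_into_one_hotspot(self):
        u = np.zeros(30)
        u[10:13] = [1, 2, 1]
        u[13:16] = [1, 3, 1]
        peaks = detect_peaks(OverviewProfile("1A", u), 0.5)
        hotspots = merge_peaks(peaks, [])
        assert len(hotspots) == 1
        assert (hotspots[0].ci_start_cM, hotspots[0].ci_end_cM) == (10.0, 16.0)

    def test_small_gap_merges_large_gap_does_not(self):
        u = np.zeros(100)
        u[10], u[13] = 1.0, 1.0  # gap of 2 empty bins <= merge_gap
        u[60] = 1.0  # far away
        peaks = detect_peaks(OverviewProfile("1A", u), 0.5)
        hotspots = merge_peaks(peaks, [], merge_gap_cM=2.0)
        spans = [(h.ci_start_cM, h.ci_end_cM) for h in hotspots]
        assert spans == [(10.0, 14.0), (60.0, 61.0)]

    def test_members_assigned_by_ci_overlap(self):
        u = np.zeros(100)
        u[50] = 1.0
        peaks = detect_peaks(OverviewProfile("1A", u), 0.5)
        inside = standardize(pmta(mta_id="in", pos=50.5, ci=1.0))
        touching = standardize(pmta(mta_id="edge", pos=52.5, ci=4.0))  # CI [50.5,54.5]
        outside = standardize(pmta(mta_id="out", pos=60.0, ci=2.0))
        (h,) = merge_peaks(peaks, [inside, touching, outside])
        assert h.member_ids == ("in", "edge")

    def test_ids_are_sequential_along_the_genome(self):
        u1 = np.zeros(50); u1[5] = 1.0; u1[40] = 1.0
        u2 = np.zeros(50); u2[10] = 1.0
        peaks = detect_peaks(OverviewProfile("1B", u2), 0.5) + detect_peaks(
            OverviewProfile("1A", u1), 0.5
        )
        ids = [(h.hotspot_id, h.chromosome, h.ci_start_cM) for h in merge_peaks(peaks, [])]
        assert ids == [(1, "1A", 5.0), (2, "1A", 40.0), (3, "1B", 10.0)]

    def test_five_planted_clusters_are_recovered_exactly(self, tmp_path):
        cfg = GeneratorConfig(
            seed=23, n_mta=100, n_planted_hotspots=5, fraction_background=0.0
        )
        paths, truth = generate_database(cfg, tmp_path)
        mta = load_mta(paths["mta"])
        gmap = load_genetic_map(paths["map"])
        ld = load_ld_decay(paths["ld_decay"])
        std = [standardize(p) for p in project_database(mta, None, gmap, ld)]
        profiles = overview_index(std, gmap)
        thr = high_threshold(mean_threshold(profiles))
        peaks = [p for c in profiles for p in detect_peaks(profiles[c], thr)]
        hotspots = merge_peaks(peaks, std)
        assert len(hotspots) == 5
        for cluster in truth.clusters:
            (match,) = [
                h for h in hotspots
                if h.chromosome == cluster.chromosome
                and h.ci_start_cM - 3 * cluster.sd_cM
                <= cluster.center_cM
                <= h.ci_end_cM + 3 * cluster.sd_cM
            ]
            recovered = len(set(cluster.member_ids) & set(match.member_ids))
            assert recovered >= 0.9 * len(cluster.member_ids)


def hot(n, pve, width, hid=1):
    return Hotspot(
        hotspot_id=hid, chromosome="1A", ci_start_cM=10.0, ci_end_cM=12.0,
        member_ids=tuple(f"m{i}" for i in range(n)), traits=("YPC",),
        pve_mean=pve, physical_ci_Mb={"Svevo": (100.0, 100.0 + width)},
    )


class TestSelectBreeding:
    @pytest.mark.parametrize(
        "n,pve,width,expected",
        [
            (5, 0.04, 10.0, True),   # boundary of the large-hotspot PVE rule
            (11, 0.07, 6.5, True),
            (3, 0.13, 4.2, True),
            (3, 0.08, 5.0, False),   # fails the strict > 0.1 small-hotspot rule
            (3, 0.10, 5.0, False),
            (6, 0.04, 25.0, False),  # fails the physical width rule
            (5, 0.039, 10.0, False),
            (2, 0.5, 1.0, False),    # fewer than 3 members is never breeding
            (4, 0.15, 5.0, True),    # 4 members follow the small-hotspot branch
        ],
    )
    def test_selection_rule(self, n, pve, width, expected):
        assert select_breeding(hot(n, pve, width)).is_breeding is expected

    def test_all_missing_pve_is_never_breeding(self):
        assert select_breeding(hot(6, None, 5.0)).is_breeding is False

    def test_missing_physical_ci_is_an_error(self):
        h = Hotspot(1, "1A", 0.0, 1.0, ("m",), ("YPC",), 0.2)
        with pytest.raises(ValidationError):
            select_breeding(h)
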