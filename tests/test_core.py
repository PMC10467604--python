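"""Reading, filtering, tiling and region profiles."""

import numpy as np
import pandas as pd
import pytest

from methylotype import (
    FilterConfig,
    combine_samples,
    filter_sites,
    read_cpg_report,
    region_mean_methylation,
    tile_100bp,
)
from conftest import make_tile_matrix


def _write(tmp_path, text, name="report.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCpgReport:
    def test_counts_are_meth_plus_unmeth(self, tmp_path):
        p = _write(tmp_path, "chr1\t101\t+\t5\t5\n")
        df = read_cpg_report(p)
        assert df.iloc[0].tolist() == ["chr1", 101, 5, 10]

    def test_minus_strand_collapses_onto_plus_cytosine(self, tmp_path):
        # expected merge computed by hand: +101 (3/6) and -102 (1/4)
        p = _write(tmp_path, "chr1\t101\t+\t3\t3\nchr1\t102\t-\t1\t3\n")
        df = read_cpg_report(p)
        assert len(df) == 1
        assert df.iloc[0].tolist() == ["chr1", 101, 4, 10]

    def test_sorted_by_position(self, tmp_path):
        p = _write(tmp_path, "chr1\t301\t+\t1\t1\nchr1\t101\t+\t1\t1\n")
        assert read_cpg_report(p)["pos"].tolist() == [101, 301]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "chr1\t101\t+\t5\t5\nchr1\tnotanint\t+\t1\t1\n")
        with pytest.raises(ValueError, match="line 2"):
            read_cpg_report(p)

    def test_negative_counts_rejected(self, tmp_path):
        p = _write(tmp_path, "chr1\t101\t+\t-1\t5\n")
        with pytest.raises(ValueError, match="negative"):
            read_cpg_report(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = _write(tmp_path, "")
        with pytest.warns(UserWarning, match="empty"):
            df = read_cpg_report(p)
        assert len(df) == 0


def _site_matrix(rows, samples):
    """rows: list of (chrom, pos, {sample: (meth, total)})."""
    data = {
        s: pd.DataFrame(
            [(c, p, mt[s][0], mt[s][1]) for c, p, mt in rows if s in mt],
            columns=["chrom", "pos", "count_meth", "count_total"],
        )
        for s in samples
    }
    return combine_samples(data)


class TestFilterSites:
    @pytest.mark.parametrize("total,kept", [(9, False), (10, True), (500, True), (501, False)])
    def test_coverage_bounds_inclusive(self, total, kept):
        sm = _site_matrix([("chr1", 101, {"A": (1, total)})], ["A"])
        out = filter_sites(sm, FilterConfig())
        assert np.isfinite(out.total["A"].iloc[0]) == kept

    def test_sex_chromosome_dropped_for_all_samples(self):
        sm = _site_matrix(
            [("chrX", 101, {"A": (5, 20)}), ("chr1", 101, {"A": (5, 20)})], ["A"]
        )
        out = filter_sites(sm, FilterConfig(excluded_chroms=frozenset({"chrX"})))
        assert out.features["chrom"].tolist() == ["chr1"]

    def test_blacklisted_position_dropped(self):
        sm = _site_matrix(
            [("chr1", 101, {"A": (5, 20)}), ("chr1", 201, {"A": (5, 20)})], ["A"]
        )
        out = filter_sites(sm, FilterConfig(snp_blacklist=frozenset({("chr1", 101)})))
        assert out.features["pos"].tolist() == [201]

    def test_masking_is_per_sample(self):
        sm = _site_matrix([("chr1", 101, {"A": (1, 5), "B": (5, 20)})], ["A", "B"])
        out = filter_sites(sm, FilterConfig())
        assert np.isnan(out.total["A"].iloc[0]) and out.total["B"].iloc[0] == 20

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(min_cov=100, max_cov=10)


class TestTiling:
    def test_sites_in_same_window_are_summed(self):
        # hand aggregation: positions 3 and 57 share window [0, 100)
        sm = _site_matrix(
            [("chr1", 3, {"A": (2, 10)}), ("chr1", 57, {"A": (3, 14)})], ["A"]
        )
        tiles = tile_100bp(sm)
        assert len(tiles) == 1
        assert tiles.features.iloc[0][["start", "end", "n_cpgs"]].tolist() == [0, 100, 2]
        assert tiles.meth["A"].iloc[0] == 5 and tiles.total["A"].iloc[0] == 24

    def test_window_boundary_arithmetic(self):
        sm = _site_matrix(
            [("chr1", 100, {"A": (1, 2)}), ("chr1", 101, {"A": (1, 2)})], ["A"]
        )
        tiles = tile_100bp(sm)
        assert tiles.features["start"].tolist() == [0, 100]

    def test_fraction_identity(self):
        sm = _site_matrix([("chr1", 10, {"A": (12, 24)})], ["A"])
        assert tile_100bp(sm).fraction()["A"].iloc[0] == 0.5

    def test_counts_conserved_under_tiling(self, small_bundle):
        sites = combine_samples(small_bundle.reports)
        sites = filter_sites(sites, FilterConfig())
        tiles = tile_100bp(sites)
        for s in list(sites.samples)[:3]:
            assert np.nansum(tiles.total[s]) == pytest.approx(np.nansum(sites.total[s]))

    def test_filter_tile_commutes_with_sample_subsetting(self, small_bundle):
        samples = list(small_bundle.reports)[:4]
        cfg = FilterConfig()
        full = tile_100bp(filter_sites(combine_samples(small_bundle.reports), cfg))
        sub = tile_100bp(filter_sites(
            combine_samples({s: small_bundle.reports[s] for s in samples}), cfg))
        merged_a = full.meth[samples].fillna(-1).to_numpy()
        # full matrix may contain extra tiles covered only in other samples
        keys_full = full.features["chrom"].astype(str) + ":" + full.features["start"].astype(str)
        keys_sub = sub.features["chrom"].astype(str) + ":" + sub.features["start"].astype(str)
        sel = keys_full.isin(set(keys_sub)).to_numpy()
        np.testing.assert_array_equal(merged_a[sel], sub.meth[samples].fillna(-1).to_numpy())


class TestRegionProfile:
    def test_constant_field_gives_flat_profile(self):
        tiles = make_tile_matrix([[7], [14], [7]], [[10], [20], [10]])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        profile, scalar, _ = region_mean_methylation(tiles, regions, flank_bp=100, n_bins=2, n_flank_bins=1)
        vals = profile["S1"].dropna()
        assert np.allclose(vals, 0.7)
        assert scalar["S1"] == pytest.approx(0.7)

    def test_scalar_is_coverage_weighted_mean(self):
        # two tiles, fractions 0.2 and 0.8 at equal coverage -> 0.5
        tiles = make_tile_matrix([[2], [8]], [[10], [10]])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200]})
        _, scalar, _ = region_mean_methylation(tiles, regions, flank_bp=100, n_bins=2, n_flank_bins=1)
        assert scalar["S1"] == pytest.approx(0.5)

    def test_invariant_to_region_order(self, small_tiles, small_bundle):
        regions = small_bundle.annotations["repeat"].head(40)
        p1, s1, _ = region_mean_methylation(small_tiles, regions)
        p2, s2, _ = region_mean_methylation(
            small_tiles, regions.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_series_equal(s1, s2)

    def test_group_offset_visible_in_repeat_profile(self, small_tiles, small_bundle):
        """KRT sits below IMU across repeat bodies, as planted globally."""
        regions = small_bundle.annotations["repeat"]
        profile, _, _ = region_mean_methylation(small_tiles, regions)
        groups = small_bundle.config.samples_by_group
        imu = profile[groups["IMU"]].mean(axis=1)
        krt = profile[groups["KRT"]].mean(axis=1)
        body = [b for b in profile.index if b.startswith("b")]
        assert (krt[body] < imu[body]).all()

    def test_empty_region_counted(self):
        tiles = make_tile_matrix([[5]], [[10]])
        regions = pd.DataFrame({"chrom": ["chr9", "chr1"], "start": [0, 0], "end": [100, 100]})
        _, _, n_empty = region_mean_methylation(tiles, regions, flank_bp=100)
        assert n_empty == 1
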