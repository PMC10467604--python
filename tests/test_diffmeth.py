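"""Differential methylation: coverage rule, dispersion, test behaviour."""

import numpy as np
import pandas as pd
import pytest

from methylotype import (
    GroupDesign,
    eligible_tiles,
    estimate_dispersion,
    simulate_tile_counts,
    summarize_dmrs,
)
from methylotype import test_tiles as wald_test
from methylotype.diffmeth import coverage_rule_threshold, summarize_counts
from conftest import make_tile_matrix


class TestGroupDesign:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupDesign(("a", "b"), ("b", "c"))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign((), ("a",))

    def test_missing_covariate_rows_rejected(self):
        cov = pd.DataFrame({"age": [60.0]}, index=["a"])
        with pytest.raises(ValueError, match="b"):
            GroupDesign(("a",), ("b",), covariates=cov)


class TestCoverageRule:
    @pytest.mark.parametrize("n,needed", [(8, 7), (10, 8), (18, 15), (5, 4)])
    def test_threshold_is_ceiling_of_80pct(self, n, needed):
        assert coverage_rule_threshold(n) == needed

    def test_six_of_eight_excluded_eight_of_ten_kept(self):
        # groupA n=8 covered in 6 -> 6 < ceil(6.4)=7 -> excluded;
        # groupB n=10 covered in 8 -> 8 = ceil(8) -> kept
        n_a, n_b = 8, 10
        total = np.ones((2, n_a + n_b)) * 20.0
        total[0, :2] = np.nan            # tile 0: 6/8 in group A
        total[1, n_a:n_a + 2] = np.nan   # tile 1: 8/10 in group B
        meth = np.where(np.isfinite(total), 10.0, np.nan)
        tiles = make_tile_matrix(meth, total)
        design = GroupDesign(tuple(tiles.samples[:n_a]), tuple(tiles.samples[n_a:]))
        mask = eligible_tiles(tiles, design)
        assert mask.tolist() == [False, True]

    def test_fully_covered_tile_kept(self):
        tiles = make_tile_matrix(np.ones((1, 18)) * 5, np.ones((1, 18)) * 20)
        design = GroupDesign(tuple(tiles.samples[:8]), tuple(tiles.samples[8:]))
        assert eligible_tiles(tiles, design).all()

    def test_no_eligible_tile_is_an_error(self):
        total = np.full((1, 4), np.nan)
        total[0, 0] = 20.0
        tiles = make_tile_matrix(np.where(np.isfinite(total), 5.0, np.nan), total)
        design = GroupDesign(tuple(tiles.samples[:2]), tuple(tiles.samples[2:]))
        with pytest.raises(ValueError, match="sparse"):
            eligible_tiles(tiles, design)


class TestDispersion:
    def _design(self, tiles, n_a=8):
        return GroupDesign(tuple(tiles.samples[:n_a]), tuple(tiles.samples[n_a:]))

    def test_identical_counts_hit_the_floor(self):
        tiles = make_tile_matrix(np.full((20, 18), 10.0), np.full((20, 18), 20.0))
        disp = estimate_dispersion(tiles, self._design(tiles))
        assert (disp.phi_raw <= 1e-5).all()

    def test_parameter_recovery_on_simulation(self):
        rng = np.random.default_rng(1)
        tiles, design = simulate_tile_counts(rng, 3000, 8, 10, 24.0, 0.1, 0.0)
        disp = estimate_dispersion(tiles, design)
        assert 0.05 <= np.median(disp.phi_shrunk) <= 0.2

    def test_infinite_shrinkage_returns_prior(self):
        rng = np.random.default_rng(2)
        tiles, design = simulate_tile_counts(rng, 200, 8, 10, 24.0, 0.1, 0.0)
        disp = estimate_dispersion(tiles, design, shrink_k=1e12)
        assert np.allclose(disp.phi_shrunk, disp.prior_center, atol=1e-6)

    def test_phi_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        tiles, design = simulate_tile_counts(rng, 500, 8, 10, 24.0, 0.3, 0.0)
        disp = estimate_dispersion(tiles, design)
        assert ((disp.phi_shrunk > 0) & (disp.phi_shrunk < 1)).all()


class TestTestTiles:
    def test_identical_groups_are_null(self):
        tiles = make_tile_matrix(np.full((5, 18), 10.0), np.full((5, 18), 20.0))
        design = GroupDesign(tuple(tiles.samples[:8]), tuple(tiles.samples[8:]))
        rec = wald_test(tiles, design)
        assert np.allclose(rec["diff_pp"], 0)
        assert (rec["p"] > 0.9).all()
        assert not rec["is_dmr"].any()

    def test_group_swap_negates_difference_keeps_p(self):
        rng = np.random.default_rng(4)
        tiles, design = simulate_tile_counts(rng, 300, 8, 10, 24.0, 0.05, 15.0)
        disp = estimate_dispersion(tiles, design)
        fwd = wald_test(tiles, design, disp)
        rev = wald_test(tiles, design.swapped(), disp)
        np.testing.assert_allclose(fwd["diff_pp"], -rev["diff_pp"], atol=1e-9)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-9)
        swapped = fwd["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        assert (swapped.to_numpy() == rev["direction"].to_numpy()).all()

    def test_dmr_set_invariant_to_record_order(self):
        rng = np.random.default_rng(5)
        tiles, design = simulate_tile_counts(rng, 400, 8, 10, 24.0, 0.05, 25.0)
        rec = wald_test(tiles, design)
        perm = np.random.default_rng(0).permutation(len(tiles))
        rec_perm = wald_test(tiles.subset(np.isin(np.arange(len(tiles)), perm)), design)
        assert set(rec.loc[rec["is_dmr"], "tile"]) == set(
            rec_perm.loc[rec_perm["is_dmr"], "tile"])

    def test_fdr_monotone_in_p(self):
        rng = np.random.default_rng(6)
        tiles, design = simulate_tile_counts(rng, 500, 8, 10, 24.0, 0.05, 0.0)
        rec = wald_test(tiles, design).sort_values("p")
        fdr = rec["fdr"].to_numpy()
        assert (np.diff(fdr) >= -1e-12).all()

    def test_group_aliased_covariate_triggers_flagged_fallback(self):
        """A covariate duplicating the group indicator makes the design
        singular; the test falls back to the covariate-free fit."""
        rng = np.random.default_rng(8)
        tiles, design = simulate_tile_counts(rng, 50, 8, 10, 24.0, 0.05, 0.0)
        alias = pd.DataFrame(
            {"dup": [1.0] * 8 + [0.0] * 10}, index=design.samples)
        bad = GroupDesign(design.group_a, design.group_b, covariates=alias)
        rec = wald_test(tiles, bad)
        assert rec["fallback"].all()
        assert np.isfinite(rec["p"]).all()

    def test_covariate_signal_is_adjusted_for(self):
        """A strong covariate effect uncorrelated with group stays null."""
        rng = np.random.default_rng(7)
        n_a, n_b = 8, 10
        cov_val = np.tile([0.0, 1.0], 9)
        base = 0.3 + 0.3 * cov_val  # methylation driven by covariate only
        cov_mat = np.broadcast_to(base, (400, 18))
        total = np.full((400, 18), 24.0)
        meth = rng.binomial(24, cov_mat).astype(float)
        tiles = make_tile_matrix(meth, total)
        cov = pd.DataFrame({"c": cov_val}, index=tiles.samples)
        design = GroupDesign(tuple(tiles.samples[:n_a]), tuple(tiles.samples[n_a:]),
                             covariates=cov)
        rec = wald_test(tiles, design)
        assert (rec["p"] < 0.05).mean() < 0.1
        assert not rec["is_dmr"].any()


class TestSummaries:
    @pytest.mark.parametrize(
        "n_tested,n_hyper,n_hypo,expect",
        [
            (3_757_540, 305_812, 14_259, (96, 4, 9)),
            (3_383_553, 266_762, 3_564, (99, 1, 8)),
            (3_453_805, 8_052, 15_705, (34, 66, 1)),
            (3_326_189, 87_889, 1_798, (98, 2, 3)),
        ],
    )
    def test_share_arithmetic(self, n_tested, n_hyper, n_hypo, expect):
        row = summarize_counts(n_tested, n_hyper, n_hypo)
        assert (row["hyper_pct"], row["hypo_pct"], row["dmr_pct"]) == expect

    def test_zero_dmrs_flagged(self):
        row = summarize_counts(1000, 0, 0)
        assert row["no_dmrs"] and row["hyper_pct"] == 0 and row["hypo_pct"] == 0

    def test_summarize_records_matches_counts(self):
        rec = pd.DataFrame({
            "contrast": "x",
            "direction": ["hyper"] * 3 + ["hypo"] * 2 + ["hyper"] * 5,
            "is_dmr": [True] * 5 + [False] * 5,
        })
        row = summarize_dmrs(rec)
        assert (row["n_hyper"], row["n_hypo"], row["n_tested"]) == (3, 2, 10)
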