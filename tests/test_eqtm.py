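"""cis-eQTM filters, candidate enumeration and association fits."""

import numpy as np
import pandas as pd
import pytest

from methylotype.eqtm import (
    EQTMFilterConfig,
    cis_pairs,
    eqtm_dmr_overlap,
    filter_eqtm_tiles,
    fit_eqtm,
)
from conftest import make_tile_matrix


def _tiles_36(frac_rows, coverage=20.0):
    frac = np.asarray(frac_rows, dtype=float)
    total = np.where(np.isfinite(frac), coverage, np.nan)
    meth = np.where(np.isfinite(frac), frac * coverage, np.nan)
    return make_tile_matrix(meth, total)


class TestFilters:
    def test_constant_tile_removed_by_cv(self):
        rng = np.random.default_rng(0)
        variable = rng.uniform(0.1, 0.9, size=(50, 36))
        rows = np.vstack([np.full((1, 36), 0.5), variable])
        mask = filter_eqtm_tiles(_tiles_36(rows))
        assert not mask[0]
        assert mask[1:].sum() > 40

    def test_28_of_36_coverage_removed(self):
        rng = np.random.default_rng(1)
        rows = rng.uniform(0.1, 0.9, size=(40, 36))
        rows[0, :8] = np.nan  # 28 of 36 < ceil(0.8*36)=29
        mask = filter_eqtm_tiles(_tiles_36(rows))
        assert not mask[0]

    def test_34_fully_unmethylated_removed(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(0.1, 0.9, size=(40, 36))
        rows[0, :34] = 0.0
        mask = filter_eqtm_tiles(_tiles_36(rows))
        assert not mask[0]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            EQTMFilterConfig(min_sample_frac=0.0)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"])


class TestCisPairs:
    def test_one_megabase_boundary_inclusive(self):
        tiles = make_tile_matrix([[0.5]], [[20.0]])  # midpoint 50
        genes = _genes([("g1", "chr1", "+", 1_000_050), ("g2", "chr1", "+", 1_000_051)])
        pairs = cis_pairs(tiles, genes)
        assert pairs["gene"].tolist() == ["g1"]
        assert pairs["tss_distance_bp"].iloc[0] == -1_000_000

    def test_other_chromosome_excluded(self):
        tiles = make_tile_matrix([[0.5]], [[20.0]])
        pairs = cis_pairs(tiles, _genes([("g1", "chr2", "+", 100)]))
        assert len(pairs) == 0

    def test_signed_distance_is_strand_aware(self):
        tiles = make_tile_matrix([[0.5]], [[20.0]])  # midpoint 50
        pairs = cis_pairs(tiles, _genes([("gm", "chr1", "-", 1000)]))
        # tile upstream on the minus strand means positive genomic offset
        assert pairs["tss_distance_bp"].iloc[0] == 950

    def test_counts_match_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        n_tiles = 300
        frac = rng.uniform(0, 1, size=(n_tiles, 1))
        tiles = make_tile_matrix(frac * 20, np.full((n_tiles, 1), 20.0))
        genes = _genes([
            (f"g{i}", "chr1", "+", int(t)) for i, t in
            enumerate(rng.integers(0, 60_000, size=200))
        ])
        pairs = cis_pairs(tiles, genes, max_dist=5_000)
        mids = tiles.features["start"].to_numpy() + 50
        expected = sum(
            int(abs(m - t) <= 5_000) for m in mids for t in genes["tss"]
        )
        assert len(pairs) == expected


class TestFit:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(4)
        frac = rng.uniform(0.1, 0.9, size=(1, 36))
        tiles = _tiles_36(frac)
        genes = _genes([("g1", "chr1", "+", 500)])
        pairs = cis_pairs(tiles, genes)
        expr = pd.DataFrame([2.0 * frac[0]], index=["g1"], columns=tiles.samples)
        out = fit_eqtm(pairs, tiles, expr)
        assert out["slope"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert out["p"].iloc[0] < 1e-12
        assert out["sign"].iloc[0] == "positive"

    def test_slope_equals_partial_regression_oracle(self):
        """With covariates, the slope equals residual-on-residual OLS."""
        rng = np.random.default_rng(5)
        frac = rng.uniform(0.1, 0.9, size=(1, 36))
        tiles = _tiles_36(frac)
        cov = pd.DataFrame(
            {"sex": rng.integers(0, 2, 36), "age": rng.normal(60, 8, 36)},
            index=tiles.samples, dtype=float,
        )
        y = 1.5 * frac[0] + 0.3 * cov["sex"].to_numpy() + rng.normal(0, 0.5, 36)
        expr = pd.DataFrame([y], index=["g1"], columns=tiles.samples)
        pairs = cis_pairs(tiles, _genes([("g1", "chr1", "+", 500)]))
        out = fit_eqtm(pairs, tiles, expr, covariates=cov)

        x_full = np.column_stack([np.ones(36), cov.to_numpy()])
        h = x_full @ np.linalg.pinv(x_full)
        rm = frac[0] - h @ frac[0]
        ry = y - h @ y
        oracle = float((rm @ ry) / (rm @ rm))
        assert out["slope"].iloc[0] == pytest.approx(oracle, rel=1e-10)

    def test_rank_deficient_pair_skipped_with_reason(self):
        frac = np.full((1, 36), np.nan)
        frac[0, :5] = 0.5
        tiles = _tiles_36(frac)
        pairs = cis_pairs(tiles, _genes([("g1", "chr1", "+", 500)]))
        expr = pd.DataFrame([np.ones(36)], index=["g1"], columns=tiles.samples)
        out = fit_eqtm(pairs, tiles, expr)
        assert out["skipped"].iloc[0] == "too_few_samples"

    def test_significant_set_invariant_to_pair_order(self):
        rng = np.random.default_rng(6)
        frac = rng.uniform(0.1, 0.9, size=(30, 36))
        tiles = _tiles_36(frac)
        genes = _genes([(f"g{i}", "chr1", "+", int(i * 100 + 50)) for i in range(30)])
        expr = pd.DataFrame(
            2.0 * frac + rng.normal(0, 1.0, size=(30, 36)),
            index=genes["gene"], columns=tiles.samples,
        )
        pairs = cis_pairs(tiles, genes, max_dist=2_000)
        out1 = fit_eqtm(pairs, tiles, expr)
        out2 = fit_eqtm(pairs.sample(frac=1.0, random_state=0), tiles, expr)
        sig1 = set(map(tuple, out1.loc[out1["significant"], ["tile", "gene"]].to_numpy()))
        sig2 = set(map(tuple, out2.loc[out2["significant"], ["tile", "gene"]].to_numpy()))
        assert sig1 == sig2


class TestOverlap:
    def test_share_arithmetic_on_printed_scale(self):
        """212,850 unique tiles with 65,917 DMR-overlapping gives 31%."""
        n_uniq, n_over = 212_850, 65_917
        eqtms = pd.DataFrame({
            "tile": [f"T{i}" for i in range(n_uniq)],
            "gene": "g",
            "sign": "positive",
            "significant": True,
        })
        dmrs = pd.DataFrame({
            "tile": [f"T{i}" for i in range(n_over)],
            "contrast": "IMU_vs_KRT",
            "direction": "hyper",
            "is_dmr": True,
        })
        res = eqtm_dmr_overlap(eqtms, dmrs)
        assert res["n_unique_eqtm_tiles"] == n_uniq
        assert res["n_overlapping_dmr"] == n_over
        assert res["overlap_pct"] == 31

    def test_empty_dmr_set_flags_nothing(self):
        eqtms = pd.DataFrame({
            "tile": ["T1", "T2"], "gene": "g", "sign": "negative",
            "significant": [True, True],
        })
        res = eqtm_dmr_overlap(eqtms, pd.DataFrame(
            columns=["tile", "contrast", "direction", "is_dmr"]))
        assert res["n_overlapping_dmr"] == 0
        assert not res["pairs"]["overlaps_dmr"].any()

    def test_counts_match_set_intersection_oracle(self):
        rng = np.random.default_rng(7)
        tiles_a = [f"T{i}" for i in rng.choice(1000, 400, replace=False)]
        tiles_b = [f"T{i}" for i in rng.choice(1000, 300, replace=False)]
        eqtms = pd.DataFrame({"tile": tiles_a, "gene": "g", "sign": "positive",
                              "significant": True})
        dmrs = pd.DataFrame({"tile": tiles_b, "contrast": "c", "direction": "hyper",
                             "is_dmr": True})
        res = eqtm_dmr_overlap(eqtms, dmrs)
        assert res["n_overlapping_dmr"] == len(set(tiles_a) & set(tiles_b))
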