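"""MIRA profiles/scores, deconvolution, pathway scores."""

import numpy as np
import pandas as pd
import pytest

from methylotype import simulate_mixtures
from methylotype.regsets import (
    deconvolve,
    deconvolve_cohort,
    mira_profile,
    mira_score,
    pathway_score,
)
from conftest import make_tile_matrix


def _regions(rows, strand=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if strand is not None:
        df["strand"] = strand
    return df


class TestMiraProfile:
    def test_uniform_methylome_gives_flat_profile(self):
        n = 200
        tiles = make_tile_matrix(np.full((n, 2), 12.0), np.full((n, 2), 20.0))
        prof = mira_profile(tiles, _regions([("chr1", 9_000, 9_400)]),
                            n_bins=11, flank_bp=2000)
        assert np.allclose(prof.dropna().to_numpy(), 0.6)

    def test_even_bin_count_rejected(self):
        tiles = make_tile_matrix([[1.0]], [[2.0]])
        with pytest.raises(ValueError, match="odd"):
            mira_profile(tiles, _regions([("chr1", 0, 100)]), n_bins=10)

    def test_invariant_to_region_order_and_strand_symmetry(self):
        rng = np.random.default_rng(0)
        n = 500
        tiles = make_tile_matrix(rng.integers(0, 20, (n, 3)).astype(float),
                                 np.full((n, 3), 20.0))
        regions = _regions([("chr1", 5_000, 5_400), ("chr1", 20_000, 20_400),
                            ("chr1", 33_000, 33_400)])
        p1 = mira_profile(tiles, regions)
        p2 = mira_profile(tiles, regions.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(p1, p2)
        # symmetric profile is unchanged by flipping all strands
        sym = mira_profile(tiles, _regions([("chr1", 20_000, 20_400)]))
        symf = mira_profile(tiles, _regions([("chr1", 20_000, 20_400)], strand="-"))
        np.testing.assert_allclose(
            sym.to_numpy(), symf.to_numpy()[::-1], equal_nan=True)

    def test_planted_dip_recovered(self, small_tiles, small_bundle):
        prof = mira_profile(small_tiles, small_bundle.region_sets["CTCF"],
                            n_bins=21, flank_bp=2000)
        center = prof.loc[0]
        shoulder = (prof.loc[-5] + prof.loc[5]) / 2
        assert (center < shoulder).all()


class TestMiraScore:
    def _profile(self, values):
        n = len(values)
        return pd.DataFrame(
            {f"S{i+1}": values for i in range(1)},
            index=np.arange(n) - n // 2,
        )

    def test_flat_profile_scores_exactly_zero(self):
        prof = self._profile([0.6] * 11)
        assert (mira_score(prof) == 0.0).all()

    def test_hand_computed_log_ratio(self):
        # shoulders 0.8, center 0.2 at offset 2 -> log2(4) = 2
        vals = [0.8] * 11
        vals[5] = 0.2
        prof = self._profile(vals)
        assert mira_score(prof, shoulder_offset=2)["S1"] == pytest.approx(2.0)

    def test_deeper_dip_scores_strictly_higher(self):
        shallow = [0.7] * 11
        deep = [0.7] * 11
        shallow[5], deep[5] = 0.2, 0.1
        assert (mira_score(self._profile(deep))["S1"]
                > mira_score(self._profile(shallow))["S1"])

    def test_zero_center_floored(self):
        vals = [0.5] * 11
        vals[5] = 0.0
        score = mira_score(self._profile(vals))
        assert np.isfinite(score["S1"]) and score["S1"] > 0

    def test_bad_offset_rejected(self):
        with pytest.raises(ValueError):
            mira_score(self._profile([0.5] * 11), shoulder_offset=9)

    def test_higher_activity_in_keratinized_groups(self, small_tiles, small_bundle):
        """KRT/HPV(-) show deeper planted dips, hence higher scores."""
        prof = mira_profile(small_tiles, small_bundle.region_sets["CTCF"],
                            n_bins=21, flank_bp=2000)
        score = mira_score(prof)
        groups = small_bundle.config.samples_by_group
        assert score[groups["KRT"]].mean() > score[groups["IMU"]].mean()


class TestDeconvolution:
    def test_pure_reference_recovered(self):
        rng = np.random.default_rng(1)
        atlas, _, _ = simulate_mixtures(rng, 1)
        sample = atlas.loc["normal1"].copy()
        sample.name = None
        res = deconvolve(sample, atlas)
        assert res["fractions"]["normal1"] >= 0.95

    def test_missing_tumor_row_rejected(self):
        atlas = pd.DataFrame([[0.5, 0.5]], index=["immune"], columns=["R1", "R2"])
        with pytest.raises(ValueError, match="tumor"):
            deconvolve(pd.Series([0.5, 0.5], index=["R1", "R2"]), atlas)

    def test_low_tumor_fraction_reports_missing_methylome(self):
        rng = np.random.default_rng(2)
        atlas, _, _ = simulate_mixtures(rng, 1)
        normals = [ix for ix in atlas.index if ix != "tumor"]
        x = atlas.loc[normals].mean(axis=0)
        res = deconvolve(x, atlas)
        assert res["tumor_fraction"] < 0.05
        assert res["cancer_specific_meth"] is None

    def test_noiseless_mixture_recovered_to_three_decimals(self):
        rng = np.random.default_rng(3)
        atlas, _, _ = simulate_mixtures(rng, 1, noise_sd=0.0)
        w = {"normal1": 0.25, "normal2": 0.15, "tumor": 0.6}
        x = sum(wv * atlas.loc[ct] for ct, wv in w.items())
        res = deconvolve(pd.Series(x.to_numpy(), index=atlas.columns), atlas)
        for ct, wv in w.items():
            assert res["fractions"][ct] == pytest.approx(wv, abs=1e-3)

    def test_cohort_fractions_on_simplex(self):
        rng = np.random.default_rng(4)
        atlas, mixes, _ = simulate_mixtures(rng, 5)
        dec = deconvolve_cohort(mixes, atlas)
        frac_cols = [c for c in dec.columns if c.startswith("frac_")]
        np.testing.assert_allclose(dec[frac_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_subtype_shift_survives_deconvolution(self, small_bundle):
        """Recovered cancer-specific methylation keeps IMU above KRT."""
        dec = deconvolve_cohort(small_bundle.deconv_meth, small_bundle.atlas)
        by = dec.set_index("sample")["cancer_meth_mean"]
        groups = small_bundle.config.samples_by_group
        assert by[groups["IMU"]].mean() > by[groups["KRT"]].mean()


class TestPathwayScore:
    def _expr(self, mat, genes, samples=None):
        samples = samples or [f"S{i+1}" for i in range(np.shape(mat)[1])]
        return pd.DataFrame(mat, index=genes, columns=samples)

    def test_scores_have_cohort_mean_zero(self):
        rng = np.random.default_rng(5)
        expr = self._expr(rng.normal(5, 1, (10, 8)), [f"g{i}" for i in range(10)])
        score = pathway_score(expr, [f"g{i}" for i in range(6)], "set")
        assert score.mean() == pytest.approx(0.0, abs=1e-12)

    def test_shifted_sample_scores_highest(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(5, 1, (10, 8))
        mat[:5, 3] += 3.0
        expr = self._expr(mat, [f"g{i}" for i in range(10)])
        score = pathway_score(expr, [f"g{i}" for i in range(5)], "set")
        assert score.idxmax() == "S4"

    def test_too_few_matched_genes_rejected(self):
        expr = self._expr(np.ones((3, 4)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="fewer than 2"):
            pathway_score(expr, ["a", "zz"], "set")

    def test_mira_score_tracks_keratinization_score(self, small_tiles, small_bundle):
        """Inferred CTCF activity correlates positively with the planted
        keratinization expression programme across samples."""
        prof = mira_profile(small_tiles, small_bundle.region_sets["CTCF"],
                            n_bins=21, flank_bp=2000)
        mira = mira_score(prof)
        kera = pathway_score(small_bundle.expression,
                             small_bundle.gene_sets["KERATINIZATION"], "KRT")
        r = np.corrcoef(mira[kera.index], kera)[0, 1]
        assert r > 0

    def test_planted_keratinization_structure(self, small_bundle):
        score = pathway_score(small_bundle.expression,
                              small_bundle.gene_sets["KERATINIZATION"], "KRT-set")
        groups = small_bundle.config.samples_by_group
        assert score[groups["KRT"]].mean() > score[groups["IMU"]].mean()
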