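"""Covariate-adjusted beta-binomial differential methylation on 100-bp tiles.

The test models tile-level methylated counts as beta-binomial: given a
sample's total coverage ``n`` the methylated count has mean ``n*p`` and
variance inflated by an intraclass dispersion ``phi``, so
``Var(m/n) = p(1-p)(1 + (n-1)*phi)/n``.  Following the dispersion-shrinkage
family of WGBS tests, per-tile method-of-moments dispersions are shrunk
toward a genome-wide prior, counts are mapped through the variance-
stabilising arcsine link ``y = arcsin(2*p~ - 1)`` (with the smoothed
fraction ``p~ = (m + 0.5)/(n + 1)``), and the group effect is tested by a
Wald statistic from a weighted least-squares fit of ``y`` on
``[intercept, group, covariates]`` with inverse-variance weights
``n / (1 + (n-1)*phi)``.  The Wald statistic is referred to the standard
normal, as is conventional for this model family; with the shrunken
dispersion plugged in this is near-exactly calibrated at the cohort sizes
the package targets (checked by simulation in the test suite).

Tiles pass the group-coverage rule when they carry usable counts in at
least 80% of the samples of *each* group (ceiling at fractional
thresholds).  A tile is called a DMR when its Benjamini-Hochberg FDR is
below 0.05 and the group methylation difference is at least 20 percentage
points in absolute value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, tile_keys

DEFAULT_FDR = 0.05
DEFAULT_MIN_DIFF_PP = 20.0
PHI_FLOOR = 1e-6
PHI_CEIL = 0.999


@dataclass
class GroupDesign:
    """Two-group contrast with optional numeric covariates.

    ``covariates`` is a samples x covariates DataFrame (numeric; categorical
    covariates must be coded beforehand, e.g. smoker vs never as 0/1,
    stage IV vs others as 0/1).  Rows are aligned to samples by index.
    """

    group_a: tuple
    group_b: tuple
    covariates: pd.DataFrame | None = None
    contrast: str = "A_vs_B"

    def __post_init__(self):
        self.group_a = tuple(self.group_a)
        self.group_b = tuple(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")
        if self.covariates is not None:
            missing = [s for s in self.samples if s not in self.covariates.index]
            if missing:
                raise ValueError(f"covariate rows missing for samples: {missing}")

    @property
    def samples(self) -> list:
        return list(self.group_a) + list(self.group_b)

    def swapped(self) -> "GroupDesign":
        return GroupDesign(self.group_b, self.group_a, self.covariates,
                           contrast=self.contrast + "_swapped")

    def design_matrix(self) -> pd.DataFrame:
        """[intercept, group(1=A), covariates] over design samples."""
        x = pd.DataFrame(index=self.samples)
        x["intercept"] = 1.0
        x["group"] = [1.0] * len(self.group_a) + [0.0] * len(self.group_b)
        if self.covariates is not None:
            cov = self.covariates.loc[self.samples].astype(float)
            for c in cov.columns:
                x[c] = cov[c]
        return x


@dataclass
class DispersionModel:
    """Raw and empirically shrunk per-tile beta-binomial dispersions."""

    phi_raw: np.ndarray
    phi_shrunk: np.ndarray
    prior_center: float
    shrink_k: float
    weights: np.ndarray = field(default=None)


def coverage_rule_threshold(n: int, frac: float = 0.8) -> int:
    """Samples required by the group-coverage rule: ceil(frac * n)."""
    return int(math.ceil(frac * n - 1e-9))


def eligible_tiles(tiles: CountMatrix, design: GroupDesign, min_frac: float = 0.8):
    """Boolean mask of tiles covered in >=80% of samples of each group."""
    covered = tiles.covered()
    na = covered[list(design.group_a)].sum(axis=1).to_numpy()
    nb = covered[list(design.group_b)].sum(axis=1).to_numpy()
    mask = (na >= coverage_rule_threshold(len(design.group_a), min_frac)) & (
        nb >= coverage_rule_threshold(len(design.group_b), min_frac)
    )
    if not mask.any():
        raise ValueError(
            "no tile passes the group-coverage rule; coverage is too sparse "
            "for this contrast"
        )
    return mask


def estimate_dispersion(
    tiles: CountMatrix, design: GroupDesign, shrink_k: float = 1000.0
) -> DispersionModel:
    """Method-of-moments dispersion per tile, shrunk to the genome-wide median.

    The raw estimate solves the moment identity
    ``E[(p_hat_j - p_bar_g)^2] ~ p(1-p) * (1/n_j + phi*(n_j-1)/n_j)``
    pooled over both groups (with a small-sample correction per group), then
    each tile's phi is pulled toward the across-tile median with weight
    ``w = m/(m + k)`` where ``m`` is the tile's total coverage; deep tiles
    keep their own estimate, shallow tiles borrow strength.
    """
    sa, sb = list(design.group_a), list(design.group_b)
    phi_raw = np.full(len(tiles), np.nan)
    m_tot = np.zeros(len(tiles))

    num = np.zeros(len(tiles))
    den = np.zeros(len(tiles))
    bin_part = np.zeros(len(tiles))
    for members in (sa, sb):
        m = tiles.meth[members].to_numpy()
        n = tiles.total[members].to_numpy()
        ok = np.isfinite(n) & (n > 0)
        m = np.where(ok, m, 0.0)
        nn = np.where(ok, n, 0.0)
        m_tot += nn.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pbar = np.where(nn.sum(axis=1) > 0, m.sum(axis=1) / np.maximum(nn.sum(axis=1), 1), np.nan)
            phat = np.where(ok, m / np.maximum(nn, 1), np.nan)
        v = pbar * (1 - pbar)
        ng = ok.sum(axis=1)
        corr = np.where(ng > 1, ng / np.maximum(ng - 1.0, 1.0), np.nan)
        resid = np.nansum((phat - pbar[:, None]) ** 2, axis=1) * corr
        with np.errstate(invalid="ignore"):
            bin_here = v * np.nansum(np.where(ok, 1.0 / np.maximum(nn, 1), np.nan), axis=1)
            den_here = v * np.nansum(np.where(ok, (nn - 1.0) / np.maximum(nn, 1), np.nan), axis=1)
        good = np.isfinite(resid) & np.isfinite(den_here)
        num[good] += resid[good]
        bin_part[good] += bin_here[good]
        den[good] += den_here[good]

    with np.errstate(invalid="ignore", divide="ignore"):
        phi_raw = (num - bin_part) / den
    phi_raw = np.where(np.isfinite(phi_raw), phi_raw, PHI_FLOOR)
    phi_raw = np.clip(phi_raw, PHI_FLOOR, PHI_CEIL)

    prior = float(np.median(phi_raw)) if len(phi_raw) else PHI_FLOOR
    w = m_tot / (m_tot + shrink_k)
    phi_shrunk = np.clip(w * phi_raw + (1 - w) * prior, PHI_FLOOR, PHI_CEIL)
    return DispersionModel(phi_raw, phi_shrunk, prior, shrink_k, w)


def _weighted_group_means(m, n, is_a):
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(m[:, is_a], axis=1) / np.nansum(n[:, is_a], axis=1)
        mb = np.nansum(m[:, ~is_a], axis=1) / np.nansum(n[:, ~is_a], axis=1)
    return ma, mb


def test_tiles(
    tiles: CountMatrix,
    design: GroupDesign,
    dispersion: DispersionModel | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    min_diff_pp: float = DEFAULT_MIN_DIFF_PP,
    shrink_k: float = 1000.0,
) -> pd.DataFrame:
    """Beta-binomial Wald test of the group effect for every tile.

    Tiles should already satisfy the coverage rule (see
    :func:`eligible_tiles`); rows that do not are tested anyway provided at
    least two samples per group carry data.  Returns one row per tile:
    ``chrom, start, end, n_cpgs, mean_a, mean_b, diff_pp, stat, p, fdr,
    direction, is_dmr, fallback``.  BH correction is applied within the
    contrast over all returned tiles.
    """
    if dispersion is None:
        dispersion = estimate_dispersion(tiles, design, shrink_k=shrink_k)
    x_full = design.design_matrix().to_numpy()
    samples = design.samples
    m = tiles.meth[samples].to_numpy()
    n = tiles.total[samples].to_numpy()
    is_a = np.array([s in set(design.group_a) for s in samples])

    mean_a, mean_b = _weighted_group_means(m, n, is_a)
    phi = dispersion.phi_shrunk

    ok = np.isfinite(n) & (n > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_sm = (m + 0.5) / (n + 1.0)
        y_all = np.arcsin(2.0 * p_sm - 1.0)
        w_all = n / (1.0 + (n - 1.0) * phi[:, None])

    stat = np.full(len(tiles), np.nan)
    pval = np.full(len(tiles), np.nan)
    fallback = np.zeros(len(tiles), dtype=bool)

    for i in range(len(tiles)):
        use = ok[i]
        if use[is_a].sum() < 2 or use[~is_a].sum() < 2:
            continue
        x = x_full[use]
        y = y_all[i, use]
        w = w_all[i, use]
        xtw = x.T * w
        a = xtw @ x
        b = xtw @ y
        try:
            if np.linalg.matrix_rank(a) < a.shape[0]:
                raise np.linalg.LinAlgError("rank-deficient design")
            beta = np.linalg.solve(a, b)
            cov = np.linalg.inv(a)
        except np.linalg.LinAlgError:
            # rank-deficient covariate design: covariate-free two-group fit
            fallback[i] = True
            x2 = x[:, :2]
            xtw = x2.T * w
            a = xtw @ x2
            b = xtw @ y
            try:
                beta = np.linalg.solve(a, b)
                cov = np.linalg.inv(a)
            except np.linalg.LinAlgError:
                continue
            x = x2
        se = math.sqrt(max(cov[1, 1], 1e-300))
        if use.sum() - x.shape[1] < 1:
            continue
        stat[i] = beta[1] / se
        pval[i] = 2.0 * stats.norm.sf(abs(stat[i]))

    fdr = np.full(len(tiles), np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        fdr[tested] = multipletests(pval[tested], method="fdr_bh")[1]

    diff_pp = (mean_a - mean_b) * 100.0
    records = tiles.features.copy()
    records["tile"] = tile_keys(tiles)
    records["mean_a"] = mean_a
    records["mean_b"] = mean_b
    records["diff_pp"] = diff_pp
    records["stat"] = stat
    records["p"] = pval
    records["fdr"] = fdr
    records["direction"] = np.where(diff_pp > 0, "hyper", "hypo")
    records["is_dmr"] = (fdr < fdr_threshold) & (np.abs(diff_pp) >= min_diff_pp)
    records["fallback"] = fallback
    records["contrast"] = design.contrast
    return records


def run_contrast(
    tiles: CountMatrix,
    design: GroupDesign,
    min_group_frac: float = 0.8,
    shrink_k: float = 1000.0,
    fdr_threshold: float = DEFAULT_FDR,
    min_diff_pp: float = DEFAULT_MIN_DIFF_PP,
) -> pd.DataFrame:
    """Coverage rule + dispersion estimation + per-tile test for a contrast."""
    mask = eligible_tiles(tiles, design, min_group_frac)
    sub = tiles.subset(mask)
    disp = estimate_dispersion(sub, design, shrink_k=shrink_k)
    return test_tiles(sub, design, disp, fdr_threshold, min_diff_pp)


def summarize_counts(n_tested: int, n_hyper: int, n_hypo: int,
                     contrast: str = "") -> dict:
    """Audit-table row from raw counts: DMR totals with whole-percent shares.

    Hyper/hypo shares are taken among DMRs, the total share among all
    tested tiles.  Zero DMRs yields 0% shares and a flag.
    """
    n_dmr = n_hyper + n_hypo
    return {
        "contrast": contrast,
        "n_tested": int(n_tested),
        "n_hyper": int(n_hyper),
        "n_hypo": int(n_hypo),
        "n_dmr": int(n_dmr),
        "hyper_pct": round(100.0 * n_hyper / n_dmr) if n_dmr else 0,
        "hypo_pct": round(100.0 * n_hypo / n_dmr) if n_dmr else 0,
        "dmr_pct": round(100.0 * n_dmr / n_tested) if n_tested else 0,
        "no_dmrs": n_dmr == 0,
    }


def summarize_dmrs(records: pd.DataFrame, contrast: str | None = None) -> dict:
    """Audit-table row for one contrast's test records."""
    if contrast is None:
        contrast = records["contrast"].iloc[0] if len(records) else ""
    dmrs = records[records["is_dmr"].astype(bool)]
    return summarize_counts(
        len(records),
        int((dmrs["direction"] == "hyper").sum()),
        int((dmrs["direction"] == "hypo").sum()),
        contrast,
    )
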