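"""cis-eQTM scan: linking tile methylation to nearby gene expression.

A candidate pair is a (tile, gene) combination whose tile midpoint lies
within 1 Mb of the gene's transcription start site.  Tiles enter the scan
only when they (i) carry data in at least 80% of samples, (ii) have a
methylation coefficient of variation above the lowest 5th percentile of
eligible tiles, and (iii) are fully unmethylated in fewer than a configured
number of samples — three filters that remove constant and outlier-driven
tiles.  Each candidate is fit by ordinary least squares,
``expression ~ intercept + methylation + covariates``, with a t-test on the
methylation coefficient and Benjamini-Hochberg correction across all
candidate pairs genome-wide; significant cis-eQTMs have FDR < 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, tile_keys

logger = logging.getLogger(__name__)

EQTM_FDR = 0.1
CIS_WINDOW_BP = 1_000_000


@dataclass
class EQTMFilterConfig:
    """Tile filters for the cis-eQTM scan.

    ``max_zero_meth_frac`` generalises the cohort-specific "fewer than 33 of
    36 fully unmethylated samples" rule as a fraction (33/36 by default).
    """

    min_sample_frac: float = 0.8
    cv_quantile: float = 0.05
    max_zero_meth_frac: float = 33.0 / 36.0

    def __post_init__(self):
        for name in ("min_sample_frac", "cv_quantile", "max_zero_meth_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


def filter_eqtm_tiles(tiles: CountMatrix, cfg: EQTMFilterConfig | None = None):
    """Boolean mask of tiles passing the three eQTM filters.

    The CV threshold is the empirical ``cv_quantile`` of the CV distribution
    over coverage-eligible tiles, so the 5% least variable tiles drop out by
    construction.  Fully-unmethylated means methylation fraction exactly 0
    for a covered sample.
    """
    cfg = cfg or EQTMFilterConfig()
    n_samples = len(tiles.samples)
    covered = tiles.covered().to_numpy()
    n_cov = covered.sum(axis=1)
    min_n = int(np.ceil(cfg.min_sample_frac * n_samples - 1e-9))
    cov_ok = n_cov >= min_n

    frac = tiles.fraction().to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(np.where(covered, frac, np.nan), axis=1)
        sd = np.nanstd(np.where(covered, frac, np.nan), axis=1, ddof=1)
        cv = np.where(mean > 0, sd / mean, 0.0)
    cv = np.where(np.isfinite(cv), cv, 0.0)

    eligible_cv = cv[cov_ok]
    if len(eligible_cv) == 0:
        raise ValueError("no tile passes the coverage filter for the eQTM scan")
    cv_threshold = float(np.quantile(eligible_cv, cfg.cv_quantile))
    cv_ok = cv > cv_threshold

    n_zero = np.sum(covered & (frac == 0.0), axis=1)
    max_zero = cfg.max_zero_meth_frac * n_samples
    zero_ok = n_zero < max_zero

    mask = cov_ok & cv_ok & zero_ok
    if not mask.any():
        raise ValueError("all tiles removed by the eQTM filters")
    logger.info("eQTM filters: %d of %d tiles retained", mask.sum(), len(mask))
    return mask


def cis_pairs(
    tiles: CountMatrix, gene_models: pd.DataFrame, max_dist: int = CIS_WINDOW_BP
) -> pd.DataFrame:
    """All (tile, gene) pairs with tile midpoint within ``max_dist`` of a TSS.

    ``gene_models`` needs columns ``gene, chrom, strand, tss`` (0-based TSS
    coordinate).  The signed distance is negative upstream of the TSS
    relative to the gene's strand; the boundary is inclusive.  Genes lacking
    a usable TSS are skipped with a log message.
    """
    feats = tiles.features
    mids = feats["start"].to_numpy() + (feats["end"].to_numpy() - feats["start"].to_numpy()) / 2.0
    keys = tile_keys(tiles).to_numpy()
    rows = []
    for chrom, sub in gene_models.groupby("chrom"):
        sel = np.flatnonzero((feats["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        m = mids[sel]
        order = np.argsort(m)
        m_sorted = m[order]
        sel_sorted = sel[order]
        for g in sub.itertuples(index=False):
            if pd.isna(g.tss):
                logger.info("gene %s has no TSS; skipped", g.gene)
                continue
            tss = float(g.tss)
            lo = np.searchsorted(m_sorted, tss - max_dist, side="left")
            hi = np.searchsorted(m_sorted, tss + max_dist, side="right")
            for j in range(lo, hi):
                d = m_sorted[j] - tss
                if abs(d) > max_dist:
                    continue
                signed = d if g.strand == "+" else -d
                rows.append((keys[sel_sorted[j]], int(sel_sorted[j]), g.gene, signed))
    return pd.DataFrame(rows, columns=["tile", "tile_index", "gene", "tss_distance_bp"])


def fit_eqtm(
    pairs: pd.DataFrame,
    tiles: CountMatrix,
    expression: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = EQTM_FDR,
    min_samples: int = 6,
) -> pd.DataFrame:
    """OLS fit of expression on methylation (+ covariates) for every pair.

    ``expression`` is genes x samples (log2-CPM scale); ``covariates`` a
    samples x covariates numeric DataFrame.  Returns the pair table with
    ``slope, p, fdr, sign, significant``; BH correction spans all candidate
    pairs.  Rank-deficient designs are skipped with a reason column.
    """
    samples = [s for s in tiles.samples if s in expression.columns]
    if len(samples) < min_samples:
        raise ValueError("too few samples shared between tiles and expression")
    frac = tiles.fraction()[samples].to_numpy()
    expr = expression[samples]
    if covariates is not None:
        cov = covariates.loc[samples].astype(float).to_numpy()
    else:
        cov = np.empty((len(samples), 0))

    slopes = np.full(len(pairs), np.nan)
    pvals = np.full(len(pairs), np.nan)
    skipped = np.full(len(pairs), "", dtype=object)
    gene_rows = {g: expr.loc[g].to_numpy() for g in pairs["gene"].unique()
                 if g in expr.index}
    for i, (tix, gene) in enumerate(zip(pairs["tile_index"], pairs["gene"])):
        y = gene_rows.get(gene)
        if y is None:
            skipped[i] = "gene_missing"
            continue
        meth = frac[tix]
        use = np.isfinite(meth) & np.isfinite(y)
        if use.sum() < min_samples:
            skipped[i] = "too_few_samples"
            continue
        x = np.column_stack([
            np.ones(use.sum()), meth[use], cov[use]
        ])
        xtx = x.T @ x
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            skipped[i] = "rank_deficient"
            continue
        beta = xtx_inv @ (x.T @ y[use])
        resid = y[use] - x @ beta
        df = use.sum() - x.shape[1]
        if df < 1:
            skipped[i] = "no_dof"
            continue
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(max(sigma2 * xtx_inv[1, 1], 1e-300))
        t = beta[1] / se
        slopes[i] = beta[1]
        pvals[i] = 2.0 * stats.t.sf(abs(t), df)

    out = pairs.copy()
    out["slope"] = slopes
    out["p"] = pvals
    tested = np.isfinite(pvals)
    fdr = np.full(len(pairs), np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["sign"] = np.where(slopes > 0, "positive", "negative")
    out["significant"] = fdr < fdr_threshold
    out["skipped"] = skipped
    return out


def eqtm_dmr_overlap(eqtms: pd.DataFrame, dmr_records: pd.DataFrame) -> dict:
    """Overlap of significant eQTM tiles with DMRs and direction/sign cross-tab.

    Both tables are keyed by tile id; DMR records may pool several
    contrasts.  Returns unique-tile overlap counts/shares and, per contrast
    and direction, counts of positive/negative eQTMs among overlapping
    pairs.
    """
    sig = eqtms[eqtms["significant"].astype(bool)]
    uniq = sig["tile"].unique()
    dmr_tiles = (
        dmr_records.loc[dmr_records["is_dmr"].astype(bool), ["tile", "contrast", "direction"]]
        if len(dmr_records) else pd.DataFrame(columns=["tile", "contrast", "direction"])
    )
    dmr_set = set(dmr_tiles["tile"])
    overlap = np.array([t in dmr_set for t in uniq])
    n_overlap = int(overlap.sum())
    share = 100.0 * n_overlap / len(uniq) if len(uniq) else 0.0

    flagged = sig.assign(overlaps_dmr=sig["tile"].isin(dmr_set))
    crosstab = {}
    if len(dmr_tiles):
        joined = flagged.merge(dmr_tiles, on="tile", how="inner")
        for (contrast, direction), sub in joined.groupby(["contrast", "direction"]):
            n_pos = int((sub["sign"] == "positive").sum())
            n_neg = int((sub["sign"] == "negative").sum())
            crosstab[f"{contrast}:{direction}"] = {
                "positive": n_pos, "negative": n_neg,
                "positive_pct": round(100.0 * n_pos / max(n_pos + n_neg, 1)),
                "negative_pct": round(100.0 * n_neg / max(n_pos + n_neg, 1)),
            }
    return {
        "n_unique_eqtm_tiles": int(len(uniq)),
        "n_overlapping_dmr": n_overlap,
        "overlap_pct": round(share),
        "pairs": flagged,
        "crosstab": crosstab,
    }
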