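"""Reading, filtering and 100-bp tiling of CpG methylation counts.

The unit of analysis throughout the package is the 100-bp methylation tile:
adjacent CpG sites are pooled into fixed, grid-anchored 100-bp windows to
raise effective coverage.  Counts live in a pair of aligned matrices
(methylated reads, total reads) with one row per site or tile and one column
per sample; ``NaN`` marks a sample/site combination masked by the coverage
filter rather than deleting the row, so group-level coverage rules stay
meaningful downstream.

Coordinates are 0-based half-open internally (BED convention); 1-based
cytosine-report positions are converted at the reader boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TILE_SIZE = 100


@dataclass
class FilterConfig:
    """Site-level filters applied before tiling.

    Coverage bounds are inclusive on both ends: a site kept for a sample
    needs ``min_cov <= total <= max_cov`` reads in that sample.  Sites on
    excluded chromosomes (sex chromosomes by default in the analyses this
    package targets) or at blacklisted positions (e.g. C>T / G>A SNPs that
    confound bisulfite conversion) are dropped for every sample.
    """

    min_cov: int = 10
    max_cov: int = 500
    snp_blacklist: frozenset = field(default_factory=frozenset)
    excluded_chroms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.min_cov > self.max_cov:
            raise ValueError(f"min_cov ({self.min_cov}) > max_cov ({self.max_cov})")
        self.snp_blacklist = frozenset(self.snp_blacklist)
        self.excluded_chroms = frozenset(self.excluded_chroms)


class CountMatrix:
    """Aligned methylated/total count matrices over genomic features.

    Parameters
    ----------
    features : pd.DataFrame
        One row per feature.  Site matrices carry ``chrom, pos`` (1-based
        CpG position); tile matrices carry ``chrom, start, end, n_cpgs``
        (0-based half-open).
    meth, total : pd.DataFrame
        Float matrices (features x samples); ``NaN`` = missing for that
        sample.
    """

    def __init__(self, features: pd.DataFrame, meth: pd.DataFrame, total: pd.DataFrame):
        if not (len(features) == len(meth) == len(total)):
            raise ValueError("features, meth and total must have equal length")
        if list(meth.columns) != list(total.columns):
            raise ValueError("meth and total must share sample columns")
        self.features = features.reset_index(drop=True)
        self.meth = meth.reset_index(drop=True).astype(float)
        self.total = total.reset_index(drop=True).astype(float)
        bad = (self.meth.to_numpy() > self.total.to_numpy() + 1e-9)
        if np.nansum(bad):
            raise ValueError("methylated count exceeds total count")

    # -- basic views ----------------------------------------------------
    @property
    def samples(self) -> list:
        return list(self.meth.columns)

    def __len__(self) -> int:
        return len(self.features)

    def fraction(self) -> pd.DataFrame:
        """Per-sample methylation fraction; NaN where total is 0/missing."""
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.meth.to_numpy() / self.total.to_numpy()
        return pd.DataFrame(frac, columns=self.meth.columns)

    def covered(self) -> pd.DataFrame:
        """Boolean matrix: sample has usable counts for the feature."""
        t = self.total.to_numpy()
        return pd.DataFrame(np.isfinite(t) & (t > 0), columns=self.meth.columns)

    def subset(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            self.features.loc[mask], self.meth.loc[mask], self.total.loc[mask]
        )

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.features, self.meth[list(samples)], self.total[list(samples)])

    def mean_coverage(self) -> float:
        """Average per-sample coverage over covered entries."""
        return float(np.nanmean(self.total.to_numpy()))


# Tile matrices are plain CountMatrix objects whose features are tiles; an
# alias keeps call sites readable.
TileMatrix = CountMatrix


def tile_keys(tiles: CountMatrix) -> pd.Series:
    """Stable string key 'chrom:start-end' for each tile row."""
    f = tiles.features
    return f["chrom"].astype(str) + ":" + f["start"].astype(str) + "-" + f["end"].astype(str)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_cpg_report(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into strand-merged CpG counts.

    Expected columns (whitespace-delimited, no header):
    ``chrom  pos(1-based)  strand  count_methylated  count_unmethylated``
    with optional trailing context columns, which are ignored.  CpGs
    reported on the minus strand are collapsed onto the plus-strand
    cytosine one base upstream, summing counts, under the usual assumption
    of symmetric CpG methylation.

    Returns a DataFrame with columns ``chrom, pos, count_meth, count_total``
    sorted by (chrom, pos).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed line {lineno}: expected >=5 fields")
            chrom, pos_s, strand, meth_s, unmeth_s = parts[:5]
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}: bad strand {strand!r} at line {lineno}")
            if strand == "-":
                pos -= 1  # collapse onto the + strand cytosine of the CpG
            rows.append((chrom, pos, meth, meth + unmeth))
    if not rows:
        warnings.warn(f"{path}: empty cytosine report", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "pos", "count_meth", "count_total"])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count_meth", "count_total"])
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)[["count_meth", "count_total"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df


def read_coverage_file(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a Bismark ``.cov``-style file (bedGraph dialect).

    Columns: ``chrom  start(1-based)  end  meth_percent  count_meth
    count_unmeth``.  Already strand-merged by convention; returned in the
    same shape as :func:`read_cpg_report`.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "pos", "end", "pct", "count_meth", "count_unmeth"],
        dtype={"chrom": str},
    )
    if ((df["count_meth"] < 0) | (df["count_unmeth"] < 0)).any():
        raise ValueError(f"{path}: negative counts")
    out = df[["chrom", "pos", "count_meth"]].copy()
    out["count_total"] = df["count_meth"] + df["count_unmeth"]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def combine_samples(reports: dict) -> CountMatrix:
    """Outer-join per-sample CpG reports into a cohort site matrix.

    ``reports`` maps sample id -> DataFrame from :func:`read_cpg_report`.
    Sites absent from a sample's report are missing (NaN) for that sample.
    """
    if not reports:
        raise ValueError("no samples given")
    meth_cols, total_cols = {}, {}
    for sample, df in reports.items():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos"]])
        meth_cols[sample] = pd.Series(df["count_meth"].to_numpy(float), index=idx)
        total_cols[sample] = pd.Series(df["count_total"].to_numpy(float), index=idx)
    meth = pd.DataFrame(meth_cols).sort_index()
    total = pd.DataFrame(total_cols).sort_index()
    features = meth.index.to_frame(index=False, name=["chrom", "pos"])
    return CountMatrix(features, meth.reset_index(drop=True), total.reset_index(drop=True))


# ---------------------------------------------------------------------------
# filtering and tiling
# ---------------------------------------------------------------------------

def filter_sites(sites: CountMatrix, cfg: FilterConfig) -> CountMatrix:
    """Apply coverage, SNP-blacklist and chromosome filters to a site matrix.

    Coverage is enforced per sample by masking (NaN), so a site can remain
    usable in some samples and missing in others.  Blacklisted positions and
    excluded chromosomes are removed for all samples.
    """
    feats = sites.features
    keep = ~feats["chrom"].isin(cfg.excluded_chroms)
    if cfg.snp_blacklist:
        in_blacklist = [
            (c, p) in cfg.snp_blacklist for c, p in zip(feats["chrom"], feats["pos"])
        ]
        keep &= ~np.asarray(in_blacklist)
    out = sites.subset(keep.to_numpy())
    total = out.total.to_numpy()
    bad = ~np.isfinite(total) | (total < cfg.min_cov) | (total > cfg.max_cov)
    meth = out.meth.to_numpy().copy()
    total = total.copy()
    meth[bad] = np.nan
    total[bad] = np.nan
    return CountMatrix(
        out.features,
        pd.DataFrame(meth, columns=out.samples),
        pd.DataFrame(total, columns=out.samples),
    )


def tile_100bp(sites: CountMatrix, tile_size: int = TILE_SIZE) -> CountMatrix:
    """Pool CpG sites into fixed-grid tiles of ``tile_size`` bp.

    A CpG at 1-based position ``pos`` falls into the window
    ``[floor((pos-1)/tile_size)*tile_size, +tile_size)``.  Counts are summed
    per sample over member CpGs; a tile is missing for a sample when no
    member site carries counts.  Tiles with zero CpG sites do not appear.
    """
    feats = sites.features
    pos0 = feats["pos"].to_numpy() - 1
    start = (pos0 // tile_size) * tile_size
    key = pd.DataFrame({"chrom": feats["chrom"].to_numpy(), "start": start})
    grouped_meth = sites.meth.groupby([key["chrom"], key["start"]], sort=True).sum(min_count=1)
    grouped_total = sites.total.groupby([key["chrom"], key["start"]], sort=True).sum(min_count=1)
    n_cpgs = key.groupby(["chrom", "start"], sort=True).size()
    features = grouped_meth.index.to_frame(index=False, name=["chrom", "start"])
    features["end"] = features["start"] + tile_size
    features["n_cpgs"] = n_cpgs.to_numpy()
    tiles = CountMatrix(
        features,
        grouped_meth.reset_index(drop=True),
        grouped_total.reset_index(drop=True),
    )
    logger.info(
        "tiled %d CpG sites into %d tiles; mean tile coverage %.1fx",
        len(sites), len(tiles), tiles.mean_coverage(),
    )
    return tiles


# ---------------------------------------------------------------------------
# region profiles
# ---------------------------------------------------------------------------

def region_mean_methylation(
    tiles: CountMatrix,
    regions: pd.DataFrame,
    flank_bp: int = 2000,
    n_bins: int = 10,
    n_flank_bins: int = 5,
):
    """Coverage-weighted methylation meta-profile over a set of regions.

    Region bodies are rescaled to a common length and split into ``n_bins``
    bins; each flank of ``flank_bp`` bp is split into ``n_flank_bins``
    fixed-width bins.  A tile contributes to the bin holding its midpoint,
    weighted by its per-sample total coverage.  Regions with a ``strand``
    column are orientation-flipped so upstream is always left.

    Returns
    -------
    profile : pd.DataFrame
        (2*n_flank_bins + n_bins) x samples mean methylation per bin.
    scalar : pd.Series
        Per-sample coverage-weighted mean over tiles inside region bodies.
    n_empty : int
        Number of regions with no overlapping covered tile.
    """
    samples = tiles.samples
    n_total_bins = 2 * n_flank_bins + n_bins
    num = np.zeros((n_total_bins, len(samples)))
    den = np.zeros((n_total_bins, len(samples)))
    body_num = np.zeros(len(samples))
    body_den = np.zeros(len(samples))

    frac = tiles.fraction().to_numpy()
    tot = np.nan_to_num(tiles.total.to_numpy())
    weighted = np.nan_to_num(frac) * tot

    feats = tiles.features
    n_empty = 0
    by_chrom = {c: idx.to_numpy() for c, idx in feats.groupby("chrom").groups.items()}
    has_strand = "strand" in regions.columns
    for row in regions.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        strand = getattr(row, "strand", "+") if has_strand else "+"
        idx = by_chrom.get(chrom)
        if idx is None:
            n_empty += 1
            continue
        tstarts = feats["start"].to_numpy()[idx]
        lo = np.searchsorted(tstarts, start - flank_bp - TILE_SIZE)
        hi = np.searchsorted(tstarts, end + flank_bp)
        sel = idx[lo:hi]
        if len(sel) == 0:
            n_empty += 1
            continue
        mids = tstarts[lo:hi] + TILE_SIZE / 2.0
        inside = (mids >= start - flank_bp) & (mids < end + flank_bp)
        sel, mids = sel[inside], mids[inside]
        if len(sel) == 0:
            n_empty += 1
            continue
        bins = np.empty(len(mids), dtype=int)
        up = mids < start
        down = mids >= end
        body = ~up & ~down
        bins[up] = ((mids[up] - (start - flank_bp)) // (flank_bp / n_flank_bins)).astype(int)
        bins[body] = n_flank_bins + np.minimum(
            ((mids[body] - start) / (end - start) * n_bins).astype(int), n_bins - 1
        )
        bins[down] = (
            n_flank_bins + n_bins
            + ((mids[down] - end) // (flank_bp / n_flank_bins)).astype(int)
        )
        if strand == "-":
            bins = n_total_bins - 1 - bins
        np.add.at(num, bins, weighted[sel])
        np.add.at(den, bins, tot[sel])
        body_sel = sel[body] if strand != "-" else sel[body]
        body_num += weighted[body_sel].sum(axis=0)
        body_den += tot[body_sel].sum(axis=0)

    if n_empty:
        logger.info("%d region(s) had no overlapping covered tiles", n_empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = pd.DataFrame(num / den, columns=samples)
        scalar = pd.Series(
            np.where(body_den > 0, body_num / np.where(body_den > 0, body_den, 1), np.nan),
            index=samples,
        )
    labels = (
        [f"u{i}" for i in range(n_flank_bins, 0, -1)]
        + [f"b{i}" for i in range(1, n_bins + 1)]
        + [f"d{i}" for i in range(1, n_flank_bins + 1)]
    )
    profile.index = labels
    return profile, scalar, n_empty
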