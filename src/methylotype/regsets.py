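"""Region-set regulatory scoring, deconvolution and pathway scores.

Regulatory activity is inferred MIRA-style: active regulatory regions
(TF binding sites, enhancers) sit in local methylation dips, so the
aggregate methylation profile across a region set — center-anchored,
binned, coverage-weighted — shows a central trough whose depth tracks
activity.  The scalar score is ``log2(shoulder / center)``: zero for a
flat profile, larger for deeper dips.

Cell-type deconvolution regresses a sample's methylation over a reference
atlas by non-negative least squares, normalises the weights to the
simplex, and recovers the cancer-cell-specific methylome from the residual
after subtracting the normal-cell contributions.  The atlas is expected to
carry a tumour reference row (as MethylCIBERSORT-style signature matrices
do); a constrained mode treating the tumour as a reference-free remainder
is available but is unidentifiable when the tumour methylome overlaps the
span of the normal references, so it is not the default.

Pathway scores are per-sample means of cohort z-scored log2-CPM over a
gene set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize

from .core import CountMatrix, TILE_SIZE

logger = logging.getLogger(__name__)

CENTER_FLOOR = 1e-3
MIN_TUMOR_FRACTION = 0.05


# ---------------------------------------------------------------------------
# MIRA-style profiles and scores
# ---------------------------------------------------------------------------

def mira_profile(
    tiles: CountMatrix, regions: pd.DataFrame, n_bins: int = 21,
    flank_bp: int = 5000,
) -> pd.DataFrame:
    """Aggregate center-anchored methylation profile over a region set.

    Each region contributes the tiles whose midpoints fall within
    ``flank_bp`` of its center, split into ``n_bins`` equal bins spanning
    ``[center - flank_bp, center + flank_bp)``; per bin and sample the
    coverage-weighted mean methylation is pooled over all regions.
    ``n_bins`` must be odd so a central bin exists.  Minus-strand regions
    are flipped.  Bins with no covered tile are NaN.
    """
    if n_bins % 2 != 1:
        raise ValueError("n_bins must be odd")
    samples = tiles.samples
    num = np.zeros((n_bins, len(samples)))
    den = np.zeros((n_bins, len(samples)))
    frac = tiles.fraction().to_numpy()
    tot = np.nan_to_num(tiles.total.to_numpy())
    weighted = np.nan_to_num(frac) * tot
    feats = tiles.features
    bin_width = 2.0 * flank_bp / n_bins
    has_strand = "strand" in regions.columns
    by_chrom = {c: idx.to_numpy() for c, idx in feats.groupby("chrom").groups.items()}
    for row in regions.itertuples(index=False):
        idx = by_chrom.get(row.chrom)
        if idx is None:
            continue
        center = (int(row.start) + int(row.end)) / 2.0
        tstarts = feats["start"].to_numpy()[idx]
        lo = np.searchsorted(tstarts, center - flank_bp - TILE_SIZE)
        hi = np.searchsorted(tstarts, center + flank_bp)
        sel = idx[lo:hi]
        mids = tstarts[lo:hi] + TILE_SIZE / 2.0
        inside = (mids >= center - flank_bp) & (mids < center + flank_bp)
        sel, mids = sel[inside], mids[inside]
        if len(sel) == 0:
            continue
        bins = ((mids - (center - flank_bp)) // bin_width).astype(int)
        bins = np.clip(bins, 0, n_bins - 1)
        if has_strand and getattr(row, "strand", "+") == "-":
            bins = n_bins - 1 - bins
        np.add.at(num, bins, weighted[sel])
        np.add.at(den, bins, tot[sel])
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = num / den
    offsets = np.arange(n_bins) - n_bins // 2
    return pd.DataFrame(prof, index=offsets, columns=samples)


def mira_score(
    profile: pd.DataFrame, shoulder_offset: int | None = None,
    center_floor: float = CENTER_FLOOR,
) -> pd.Series:
    """``log2(mean(shoulder bins) / center bin)`` per sample.

    The shoulder is the pair of bins ``±shoulder_offset`` from the center
    (default: half the flank, ``floor(B/2)`` for ``B`` flank bins per
    side).  Flat profiles score exactly 0; deeper central dips score
    higher.  A center at 0 is floored at ``center_floor`` and flagged via a
    log message.
    """
    n_bins = len(profile)
    b = n_bins // 2
    if shoulder_offset is None:
        shoulder_offset = max(1, b // 2)
    if not 1 <= shoulder_offset <= b:
        raise ValueError(f"shoulder_offset must be in [1, {b}]")
    center = profile.loc[0]
    shoulder = (profile.loc[-shoulder_offset] + profile.loc[shoulder_offset]) / 2.0
    floored = center <= center_floor
    if floored.any():
        logger.info("MIRA center floored for %d sample(s)", int(floored.sum()))
    center = center.clip(lower=center_floor)
    return np.log2(shoulder / center)


# ---------------------------------------------------------------------------
# reference-based deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    sample_meth: pd.Series,
    atlas: pd.DataFrame,
    tumor_row: str = "tumor",
    min_tumor_fraction: float = MIN_TUMOR_FRACTION,
) -> dict:
    """Cell-type fractions and cancer-specific methylation for one sample.

    ``sample_meth``: per-region methylation fractions indexed like the
    atlas columns.  ``atlas``: cell types (rows, including ``tumor_row``) x
    regions.  Non-negative least squares weights are normalised to the
    simplex; the cancer-cell-specific methylome is the residual after
    removing the normal contributions, divided by the tumour weight and
    clipped to [0, 1] (clip events counted).  When the tumour weight falls
    below ``min_tumor_fraction`` the division is unstable and the
    cancer-specific methylome is reported missing.
    """
    if tumor_row not in atlas.index:
        raise ValueError(f"atlas has no row {tumor_row!r}")
    regions = [r for r in atlas.columns if r in sample_meth.index]
    if len(regions) < len(atlas):
        raise ValueError("fewer informative regions than atlas components")
    a = atlas[regions].to_numpy().T          # regions x cell types
    x = sample_meth.loc[regions].to_numpy().astype(float)
    w, _ = optimize.nnls(a, x)
    if w.sum() <= 0:
        raise ValueError("degenerate fit: all weights zero")
    w = w / w.sum()
    fractions = pd.Series(w, index=atlas.index)
    w_t = float(fractions[tumor_row])
    result = {"fractions": fractions, "tumor_fraction": w_t,
              "cancer_specific_meth": None, "n_clipped": 0}
    if w_t >= min_tumor_fraction:
        normals = [ct for ct in atlas.index if ct != tumor_row]
        normal_part = fractions[normals].to_numpy() @ atlas.loc[normals, regions].to_numpy()
        raw = (x - normal_part) / w_t
        clipped = np.clip(raw, 0.0, 1.0)
        result["n_clipped"] = int((raw != clipped).sum())
        result["cancer_specific_meth"] = pd.Series(clipped, index=regions)
    return result


def deconvolve_free_tumor(sample_meth: pd.Series, atlas: pd.DataFrame) -> dict:
    """Deconvolution without a tumour reference (constrained remainder).

    Fits non-negative weights over the normal references under
    ``sum(w) <= 1`` and attributes the remainder ``1 - sum(w)`` to an
    uncharacterised tumour component.  Only identifiable when the tumour
    methylome is nearly orthogonal to the normal references; provided for
    sensitivity analyses.
    """
    regions = [r for r in atlas.columns if r in sample_meth.index]
    a = atlas[regions].to_numpy().T
    x = sample_meth.loc[regions].to_numpy().astype(float)
    n = a.shape[1]
    lam = 1e3  # soft equality sum(w) + slack = 1
    a_aug = np.vstack([np.hstack([a, np.zeros((a.shape[0], 1))]),
                       lam * np.ones((1, n + 1))])
    x_aug = np.concatenate([x, [lam]])
    w, _ = optimize.nnls(a_aug, x_aug)
    w = w / w.sum()
    fractions = pd.Series(w[:-1], index=atlas.index)
    return {"fractions": fractions, "tumor_fraction": float(w[-1])}


def deconvolve_cohort(
    meth: pd.DataFrame, atlas: pd.DataFrame, tumor_row: str = "tumor"
) -> pd.DataFrame:
    """Run :func:`deconvolve` per sample; summarises to a tidy frame."""
    rows = []
    for s in meth.columns:
        res = deconvolve(meth[s], atlas, tumor_row=tumor_row)
        csm = res["cancer_specific_meth"]
        row = {"sample": s, "tumor_fraction": res["tumor_fraction"],
               "cancer_meth_mean": float(csm.mean()) if csm is not None else np.nan,
               "n_clipped": res["n_clipped"]}
        for ct, v in res["fractions"].items():
            row[f"frac_{ct}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression pathway scores
# ---------------------------------------------------------------------------

def pathway_score(expression: pd.DataFrame, gene_set, name: str = "") -> pd.Series:
    """Mean cohort-z-scored log2-CPM across a gene set, per sample.

    Genes absent from the matrix are logged and ignored; fewer than two
    matched genes is an error.  Scores have cohort mean ~0 by construction.
    """
    present = [g for g in gene_set if g in expression.index]
    missing = set(gene_set) - set(present)
    if missing:
        logger.info("pathway %s: %d gene(s) missing from matrix", name, len(missing))
    if len(present) < 2:
        raise ValueError(f"pathway {name!r}: fewer than 2 genes matched")
    sub = expression.loc[present]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0).replace(0, np.nan), axis=0)
    score = z.mean(axis=0)
    score.name = name or "pathway_score"
    return score
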