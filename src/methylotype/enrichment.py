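"""Genomic annotation of DMRs and enrichment versus matched random regions.

DMRs are assigned to annotation classes (promoters, exons, introns, CpG
islands/shores/shelves, repeat families, ...) by >=1 bp overlap; a region
may belong to several classes.  Enrichment of each class is tested with a
two-sided Fisher exact test of the 2x2 table {DMR, random} x {in, out},
where the random regions match the DMRs in number and width distribution
and are placed uniformly over the allowed genome.  A class is flagged
enriched when its Benjamini-Hochberg FDR is below 0.05 and the odds ratio
exceeds 1.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENRICH_FDR = 0.05
ENRICH_OR = 1.5


def _build_trees(bed: pd.DataFrame) -> dict:
    trees = {}
    for chrom, sub in bed.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            if e > s:
                t.addi(int(s), int(e))
        trees[str(chrom)] = t
    return trees


def annotate(regions: pd.DataFrame, classes: dict) -> pd.DataFrame:
    """Boolean membership table: regions (rows) x annotation classes.

    ``regions`` needs ``chrom, start, end`` (0-based half-open); ``classes``
    maps class name -> BED DataFrame.  Membership means at least 1 bp of
    overlap; half-open adjacency does not count.  Chromosomes absent from a
    class's intervals simply yield out-of-class.
    """
    out = {}
    for name, bed in classes.items():
        trees = _build_trees(bed)
        hits = np.zeros(len(regions), dtype=bool)
        for i, (chrom, s, e) in enumerate(
            zip(regions["chrom"], regions["start"], regions["end"])
        ):
            t = trees.get(str(chrom))
            if t is not None and t.overlap(int(s), int(e)):
                hits[i] = True
        out[name] = hits
    return pd.DataFrame(out, index=regions.index)


def random_matched_regions(
    regions: pd.DataFrame, chrom_sizes: dict, seed=None, rng=None,
    excluded_chroms=(),
) -> pd.DataFrame:
    """Random regions matching the input in count and width distribution.

    Widths are the input widths in shuffled order (resampled without
    replacement); placement is uniform over the allowed genome, choosing a
    chromosome with probability proportional to the room it offers the
    width.  Deterministic under ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    allowed = {c: sz for c, sz in chrom_sizes.items() if c not in set(excluded_chroms)}
    if not allowed:
        raise ValueError("no chromosomes left after exclusions")
    widths = (regions["end"] - regions["start"]).to_numpy()
    widths = widths[rng.permutation(len(widths))]
    chroms = list(allowed)
    sizes = np.array([allowed[c] for c in chroms], dtype=float)
    rows = []
    for w in widths:
        room = np.maximum(sizes - w + 1, 0)
        if room.sum() == 0:
            warnings.warn(f"region width {w} exceeds every chromosome; skipped")
            continue
        ci = rng.choice(len(chroms), p=room / room.sum())
        start = int(rng.integers(0, int(room[ci])))
        rows.append((chroms[ci], start, start + int(w)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _odds_ratio(a, b, c, d):
    if min(a, b, c, d) == 0:  # Haldane-Anscombe correction
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_enrichment(
    dmr_membership: pd.DataFrame, rand_membership: pd.DataFrame,
    fdr_threshold: float = ENRICH_FDR, or_threshold: float = ENRICH_OR,
) -> pd.DataFrame:
    """Per-class Fisher exact enrichment of DMRs against random regions.

    Both membership tables must cover the same classes.  The flag
    ``enriched`` requires FDR < 0.05 *and* OR > 1.5 (depletion is reported
    through the two-sided p but never flagged).
    """
    classes = list(dmr_membership.columns)
    if set(classes) != set(rand_membership.columns):
        raise ValueError("membership tables cover different classes")
    rows = []
    for name in classes:
        a = int(dmr_membership[name].sum())          # DMR in class
        b = int(len(dmr_membership) - a)             # DMR out
        c = int(rand_membership[name].sum())         # random in
        d = int(len(rand_membership) - c)
        if a + b == 0 or c + d == 0:
            rows.append({"class": name, "n_dmr_in": a, "n_dmr_out": b,
                         "n_rand_in": c, "n_rand_out": d,
                         "odds_ratio": np.nan, "p": 1.0, "degenerate": True})
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"class": name, "n_dmr_in": a, "n_dmr_out": b,
                     "n_rand_in": c, "n_rand_out": d,
                     "odds_ratio": _odds_ratio(a, b, c, d), "p": p,
                     "degenerate": False})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = (out["fdr"] < fdr_threshold) & (out["odds_ratio"] > or_threshold)
    return out


def enrich_dmrs(
    dmrs: pd.DataFrame, classes: dict, chrom_sizes: dict, seed=None,
    excluded_chroms=(),
) -> pd.DataFrame:
    """Convenience wrapper: annotate DMRs + matched randoms, then test."""
    dmr_mem = annotate(dmrs, classes)
    rand = random_matched_regions(dmrs, chrom_sizes, seed=seed,
                                  excluded_chroms=excluded_chroms)
    rand_mem = annotate(rand, classes)
    return fisher_enrichment(dmr_mem, rand_mem)
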