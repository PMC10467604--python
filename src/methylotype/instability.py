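"""Genomic instability scoring from copy-number segments.

The score is a modified large-scale-transition summary over copy-number
changes spanning more than 10 Mb: an arm-level alteration (a segment
covering most of a chromosome arm) contributes ``|CN - 2|``, a sub-arm
alteration larger than 10 Mb contributes a binary 1, and segments of 10 Mb
or less, or with near-neutral copy number, contribute nothing.  Segments
spanning the centromere gap are split at arm boundaries before
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SEGMENT_LEN = 10_000_000
NEUTRAL_CN = 2.0
NEUTRAL_BAND = 0.3
ARM_FRACTION = 0.9


@dataclass
class InstabilityScore:
    sample: str
    score: float
    n_arm_terms: int
    n_subarm_terms: int


def _split_to_arms(segments: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    """Intersect segments with arm intervals (splitting at boundaries)."""
    rows = []
    arm_by_chrom = {c: sub for c, sub in arms.groupby("chrom")}
    for seg in segments.itertuples(index=False):
        sub = arm_by_chrom.get(seg.chrom)
        if sub is None:
            logger.info("segment on %s matches no arm definition; ignored", seg.chrom)
            continue
        pieces = 0
        for arm in sub.itertuples(index=False):
            s = max(seg.start, arm.start)
            e = min(seg.end, arm.end)
            if e > s:
                rows.append((seg.sample, seg.chrom, s, e, seg.copy_number,
                             arm.arm, arm.end - arm.start))
                pieces += 1
        if pieces > 1:
            logger.info("segment %s:%d-%d spans the centromere; split",
                        seg.chrom, seg.start, seg.end)
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "copy_number", "arm", "arm_len"],
    )


def instability_score(
    segments: pd.DataFrame,
    arms: pd.DataFrame,
    min_len: int = MIN_SEGMENT_LEN,
    neutral_cn: float = NEUTRAL_CN,
    neutral_band: float = NEUTRAL_BAND,
    arm_fraction: float = ARM_FRACTION,
) -> list:
    """Per-sample instability scores from a SEG-like segment table.

    ``segments``: columns ``sample, chrom, start, end, copy_number``
    (0-based half-open, CN real-valued).  ``arms``: ``chrom, start, end,
    arm``.  A segment counts as arm-level when it covers at least
    ``arm_fraction`` of its arm; the length threshold ``min_len`` is strict
    (> 10 Mb); copy numbers within ``neutral_band`` of ``neutral_cn`` are
    treated as no alteration.
    """
    pieces = _split_to_arms(segments, arms)
    out = []
    all_samples = list(dict.fromkeys(segments["sample"]))
    by_sample = dict(tuple(pieces.groupby("sample"))) if len(pieces) else {}
    for sample in all_samples:
        sub = by_sample.get(sample)
        score, n_arm, n_sub = 0.0, 0, 0
        if sub is not None:
            for seg in sub.itertuples(index=False):
                length = seg.end - seg.start
                dev = abs(seg.copy_number - neutral_cn)
                if dev < neutral_band or length <= min_len:
                    continue
                if length >= arm_fraction * seg.arm_len:
                    score += dev
                    n_arm += 1
                else:
                    score += 1.0
                    n_sub += 1
        out.append(InstabilityScore(sample, float(score), n_arm, n_sub))
    return out


def scores_frame(scores: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.score, s.n_arm_terms, s.n_subarm_terms) for s in scores],
        columns=["sample", "score", "n_arm_terms", "n_subarm_terms"],
    )


def methylation_instability_correlation(
    meth_scores: pd.Series, scores: list, labels: pd.Series | None = None
) -> dict:
    """Pearson correlation between per-sample methylation and instability.

    ``meth_scores``: per-sample methylation fractions (e.g. cancer-cell
    specific means); ``labels``: optional per-sample group labels for the
    per-group means.  Requires at least 3 paired samples and non-degenerate
    variance in both vectors.
    """
    inst = scores_frame(scores).set_index("sample")["score"]
    common = [s for s in meth_scores.index if s in inst.index]
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    x = meth_scores.loc[common].astype(float)
    y = inst.loc[common].astype(float)
    if np.isclose(x.std(ddof=0), 0) or np.isclose(y.std(ddof=0), 0):
        raise ValueError("zero variance in methylation or instability vector")
    r, p = stats.pearsonr(x, y)
    result = {"pearson_r": float(r), "p": float(p), "n": len(common)}
    if labels is not None:
        lab = labels.loc[common]
        result["group_means"] = {
            g: {"methylation": float(x[lab == g].mean()),
                "instability": float(y[lab == g].mean())}
            for g in lab.unique()
        }
    return result
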