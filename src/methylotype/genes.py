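"""Gene-centric DMR summaries and methylation-direction calling.

Promoters are the 1,000 bp strand-aware regions immediately upstream of a
gene's TSS; the gene body is the transcribed span.  A gene's methylation
direction for a contrast is called by directly comparing the counts of
hypermethylated and hypomethylated DMRs overlapping its body.  The module
also classifies genes against a literature table of previously reported
directions (e.g. genes reported differentially methylated by HPV status)
and cross-tabulates site-level directions between two cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PROMOTER_BP = 1000


def gene_regions(gene_models: pd.DataFrame, promoter_bp: int = PROMOTER_BP) -> pd.DataFrame:
    """Add ``promoter_start/promoter_end`` (strand-aware, abutting the TSS).

    ``gene_models`` needs ``gene, chrom, strand, tss, start, end`` with a
    0-based TSS coordinate and half-open body interval.
    """
    g = gene_models.copy()
    plus = g["strand"] == "+"
    g["promoter_start"] = np.where(plus, np.maximum(g["tss"] - promoter_bp, 0), g["tss"] + 1)
    g["promoter_end"] = np.where(plus, g["tss"], g["tss"] + 1 + promoter_bp)
    return g


def count_gene_dmrs(
    dmrs: pd.DataFrame, gene_models: pd.DataFrame, region: str = "body",
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Hyper/hypo DMR counts per gene over its promoter or body.

    A DMR overlapping several genes' regions is counted for every one of
    them (>=1 bp overlap, half-open intervals).  ``dmrs`` must carry
    ``chrom, start, end, direction`` and contain significant records only.
    """
    if region not in {"body", "promoter"}:
        raise ValueError("region must be 'body' or 'promoter'")
    g = gene_regions(gene_models, promoter_bp)
    if region == "body":
        starts, ends = g["start"], g["end"]
    else:
        starts, ends = g["promoter_start"], g["promoter_end"]

    trees = {}
    for i, (chrom, s, e) in enumerate(zip(g["chrom"], starts, ends)):
        if e > s:
            trees.setdefault(str(chrom), IntervalTree()).addi(int(s), int(e), i)
    n_hyper = np.zeros(len(g), dtype=int)
    n_hypo = np.zeros(len(g), dtype=int)
    for chrom, s, e, direction in zip(dmrs["chrom"], dmrs["start"], dmrs["end"], dmrs["direction"]):
        t = trees.get(str(chrom))
        if t is None:
            continue
        for iv in t.overlap(int(s), int(e)):
            if direction == "hyper":
                n_hyper[iv.data] += 1
            else:
                n_hypo[iv.data] += 1
    out = g[["gene", "chrom", "strand"]].copy()
    out["n_hyper"] = n_hyper
    out["n_hypo"] = n_hypo
    return out


def call_direction(counts: pd.DataFrame) -> pd.DataFrame:
    """Direction call per gene from hyper/hypo DMR counts.

    hyper when ``n_hyper > n_hypo``; hypo when ``n_hypo > n_hyper``; tied
    when equal and non-zero; none when the gene has no DMR.
    """
    out = counts.copy()
    conds = [
        counts["n_hyper"] > counts["n_hypo"],
        counts["n_hypo"] > counts["n_hyper"],
        (counts["n_hyper"] == counts["n_hypo"]) & (counts["n_hyper"] > 0),
    ]
    out["direction"] = np.select(conds, ["hyper", "hypo", "tied"], default="none")
    return out


def literature_concordance(
    calls_imu: pd.DataFrame, calls_krt: pd.DataFrame, literature: pd.DataFrame
) -> dict:
    """Classify literature genes against per-subtype direction calls.

    ``calls_imu``/``calls_krt`` are :func:`call_direction` outputs for the
    IMU-vs-reference and KRT-vs-reference contrasts; ``literature`` has
    columns ``gene, direction``.  Classes: ``both`` (both subtypes agree
    with the reported direction), ``imu_only``, ``krt_only``, ``no_dmr``
    (neither subtype shows any DMR), ``discordant`` (otherwise, including
    genes whose calls oppose the report in both subtypes), ``unmapped``
    (gene absent from the gene models).
    """

    def _lookup(calls):
        return calls.set_index("gene")["direction"].to_dict()

    imu, krt = _lookup(calls_imu), _lookup(calls_krt)
    opposite = {"hyper": "hypo", "hypo": "hyper"}
    rows = []
    for r in literature.itertuples(index=False):
        gene, reported = r.gene, r.direction
        if gene not in imu and gene not in krt:
            rows.append((gene, reported, None, None, "unmapped"))
            continue
        ci = imu.get(gene, "none")
        ck = krt.get(gene, "none")
        if ci == reported and ck == reported:
            cls = "both"
        elif ci == reported:
            cls = "imu_only"
        elif ck == reported:
            cls = "krt_only"
        elif ci == "none" and ck == "none":
            cls = "no_dmr"
        else:
            cls = "discordant"
        rows.append((gene, reported, ci, ck, cls))
    table = pd.DataFrame(
        rows, columns=["gene", "reported", "call_imu", "call_krt", "class"]
    )
    counts = table["class"].value_counts().to_dict()
    retained = len(table) - counts.get("discordant", 0) - counts.get("unmapped", 0)
    concordant = counts.get("both", 0) + counts.get("imu_only", 0) + counts.get("krt_only", 0)
    summary = {
        "n_genes": int(len(table)),
        "n_retained": int(retained),
        "counts": {k: int(v) for k, v in counts.items()},
        "imu_only_pct_of_concordant": (
            round(100.0 * counts.get("imu_only", 0) / concordant) if concordant else 0
        ),
    }
    return {"table": table, "summary": summary}


def direction_crosstab(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Concordance cross-tab of site/region-level directions in two cohorts.

    Both inputs need a join key column (``tile`` or ``chrom,start,end``)
    and a ``direction`` column restricted to {hyper, hypo}.  Returns the
    2x2 counts, the concordant/reversed fractions, and the reversed-site
    table.
    """
    key = "tile" if "tile" in calls_a.columns and "tile" in calls_b.columns else None
    if key is None:
        for df in (calls_a, calls_b):
            if not {"chrom", "start", "end"}.issubset(df.columns):
                raise ValueError("need 'tile' or 'chrom,start,end' keys")
        calls_a = calls_a.assign(
            tile=calls_a["chrom"].astype(str) + ":" + calls_a["start"].astype(str)
            + "-" + calls_a["end"].astype(str))
        calls_b = calls_b.assign(
            tile=calls_b["chrom"].astype(str) + ":" + calls_b["start"].astype(str)
            + "-" + calls_b["end"].astype(str))
    joined = calls_a[["tile", "direction"]].merge(
        calls_b[["tile", "direction"]], on="tile", suffixes=("_a", "_b")
    )
    if len(joined) == 0:
        raise ValueError("no shared sites between the two direction tables")
    table = pd.crosstab(joined["direction_a"], joined["direction_b"])
    concordant = int((joined["direction_a"] == joined["direction_b"]).sum())
    reversed_sites = joined[joined["direction_a"] != joined["direction_b"]]
    return {
        "crosstab": table,
        "n_shared": int(len(joined)),
        "n_concordant": concordant,
        "n_reversed": int(len(reversed_sites)),
        "reversed_fraction": len(reversed_sites) / len(joined),
        "reversed_sites": reversed_sites.reset_index(drop=True),
    }
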