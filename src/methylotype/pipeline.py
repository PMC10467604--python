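"""End-to-end orchestration: cohort directory in, analysis tables out.

The pipeline consumes a cohort directory in the layout written by
:func:`methylotype.simulate.write_cohort` (per-sample cytosine reports,
metadata, gene models, annotation and region-set BEDs, expression matrix,
SEG file, arm definitions, atlas and deconvolution panel) and runs the
stages in order: tile -> differential methylation -> {enrichment, gene
summaries} -> cis-eQTM -> instability -> region sets/deconvolution.  Every
artifact is written as TSV/JSON with deterministic formatting, and a
manifest with SHA-256 checksums makes reruns byte-comparable.  Stages whose
inputs are absent (e.g. no expression matrix) are skipped with an explicit
notice in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, diffmeth, enrichment, eqtm, genes as genes_mod, instability, regsets
from .core import FilterConfig
from .diffmeth import GroupDesign

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, each under its conventional default."""

    input_dir: str = "."
    output_dir: str = "results"
    contrasts: list = field(default_factory=lambda: [
        ["IMU", "KRT"], ["IMU", "HPVneg"], ["KRT", "HPVneg"],
    ])
    # hpv_cpm is available as a covariate but not default: it is structurally
    # collinear with group in HPV(+) vs HPV(-) contrasts (zero for every
    # HPV(-) sample) and would absorb the group effect.
    covariates: list = field(default_factory=lambda: [
        "sex", "age", "smoking", "stage_iv",
    ])
    min_cov: int = 10
    max_cov: int = 500
    excluded_chroms: list = field(default_factory=lambda: ["chrX", "chrY"])
    fdr_dmr: float = 0.05
    min_diff_pp: float = 20.0
    min_group_frac: float = 0.8
    fdr_eqtm: float = 0.1
    cis_bp: int = 1_000_000
    promoter_bp: int = 1000
    instability_min_len: int = 10_000_000
    mira_bins: int = 21
    mira_flank_bp: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def encode_covariates(metadata: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric covariate matrix from a metadata table (sex coded M=1)."""
    out = pd.DataFrame(index=metadata.index)
    for name in names:
        if name not in metadata.columns:
            raise ValueError(f"covariate {name!r} missing from metadata")
        col = metadata[name]
        if name == "sex":
            out[name] = (col == "M").astype(float)
        else:
            out[name] = col.astype(float)
    return out


def read_cohort(indir) -> dict:
    """Load a cohort directory (the :func:`write_cohort` layout)."""
    indir = Path(indir)
    bundle = {}
    rep_dir = indir / "cpg_reports"
    bundle["reports"] = {
        p.name.split(".")[0]: core.read_cpg_report(p)
        for p in sorted(rep_dir.glob("*.cytosine_report.txt"))
    }
    bundle["metadata"] = pd.read_csv(indir / "metadata.tsv", sep="\t").set_index(
        "sample", drop=False
    )
    bundle["gene_models"] = pd.read_csv(indir / "gene_models.tsv", sep="\t")
    bundle["chrom_sizes"] = {}
    with open(indir / "chrom.sizes") as fh:
        for line in fh:
            c, sz = line.split()
            bundle["chrom_sizes"][c] = int(sz)
    bed_cols = ["chrom", "start", "end", "name", "score", "strand"]

    def _read_bed(p):
        df = pd.read_csv(p, sep="\t", header=None)
        df.columns = bed_cols[: df.shape[1]]
        return df

    bundle["annotations"] = {
        p.stem: _read_bed(p) for p in sorted((indir / "annotations").glob("*.bed"))
    }
    bundle["region_sets"] = {
        p.stem: _read_bed(p) for p in sorted((indir / "region_sets").glob("*.bed"))
    }
    expr_path = indir / "expression.tsv"
    bundle["expression"] = (
        pd.read_csv(expr_path, sep="\t", index_col=0) if expr_path.exists() else None
    )
    gs_path = indir / "gene_sets.json"
    bundle["gene_sets"] = json.loads(gs_path.read_text()) if gs_path.exists() else {}
    seg_path = indir / "cna_segments.seg"
    bundle["cna_segments"] = (
        pd.read_csv(seg_path, sep="\t") if seg_path.exists() else None
    )
    arms_path = indir / "chrom_arms.bed"
    bundle["arms"] = (
        pd.read_csv(arms_path, sep="\t", header=None,
                    names=["chrom", "start", "end", "arm"])
        if arms_path.exists() else None
    )
    atlas_path = indir / "atlas.tsv"
    bundle["atlas"] = (
        pd.read_csv(atlas_path, sep="\t", index_col=0) if atlas_path.exists() else None
    )
    panel_path = indir / "deconvolution_panel.tsv"
    bundle["deconv_meth"] = (
        pd.read_csv(panel_path, sep="\t", index_col=0) if panel_path.exists() else None
    )
    return bundle


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files = {}
        self.notes = []

    def add(self, path: Path, n_rows=None):
        rel = str(path.relative_to(self.outdir))
        self.files[rel] = {"sha256": _sha256(path)}
        if n_rows is not None:
            self.files[rel]["n_rows"] = int(n_rows)

    def note(self, msg):
        self.notes.append(msg)
        logger.info(msg)

    def write(self):
        p = self.outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump({"files": self.files, "notes": self.notes}, fh,
                      indent=1, sort_keys=True)
        return p


def _write_tsv(df: pd.DataFrame, path: Path, manifest: _Manifest, index=False):
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    manifest.add(path, n_rows=len(df))


def run_all(config: PipelineConfig, bundle: dict | None = None) -> dict:
    """Run every stage; returns in-memory results plus the manifest path.

    ``bundle`` may be passed directly (the dict layout of
    :func:`read_cohort` or a :class:`~methylotype.simulate.CohortBundle`'s
    fields) to skip re-reading from disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    if bundle is None:
        bundle = read_cohort(config.input_dir)
    elif not isinstance(bundle, dict):
        bundle = {k: getattr(bundle, k) for k in (
            "reports", "metadata", "gene_models", "chrom_sizes", "annotations",
            "region_sets", "expression", "gene_sets", "cna_segments", "arms",
            "atlas", "deconv_meth",
        )}
    results = {}

    # ---- stage: tile ---------------------------------------------------
    fcfg = FilterConfig(
        min_cov=config.min_cov, max_cov=config.max_cov,
        excluded_chroms=frozenset(config.excluded_chroms),
    )
    sites = core.combine_samples(bundle["reports"])
    sites = core.filter_sites(sites, fcfg)
    tiles = core.tile_100bp(sites)
    results["tiles"] = tiles
    manifest.note(f"tile: {len(sites)} sites -> {len(tiles)} tiles, "
                  f"mean coverage {tiles.mean_coverage():.1f}x")

    meta = bundle["metadata"]
    cov = encode_covariates(meta, config.covariates)
    # drop covariates that are constant across the cohort (uninformative)
    cov = cov.loc[:, cov.std() > 0]

    # ---- stage: differential methylation -------------------------------
    groups = {g: list(sub.index) for g, sub in meta.groupby("group")}
    all_records = []
    summaries = []
    for a, b in config.contrasts:
        members = groups[a] + groups[b]
        grp = np.array([1.0] * len(groups[a]) + [0.0] * len(groups[b]))
        use_cov = cov.loc[members]
        # collinearity guard: a covariate nearly aliasing the group label
        # would absorb the effect under test
        keep_cols = []
        for c in use_cov.columns:
            v = use_cov[c].to_numpy()
            if np.std(v) == 0:
                continue
            if abs(np.corrcoef(v, grp)[0, 1]) > 0.95:
                manifest.note(f"covariate {c} dropped for {a}_vs_{b}: aliases group")
                continue
            keep_cols.append(c)
        design = GroupDesign(groups[a], groups[b], covariates=use_cov[keep_cols],
                             contrast=f"{a}_vs_{b}")
        rec = diffmeth.run_contrast(
            tiles, design, min_group_frac=config.min_group_frac,
            fdr_threshold=config.fdr_dmr, min_diff_pp=config.min_diff_pp,
        )
        all_records.append(rec)
        summaries.append(diffmeth.summarize_dmrs(rec))
        _write_tsv(rec, outdir / f"dmr_{a}_vs_{b}.tsv", manifest)
        sig = rec[rec["is_dmr"]]
        _write_tsv(sig[["chrom", "start", "end", "direction", "diff_pp", "fdr"]],
                   outdir / f"dmr_{a}_vs_{b}.bed", manifest)
    dmr_records = pd.concat(all_records, ignore_index=True)
    summary_df = pd.DataFrame(summaries)
    _write_tsv(summary_df, outdir / "dmr_summary.tsv", manifest)
    results["dmr_records"] = dmr_records
    results["dmr_summary"] = summary_df

    # ---- stage: annotation enrichment ----------------------------------
    classes = bundle["annotations"]
    enrich_tables = {}
    for (a, b) in config.contrasts:
        name = f"{a}_vs_{b}"
        sig = dmr_records[(dmr_records["contrast"] == name) & dmr_records["is_dmr"]]
        if len(sig) < 10:
            manifest.note(f"enrichment skipped for {name}: {len(sig)} DMRs")
            continue
        table = enrichment.enrich_dmrs(
            sig[["chrom", "start", "end"]].reset_index(drop=True), classes,
            bundle["chrom_sizes"], seed=config.seed,
            excluded_chroms=config.excluded_chroms,
        )
        enrich_tables[name] = table
        _write_tsv(table, outdir / f"enrichment_{name}.tsv", manifest)
    results["enrichment"] = enrich_tables

    # ---- stage: gene-level summaries -----------------------------------
    gmodels = bundle["gene_models"]
    direction_calls = {}
    for (a, b) in config.contrasts:
        name = f"{a}_vs_{b}"
        sig = dmr_records[(dmr_records["contrast"] == name) & dmr_records["is_dmr"]]
        for region in ("promoter", "body"):
            counts = genes_mod.count_gene_dmrs(
                sig, gmodels, region=region, promoter_bp=config.promoter_bp
            )
            calls = genes_mod.call_direction(counts)
            direction_calls[(name, region)] = calls
            _write_tsv(calls, outdir / f"gene_dmrs_{name}_{region}.tsv", manifest)
    results["gene_direction"] = direction_calls

    # ---- stage: cis-eQTM ------------------------------------------------
    expression = bundle.get("expression")
    if expression is None:
        manifest.note("eqtm skipped: no expression matrix")
        results["eqtm"] = None
    else:
        mask = eqtm.filter_eqtm_tiles(tiles)
        sub = tiles.subset(mask)
        pairs = eqtm.cis_pairs(sub, gmodels, max_dist=config.cis_bp)
        eqtm_cov_names = [c for c in ("sex", "age", "stage_iv", "smoking")
                          if c in cov.columns]
        fitted = eqtm.fit_eqtm(pairs, sub, expression,
                               covariates=cov[eqtm_cov_names],
                               fdr_threshold=config.fdr_eqtm)
        overlap = eqtm.eqtm_dmr_overlap(fitted, dmr_records)
        _write_tsv(fitted[fitted["significant"]].drop(columns=["tile_index"]),
                   outdir / "eqtm_significant.tsv", manifest)
        manifest.note(
            f"eqtm: {len(pairs)} candidate pairs, "
            f"{int(fitted['significant'].sum())} significant, "
            f"{overlap['n_unique_eqtm_tiles']} unique tiles, "
            f"{overlap['overlap_pct']}% overlapping DMRs"
        )
        results["eqtm"] = fitted
        results["eqtm_overlap"] = {
            k: v for k, v in overlap.items() if k != "pairs"
        }

    # ---- stage: genomic instability ------------------------------------
    segs, arms = bundle.get("cna_segments"), bundle.get("arms")
    if segs is None or arms is None:
        manifest.note("instability skipped: no CNA segments or arm definitions")
        results["instability"] = None
    else:
        scores = instability.instability_score(
            segs, arms, min_len=config.instability_min_len
        )
        sdf = instability.scores_frame(scores)
        _write_tsv(sdf, outdir / "instability_scores.tsv", manifest)
        results["instability"] = scores

    # ---- stage: region sets, deconvolution, pathways -------------------
    mira_tables = []
    for name, bed in bundle["region_sets"].items():
        prof = regsets.mira_profile(tiles, bed, n_bins=config.mira_bins,
                                    flank_bp=config.mira_flank_bp)
        score = regsets.mira_score(prof)
        _write_tsv(prof, outdir / f"mira_profile_{name}.tsv", manifest, index=True)
        mira_tables.append(pd.DataFrame({
            "sample": score.index, "region_set": name, "score": score.to_numpy(),
        }))
    if mira_tables:
        mira_df = pd.concat(mira_tables, ignore_index=True)
        _write_tsv(mira_df, outdir / "mira_scores.tsv", manifest)
        results["mira_scores"] = mira_df

    atlas, panel = bundle.get("atlas"), bundle.get("deconv_meth")
    if atlas is None or panel is None:
        manifest.note("deconvolution skipped: no atlas or panel")
        results["deconvolution"] = None
    else:
        dec = regsets.deconvolve_cohort(panel, atlas)
        _write_tsv(dec, outdir / "deconvolution.tsv", manifest)
        results["deconvolution"] = dec
        if results.get("instability"):
            meth_scores = dec.set_index("sample")["cancer_meth_mean"].dropna()
            try:
                corr = instability.methylation_instability_correlation(
                    meth_scores, results["instability"], labels=meta["group"]
                )
                results["meth_instability_corr"] = corr
                with open(outdir / "instability_correlation.json", "w") as fh:
                    json.dump(corr, fh, indent=1, sort_keys=True)
                manifest.add(outdir / "instability_correlation.json")
                manifest.note(
                    f"cancer-specific methylation vs instability: "
                    f"r={corr['pearson_r']:.3f} p={corr['p']:.2g}"
                )
            except ValueError as exc:
                manifest.note(f"instability correlation skipped: {exc}")

    if expression is not None and bundle.get("gene_sets"):
        ps = {name: regsets.pathway_score(expression, members, name)
              for name, members in bundle["gene_sets"].items()}
        ps_df = pd.DataFrame(ps)
        _write_tsv(ps_df, outdir / "pathway_scores.tsv", manifest, index=True)
        results["pathway_scores"] = ps_df

    cfg_dump = {k: v for k, v in asdict(config).items()
                if k not in ("input_dir", "output_dir")}
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg_dump, fh, indent=1, sort_keys=True)
    manifest.add(outdir / "config.json")
    results["manifest_path"] = manifest.write()
    return results


def run_demo(outdir, seed: int = 0, sim_config=None,
             pipeline_config: PipelineConfig | None = None) -> dict:
    """Simulate the demo cohort, write it, and run the full pipeline."""
    from .simulate import SimConfig, simulate_cohort, write_cohort

    outdir = Path(outdir)
    cohort_dir = outdir / "cohort"
    if sim_config is None:
        sim_config = SimConfig(seed=seed)
    bundle = simulate_cohort(sim_config)
    write_cohort(bundle, cohort_dir)
    cfg = pipeline_config or PipelineConfig()
    cfg.input_dir = str(cohort_dir)
    cfg.output_dir = str(outdir / "analysis")
    cfg.seed = seed
    return run_all(cfg, bundle=bundle)
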