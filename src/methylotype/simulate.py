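"""Synthetic WGBS mini-cohort with known ground truth.

Generates everything the downstream stages consume — per-sample CpG count
reports, sample metadata, gene models, annotation BEDs, an expression
matrix, copy-number segments with arm definitions, regulatory region sets,
and a reference methylation atlas — for a cohort emulating the structure of
an HPV-stratified head-and-neck tumour study: an immune-strong HPV(+)
subtype (IMU, globally hypermethylated, mean ~62%), a keratinised HPV(+)
subtype (KRT, ~51%) and HPV(−) tumours (~52%).

The count model is beta-binomial and deliberately matches the model family
of the differential test: for each (tile, sample) a latent methylation
level is drawn from a Beta distribution with the site mean and intraclass
dispersion ``phi``, shared across the CpGs of a 100-bp tile, and methylated
reads are binomial given the per-CpG coverage.  Planted differentially
methylated blocks, methylation-coupled genes, copy-number segment sets
with known instability and known cell-type mixtures are recorded in a
:class:`GroundTruth` object so every downstream stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, TILE_SIZE
from .diffmeth import GroupDesign

EPS = 1e-3


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_group_sizes():
    return {"IMU": 8, "KRT": 10, "HPVneg": 18}


def _default_group_meth():
    return {"IMU": 0.62, "KRT": 0.51, "HPVneg": 0.52}


def _default_cna_counts():
    return {"IMU": 2, "KRT": 4, "HPVneg": 6}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the cohort structure the package is designed around:
    36 tumours (8 IMU, 10 KRT, 18 HPV(−)); group-wise global methylation
    means of 0.62 / 0.51 / 0.52; ~24x mean coverage.  ``beta_dispersion_phi``
    is the within-group biological (intraclass) dispersion of tile
    methylation; WGBS cohorts typically show tile-level dispersions of a few
    percent, so the default is 0.05 and tests sweep 0.05-0.2.
    """

    n_chroms: int = 3
    chrom_len_bp: int = 30_000_000
    cpg_spacing_mean_bp: int = 1200
    group_sizes: dict = field(default_factory=_default_group_sizes)
    group_global_meth: dict = field(default_factory=_default_group_meth)
    n_dmr_blocks: int = 60
    dmr_effect_pp: float = 30.0
    mean_coverage: float = 24.0
    coverage_dispersion: float = 0.3
    beta_dispersion_phi: float = 0.05
    n_eqtm_genes: int = 40
    eqtm_slope: float = 2.0
    n_genes: int = 120
    n_cna_segments: dict = field(default_factory=_default_cna_counts)
    seed: int = 0
    # genome texture
    island_spacing_bp: int = 120_000
    island_len_bp: int = 1000
    island_cpg_spacing_bp: int = 12
    dmr_island_odds: float = 2.0
    sample_meth_sd: float = 0.04
    expr_noise_sd: float = 0.5
    confounded: bool = False
    # region sets / deconvolution panel
    n_regions_per_set: int = 150
    n_atlas_regions: int = 500
    n_atlas_cell_types: int = 4
    tumor_fraction_mean: float = 0.6

    def __post_init__(self):
        for g, v in self.group_global_meth.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"group_global_meth[{g}]={v} outside [0,1]")
        for name in ("n_chroms", "chrom_len_bp", "cpg_spacing_mean_bp", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.beta_dispersion_phi < 1.0:
            if self.beta_dispersion_phi != 0.0:
                raise ValueError("beta_dispersion_phi must lie in [0, 1)")

    @property
    def samples_by_group(self) -> dict:
        return {
            g: [f"{g}{i + 1}" for i in range(n)] for g, n in self.group_sizes.items()
        }

    @property
    def samples(self) -> list:
        return [s for ss in self.samples_by_group.values() for s in ss]


@dataclass
class GroundTruth:
    """What was planted, for scoring the downstream stages."""

    planted_dmrs: list = field(default_factory=list)
    planted_eqtms: list = field(default_factory=list)
    true_instability: dict = field(default_factory=dict)
    true_cell_fractions: dict = field(default_factory=dict)
    true_cancer_meth_mean: dict = field(default_factory=dict)
    mira_dip_depths: dict = field(default_factory=dict)
    clip_warnings: int = 0


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: inputs for every pipeline stage."""

    config: SimConfig
    metadata: pd.DataFrame
    reports: dict                 # sample -> CpG count DataFrame
    chrom_sizes: dict
    annotations: dict             # class name -> BED DataFrame
    gene_models: pd.DataFrame
    gene_sets: dict
    expression: pd.DataFrame      # genes x samples (log2-CPM-like)
    cna_segments: pd.DataFrame
    arms: pd.DataFrame
    region_sets: dict             # set name -> BED DataFrame
    atlas: pd.DataFrame           # cell types (rows) x panel regions
    deconv_meth: pd.DataFrame     # panel regions x samples
    truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level draws
# ---------------------------------------------------------------------------

def _beta_params(mean, phi):
    mean = np.clip(mean, EPS, 1 - EPS)
    s = (1.0 - phi) / phi
    return mean * s, (1.0 - mean) * s


def draw_beta_binomial(rng, mean, phi, coverage):
    """Methylated counts ~ BetaBinomial(coverage, mean, phi), elementwise."""
    mean = np.asarray(mean, dtype=float)
    coverage = np.asarray(coverage)
    if phi <= 1e-9:
        p = np.clip(mean, EPS, 1 - EPS)
    else:
        a, b = _beta_params(mean, phi)
        p = rng.beta(a, b)
    return rng.binomial(coverage.astype(int), p)


def draw_coverage(rng, mean_coverage, dispersion, size):
    """Gamma-Poisson (negative-binomial) read depth, floored at 1."""
    if dispersion <= 1e-9:
        cov = rng.poisson(mean_coverage, size=size)
    else:
        lam = rng.gamma(1.0 / dispersion, mean_coverage * dispersion, size=size)
        cov = rng.poisson(lam)
    return np.maximum(cov, 1)


def simulate_tile_counts(
    rng,
    n_tiles: int,
    n_a: int = 8,
    n_b: int = 10,
    coverage: float = 24.0,
    phi: float = 0.05,
    effect_pp: float = 0.0,
    coverage_dispersion: float = 0.3,
    base_range=(0.2, 0.8),
):
    """Direct two-group tile count matrices for calibration/power studies.

    Per tile a base methylation mean is drawn uniformly from ``base_range``;
    group A means are shifted by ``effect_pp`` percentage points (clipped).
    Returns ``(CountMatrix, GroupDesign)`` with samples ``A1.. / B1..``.
    """
    base = rng.uniform(*base_range, size=n_tiles)
    mean_b = base
    mean_a = np.clip(base + effect_pp / 100.0, EPS, 1 - EPS)
    samples = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    means = np.column_stack([np.repeat(mean_a[:, None], n_a, axis=1),
                             np.repeat(mean_b[:, None], n_b, axis=1)])
    cov = draw_coverage(rng, coverage, coverage_dispersion, (n_tiles, n_a + n_b))
    meth = draw_beta_binomial(rng, means, phi, cov)
    features = pd.DataFrame({
        "chrom": "chrS",
        "start": np.arange(n_tiles) * TILE_SIZE,
        "end": (np.arange(n_tiles) + 1) * TILE_SIZE,
        "n_cpgs": 1,
    })
    tiles = CountMatrix(
        features,
        pd.DataFrame(meth.astype(float), columns=samples),
        pd.DataFrame(cov.astype(float), columns=samples),
    )
    design = GroupDesign(tuple(samples[:n_a]), tuple(samples[n_a:]), contrast="A_vs_B")
    return tiles, design


def simulate_eqtm_pairs(
    rng,
    n_pairs: int,
    n_samples: int = 36,
    slope: float = 2.0,
    noise_sd: float = 0.5,
    phi: float = 0.05,
):
    """Methylation/expression pairs emulating CV-filtered variable tiles.

    Each pair's tile has a bimodal across-sample methylation pattern (two
    latent levels, as a variable tile passing the coefficient-of-variation
    filter would), beta-distributed around each level; expression is
    ``intercept + slope * methylation + N(0, noise_sd)``.  ``slope`` may be
    an array of per-pair signed slopes.  Returns (meth, expr) arrays of
    shape (n_pairs, n_samples) and the slope array used.
    """
    slopes = np.broadcast_to(np.asarray(slope, dtype=float), (n_pairs,)).copy()
    lo = rng.uniform(0.15, 0.4, size=n_pairs)
    hi = lo + rng.uniform(0.25, 0.45, size=n_pairs)
    split = rng.integers(n_samples // 3, 2 * n_samples // 3, size=n_pairs)
    levels = np.where(
        np.arange(n_samples)[None, :] < split[:, None], lo[:, None], hi[:, None]
    )
    # per-sample permutation so the two levels are not tied to sample order
    perm = np.argsort(rng.random((n_pairs, n_samples)), axis=1)
    levels = np.take_along_axis(levels, perm, axis=1)
    if phi > 1e-9:
        a, b = _beta_params(levels, phi)
        meth = rng.beta(a, b)
    else:
        meth = levels
    expr = 5.0 + slopes[:, None] * meth + rng.normal(0, noise_sd, size=meth.shape)
    return meth, expr, slopes


def simulate_mixtures(
    rng,
    n_mixtures: int,
    n_regions: int = 500,
    noise_sd: float = 0.03,
    n_cell_types: int = 4,
    tumor_profile_sd: float = 0.02,
):
    """Controlled bulk-methylome mixtures for deconvolution recovery studies.

    Builds a marker-structured atlas (``n_cell_types`` normal references
    plus a tumour row), draws mixture weights (tumour fraction uniform on
    [0.4, 0.8], remainder Dirichlet over the normals), perturbs the tumour
    methylome per mixture by ``tumor_profile_sd``, and adds measurement
    noise.  Returns ``(atlas, mixtures, truth)`` where ``truth`` holds per
    mixture the true fractions and the true tumour methylome mean.
    """
    cell_types = [f"normal{i+1}" for i in range(n_cell_types)] + ["tumor"]
    n_marker = max(5, n_regions // (len(cell_types) + 1))
    baseline = rng.uniform(0.3, 0.7, size=n_regions)
    profiles = {ct: baseline + rng.normal(0, 0.02, size=n_regions) for ct in cell_types}
    for k, ct in enumerate(cell_types):
        sl = slice(k * n_marker, (k + 1) * n_marker)
        for other in cell_types:
            profiles[other][sl] = 0.85 if other == ct else 0.12
    atlas = pd.DataFrame(
        {ct: np.clip(v, 0.01, 0.99) for ct, v in profiles.items()},
        index=[f"R{i+1:04d}" for i in range(n_regions)],
    ).T
    mixtures = {}
    truth = {}
    for i in range(n_mixtures):
        name = f"mix{i+1}"
        w_t = float(rng.uniform(0.4, 0.8))
        w_n = rng.dirichlet(np.full(n_cell_types, 2.0)) * (1 - w_t)
        t_prof = np.clip(
            atlas.loc["tumor"].to_numpy() + rng.normal(0, tumor_profile_sd, n_regions),
            0.01, 0.99,
        )
        x = w_t * t_prof
        for w, ct in zip(w_n, cell_types[:-1]):
            x = x + w * atlas.loc[ct].to_numpy()
        mixtures[name] = np.clip(x + rng.normal(0, noise_sd, n_regions), 0.0, 1.0)
        truth[name] = {
            "tumor_fraction": w_t,
            "fractions": {ct: float(w) for ct, w in zip(cell_types[:-1], w_n)},
            "tumor_meth_mean": float(t_prof.mean()),
        }
    return atlas, pd.DataFrame(mixtures, index=atlas.columns), truth


# ---------------------------------------------------------------------------
# genome scaffolding
# ---------------------------------------------------------------------------

def _simulate_genome(cfg: SimConfig, rng):
    """CpG positions (1-based), island intervals, per-chrom sizes."""
    chrom_sizes = {f"chr{i+1}": cfg.chrom_len_bp for i in range(cfg.n_chroms)}
    positions, chroms, islands = [], [], []
    for chrom, size in chrom_sizes.items():
        # background CpGs with exponential spacing
        n_bg = int(size / cfg.cpg_spacing_mean_bp * 1.2)
        gaps = rng.exponential(cfg.cpg_spacing_mean_bp, size=n_bg)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        pos = pos[pos <= size - 2]
        site_pos = [pos]
        # island hotspots: dense CpG runs at regular-ish spacing
        start = cfg.island_spacing_bp
        while start + cfg.island_len_bp < size - cfg.island_spacing_bp // 2:
            jitter = int(rng.integers(-cfg.island_spacing_bp // 5, cfg.island_spacing_bp // 5))
            s = max(1, start + jitter)
            e = s + cfg.island_len_bp
            islands.append((chrom, s - 1, e - 1))  # BED, 0-based half-open
            ipos = np.arange(s, e, cfg.island_cpg_spacing_bp, dtype=np.int64)
            site_pos.append(ipos)
            start += cfg.island_spacing_bp
        allpos = np.unique(np.concatenate(site_pos))
        positions.append(allpos)
        chroms.append(np.repeat(chrom, len(allpos)))
    sites = pd.DataFrame({
        "chrom": np.concatenate(chroms),
        "pos": np.concatenate(positions),
    })
    island_bed = pd.DataFrame(islands, columns=["chrom", "start", "end"])
    return sites, island_bed, chrom_sizes


def _in_intervals(sites: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    """Membership of (1-based) sites in 0-based half-open BED intervals."""
    member = np.zeros(len(sites), dtype=bool)
    pos0 = sites["pos"].to_numpy() - 1
    for chrom, sub in bed.groupby("chrom"):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = pos0[sel][ok] < ends[idx[ok]]
        member[sel] = hit
    return member


def _calibrate_offset(base: np.ndarray, target: float) -> float:
    """Additive offset delta with mean(clip(base + delta)) == target."""
    lo, hi = -1.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.mean(np.clip(base + mid, EPS, 1 - EPS)) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig | None = None) -> CohortBundle:
    """Generate the full synthetic cohort bundle (deterministic per seed)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    sites, island_bed, chrom_sizes = _simulate_genome(cfg, rng)
    n_sites = len(sites)
    is_island = _in_intervals(sites, island_bed)

    # base site means: hypermethylated background, hypomethylated islands
    base = np.empty(n_sites)
    base[~is_island] = rng.beta(5.0, 2.2, size=(~is_island).sum())   # mean ~0.69
    base[is_island] = rng.beta(1.5, 9.0, size=is_island.sum())       # mean ~0.14

    groups = list(cfg.group_sizes)
    samples_by_group = cfg.samples_by_group
    samples = cfg.samples
    group_of = {s: g for g, ss in samples_by_group.items() for s in ss}

    # regulatory region sets with group-specific methylation dips
    region_sets, dip_factor = _make_region_sets(cfg, rng, chrom_sizes, sites, groups)
    truth.mira_dip_depths = {
        name: depths for name, (_, depths) in region_sets.items()
    }
    region_set_beds = {name: bed for name, (bed, _) in region_sets.items()}

    # group-level site means, calibrated to the configured global means
    group_mean = {}
    for g in groups:
        shaped = base * dip_factor[g]
        delta = _calibrate_offset(shaped, cfg.group_global_meth[g])
        group_mean[g] = np.clip(shaped + delta, EPS, 1 - EPS)

    _plant_dmrs(cfg, rng, sites, is_island, island_bed, group_mean, truth)

    # per-sample latent factor: shifts methylation, anti-shifts CNA burden.
    # Centered within each group so group_global_meth stays the group mean.
    z = rng.normal(0, 1, size=len(samples))
    offset = 0
    for g in groups:
        n_g = cfg.group_sizes[g]
        z[offset:offset + n_g] -= z[offset:offset + n_g].mean()
        offset += n_g
    sample_delta = {s: cfg.sample_meth_sd * z[i] for i, s in enumerate(samples)}

    gene_models, annotations = _make_genes_and_annotations(
        cfg, rng, chrom_sizes, island_bed
    )
    # methylation-coupled genes: their TSS-proximal tile gets a bimodal
    # across-sample shift (the high-variability pattern the eQTM CV filter
    # selects for), recorded for expression coupling below
    eqtm_plan = _pick_eqtm_tiles(cfg, rng, gene_models, sites, samples)

    # tile-shared beta quantile -> beta-binomial closure at the tile level
    pos0 = sites["pos"].to_numpy() - 1
    tile_id = pd.factorize(
        sites["chrom"].astype(str) + ":" + ((pos0 // TILE_SIZE)).astype(str)
    )[0]
    n_tiles = tile_id.max() + 1

    reports = {}
    phi = cfg.beta_dispersion_phi
    for s in samples:
        mu = group_mean[group_of[s]] + sample_delta[s]
        for plan in eqtm_plan:
            mu = mu.copy() if mu is group_mean[group_of[s]] else mu
            shift = plan["shift"] if s in plan["hi_samples"] else -plan["shift"]
            mu[plan["site_idx"]] = mu[plan["site_idx"]] + shift
        mu = np.clip(mu, EPS, 1 - EPS)
        cov = draw_coverage(rng, cfg.mean_coverage, cfg.coverage_dispersion, n_sites)
        if phi > 1e-9:
            q = rng.random(n_tiles)[tile_id]
            a, b = _beta_params(mu, phi)
            p = stats.beta.ppf(q, a, b)
        else:
            p = mu
        meth = rng.binomial(cov, np.clip(p, 0.0, 1.0))
        reports[s] = pd.DataFrame({
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "count_meth": meth,
            "count_total": cov,
        })

    metadata = _make_metadata(cfg, rng, samples_by_group)
    expression, gene_sets = _make_expression(
        cfg, rng, gene_models, eqtm_plan, reports, metadata, truth
    )
    cna_segments, arms = _make_cna(cfg, rng, chrom_sizes, samples, group_of, z, truth)
    atlas, deconv_meth = _make_deconvolution_panel(
        cfg, rng, samples, group_of, sample_delta, truth
    )

    return CohortBundle(
        config=cfg,
        metadata=metadata,
        reports=reports,
        chrom_sizes=chrom_sizes,
        annotations=annotations,
        gene_models=gene_models,
        gene_sets=gene_sets,
        expression=expression,
        cna_segments=cna_segments,
        arms=arms,
        region_sets=region_set_beds,
        atlas=atlas,
        deconv_meth=deconv_meth,
        truth=truth,
    )


def _make_region_sets(cfg, rng, chrom_sizes, sites, groups):
    """TF/enhancer-like region sets; returns beds and per-group dip factors."""
    specs = {
        "CTCF": (400, {"IMU": 0.35, "KRT": 0.60, "HPVneg": 0.55}),
        "NHEK_strong_enhancer": (800, {"IMU": 0.30, "KRT": 0.55, "HPVneg": 0.50}),
    }
    chroms = list(chrom_sizes)
    out = {}
    dip_factor = {g: np.ones(len(sites)) for g in groups}
    pos = sites["pos"].to_numpy()
    site_chrom = sites["chrom"].to_numpy()
    sigma = 150.0
    for name, (width, depths) in specs.items():
        rows = []
        for _ in range(cfg.n_regions_per_set):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            rows.append((chrom, start, start + width, name, 0, "+" if rng.random() < 0.5 else "-"))
            center = start + width / 2.0
            sel = (site_chrom == chrom) & (np.abs(pos - center) < 4 * sigma)
            if sel.any():
                g_shape = np.exp(-((pos[sel] - center) ** 2) / (2 * sigma**2))
                for g in groups:
                    d = depths.get(g, 0.4)
                    dip_factor[g][sel] *= 1.0 - d * g_shape
        bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        out[name] = (bed.sort_values(["chrom", "start"]).reset_index(drop=True), depths)
    return out, dip_factor


def _plant_dmrs(cfg, rng, sites, is_island, island_bed, group_mean, truth):
    """Plant blocks of differential methylation between group pairs.

    Hyper-in-IMU effects dominate, mirroring the subtype structure the
    cohort emulates (IMU hypermethylated against both KRT and HPV(−); the
    KRT vs HPV(−) contrast mixed and mostly hypomethylated in KRT).
    Island placement uses ``dmr_island_odds``-weighted sampling.
    """
    if cfg.n_dmr_blocks == 0 or cfg.dmr_effect_pp == 0:
        return
    pair_cycle = [
        (("IMU", "KRT"), 0.9),
        (("IMU", "HPVneg"), 0.9),
        (("KRT", "HPVneg"), 0.35),
    ]
    pos0 = sites["pos"].to_numpy() - 1
    tile_start = (pos0 // TILE_SIZE) * TILE_SIZE
    keyframe = pd.DataFrame({
        "chrom": sites["chrom"], "tstart": tile_start, "island": is_island
    })
    tiles = keyframe.groupby(["chrom", "tstart"], sort=True).agg(
        island=("island", "any"), n=("island", "size")
    ).reset_index()
    tiles = tiles[tiles["n"] >= 1].reset_index(drop=True)
    w = np.where(tiles["island"], cfg.dmr_island_odds, 1.0)
    w = w / w.sum()
    chosen = rng.choice(len(tiles), size=min(cfg.n_dmr_blocks, len(tiles)),
                        replace=False, p=w)
    site_key = sites["chrom"].astype(str) + ":" + tile_start.astype(str)
    site_key = site_key.to_numpy()
    for i, t_idx in enumerate(chosen):
        (pair, p_hyper) = pair_cycle[i % len(pair_cycle)]
        a, b = pair
        sign = 1.0 if rng.random() < p_hyper else -1.0
        effect = sign * cfg.dmr_effect_pp / 100.0
        row = tiles.iloc[t_idx]
        key = f"{row['chrom']}:{row['tstart']}"
        sel = site_key == key
        raw = group_mean[a][sel] + effect
        clipped = int(((raw < EPS) | (raw > 1 - EPS)).sum())
        if clipped:
            truth.clip_warnings += clipped
        group_mean[a][sel] = np.clip(raw, EPS, 1 - EPS)
        truth.planted_dmrs.append({
            "chrom": str(row["chrom"]),
            "start": int(row["tstart"]),
            "end": int(row["tstart"]) + TILE_SIZE,
            "group_a": a,
            "group_b": b,
            "effect_pp": float(sign * cfg.dmr_effect_pp),
        })


def _make_metadata(cfg, rng, samples_by_group):
    rows = []
    for g, ss in samples_by_group.items():
        for s in ss:
            if cfg.confounded:
                p_smoke = 0.8 if g == "HPVneg" else 0.3
            else:
                p_smoke = 0.5
            rows.append({
                "sample": s,
                "group": g,
                "sex": "M" if rng.random() < 0.7 else "F",
                "age": int(np.round(rng.normal(60, 8))),
                "smoking": int(rng.random() < p_smoke),
                "stage_iv": int(rng.random() < 0.4),
                "hpv_cpm": 0.0 if g == "HPVneg" else float(np.round(np.exp(rng.normal(3.0, 1.0)), 3)),
                "hpv_integration": int(rng.random() < (0.3 if g == "IMU" else 0.7)) if g != "HPVneg" else 0,
            })
    return pd.DataFrame(rows).set_index("sample", drop=False)


def _make_genes_and_annotations(cfg, rng, chrom_sizes, island_bed):
    chroms = list(chrom_sizes)
    rows = []
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        size = chrom_sizes[chrom]
        margin = min(1_000_000, size // 6)
        tss0 = int(rng.integers(margin, size - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(5_000, min(50_000, max(10_000, size // 20))))
        if strand == "+":
            start, end = tss0, min(tss0 + body_len, size)
        else:
            start, end = max(tss0 - body_len + 1, 0), tss0 + 1
        rows.append({
            "gene": f"G{i+1:04d}", "chrom": chrom, "strand": strand,
            "tss": tss0, "start": start, "end": end,
        })
    genes = pd.DataFrame(rows)

    promoters, exons, introns = [], [], []
    for r in genes.itertuples(index=False):
        if r.strand == "+":
            promoters.append((r.chrom, max(0, r.tss - 1000), r.tss, r.gene))
        else:
            promoters.append((r.chrom, r.tss + 1, r.tss + 1001, r.gene))
        length = r.end - r.start
        cuts = [0, 0.2, 0.4, 0.6, 0.8, 1.0]
        for j in range(5):
            s = r.start + int(cuts[j] * length)
            e = r.start + int(cuts[j + 1] * length)
            (exons if j % 2 == 0 else introns).append((r.chrom, s, e, r.gene))
    repeat_rows = []
    fams = ["AluY", "L1", "L2"]
    for chrom, size in chrom_sizes.items():
        for _ in range(200):
            s = int(rng.integers(0, size - 6000))
            ln = int(rng.integers(300, 3000))
            repeat_rows.append((chrom, s, s + ln, fams[rng.integers(3)]))

    def _bed(rows4):
        return (pd.DataFrame(rows4, columns=["chrom", "start", "end", "name"])
                .sort_values(["chrom", "start"]).reset_index(drop=True))

    shores, shelves = _island_flanks(island_bed, chrom_sizes)
    annotations = {
        "promoter": _bed(promoters),
        "exon": _bed(exons),
        "intron": _bed(introns),
        "cpg_island": island_bed.assign(name="cpg_island"),
        "cpg_shore": shores,
        "cpg_shelf": shelves,
        "repeat": _bed(repeat_rows),
    }
    return genes, annotations


def _island_flanks(island_bed, chrom_sizes):
    shores, shelves = [], []
    for r in island_bed.itertuples(index=False):
        size = chrom_sizes[r.chrom]
        shores.append((r.chrom, max(0, r.start - 2000), r.start, "shore"))
        shores.append((r.chrom, r.end, min(size, r.end + 2000), "shore"))
        shelves.append((r.chrom, max(0, r.start - 4000), max(0, r.start - 2000), "shelf"))
        shelves.append((r.chrom, min(size, r.end + 2000), min(size, r.end + 4000), "shelf"))
    cols = ["chrom", "start", "end", "name"]
    return (pd.DataFrame(shores, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True),
            pd.DataFrame(shelves, columns=cols).sort_values(["chrom", "start"]).reset_index(drop=True))


def _pick_eqtm_tiles(cfg, rng, genes, sites, samples):
    """Choose TSS-proximal tiles for methylation-coupled genes.

    Each chosen tile's CpG means are later shifted by ``+shift`` for a
    random half of the samples and ``-shift`` for the rest, emulating the
    strongly variable tiles that drive detectable cis associations.
    """
    site_chrom = sites["chrom"].to_numpy()
    site_pos = sites["pos"].to_numpy()
    tile_start = ((site_pos - 1) // TILE_SIZE) * TILE_SIZE
    order = rng.permutation(len(genes))
    plan = []
    sign = 1.0
    for gi in order:
        if len(plan) >= cfg.n_eqtm_genes:
            break
        r = genes.iloc[gi]
        sel = site_chrom == r["chrom"]
        if not sel.any():
            continue
        d = np.abs(site_pos[sel] - (r["tss"] + 1))
        j = int(np.argmin(d))
        if d[j] > 100_000:
            continue
        t_start = int(tile_start[sel][j])
        site_idx = np.flatnonzero(sel & (tile_start == t_start))
        hi = set(np.array(samples)[rng.permutation(len(samples))[: len(samples) // 2]])
        plan.append({
            "gene": r["gene"],
            "gene_index": int(gi),
            "tile": f"{r['chrom']}:{t_start}-{t_start + TILE_SIZE}",
            "site_idx": site_idx,
            "hi_samples": hi,
            "shift": 0.22,
            "slope": float(sign * cfg.eqtm_slope),
        })
        sign = -sign
    return plan


def _make_expression(cfg, rng, genes, eqtm_plan, reports, metadata, truth):
    """Expression matrix with methylation-coupled genes and pathway structure."""
    samples = list(reports)
    n_genes = len(genes)
    eqtm_idx = np.array([p["gene_index"] for p in eqtm_plan], dtype=int)
    rest = np.array([i for i in rng.permutation(n_genes) if i not in set(eqtm_idx)])
    third = max(1, len(rest) // 6)
    gene_sets = {
        "KERATINIZATION": sorted(genes["gene"].iloc[rest[:third]]),
        "TCELL": sorted(genes["gene"].iloc[rest[third:2 * third]]),
        "EMT": sorted(genes["gene"].iloc[rest[2 * third:3 * third]]),
    }
    set_effect = {  # expression shifts per group, planted subtype biology
        "KERATINIZATION": {"IMU": -1.0, "KRT": 1.0, "HPVneg": 0.8},
        "TCELL": {"IMU": 1.2, "KRT": -0.5, "HPVneg": -0.5},
        "EMT": {"IMU": 0.8, "KRT": -0.5, "HPVneg": 0.0},
    }
    group_of = metadata["group"].to_dict()

    expr = np.empty((n_genes, len(samples)))
    base_expr = rng.normal(5.0, 1.0, size=n_genes)
    noise = rng.normal(0, 1.0, size=(n_genes, len(samples)))
    for gi in range(n_genes):
        expr[gi] = base_expr[gi] + noise[gi]
    for name, members in gene_sets.items():
        gidx = genes.index[genes["gene"].isin(members)]
        for si, s in enumerate(samples):
            expr[gidx, si] += set_effect[name][group_of[s]]

    # methylation-coupled genes: expression follows the realized fraction of
    # the planted TSS-proximal tile
    for plan in eqtm_plan:
        gi = plan["gene_index"]
        fracs = np.empty(len(samples))
        for si, s in enumerate(samples):
            rep = reports[s]
            mm = rep["count_meth"].to_numpy()[plan["site_idx"]].sum()
            nn = rep["count_total"].to_numpy()[plan["site_idx"]].sum()
            fracs[si] = mm / nn if nn > 0 else 0.5
        expr[gi] = (
            base_expr[gi]
            + plan["slope"] * fracs
            + rng.normal(0, cfg.expr_noise_sd, size=len(samples))
        )
        truth.planted_eqtms.append({
            "tile": plan["tile"], "gene": plan["gene"], "slope": plan["slope"],
        })
    return (
        pd.DataFrame(expr, index=genes["gene"], columns=samples),
        gene_sets,
    )


def _make_cna(cfg, rng, chrom_sizes, samples, group_of, z, truth):
    """Copy-number segment sets with brute-force-known instability."""
    arm_rows = []
    for chrom, size in chrom_sizes.items():
        arm_rows.append((chrom, 0, int(0.45 * size), f"{chrom}p"))
        arm_rows.append((chrom, int(0.55 * size), size, f"{chrom}q"))
    arms = pd.DataFrame(arm_rows, columns=["chrom", "start", "end", "arm"])

    cn_choices = np.array([0, 1, 3, 4])
    cn_weights = np.array([0.15, 0.35, 0.35, 0.15])
    seg_rows = []
    for si, s in enumerate(samples):
        g = group_of[s]
        base_n = cfg.n_cna_segments.get(g, 3)
        n_seg = max(0, int(np.round(base_n - 1.2 * z[si] + rng.normal(0, 0.7))))
        used = {i: [] for i in range(len(arms))}
        score = 0.0
        placed = 0
        attempts = 0
        while placed < n_seg and attempts < n_seg * 12:
            attempts += 1
            ai = int(rng.integers(len(arms)))
            arm = arms.iloc[ai]
            arm_len = arm["end"] - arm["start"]
            kind = rng.random()
            cn = int(rng.choice(cn_choices, p=cn_weights))
            if kind < 0.8 and 0.84 * arm_len <= 10.3e6:
                kind = 0.0  # arm too short for a sub-arm >10 Mb event
            if kind < 0.4:  # arm-level event
                s0, e0 = int(arm["start"]), int(arm["end"])
            elif kind < 0.8:  # large focal, kept clearly sub-arm (<85% of arm)
                ln = int(rng.uniform(10.3e6, 0.84 * arm_len))
                s0 = int(arm["start"] + rng.integers(0, arm_len - ln))
                e0 = s0 + ln
            else:  # small focal, below the 10 Mb threshold
                ln = int(rng.uniform(1e6, min(9e6, max(2e6, 0.5 * arm_len))))
                s0 = int(arm["start"] + rng.integers(0, max(arm_len - ln, 1)))
                e0 = s0 + ln
            if any(s0 < e1 and e0 > s1 for s1, e1 in used[ai]):
                continue
            used[ai].append((s0, e0))
            seg_rows.append((s, arm["chrom"], s0, e0, cn))
            placed += 1
            length = e0 - s0
            if length > 10_000_000 and abs(cn - 2) >= 0.3:
                score += abs(cn - 2) if length >= 0.9 * arm_len else 1.0
        truth.true_instability[s] = float(score)
    segs = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "copy_number"]
    ).sort_values(["sample", "chrom", "start"]).reset_index(drop=True)
    return segs, arms


def _make_deconvolution_panel(cfg, rng, samples, group_of, sample_delta, truth):
    """Reference atlas (normal cell types + tumour row) and mixed methylomes."""
    n_reg = cfg.n_atlas_regions
    cell_types = ["epithelial", "immune", "fibroblast", "endothelial"][: cfg.n_atlas_cell_types]
    n_marker = max(10, n_reg // (len(cell_types) + 2))
    baseline = rng.uniform(0.3, 0.7, size=n_reg)
    atlas = {}
    marker_slices = {}
    offset = 0
    for ct in cell_types + ["tumor"]:
        prof = baseline + rng.normal(0, 0.02, size=n_reg)
        marker_slices[ct] = slice(offset, offset + n_marker)
        offset += n_marker
        atlas[ct] = prof
    for ct in cell_types + ["tumor"]:
        for other in cell_types + ["tumor"]:
            atlas[other][marker_slices[ct]] = 0.85 if other == ct else 0.12
        atlas[ct] = np.clip(atlas[ct] + rng.normal(0, 0.01, size=n_reg), 0.01, 0.99)
    atlas_df = pd.DataFrame(
        atlas, index=[f"R{i+1:04d}" for i in range(n_reg)]
    ).T

    shift = {"IMU": 0.08, "KRT": -0.06, "HPVneg": -0.05}
    mix = {}
    for s in samples:
        g = group_of[s]
        w_t = float(np.clip(rng.normal(cfg.tumor_fraction_mean, 0.1), 0.25, 0.9))
        w_n = rng.dirichlet(np.full(len(cell_types), 2.0)) * (1 - w_t)
        tumor_prof = np.clip(
            atlas_df.loc["tumor"].to_numpy()
            + shift.get(g, 0.0)
            + 0.5 * sample_delta[s]
            + rng.normal(0, 0.03, size=n_reg),
            0.01, 0.99,
        )
        x = tumor_prof * w_t
        for w, ct in zip(w_n, cell_types):
            x = x + w * atlas_df.loc[ct].to_numpy()
        x = np.clip(x + rng.normal(0, 0.01, size=n_reg), 0.0, 1.0)
        mix[s] = x
        fr = {ct: float(w) for ct, w in zip(cell_types, w_n)}
        fr["tumor"] = w_t
        truth.true_cell_fractions[s] = fr
        truth.true_cancer_meth_mean[s] = float(tumor_prof.mean())
    deconv_meth = pd.DataFrame(mix, index=atlas_df.columns)
    return atlas_df, deconv_meth


# ---------------------------------------------------------------------------
# writers (plain-text artifacts)
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir) -> list:
    """Write the bundle as plain-text files; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    rep_dir = outdir / "cpg_reports"
    rep_dir.mkdir(exist_ok=True)
    for s, df in bundle.reports.items():
        p = rep_dir / f"{s}.cytosine_report.txt"
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": "+",
            "count_meth": df["count_meth"].astype(int),
            "count_unmeth": (df["count_total"] - df["count_meth"]).astype(int),
        })
        out.to_csv(p, sep="\t", header=False, index=False)
        paths.append(p)

    bundle.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    bundle.gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t")
    bundle.cna_segments.to_csv(outdir / "cna_segments.seg", sep="\t", index=False)
    bundle.arms.to_csv(outdir / "chrom_arms.bed", sep="\t", header=False, index=False)
    bundle.atlas.to_csv(outdir / "atlas.tsv", sep="\t")
    bundle.deconv_meth.to_csv(outdir / "deconvolution_panel.tsv", sep="\t")
    with open(outdir / "chrom.sizes", "w") as fh:
        for c, sz in bundle.chrom_sizes.items():
            fh.write(f"{c}\t{sz}\n")
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    for name, bed in bundle.annotations.items():
        bed.to_csv(ann_dir / f"{name}.bed", sep="\t", header=False, index=False)
    rs_dir = outdir / "region_sets"
    rs_dir.mkdir(exist_ok=True)
    for name, bed in bundle.region_sets.items():
        bed.to_csv(rs_dir / f"{name}.bed", sep="\t", header=False, index=False)
    with open(outdir / "gene_sets.json", "w") as fh:
        json.dump(bundle.gene_sets, fh, indent=1, sort_keys=True)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(asdict(bundle.truth), fh, indent=1, sort_keys=True)
    paths += sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.seg"))
    return paths
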