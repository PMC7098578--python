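"""Synthetic genotype panels, augmented field trials and individual
grain-size populations.

The generator produces the statistical structure the downstream analysis
assumes, with a truth record for parameter-recovery tests:

* genotypes: a founder-mosaic haplotype model.  Each individual carries two
  haplotypes, each a mosaic of founder haplotypes with per-bp recombination,
  so linkage disequilibrium decays with physical distance at a tunable rate
  while staying seed-stable;
* field layout: an augmented design (4 blocks of 2 sub-blocks each) in which
  replicated check genotypes carry the spatial information and most entries
  appear once;
* plot traits: spikes per m^2 (SPM2) and grains per spike (GPS) with
  additive QTL, environment shifts, sub-block effects and a tillering
  compensation (GPS falls as SPM2 rises); grains per m^2 GPM2 = SPM2 * GPS;
  mean grain area responds negatively to GPM2 (source limitation), giving an
  emergent GPM2-TKW trade-off;
* individual grains: a two-level mixture (main vs secondary-tiller spikes,
  then proximal vs distal grain positions), with a per-plot dispersion
  multiplied by exp(dispersion-QTL value) and an upper-tail cap that
  tightens as SPM2 grows.  The cap is a soft truncation (draws above it are
  resampled), which is what makes the within-plot variance GSV fall with
  spike density -- the emergent negative SPM2-GSV correlation;
* grain mass: a linear area -> mass link with noise (per-grain R^2 ~ 0.8);
  thousand-kernel weight is back-computed from the sampled grains and
  expressed at 15% humidity; yield GY = GPM2 * TKW / 1e5 t/ha.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grainmetrics import to_15pc_humidity
from .panel import GenotypePanel, write_tsv, write_vcf

__all__ = [
    "EnvironmentSpec",
    "TillerParams",
    "SimConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_trial",
    "write_outputs",
    "InvalidConfigError",
]

TRAITS = ("SPM2", "GPS", "TKW", "GSV")  # genetic-effect channels


class InvalidConfigError(ValueError):
    pass


@dataclass
class EnvironmentSpec:
    label: str
    spm2_shift: float = 0.0
    gps_shift: float = 0.0
    area_shift: float = 0.0


@dataclass
class TillerParams:
    """Canopy-structure parameters of the grain mixture.

    The within-spike size hierarchy has no canonical quantitative values;
    these defaults are free parameters of the generator, chosen to give a
    realistic small-grain fraction and the emergent canopy-variance
    coupling, and are documented rather than fitted.
    """

    sec_prop_base: float = 0.15     # secondary-tiller spike proportion at reference SPM2
    sec_prop_slope: float = 0.0008  # d(proportion)/d(SPM2), per spike
    sec_size_ratio: float = 0.90    # secondary-spike grain mean / main-spike mean
    distal_prop: float = 0.30       # distal grain-position proportion
    distal_shrink: float = 0.85     # distal grain mean / proximal mean
    cap_base: float = 2.6           # upper-tail cap, in grain SD units above the mean
    cap_slope: float = 0.004        # cap tightening per extra spike per m^2


def _default_envs() -> list[EnvironmentSpec]:
    # one well-watered and one water-deficit environment
    return [
        EnvironmentSpec("E1"),
        EnvironmentSpec("E2", spm2_shift=-80.0, gps_shift=-2.0, area_shift=-1.0),
    ]


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel (two-environment trial)."""

    n_genotypes: int = 300
    n_checks: int = 4
    n_chromosomes: int = 3
    snps_per_chromosome: int = 1000
    chromosome_length_bp: int = 600_000_000
    n_founder_haplotypes: int = 30
    recomb_rate: float = 2e-7          # per bp, per meiosis-equivalent mosaic
    founder_ld_rate: float = 1e-7      # per-bp decay of founder-haplotype correlation
    missing_rate: float = 0.01
    environments: list = field(default_factory=_default_envs)
    n_qtl_per_trait: dict = field(
        default_factory=lambda: {"SPM2": 4, "GPS": 4, "TKW": 4, "GSV": 4}
    )
    pleiotropy_spec: dict = field(default_factory=dict)  # {(traits...): n shared loci}
    effect_sd: dict = field(
        default_factory=lambda: {"SPM2": 35.0, "GPS": 1.8, "TKW": 0.55, "GSV": 0.10}
    )
    sigma_subblock: dict = field(
        default_factory=lambda: {"SPM2": 15.0, "GPS": 1.0, "area": 0.30}
    )
    sigma_plot: dict = field(
        default_factory=lambda: {"SPM2": 25.0, "GPS": 1.5, "area": 0.35}
    )
    tradeoff_gamma: float = 3e-4       # mm^2 per (grain m^-2)
    tiller_params: TillerParams = field(default_factory=TillerParams)
    grains_min: int = 300
    grains_max: int = 500
    seed: int = 0

    # trial geometry and trait baselines
    n_blocks: int = 4
    subblocks_per_block: int = 2
    check_reps_per_subblock: int = 1
    spm2_base: float = 520.0
    gps_base: float = 34.0
    gps_coupling: float = 0.5          # tillering compensation strength
    area_base: float = 17.0            # mm^2 at reference canopy
    grain_sd_base: float = 2.0         # mm^2 within-plot grain SD at reference
    mass_slope_mg: float = 2.25        # dry mg per mm^2 (area -> mass link)
    mass_intercept_mg: float = 0.0
    mass_noise_mg: float = 1.15        # per-grain mass noise (R^2 ~ 0.8)
    qtl_min_maf: float = 0.15
    qtl_min_sep_bp: int = 30_000_000  # min distance between planted loci
    spm2_floor: float = 50.0
    gps_floor: float = 5.0
    moisture: float = 0.15

    def validate(self) -> None:
        counts = (
            self.n_genotypes, self.n_checks, self.n_chromosomes,
            self.snps_per_chromosome, self.chromosome_length_bp,
            self.n_blocks, self.subblocks_per_block,
        )
        if any(c <= 0 for c in counts):
            raise InvalidConfigError("all counts must be positive")
        if self.n_founder_haplotypes < 2:
            raise InvalidConfigError("need at least 2 founder haplotypes")
        if self.grains_min > self.grains_max:
            raise InvalidConfigError("grains_min must be <= grains_max")
        for p in (self.recomb_rate, self.missing_rate, self.moisture):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError("probabilities must lie in [0, 1]")
        if self.n_checks >= self.n_genotypes:
            raise InvalidConfigError("n_checks must be < n_genotypes")


@dataclass
class TruthRecord:
    """Ground truth of one simulated trial, for recovery tests."""

    qtl_loci: list          # dicts: trait, chrom, bp, marker_index, marker_id, effect
    genotype_values: dict   # trait -> list aligned with genotype ids
    genotype_ids: list
    spatial_effects: dict   # env -> channel -> subblock -> value
    variance_components: dict  # trait -> {"sigma2_G": ..., "sigma2_eps": ...}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _unique_positions(rng, length: int, m: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length, size=2 * m))
    while pos.size < m:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length, size=m)]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def _founder_haplotypes(rng, f: int, pos: np.ndarray, freq: np.ndarray,
                        ld_rate: float) -> np.ndarray:
    """Founder haplotypes with along-chromosome allele correlation.

    A latent AR(1) Gaussian field per founder (correlation exp(-d * ld_rate)
    between markers d bp apart) is thresholded at each marker's allele
    frequency, so founders themselves carry decaying LD; the individual
    mosaics then erode it further at the recombination scale.
    """
    from scipy.stats import norm

    m = len(pos)
    z = np.empty((f, m))
    z[:, 0] = rng.standard_normal(f)
    gaps = np.diff(pos).astype(float)
    phi = np.exp(-ld_rate * gaps)
    innov = rng.standard_normal((f, m - 1)) if m > 1 else None
    for j in range(1, m):
        p = phi[j - 1]
        z[:, j] = p * z[:, j - 1] + np.sqrt(max(1.0 - p * p, 0.0)) * innov[:, j - 1]
    thresh = norm.ppf(freq)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Founder-mosaic dosage matrix with LD decaying over physical distance."""
    cfg.validate()
    rng = _rng_for(cfg, 1)
    n, f = cfg.n_genotypes, cfg.n_founder_haplotypes
    all_dos, maps = [], []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1:02d}"
        m = cfg.snps_per_chromosome
        length = cfg.chromosome_length_bp
        pos = _unique_positions(rng, length, m)
        freq = rng.uniform(0.05, 0.95, size=m)
        founders = _founder_haplotypes(rng, f, pos, freq, cfg.founder_ld_rate)
        haplos = np.empty((2 * n, m), dtype=np.int8)
        lam = cfg.recomb_rate * length
        for h in range(2 * n):
            n_break = rng.poisson(lam)
            breaks = np.sort(rng.integers(1, length, size=n_break))
            founder_ids = rng.integers(0, f, size=n_break + 1)
            seg = np.searchsorted(breaks, pos, side="right")
            haplos[h] = founders[founder_ids[seg], np.arange(m)]
        dos = (haplos[0::2] + haplos[1::2]).astype(float)
        if cfg.missing_rate > 0:
            dos[rng.random(dos.shape) < cfg.missing_rate] = np.nan
        all_dos.append(dos)
        maps.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom}_s{j:05d}" for j in range(m)],
                    "chrom": chrom,
                    "bp": pos.astype(int),
                }
            )
        )
    panel = GenotypePanel(
        dosages=np.concatenate(all_dos, axis=1),
        markers=pd.concat(maps, ignore_index=True),
        genotype_ids=[f"g{i:04d}" for i in range(n)],
    )
    return panel.with_stats()


# ---------------------------------------------------------------- trial ----


def _draw_qtl(cfg: SimConfig, panel: GenotypePanel, rng) -> list[dict]:
    """Assign QTL marker indices and per-trait allele effects.

    Pleiotropy groups (tuples of traits) share a locus and a common
    standardised effect sign/magnitude, scaled by each trait's effect SD.
    """
    maf = panel.maf()
    eligible = list(np.nonzero(maf >= cfg.qtl_min_maf)[0])
    rng.shuffle(eligible)
    taken = 0
    loci = []
    counts = {t: 0 for t in TRAITS}
    placed: list[tuple[str, int]] = []  # (chrom, bp) of chosen loci

    def next_idx():
        nonlocal taken
        while taken < len(eligible):
            idx = int(eligible[taken])
            taken += 1
            row = panel.markers.iloc[idx]
            ok = all(
                row["chrom"] != c or abs(int(row["bp"]) - b) >= cfg.qtl_min_sep_bp
                for c, b in placed
            )
            if ok:
                placed.append((str(row["chrom"]), int(row["bp"])))
                return idx
        raise InvalidConfigError(
            "not enough well-separated polymorphic markers for QTL"
        )

    for group, n_shared in cfg.pleiotropy_spec.items():
        group = tuple(group)
        for _ in range(n_shared):
            idx = next_idx()
            z = rng.standard_normal()
            for t in group:
                loci.append({"trait": t, "marker_index": idx,
                             "effect": float(z * cfg.effect_sd[t])})
                counts[t] += 1
    for t in TRAITS:
        for _ in range(max(cfg.n_qtl_per_trait.get(t, 0) - counts[t], 0)):
            idx = next_idx()
            loci.append({"trait": t, "marker_index": idx,
                         "effect": float(rng.standard_normal() * cfg.effect_sd[t])})
    for rec in loci:
        row = panel.markers.iloc[rec["marker_index"]]
        rec["chrom"] = str(row["chrom"])
        rec["bp"] = int(row["bp"])
        rec["marker_id"] = str(row["marker_id"])
    return loci


def _genetic_values(panel: GenotypePanel, loci: list[dict]) -> dict:
    dos = panel.dosages.copy()
    col_mean = np.nanmean(dos, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    dos[nan_r, nan_c] = col_mean[nan_c]
    centered = dos - col_mean
    g = {t: np.zeros(panel.n_genotypes) for t in TRAITS}
    for rec in loci:
        g[rec["trait"]] += rec["effect"] * centered[:, rec["marker_index"]]
    return g


def _layout(cfg: SimConfig, rng) -> pd.DataFrame:
    """One environment's augmented layout (genotype, block, subblock, rep)."""
    checks = [f"g{i:04d}" for i in range(cfg.n_checks)]
    others = [f"g{i:04d}" for i in range(cfg.n_checks, cfg.n_genotypes)]
    rng.shuffle(others)
    sb_labels = [
        (f"b{b + 1}", f"sb{b * cfg.subblocks_per_block + s + 1}")
        for b in range(cfg.n_blocks)
        for s in range(cfg.subblocks_per_block)
    ]
    rows = []
    for block, sb in sb_labels:
        for chk in checks:
            for r in range(cfg.check_reps_per_subblock):
                rows.append({"genotype": chk, "block": block, "subblock": sb,
                             "rep": r + 1, "is_check": True})
    for i, g in enumerate(others):
        block, sb = sb_labels[i % len(sb_labels)]
        rows.append({"genotype": g, "block": block, "subblock": sb,
                     "rep": 1, "is_check": False})
    return pd.DataFrame(rows)


def _draw_grains(cfg: SimConfig, rng, mu_area, sigma, spm2, n_grains) -> np.ndarray:
    """Two-level mixture with soft upper truncation; all areas > 0."""
    tp = cfg.tiller_params
    p_sec = float(np.clip(
        tp.sec_prop_base + tp.sec_prop_slope * (spm2 - cfg.spm2_base), 0.0, 0.6
    ))
    spike = np.where(rng.random(n_grains) < p_sec, tp.sec_size_ratio, 1.0)
    posn = np.where(rng.random(n_grains) < tp.distal_prop, tp.distal_shrink, 1.0)
    factor = spike * posn
    mean_factor = ((1 - p_sec) + p_sec * tp.sec_size_ratio) * (
        (1 - tp.distal_prop) + tp.distal_prop * tp.distal_shrink
    )
    mu0 = mu_area / mean_factor
    means = mu0 * factor
    cap_z = max(tp.cap_base - tp.cap_slope * (spm2 - cfg.spm2_base), 0.8)
    cap = mu_area + cap_z * sigma
    areas = rng.normal(means, sigma)
    lo = 0.5  # hard physical floor, mm^2
    for _ in range(50):
        bad = (areas > cap) | (areas < lo)
        if not bad.any():
            break
        areas[bad] = rng.normal(means[bad], sigma)
    np.clip(areas, lo, cap, out=areas)
    return areas


def simulate_trial(
    cfg: SimConfig, panel: GenotypePanel
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate the plot table, the long grain table and the truth record."""
    cfg.validate()
    if panel.n_genotypes != cfg.n_genotypes:
        raise ValueError("panel size does not match cfg.n_genotypes")
    rng = _rng_for(cfg, 2)
    loci = _draw_qtl(cfg, panel, rng)
    g = _genetic_values(panel, loci)
    gid_pos = {gid: i for i, gid in enumerate(panel.genotype_ids)}

    plot_rows, grain_frames = [], []
    spatial: dict = {}
    gpm2_ref = cfg.spm2_base * cfg.gps_base
    n_clipped = 0
    for env in cfg.environments:
        lay = _layout(cfg, rng)
        sbs = sorted(lay["subblock"].unique())
        b_eff = {
            ch: dict(zip(sbs, rng.normal(0.0, cfg.sigma_subblock[ch], len(sbs))))
            for ch in ("SPM2", "GPS", "area")
        }
        spatial[env.label] = {ch: dict(b_eff[ch]) for ch in b_eff}
        for k, row in enumerate(lay.itertuples(index=False)):
            i = gid_pos[row.genotype]
            sb = row.subblock
            spm2 = (
                cfg.spm2_base + env.spm2_shift + g["SPM2"][i]
                + b_eff["SPM2"][sb] + rng.normal(0.0, cfg.sigma_plot["SPM2"])
            )
            if spm2 < cfg.spm2_floor:
                spm2, n_clipped = cfg.spm2_floor, n_clipped + 1
            gps = (
                cfg.gps_base + env.gps_shift + g["GPS"][i]
                - cfg.gps_coupling * (spm2 - cfg.spm2_base - env.spm2_shift)
                * cfg.gps_base / cfg.spm2_base
                + b_eff["GPS"][sb] + rng.normal(0.0, cfg.sigma_plot["GPS"])
            )
            if gps < cfg.gps_floor:
                gps, n_clipped = cfg.gps_floor, n_clipped + 1
            gpm2 = spm2 * gps
            mu_area = (
                cfg.area_base + env.area_shift
                - cfg.tradeoff_gamma * (gpm2 - gpm2_ref)
                + g["TKW"][i]
                + b_eff["area"][sb] + rng.normal(0.0, cfg.sigma_plot["area"])
            )
            mu_area = max(mu_area, 5.0)
            sigma = (
                cfg.grain_sd_base * (mu_area / cfg.area_base) * np.exp(g["GSV"][i])
            )
            n_grains = int(rng.integers(cfg.grains_min, cfg.grains_max + 1))
            areas = _draw_grains(cfg, rng, mu_area, sigma, spm2, n_grains)
            mass_mg = (
                cfg.mass_slope_mg * areas + cfg.mass_intercept_mg
                + rng.normal(0.0, cfg.mass_noise_mg, n_grains)
            )
            tkw = to_15pc_humidity(float(mass_mg.mean()), cfg.moisture)
            gy = gpm2 * tkw / 1e5  # t/ha
            plot_id = f"{env.label}_p{k:04d}"
            plot_rows.append(
                {
                    "plot_id": plot_id,
                    "genotype": row.genotype,
                    "env": env.label,
                    "block": row.block,
                    "subblock": sb,
                    "rep": row.rep,
                    "is_check": row.is_check,
                    "SPM2": spm2,
                    "TKW_g": tkw,
                    "GY_t_ha": gy,
                }
            )
            grain_frames.append(
                pd.DataFrame({"plot_id": plot_id, "area_mm2": areas})
            )
    plots = pd.DataFrame(plot_rows)
    grains = pd.concat(grain_frames, ignore_index=True)
    truth = TruthRecord(
        qtl_loci=loci,
        genotype_values={t: [float(v) for v in g[t]] for t in TRAITS},
        genotype_ids=list(panel.genotype_ids),
        spatial_effects=spatial,
        variance_components={
            "SPM2": {"sigma2_G": float(np.var(g["SPM2"])),
                     "sigma2_eps": float(cfg.sigma_plot["SPM2"] ** 2)},
            "GPS": {"sigma2_G": float(np.var(g["GPS"])),
                    "sigma2_eps": float(cfg.sigma_plot["GPS"] ** 2)},
            "TKW": {"sigma2_G": float(np.var(g["TKW"])),
                    "sigma2_eps": float(cfg.sigma_plot["area"] ** 2)},
            "GSV": {"sigma2_G": float(np.var(g["GSV"])), "sigma2_eps": 0.0},
        },
    )
    return plots, grains, truth


def write_outputs(outdir, panel: GenotypePanel, plots, grains, truth) -> dict:
    """Write all simulator products as plain text; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "matrix": outdir / "genotypes.tsv",
        "map": outdir / "map.tsv",
        "plots": outdir / "plots.csv",
        "grains": outdir / "grains.csv",
        "truth": outdir / "truth.json",
    }
    write_vcf(panel, paths["vcf"])
    write_tsv(panel, paths["matrix"], paths["map"])
    plots.to_csv(paths["plots"], index=False)
    grains.to_csv(paths["grains"], index=False, float_format="%.4f")
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
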