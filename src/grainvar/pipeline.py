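"""End-to-end orchestration: simulate -> grain metrics -> spatial adjustment
-> descriptive statistics -> LOCO mixed-model scan -> QTL intervals ->
driven/specific classification -> machine-readable report.

Every stage reads its inputs from, and writes plain-text products to, the
run directory, so any stage can be re-run in isolation and reproduces the
full-run output bit for bit.  All randomness flows from the single run seed
through named per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import impute_missing, kinship_loco, mlm_scan, qc_filter
from .classify import (
    classify_qtl,
    cross_environment,
    peak_selection,
    stepwise_opt,
    tally_percentages,
    variance_partition,
)
from .fieldadjust import adjusted_means, heritability_panel2016, heritability_panel2017
from .grainmetrics import derive_components, metrics_table, read_grain_csv
from .panel import read_tsv, write_tsv
from .qtlmap import build_qtl, critical_ld, fit_ld_decay, ld_blocks, prune_redundant, qtl_to_bed
from .simdata import SimConfig, simulate_genotypes, simulate_trial, write_outputs
from .traitstats import compare_correlations, correlation_panel, cv_from_summary

__all__ = ["RunConfig", "run_all", "STAGES"]

log = logging.getLogger(__name__)

ADJUST_TRAITS = ("GSV", "GSM", "P5", "P95", "SPM2", "GPS", "GPM2", "TKW", "GY")
SCAN_TRAITS = ("GSV", "SPM2", "GPS", "GPM2", "TKW")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "runs/default"
    seed: int = 0
    lod_threshold: float = 3.0
    prune_r2: float = 0.9
    maf_min: float = 0.05
    miss_max: float = 0.10
    critical_ld_method: str = "empirical-95th"
    n_ld_pairs: int = 10_000
    peak_rule: str = "effect"
    coloc_rule: str = "interval"
    heritability_model: str = "twostep"  # "twostep" | "checks"
    scan_traits: tuple = SCAN_TRAITS

    def __post_init__(self):
        if not 0 < self.prune_r2 <= 1 or not 0 <= self.maf_min < 0.5:
            raise ValueError("thresholds out of range")
        self.sim.seed = self.seed

    def validate(self) -> None:
        self.sim.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            from .simdata import EnvironmentSpec, TillerParams

            if "environments" in sim:
                sim["environments"] = [
                    EnvironmentSpec(**e) if isinstance(e, dict) else e
                    for e in sim["environments"]
                ]
            if isinstance(sim.get("tiller_params"), dict):
                sim["tiller_params"] = TillerParams(**sim["tiller_params"])
            if "pleiotropy_spec" in sim and isinstance(sim["pleiotropy_spec"], dict):
                sim["pleiotropy_spec"] = {
                    tuple(k.split("+")) if isinstance(k, str) else tuple(k): v
                    for k, v in sim["pleiotropy_spec"].items()
                }
            sim = SimConfig(**sim)
        if "scan_traits" in d:
            d["scan_traits"] = tuple(d["scan_traits"])
        return cls(sim=sim, **d)


def _sub_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ------------------------------------------------------------- stages ----


def stage_simulate(cfg: RunConfig) -> dict:
    panel = simulate_genotypes(cfg.sim)
    plots, grains, truth = simulate_trial(cfg.sim, panel)
    paths = write_outputs(_out(cfg), panel, plots, grains, truth)
    return {"n_genotypes": panel.n_genotypes, "n_markers": panel.n_markers,
            "n_plots": len(plots), "n_grain_rows": len(grains)}


def stage_metrics(cfg: RunConfig) -> dict:
    out = _out(cfg)
    plots = pd.read_csv(out / "plots.csv")
    grains = read_grain_csv(out / "grains.csv")
    gm = metrics_table(grains)
    df = plots.merge(gm, on="plot_id", how="left")
    comp = [derive_components(r.GY_t_ha, r.SPM2, r.TKW_g) for r in df.itertuples()]
    df["GPM2"] = [c.gpm2 for c in comp]
    df["GPS"] = [c.gps for c in comp]
    df = df.rename(columns={"TKW_g": "TKW", "GY_t_ha": "GY"})
    df.to_csv(out / "plot_metrics.csv", index=False)
    return {"n_plots": len(df)}


def stage_adjust(cfg: RunConfig) -> dict:
    out = _out(cfg)
    plots = pd.read_csv(out / "plot_metrics.csv")
    adj = pd.concat(
        [adjusted_means(plots, t) for t in ADJUST_TRAITS], ignore_index=True
    )
    adj.to_csv(out / "adjusted_means.csv", index=False)
    herit_fn = (
        heritability_panel2016 if cfg.heritability_model == "checks"
        else heritability_panel2017
    )
    her = pd.concat([herit_fn(plots, t) for t in ADJUST_TRAITS], ignore_index=True)
    her.to_csv(out / "heritability.csv", index=False)
    return {"n_adjusted": len(adj), "n_heritabilities": len(her)}


def stage_stats(cfg: RunConfig) -> dict:
    out = _out(cfg)
    adj = pd.read_csv(out / "adjusted_means.csv")
    envs = sorted(adj["env"].unique())
    letters: dict = {}
    if len(envs) >= 2:
        from .traitstats import environment_anova

        for metric in ("GSM", "GSV", "P95", "P5"):
            la = environment_anova(adj, metric)
            letters[metric] = dict(zip(la["env"], la["letter"]))
    cv_rows = []
    for env in envs:
        for metric in ("GSM", "GSV", "P95", "P5"):
            vals = adj.loc[
                (adj["env"] == env) & (adj["trait"] == metric), "value"
            ].to_numpy()
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            cv_rows.append(
                {"metric": metric, "env": env, "mean": mean, "sd": sd,
                 "cv_pct": cv_from_summary(mean, sd) if mean > 0 else np.nan,
                 "letter": letters.get(metric, {}).get(env, "")}
            )
        # SD-scale CV (sqrt of GSV) for the variance-vs-mean comparison
        gsv = adj.loc[(adj["env"] == env) & (adj["trait"] == "GSV"), "value"]
        gsd = np.sqrt(np.clip(gsv.to_numpy(), 0, None))
        cv_rows.append(
            {"metric": "sqrt_GSV", "env": env, "mean": float(gsd.mean()),
             "sd": float(gsd.std(ddof=1)),
             "cv_pct": cv_from_summary(float(gsd.mean()), float(gsd.std(ddof=1))),
             "letter": ""}
        )
    pd.DataFrame(cv_rows).to_csv(out / "cv_table.csv", index=False)
    traits = ["GSV", "SPM2", "GPS", "GPM2", "TKW", "GY"]
    panels = pd.concat(
        [correlation_panel(adj, traits, env) for env in envs], ignore_index=True
    )
    panels.to_csv(out / "correlations.csv", index=False)
    comp_rows = []
    if len(envs) >= 2:
        for pair in (("SPM2", "GSV"), ("TKW", "GSV")):
            sel = panels[(panels["trait1"].isin(pair)) & (panels["trait2"].isin(pair))]
            for a in range(len(envs)):
                for b in range(a + 1, len(envs)):
                    r1 = sel[sel["env"] == envs[a]].iloc[0]
                    r2 = sel[sel["env"] == envs[b]].iloc[0]
                    comp_rows.append(
                        {
                            "pair": "-".join(pair),
                            "env1": envs[a],
                            "env2": envs[b],
                            "r1": r1["r"],
                            "r2": r2["r"],
                            "p_equal": compare_correlations(
                                r1["r"], int(r1["n"]), r2["r"], int(r2["n"])
                            ),
                        }
                    )
    pd.DataFrame(comp_rows).to_csv(out / "correlation_comparisons.csv", index=False)
    return {"n_cv_rows": len(cv_rows), "n_correlations": len(panels)}


def stage_gwas(cfg: RunConfig) -> dict:
    out = _out(cfg)
    panel = read_tsv(out / "genotypes.tsv", out / "map.tsv")
    panel = qc_filter(panel, max_missing=cfg.miss_max, min_maf=cfg.maf_min)
    panel = impute_missing(panel)
    panel = prune_redundant(panel, threshold=cfg.prune_r2)
    write_tsv(panel, out / "genotypes_pruned.tsv", out / "map_pruned.tsv")
    crit = critical_ld(
        panel, n_pairs=cfg.n_ld_pairs, seed=_sub_seed(cfg.seed, 11),
        method=cfg.critical_ld_method,
    )
    decay = fit_ld_decay(panel, crit, seed=_sub_seed(cfg.seed, 12))
    with open(out / "ld.json", "w") as fh:
        json.dump(
            {
                "critical_ld": crit.value,
                "critical_method": crit.method,
                "n_pairs": crit.n_pairs,
                "rho": decay.rho,
                "extension_bp": decay.extension_bp,
            },
            fh, indent=1, sort_keys=True,
        )
    adj = pd.read_csv(out / "adjusted_means.csv")
    adj["genotype"] = adj["genotype"].astype(str)
    k_set = kinship_loco(panel)
    cache: dict = {}
    frames = []
    for env in sorted(adj["env"].unique()):
        for trait in cfg.scan_traits:
            frames.append(
                mlm_scan(adj, panel, k_set, trait, env,
                         lod_threshold=cfg.lod_threshold, eigen_cache=cache)
            )
    res = pd.concat(frames, ignore_index=True)
    res.to_csv(out / "assoc.tsv", sep="\t", index=False)
    return {
        "n_markers_postqc": panel.n_markers,
        "n_tests": len(res),
        "n_significant": int(res["significant"].sum()),
        "critical_ld": crit.value,
        "extension_mb": decay.extension_bp / 1e6,
    }


def _members_from_str(s):
    return tuple(s.split(";")) if isinstance(s, str) and s else tuple()


def stage_qtl(cfg: RunConfig) -> dict:
    out = _out(cfg)
    panel = read_tsv(out / "genotypes_pruned.tsv", out / "map_pruned.tsv")
    with open(out / "ld.json") as fh:
        ld = json.load(fh)
    res = pd.read_csv(out / "assoc.tsv", sep="\t")
    qtl_frames = []
    for env in sorted(res["env"].unique()):
        sig = res[(res["env"] == env) & (res["trait"] == "GSV") & res["significant"]]
        if sig.empty:
            continue
        blocks = ld_blocks(sig, panel, ld["critical_ld"])
        qtl = build_qtl(
            blocks, ld["extension_bp"], sig_snps=sig,
            chrom_length=cfg.sim.chromosome_length_bp,
        )
        qtl["env"] = env
        qtl["trait"] = "GSV"
        qtl["qtl_id"] = env + "_" + qtl["qtl_id"]
        qtl_frames.append(qtl)
    if qtl_frames:
        qtl_all = pd.concat(qtl_frames, ignore_index=True)
    else:
        qtl_all = pd.DataFrame(
            columns=["qtl_id", "chrom", "core_start_bp", "core_end_bp", "start_bp",
                     "end_bp", "size_mb", "n_snps", "members", "peak_snp",
                     "peak_lod", "peak_maf", "env", "trait"]
        )
    to_write = qtl_all.copy()
    to_write["members"] = [";".join(m) for m in to_write["members"]]
    to_write.to_csv(out / "qtl.tsv", sep="\t", index=False)
    if len(qtl_all):
        qtl_to_bed(qtl_all, out / "qtl.bed")
    else:
        (out / "qtl.bed").write_text("")
    return {"n_qtl": len(qtl_all),
            "mean_size_mb": float(qtl_all["size_mb"].mean()) if len(qtl_all) else 0.0}


def stage_classify(cfg: RunConfig) -> dict:
    out = _out(cfg)
    panel = read_tsv(out / "genotypes_pruned.tsv", out / "map_pruned.tsv")
    res = pd.read_csv(out / "assoc.tsv", sep="\t")
    adj = pd.read_csv(out / "adjusted_means.csv")
    adj["genotype"] = adj["genotype"].astype(str)
    qtl_all = pd.read_csv(out / "qtl.tsv", sep="\t")
    qtl_all["members"] = qtl_all["members"].map(_members_from_str)
    envs = sorted(qtl_all["env"].unique()) if len(qtl_all) else []
    class_frames, part_rows, opt_rows = [], [], []
    qtl_by_env = {}
    for env in envs:
        qtl_env = qtl_all[qtl_all["env"] == env].reset_index(drop=True)
        qtl_by_env[env] = qtl_env
        hits = {
            t: res[(res["env"] == env) & (res["trait"] == t) & res["significant"]]
            for t in cfg.scan_traits if t != "GSV"
        }
        cls = classify_qtl(qtl_env, hits, env, rule=cfg.coloc_rule)
        class_frames.append(cls)
        scan_env = res[(res["env"] == env) & (res["trait"] == "GSV")]
        peaks = peak_selection(qtl_env, scan_env, rule=cfg.peak_rule)
        part_rows.append(variance_partition(adj, peaks, cls, panel, env))
        opt_rows.append(stepwise_opt(adj, peaks, panel, env, classes=cls))
    classes = (
        pd.concat(class_frames, ignore_index=True)
        if class_frames
        else pd.DataFrame(columns=["qtl_id", "env", "chrom", "qtl_class",
                                   "colocalised_traits"])
    )
    common = (
        cross_environment(qtl_by_env) if len(envs) >= 2
        else pd.DataFrame(columns=["env", "qtl_id", "common_envs",
                                   "common_to_environments", "common_to_panels"])
    )
    merged = classes.merge(common, on=["qtl_id", "env"], how="left")
    merged["common_to_environments"] = merged.get(
        "common_to_environments", pd.Series(dtype=bool)
    ).fillna(False)
    merged.to_csv(out / "classification.tsv", sep="\t", index=False)

    total = len(merged)
    tally_rows = []
    for klass in ("specific", "driven"):
        sub = merged[merged["qtl_class"] == klass]
        n = len(sub)
        n_common = int(sub["common_to_environments"].sum())
        tally_rows.append(
            {
                "qtl_class": klass,
                "n_total": n,
                "pct_total": tally_percentages({"x": n}, total)["x"] if total else 0.0,
                "n_single_env": n - n_common,
                "n_common_two_envs": n_common,
            }
        )
    t4 = pd.DataFrame(tally_rows)
    t4.to_csv(out / "table4_tally.csv", index=False)
    if part_rows:
        t5 = pd.DataFrame(part_rows).merge(
            pd.DataFrame(opt_rows).drop(columns=["selected_qtl", "aic"]),
            on="env", how="outer",
        )
    else:
        t5 = pd.DataFrame(
            columns=["env", "r2_all", "n_all", "r2_specific", "n_specific",
                     "r2_driven", "n_driven", "n_selected",
                     "n_selected_driven", "r2_opt"]
        )
    t5.to_csv(out / "table5_partition.csv", index=False)
    return {
        "n_classified": total,
        "n_specific": int((merged["qtl_class"] == "specific").sum()) if total else 0,
        "n_driven": int((merged["qtl_class"] == "driven").sum()) if total else 0,
        "n_common_two_envs": int(merged["common_to_environments"].sum()) if total else 0,
    }


def stage_report(cfg: RunConfig, stage_stats_in: dict | None = None) -> dict:
    out = _out(cfg)
    report: dict = {
        "software": {"name": "grainvar", "version": __version__},
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "stages": stage_stats_in or {},
        "tables": {},
    }
    for name, fname in (
        ("cv", "cv_table.csv"),
        ("correlations", "correlations.csv"),
        ("heritability", "heritability.csv"),
        ("qtl", "qtl.tsv"),
        ("classification", "classification.tsv"),
        ("tally", "table4_tally.csv"),
        ("partition", "table5_partition.csv"),
    ):
        path = out / fname
        if path.exists():
            sep = "\t" if fname.endswith(".tsv") else ","
            try:
                df = pd.read_csv(path, sep=sep)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame()
            report["tables"][name] = json.loads(df.to_json(orient="records"))
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return {"files": sorted(p.name for p in out.iterdir())}


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("outdir", None)  # reports must not depend on where the run lives
    d["sim"]["pleiotropy_spec"] = {
        "+".join(k): v for k, v in cfg.sim.pleiotropy_spec.items()
    }
    return json.loads(json.dumps(d, default=str))


STAGES = (
    ("simulate", stage_simulate),
    ("metrics", stage_metrics),
    ("adjust", stage_adjust),
    ("stats", stage_stats),
    ("gwas", stage_gwas),
    ("qtl", stage_qtl),
    ("classify", stage_classify),
)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the report dict.

    Any stage failure aborts with the stage name and cause; products of the
    completed stages stay on disk next to a FAILED marker.
    """
    cfg.validate()
    stats: dict = {}
    for name, fn in STAGES:
        log.info("stage %s ...", name)
        try:
            stats[name] = fn(cfg)
        except Exception as exc:
            (_out(cfg) / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    stage_report(cfg, stats)
    with open(_out(cfg) / "report.json") as fh:
        return json.load(fh)
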