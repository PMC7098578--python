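"""From significant SNPs to QTL intervals.

Background ("critical") LD is the 95th percentile of r^2 over unlinked
marker pairs; significant SNPs are clustered by average linkage at distance
1 - r^2 (cut at 1 - critical LD); blocks are widened by the distance at
which a fitted Hill-Weir r^2 decay curve crosses the critical LD, and
overlapping intervals merge into QTL.
"""

from grainvar import (
    SimConfig,
    adjusted_means,
    build_qtl,
    critical_ld,
    fit_ld_decay,
    impute_missing,
    kinship_loco,
    ld_blocks,
    mlm_scan,
    qc_filter,
    simulate_genotypes,
    simulate_trial,
)
from grainvar.grainmetrics import metrics_table

cfg = SimConfig(seed=31, n_genotypes=200, snps_per_chromosome=300)
panel = simulate_genotypes(cfg)
plots, grains, _ = simulate_trial(cfg, panel)
df = plots.merge(metrics_table(grains), on="plot_id")

qpanel = impute_missing(qc_filter(panel))
adj = adjusted_means(df, "GSV")
res = mlm_scan(adj, qpanel, kinship_loco(qpanel), "GSV", "E1")
sig = res[res["significant"]]

crit = critical_ld(qpanel, n_pairs=5000, seed=0)
decay = fit_ld_decay(qpanel, crit, seed=0)
print(f"critical LD (95th pct of unlinked r^2): {crit.value:.4f}")
print(f"LD decay crosses it at {decay.extension_bp / 1e6:.1f} Mb")

blocks = ld_blocks(sig, qpanel, crit)
qtl = build_qtl(blocks, decay, sig_snps=sig,
                chrom_length=cfg.chromosome_length_bp)
print(f"\n{len(sig)} significant SNPs -> {len(blocks)} LD blocks "
      f"-> {len(qtl)} QTL")
print(qtl[["qtl_id", "chrom", "start_bp", "end_bp", "size_mb", "n_snps",
           "peak_snp", "peak_lod"]].round(2).to_string(index=False))
# Each QTL is one chromosomal interval: an LD block of associated SNPs plus
# the decay-distance margin on both sides, merged where intervals overlap.
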