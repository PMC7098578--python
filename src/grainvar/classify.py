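"""Driven vs specific classification of grain-size-variance QTL,
cross-environment commonality, and variance partitioning.

A GSV QTL is "driven" when it colocalises with at least one significant
yield-component association (the variance signal rides on a canopy/mean
locus); it is "specific" when no component association falls inside it.
Within an environment colocalisation is tested against the extended QTL
interval; between environments two QTL are "common" only when they share at
least one significant GSV SNP -- two deliberately different rules matching
the two different questions (pleiotropy vs replication).

Variance partitioning regresses adjusted GSV on the peak-SNP dosages of all
/ specific-only / driven-only QTL; a forward stepwise search minimising AIC
gives the optimal QTL subset and its r^2_opt.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .panel import GenotypePanel
from .traitstats import round_half_up

__all__ = [
    "YIELD_COMPONENTS",
    "classify_qtl",
    "cross_environment",
    "tally_percentages",
    "peak_selection",
    "variance_partition",
    "stepwise_opt",
]

log = logging.getLogger(__name__)

YIELD_COMPONENTS = ("SPM2", "GPS", "GPM2", "TKW", "GY")


def classify_qtl(
    gsv_qtl: pd.DataFrame,
    component_hits: dict,
    env: str,
    rule: str = "interval",
) -> pd.DataFrame:
    """Classify each GSV QTL as driven or specific for one environment.

    ``component_hits`` maps yield-component trait -> significant-SNP table
    (marker_id, chrom, bp).  ``rule='interval'`` tests whether a component
    SNP lies inside the extended interval; ``rule='members'`` requires a
    shared member SNP.
    """
    unknown = set(component_hits) - set(YIELD_COMPONENTS)
    if unknown:
        raise ValueError(f"unknown yield components: {sorted(unknown)}")
    if rule not in ("interval", "members"):
        raise ValueError("rule must be 'interval' or 'members'")
    rows = []
    for _, q in gsv_qtl.iterrows():
        coloc = []
        for trait, hits in component_hits.items():
            hits_sig = hits[hits["significant"]] if "significant" in hits else hits
            if rule == "interval":
                inside = hits_sig[
                    (hits_sig["chrom"] == q["chrom"])
                    & (hits_sig["bp"] >= q["start_bp"])
                    & (hits_sig["bp"] <= q["end_bp"])
                ]
                hit = len(inside) > 0 or bool(
                    set(hits_sig["marker_id"]) & set(q["members"])
                )
            else:
                hit = bool(set(hits_sig["marker_id"]) & set(q["members"]))
            if hit:
                coloc.append(trait)
        rows.append(
            {
                "qtl_id": q["qtl_id"],
                "env": env,
                "chrom": q["chrom"],
                "qtl_class": "driven" if coloc else "specific",
                "colocalised_traits": tuple(sorted(coloc)),
            }
        )
    return pd.DataFrame(rows)


def cross_environment(qtl_by_env: dict, panel_of_env: dict | None = None) -> pd.DataFrame:
    """Commonality of QTL across environments by shared significant GSV SNPs.

    ``qtl_by_env`` maps environment -> QTL table (with ``members`` tuples).
    Two QTL from different environments are common iff they share at least
    one member SNP.  Returns one row per QTL with the set of environments it
    is common with, plus panel-level commonality when ``panel_of_env`` maps
    environments to panel labels.
    """
    rows = []
    envs = sorted(qtl_by_env)
    for env in envs:
        for _, q in qtl_by_env[env].iterrows():
            shared_envs, shared_panels = set(), set()
            my_panel = (panel_of_env or {}).get(env)
            for other in envs:
                if other == env:
                    continue
                for _, p in qtl_by_env[other].iterrows():
                    if set(q["members"]) & set(p["members"]):
                        shared_envs.add(other)
                        op = (panel_of_env or {}).get(other)
                        if my_panel is not None and op is not None and op != my_panel:
                            shared_panels.add(op)
            rows.append(
                {
                    "env": env,
                    "qtl_id": q["qtl_id"],
                    "common_envs": tuple(sorted(shared_envs)),
                    "common_to_environments": bool(shared_envs),
                    "common_to_panels": bool(shared_panels),
                }
            )
    return pd.DataFrame(rows)


def tally_percentages(counts: dict, total: int) -> dict:
    """Percentages of a QTL tally at one decimal, half-up (report style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()}


def peak_selection(
    qtl_list: pd.DataFrame, assoc: pd.DataFrame, rule: str = "effect"
) -> pd.DataFrame:
    """One representative SNP per QTL.

    ``rule='effect'``: the member with maximum |minor-allele effect|, ties
    broken by higher LOD then lower bp; ``rule='lod'``: maximum LOD first.
    """
    if rule not in ("effect", "lod"):
        raise ValueError("rule must be 'effect' or 'lod'")
    info = (
        assoc.sort_values("lod")
        .drop_duplicates("marker_id", keep="last")
        .set_index("marker_id")
    )
    rows = []
    for _, q in qtl_list.iterrows():
        members = [m for m in q["members"] if m in info.index]
        if not members:
            raise ValueError(f"QTL {q['qtl_id']} has no member in the scan table")
        sub = info.loc[members].copy()
        sub["_abs_effect"] = sub["effect"].abs()
        order = (
            ["_abs_effect", "lod", "bp"] if rule == "effect"
            else ["lod", "_abs_effect", "bp"]
        )
        sub = sub.sort_values(order, ascending=[False, False, True])
        best = sub.index[0]
        rows.append(
            {
                "qtl_id": q["qtl_id"],
                "peak_snp": best,
                "effect": float(info.loc[best, "effect"]),
                "lod": float(info.loc[best, "lod"]),
                "bp": int(info.loc[best, "bp"]),
                "chrom": info.loc[best, "chrom"],
            }
        )
    return pd.DataFrame(rows)


def _peak_matrix(peaks: pd.DataFrame, panel: GenotypePanel, genotypes) -> np.ndarray:
    idx_of = {mid: k for k, mid in enumerate(panel.markers["marker_id"])}
    rows = [list(panel.genotype_ids).index(g) for g in genotypes]
    cols = [idx_of[m] for m in peaks["peak_snp"]]
    return panel.dosages[np.ix_(rows, cols)]


def _ols_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """r^2 of y on [1, X], dropping collinear columns (pivoted)."""
    n = len(y)
    xd = np.column_stack([np.ones(n), x])
    q, r, piv = qr(xd, mode="economic", pivoting=True)
    tol = np.abs(r[0, 0]) * max(xd.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    if rank < xd.shape[1]:
        log.warning("dropping %d collinear peak column(s)", xd.shape[1] - rank)
        keep = sorted(piv[:rank])
        xd = xd[:, keep]
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0, xd.shape[1] - 1
    return float(1.0 - np.sum(resid ** 2) / tss), xd.shape[1] - 1


def variance_partition(
    adjusted_gsv: pd.DataFrame,
    peaks: pd.DataFrame,
    classes: pd.DataFrame,
    panel: GenotypePanel,
    env: str,
) -> dict:
    """r^2 of adjusted GSV on peak dosages: all / specific-only / driven-only."""
    sub = adjusted_gsv[
        (adjusted_gsv["trait"] == "GSV") & (adjusted_gsv["env"] == env)
    ]
    genos = [g for g in sub["genotype"] if g in set(panel.genotype_ids)]
    y = sub.set_index("genotype").loc[genos, "value"].to_numpy(dtype=float)
    cls = classes.set_index("qtl_id")["qtl_class"]
    out = {"env": env}
    for label, sel in (
        ("all", peaks),
        ("specific", peaks[peaks["qtl_id"].map(cls) == "specific"]),
        ("driven", peaks[peaks["qtl_id"].map(cls) == "driven"]),
    ):
        if len(sel) == 0:
            out[f"r2_{label}"], out[f"n_{label}"] = 0.0, 0
            continue
        x = _peak_matrix(sel, panel, genos)
        r2, k = _ols_r2(y, x)
        out[f"r2_{label}"], out[f"n_{label}"] = r2, len(sel)
    return out


def _aic(y: np.ndarray, x: np.ndarray) -> float:
    """Gaussian AIC: n log(RSS/n) + 2 (k + 1), k = columns of the design."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(np.sum((y - x @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (x.shape[1] + 1)


def stepwise_opt(
    adjusted_gsv: pd.DataFrame,
    peaks: pd.DataFrame,
    panel: GenotypePanel,
    env: str,
    classes: pd.DataFrame | None = None,
) -> dict:
    """Forward AIC selection of QTL peaks for adjusted GSV.

    Starts from the intercept-only model, at each step adds the candidate
    lowering AIC the most, and stops when no addition lowers it.  Returns
    the selected peak set, its size, the count of driven QTL among them
    (when classes are supplied) and the final model r^2.
    """
    sub = adjusted_gsv[
        (adjusted_gsv["trait"] == "GSV") & (adjusted_gsv["env"] == env)
    ]
    genos = [g for g in sub["genotype"] if g in set(panel.genotype_ids)]
    y = sub.set_index("genotype").loc[genos, "value"].to_numpy(dtype=float)
    xfull = _peak_matrix(peaks, panel, genos)
    n = len(y)
    selected: list[int] = []
    remaining = list(range(xfull.shape[1]))
    cur_x = np.ones((n, 1))
    cur_aic = _aic(y, cur_x)
    while remaining:
        cands = [(_aic(y, np.column_stack([cur_x, xfull[:, j]])), j) for j in remaining]
        best_aic, best_j = min(cands)
        if best_aic >= cur_aic:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        cur_x = np.column_stack([cur_x, xfull[:, best_j]])
        cur_aic = best_aic
    r2, _ = _ols_r2(y, cur_x[:, 1:]) if selected else (0.0, 0)
    sel_ids = [peaks["qtl_id"].iloc[j] for j in selected]
    n_driven = 0
    if classes is not None and selected:
        cls = classes.set_index("qtl_id")["qtl_class"]
        n_driven = int(sum(cls.get(q) == "driven" for q in sel_ids))
    return {
        "env": env,
        "selected_qtl": sel_ids,
        "n_selected": len(sel_ids),
        "n_selected_driven": n_driven,
        "r2_opt": r2,
        "aic": cur_aic,
    }
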