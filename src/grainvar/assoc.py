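"""Marker QC and the kinship-corrected single-marker mixed-model scan.

The scan follows the EMMAX/P3D scheme with leave-one-chromosome-out (LOCO)
relationship matrices: for each chromosome the variance ratio
lam = sigma2_g / sigma2_e is estimated once by REML under the no-marker null
with K built from all *other* chromosomes; every marker on the chromosome is
then tested by generalised least squares at that fixed ratio, with a 1-df
Wald t-test.  LOD = -log10(p); markers with LOD above the threshold
(default 3, strict) are flagged significant.  Effects are reported for the
minor allele.  No principal-component covariates are used (kinship only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import EigenA, eigen_a, reml_fit
from .panel import GenotypePanel

__all__ = [
    "qc_filter",
    "impute_missing",
    "kinship_loco",
    "mlm_scan",
    "lod_from_p",
    "EmptyPanelError",
]

log = logging.getLogger(__name__)

K_JITTER = 1e-8  # diagonal stabiliser before eigen-decomposition


class EmptyPanelError(ValueError):
    pass


def qc_filter(
    panel: GenotypePanel,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
) -> GenotypePanel:
    """Remove markers with missingness > 10%, MAF < 5%, and monomorphic ones.

    MAF is recomputed over the surviving markers' non-missing calls.
    """
    miss = panel.missing_rate()
    maf = panel.maf()
    mono = maf == 0.0
    bad_miss = miss > max_missing
    bad_maf = (maf < min_maf) & ~mono
    keep = ~(mono | bad_miss | bad_maf)
    log.info(
        "QC: removed %d missingness>%g, %d MAF<%g, %d monomorphic; %d of %d kept",
        int(bad_miss.sum()), max_missing, int(bad_maf.sum()), min_maf,
        int(mono.sum()), int(keep.sum()), panel.n_markers,
    )
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")
    return panel.subset_markers(np.nonzero(keep)[0]).with_stats()


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the marker's mean dosage (deterministic)."""
    dos = panel.dosages
    nan_mask = np.isnan(dos)
    if not nan_mask.any():
        return panel
    dos = dos.copy()
    col_mean = np.nanmean(dos, axis=0)
    r, c = np.nonzero(nan_mask)
    dos[r, c] = col_mean[c]
    log.info("imputed %d missing calls (%.3f%% of matrix)",
             nan_mask.sum(), 100.0 * nan_mask.mean())
    return GenotypePanel(dos, panel.markers.copy(), list(panel.genotype_ids))


def _vanraden(dos: np.ndarray) -> np.ndarray:
    """VanRaden centered genomic relationship matrix from a dosage block."""
    p = dos.mean(axis=0) / 2.0
    w = dos - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    return (w @ w.T) / denom


def kinship_loco(panel: GenotypePanel) -> dict:
    """Per-chromosome LOCO VanRaden kinship matrices.

    For chromosome c, K_c uses every marker NOT on c.  A single-chromosome
    panel cannot do LOCO; the full-genome K is returned for it with a
    warning.
    """
    if np.isnan(panel.dosages).any():
        raise ValueError("impute the panel before computing kinship")
    chroms = panel.chromosomes
    chrom_arr = panel.markers["chrom"].to_numpy()
    if len(chroms) < 2:
        log.warning("single-chromosome panel: LOCO impossible, using full-genome K")
        k = _vanraden(panel.dosages)
        return {chroms[0]: k}
    return {
        c: _vanraden(panel.dosages[:, chrom_arr != c])
        for c in chroms
    }


def lod_from_p(p) -> np.ndarray | float:
    """LOD = -log10(p); strictly decreasing in p, defined on (0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr > 1.0):
        raise ValueError("p must lie in (0, 1]")
    out = -np.log10(arr)
    return float(out) if np.isscalar(p) else out


def _align(adjusted: pd.DataFrame, panel: GenotypePanel, trait: str, env: str):
    sub = adjusted[(adjusted["trait"] == trait) & (adjusted["env"] == env)]
    sub = sub.set_index("genotype")["value"]
    panel_ids = [str(g) for g in panel.genotype_ids]
    orphans_p = sorted(set(sub.index) - set(panel_ids))
    common = [g for g in panel_ids if g in sub.index]
    if not common:
        raise KeyError("no genotype ids shared between phenotypes and panel")
    if orphans_p:
        raise KeyError(f"phenotyped genotypes absent from the panel: {orphans_p[:10]}")
    rows = [panel_ids.index(g) for g in common]
    return np.asarray(sub.loc[common], dtype=float), np.asarray(rows, dtype=int)


def _scan_chromosome(y, dos, eig: EigenA, lam: float):
    """Vectorised GLS of [1, x_m] for every marker at fixed variance ratio."""
    n = y.shape[0]
    u = eig.vectors
    d = eig.values
    w = 1.0 / (1.0 + lam * d)
    yr = u.T @ y
    one_r = u.T @ np.ones(n)
    xr = u.T @ dos  # (n, m)
    a11 = float(np.sum(w * one_r * one_r))
    a12 = (w * one_r) @ xr
    a22 = np.einsum("i,im,im->m", w, xr, xr)
    b1 = float(np.sum(w * one_r * yr))
    b2 = (w * yr) @ xr
    det = a11 * a22 - a12 ** 2
    det = np.where(det <= 0, np.nan, det)
    beta = (a11 * b2 - a12 * b1) / det
    mu = (a22 * b1 - a12 * b2) / det
    yy = float(np.sum(w * yr * yr))
    rss = yy - mu * b1 - beta * b2
    df = n - 2
    sigma2 = np.clip(rss, 1e-300, None) / df
    se = np.sqrt(sigma2 * a11 / det)
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    pval = np.clip(pval, 1e-300, 1.0)
    return beta, se, pval


def mlm_scan(
    adjusted: pd.DataFrame,
    panel: GenotypePanel,
    k_set: dict,
    trait: str,
    env: str,
    lod_threshold: float = 3.0,
    method: str = "p3d",
    eigen_cache: dict | None = None,
) -> pd.DataFrame:
    """Single-marker mixed-model scan of one trait in one environment.

    ``adjusted`` is the long adjusted-means table; ``k_set`` maps chromosome
    -> LOCO kinship.  ``method='p3d'`` estimates the variance ratio once per
    chromosome under the null; ``method='exact'`` re-estimates it for every
    marker (slow, reference behaviour).
    """
    if method not in ("p3d", "exact"):
        raise ValueError("method must be 'p3d' or 'exact'")
    y, rows = _align(adjusted, panel, trait, env)
    results = []
    chrom_arr = panel.markers["chrom"].to_numpy()
    maf_all = panel.maf()
    for chrom in panel.chromosomes:
        k = k_set[chrom]
        key = (chrom, len(rows))
        if eigen_cache is not None and key in eigen_cache:
            eig = eigen_cache[key]
        else:
            eig = eigen_a(np.asarray(k)[np.ix_(rows, rows)], jitter=K_JITTER)
            if eigen_cache is not None:
                eigen_cache[key] = eig
        cols = np.nonzero(chrom_arr == chrom)[0]
        dos = panel.dosages[np.ix_(rows, cols)]
        if np.isnan(dos).any():
            raise ValueError("impute the panel before scanning")
        null = reml_fit(y, np.ones((len(y), 1)), eig)
        if method == "p3d":
            beta, se, pval = _scan_chromosome(y, dos, eig, null.lam)
        else:
            beta = np.empty(len(cols))
            se = np.empty(len(cols))
            pval = np.empty(len(cols))
            for j in range(len(cols)):
                x = np.column_stack([np.ones(len(y)), dos[:, j]])
                try:
                    fit = reml_fit(y, x, eig)
                except Exception:
                    beta[j], se[j], pval[j] = np.nan, np.nan, 1.0
                    continue
                b = fit.beta[1]
                s = float(np.sqrt(fit.cov_beta[1, 1]))
                tval = b / s if s > 0 else 0.0
                beta[j], se[j] = b, s
                pval[j] = float(2.0 * stats.t.sf(abs(tval), len(y) - 2))
        # report the effect of the minor allele
        freq = dos.mean(axis=0) / 2.0
        flip = freq > 0.5
        beta = np.where(flip, -beta, beta)
        lod = -np.log10(np.clip(pval, 1e-300, 1.0))
        sub = panel.markers.iloc[cols]
        results.append(
            pd.DataFrame(
                {
                    "marker_id": sub["marker_id"].to_numpy(),
                    "chrom": chrom,
                    "bp": sub["bp"].to_numpy(),
                    "trait": trait,
                    "env": env,
                    "maf": maf_all[cols],
                    "effect": beta,
                    "se": se,
                    "p_value": pval,
                    "lod": lod,
                    "significant": lod > lod_threshold,
                }
            )
        )
    return pd.concat(results, ignore_index=True)
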