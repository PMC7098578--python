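"""From significant SNPs to QTL intervals.

The interval-building chain: (1) background ("critical") LD from unlinked
marker pairs; (2) pruning of near-duplicate markers (r^2 > 0.9); (3)
average-linkage clustering of significant SNPs at distance 1 - r^2, cut at
1 - critical LD, giving LD blocks; (4) a Hill-Weir expected-r^2 decay curve
fitted to intra-chromosomal pairs, whose crossing point with the critical LD
gives the boundary-extension distance; (5) block extension and merging of
overlapping intervals into QTL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq, curve_fit
from scipy.spatial.distance import squareform

from .panel import GenotypePanel

__all__ = [
    "pairwise_r2",
    "r2_matrix",
    "critical_ld",
    "critical_ld_from_r2",
    "CriticalLd",
    "prune_redundant",
    "ld_blocks",
    "LdDecayModel",
    "fit_ld_decay",
    "hill_weir_r2",
    "build_qtl",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CriticalLd:
    value: float
    n_pairs: int
    method: str  # "empirical-95th" | "parametric-sqrt"


@dataclass(frozen=True)
class LdDecayModel:
    rho: float          # Hill-Weir recombination-scale parameter (per bp)
    n: int              # sample size used in the expectation
    extension_bp: float  # distance where E[r^2] crosses the critical LD (inf if never)
    critical: float


def _r2_vec(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    c = np.corrcoef(a, b)[0, 1]
    return float(c * c)


def pairwise_r2(panel: GenotypePanel, pairs) -> pd.DataFrame:
    """Squared dosage correlation for explicit marker-index pairs.

    Zero-variance markers give an undefined (NaN) r^2 with a flag.  Distance
    is physical bp when the pair shares a chromosome, else the pair is
    marked unlinked.
    """
    rows = []
    mk = panel.markers
    for i, j in pairs:
        r2 = _r2_vec(panel.dosages[:, i], panel.dosages[:, j])
        same = mk["chrom"].iat[i] == mk["chrom"].iat[j]
        rows.append(
            {
                "i": int(i),
                "j": int(j),
                "marker_i": mk["marker_id"].iat[i],
                "marker_j": mk["marker_id"].iat[j],
                "r2": r2,
                "distance_bp": abs(int(mk["bp"].iat[i]) - int(mk["bp"].iat[j]))
                if same else np.nan,
                "unlinked": not same,
                "undefined": bool(np.isnan(r2)),
            }
        )
    return pd.DataFrame(rows)


def r2_matrix(dos: np.ndarray) -> np.ndarray:
    """All-pairs r^2 of dosage columns (NaN rows for zero-variance markers)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(dos.T)
    return c * c


def critical_ld_from_r2(r2: np.ndarray, method: str = "empirical-95th") -> float:
    """Critical-LD value from a vector of unlinked-pair r^2 values.

    ``empirical-95th``: the 95th percentile (linear interpolation).
    ``parametric-sqrt``: normal 95th percentile of sqrt(r^2), squared back.
    """
    r2 = np.asarray(r2, dtype=float)
    r2 = r2[~np.isnan(r2)]
    if r2.size == 0:
        raise ValueError("no defined r^2 values")
    if method == "empirical-95th":
        v = float(np.percentile(r2, 95.0))
    elif method == "parametric-sqrt":
        z = np.sqrt(r2)
        v = float((z.mean() + 1.6448536269514722 * z.std(ddof=1)) ** 2)
    else:
        raise ValueError(f"unknown critical-LD method: {method}")
    return float(np.clip(v, 0.0, 1.0))


def critical_ld(
    panel: GenotypePanel,
    n_pairs: int = 10_000,
    seed: int = 0,
    method: str = "empirical-95th",
) -> CriticalLd:
    """Background LD: r^2 over random inter-chromosomal marker pairs."""
    chroms = panel.markers["chrom"].to_numpy()
    if len(set(chroms)) < 2:
        raise ValueError("critical LD needs >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    m = panel.n_markers
    max_pairs = int(np.sum([
        (chroms != c).sum() * (chroms == c).sum() for c in set(chroms)
    ]) // 2)
    if n_pairs > max_pairs:
        log.warning("requested %d pairs > %d available; sampling with replacement",
                    n_pairs, max_pairs)
    ii = rng.integers(0, m, size=4 * n_pairs)
    jj = rng.integers(0, m, size=4 * n_pairs)
    keep = chroms[ii] != chroms[jj]
    ii, jj = ii[keep][:n_pairs], jj[keep][:n_pairs]
    while ii.size < n_pairs:  # top-up, pathological maps only
        a = rng.integers(0, m, size=n_pairs)
        b = rng.integers(0, m, size=n_pairs)
        k = chroms[a] != chroms[b]
        ii = np.concatenate([ii, a[k]])[:n_pairs]
        jj = np.concatenate([jj, b[k]])[:n_pairs]
    dos = panel.dosages
    da = dos[:, ii] - dos[:, ii].mean(axis=0)
    db = dos[:, jj] - dos[:, jj].mean(axis=0)
    num = np.einsum("nk,nk->k", da, db)
    den = np.sqrt(np.einsum("nk,nk->k", da, da) * np.einsum("nk,nk->k", db, db))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (num / den) ** 2
    return CriticalLd(
        value=critical_ld_from_r2(r2, method=method),
        n_pairs=int(ii.size),
        method=method,
    )


def prune_redundant(panel: GenotypePanel, threshold: float = 0.9) -> GenotypePanel:
    """Greedy left-to-right (ascending bp) pruning within each chromosome.

    Among retained markers no pair has r^2 > threshold.  The retained set
    depends on the scan order, which is why the order is fixed and
    documented: ascending physical position.
    """
    chrom_arr = panel.markers["chrom"].to_numpy()
    keep_global = []
    for chrom in panel.chromosomes:
        cols = np.nonzero(chrom_arr == chrom)[0]  # map is bp-sorted already
        dos = panel.dosages[:, cols]
        centered = dos - dos.mean(axis=0)
        norms = np.sqrt((centered ** 2).sum(axis=0))
        kept: list[int] = []
        for j in range(len(cols)):
            if norms[j] == 0:
                kept.append(j)  # monomorphic: r^2 undefined, not "in LD"
                continue
            if kept:
                prev = [k for k in kept if norms[k] > 0]
                if prev:
                    r = (centered[:, prev].T @ centered[:, j]) / (
                        norms[prev] * norms[j]
                    )
                    if np.any(r * r > threshold):
                        continue
            kept.append(j)
        keep_global.extend(cols[kept])
        log.info("prune %s: kept %d of %d markers", chrom, len(kept), len(cols))
    return panel.subset_markers(np.sort(np.asarray(keep_global)))


def ld_blocks(
    sig_snps: pd.DataFrame,
    panel: GenotypePanel,
    critical: CriticalLd | float,
) -> pd.DataFrame:
    """Average-linkage LD blocks of significant SNPs, per chromosome.

    Distance is 1 - r^2; the dendrogram is cut at 1 - critical LD.  Blocks
    never span chromosomes (a QTL is a chromosomal interval); the clustering
    is invariant to input order because SNPs are first sorted by position.
    """
    cut = 1.0 - (critical.value if isinstance(critical, CriticalLd) else float(critical))
    idx_of = {mid: k for k, mid in enumerate(panel.markers["marker_id"])}
    snps = sig_snps.drop_duplicates("marker_id").copy()
    snps["_col"] = snps["marker_id"].map(idx_of)
    if snps["_col"].isna().any():
        missing = snps.loc[snps["_col"].isna(), "marker_id"].tolist()
        raise KeyError(f"significant SNPs absent from panel: {missing[:5]}")
    rows = []
    block_id = 0
    for chrom, grp in snps.groupby("chrom", sort=True):
        grp = grp.sort_values("bp")
        cols = grp["_col"].astype(int).to_numpy()
        if len(cols) == 1:
            members = [grp["marker_id"].iloc[0]]
            labels = np.array([1])
        else:
            r2 = r2_matrix(panel.dosages[:, cols])
            d = 1.0 - np.nan_to_num(r2, nan=0.0)
            np.fill_diagonal(d, 0.0)
            d = np.clip((d + d.T) / 2.0, 0.0, None)
            labels = fcluster(linkage(squareform(d, checks=False), method="average"),
                              t=cut, criterion="distance")
        for lab in np.unique(labels):
            sel = grp.iloc[np.nonzero(labels == lab)[0]]
            block_id += 1
            rows.append(
                {
                    "block_id": f"blk{block_id:03d}",
                    "chrom": chrom,
                    "start_bp": int(sel["bp"].min()),
                    "end_bp": int(sel["bp"].max()),
                    "members": tuple(sel["marker_id"]),
                }
            )
    return pd.DataFrame(rows)


def hill_weir_r2(d_bp: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Hill-Weir drift expectation of r^2 at recombination scale C = rho * d."""
    c = rho * np.asarray(d_bp, dtype=float)
    t1 = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    t2 = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return t1 * t2


def fit_ld_decay(
    panel: GenotypePanel,
    critical: CriticalLd | float,
    max_dist_bp: float | None = None,
    n_pairs: int = 20_000,
    seed: int = 0,
) -> LdDecayModel:
    """Fit the Hill-Weir decay to sampled intra-chromosomal pairs.

    Returns the fitted rho and the extension distance d* where the curve
    crosses the critical LD (bisection; inf when the curve never crosses).
    """
    crit = critical.value if isinstance(critical, CriticalLd) else float(critical)
    chroms = panel.markers["chrom"].to_numpy()
    bp = panel.markers["bp"].to_numpy()
    rng = np.random.default_rng(seed)
    m = panel.n_markers
    ii = rng.integers(0, m, size=6 * n_pairs)
    jj = rng.integers(0, m, size=6 * n_pairs)
    keep = (chroms[ii] == chroms[jj]) & (ii != jj)
    if max_dist_bp is not None:
        keep &= np.abs(bp[ii] - bp[jj]) <= max_dist_bp
    ii, jj = ii[keep][:n_pairs], jj[keep][:n_pairs]
    if ii.size < 50:
        raise ValueError("too few intra-chromosomal pairs to fit the decay")
    dos = panel.dosages
    da = dos[:, ii] - dos[:, ii].mean(axis=0)
    db = dos[:, jj] - dos[:, jj].mean(axis=0)
    num = np.einsum("nk,nk->k", da, db)
    den = np.sqrt(np.einsum("nk,nk->k", da, da) * np.einsum("nk,nk->k", db, db))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (num / den) ** 2
    dist = np.abs(bp[ii] - bp[jj]).astype(float)
    ok = ~np.isnan(r2)
    r2, dist = r2[ok], dist[ok]
    n = panel.n_genotypes

    def model(d, rho):
        return hill_weir_r2(d, rho, n)

    med = np.median(dist[dist > 0]) or 1.0
    popt, _ = curve_fit(
        model, dist, r2, p0=[1.0 / med], bounds=(1e-15, 1.0), maxfev=10_000
    )
    rho = float(popt[0])
    span = float(bp.max()) * 10.0
    floor = hill_weir_r2(np.array([span]), rho, n)[0]
    if floor >= crit:
        ext = float("inf")
        log.warning("LD decay never crosses critical LD %.3f; extension infinite", crit)
    elif hill_weir_r2(np.array([1.0]), rho, n)[0] <= crit:
        ext = 0.0
    else:
        ext = float(brentq(lambda d: hill_weir_r2(np.array([d]), rho, n)[0] - crit,
                           1.0, span, xtol=1e-3))
    return LdDecayModel(rho=rho, n=n, extension_bp=ext, critical=crit)


def build_qtl(
    blocks: pd.DataFrame,
    decay: LdDecayModel | float,
    sig_snps: pd.DataFrame | None = None,
    chrom_length: dict | int | None = None,
    merge: bool = True,
) -> pd.DataFrame:
    """Extend LD blocks by the decay distance and merge overlaps into QTL.

    ``sig_snps`` (marker_id, lod, effect, maf, bp ...) supplies the peak SNP
    (max LOD) per QTL.  Coordinates are clipped to [1, chromosome length].
    """
    ext = decay.extension_bp if isinstance(decay, LdDecayModel) else float(decay)
    if not np.isfinite(ext):
        raise ValueError("infinite extension distance; lower the critical LD")
    recs = []
    for _, b in blocks.iterrows():
        if chrom_length is None:
            hi = np.inf
        elif isinstance(chrom_length, dict):
            hi = chrom_length[b["chrom"]]
        else:
            hi = float(chrom_length)
        recs.append(
            {
                "chrom": b["chrom"],
                "core_start": int(b["start_bp"]),
                "core_end": int(b["end_bp"]),
                "start_bp": int(max(b["start_bp"] - ext, 1)),
                "end_bp": int(min(b["end_bp"] + ext, hi)),
                "members": set(b["members"]),
            }
        )
    merged = []
    for chrom in sorted({r["chrom"] for r in recs}):
        intervals = sorted(
            (r for r in recs if r["chrom"] == chrom), key=lambda r: r["start_bp"]
        )
        cur = None
        for r in intervals:
            if merge and cur is not None and r["start_bp"] <= cur["end_bp"]:
                cur["end_bp"] = max(cur["end_bp"], r["end_bp"])
                cur["core_start"] = min(cur["core_start"], r["core_start"])
                cur["core_end"] = max(cur["core_end"], r["core_end"])
                cur["members"] |= r["members"]
            else:
                if cur is not None:
                    merged.append(cur)
                cur = dict(r)
                cur["members"] = set(r["members"])
        if cur is not None:
            merged.append(cur)
    lod_of = {}
    if sig_snps is not None:
        best = sig_snps.sort_values("lod").drop_duplicates("marker_id", keep="last")
        lod_of = best.set_index("marker_id").to_dict("index")
    rows = []
    for q, r in enumerate(merged, start=1):
        members = sorted(r["members"])
        peak, peak_lod, peak_maf = None, -np.inf, np.nan
        for mid in members:
            info = lod_of.get(mid)
            if info is not None and info.get("lod", -np.inf) > peak_lod:
                peak, peak_lod = mid, float(info["lod"])
                peak_maf = float(info.get("maf", np.nan))
        rows.append(
            {
                "qtl_id": f"qtl{q:03d}",
                "chrom": r["chrom"],
                "core_start_bp": r["core_start"],
                "core_end_bp": r["core_end"],
                "start_bp": r["start_bp"],
                "end_bp": r["end_bp"],
                "size_mb": (r["end_bp"] - r["start_bp"]) / 1e6,
                "n_snps": len(members),
                "members": tuple(members),
                "peak_snp": peak,
                "peak_lod": peak_lod if np.isfinite(peak_lod) else np.nan,
                "peak_maf": peak_maf,
            }
        )
    return pd.DataFrame(rows)


def qtl_to_bed(qtl: pd.DataFrame, path) -> None:
    """Write QTL intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, r in qtl.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start_bp']) - 1}\t{int(r['end_bp'])}\t"
                     f"{r['qtl_id']}\n")
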