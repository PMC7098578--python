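"""Spatially adjusted genotype means and broad-sense heritability for
augmented field designs.

Most genotypes in an augmented trial are unreplicated; replicated check
genotypes carry the information on spatial (block / sub-block) effects.
Three related mixed models are used, all fitted by profiled REML
(:mod:`grainvar.lmm`):

* adjusted means: Y = mu + SB(random) + B(fixed) + G(fixed) + e, returning
  mu + G_i per genotype ("BLUE"-style adjusted mean);
* heritability, replicated-checks layout: sub-block effects are estimated
  from the checks only, observations are corrected, and a random-genotype
  model yields sigma2_G / (sigma2_G + sigma2_e);
* heritability, two-step layout: checks-only model estimates sub-block and
  block effects, all plots are corrected for both, then an intercept +
  random-genotype model is fitted.

Identifiability uses sum-to-zero contrasts on blocks and genotypes, so the
adjusted mean mu + G_i is a population-centred genotype value.  H2 here is
on a per-plot basis (no replication divisor): most entries are unreplicated,
so the plot residual is the natural error unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .lmm import EigenA, NonEstimableError, eigen_a, reml_fit

__all__ = [
    "AdjustedMeans",
    "HeritabilityEstimate",
    "adjusted_means",
    "heritability_panel2016",
    "heritability_panel2017",
    "DesignError",
]

REQUIRED_COLUMNS = ("genotype", "env", "block", "subblock")


class DesignError(ValueError):
    """Layout violates the assumptions of the augmented-design models."""


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    env: str
    sigma2_G: float
    sigma2_eps: float
    H2: float
    boundary: bool  # True when the genotype variance hit the zero bound


def _check_columns(plots: pd.DataFrame, trait: str) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, trait) if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table missing columns: {missing}")


def _sum_zero(factor: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero contrast columns for a factor (levels sorted; last level
    coded -1 on every column)."""
    levels = sorted(factor.unique())
    k = len(levels)
    x = np.zeros((len(factor), max(k - 1, 0)))
    pos = {lv: i for i, lv in enumerate(levels)}
    codes = factor.map(pos).to_numpy()
    for col in range(k - 1):
        x[codes == col, col] = 1.0
        x[codes == k - 1, col] = -1.0
    return x, levels


def _one_hot(factor: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(factor.unique())
    pos = {lv: i for i, lv in enumerate(levels)}
    z = np.zeros((len(factor), len(levels)))
    z[np.arange(len(factor)), factor.map(pos).to_numpy()] = 1.0
    return z, levels


def _assert_estimable(x: np.ndarray, geno_cols: slice, geno_levels: list) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    _, _, piv = qr(x, mode="economic", pivoting=True)
    aliased_cols = sorted(piv[rank:])
    aliased = [
        geno_levels[c - geno_cols.start]
        for c in aliased_cols
        if geno_cols.start <= c < geno_cols.stop
    ]
    raise NonEstimableError(
        f"design is confounded; aliased genotype effects: {aliased or aliased_cols}"
    )


def _fit_env(sub: pd.DataFrame, trait: str):
    """Model (adjusted means): fixed blocks + genotypes, random sub-block."""
    y = sub[trait].to_numpy(dtype=float)
    xb, _ = _sum_zero(sub["block"].astype(str))
    xg, geno_levels = _sum_zero(sub["genotype"].astype(str))
    x = np.column_stack([np.ones(len(sub)), xb, xg])
    geno_cols = slice(1 + xb.shape[1], x.shape[1])
    _assert_estimable(x, geno_cols, geno_levels)
    z, _ = _one_hot(sub["subblock"].astype(str))
    fit = reml_fit(y, x, eigen_a(z @ z.T))
    return fit, x, geno_cols, geno_levels


def adjusted_means(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Spatially adjusted genotype means (mu + G_i) per environment.

    Returns a long table (genotype, env, trait, value, se).
    """
    _check_columns(plots, trait)
    out = []
    for env, sub in plots.groupby("env", sort=True):
        sub = sub.dropna(subset=[trait]).reset_index(drop=True)
        fit, x, geno_cols, geno_levels = _fit_env(sub, trait)
        beta, cov = fit.beta, fit.cov_beta
        p = x.shape[1]
        n_g = len(geno_levels)
        for i, g in enumerate(geno_levels):
            c = np.zeros(p)
            c[0] = 1.0
            if i < n_g - 1:
                c[geno_cols.start + i] = 1.0
            else:  # last level: effect is minus the sum of the contrasts
                c[geno_cols] = -1.0
            out.append(
                {
                    "genotype": g,
                    "env": env,
                    "trait": trait,
                    "value": float(c @ beta),
                    "se": float(np.sqrt(c @ cov @ c)),
                }
            )
    return pd.DataFrame(out)


def _check_subblocks(sub: pd.DataFrame) -> pd.DataFrame:
    if "is_check" not in sub.columns:
        raise DesignError("plot table lacks an is_check column")
    checks = sub[sub["is_check"].astype(bool)]
    if checks.empty or checks.groupby("genotype").size().max() < 2:
        raise DesignError("no replicated check genotypes in this environment")
    missing_sb = set(sub["subblock"].astype(str)) - set(checks["subblock"].astype(str))
    if missing_sb:
        raise DesignError(f"sub-blocks without checks: {sorted(missing_sb)}")
    return checks


def _spatial_from_checks(sub: pd.DataFrame, trait: str):
    """Checks-only model: Y = mu + SB(random) + B(fixed) + G_check(fixed) + e.

    Returns (sub-block BLUP lookup, block effect lookup)."""
    checks = _check_subblocks(sub).reset_index(drop=True)
    y = checks[trait].to_numpy(dtype=float)
    xb, block_levels = _sum_zero(checks["block"].astype(str))
    xg, geno_levels = _sum_zero(checks["genotype"].astype(str))
    x = np.column_stack([np.ones(len(checks)), xb, xg])
    z, sb_levels = _one_hot(checks["subblock"].astype(str))
    fit = reml_fit(y, x, eigen_a(z @ z.T))
    u = fit.blup_u()  # per-observation sub-block BLUP
    sb_effect = {}
    for j, lv in enumerate(sb_levels):
        rows = np.nonzero(z[:, j])[0]
        sb_effect[lv] = float(u[rows[0]])
    nb = len(block_levels)
    block_effect = {}
    for k, lv in enumerate(block_levels):
        if k < nb - 1:
            block_effect[lv] = float(fit.beta[1 + k])
        else:
            block_effect[lv] = float(-fit.beta[1:nb].sum())
    return sb_effect, block_effect


def _random_genotype_fit(y: np.ndarray, x: np.ndarray, geno: pd.Series):
    zg, _ = _one_hot(geno.astype(str))
    fit = reml_fit(y, x, eigen_a(zg @ zg.T))
    s2g, s2e = fit.sigma2_u, fit.sigma2_e
    h2 = s2g / (s2g + s2e) if (s2g + s2e) > 0 else 0.0
    return s2g, s2e, h2, fit.lam == 0.0


def heritability_panel2016(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """H2 for the replicated-checks layout.

    Sub-block effects come from the checks only; observations corrected for
    them feed a blocks-fixed, genotype-random REML fit.
    """
    _check_columns(plots, trait)
    rows = []
    for env, sub in plots.groupby("env", sort=True):
        sub = sub.dropna(subset=[trait]).reset_index(drop=True)
        sb_effect, _ = _spatial_from_checks(sub, trait)
        ycorr = sub[trait].to_numpy(dtype=float) - np.array(
            [sb_effect.get(s, 0.0) for s in sub["subblock"].astype(str)]
        )
        xb, _ = _sum_zero(sub["block"].astype(str))
        x = np.column_stack([np.ones(len(sub)), xb])
        s2g, s2e, h2, bound = _random_genotype_fit(ycorr, x, sub["genotype"])
        rows.append(HeritabilityEstimate(trait, env, s2g, s2e, h2, bound).__dict__)
    return pd.DataFrame(rows)


def heritability_panel2017(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """H2 for the unreplicated layout: two-step spatial correction.

    Step 1 estimates sub-block BLUPs and block effects from the checks;
    step 2 subtracts both from every plot and fits intercept + random
    genotype.
    """
    _check_columns(plots, trait)
    rows = []
    for env, sub in plots.groupby("env", sort=True):
        sub = sub.dropna(subset=[trait]).reset_index(drop=True)
        sb_effect, block_effect = _spatial_from_checks(sub, trait)
        ycorr = (
            sub[trait].to_numpy(dtype=float)
            - np.array([sb_effect.get(s, 0.0) for s in sub["subblock"].astype(str)])
            - np.array([block_effect.get(b, 0.0) for b in sub["block"].astype(str)])
        )
        x = np.ones((len(sub), 1))
        s2g, s2e, h2, bound = _random_genotype_fit(ycorr, x, sub["genotype"])
        rows.append(HeritabilityEstimate(trait, env, s2g, s2e, h2, bound).__dict__)
    return pd.DataFrame(rows)
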