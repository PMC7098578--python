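"""Across-genotype descriptive statistics: coefficients of variation,
Pearson correlation panels, between-environment correlation comparison, and
Tukey letter groups for environment contrasts."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv_from_summary",
    "round_half_up",
    "correlation_panel",
    "compare_correlations",
    "environment_anova",
    "significance_stars",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cv_from_summary(mean: float, sd: float, ndigits: int = 2) -> float:
    """Coefficient of variation, percent: 100 * sd / mean, rounded half-up."""
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return round_half_up(100.0 * sd / mean, ndigits)


def significance_stars(p: float) -> str:
    """Figure-legend star coding: . <0.1, * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def correlation_panel(
    adjusted: pd.DataFrame,
    traits: list[str],
    env: str | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between adjusted genotype means.

    ``adjusted`` is a long table (genotype, env, trait, value); rows for one
    environment are pivoted to genotype x trait and each trait pair is
    correlated over its complete cases.  Constant traits yield an undefined
    (NaN) correlation with a flag rather than an error.
    """
    df = adjusted if env is None else adjusted[adjusted["env"] == env]
    wide = df.pivot_table(index="genotype", columns="trait", values="value")
    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            sub = wide[[t1, t2]].dropna()
            n = len(sub)
            if n < 3:
                raise ValueError(f"fewer than 3 genotypes with both {t1} and {t2}")
            x, y = sub[t1].to_numpy(), sub[t2].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                r, p, flag = np.nan, np.nan, "constant-trait"
            else:
                r, p = stats.pearsonr(x, y)
                flag = ""
            rows.append(
                {
                    "env": env,
                    "trait1": t1,
                    "trait2": t2,
                    "r": float(r),
                    "n": n,
                    "p_value": float(p),
                    "stars": significance_stars(p) if flag == "" else "",
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for equality of two independent Pearson correlations.

    Fisher r-to-z on each sample, z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)),
    referred to the standard normal.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| = 1: z transform infinite")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def _letters_from_nsd(groups: list[str], nsd: np.ndarray, means: dict) -> dict:
    """Compact letter display by insert-and-absorb over the not-significantly-
    different (boolean) matrix; groups processed in descending mean order."""
    order = sorted(groups, key=lambda g: -means[g])
    idx = {g: groups.index(g) for g in groups}
    letter_sets: list[set] = []  # each set = groups sharing one letter
    for g in order:
        placed = False
        for s in letter_sets:
            if all(nsd[idx[g], idx[h]] for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant sets
    keep = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if t is not s):
            keep.append(s)
    keep.sort(key=lambda s: min(-means[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, keep):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in groups}


def environment_anova(
    adjusted: pd.DataFrame, trait: str, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of a trait across environments with Tukey HSD letters.

    Environments sharing a letter are not significantly different at
    ``alpha``.  Letters are assigned deterministically (groups ranked by
    mean) and are invariant to the input ordering of environments.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = adjusted[adjusted["trait"] == trait].dropna(subset=["value"])
    envs = sorted(df["env"].unique())
    if len(envs) < 2:
        raise ValueError("need >= 2 environments to compare")
    for e in envs:
        if (df["env"] == e).sum() < 2:
            raise ValueError(f"environment {e} has < 2 values")
    groups = [df.loc[df["env"] == e, "value"].to_numpy() for e in envs]
    f_stat, p_anova = stats.f_oneway(*groups)
    tuk = pairwise_tukeyhsd(df["value"].to_numpy(), df["env"].to_numpy(), alpha=alpha)
    k = len(envs)
    nsd = np.eye(k, dtype=bool)
    tuk_envs = list(tuk.groupsunique)
    for (i, j), reject in zip(
        [(i, j) for i in range(k) for j in range(i + 1, k)], tuk.reject
    ):
        a, b = envs.index(tuk_envs[i]), envs.index(tuk_envs[j])
        nsd[a, b] = nsd[b, a] = not reject
    means = {e: float(df.loc[df["env"] == e, "value"].mean()) for e in envs}
    letters = _letters_from_nsd(envs, nsd, means)
    return pd.DataFrame(
        {
            "env": envs,
            "mean": [means[e] for e in envs],
            "letter": [letters[e] for e in envs],
            "anova_F": f_stat,
            "anova_p": p_anova,
        }
    )
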