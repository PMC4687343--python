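"""Gene-wise KO-vs-WT differential expression with moderated t-statistics.

For each gene a two-group linear model is fitted within one stratum
(system x region): the effect is the mean log2 difference KO - WT, the
residual variance is pooled across the two groups, and gene-wise variances
are shrunk toward a common prior by the standard empirical-Bayes scheme.
Writing s_g^2 for the gene's residual variance on d_g degrees of freedom,
the hierarchical model s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_{d_g}/d_g with
1/sigma_g^2 ~ (1/(d_0 s_0^2)) chi^2_{d_0} gives the posterior variance

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and a moderated t = beta / sqrt(s_post^2 (1/n_KO + 1/n_WT)) on d_0 + d_g
degrees of freedom. The hyperparameters (d_0, s_0^2) are estimated by the
method of moments on log s^2 (digamma/trigamma matching with Newton
inversion of the trigamma function).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModeratedStats",
    "fit_genewise_model",
    "trigamma_inverse",
    "moderate_variances",
    "de_table",
    "select_de",
    "collapse_duplicates",
]

_D0_CAP = 1e6  # treated as an infinite prior (complete shrinkage) above this
_P_FLOOR = np.finfo(float).tiny  # keeps p in (0, 1]


@dataclass
class ModeratedStats:
    """Empirical-Bayes variance hyperparameters and posterior variances."""

    df_prior: float          # d0; np.inf when all variances coincide
    s2_prior: float          # s0^2
    s2_posterior: np.ndarray


def _group_columns(meta: pd.DataFrame, contrast: str, levels: tuple[str, str],
                   stratum: dict | None) -> tuple[pd.Index, pd.Index, str]:
    sel = meta
    desc = []
    if stratum:
        for key, val in stratum.items():
            sel = sel[sel[key] == val]
            desc.append(f"{key}={val}")
    label = ",".join(desc) or "all samples"
    g1 = sel.index[sel[contrast] == levels[0]]
    g2 = sel.index[sel[contrast] == levels[1]]
    for name, grp in zip(levels, (g1, g2)):
        if len(grp) < 2:
            raise ValueError(
                f"group {contrast}={name} has {len(grp)} samples in stratum "
                f"({label}); need >= 2")
    return g1, g2, label


def fit_genewise_model(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str = "genotype",
    levels: tuple[str, str] = ("KO", "WT"),
    stratum: dict | None = None,
) -> pd.DataFrame:
    """Per-gene effect, pooled residual variance and degrees of freedom.

    ``levels = (test, reference)``: the effect is mean(test) - mean(reference).
    ``stratum`` restricts to metadata rows matching e.g.
    ``{"system": "culture", "region": "cortex"}``.
    """
    g1, g2, _ = _group_columns(meta, contrast, levels, stratum)
    x1 = expr[g1].to_numpy(float)
    x2 = expr[g2].to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    beta = x1.mean(axis=1) - x2.mean(axis=1)
    ss = (((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    df = n1 + n2 - 2
    return pd.DataFrame({
        "beta_hat": beta,
        "s2": ss / df,
        "df_residual": df,
        "n_test": n1,
        "n_ref": n2,
    }, index=expr.index)


def trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the asymptotic start y ~ 1/x and the monotone update on 1/y;
    converges in a handful of iterations for any positive x.
    """
    x = np.asarray(x, float)
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def moderate_variances(s2: np.ndarray, df: np.ndarray | float) -> ModeratedStats:
    """Estimate (d0, s0^2) from the gene-wise variances and shrink.

    Method of moments on z = log s^2: E z = log sigma^2 + digamma(df/2)
    - log(df/2), Var z = trigamma(df/2) + trigamma(d0/2). If the observed
    spread of z does not exceed the chi-square sampling noise, d0 is
    infinite and every posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    if s2.size < 10:
        warnings.warn("fewer than 10 genes: falling back to ordinary t (d0=0)")
        return ModeratedStats(0.0, float(np.median(s2)), s2.copy())

    ok = s2 > 0
    if not ok.any():
        return ModeratedStats(np.inf, 0.0, np.zeros_like(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df[ok] / 2.0).mean()
    if evar <= 0 or np.allclose(s2[ok], s2[ok][0]):
        d0 = np.inf
        s0 = float(np.exp(emean)) if not np.allclose(s2[ok], s2[ok][0]) \
            else float(s2[ok][0])
        return ModeratedStats(d0, s0, np.full_like(s2, s0))
    d0 = float(2.0 * trigamma_inverse(np.array([evar]))[0])
    if d0 > _D0_CAP:
        s0 = float(np.exp(emean))
        return ModeratedStats(np.inf, s0, np.full_like(s2, s0))
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return ModeratedStats(d0, s0, post)


def de_table(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: str = "genotype",
    levels: tuple[str, str] = ("KO", "WT"),
    stratum: dict | None = None,
    moderate: bool = True,
) -> pd.DataFrame:
    """Full differential-expression table for one stratum.

    Columns: beta_hat (log2FC, test minus reference), s2, df_residual,
    t_ordinary, s2_posterior, df_prior, s2_prior, t_moderated, p_value
    (two-sided) and direction ('up'/'down' by the sign of beta_hat).
    """
    fit = fit_genewise_model(expr, meta, contrast, levels, stratum)
    n1 = fit["n_test"].iloc[0]
    n2 = fit["n_ref"].iloc[0]
    scale = 1.0 / n1 + 1.0 / n2
    s2 = fit["s2"].to_numpy()
    df = fit["df_residual"].to_numpy(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = fit["beta_hat"].to_numpy() / np.sqrt(s2 * scale)

    if moderate:
        mod = moderate_variances(s2, df)
    else:
        mod = ModeratedStats(0.0, float(np.median(s2)), s2.copy())

    beta = fit["beta_hat"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta / np.sqrt(mod.s2_posterior * scale)
    df_total = df + (mod.df_prior if np.isfinite(mod.df_prior) else np.inf)

    # degenerate rows: zero posterior variance
    zero = mod.s2_posterior <= 0
    t_mod = np.where(zero & (beta == 0), 0.0, t_mod)
    t_mod = np.where(zero & (beta > 0), np.inf, t_mod)
    t_mod = np.where(zero & (beta < 0), -np.inf, t_mod)

    if np.all(np.isinf(df_total)):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, _P_FLOOR, 1.0)

    out = fit.drop(columns=["n_test", "n_ref"]).copy()
    out["t_ordinary"] = np.where(np.isnan(t_ord) & (beta == 0), 0.0, t_ord)
    out["s2_posterior"] = mod.s2_posterior
    out["df_prior"] = mod.df_prior
    out["s2_prior"] = mod.s2_prior
    out["t_moderated"] = t_mod
    out["p_value"] = p
    out["direction"] = np.where(beta >= 0, "up", "down")
    return out


def select_de(
    de: pd.DataFrame, alpha: float = 0.05, adjust: str | None = None
) -> tuple[list, list, list]:
    """Partition genes significant at ``alpha`` into (up, down, combined).

    ``adjust='bh'`` applies Benjamini-Hochberg before thresholding; the
    default (None) uses unadjusted p-values, the pipeline's significance
    rule.
    """
    p = de["p_value"].to_numpy(float)
    if adjust == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1.0)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(p)
        q[order] = np.minimum(adj, 1.0)
        p = q
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sig = p < alpha
    up = de.index[sig & (de["direction"] == "up")].tolist()
    down = de.index[sig & (de["direction"] == "down")].tolist()
    return up, down, up + down


def collapse_duplicates(expr: pd.DataFrame, meta: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical duplicate columns into their source columns.

    Duplicates are metadata rows whose ``source_id`` names another sample.
    """
    if "source_id" not in meta.columns:
        return expr, meta
    dup = meta["source_id"].fillna("").astype(str) != ""
    out = expr.copy()
    for did, src in meta.loc[dup, "source_id"].items():
        out[src] = (out[src] + out[did]) / 2.0
    keep = meta.index[~dup]
    return out[list(keep)], meta.loc[keep]
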