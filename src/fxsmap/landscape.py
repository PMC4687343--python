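"""Transcriptomic landscape: rank-standardized PCA and genotype separation.

The whole-dataset view places each sample in gene space after replacing
every sample's values by within-sample ranks and standardizing each
sample to mean zero / variance one. PCA of the samples then exposes the
dominant axes of variation (culture-vs-tissue, then brain region), and
the genotype effect in each stratum is summarized as the absolute
KO-vs-WT centroid distance along each of the first two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PCAResult", "rank_standardize", "pca", "centroid_separation"]


@dataclass
class PCAResult:
    """Scores (observations x components), loadings and variance fractions.

    ``variance_fraction[k]`` is sigma_k^2 / sum_i sigma_i^2 over *all*
    singular values of the centered matrix, so the retained fractions are
    nonincreasing and sum to <= 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


def rank_standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """Within each sample column: replace values by average ranks, then
    center and scale the column to mean 0, variance 1 (ddof=1).

    Invariant under any strictly monotone per-column transform. Raises for
    constant columns (undefined scaling) and matrices with < 2 rows.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 rows per column to rank-standardize")
    ranks = np.apply_along_axis(sps.rankdata, 0, expr.to_numpy(float))
    sd = ranks.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = expr.columns[sd == 0].tolist()
        raise ValueError(f"constant column(s) {bad[:5]}: scaling undefined")
    z = (ranks - ranks.mean(axis=0)) / sd
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def pca(matrix: pd.DataFrame, n_components: int = 2, center: bool = True
        ) -> PCAResult:
    """PCA of the rows of ``matrix`` (observations x variables) via SVD.

    The sign of each component is fixed so its largest-magnitude loading
    is positive, making stored scores reproducible. For a samples-in-gene-
    space analysis pass the expression matrix transposed.
    """
    k = int(n_components)
    if k < 1 or k > min(matrix.shape):
        raise ValueError(f"n_components={k} out of range for shape {matrix.shape}")
    x = matrix.to_numpy(float)
    if center:
        x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    total = float((s ** 2).sum())
    frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=matrix.index, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=matrix.columns, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=frac[:k])


def centroid_separation(
    result: PCAResult,
    meta: pd.DataFrame,
    contrast: str = "genotype",
    levels: tuple[str, str] = ("KO", "WT"),
    strata: tuple[str, ...] = ("system", "region"),
) -> pd.DataFrame:
    """|KO centroid - WT centroid| along PC1 and PC2 per stratum.

    Strata missing either genotype are skipped with a warning. Returns a
    frame indexed by the stratum columns with ``dPC1``/``dPC2``.
    """
    scores = result.scores
    meta = meta.loc[scores.index]
    rows = []
    for key, sub in meta.groupby(list(strata), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        a = scores.loc[sub.index[sub[contrast] == levels[0]]]
        b = scores.loc[sub.index[sub[contrast] == levels[1]]]
        if a.empty or b.empty:
            warnings.warn(f"stratum {dict(zip(strata, key))} lacks a "
                          f"{contrast} group; skipped")
            continue
        diff = (a.mean(axis=0) - b.mean(axis=0)).abs()
        rows.append({**dict(zip(strata, key)),
                     "dPC1": float(diff.get("PC1", np.nan)),
                     "dPC2": float(diff.get("PC2", np.nan))})
    out = pd.DataFrame(rows, columns=[*strata, "dPC1", "dPC2"])
    return out.set_index(list(strata))
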