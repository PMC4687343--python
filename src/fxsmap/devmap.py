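"""Human developmental transcriptome map and cross-species projection.

Pipeline for one brain region of the staged human series:

1. standardize every sample (column) to mean 0 / variance 1 across genes;
2. PCA of genes in sample space (each gene is a point in R^{n_samples});
3. k-means with k = 3 on the first two gene scores, giving three
   co-expression clusters;
4. label the clusters early / mid / late by the peak stage of each
   cluster's median temporal profile;
5. project mouse differentially-expressed gene lists (through a homology
   map) onto the clusters and measure over-representation in the early
   cluster as an odds ratio with a Woolf 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .enrichment import OverlapStats, or_ci_from_table
from .landscape import PCAResult, pca

logger = logging.getLogger(__name__)

__all__ = [
    "DevClusterModel",
    "ProjectionResult",
    "standardize_samples",
    "gene_space_pca",
    "kmeans3",
    "cluster_median_profiles",
    "assign_temporal_labels",
    "build_dev_model",
    "project_de_genes",
    "early_enrichment_or",
    "early_or_from_counts",
    "percentages",
]

LABELS = ("early", "mid", "late")


def standardize_samples(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to mean 0, variance 1 (ddof=1) across genes."""
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes to standardize samples")
    x = expr.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = expr.columns[sd == 0].tolist()
        raise ValueError(f"constant sample column(s) {bad[:5]}")
    z = (x - x.mean(axis=0)) / sd
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def gene_space_pca(expr: pd.DataFrame, n_components: int = 2,
                   center_genes: bool = True) -> PCAResult:
    """PCA with genes as observations and samples as variables.

    ``expr`` should already be sample-standardized; scores are per gene.
    With ``center_genes`` (default) each gene's mean across samples is
    removed first, so the leading components capture temporal *shape*
    rather than overall expression level — without it the first component
    is dominated by per-gene baseline differences and the temporal
    contrasts are pushed into later components.
    """
    if expr.shape[1] < n_components:
        raise ValueError("fewer samples than requested components")
    if center_genes:
        x = expr.to_numpy(float)
        expr = pd.DataFrame(x - x.mean(axis=1, keepdims=True),
                            index=expr.index, columns=expr.columns)
    return pca(expr, n_components=n_components)


def kmeans3(scores: pd.DataFrame, seed: int = 0, n_restarts: int = 20
            ) -> pd.Series:
    """k=3 Lloyd k-means on the score matrix; best of ``n_restarts`` starts.

    Deterministic given ``seed``. Raises if fewer than 3 distinct points.
    """
    pts = scores.to_numpy(float)
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("fewer than 3 distinct points: k=3 is degenerate")
    km = KMeans(n_clusters=3, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    labels = km.fit_predict(pts)
    return pd.Series(labels, index=scores.index, name="cluster")


def cluster_median_profiles(
    standardized: pd.DataFrame,
    stages: pd.Series,
    assignments: pd.Series,
) -> pd.DataFrame:
    """Per-cluster median of member genes' per-stage mean expression.

    Returns clusters x stages; input should be the sample-standardized
    matrix used for the map.
    """
    stages = stages.loc[standardized.columns].astype(int)
    stage_means = standardized.T.groupby(stages).mean().T  # genes x stages
    prof = stage_means.groupby(assignments.loc[stage_means.index]).median()
    prof.index.name = "cluster"
    prof.columns.name = "stage"
    return prof.sort_index()


def assign_temporal_labels(profiles: pd.DataFrame) -> dict[int, str]:
    """Map cluster index -> 'early'/'mid'/'late' by peak stage.

    Clusters are ordered by the argmax stage of their median profile; ties
    are broken by the earlier center of mass of the (min-shifted) profile.
    Two clusters identical in both are a degenerate map and raise.
    """
    stages = profiles.columns.to_numpy(float)
    keys = {}
    for cl, prof in profiles.iterrows():
        v = prof.to_numpy(float)
        w = v - v.min()
        com = float((stages * w).sum() / w.sum()) if w.sum() > 0 else float(
            stages.mean())
        keys[cl] = (float(stages[int(np.argmax(v))]), com)
    vals = sorted(keys.values())
    if len(set(vals)) < len(vals):
        raise ValueError("degenerate temporal profiles: identical peak stage "
                         "and center of mass")
    order = sorted(keys, key=keys.get)
    return {cl: LABELS[i] for i, cl in enumerate(order)}


@dataclass
class DevClusterModel:
    """A labeled k=3 temporal clustering of one region's genes."""

    assignments: pd.Series               # gene -> cluster index {0,1,2}
    labels: dict[int, str]               # cluster index -> early/mid/late
    median_profiles: pd.DataFrame        # clusters x stages
    scores: pd.DataFrame                 # gene PC scores
    variance_fraction: np.ndarray
    region: str = ""

    @property
    def universe(self) -> pd.Index:
        return self.assignments.index

    def label_of(self) -> pd.Series:
        """Per-gene early/mid/late label."""
        return self.assignments.map(self.labels)

    def cluster_totals(self) -> pd.Series:
        """Universe gene counts per temporal label, ordered early/mid/late."""
        counts = self.label_of().value_counts()
        return counts.reindex(list(LABELS), fill_value=0)

    def proportions(self) -> pd.Series:
        tot = self.cluster_totals()
        return tot / tot.sum()


def build_dev_model(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    region: str | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    feature_space: str = "pca",
) -> DevClusterModel:
    """Fit the developmental map for one region of the staged series.

    ``feature_space='pca'`` clusters the first two gene-space PC scores
    (the map as displayed); ``'profile'`` clusters full standardized
    stage-mean profiles instead.
    """
    if region is not None:
        cols = meta.index[meta["region"] == region]
        if len(cols) == 0:
            raise ValueError(f"no samples for region {region!r}")
        expr = expr[list(cols)]
        meta = meta.loc[cols]
    std = standardize_samples(expr)
    res = gene_space_pca(std, n_components=2)
    if feature_space == "pca":
        feats = res.scores
    elif feature_space == "profile":
        stages = meta["stage"].loc[std.columns].astype(int)
        feats = std.T.groupby(stages).mean().T
    else:
        raise ValueError(f"unknown feature_space {feature_space!r}")
    assign = kmeans3(feats, seed=seed, n_restarts=n_restarts)
    profiles = cluster_median_profiles(std, meta["stage"], assign)
    labels = assign_temporal_labels(profiles)
    return DevClusterModel(assignments=assign, labels=labels,
                           median_profiles=profiles, scores=res.scores,
                           variance_fraction=res.variance_fraction,
                           region=region or "")


@dataclass
class ProjectionResult:
    """Cluster membership of projected DE gene lists.

    ``counts``/``percent`` are lists x (early, mid, late); ``totals`` are
    whole-universe cluster sizes; ``dropped`` counts list genes that did
    not map into the model universe.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    totals: pd.Series
    dropped: dict[str, int] = field(default_factory=dict)


def percentages(counts: Sequence[float], ndigits: int = 0) -> np.ndarray:
    """Counts -> percent of their sum, rounded to ``ndigits`` decimals."""
    arr = np.asarray(counts, float)
    tot = arr.sum()
    if tot == 0:
        return np.zeros_like(arr)
    return np.round(100.0 * arr / tot, ndigits)


def project_de_genes(
    de_lists: Mapping[str, Collection[int]],
    model: DevClusterModel,
    homology: Mapping[int, int] | None = None,
    percent_digits: int = 0,
) -> ProjectionResult:
    """Count each DE list's genes per temporal cluster.

    ``homology`` (mouse gene -> model gene ID) is applied before lookup
    when given; genes outside the model universe are dropped with a logged
    count. Percentages are count / list-total x 100.
    """
    gene_label = model.label_of()
    uni = set(model.universe)
    count_rows, pct_rows, dropped = {}, {}, {}
    for name, genes in de_lists.items():
        mapped = [homology.get(g) if homology else g for g in set(genes)]
        inside = [g for g in mapped if g in uni]
        dropped[name] = len(mapped) - len(inside)
        if dropped[name]:
            logger.info("list %s: %d genes outside the universe dropped",
                        name, dropped[name])
        if not inside:
            logger.warning("list %s maps to no universe genes", name)
        lab = gene_label.loc[inside]
        counts = lab.value_counts().reindex(list(LABELS), fill_value=0)
        count_rows[name] = counts
        pct_rows[name] = pd.Series(
            percentages(counts.to_numpy(), percent_digits), index=list(LABELS))
    counts = pd.DataFrame(count_rows).T.reindex(columns=list(LABELS))
    pct = pd.DataFrame(pct_rows).T.reindex(columns=list(LABELS))
    return ProjectionResult(counts=counts, percent=pct,
                            totals=model.cluster_totals(), dropped=dropped)


def early_or_from_counts(list_counts: Sequence[int],
                         totals: Sequence[int]) -> OverlapStats:
    """Early-cluster enrichment OR from (early, mid, late) counts.

    ``list_counts`` are the DE list's per-cluster counts and ``totals`` the
    whole-universe cluster sizes (DE genes included). The 2x2 table is
    a = DE in early, b = DE elsewhere, c = remaining early genes,
    d = remaining genes elsewhere.
    """
    lc = [int(x) for x in list_counts]
    tot = [int(x) for x in totals]
    if len(lc) != 3 or len(tot) != 3:
        raise ValueError("expected three per-cluster counts")
    a = lc[0]
    b = lc[1] + lc[2]
    c = tot[0] - a
    d = (tot[1] + tot[2]) - b
    if c < 0 or d < 0:
        raise ValueError("list counts exceed cluster totals")
    return or_ci_from_table(a, b, c, d)


def early_enrichment_or(projection: ProjectionResult,
                        list_name: str) -> OverlapStats:
    """Early-cluster enrichment OR for one projected list."""
    row = projection.counts.loc[list_name]
    return early_or_from_counts(row.to_numpy(), projection.totals.to_numpy())
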