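"""Synthetic expression datasets with the structure the analysis assumes.

Two generators are provided:

* :func:`simulate_mouse_dataset` — a 42-sample Fmr1-KO/WT design
  (2 genotypes x {cortex, hippocampus} x {culture, tissue}) in which
  between-sample variance is dominated by culture-vs-tissue, then brain
  region, then genotype; the genotype effect is larger in culture than in
  tissue, and a designated "Fmr1" gene is knocked down ~2-fold in every KO
  column.
* :func:`simulate_human_devseries` — a human brain developmental series
  (15 stages x 2 regions) in which every gene follows one of three
  temporal archetypes: early-peaking, mid-peaking or late-rising.

Both return ``(expression, metadata, truth)`` where *truth* records the
planted effects for recovery tests. :func:`write_fixture_bundle` writes a
complete on-disk fixture (expression, metadata, annotation, homology,
gene sets, curated lists, JSON manifest) for end-to-end runs.

All noise is Gaussian on the log2 scale and all randomness derives from
the config seeds, so outputs are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as fio

__all__ = [
    "MouseSimConfig",
    "HumanSimConfig",
    "SimTruth",
    "ARCHETYPES",
    "archetype_curves",
    "simulate_mouse_dataset",
    "simulate_human_devseries",
    "write_fixture_bundle",
    "HOMOLOGY_OFFSET",
]

GENOTYPES = ("KO", "WT")
REGIONS = ("cortex", "hippocampus")
SYSTEMS = ("culture", "tissue")
ARCHETYPES = ("early", "mid", "late")

#: human gene ID = mouse gene ID + this constant in synthetic homology tables
HOMOLOGY_OFFSET = 50000

#: replicate counts per (region, system) cell, per genotype, of the emulated
#: design: primary cortex n=5, primary hippocampus n=6, cortical culture n=5,
#: hippocampal culture n=5 -> 2 x 21 = 42 samples.
DESIGN_42 = {
    ("cortex", "tissue"): 5,
    ("hippocampus", "tissue"): 6,
    ("cortex", "culture"): 5,
    ("hippocampus", "culture"): 5,
}


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass
class MouseSimConfig:
    """Parameters of the mouse KO/WT generator.

    All effect sizes are SDs of per-gene mean shifts in log2 units. The
    ordering ``delta_system > delta_region > max(genotype deltas)`` enforces
    the variance hierarchy the landscape analysis assumes.

    ``genotype_alignment`` is the fraction of each planted genotype effect
    aligned with the culture-vs-tissue gene axis (the per-gene marginal SD
    stays ``delta_genotype_*``); it emulates the observed coupling between
    the KO signature and the maturation axis, which is what makes the
    genotype contrast visible on PC1.
    """

    n_genes: int = 2000
    n_replicates_per_cell: int | Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DESIGN_42)
    )
    duplicate_fraction: float = 0.0
    sigma_noise: float = 0.5
    delta_system: float = 2.0
    delta_region: float = 1.0
    delta_genotype_culture: float = 0.6
    delta_genotype_tissue: float = 0.15
    frac_de_culture: float = 0.15
    frac_de_tissue: float = 0.05
    fmr1_log2fc: float = -1.0
    genotype_alignment: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 2, "n_genes must be >= 2")
        for name in ("sigma_noise", "delta_system", "delta_region",
                     "delta_genotype_culture", "delta_genotype_tissue",
                     "baseline_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("duplicate_fraction", "frac_de_culture", "frac_de_tissue"):
            _require(0.0 <= getattr(self, name) <= 1.0,
                     f"{name} must be in [0, 1]")
        _require(0.0 <= self.genotype_alignment <= 1.0,
                 "genotype_alignment must be in [0, 1]")
        gmax = max(self.delta_genotype_culture, self.delta_genotype_tissue)
        # variance hierarchy; equalities only allowed in the all-zero
        # degenerate (noise-free) case
        _require(self.delta_system >= self.delta_region >= gmax and
                 (self.delta_region == 0 or self.delta_system > self.delta_region) and
                 (gmax == 0 or self.delta_region > gmax),
                 "delta_system > delta_region > genotype deltas is required")
        _require(self.delta_genotype_culture > self.delta_genotype_tissue or
                 self.delta_genotype_culture == self.delta_genotype_tissue == 0,
                 "delta_genotype_culture must exceed delta_genotype_tissue")
        if isinstance(self.n_replicates_per_cell, Mapping):
            for key in DESIGN_42:
                _require(key in self.n_replicates_per_cell and
                         int(self.n_replicates_per_cell[key]) >= 2,
                         f"n_replicates_per_cell missing or < 2 for {key}")
        else:
            _require(int(self.n_replicates_per_cell) >= 2,
                     "n_replicates_per_cell must be >= 2")

    def cell_count(self, region: str, system: str) -> int:
        if isinstance(self.n_replicates_per_cell, Mapping):
            return int(self.n_replicates_per_cell[(region, system)])
        return int(self.n_replicates_per_cell)


@dataclass
class HumanSimConfig:
    """Parameters of the human developmental-series generator.

    ``cluster_proportions`` are the early/mid/late archetype frequencies;
    ``amplitude`` is the peak-to-baseline half-range of the archetype curves
    in log2 units (each gene gets a uniform 0.8-1.2x multiplier).
    """

    n_genes: int = 2000
    n_stages: int = 15
    samples_per_stage: int = 3
    regions: tuple[str, ...] = ("NCX", "HIP")
    cluster_proportions: tuple[float, float, float] = (0.40, 0.30, 0.30)
    amplitude: float = 1.0
    sigma_noise: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    gene_id_offset: int = HOMOLOGY_OFFSET
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 3, "n_genes must be >= 3")
        _require(self.n_stages >= 5, "n_stages must be >= 5")
        _require(self.samples_per_stage >= 1, "samples_per_stage must be >= 1")
        _require(abs(sum(self.cluster_proportions) - 1.0) < 1e-6,
                 "cluster_proportions must sum to 1")
        _require(all(p >= 0 for p in self.cluster_proportions),
                 "cluster_proportions must be >= 0")
        for name in ("amplitude", "sigma_noise", "baseline_sd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        curves = archetype_curves(self.n_stages)
        peaks = curves.to_numpy().argmax(axis=1) + 1
        _require(len(set(peaks)) == 3, "archetype argmax stages must differ")
        if self.n_stages == 15:
            early, mid, late = peaks
            _require(early <= 6 and 7 <= mid <= 11 and late >= 12,
                     "archetype peaks must fall in the early/mid/late windows")


def archetype_curves(n_stages: int = 15) -> pd.DataFrame:
    """Default temporal archetype mean curves (rows early/mid/late x stages).

    Piecewise-linear, amplitude 1: the early curve rises to a peak at ~40% of
    the series (stage 6 of 15) then falls; the mid curve peaks at ~60%
    (stage 9); the late curve rises to ~80% (stage 12) and stays high.
    """
    s = np.arange(1, n_stages + 1, dtype=float)
    p_early = round(0.4 * n_stages)
    p_mid = round(0.6 * n_stages)
    p_late = round(0.8 * n_stages)
    curves = np.vstack([
        np.interp(s, [1, p_early, n_stages], [-1.0, 1.0, -1.0]),
        np.interp(s, [1, p_mid, n_stages], [-1.0, 1.0, -1.0]),
        np.interp(s, [1, p_late, n_stages], [-1.0, 1.0, 1.0]),
    ])
    return pd.DataFrame(curves, index=list(ARCHETYPES),
                        columns=pd.RangeIndex(1, n_stages + 1, name="stage"))


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``genes`` holds per-gene planted quantities (log2 fold changes by system
    for the mouse generator, archetype labels for the human one); ``design``
    is the emitted sample table; ``params`` records scalar truth parameters.
    """

    genes: pd.DataFrame
    design: pd.DataFrame
    params: dict


def simulate_mouse_dataset(
    config: MouseSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the KO/WT mouse design; see the module docstring.

    Returns ``(expression, metadata, truth)``; expression rows are integer
    gene IDs starting at 101, with the first gene designated "Fmr1" and
    shifted by ``fmr1_log2fc`` in every KO column.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = np.arange(101, 101 + g)
    fmr1_id = int(gene_ids[0])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, g)
    v_sys = rng.normal(0.0, cfg.delta_system, g)    # +1/2 culture, -1/2 tissue
    v_reg = rng.normal(0.0, cfg.delta_region, g)    # +1/2 cortex, -1/2 hippocampus

    def planted_effect(frac: float, delta: float) -> tuple[np.ndarray, np.ndarray]:
        n_de = int(round(frac * g))
        # never plant a random effect on the Fmr1 row (index 0)
        de_idx = rng.choice(np.arange(1, g), size=min(n_de, g - 1), replace=False)
        lfc = np.zeros(g)
        if delta > 0 and len(de_idx):
            a = cfg.genotype_alignment
            aligned = v_sys[de_idx] / cfg.delta_system if cfg.delta_system else 0.0
            lfc[de_idx] = delta * (a * aligned +
                                   np.sqrt(1.0 - a * a) * rng.standard_normal(len(de_idx)))
        mask = np.zeros(g, bool)
        mask[de_idx] = True
        return lfc, mask

    lfc_culture, de_culture = planted_effect(cfg.frac_de_culture,
                                             cfg.delta_genotype_culture)
    lfc_tissue, de_tissue = planted_effect(cfg.frac_de_tissue,
                                           cfg.delta_genotype_tissue)
    lfc_culture[0] = cfg.fmr1_log2fc
    lfc_tissue[0] = cfg.fmr1_log2fc
    lfc_by_system = {"culture": lfc_culture, "tissue": lfc_tissue}

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for genotype in GENOTYPES:
        for system in SYSTEMS:
            for region in REGIONS:
                mean = (baseline
                        + (0.5 if system == "culture" else -0.5) * v_sys
                        + (0.5 if region == "cortex" else -0.5) * v_reg)
                if genotype == "KO":
                    mean = mean + lfc_by_system[system]
                for i in range(cfg.cell_count(region, system)):
                    sid = f"{genotype}_{region[:2]}_{system[:2]}_{i + 1}"
                    columns[sid] = mean + rng.normal(0.0, cfg.sigma_noise, g)
                    meta_rows.append({"sample_id": sid, "genotype": genotype,
                                      "system": system, "region": region,
                                      "source_id": ""})

    # technical duplicates: a fraction of columns re-emitted with fresh noise
    base_ids = list(columns)
    n_dup = int(round(cfg.duplicate_fraction * len(base_ids)))
    dup_ids = list(rng.choice(base_ids, size=n_dup, replace=False)) if n_dup else []
    for sid in dup_ids:
        did = sid + "_d"
        columns[did] = columns[sid] + rng.normal(0.0, cfg.sigma_noise / 2.0, g)
        src = next(r for r in meta_rows if r["sample_id"] == sid)
        meta_rows.append({**src, "sample_id": did, "source_id": sid})

    expr = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_genes = pd.DataFrame({
        "lfc_culture": lfc_culture,
        "lfc_tissue": lfc_tissue,
        "is_de_culture": de_culture,
        "is_de_tissue": de_tissue,
    }, index=expr.index)
    truth_genes.loc[fmr1_id, ["is_de_culture", "is_de_tissue"]] = True
    truth = SimTruth(genes=truth_genes, design=meta.reset_index(),
                     params={"fmr1_gene_id": fmr1_id,
                             "fmr1_log2fc": cfg.fmr1_log2fc,
                             "seed": cfg.seed})
    return expr, meta, truth


def simulate_human_devseries(
    config: HumanSimConfig,
    forced_labels: Mapping[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the staged human series; see the module docstring.

    ``forced_labels`` optionally pins archetype indices (0=early, 1=mid,
    2=late) for chosen gene IDs, used to plant cross-species structure in
    fixture bundles; unlisted genes are drawn from ``cluster_proportions``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = np.arange(101, 101 + g) + cfg.gene_id_offset
    curves = archetype_curves(cfg.n_stages).to_numpy()

    labels = rng.choice(3, size=g, p=np.asarray(cfg.cluster_proportions))
    if forced_labels:
        id_pos = {int(gid): i for i, gid in enumerate(gene_ids)}
        for gid, lab in forced_labels.items():
            if int(gid) in id_pos:
                labels[id_pos[int(gid)]] = int(lab)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, g)
    amp = cfg.amplitude * rng.uniform(0.8, 1.2, g)
    profile = baseline[:, None] + amp[:, None] * curves[labels]  # genes x stages

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for region in cfg.regions:
        for stage in range(1, cfg.n_stages + 1):
            for i in range(cfg.samples_per_stage):
                sid = f"{region}_s{stage:02d}_{i + 1}"
                noise = rng.normal(0.0, cfg.sigma_noise, g)
                columns[sid] = profile[:, stage - 1] + noise
                meta_rows.append({"sample_id": sid, "region": region,
                                  "stage": stage})

    expr = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_genes = pd.DataFrame({
        "archetype_index": labels,
        "archetype": [ARCHETYPES[k] for k in labels],
    }, index=expr.index)
    truth = SimTruth(genes=truth_genes, design=meta.reset_index(),
                     params={"seed": cfg.seed, "n_stages": cfg.n_stages})
    return expr, meta, truth


# ---------------------------------------------------------------------------
# fixture bundle


def _planted_gene_sets(truth: SimTruth, rng: np.random.Generator) -> dict[str, list[int]]:
    genes = truth.genes
    ids = genes.index.to_numpy()
    de_culture = ids[genes["is_de_culture"].to_numpy(bool)]
    non_de = ids[~genes["is_de_culture"].to_numpy(bool)]
    sets: dict[str, list[int]] = {}
    n_hit = min(40, len(de_culture))
    n_fill = min(50 - n_hit, len(non_de))
    hits = rng.choice(de_culture, size=n_hit, replace=False)
    fill = rng.choice(non_de, size=n_fill, replace=False)
    sets["planted_de_culture"] = sorted(int(x) for x in np.concatenate([hits, fill]))
    for k in range(1, 6):
        sets[f"random_set_{k}"] = sorted(
            int(x) for x in rng.choice(ids, size=min(50, len(ids)),
                                       replace=False))
    return sets


def _curated_lists(truth: SimTruth, rng: np.random.Generator) -> dict[str, list[int]]:
    """Three curated-list stand-ins (MGI-like, SFARI-like, FMRP-target-like):
    each enriched for planted down-regulated culture DE genes."""
    genes = truth.genes
    ids = genes.index.to_numpy()
    down = ids[(genes["is_de_culture"] & (genes["lfc_culture"] < 0)).to_numpy(bool)]
    rest = ids[~genes["is_de_culture"].to_numpy(bool)]
    lists = {}
    for name in ("mgi_like", "sfari_like", "fmrp_targets_like"):
        n_hit = min(60, len(down))
        n_pad = min(100 - n_hit, len(rest))
        hit = rng.choice(down, size=n_hit, replace=False)
        pad = rng.choice(rest, size=n_pad, replace=False)
        lists[name] = sorted(int(x) for x in np.concatenate([hit, pad]))
    return lists


def write_fixture_bundle(
    dir_path,
    mouse_cfg: MouseSimConfig | None = None,
    human_cfg: HumanSimConfig | None = None,
    early_bias_up_culture: float = 0.7,
) -> dict:
    """Write a complete text fixture bundle and return its manifest.

    Besides the two expression/metadata pairs this writes a probe
    annotation table (with a few multi-ID and unannotated probes to
    exercise the collapsing rules), an identity-with-offset homology
    table, a GMT collection with one planted enriched set, three curated
    gene lists, and ``manifest.json``. ``early_bias_up_culture`` is the
    probability that a gene up-regulated in KO culture is assigned the
    early human archetype, planting the cross-species developmental
    signal the projection stage measures.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    mouse_cfg = mouse_cfg or MouseSimConfig()
    human_cfg = human_cfg or HumanSimConfig(n_genes=mouse_cfg.n_genes,
                                            seed=mouse_cfg.seed + 1)
    rng = np.random.default_rng(mouse_cfg.seed + 1_000_003)

    m_expr, m_meta, m_truth = simulate_mouse_dataset(mouse_cfg)

    up_culture = m_truth.genes.index[
        (m_truth.genes["is_de_culture"] & (m_truth.genes["lfc_culture"] > 0))]
    forced = {}
    p = early_bias_up_culture
    rest = (1.0 - p) / 2.0
    for gid in up_culture:
        forced[int(gid) + human_cfg.gene_id_offset] = int(
            rng.choice(3, p=[p, rest, rest]))
    h_expr, h_meta, h_truth = simulate_human_devseries(human_cfg, forced_labels=forced)

    files: dict[str, dict] = {}

    def _write(name: str, writer) -> None:
        path = out / name
        try:
            writer(path)
        except OSError as exc:
            raise OSError(f"failed writing fixture file {path}: {exc}") from exc
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files[name] = {"sha256": digest}

    _write("mouse_expression.tsv", lambda p: fio.write_expression_tsv(m_expr, p))
    _write("mouse_metadata.tsv",
           lambda p: m_meta.to_csv(p, sep="\t", index_label="sample_id"))
    _write("human_expression.tsv", lambda p: fio.write_expression_tsv(h_expr, p))
    _write("human_metadata.tsv",
           lambda p: h_meta.to_csv(p, sep="\t", index_label="sample_id"))
    files["mouse_expression.tsv"].update(rows=int(m_expr.shape[0]),
                                         cols=int(m_expr.shape[1]))
    files["human_expression.tsv"].update(rows=int(h_expr.shape[0]),
                                         cols=int(h_expr.shape[1]))

    # probe annotation: one probe per gene, plus collapse-rule exercisers
    ann_rows = [{"probe_id": f"p{gid}", "gene_ids": str(gid)}
                for gid in m_expr.index]
    first, second = int(m_expr.index[0]), int(m_expr.index[1])
    ann_rows.append({"probe_id": "p_multi", "gene_ids": f"{second},{first}"})
    ann_rows.append({"probe_id": "p_orphan", "gene_ids": ""})
    _write("annotation.tsv",
           lambda p: pd.DataFrame(ann_rows).to_csv(p, sep="\t", index=False))

    hom = pd.DataFrame({
        "human_id": [int(g) + human_cfg.gene_id_offset for g in m_expr.index],
        "mouse_id": [int(g) for g in m_expr.index],
    })
    _write("homology.tsv", lambda p: hom.to_csv(p, sep="\t", index=False))

    gene_sets = _planted_gene_sets(m_truth, rng)
    _write("genesets.gmt", lambda p: fio.write_gmt(gene_sets, p))
    for name, members in _curated_lists(m_truth, rng).items():
        _write(f"list_{name}.txt",
               lambda p, mem=members: p.write_text("\n".join(map(str, mem)) + "\n"))

    manifest = {
        "files": files,
        "mouse": {"n_genes": mouse_cfg.n_genes, "seed": mouse_cfg.seed,
                  "fmr1_gene_id": m_truth.params["fmr1_gene_id"],
                  "fmr1_log2fc": mouse_cfg.fmr1_log2fc,
                  "n_samples": int(m_expr.shape[1])},
        "human": {"n_genes": human_cfg.n_genes, "seed": human_cfg.seed,
                  "n_stages": human_cfg.n_stages,
                  "gene_id_offset": human_cfg.gene_id_offset,
                  "early_bias_up_culture": early_bias_up_culture},
        "planted_sets": {k: len(v) for k, v in gene_sets.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    # ground truth for recovery tests rides along as TSV
    m_truth.genes.to_csv(out / "mouse_truth.tsv", sep="\t", index_label="gene_id")
    h_truth.genes.to_csv(out / "human_truth.tsv", sep="\t", index_label="gene_id")
    return manifest
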