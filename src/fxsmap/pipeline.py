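"""End-to-end orchestration: simulate/load -> landscape -> DE -> enrichment
-> developmental projection, with a machine-readable JSON report.

A :class:`PipelineConfig` names either on-disk inputs or simulation
configs for the mouse and human datasets (exactly one source each). The
run writes stage TSVs plus ``report.json`` under the output directory;
all randomness derives from the config seeds, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import devmap as dm
from . import diffexpr as de
from . import enrichment as en
from . import io as fio
from . import landscape as ls
from . import published, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STRATA"]

#: (name, region, system) of the four mouse differential contrasts
STRATA = (
    ("hippocampal_culture", "hippocampus", "culture"),
    ("cortical_culture", "cortex", "culture"),
    ("hippocampus_tissue", "hippocampus", "tissue"),
    ("cortex_tissue", "cortex", "tissue"),
)

_REGION_MAP = {"hippocampus": "HIP", "cortex": "NCX"}


@dataclass
class PipelineConfig:
    """Run configuration; see module docstring.

    ``mouse``/``human`` are simulation parameter dicts; ``mouse_paths``/
    ``human_paths`` point at expression+metadata TSVs instead. ``stages``
    toggles the analysis stages (landscape, diffexpr, enrichment, devmap).
    """

    outdir: str = "fxsmap_run"
    mouse: dict | None = field(default_factory=dict)
    human: dict | None = field(default_factory=dict)
    mouse_paths: dict | None = None
    human_paths: dict | None = None
    genesets_path: str | None = None
    homology_path: str | None = None
    alpha: float = 0.05
    ease_threshold: float = 0.1
    kmeans_seed: int = 0
    kmeans_restarts: int = 20
    collapse_duplicates: bool = False
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "landscape": True, "diffexpr": True, "enrichment": True,
        "devmap": True})

    def __post_init__(self) -> None:
        for name, sim, paths in (("mouse", self.mouse, self.mouse_paths),
                                 ("human", self.human, self.human_paths)):
            if (sim is None) == (paths is None):
                raise ValueError(
                    f"exactly one of {name} (simulation) or {name}_paths "
                    f"(files) must be given")
            if paths is not None:
                for key in ("expression", "metadata"):
                    if key not in paths or not Path(paths[key]).exists():
                        raise ValueError(f"{name}_paths.{key} missing")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return out
        return run
    return wrap


def _load_inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    """Simulate (writing a fixture bundle) or load the two datasets."""
    data: dict = {}
    if cfg.mouse is not None or cfg.human is not None:
        mouse_cfg = synthetic.MouseSimConfig(**{**(cfg.mouse or {}),
                                                "seed": (cfg.mouse or {}).get(
                                                    "seed", cfg.seed)})
        human_cfg = synthetic.HumanSimConfig(**{**(cfg.human or {}),
                                                "seed": (cfg.human or {}).get(
                                                    "seed", cfg.seed + 1),
                                                "n_genes": (cfg.human or {}).get(
                                                    "n_genes",
                                                    mouse_cfg.n_genes)})
        bundle = outdir / "inputs"
        synthetic.write_fixture_bundle(bundle, mouse_cfg, human_cfg)
        data["bundle"] = bundle
        m_expr = fio.read_expression_tsv(bundle / "mouse_expression.tsv")
        m_expr.index = m_expr.index.astype(int)
        m_meta = fio.read_metadata_tsv(bundle / "mouse_metadata.tsv")
        h_expr = fio.read_expression_tsv(bundle / "human_expression.tsv")
        h_expr.index = h_expr.index.astype(int)
        h_meta = fio.read_metadata_tsv(bundle / "human_metadata.tsv")
        data["genesets"] = fio.read_gmt(bundle / "genesets.gmt")
        data["homology"] = fio.read_homology_tsv(bundle / "homology.tsv")
        data["fmr1_gene_id"] = json.loads(
            (bundle / "manifest.json").read_text())["mouse"]["fmr1_gene_id"]
    else:
        m_expr = fio.read_expression_tsv(cfg.mouse_paths["expression"])
        m_meta = fio.read_metadata_tsv(cfg.mouse_paths["metadata"])
        h_expr = fio.read_expression_tsv(cfg.human_paths["expression"])
        h_meta = fio.read_metadata_tsv(cfg.human_paths["metadata"])
        try:
            m_expr.index = m_expr.index.astype(int)
            h_expr.index = h_expr.index.astype(int)
        except (TypeError, ValueError):
            pass
        data["genesets"] = (fio.read_gmt(cfg.genesets_path)
                            if cfg.genesets_path else None)
        data["homology"] = (fio.read_homology_tsv(cfg.homology_path)
                            if cfg.homology_path else None)
        data["fmr1_gene_id"] = None
    data.update(mouse_expr=m_expr, mouse_meta=m_meta,
                human_expr=h_expr, human_meta=h_meta)
    logger.info("inputs: mouse %s, human %s", m_expr.shape, h_expr.shape)
    return data


@_stage("landscape")
def _run_landscape(data: dict, outdir: Path) -> dict:
    std = ls.rank_standardize(data["mouse_expr"])
    res = ls.pca(std.T, n_components=2)
    sep = ls.centroid_separation(res, data["mouse_meta"])
    res.scores.to_csv(outdir / "landscape_scores.tsv", sep="\t",
                      index_label="sample_id")
    sep.to_csv(outdir / "landscape_separation.tsv", sep="\t")
    logger.info("landscape: PC variance fractions %s",
                np.round(res.variance_fraction, 3))
    return {
        "variance_fraction": [float(v) for v in res.variance_fraction],
        "separation": {
            "|".join(map(str, idx)): {"dPC1": float(row["dPC1"]),
                                      "dPC2": float(row["dPC2"])}
            for idx, row in sep.iterrows()},
    }


@_stage("diffexpr")
def _run_diffexpr(data: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    expr, meta = data["mouse_expr"], data["mouse_meta"]
    if cfg.collapse_duplicates:
        expr, meta = de.collapse_duplicates(expr, meta)
    out: dict = {"strata": {}}
    de_lists: dict[str, dict[str, list]] = {}
    for name, region, system in STRATA:
        tab = de.de_table(expr, meta,
                          stratum={"region": region, "system": system})
        up, down, combined = de.select_de(tab, alpha=cfg.alpha)
        tab.to_csv(outdir / f"de_{name}.tsv", sep="\t", index_label="gene_id")
        de_lists[name] = {"up": up, "down": down, "combined": combined}
        entry = {"n_up": len(up), "n_down": len(down),
                 "n_de": len(combined), "df_prior": float(tab["df_prior"].iloc[0])}
        fmr1 = data.get("fmr1_gene_id")
        if fmr1 is not None and fmr1 in tab.index:
            down_tab = tab[tab["direction"] == "down"]
            entry["fmr1_p"] = float(tab.loc[fmr1, "p_value"])
            entry["fmr1_rank_down"] = int(
                (down_tab["p_value"] < tab.loc[fmr1, "p_value"]).sum() + 1)
        out["strata"][name] = entry
        logger.info("diffexpr %s: %d up, %d down", name, len(up), len(down))
    data["de_lists"] = de_lists
    return out


@_stage("enrichment")
def _run_enrichment(data: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    sets = data.get("genesets")
    if sets is None:
        logger.info("enrichment: no gene-set collection supplied; skipped")
        return {"skipped": "no gene sets"}
    background = [int(g) for g in data["mouse_expr"].index]
    sets = {name: {int(m) for m in members if str(m).lstrip("-").isdigit()}
            for name, members in sets.items()}
    out = {}
    for name, lists in data["de_lists"].items():
        tab = en.enrich_collection(lists["combined"], sets, background,
                                   ease_threshold=cfg.ease_threshold)
        tab.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        out[name] = tab.to_dict(orient="records")
        logger.info("enrichment %s: %d sets below EASE %.2g", name, len(tab),
                    cfg.ease_threshold)
    return out


@_stage("devmap")
def _run_devmap(data: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    homology = data.get("homology")
    if homology is None:
        return {"skipped": "no homology table"}
    h_expr, h_meta = data["human_expr"], data["human_meta"]
    universe = fio.build_common_universe(
        [int(g) for g in data["mouse_expr"].index],
        [int(g) for g in h_expr.index], homology)
    mouse_of = {h: m for h, m in homology.items() if m in set(universe)}
    keep = [h for h in h_expr.index if int(h) in mouse_of]
    h_expr = h_expr.loc[keep]
    h_expr.index = pd.Index([mouse_of[int(h)] for h in keep], name="gene_id")

    out: dict = {"universe_size": len(universe), "regions": {}, "early_or": {}}
    for mouse_region, human_region in _REGION_MAP.items():
        model = dm.build_dev_model(h_expr, h_meta, region=human_region,
                                   seed=cfg.kmeans_seed,
                                   n_restarts=cfg.kmeans_restarts)
        lists = {
            f"{name}_{direction}": data["de_lists"][name][direction]
            for name, region, system in STRATA if region == mouse_region
            for direction in ("up", "down", "combined")
        }
        proj = dm.project_de_genes(lists, model)
        proj.counts.to_csv(outdir / f"projection_{human_region}_counts.tsv",
                           sep="\t", index_label="list")
        proj.percent.to_csv(outdir / f"projection_{human_region}_percent.tsv",
                            sep="\t", index_label="list")
        out["regions"][human_region] = {
            "variance_fraction": [float(v) for v in model.variance_fraction],
            "cluster_totals": {k: int(v)
                               for k, v in model.cluster_totals().items()},
            "counts": {k: [int(x) for x in row]
                       for k, row in proj.counts.iterrows()},
            "percent": {k: [float(x) for x in row]
                        for k, row in proj.percent.iterrows()},
        }
        for name, region, system in STRATA:
            if region != mouse_region:
                continue
            st = dm.early_enrichment_or(proj, f"{name}_combined")
            out["early_or"][name] = {
                "odds_ratio": round(st.odds_ratio, 4),
                "ci_low": round(st.ci_low, 4), "ci_high": round(st.ci_high, 4),
                "fisher_p": st.fisher_p,
            }
        logger.info("devmap %s: totals %s", human_region,
                    model.cluster_totals().to_dict())
    rows = [{"stratum": k, **v} for k, v in out["early_or"].items()]
    pd.DataFrame(rows).to_csv(outdir / "early_or.tsv", sep="\t", index=False)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report.

    The report is also written to ``<outdir>/report.json``. A stage
    failure aborts the run with the stage name; outputs of completed
    stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "package_version": __import__("fxsmap").__version__,
    }
    data = _load_inputs(config, outdir)
    report["inputs"] = {
        "mouse_shape": list(data["mouse_expr"].shape),
        "human_shape": list(data["human_expr"].shape),
    }
    if config.stages.get("landscape", True):
        report["landscape"] = _run_landscape(data, outdir)
    if config.stages.get("diffexpr", True):
        report["diffexpr"] = _run_diffexpr(data, config, outdir)
    if config.stages.get("enrichment", True) and "de_lists" in data:
        report["enrichment"] = _run_enrichment(data, config, outdir)
    if config.stages.get("devmap", True) and "de_lists" in data:
        report["devmap"] = _run_devmap(data, config, outdir)
    report["reference_checks"] = published.verify_reference_tables()
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
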