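"""Readers and identifier-mapping utilities.

Expression matrices are plain :class:`pandas.DataFrame` objects
(rows = probes or genes, columns = samples, values on the log2 scale).
This module reads/writes the on-disk TSV formats, parses GMT gene-set
collections, and implements the probe-to-gene collapsing rules used
throughout the pipeline:

* annotation collapsing — a probe annotated with more than one Entrez
  gene ID is assigned the numerically smallest ID;
* statistical collapsing — a gene measured by several probes is
  represented by the probe with the smallest differential-expression
  p-value, or (for the developmental series) by the probe with the
  minimal sum of per-stage coefficients of variation;
* construction of the common mouse–human gene universe through a
  homology table.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "read_gmt",
    "write_gmt",
    "read_annotation_tsv",
    "read_homology_tsv",
    "read_gene_list",
    "collapse_probe_to_min_gene_id",
    "collapse_gene_by_min_pvalue",
    "coefvar_scores",
    "collapse_gene_by_min_coefvar",
    "apply_probe_selection",
    "build_common_universe",
]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def _check_unique(ids: Sequence, what: str, path) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what} {dup[:5]} in {path}")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a log2 expression matrix (first column = row ID, header = samples).

    Raises :class:`ParseError` for duplicate row/column IDs, ragged rows or
    non-numeric cells, naming the offending line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header) - 1
        if ncol < 1:
            raise ParseError(f"no sample columns in {path}")
        _check_unique(header[1:], "sample ID", path)
        row_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol + 1} fields, got {len(fields)}"
                )
            row_ids.append(fields[0])
            try:
                rows.append(np.array(fields[1:], dtype=float))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    _check_unique(row_ids, "row ID", path)
    values = np.vstack(rows) if rows else np.empty((0, ncol))
    if not np.all(np.isfinite(values)):
        raise ParseError(f"non-finite values in {path}")
    df = pd.DataFrame(values, index=row_ids, columns=header[1:])
    df.index.name = header[0] or "id"
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "id")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a sample-metadata table indexed by ``sample_id``."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ParseError(f"missing sample_id column in {path}")
    _check_unique(meta["sample_id"], "sample_id", path)
    meta = meta.set_index("sample_id")
    if "stage" in meta.columns:
        meta["stage"] = meta["stage"].astype(int)
    return meta


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Parse a GMT file into ``{set_name: members}``.

    Each line is ``name<TAB>description<TAB>member...``; duplicate members
    within a set are counted once. The description is discarded.
    """
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable], path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            mem = "\t".join(str(m) for m in sorted(set(members)))
            fh.write(f"{name}\t{description}\t{mem}\n")


def read_annotation_tsv(path) -> dict[str, frozenset[int]]:
    """Read probe annotation: columns ``probe_id``, ``gene_ids`` (comma-separated).

    An empty ``gene_ids`` field yields an unannotated probe (empty set).
    """
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _check_unique(tab["probe_id"], "probe_id", path)
    out: dict[str, frozenset[int]] = {}
    for probe, genes in zip(tab["probe_id"], tab["gene_ids"]):
        ids = frozenset(int(g) for g in genes.split(",") if g.strip())
        out[str(probe)] = ids
    return out


def read_homology_tsv(path) -> dict[int, int]:
    """Read a homology table with columns ``human_id``, ``mouse_id``."""
    tab = pd.read_csv(path, sep="\t")
    _check_unique(tab["human_id"], "human_id", path)
    return dict(zip(tab["human_id"].astype(int), tab["mouse_id"].astype(int)))


def read_gene_list(path) -> list:
    """Read a curated gene list, one identifier per line; '#' lines skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(int(line) if line.lstrip("-").isdigit() else line)
    return out


# ---------------------------------------------------------------------------
# probe -> gene collapsing


def _id_sort_key(gene_id):
    # Entrez IDs are integers; fall back to lexicographic order for string IDs.
    if isinstance(gene_id, (int, np.integer)):
        return (0, int(gene_id), "")
    try:
        return (0, int(gene_id), "")
    except (TypeError, ValueError):
        return (1, 0, str(gene_id))


def collapse_probe_to_min_gene_id(
    annotation: Mapping[str, Iterable],
) -> dict[str, int]:
    """Assign each annotated probe its numerically smallest gene ID.

    Probes with an empty annotation are dropped; their count is logged.
    """
    out: dict[str, int] = {}
    dropped = 0
    warned = False
    for probe, genes in annotation.items():
        genes = list(genes)
        if not genes:
            dropped += 1
            continue
        if not warned and any(not isinstance(g, (int, np.integer)) for g in genes):
            logger.warning("non-integer gene IDs compared lexicographically")
            warned = True
        out[probe] = min(genes, key=_id_sort_key)
    if dropped:
        logger.info("dropped %d unannotated probes", dropped)
    return out


def collapse_gene_by_min_pvalue(
    de: pd.DataFrame, probe_to_gene: Mapping[str, int], p_col: str = "p_value"
) -> pd.DataFrame:
    """Collapse a probe-level statistics table to gene level.

    Each gene is represented by the full row of its smallest-p probe
    (ties broken by smallest probe ID so the result is order-invariant).
    The chosen probe is retained in a ``probe_id`` column; the result is
    indexed by gene ID.
    """
    missing = [p for p in de.index if p not in probe_to_gene]
    if missing:
        raise KeyError(f"probes missing from the probe->gene map: {missing[:5]}")
    order = pd.DataFrame({
        "pos": np.arange(len(de)),
        "probe": de.index.astype(str),
        "gene": [probe_to_gene[p] for p in de.index],
        "p": de[p_col].to_numpy(),
    }).sort_values(["gene", "p", "probe"], kind="stable")
    best = order.drop_duplicates("gene", keep="first").sort_values(
        "gene", key=lambda s: s.map(_id_sort_key))
    out = de.iloc[best["pos"].to_numpy()].copy()
    out.insert(0, "probe_id", best["probe"].to_numpy())
    out.index = pd.Index(best["gene"].to_numpy(), name="gene_id")
    return out


def coefvar_scores(
    expr: pd.DataFrame,
    stages: pd.Series,
    stage_window: tuple[int, int] = (2, 15),
) -> pd.Series:
    """Per-probe sum of per-stage coefficients of variation (SD/mean).

    For each stage in ``stage_window`` the coefficient of variation of a
    probe is the sample SD (ddof=1) across that stage's samples divided by
    their mean; stages with a single sample contribute SD = 0 (warned).
    A zero mean at any stage makes the probe's score ``+inf`` so it can
    never be selected.
    """
    stages = stages.loc[expr.columns].astype(int)
    lo, hi = stage_window
    score = pd.Series(0.0, index=expr.index)
    for stage in range(lo, hi + 1):
        cols = stages.index[stages == stage]
        if len(cols) == 0:
            continue
        vals = expr[cols].to_numpy(float)
        mean = vals.mean(axis=1)
        if len(cols) < 2:
            logger.warning("stage %d has a single sample; SD taken as 0", stage)
            sd = np.zeros_like(mean)
        else:
            sd = vals.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean == 0.0, np.inf, sd / mean)
        if np.isinf(cv).any():
            logger.warning("zero stage mean for %d probes at stage %d",
                           int(np.isinf(cv).sum()), stage)
        score += cv
    return score


def collapse_gene_by_min_coefvar(
    expr: pd.DataFrame,
    stages: pd.Series,
    probe_to_gene: Mapping[str, int],
    stage_window: tuple[int, int] = (2, 15),
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Represent each gene by its probe with the minimal coefvar-sum score.

    Returns the gene-level matrix (indexed by gene ID) and the chosen
    ``{gene_id: probe_id}`` selection, which :func:`apply_probe_selection`
    can re-apply to a second region's matrix so that both regions use the
    same representative probes.
    """
    score = coefvar_scores(expr, stages, stage_window)
    tab = pd.DataFrame({
        "probe_id": expr.index.astype(str),
        "gene_id": [probe_to_gene[p] for p in expr.index],
        "score": score.to_numpy(),
    })
    tab = tab.sort_values(["gene_id", "score", "probe_id"], kind="stable")
    best = tab.drop_duplicates("gene_id", keep="first")
    chosen = dict(zip(best["gene_id"], best["probe_id"]))
    return apply_probe_selection(expr, chosen), chosen


def apply_probe_selection(
    expr: pd.DataFrame, chosen: Mapping[int, str]
) -> pd.DataFrame:
    """Subset a probe-level matrix to the chosen probes, re-indexed by gene."""
    genes = sorted(chosen, key=_id_sort_key)
    out = expr.loc[[chosen[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return out


def build_common_universe(
    mouse_genes: Iterable[int],
    human_genes: Iterable[int],
    homology: Mapping[int, int],
) -> list[int]:
    """Mouse genes with a homolog present in the human data, sorted by ID.

    ``homology`` maps human gene ID -> mouse gene ID (many-to-one at most).
    """
    mouse = set(mouse_genes)
    mapped = {homology[h] for h in human_genes if h in homology}
    universe = sorted(mouse & mapped, key=_id_sort_key)
    if not universe:
        raise ValueError("empty mouse-human gene universe")
    return universe
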