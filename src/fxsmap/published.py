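"""Published reference counts from the Fmr1-KO developmental-mapping study.

The study (mouse arrays GSE71034 integrated with the human brain
transcriptome GSE25219) reported, for each mouse stratum, how its KO/WT
differentially expressed genes distribute over the three temporal
clusters of the 13,830-gene human map, together with early-cluster
enrichment odds ratios. The printed per-cluster counts are packaged here
as inputs so that the odds-ratio / confidence-interval / percentage
arithmetic can be recomputed and checked end to end without the original
microarray data.

Cluster totals are (early, mid, late) gene counts of the whole universe;
projection counts are per-cluster counts for each DE list.
"""

from __future__ import annotations

from .devmap import early_or_from_counts, percentages

__all__ = [
    "UNIVERSE_SIZE",
    "CLUSTER_TOTALS",
    "PROJECTION_COUNTS",
    "REPORTED",
    "verify_reference_tables",
]

UNIVERSE_SIZE = 13830

#: whole-universe gene counts per temporal cluster (early, mid, late)
CLUSTER_TOTALS = {
    "hippocampus": (5808, 4242, 3780),   # clusters H0, H1, H2
    "neocortex": (5572, 4217, 4041),     # clusters C0, C1, C2
}

#: per-cluster counts of mouse DE genes projected onto the matching region
#: of the human map; keys are (stratum, direction)
PROJECTION_COUNTS = {
    ("hippocampal_culture", "down"): (239, 200, 260),
    ("hippocampal_culture", "up"): (821, 191, 298),
    ("hippocampal_culture", "combined"): (1060, 391, 558),
    ("cortical_culture", "down"): (428, 461, 408),
    ("cortical_culture", "up"): (732, 268, 168),
    ("cortical_culture", "combined"): (1160, 729, 576),
    ("hippocampus_tissue", "down"): (92, 126, 65),
    ("hippocampus_tissue", "up"): (61, 71, 39),
    ("hippocampus_tissue", "combined"): (153, 197, 104),
    ("cortex_tissue", "down"): (102, 52, 57),
    ("cortex_tissue", "up"): (96, 81, 162),
    ("cortex_tissue", "combined"): (198, 133, 219),
}

_REGION_OF = {
    "hippocampal_culture": "hippocampus",
    "hippocampus_tissue": "hippocampus",
    "cortical_culture": "neocortex",
    "cortex_tissue": "neocortex",
}

#: reported values the arithmetic must reproduce (printed precision)
REPORTED = {
    "or_cortical_culture": 1.4,
    "or_hippocampal_culture": 1.66,
    "or_cortex_tissue": 0.83,
    "or_hippocampus_tissue": 0.69,
    "ci_low_cortical_culture": 1.28,
    "ci_high_cortical_culture": 1.53,
    "pct_early_hippocampus": 42.0,
    "pct_early_neocortex": 40.0,
}


def early_or(stratum: str, direction: str = "combined"):
    """Early-cluster enrichment OverlapStats for one published stratum."""
    counts = PROJECTION_COUNTS[(stratum, direction)]
    totals = CLUSTER_TOTALS[_REGION_OF[stratum]]
    return early_or_from_counts(counts, totals)


def verify_reference_tables(tolerance: float = 0.005) -> list[dict]:
    """Recompute the published summary numbers from the packaged counts.

    Returns one check per reported value (8 in total): the four
    early-cluster enrichment odds ratios, the two cortical-culture CI
    endpoints, and the early-cluster percentage of the universe in each
    region. ``tolerance`` is the allowed absolute deviation beyond printed
    rounding (ORs and CIs are printed to 2 decimals, percentages to
    integers).
    """
    checks: list[dict] = []

    def add(name: str, computed: float, decimals: int) -> None:
        expected = REPORTED[name]
        ok = abs(round(computed, decimals) - expected) <= tolerance
        checks.append({"check": name, "computed": float(computed),
                       "reported": expected, "passed": bool(ok)})

    for stratum in ("cortical_culture", "hippocampal_culture",
                    "cortex_tissue", "hippocampus_tissue"):
        add(f"or_{stratum}", early_or(stratum).odds_ratio, 2)
    ci = early_or("cortical_culture")
    add("ci_low_cortical_culture", ci.ci_low, 2)
    add("ci_high_cortical_culture", ci.ci_high, 2)
    for region in ("hippocampus", "neocortex"):
        pct = percentages(CLUSTER_TOTALS[region], ndigits=0)[0]
        add(f"pct_early_{region}", pct, 0)
    return checks
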