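"""Fisher-exact / EASE gene-set enrichment and list-overlap odds ratios.

All statistics operate on a 2x2 table of counts::

                in set   not in set
    in list        a         b
    not in list    c         d

Pathway enrichment uses the one-sided ("greater") Fisher exact test and
its conservative EASE variant (the overlap cell is decremented by one
before testing, DAVID's "jackknifed" score), plus DAVID-style fold
enrichment. List-vs-list overlap is summarized by the sample odds ratio
ad/bc with a 95% Woolf (logit) interval and a two-sided Fisher p-value.

Tail probabilities are computed by summing hypergeometric log-pmf terms
(log-sum-exp), so extreme tables do not underflow. The two-sided p uses
the "minlike" rule: the sum of all table probabilities no larger than the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "OverlapStats",
    "fisher_exact_2x2",
    "ease_score",
    "fold_enrichment",
    "enrich_collection",
    "overlap_or_ci",
    "or_ci_from_table",
]

_REL_EPS = 1.0 + 1e-7  # tolerance when comparing pmf terms in the minlike rule


@dataclass
class OverlapStats:
    """2x2 overlap summary: counts, OR with 95% Woolf CI, two-sided Fisher p.

    ``haldane`` flags that a zero cell forced the +0.5 continuity
    correction for the OR and CI (the p-value is always exact).
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    haldane: bool = False


def _check_counts(*cells: int) -> tuple[int, ...]:
    out = []
    for x in cells:
        xi = int(x)
        if xi != x or xi < 0:
            raise ValueError(f"cell counts must be nonnegative integers, got {x}")
        out.append(xi)
    return tuple(out)


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    ``alternative``: 'greater' (enrichment of the a-cell), 'less', or
    'two-sided' (minlike rule). Degenerate margins give p = 1.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, n, col1, row1)
    obs = logpmf[a - lo]
    if alternative == "greater":
        keep = support >= a
    elif alternative == "less":
        keep = support <= a
    elif alternative == "two-sided":
        keep = logpmf <= obs + np.log(_REL_EPS)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if keep.all():
        return 1.0
    p = float(np.exp(logsumexp(logpmf[keep])))
    # clamp into (0, 1]: guards exp underflow for extreme tables
    return min(1.0, max(p, np.finfo(float).tiny))


def ease_score(a: int, b: int, c: int, d: int) -> float:
    """EASE p-value: one-sided Fisher recomputed with the overlap cell a-1.

    Always >= the plain Fisher p; a table with a <= 1 scores 1.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    if a < 1:
        return 1.0
    return fisher_exact_2x2(a - 1, b, c, d, alternative="greater")


def fold_enrichment(a: int, b: int, c: int, d: int) -> float:
    """(a / (a+b)) / ((a+c) / N): list proportion over background proportion.

    Returns NaN when a margin is empty (undefined).
    """
    a, b, c, d = _check_counts(a, b, c, d)
    n = a + b + c + d
    if a + b == 0 or a + c == 0 or n == 0:
        return float("nan")
    return (a / (a + b)) / ((a + c) / n)


def enrich_collection(
    gene_list: Collection,
    collection: Mapping[str, Iterable],
    background: Collection,
    ease_threshold: float = 0.1,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test every set in a collection against a gene list.

    Sets are intersected with ``background`` before counting; the list must
    be a subset of the background. One row per set with overlap >= 1,
    sorted by EASE p ascending and filtered at ``ease_threshold``. Columns:
    set, a, list_n, set_n, bg_n, fisher_p, ease_p, fold_enrichment.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    lst = set(gene_list)
    outside = lst - bg
    if outside:
        raise ValueError(f"{len(outside)} list genes outside the background, "
                         f"e.g. {sorted(outside)[:3]}")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & bg
        a = len(lst & members)
        if a < 1:
            continue
        b = len(lst) - a
        c = len(members) - a
        d = len(bg) - a - b - c
        rows.append({
            "set": name, "a": a, "list_n": len(lst), "set_n": len(members),
            "bg_n": len(bg),
            "fisher_p": fisher_exact_2x2(a, b, c, d, alternative=alternative),
            "ease_p": ease_score(a, b, c, d),
            "fold_enrichment": fold_enrichment(a, b, c, d),
        })
    out = pd.DataFrame(rows, columns=["set", "a", "list_n", "set_n", "bg_n",
                                      "fisher_p", "ease_p", "fold_enrichment"])
    out = out[out["ease_p"] < ease_threshold]
    return out.sort_values(["ease_p", "set"], kind="stable").reset_index(drop=True)


def or_ci_from_table(a: int, b: int, c: int, d: int,
                     z: float = 1.96) -> OverlapStats:
    """Odds ratio ad/bc with a Woolf logit CI and two-sided Fisher p.

    A zero cell triggers the Haldane-Anscombe +0.5 correction for the OR
    and interval (flagged in the result); the Fisher p is unaffected.
    """
    a, b, c, d = _check_counts(a, b, c, d)
    p = fisher_exact_2x2(a, b, c, d, alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    aa, bb, cc, dd = float(aa), float(bb), float(cc), float(dd)
    odds = (aa * dd) / (bb * cc)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    lo = float(np.exp(np.log(odds) - z * se))
    hi = float(np.exp(np.log(odds) + z * se))
    return OverlapStats(a=a, b=b, c=c, d=d, odds_ratio=float(odds),
                        ci_low=lo, ci_high=hi, fisher_p=p, haldane=corrected)


def overlap_or_ci(list_a: Collection, list_b: Collection,
                  universe: Collection) -> OverlapStats:
    """Overlap statistics for two gene lists within a common universe."""
    uni = set(universe)
    sa, sb = set(list_a), set(list_b)
    for name, s in (("list_a", sa), ("list_b", sb)):
        if s - uni:
            raise ValueError(f"{name} has {len(s - uni)} genes outside the universe")
    a = len(sa & sb)
    b = len(sa - sb)
    c = len(sb - sa)
    d = len(uni) - a - b - c
    return or_ci_from_table(a, b, c, d)
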