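"""Per-tissue summary tables and the nonparametric group comparisons.

The central artefact is a wide per-(tissue, group) table of the nine category
counts — the shape in which reciprocal-cross splicing-inheritance studies
report their results — plus derived percentage summaries per category family
and two rank-based tests:

* Kruskal-Wallis across tissues on per-group proportions of a family;
* Mann-Whitney within a tissue contrasting up- vs down-dominance,
  over- vs under-dominance, or CG- vs WL-dominance counts.

Small samples (these tables have 2-4 groups per tissue) get exact
permutation/enumeration p-values; larger inputs fall back to the usual
chi-square / normal approximations with tie correction.
"""

from __future__ import annotations

import itertools
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, mannwhitneyu, rankdata

from .inheritance import CATEGORIES

#: Category families used for percentage summaries; values are column groups.
FAMILIES = {
    "conserved": ("conserved",),
    "additive": ("additive_cg_high", "additive_wl_high"),
    "dominant_cg": ("dominant_cg_up", "dominant_cg_down"),
    "dominant_wl": ("dominant_wl_up", "dominant_wl_down"),
    "dominance_total": (
        "dominant_cg_up", "dominant_cg_down", "dominant_wl_up", "dominant_wl_down",
    ),
    "transgressive": ("over_dominant", "under_dominant"),
}

CONTRASTS = {
    "up_vs_down_dominant": (
        ("dominant_cg_up", "dominant_wl_up"),
        ("dominant_cg_down", "dominant_wl_down"),
    ),
    "over_vs_under": (("over_dominant",), ("under_dominant",)),
    "cg_vs_wl_dominant": (
        ("dominant_cg_up", "dominant_cg_down"),
        ("dominant_wl_up", "dominant_wl_down"),
    ),
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for reported percentages (0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def tabulate(calls: pd.DataFrame) -> pd.DataFrame:
    """Exact per-(tissue, group) counts of the nine categories.

    ``calls`` must come from a single method.  Returns a wide table with one
    column per category plus ``n_classified``.
    """
    cols = ["tissue", "group", *CATEGORIES, "n_classified"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    if "method" in calls.columns and calls["method"].nunique() > 1:
        raise ValueError("tabulate expects calls from a single method")
    counts = (
        calls.groupby(["tissue", "group", "category"]).size().unstack("category", fill_value=0)
    )
    for c in CATEGORIES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(CATEGORIES)]
    counts["n_classified"] = counts.sum(axis=1)
    counts.columns.name = None
    return counts.reset_index()[cols]


def category_percentages(
    table: pd.DataFrame,
    denominators: Mapping[str, int],
    ndigits: int = 1,
) -> pd.DataFrame:
    """Per-group and tissue-mean percentages per category family.

    ``denominators`` gives, per tissue, the number of events entering
    classification (the merge-step count), which is the denominator for every
    group in that tissue.  Tissue means are arithmetic means over that
    tissue's groups, rounded half-up to ``ndigits`` decimals in the
    ``pct_rounded``/``tissue_mean_pct_rounded`` columns (exact values are kept
    alongside).
    """
    rows = []
    for tissue, sub in table.groupby("tissue"):
        if tissue not in denominators:
            raise ValueError(f"missing denominator for tissue {tissue!r}")
        denom = denominators[tissue]
        if denom <= 0:
            raise ValueError(f"denominator for tissue {tissue!r} must be positive")
        for family, cols in FAMILIES.items():
            pcts = []
            for row in sub.itertuples(index=False):
                count = sum(getattr(row, c) for c in cols)
                pct = 100.0 * count / denom
                pcts.append((row.group, count, pct))
            mean_pct = float(np.mean([p for _, _, p in pcts]))
            for group, count, pct in pcts:
                rows.append(
                    {
                        "tissue": tissue,
                        "group": group,
                        "family": family,
                        "count": count,
                        "denominator": denom,
                        "pct": pct,
                        "pct_rounded": round_half_up(pct, ndigits),
                        "tissue_mean_pct": mean_pct,
                        "tissue_mean_pct_rounded": round_half_up(mean_pct, ndigits),
                    }
                )
    return pd.DataFrame(rows)


def _kw_h(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H for a list of observation vectors."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction == 0.0:
        return 0.0  # all observations identical
    return h / correction


def _partitions(indices: list[int], sizes: list[int]):
    """All ways to split ``indices`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = [i for i in indices if i not in set(first)]
        for tail in _partitions(rest, sizes[1:]):
            yield (first, *tail)


def _kw_exact_pvalue(groups: Sequence[np.ndarray], h_obs: float) -> float:
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    count = 0
    total = 0
    for part in _partitions(list(range(len(pooled))), sizes):
        perm = [pooled[list(idx)] for idx in part]
        total += 1
        if _kw_h(perm) >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_wallis_across_tissues(
    percentages: pd.DataFrame,
    family: str,
    use: str = "pct",
) -> tuple[float, float]:
    """Kruskal-Wallis across tissues on per-group values of one family.

    Observations are the per-group proportions (``use="pct"``) or raw counts
    (``use="count"``) from :func:`category_percentages`.  The tie-corrected H
    statistic is always returned; the p-value is the exact permutation
    probability when the total number of observations is <= 10, otherwise the
    chi-square approximation with (k - 1) df.
    """
    sub = percentages[percentages["family"] == family]
    groups = [
        sub.loc[sub["tissue"] == t, use].to_numpy(dtype=float)
        for t in sorted(sub["tissue"].unique())
    ]
    if len(groups) < 2:
        raise ValueError("need at least two tissues")
    h = _kw_h(groups)
    n = sum(len(g) for g in groups)
    if n <= 10:
        p = _kw_exact_pvalue(groups, h)
    else:
        p = float(chi2.sf(h, df=len(groups) - 1))
    return float(h), float(p)


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y with the midrank tie convention."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def _mw_exact_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments (ties allowed)."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    center = n * m / 2.0
    dev = abs(u_obs - center)
    count = 0
    total = comb(n + m, n)
    idx = list(range(n + m))
    for chosen in itertools.combinations(idx, n):
        chosen_set = set(chosen)
        xs = pooled[list(chosen)]
        ys = pooled[[i for i in idx if i not in chosen_set]]
        if abs(_mw_u(xs, ys) - center) >= dev - 1e-12:
            count += 1
    return count / total


def mannwhitney_updown(
    table: pd.DataFrame,
    tissue: str,
    contrast: str = "up_vs_down_dominant",
) -> tuple[float, float]:
    """Mann-Whitney U contrasting two category sides within one tissue.

    The two observation vectors are the per-group counts of each side of the
    contrast (see :data:`CONTRASTS`).  Exact enumeration when both sides have
    <= 8 observations, otherwise the normal approximation with tie
    correction.  Returns ``(U, p)``; raises if a side is empty.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; options: {sorted(CONTRASTS)}")
    side_a_cols, side_b_cols = CONTRASTS[contrast]
    sub = table[table["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"no rows for tissue {tissue!r}")
    x = sub[list(side_a_cols)].sum(axis=1).to_numpy(dtype=float)
    y = sub[list(side_b_cols)].sum(axis=1).to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty contrast side")
    u = _mw_u(x, y)
    if len(x) <= 8 and len(y) <= 8:
        p = _mw_exact_pvalue(x, y, u)
    else:
        p = float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1])
    return u, p


def summary_report(
    table: pd.DataFrame,
    percentages: pd.DataFrame,
    tests: pd.DataFrame | None = None,
) -> str:
    """Small human-readable markdown report of counts, percentages and tests."""
    lines = ["# Splicing inheritance summary", "", "## Category counts", ""]
    lines.append(table.to_markdown(index=False) if hasattr(table, "to_markdown") else str(table))
    lines += ["", "## Tissue-mean percentages by family", ""]
    tissue_means = (
        percentages.drop_duplicates(["tissue", "family"])
        [["tissue", "family", "tissue_mean_pct_rounded"]]
    )
    lines.append(tissue_means.to_markdown(index=False))
    if tests is not None and not tests.empty:
        lines += ["", "## Nonparametric tests", "", tests.to_markdown(index=False)]
    return "\n".join(lines) + "\n"
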