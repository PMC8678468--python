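"""Nine-way inheritance-pattern classification of hybrid splicing.

Each parentally divergent, hybrid-expressed splice event is compared across
a (parent 1 = CG, parent 2 = WL, hybrid) triple of group-mean PSI values and
assigned exactly one of nine categories:

====================  =====================================================
conserved             hybrid similar to both parents
additive_cg_high      hybrid strictly between parents, CG the higher parent
additive_wl_high      hybrid strictly between parents, WL the higher parent
dominant_cg_up        hybrid similar to CG only; CG is the higher parent
dominant_cg_down      hybrid similar to CG only; CG is the lower parent
dominant_wl_up        hybrid similar to WL only; WL is the higher parent
dominant_wl_down      hybrid similar to WL only; WL is the lower parent
over_dominant         hybrid similar to neither, at or above both parents
under_dominant        hybrid similar to neither, at or below both parents
====================  =====================================================

"Similar" is a symmetric fold-ratio criterion on PSI:
``(max(a, b) + eps) / (min(a, b) + eps) <= fold`` with ``fold = 1.25`` and a
pseudocount ``eps = 0.01`` guarding values near zero.  Similarity to both
parents takes precedence (conserved), boundary ties resolve toward
"similar", and the eight non-conserved outcomes partition the remainder, so
the classification is exhaustive and mutually exclusive.

A second, test-based variant replaces the fold-ratio with two Fisher exact
tests on replicate-pooled counts (hybrid vs each parent), BH-adjusted per
comparison family; "similar" then means "not significantly different".

Comparison groups follow the reciprocal-cross design: MC (CG/WL/CL males),
FC (females), MR (CG/WL/LC males), FR (females).  A consensus rule promotes
a non-conserved mode to the tissue level when the same (collapsed) mode is
called in at least ``min_groups`` groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .divergence import bh_fdr

CATEGORIES = (
    "conserved",
    "additive_cg_high",
    "additive_wl_high",
    "dominant_cg_up",
    "dominant_cg_down",
    "dominant_wl_up",
    "dominant_wl_down",
    "over_dominant",
    "under_dominant",
)

#: Collapsed (mode-family) view used by the consensus rule and summaries.
COLLAPSE = {
    "conserved": "conserved",
    "additive_cg_high": "additive",
    "additive_wl_high": "additive",
    "dominant_cg_up": "dominant_cg",
    "dominant_cg_down": "dominant_cg",
    "dominant_wl_up": "dominant_wl",
    "dominant_wl_down": "dominant_wl",
    "over_dominant": "transgressive",
    "under_dominant": "transgressive",
}

#: Category image under exchanging the parental labels (CG <-> WL).
SWAP_PARENTS = {
    "conserved": "conserved",
    "additive_cg_high": "additive_wl_high",
    "additive_wl_high": "additive_cg_high",
    "dominant_cg_up": "dominant_wl_up",
    "dominant_cg_down": "dominant_wl_down",
    "dominant_wl_up": "dominant_cg_up",
    "dominant_wl_down": "dominant_cg_down",
    "over_dominant": "over_dominant",
    "under_dominant": "under_dominant",
}

GROUP_LABELS = ("MC", "FC", "MR", "FR")
#: (sex, hybrid strain) behind each comparison-group label.
GROUP_DESIGN = {
    "MC": ("M", "CL"),
    "FC": ("F", "CL"),
    "MR": ("M", "LC"),
    "FR": ("F", "LC"),
}


@dataclass(frozen=True)
class ComparisonGroup:
    """One parent1/parent2/hybrid sample constellation within a tissue."""

    label: str
    tissue: str
    sex: str
    hybrid_strain: str
    parent1_samples: tuple[str, ...]
    parent2_samples: tuple[str, ...]
    hybrid_samples: tuple[str, ...]


def fold_ratio(a, b, eps: float = 0.01):
    """Symmetric fold change ``(max + eps) / (min + eps)``; >= 1, equals 1 at a == b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    out = (hi + eps) / (lo + eps)
    return float(out) if out.ndim == 0 else out


def _decide(sim1, sim2, p1, p2, h) -> np.ndarray:
    """Shared decision table over similarity flags and the PSI triple.

    sim1/sim2: hybrid "similar to" parent 1 / parent 2.  Exhaustive and
    mutually exclusive by construction; similarity to both wins (conserved).
    """
    sim1 = np.asarray(sim1, dtype=bool)
    sim2 = np.asarray(sim2, dtype=bool)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h = np.asarray(h, dtype=float)

    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    between = (h > lo) & (h < hi)
    conditions = [
        sim1 & sim2,
        sim1 & ~sim2 & (p1 > p2),
        sim1 & ~sim2 & (p1 <= p2),
        sim2 & ~sim1 & (p2 > p1),
        sim2 & ~sim1 & (p2 <= p1),
        ~sim1 & ~sim2 & between & (p1 > p2),
        ~sim1 & ~sim2 & between & (p1 <= p2),
        ~sim1 & ~sim2 & ~between & (h >= hi),
        ~sim1 & ~sim2 & ~between & (h <= lo),
    ]
    choices = [
        "conserved",
        "dominant_cg_up",
        "dominant_cg_down",
        "dominant_wl_up",
        "dominant_wl_down",
        "additive_cg_high",
        "additive_wl_high",
        "over_dominant",
        "under_dominant",
    ]
    out = np.select(conditions, choices, default="")
    if np.any(out == ""):
        raise AssertionError("decision table failed to cover an input")  # pragma: no cover
    return out


def classify_threshold(psi_p1, psi_p2, psi_h, fold: float = 1.25, eps: float = 0.01):
    """Classify PSI triple(s) by the symmetric fold-ratio criterion.

    Scalars in, a category string out; arrays in, an object array out.
    Inputs must be defined (not NaN) — callers skip events with a missing
    group mean.
    """
    p1 = np.asarray(psi_p1, dtype=float)
    p2 = np.asarray(psi_p2, dtype=float)
    h = np.asarray(psi_h, dtype=float)
    if np.any(np.isnan(p1)) or np.any(np.isnan(p2)) or np.any(np.isnan(h)):
        raise ValueError("classify_threshold requires defined PSI values; filter missing first")
    sim1 = fold_ratio(h, p1, eps) <= fold
    sim2 = fold_ratio(h, p2, eps) <= fold
    out = _decide(sim1, sim2, p1, p2, h)
    return str(out[()]) if out.ndim == 0 else out


def fisher_pvalue(ijc1: int, sjc1: int, ijc2: int, sjc2: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 inclusion/skipping table."""
    return float(fisher_exact([[ijc1, sjc1], [ijc2, sjc2]], alternative="two-sided")[1])


def classify_fisher_frame(
    pooled: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-variant classification over one comparison group's events.

    ``pooled`` needs replicate-summed counts per event:
    ``ijc_p1, sjc_p1, ijc_p2, sjc_p2, ijc_h, sjc_h`` (indexed or keyed by
    ``event_id``).  Hybrid-vs-parent1 and hybrid-vs-parent2 p-values are each
    BH-adjusted across the frame's events (one family per parent comparison);
    "similar" means adjusted p >= alpha.  Between/outside placement uses the
    pooled PSI point estimates.  Events with a zero-total group get no call.

    Returns the frame with ``p_vs_p1``, ``p_vs_p2``, ``q_vs_p1``, ``q_vs_p2``,
    pooled PSI columns and ``category`` (empty string = no call).
    """
    df = pooled.copy()
    totals = {
        "p1": df["ijc_p1"] + df["sjc_p1"],
        "p2": df["ijc_p2"] + df["sjc_p2"],
        "h": df["ijc_h"] + df["sjc_h"],
    }
    callable_mask = (totals["p1"] > 0) & (totals["p2"] > 0) & (totals["h"] > 0)

    for side in ("p1", "p2"):
        pvals = np.full(len(df), np.nan)
        for i, row in enumerate(df.itertuples(index=False)):
            if not callable_mask.iloc[i]:
                continue
            pvals[i] = fisher_pvalue(
                int(row.ijc_h), int(row.sjc_h),
                int(getattr(row, f"ijc_{side}")), int(getattr(row, f"sjc_{side}")),
            )
        df[f"p_vs_{side}"] = pvals
        q = np.full(len(df), np.nan)
        ok = ~np.isnan(pvals)
        if ok.any():
            q[ok] = bh_fdr(pvals[ok])
        df[f"q_vs_{side}"] = q

    with np.errstate(invalid="ignore", divide="ignore"):
        df["psi_p1"] = df["ijc_p1"] / totals["p1"]
        df["psi_p2"] = df["ijc_p2"] / totals["p2"]
        df["psi_h"] = df["ijc_h"] / totals["h"]

    category = np.full(len(df), "", dtype=object)
    m = callable_mask.to_numpy()
    if m.any():
        sim1 = df.loc[m, "q_vs_p1"].to_numpy() >= alpha
        sim2 = df.loc[m, "q_vs_p2"].to_numpy() >= alpha
        category[m] = _decide(
            sim1, sim2,
            df.loc[m, "psi_p1"].to_numpy(),
            df.loc[m, "psi_p2"].to_numpy(),
            df.loc[m, "psi_h"].to_numpy(),
        )
    df["category"] = category
    return df


def build_comparison_groups(sheet: pd.DataFrame, tissue: str) -> dict[str, ComparisonGroup]:
    """Construct the MC/FC/MR/FR groups available in one tissue.

    A group is omitted (rather than raising) when any of its three sample
    sets is empty — e.g. liver FC/FR when hybrid-female liver samples were
    removed from the design.
    """
    sub = sheet[sheet["tissue"] == tissue]

    def samples(strain: str, sex: str) -> tuple[str, ...]:
        rows = sub[(sub["strain"] == strain) & (sub["sex"] == sex)]
        return tuple(rows.sort_values("replicate_index")["sample_id"])

    groups = {}
    for label, (sex, hybrid) in GROUP_DESIGN.items():
        p1 = samples("CG", sex)
        p2 = samples("WL", sex)
        hyb = samples(hybrid, sex)
        if p1 and p2 and hyb:
            groups[label] = ComparisonGroup(
                label=label, tissue=tissue, sex=sex, hybrid_strain=hybrid,
                parent1_samples=p1, parent2_samples=p2, hybrid_samples=hyb,
            )
    return groups


def merge_divergent_with_expressed(
    divergence: pd.DataFrame,
    group_psi: pd.DataFrame,
    group: ComparisonGroup,
) -> list[str]:
    """Events significant between parents AND expressed (defined PSI) in the hybrid.

    ``group_psi`` is the (strain, sex, tissue)-level mean-PSI table from
    :func:`asinherit.quantify.group_mean_psi`.  Raises if the divergence
    results were computed for a different tissue.
    """
    tissues = set(divergence["tissue"].unique()) if not divergence.empty else set()
    if tissues and tissues != {group.tissue}:
        raise ValueError(
            f"divergence results are for tissue(s) {sorted(tissues)}, group is {group.tissue}"
        )
    significant = set(divergence.loc[divergence["significant"], "event_id"])
    hyb = group_psi[
        (group_psi["strain"] == group.hybrid_strain)
        & (group_psi["sex"] == group.sex)
        & (group_psi["tissue"] == group.tissue)
        & group_psi["mean_psi"].notna()
    ]
    expressed = set(hyb["event_id"])
    return sorted(significant & expressed)


def _group_triples(
    group_psi: pd.DataFrame, group: ComparisonGroup, event_ids: list[str]
) -> pd.DataFrame:
    """Wide (event x {psi_p1, psi_p2, psi_h}) table of group-mean PSI."""
    sub = group_psi[
        (group_psi["tissue"] == group.tissue) & (group_psi["sex"] == group.sex)
    ]
    pivot = sub.pivot_table(index="event_id", columns="strain", values="mean_psi", aggfunc="first")
    pivot = pivot.reindex(event_ids)
    out = pd.DataFrame(index=pivot.index)
    out["psi_p1"] = pivot.get("CG")
    out["psi_p2"] = pivot.get("WL")
    out["psi_h"] = pivot.get(group.hybrid_strain)
    return out


def classify_group_threshold(
    group_psi: pd.DataFrame,
    group: ComparisonGroup,
    event_ids: list[str],
    fold: float = 1.25,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Per-event threshold-method calls for one comparison group.

    Events with any missing group mean are skipped (no call).  Returns the
    call table with the PSI triple and both hybrid/parent fold ratios.
    """
    triples = _group_triples(group_psi, group, event_ids)
    ok = triples.notna().all(axis=1)
    triples = triples[ok]
    if triples.empty:
        return pd.DataFrame(
            columns=["event_id", "tissue", "group", "method", "category",
                     "psi_p1", "psi_p2", "psi_h", "ratio_h_p1", "ratio_h_p2"]
        )
    p1 = triples["psi_p1"].to_numpy()
    p2 = triples["psi_p2"].to_numpy()
    h = triples["psi_h"].to_numpy()
    cats = classify_threshold(p1, p2, h, fold=fold, eps=eps)
    return pd.DataFrame(
        {
            "event_id": triples.index,
            "tissue": group.tissue,
            "group": group.label,
            "method": "threshold",
            "category": cats,
            "psi_p1": p1,
            "psi_p2": p2,
            "psi_h": h,
            "ratio_h_p1": fold_ratio(h, p1, eps),
            "ratio_h_p2": fold_ratio(h, p2, eps),
        }
    ).reset_index(drop=True)


def classify_group_fisher(
    counts: pd.DataFrame,
    group: ComparisonGroup,
    event_ids: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-event Fisher-method calls for one comparison group (pooled replicates)."""
    pooled_parts = {}
    for role, samples in (
        ("p1", group.parent1_samples),
        ("p2", group.parent2_samples),
        ("h", group.hybrid_samples),
    ):
        sub = counts[counts["sample_id"].isin(samples) & counts["event_id"].isin(event_ids)]
        agg = sub.groupby("event_id")[["ijc", "sjc"]].sum()
        pooled_parts[role] = agg.rename(columns={"ijc": f"ijc_{role}", "sjc": f"sjc_{role}"})
    pooled = pd.concat(pooled_parts.values(), axis=1).reindex(event_ids).fillna(0).astype(int)
    pooled.index.name = "event_id"
    result = classify_fisher_frame(pooled.reset_index(), alpha=alpha)
    result = result[result["category"] != ""].copy()
    result["tissue"] = group.tissue
    result["group"] = group.label
    result["method"] = "fisher"
    return result[
        ["event_id", "tissue", "group", "method", "category",
         "psi_p1", "psi_p2", "psi_h", "p_vs_p1", "p_vs_p2", "q_vs_p1", "q_vs_p2"]
    ].reset_index(drop=True)


def consensus(
    calls: pd.DataFrame,
    min_groups: int = 2,
    collapse: bool = True,
    key: str = "gene_id",
) -> pd.DataFrame:
    """Promote non-conserved modes supported by >= ``min_groups`` groups in a tissue.

    ``calls`` is a per-(event, group) call table from one method; ``key`` is
    ``"gene_id"`` (requires that column, the default) or ``"event_id"``.
    When two modes both reach the support threshold for the same key the tie
    is unresolvable and no call is emitted.  Conserved calls never form a
    consensus mode.
    """
    if calls.empty:
        return pd.DataFrame(columns=[key, "tissue", "category", "n_supporting_groups"])
    if calls["method"].nunique() > 1:
        raise ValueError("consensus expects calls from a single method")
    df = calls.copy()
    df["mode"] = df["category"].map(COLLAPSE) if collapse else df["category"]
    df = df[df["mode"] != "conserved"]
    # one vote per (key, tissue, group, mode)
    votes = df.drop_duplicates([key, "tissue", "group", "mode"])
    support = (
        votes.groupby([key, "tissue", "mode"])["group"].nunique().rename("n_supporting_groups")
    )
    support = support[support >= min_groups].reset_index()
    # drop keys where two modes tie at/above the threshold
    n_modes = support.groupby([key, "tissue"])["mode"].transform("size")
    support = support[n_modes == 1]
    return support.rename(columns={"mode": "category"})[
        [key, "tissue", "category", "n_supporting_groups"]
    ].reset_index(drop=True)
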