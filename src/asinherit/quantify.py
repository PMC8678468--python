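"""PSI quantification and event-level filtering.

Percent spliced-in (PSI) for a junction-count record is the fraction of
evidence supporting the inclusion isoform.  Two conventions are supported:

* length-normalised (default, the rMATS ``IncLevel`` convention):
  ``(ijc/inc_len) / (ijc/inc_len + sjc/skip_len)`` — corrects for the
  inclusion isoform exposing more read positions than the skipping isoform;
* raw-count: ``ijc / (ijc + sjc)``.

Both are undefined (missing, NaN) when ``ijc + sjc == 0``, and agree exactly
whenever the two effective lengths are equal.

Filtering follows the study design this package targets: an event is kept
only if, in *every* replicate group, the mean total junction count
(``ijc + sjc``) is at least ``min_mean_total`` (default 10), and only events
on autosomes survive — the chicken Z/W sex chromosomes are excluded because
of incomplete dosage compensation, and mitochondrial/unplaced sequences are
dropped conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_SEX_CHROMS = frozenset({"Z", "W"})
DEFAULT_EXTRA_DROP = frozenset({"MT"})

REASON_KEPT = "kept"
REASON_LOW_COUNT = "low_count"
REASON_SEX_CHROM = "sex_chromosome"


@dataclass
class FilterReport:
    """Bookkeeping for event filtering.

    ``reasons`` maps every input event_id to one of ``kept``, ``low_count``,
    ``sex_chromosome``.
    """

    n_input_events: int
    n_after_lowcount: int
    n_after_autosome: int
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def kept_events(self) -> list[str]:
        return [e for e, r in self.reasons.items() if r == REASON_KEPT]


def compute_psi(ijc, sjc, inc_len=1, skip_len=1, length_normalize: bool = True):
    """PSI for one record or elementwise over arrays; NaN where ijc+sjc == 0."""
    ijc = np.asarray(ijc, dtype=float)
    sjc = np.asarray(sjc, dtype=float)
    if length_normalize:
        inc = ijc / np.asarray(inc_len, dtype=float)
        skip = sjc / np.asarray(skip_len, dtype=float)
    else:
        inc, skip = ijc, sjc
    total = inc + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(ijc + sjc > 0, inc / np.where(total > 0, total, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def psi_table(counts: pd.DataFrame, length_normalize: bool = True) -> pd.DataFrame:
    """Long-format per-sample PSI table: (event_id, sample_id, psi)."""
    psi = compute_psi(
        counts["ijc"].to_numpy(),
        counts["sjc"].to_numpy(),
        counts["inc_len"].to_numpy(),
        counts["skip_len"].to_numpy(),
        length_normalize=length_normalize,
    )
    out = counts[["event_id", "sample_id"]].copy()
    out["psi"] = psi
    return out


def lowcount_filter(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_mean_total: float = 10.0,
) -> FilterReport:
    """Keep an event iff every replicate group's mean total count is >= threshold.

    ``groups`` maps a group label to its sample ids (e.g. one entry per
    (strain, sex) cell present in a tissue).  Raises on an empty group.
    """
    for label, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"replicate group {label!r} is empty")

    df = counts.copy()
    df["total"] = df["ijc"] + df["sjc"]
    sample_to_group: dict[str, str] = {}
    for label, samples in groups.items():
        for s in samples:
            sample_to_group[s] = label
    df = df[df["sample_id"].isin(sample_to_group)]
    df["group"] = df["sample_id"].map(sample_to_group)

    group_means = df.groupby(["event_id", "group"])["total"].mean().unstack("group")
    # An event absent from a group entirely has no coverage there: treat as 0.
    group_means = group_means.reindex(columns=list(groups)).fillna(0.0)
    keep = (group_means >= min_mean_total).all(axis=1)

    all_events = list(pd.unique(counts["event_id"]))
    reasons = {
        e: (REASON_KEPT if bool(keep.get(e, False)) else REASON_LOW_COUNT)
        for e in all_events
    }
    n_kept = sum(r == REASON_KEPT for r in reasons.values())
    return FilterReport(
        n_input_events=len(all_events),
        n_after_lowcount=n_kept,
        n_after_autosome=n_kept,
        reasons=reasons,
    )


def autosome_filter(
    events: pd.DataFrame,
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
    extra_drop: frozenset[str] | set[str] = DEFAULT_EXTRA_DROP,
) -> FilterReport:
    """Drop events on sex chromosomes (Z/W) and on MT/unplaced sequences."""
    drop = {c.upper() for c in set(sex_chroms) | set(extra_drop)}
    reasons = {}
    for row in events.itertuples(index=False):
        chrom = str(row.chrom).upper()
        on_drop = chrom in drop or chrom.startswith(("SCAFFOLD", "UN", "JH", "KZ", "NW"))
        reasons[row.event_id] = REASON_SEX_CHROM if on_drop else REASON_KEPT
    n_kept = sum(r == REASON_KEPT for r in reasons.values())
    return FilterReport(
        n_input_events=len(reasons),
        n_after_lowcount=len(reasons),
        n_after_autosome=n_kept,
        reasons=reasons,
    )


def filter_events(
    events: pd.DataFrame,
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_mean_total: float = 10.0,
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
) -> FilterReport:
    """Apply the low-count and autosome filters; combined report.

    The two filters commute; the report attributes each dropped event to the
    first rule that catches it in the order low-count, then autosome.
    """
    low = lowcount_filter(counts, groups, min_mean_total=min_mean_total)
    auto = autosome_filter(events, sex_chroms=sex_chroms)
    reasons = {}
    for e in events["event_id"]:
        if low.reasons.get(e, REASON_LOW_COUNT) != REASON_KEPT:
            reasons[e] = REASON_LOW_COUNT
        elif auto.reasons[e] != REASON_KEPT:
            reasons[e] = REASON_SEX_CHROM
        else:
            reasons[e] = REASON_KEPT
    n_after_low = sum(low.reasons.get(e, REASON_LOW_COUNT) == REASON_KEPT for e in events["event_id"])
    n_kept = sum(r == REASON_KEPT for r in reasons.values())
    return FilterReport(
        n_input_events=len(events),
        n_after_lowcount=n_after_low,
        n_after_autosome=n_kept,
        reasons=reasons,
    )


def group_mean_psi(
    psi: pd.DataFrame,
    sheet: pd.DataFrame,
    by: Sequence[str] = ("strain", "sex", "tissue"),
) -> pd.DataFrame:
    """Arithmetic mean of defined replicate PSI values per (event, group).

    Missing replicate values are ignored; a group whose replicates are all
    missing yields a missing mean with ``n_replicates = 0``.
    """
    merged = psi.merge(sheet[["sample_id", *by]], on="sample_id", how="inner")
    grouped = merged.groupby(["event_id", *list(by)])["psi"]
    out = grouped.agg(mean_psi="mean", n_replicates="count").reset_index()
    return out
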