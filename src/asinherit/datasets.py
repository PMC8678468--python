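"""Bundled reference tables from a chicken reciprocal-cross splicing study.

A published broiler x layer (Cornish Game x White Leghorn) reciprocal-cross
experiment classified parentally divergent splice events in brain, breast
muscle and liver into the nine inheritance categories this package
implements, across the four comparison groups (MC/FC/MR/FR; only the male
groups exist for liver because hybrid-female liver samples were removed).
The per-(tissue, group) category counts and the per-tissue numbers of events
entering classification are bundled here so the summary statistics can be
validated against known output without any sequence data.
"""

from __future__ import annotations

import pandas as pd

from .inheritance import CATEGORIES

#: Events entering classification ("used for further analysis") per tissue —
#: the denominators for all percentage summaries.
REFERENCE_DENOMINATORS = {"brain": 1030, "muscle": 1950, "liver": 754}

# tissue, group, conserved, additive CG>WL, additive CG<WL, dominant-CG up,
# dominant-CG down, dominant-WL up, dominant-WL down, over-, under-dominant
_ROWS = [
    ("brain", "FC", 350, 55, 42, 117, 42, 102, 40, 120, 121),
    ("brain", "MC", 371, 45, 42, 104, 36, 91, 65, 118, 119),
    ("brain", "FR", 333, 41, 38, 144, 52, 100, 55, 109, 117),
    ("brain", "MR", 371, 54, 43, 104, 35, 87, 65, 111, 121),
    ("muscle", "FC", 808, 94, 84, 145, 121, 182, 117, 119, 128),
    ("muscle", "MC", 840, 103, 87, 111, 65, 250, 153, 91, 93),
    ("muscle", "FR", 769, 100, 68, 186, 222, 127, 86, 126, 130),
    ("muscle", "MR", 794, 91, 104, 160, 123, 195, 118, 100, 120),
    ("liver", "MC", 261, 29, 37, 86, 41, 46, 39, 78, 99),
    ("liver", "MR", 259, 26, 28, 96, 47, 52, 33, 73, 90),
]


def reference_summary_table() -> pd.DataFrame:
    """The reference per-(tissue, group) category counts as a SummaryTable frame.

    Same wide layout as :func:`asinherit.summarize.tabulate` output: one
    column per category plus ``n_classified`` (the row sum; rows can classify
    fewer events than the tissue denominator when group means are missing).
    """
    table = pd.DataFrame(_ROWS, columns=["tissue", "group", *CATEGORIES])
    table["n_classified"] = table[list(CATEGORIES)].sum(axis=1)
    return table


def reference_calls() -> pd.DataFrame:
    """The reference counts expanded to one synthetic call row per event.

    PSI columns are absent — only (tissue, group, category) multiplicity is
    represented — which is all the tabulation and percentage operations need.
    """
    table = reference_summary_table()
    rows = []
    for rec in table.itertuples(index=False):
        for cat in CATEGORIES:
            rows += [
                {"tissue": rec.tissue, "group": rec.group, "method": "threshold",
                 "category": cat}
            ] * int(getattr(rec, cat))
    calls = pd.DataFrame(rows)
    calls["event_id"] = [f"ref{i:06d}" for i in range(len(calls))]
    return calls
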