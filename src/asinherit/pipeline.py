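"""End-to-end orchestration: files in, classified inheritance patterns out.

``run_pipeline`` chains the stages on an input directory in the layout the
simulator emits (and that a real rMATS run can be massaged into):

* ``{SE,A3SS,A5SS,MXE,RI}.MATS.JC.txt`` — junction-count tables (any subset);
* ``sample_sheet.tsv`` — sample to (strain, sex, tissue, replicate) mapping;
* ``groups.tsv`` — the replicate order behind SAMPLE_1/SAMPLE_2 cells.

Each stage writes its result as TSV into the output directory, so any stage
can be re-run or replaced (e.g. substituting an external rMATS divergence
table for the internal test) without touching the others.  A ``manifest.json``
records the configuration, package version and input checksums; given the
same inputs and configuration the non-log outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .divergence import divergence_scan
from .inheritance import (
    COLLAPSE,
    build_comparison_groups,
    classify_group_fisher,
    classify_group_threshold,
    consensus,
    merge_divergent_with_expressed,
)
from .io_rmats import (
    EVENT_TYPES,
    check_counts_against_sheet,
    read_rmats_table,
    read_sample_sheet,
)
from .quantify import filter_events, group_mean_psi, psi_table
from .summarize import (
    CONTRASTS,
    FAMILIES,
    category_percentages,
    kruskal_wallis_across_tissues,
    mannwhitney_updown,
    summary_report,
    tabulate,
)


@dataclass
class RunConfig:
    """Validated pipeline configuration with the documented defaults."""

    input_dir: str
    out_dir: str
    length_normalize: bool = True
    min_mean_total: float = 10.0
    sex_chroms: tuple[str, ...] = ("Z", "W")
    alpha: float = 0.05
    test: str = "betabinom"  # or "external"
    external_pvals: str | None = None
    fold: float = 1.25
    eps: float = 0.01
    method: str = "threshold"  # "threshold" | "fisher" | "both"
    consensus_min: int = 2
    consensus_key: str = "gene_id"
    seed: int = 20211203


def validate_config(mapping: dict) -> RunConfig:
    """Fill defaults, reject unknown keys and contradictory values."""
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    missing = [k for k in ("input_dir", "out_dir") if k not in mapping]
    if missing:
        raise ValueError(f"missing required configuration key(s): {', '.join(missing)}")
    config = RunConfig(**mapping)
    if not config.fold > 1:
        raise ValueError(f"fold must be > 1, got {config.fold}")
    if not (0 < config.alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.min_mean_total <= 0:
        raise ValueError("min_mean_total must be positive")
    if config.consensus_min < 1:
        raise ValueError("consensus_min must be >= 1")
    if config.method not in ("threshold", "fisher", "both"):
        raise ValueError(f"method must be threshold/fisher/both, got {config.method!r}")
    if config.test not in ("betabinom", "external"):
        raise ValueError(f"test must be betabinom/external, got {config.test!r}")
    if config.test == "external" and not config.external_pvals:
        raise ValueError("test='external' requires external_pvals")
    if config.consensus_key not in ("gene_id", "event_id"):
        raise ValueError("consensus_key must be gene_id or event_id")
    return config


def _read_inputs(config: RunConfig):
    in_dir = Path(config.input_dir)
    sheet = read_sample_sheet(in_dir / "sample_sheet.tsv")
    groups_file = in_dir / "groups.tsv"
    if not groups_file.exists():
        raise FileNotFoundError(f"{groups_file} (SAMPLE_1/SAMPLE_2 replicate order) not found")
    group_order = {}
    for line in groups_file.read_text().splitlines()[1:]:
        label, samples = line.split("\t")
        group_order[label] = samples.split(",") if samples else []

    all_events, all_counts = [], []
    for event_type in EVENT_TYPES:
        path = in_dir / f"{event_type}.MATS.JC.txt"
        if not path.exists():
            continue
        events, counts = read_rmats_table(
            path, event_type, group_order["SAMPLE_1"], group_order["SAMPLE_2"]
        )
        all_events.append(events)
        all_counts.append(counts)
    if not all_events:
        raise FileNotFoundError(f"no *.MATS.JC.txt tables found in {in_dir}")
    events = pd.concat(all_events, ignore_index=True)
    if events["event_id"].duplicated().any():
        # rMATS numbers events per file; disambiguate ids across event types
        for ev, cnt in zip(all_events, all_counts):
            prefix = ev["event_type"].iloc[0] + ":"
            ev["event_id"] = prefix + ev["event_id"]
            cnt["event_id"] = prefix + cnt["event_id"]
        events = pd.concat(all_events, ignore_index=True)
    counts = pd.concat(all_counts, ignore_index=True)
    check_counts_against_sheet(counts, sheet)
    return events, counts, sheet


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write per-stage TSVs plus a manifest.

    Returns a name -> path mapping of the written artefacts.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events, counts, sheet = _read_inputs(config)

    external = None
    if config.test == "external":
        external = pd.read_csv(config.external_pvals, sep="\t")

    methods = ["threshold", "fisher"] if config.method == "both" else [config.method]
    tissues = sorted(sheet["tissue"].unique())

    all_group_psi = []
    all_divergence = []
    all_calls = {m: [] for m in methods}
    denominators: dict[str, int] = {}
    filter_rows = []

    for tissue in tissues:
        t_sheet = sheet[sheet["tissue"] == tissue]
        t_counts = counts[counts["sample_id"].isin(set(t_sheet["sample_id"]))]
        rep_groups = {
            f"{strain}_{sex}": grp["sample_id"].tolist()
            for (strain, sex), grp in t_sheet.groupby(["strain", "sex"])
        }
        report = filter_events(
            events, t_counts, rep_groups,
            min_mean_total=config.min_mean_total,
            sex_chroms=set(config.sex_chroms),
        )
        kept = set(report.kept_events)
        filter_rows.append(
            {
                "tissue": tissue,
                "n_input": report.n_input_events,
                "n_after_lowcount": report.n_after_lowcount,
                "n_after_autosome": report.n_after_autosome,
            }
        )
        t_counts = t_counts[t_counts["event_id"].isin(kept)]

        psi = psi_table(t_counts, length_normalize=config.length_normalize)
        gpsi = group_mean_psi(psi, t_sheet)
        all_group_psi.append(gpsi)

        div = divergence_scan(
            t_counts, t_sheet, tissue,
            alpha=config.alpha,
            length_normalize=config.length_normalize,
            external_pvalues=external,
        )
        all_divergence.append(div)

        cmp_groups = build_comparison_groups(t_sheet, tissue)
        merged_union: set[str] = set()
        for label, group in sorted(cmp_groups.items()):
            event_ids = merge_divergent_with_expressed(div, gpsi, group)
            merged_union |= set(event_ids)
            for m in methods:
                if m == "threshold":
                    calls = classify_group_threshold(
                        gpsi, group, event_ids, fold=config.fold, eps=config.eps
                    )
                else:
                    calls = classify_group_fisher(
                        t_counts, group, event_ids, alpha=config.alpha
                    )
                all_calls[m].append(calls)
        denominators[tissue] = len(merged_union)

    gene_map = events.set_index("event_id")["gene_id"]
    written: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[name] = path

    write("group_mean_psi.tsv", pd.concat(all_group_psi, ignore_index=True))
    write("divergence.tsv", pd.concat(all_divergence, ignore_index=True))
    write("filter_report.tsv", pd.DataFrame(filter_rows))
    write(
        "denominators.tsv",
        pd.DataFrame(
            [{"tissue": t, "n_merged": n} for t, n in sorted(denominators.items())]
        ),
    )

    stats_frames = []
    for m in methods:
        calls = (
            pd.concat(all_calls[m], ignore_index=True)
            if all_calls[m]
            else pd.DataFrame(columns=["event_id", "tissue", "group", "method", "category"])
        )
        if not calls.empty:
            calls.insert(1, "gene_id", calls["event_id"].map(gene_map))
        write(f"calls_{m}.tsv", calls)

        cons = consensus(
            calls, min_groups=config.consensus_min, collapse=True, key=config.consensus_key
        ) if not calls.empty else pd.DataFrame()
        write(f"consensus_{m}.tsv", cons)

        table = tabulate(calls)
        write(f"summary_{m}.tsv", table)
        if not table.empty and all(denominators.get(t, 0) > 0 for t in table["tissue"].unique()):
            pct = category_percentages(table, denominators)
            write(f"percentages_{m}.tsv", pct)
            stats_frames.append(_stats_table(table, pct, m))

    if stats_frames:
        stats = pd.concat(stats_frames, ignore_index=True)
        write("stats.tsv", stats)
        first = methods[0]
        if f"percentages_{first}.tsv" in written:
            report_path = out_dir / "report.md"
            report_path.write_text(
                summary_report(
                    pd.read_csv(written[f"summary_{first}.tsv"], sep="\t"),
                    pd.read_csv(written[f"percentages_{first}.tsv"], sep="\t"),
                    stats[stats["method"] == first],
                )
            )
            written["report.md"] = report_path

    if config.method == "both":
        write("method_overlap.tsv", method_overlap(
            pd.read_csv(written["calls_threshold.tsv"], sep="\t"),
            pd.read_csv(written["calls_fisher.tsv"], sep="\t"),
        ))

    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "inputs": {
            p.name: _checksum(p) for p in sorted(in_dir.glob("*.tsv"))
        } | {
            p.name: _checksum(p) for p in sorted(in_dir.glob("*.MATS.JC.txt"))
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written["manifest.json"] = manifest_path
    return written


def _stats_table(table: pd.DataFrame, pct: pd.DataFrame, method: str) -> pd.DataFrame:
    """Kruskal-Wallis per family (if >= 2 tissues) and Mann-Whitney per tissue."""
    rows = []
    if pct["tissue"].nunique() >= 2:
        for family in FAMILIES:
            try:
                h, p = kruskal_wallis_across_tissues(pct, family)
            except ValueError:
                continue
            rows.append(
                {"method": method, "test": "kruskal_wallis", "scope": family,
                 "statistic": h, "p_value": p}
            )
    for tissue in sorted(table["tissue"].unique()):
        for contrast in CONTRASTS:
            try:
                u, p = mannwhitney_updown(table, tissue, contrast)
            except ValueError:
                continue
            rows.append(
                {"method": method, "test": "mann_whitney", "scope": f"{tissue}:{contrast}",
                 "statistic": u, "p_value": p}
            )
    return pd.DataFrame(rows)


def method_overlap(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Per-category Jaccard overlap between two call sets.

    Calls are keyed by (event, tissue, group); for each collapsed category
    the overlap is |both methods called it| / |either method called it|.
    """
    key = ["event_id", "tissue", "group"]

    def keyed(calls: pd.DataFrame) -> pd.DataFrame:
        out = calls[key + ["category"]].copy()
        out["mode"] = out["category"].map(COLLAPSE)
        return out

    a = keyed(calls_a)
    b = keyed(calls_b)
    rows = []
    for mode in sorted(set(COLLAPSE.values())):
        sa = set(map(tuple, a.loc[a["mode"] == mode, key].to_numpy()))
        sb = set(map(tuple, b.loc[b["mode"] == mode, key].to_numpy()))
        union = sa | sb
        rows.append(
            {
                "mode": mode,
                "n_threshold": len(sa),
                "n_fisher": len(sb),
                "n_both": len(sa & sb),
                "overlap": (len(sa & sb) / len(union)) if union else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def recovery_metrics(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    consensus_calls: pd.DataFrame,
    key: str = "event_id",
) -> dict[str, float]:
    """Compare pipeline output with the simulator's planted modes.

    Returns per-(event, group) call accuracy on collapsed modes, and
    consensus-level accuracy (fraction of consensus calls whose mode matches
    the planted one), with the respective denominators.
    """
    planted = truth.set_index("event_id")["planted_mode"]
    out: dict[str, float] = {}
    if not calls.empty:
        modes = calls["category"].map(COLLAPSE)
        match = modes.to_numpy() == calls["event_id"].map(planted).to_numpy()
        out["per_call_accuracy"] = float(match.mean())
        out["n_calls"] = float(len(calls))
    else:
        out["per_call_accuracy"] = float("nan")
        out["n_calls"] = 0.0
    if consensus_calls is not None and not consensus_calls.empty:
        truth_keyed = truth.set_index(key)["planted_mode"]
        match = (
            consensus_calls["category"].to_numpy()
            == consensus_calls[key].map(truth_keyed).to_numpy()
        )
        out["consensus_accuracy"] = float(match.mean())
        out["n_consensus"] = float(len(consensus_calls))
    else:
        out["consensus_accuracy"] = float("nan")
        out["n_consensus"] = 0.0
    return out
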