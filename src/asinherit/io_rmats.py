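"""Reading and writing rMATS-style junction-count tables and sample sheets.

The on-disk dialect is the ``*.MATS.JC.txt`` layout produced by rMATS: one
tab-separated file per splice-event type (SE, A3SS, A5SS, MXE, RI), one row
per event, with per-replicate inclusion- and skipping-junction counts
comma-joined inside a single cell for each of the two sample groups.

Internally everything is normalised into two tidy pandas DataFrames:

``events``
    one row per splice event — ``event_id``, ``event_type``, ``gene_id``,
    ``chrom`` (``chr`` prefix stripped), ``strand`` and ``coords`` (a tuple of
    0-based half-open genomic positions whose arity depends on the event type).

``counts``
    one row per (event, sample) — ``event_id``, ``sample_id``, ``ijc``,
    ``sjc``, ``inc_len``, ``skip_len``.

The rMATS statistical columns (PValue, FDR, IncLevel1/2), when present, are
ignored: every statistic downstream is recomputed from the raw counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

EVENT_TYPES = ("SE", "A3SS", "A5SS", "MXE", "RI")

#: rMATS coordinate columns per event type, in file order.  SE and RI carry
#: three exon intervals (cassette/retained + flanking), MXE four, and the
#: alternative-splice-site types a long/short/flanking exon triple.
COORD_COLUMNS: dict[str, tuple[str, ...]] = {
    "SE": (
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "MXE": (
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "A3SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "A5SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "RI": (
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
}

COUNT_COLUMNS = (
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen",
)

STRAINS = ("CG", "WL", "CL", "LC")
SEXES = ("M", "F")
TISSUES = ("brain", "muscle", "liver")

EVENT_COLUMNS = ("event_id", "event_type", "gene_id", "chrom", "strand", "coords")
COUNT_RECORD_COLUMNS = ("event_id", "sample_id", "ijc", "sjc", "inc_len", "skip_len")


class RmatsFormatError(ValueError):
    """A junction-count table or sample sheet violates the expected dialect."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix; chromosome names are stored bare."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


def _split_counts(cell: str, line_no: int, column: str, n_expected: int) -> list[int]:
    parts = str(cell).strip().split(",")
    if len(parts) != n_expected:
        raise RmatsFormatError(
            f"line {line_no}: column {column} has {len(parts)} replicate "
            f"counts, expected {n_expected}"
        )
    try:
        values = [int(p) for p in parts]
    except ValueError as exc:
        raise RmatsFormatError(f"line {line_no}: non-integer count in {column}: {cell!r}") from exc
    if any(v < 0 for v in values):
        raise RmatsFormatError(f"line {line_no}: negative count in {column}: {cell!r}")
    return values


def validate_events(events: pd.DataFrame) -> None:
    """Check event-table invariants: coord arity per type, half-open intervals."""
    for row in events.itertuples(index=False):
        if row.event_type not in EVENT_TYPES:
            raise RmatsFormatError(f"unknown event type {row.event_type!r}")
        arity = len(COORD_COLUMNS[row.event_type])
        coords = tuple(row.coords)
        if len(coords) != arity:
            raise RmatsFormatError(
                f"event {row.event_id}: {row.event_type} needs {arity} "
                f"coordinates, got {len(coords)}"
            )
        if any(c < 0 for c in coords):
            raise RmatsFormatError(f"event {row.event_id}: negative coordinate")
        for start, end in zip(coords[::2], coords[1::2]):
            if not start < end:
                raise RmatsFormatError(
                    f"event {row.event_id}: interval [{start}, {end}) is empty or inverted"
                )
        if row.strand not in ("+", "-"):
            raise RmatsFormatError(f"event {row.event_id}: bad strand {row.strand!r}")
    if events["event_id"].duplicated().any():
        dups = events.loc[events["event_id"].duplicated(), "event_id"].tolist()
        raise RmatsFormatError(f"duplicate event ids: {dups[:5]}")


def read_rmats_table(
    path: str | Path,
    event_type: str,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse one rMATS JC table into (events, counts) DataFrames.

    ``group1_samples`` / ``group2_samples`` name, in order, the replicates
    behind the comma-joined ``*_SAMPLE_1`` / ``*_SAMPLE_2`` cells.

    Raises
    ------
    RmatsFormatError
        If a required column is missing, a replicate cell's arity does not
        match the declared sample list, or a row is otherwise malformed
        (reported with its 1-based line number in the file).
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"event_type must be one of {EVENT_TYPES}, got {event_type!r}")
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["ID", "GeneID", "chr", "strand", *COORD_COLUMNS[event_type], *COUNT_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise RmatsFormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    event_rows: list[dict] = []
    count_rows: list[dict] = []
    for i, row in enumerate(table.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header line
        rec = dict(zip(table.columns, row))
        try:
            coords = tuple(int(rec[c]) for c in COORD_COLUMNS[event_type])
        except ValueError as exc:
            raise RmatsFormatError(f"line {line_no}: non-integer coordinate") from exc
        event_id = str(rec["ID"])
        event_rows.append(
            {
                "event_id": event_id,
                "event_type": event_type,
                "gene_id": str(rec["GeneID"]),
                "chrom": normalize_chrom(rec["chr"]),
                "strand": str(rec["strand"]).strip(),
                "coords": coords,
            }
        )
        try:
            inc_len = int(rec["IncFormLen"])
            skip_len = int(rec["SkipFormLen"])
        except ValueError as exc:
            raise RmatsFormatError(f"line {line_no}: non-integer effective length") from exc
        if inc_len < 1 or skip_len < 1:
            raise RmatsFormatError(f"line {line_no}: effective lengths must be >= 1")
        for samples, ijc_col, sjc_col in (
            (group1_samples, "IJC_SAMPLE_1", "SJC_SAMPLE_1"),
            (group2_samples, "IJC_SAMPLE_2", "SJC_SAMPLE_2"),
        ):
            ijc = _split_counts(rec[ijc_col], line_no, ijc_col, len(samples))
            sjc = _split_counts(rec[sjc_col], line_no, sjc_col, len(samples))
            for sample_id, i_val, s_val in zip(samples, ijc, sjc):
                count_rows.append(
                    {
                        "event_id": event_id,
                        "sample_id": sample_id,
                        "ijc": i_val,
                        "sjc": s_val,
                        "inc_len": inc_len,
                        "skip_len": skip_len,
                    }
                )

    events = pd.DataFrame(event_rows, columns=list(EVENT_COLUMNS))
    counts = pd.DataFrame(count_rows, columns=list(COUNT_RECORD_COLUMNS))
    if not events.empty:
        validate_events(events)
    return events, counts


def write_rmats_table(
    events: pd.DataFrame,
    counts: pd.DataFrame,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
    path: str | Path,
) -> Path:
    """Emit an rMATS-dialect JC table that :func:`read_rmats_table` round-trips.

    All events must share one event type, and every (event, sample) pair for
    the declared groups must have a count record; missing pairs raise with an
    explicit listing.
    """
    path = Path(path)
    if events.empty:
        etypes = set()
    else:
        etypes = set(events["event_type"].unique())
        if len(etypes) > 1:
            raise ValueError(f"one table per event type; got {sorted(etypes)}")
    event_type = etypes.pop() if etypes else "SE"
    coord_cols = COORD_COLUMNS[event_type]

    wide = counts.set_index(["event_id", "sample_id"]) if not counts.empty else None
    all_samples = list(group1_samples) + list(group2_samples)
    missing_pairs = []
    if not events.empty:
        for event_id in events["event_id"]:
            for s in all_samples:
                if wide is None or (event_id, s) not in wide.index:
                    missing_pairs.append((event_id, s))
    if missing_pairs:
        raise ValueError(f"missing count records for (event, sample) pairs: {missing_pairs[:10]}")

    header = ["ID", "GeneID", "geneSymbol", "chr", "strand", *coord_cols,
              "ID.1", *COUNT_COLUMNS]
    lines = ["\t".join(header)]
    for row in events.itertuples(index=False):
        sub = wide.loc[row.event_id]
        ijc1 = ",".join(str(int(sub.loc[s, "ijc"])) for s in group1_samples)
        sjc1 = ",".join(str(int(sub.loc[s, "sjc"])) for s in group1_samples)
        ijc2 = ",".join(str(int(sub.loc[s, "ijc"])) for s in group2_samples)
        sjc2 = ",".join(str(int(sub.loc[s, "sjc"])) for s in group2_samples)
        first = sub.loc[all_samples[0]]
        fields = [
            row.event_id, row.gene_id, row.gene_id, row.chrom, row.strand,
            *[str(int(c)) for c in row.coords],
            row.event_id, ijc1, sjc1, ijc2, sjc2,
            str(int(first["inc_len"])), str(int(first["skip_len"])),
        ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet (TSV).

    Columns: ``sample_id``, ``strain`` (CG/WL/CL/LC), ``sex`` (M/F),
    ``tissue`` (brain/muscle/liver), ``replicate_index`` (positive int).
    The (strain, sex, tissue, replicate_index) combination must be unique.
    """
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "strain", "sex", "tissue", "replicate_index"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise RmatsFormatError(f"sample sheet missing column(s): {', '.join(missing)}")
    sheet = sheet[required].copy()
    sheet["replicate_index"] = sheet["replicate_index"].astype(int)

    bad_strain = sorted(set(sheet["strain"]) - set(STRAINS))
    if bad_strain:
        raise RmatsFormatError(f"unknown strain value(s): {bad_strain}")
    bad_sex = sorted(set(sheet["sex"]) - set(SEXES))
    if bad_sex:
        raise RmatsFormatError(f"unknown sex value(s): {bad_sex}")
    bad_tissue = sorted(set(sheet["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise RmatsFormatError(f"unknown tissue value(s): {bad_tissue}")
    if (sheet["replicate_index"] < 1).any():
        raise RmatsFormatError("replicate_index must be positive")

    key = ["strain", "sex", "tissue", "replicate_index"]
    if sheet.duplicated(key).any():
        dups = sheet.loc[sheet.duplicated(key), key].to_records(index=False).tolist()
        raise RmatsFormatError(f"duplicate (strain, sex, tissue, replicate) rows: {dups[:5]}")
    if sheet["sample_id"].duplicated().any():
        raise RmatsFormatError("duplicate sample_id values")
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["sample_id", "strain", "sex", "tissue", "replicate_index"]
    sheet[cols].to_csv(path, sep="\t", index=False)
    return path


def check_counts_against_sheet(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    """Every sample referenced by a count record must exist in the sheet."""
    unknown = set(counts["sample_id"].unique()) - set(sheet["sample_id"])
    if unknown:
        raise RmatsFormatError(f"count records reference unknown sample(s): {sorted(unknown)[:10]}")
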