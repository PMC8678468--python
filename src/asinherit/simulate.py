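"""Synthetic reciprocal-cross splicing datasets with known inheritance modes.

The generator emulates the experimental design this package analyses: two
divergent parental strains (CG, WL), the two reciprocal F1 hybrids (CL, LC),
sexes and replicate structure, three tissues, and junction counts written in
the rMATS dialect so the whole pipeline runs on files it could have received
from a real aligner/rMATS run.

Per event, a true PSI triple (CG, WL, hybrid) is planted so that the
noiseless fold-ratio classification recovers a requested inheritance mode
with a configurable safety margin around the 1.25-fold boundary.  Counts are
then drawn per sample: total junction depth is negative-binomial (Poisson
when the dispersion is zero) and the inclusion count is beta-binomial around
the true PSI with intra-class correlation ``rho`` — the same noise family
the divergence test assumes.

A configurable fraction of events is planted at low depth (to exercise the
low-count filter) and on the Z sex chromosome (to exercise the autosome
filter); both default to small, realistic contamination levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .inheritance import CATEGORIES, COLLAPSE, classify_threshold, fold_ratio
from .io_rmats import (
    COORD_COLUMNS,
    validate_sample_sheet,
    write_rmats_table,
    write_sample_sheet,
)

#: Mode mix loosely matching the published chicken reciprocal-cross tables
#: (roughly: conserved 36%, additive 10%, each dominant family 16%,
#: transgressive 22%).
DEFAULT_MODE_PROPORTIONS = {
    "conserved": 0.36,
    "additive_cg_high": 0.05,
    "additive_wl_high": 0.05,
    "dominant_cg_up": 0.09,
    "dominant_cg_down": 0.07,
    "dominant_wl_up": 0.09,
    "dominant_wl_down": 0.07,
    "over_dominant": 0.11,
    "under_dominant": 0.11,
}

DEFAULT_EVENT_TYPE_MIX = {"SE": 0.36, "A3SS": 0.24, "A5SS": 0.18, "MXE": 0.15, "RI": 0.07}


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults encode the conditions the downstream stages are validated under:
    3 replicates per (strain, sex) cell, mean junction depth 100 per event
    and sample, biological intra-class correlation ``rho = 0.05``, parental
    PSI separation 0.3 for non-conserved events, and planted modes sitting a
    factor ``fold_margin`` clear of the 1.25-fold decision boundary.
    """

    n_events: int = 2000
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    n_replicates: int | Mapping[tuple[str, str], int] = 3
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1
    psi_overdispersion: float = 0.05
    parental_separation: float = 0.3
    fold: float = 1.25
    fold_margin: float = 1.15
    eps: float = 0.01
    seed: int = 20211203
    tissues: tuple[str, ...] = ("brain", "muscle", "liver")
    event_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_TYPE_MIX)
    )
    psi_range: tuple[float, float] = (0.05, 0.95)
    low_expression_fraction: float = 0.05
    low_expression_depth: float = 4.0
    sex_chrom_fraction: float = 0.03
    parent_origin_offset: float = 0.0
    drop_liver_hybrid_females: bool = False

    def validate(self) -> None:
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_proportions must sum to 1, got {total}")
        unknown = set(self.mode_proportions) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mode_proportions: {sorted(unknown)}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not (0 <= self.psi_overdispersion < 1):
            raise ValueError("psi_overdispersion must lie in [0, 1)")
        if not (1.0 < self.fold_margin <= self.fold):
            raise ValueError(
                "fold_margin must lie in (1, fold]: the 'similar' side of a planted "
                "triple needs fold/fold_margin >= 1"
            )
        if not (0 < self.parental_separation <= 1):
            raise ValueError("parental_separation must lie in (0, 1]")


def replicate_map(config: SimConfig) -> dict[tuple[str, str], int]:
    if isinstance(config.n_replicates, int):
        return {
            (strain, sex): config.n_replicates
            for strain in ("CG", "WL", "CL", "LC")
            for sex in ("M", "F")
        }
    return dict(config.n_replicates)


def make_reference_design(**overrides) -> SimConfig:
    """SimConfig for the reference reciprocal-cross design.

    4 strains x 2 sexes x 3 replicates with only two CL females, i.e. 23
    sample columns per tissue across brain, muscle and liver, and a
    published-table-like mode mix.  Keyword overrides replace any field.
    """
    reps = {
        (strain, sex): 3 for strain in ("CG", "WL", "CL", "LC") for sex in ("M", "F")
    }
    reps[("CL", "F")] = 2
    base = SimConfig(n_replicates=reps)
    config = replace(base, **overrides)
    config.validate()
    return config


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _similar_window(p: float, fold_s: float, eps: float, lo: float, hi: float):
    """PSI window whose fold-ratio to ``p`` is <= fold_s, clipped to [lo, hi]."""
    a = (p + eps) / fold_s - eps
    b = (p + eps) * fold_s - eps
    return max(a, lo), min(b, hi)


def plant_psi_triple(
    category: str,
    rng: np.random.Generator,
    parental_separation: float = 0.3,
    fold: float = 1.25,
    fold_margin: float = 1.15,
    eps: float = 0.01,
    psi_range: tuple[float, float] = (0.05, 0.95),
    max_attempts: int = 10000,
) -> tuple[float, float, float]:
    """Draw a true (psi_cg, psi_wl, psi_h) triple realising ``category``.

    Every "similar" relation in the planted triple has fold-ratio
    <= fold/fold_margin and every "different" relation >= fold*fold_margin,
    so the noiseless classification is unambiguous with margin; non-conserved
    triples additionally separate the parents by at least
    ``parental_separation``.  Rejection sampling; raises if the constraint
    set cannot be satisfied within ``max_attempts`` draws.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    lo, hi = psi_range
    fold_s = fold / fold_margin   # planted "similar" ratios stay below this
    fold_d = fold * fold_margin   # planted "different" ratios stay above this
    sep = parental_separation

    for _ in range(max_attempts):
        if category == "conserved":
            p1 = _uniform(rng, lo, hi)
            w = _similar_window(p1, fold_s, eps, lo, hi)
            if w[0] >= w[1]:
                continue
            p2 = _uniform(rng, *w)
            wa = _similar_window(p1, fold_s, eps, lo, hi)
            wb = _similar_window(p2, fold_s, eps, lo, hi)
            w = (max(wa[0], wb[0]), min(wa[1], wb[1]))
            if w[0] >= w[1]:
                continue
            h = _uniform(rng, *w)
        else:
            p1 = _uniform(rng, lo, hi)
            p2 = _uniform(rng, lo, hi)
            if abs(p1 - p2) < sep:
                continue
            if category in ("additive_cg_high", "dominant_cg_up", "dominant_wl_down"):
                if not p1 > p2:
                    continue
            if category in ("additive_wl_high", "dominant_cg_down", "dominant_wl_up"):
                if not p2 > p1:
                    continue
            p_lo, p_hi = min(p1, p2), max(p1, p2)
            if category.startswith("additive"):
                h = _uniform(rng, p_lo, p_hi)
            elif category.startswith("dominant_cg"):
                w = _similar_window(p1, fold_s, eps, lo, hi)
                if w[0] >= w[1]:
                    continue
                h = _uniform(rng, *w)
            elif category.startswith("dominant_wl"):
                w = _similar_window(p2, fold_s, eps, lo, hi)
                if w[0] >= w[1]:
                    continue
                h = _uniform(rng, *w)
            elif category == "over_dominant":
                if p_hi >= hi:
                    continue
                h = _uniform(rng, p_hi, hi)
            else:  # under_dominant
                if p_lo <= lo:
                    continue
                h = _uniform(rng, lo, p_lo)

        if _triple_ok(category, p1, p2, h, fold_s, fold_d, eps, sep):
            assert classify_threshold(p1, p2, h, fold=fold, eps=eps) == category
            return p1, p2, h
    raise ValueError(
        f"could not plant a {category!r} triple within {max_attempts} attempts: "
        f"separation={sep}, fold_margin={fold_margin}, psi_range={psi_range} "
        "are jointly infeasible"
    )


def _triple_ok(category, p1, p2, h, fold_s, fold_d, eps, sep) -> bool:
    r1 = fold_ratio(h, p1, eps)
    r2 = fold_ratio(h, p2, eps)
    rp = fold_ratio(p1, p2, eps)
    if category == "conserved":
        return r1 <= fold_s and r2 <= fold_s and rp <= fold_s
    if abs(p1 - p2) < sep:
        return False
    if category.startswith("additive"):
        ordered = p1 > p2 if category == "additive_cg_high" else p2 > p1
        return ordered and min(p1, p2) < h < max(p1, p2) and r1 >= fold_d and r2 >= fold_d
    if category.startswith("dominant_cg"):
        up = category.endswith("up")
        ordered = p1 > p2 if up else p2 > p1
        return ordered and r1 <= fold_s and r2 >= fold_d
    if category.startswith("dominant_wl"):
        up = category.endswith("up")
        ordered = p2 > p1 if up else p1 > p2
        return ordered and r2 <= fold_s and r1 >= fold_d
    if category == "over_dominant":
        return h > max(p1, p2) and r1 >= fold_d and r2 >= fold_d
    return h < min(p1, p2) and r1 >= fold_d and r2 >= fold_d


def plant_ground_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plant one true PSI triple and mode per event.

    Returns a frame with event metadata (id, gene, event type, chromosome)
    and the true PSI values: ``psi_cg``, ``psi_wl``, ``psi_cl``, ``psi_lc``
    (the two hybrids share a true value unless ``parent_origin_offset`` is
    set) plus the planted and collapsed categories and the low-expression /
    sex-chromosome planting flags.
    """
    config.validate()
    cats = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    planted = rng.choice(cats, size=config.n_events, p=probs)

    etypes = list(config.event_type_mix)
    eprobs = np.array([config.event_type_mix[t] for t in etypes], dtype=float)
    eprobs = eprobs / eprobs.sum()
    event_types = rng.choice(etypes, size=config.n_events, p=eprobs)

    low = rng.random(config.n_events) < config.low_expression_fraction
    on_z = rng.random(config.n_events) < config.sex_chrom_fraction

    rows = []
    for i in range(config.n_events):
        cat = str(planted[i])
        p1, p2, h = plant_psi_triple(
            cat, rng,
            parental_separation=config.parental_separation,
            fold=config.fold, fold_margin=config.fold_margin, eps=config.eps,
            psi_range=config.psi_range,
        )
        h_lc = h
        if config.parent_origin_offset:
            h_lc = float(np.clip(h + config.parent_origin_offset, 0.0, 1.0))
        rows.append(
            {
                "event_id": f"ev{i:06d}",
                "gene_id": f"gene{i:06d}",
                "event_type": str(event_types[i]),
                "chrom": "Z" if on_z[i] else str(1 + i % 28),
                "psi_cg": p1,
                "psi_wl": p2,
                "psi_cl": h,
                "psi_lc": h_lc,
                "planted_category": cat,
                "planted_mode": COLLAPSE[cat],
                "low_expression": bool(low[i]),
                "on_sex_chrom": bool(on_z[i]),
            }
        )
    columns = [
        "event_id", "gene_id", "event_type", "chrom",
        "psi_cg", "psi_wl", "psi_cl", "psi_lc",
        "planted_category", "planted_mode", "low_expression", "on_sex_chrom",
    ]
    return pd.DataFrame(rows, columns=columns)


def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    reps = replicate_map(config)
    rows = []
    for tissue in config.tissues:
        for (strain, sex), n in sorted(reps.items()):
            if (
                config.drop_liver_hybrid_females
                and tissue == "liver"
                and sex == "F"
                and strain in ("CL", "LC")
            ):
                continue
            for r in range(1, n + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{sex}_{tissue}_{r}",
                        "strain": strain,
                        "sex": sex,
                        "tissue": tissue,
                        "replicate_index": r,
                    }
                )
    return validate_sample_sheet(pd.DataFrame(rows))


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw junction counts for every (event, sample) of the design.

    Returns ``(events, counts, sheet)`` in the same tidy shapes the rMATS
    reader produces.  Effective lengths are drawn once per event
    (inclusion ~ U{50..300}, skipping ~ U{30..150}) and shared across
    samples; truth PSI values are interpreted on the length-normalised scale.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sheet = _sample_sheet(config)
    if truth.empty:
        events = pd.DataFrame(
            columns=["event_id", "event_type", "gene_id", "chrom", "strand", "coords"]
        )
        counts = pd.DataFrame(
            columns=["event_id", "sample_id", "ijc", "sjc", "inc_len", "skip_len"]
        )
        return events, counts, sheet

    n = len(truth)
    inc_len = rng.integers(50, 301, size=n)
    skip_len = rng.integers(30, 151, size=n)

    event_rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        coords = _random_coords(row.event_type, rng)
        event_rows.append(
            {
                "event_id": row.event_id,
                "event_type": row.event_type,
                "gene_id": row.gene_id,
                "chrom": row.chrom,
                "strand": "+" if rng.random() < 0.5 else "-",
                "coords": coords,
            }
        )
    events = pd.DataFrame(event_rows)

    psi_by_strain = {
        "CG": truth["psi_cg"].to_numpy(),
        "WL": truth["psi_wl"].to_numpy(),
        "CL": truth["psi_cl"].to_numpy(),
        "LC": truth["psi_lc"].to_numpy(),
    }
    depth = np.where(
        truth["low_expression"].to_numpy(), config.low_expression_depth, config.depth_mean
    )

    count_frames = []
    event_ids = truth["event_id"].to_numpy()
    # Truth PSI lives on the length-normalised scale; the count-level
    # inclusion fraction is its length-weighted image, so that the pipeline's
    # normalised PSI estimates the planted value.
    inc_frac_by_strain = {
        strain: psi * inc_len / (psi * inc_len + (1.0 - psi) * skip_len)
        for strain, psi in psi_by_strain.items()
    }
    for sample in sheet.itertuples(index=False):
        totals = _draw_totals_vec(rng, depth, config.depth_dispersion)
        psis = inc_frac_by_strain[sample.strain]
        ijc = _draw_ijc_vec(rng, totals, psis, config.psi_overdispersion)
        count_frames.append(
            pd.DataFrame(
                {
                    "event_id": event_ids,
                    "sample_id": sample.sample_id,
                    "ijc": ijc,
                    "sjc": totals - ijc,
                    "inc_len": inc_len,
                    "skip_len": skip_len,
                }
            )
        )
    counts = pd.concat(count_frames, ignore_index=True)
    return events, counts, sheet


def _draw_totals_vec(rng, means: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def _draw_ijc_vec(rng, totals: np.ndarray, psis: np.ndarray, rho: float) -> np.ndarray:
    psis = np.clip(psis, 1e-6, 1 - 1e-6)
    if rho <= 0:
        return rng.binomial(totals, psis)
    s = (1.0 - rho) / rho
    p = rng.beta(psis * s, (1.0 - psis) * s)
    return rng.binomial(totals, p)


def _random_coords(event_type: str, rng: np.random.Generator) -> tuple[int, ...]:
    """Plausible ordered half-open intervals matching the type's arity."""
    n_intervals = len(COORD_COLUMNS[event_type]) // 2
    pos = int(rng.integers(1000, 10_000_000))
    coords = []
    for _ in range(n_intervals):
        start = pos
        end = start + int(rng.integers(50, 500))
        coords += [start, end]
        pos = end + int(rng.integers(100, 5000))
    return tuple(coords)


def simulate_dataset(
    config: SimConfig, out_dir: str | Path, rng: np.random.Generator | None = None
) -> dict[str, Path]:
    """Generate a complete on-disk dataset: rMATS tables, sample sheet, truth.

    One JC-dialect table per event type present, with SAMPLE_1 = all CG+WL
    samples and SAMPLE_2 = all CL+LC samples (column order recorded in
    ``groups.tsv`` so readers know the replicate layout).  Deterministic for
    a given config: byte-identical files on re-run.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = plant_ground_truth(config, rng)
    events, counts, sheet = simulate_counts(truth, config, rng)

    parent_samples = sheet.loc[sheet["strain"].isin(["CG", "WL"]), "sample_id"].tolist()
    hybrid_samples = sheet.loc[sheet["strain"].isin(["CL", "LC"]), "sample_id"].tolist()

    paths: dict[str, Path] = {}
    for event_type, ev_sub in events.groupby("event_type", sort=True):
        sub_counts = counts[counts["event_id"].isin(set(ev_sub["event_id"]))]
        path = out_dir / f"{event_type}.MATS.JC.txt"
        write_rmats_table(ev_sub, sub_counts, parent_samples, hybrid_samples, path)
        paths[event_type] = path

    paths["sample_sheet"] = write_sample_sheet(sheet, out_dir / "sample_sheet.tsv")
    truth_path = out_dir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    paths["ground_truth"] = truth_path

    groups_path = out_dir / "groups.tsv"
    groups_path.write_text(
        "group\tsamples\n"
        f"SAMPLE_1\t{','.join(parent_samples)}\n"
        f"SAMPLE_2\t{','.join(hybrid_samples)}\n"
    )
    paths["groups"] = groups_path
    return paths
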