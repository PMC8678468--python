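import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asinherit.inheritance import (
    CATEGORIES,
    COLLAPSE,
    SWAP_PARENTS,
    ComparisonGroup,
    build_comparison_groups,
    classify_fisher_frame,
    classify_threshold,
    consensus,
    fisher_pvalue,
    fold_ratio,
    merge_divergent_with_expressed,
)
from tests._oracles import decision_table, fisher_two_sided

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestFoldRatio:
    def test_worked_value(self):
        assert fold_ratio(0.5, 0.4) == pytest.approx(0.51 / 0.41)

    def test_degenerate_equality(self):
        assert fold_ratio(0.0, 0.0) == 1.0
        assert fold_ratio(0.37, 0.37) == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(unit, unit)
    def test_symmetric_and_at_least_one(self, a, b):
        assert fold_ratio(a, b) == fold_ratio(b, a)
        assert fold_ratio(a, b) >= 1.0


class TestClassifyThreshold:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((0.8, 0.2, 0.5), "additive_cg_high"),
            ((0.2, 0.8, 0.5), "additive_wl_high"),
            ((0.8, 0.2, 0.78), "dominant_cg_up"),
            ((0.2, 0.8, 0.22), "dominant_cg_down"),
            ((0.2, 0.8, 0.78), "dominant_wl_up"),
            ((0.8, 0.2, 0.22), "dominant_wl_down"),
            ((0.4, 0.2, 0.9), "over_dominant"),
            ((0.4, 0.6, 0.05), "under_dominant"),
            ((0.5, 0.45, 0.5), "conserved"),
        ],
    )
    def test_worked_examples(self, triple, expected):
        assert classify_threshold(*triple) == expected

    def test_similarity_to_both_parents_wins(self):
        # hybrid within 1.25-fold of both parents -> conserved, even though
        # each one-parent condition holds on its own
        assert classify_threshold(0.5, 0.55, 0.52) == "conserved"

    def test_matches_decision_table_on_grid(self):
        """Vectorised classifier equals the scalar oracle on a coarse sweep.

        (The exhaustive 0.01-step sweep runs in the acceptance suite.)
        """
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        p1, p2, h = np.meshgrid(grid, grid, grid, indexing="ij")
        got = classify_threshold(p1.ravel(), p2.ravel(), h.ravel())
        expected = [decision_table(a, b, c) for a, b, c in zip(p1.ravel(), p2.ravel(), h.ravel())]
        assert got.tolist() == expected

    @settings(max_examples=300, derandomize=True)
    @given(unit, unit, unit)
    def test_parent_swap_symmetry(self, p1, p2, h):
        direct = classify_threshold(p1, p2, h)
        swapped = classify_threshold(p2, p1, h)
        assert swapped == SWAP_PARENTS[direct]

    @settings(max_examples=100, derandomize=True)
    @given(unit, unit, unit)
    def test_fold_limits(self, p1, p2, h):
        assert classify_threshold(p1, p2, h, fold=1e9) == "conserved"
        # just above 1: nothing is similar unless numerically equal
        if len({round(p1, 6), round(p2, 6), round(h, 6)}) == 3:
            assert classify_threshold(p1, p2, h, fold=1.0 + 1e-12) != "conserved"

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError, match="defined"):
            classify_threshold(0.5, np.nan, 0.5)


class TestFisherVariant:
    def test_exact_pvalue_diagonal_table(self):
        # [[5,0],[0,5]]: two-sided p = 2/C(10,5) = 2/252
        assert fisher_pvalue(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-12)

    @pytest.mark.parametrize("table", [(5, 0, 0, 5), (3, 9, 7, 2), (12, 4, 9, 8), (0, 7, 7, 0)])
    def test_pvalue_matches_enumeration(self, table):
        assert fisher_pvalue(*table) == pytest.approx(fisher_two_sided(*table), abs=1e-10)

    def test_identical_tables_conserved(self):
        frame = pd.DataFrame(
            [{"event_id": "e1", "ijc_p1": 10, "sjc_p1": 10, "ijc_p2": 10, "sjc_p2": 10,
              "ijc_h": 10, "sjc_h": 10}]
        )
        out = classify_fisher_frame(frame)
        assert out["category"].iloc[0] == "conserved"
        assert out["p_vs_p1"].iloc[0] == pytest.approx(1.0)

    def test_dominant_toward_matching_parent(self):
        frame = pd.DataFrame(
            [{"event_id": "e1", "ijc_p1": 500, "sjc_p1": 500, "ijc_p2": 900, "sjc_p2": 100,
              "ijc_h": 500, "sjc_h": 500}]
        )
        out = classify_fisher_frame(frame)
        # hybrid indistinguishable from parent 1 (CG), far from parent 2; CG is lower
        assert out["category"].iloc[0] == "dominant_cg_down"
        assert out["p_vs_p1"].iloc[0] == pytest.approx(
            fisher_two_sided(500, 500, 500, 500), abs=1e-10
        )
        assert out["p_vs_p2"].iloc[0] == pytest.approx(
            fisher_two_sided(500, 500, 900, 100), abs=1e-10
        )

    def test_zero_total_group_gets_no_call(self):
        frame = pd.DataFrame(
            [{"event_id": "e1", "ijc_p1": 0, "sjc_p1": 0, "ijc_p2": 10, "sjc_p2": 10,
              "ijc_h": 10, "sjc_h": 10}]
        )
        assert classify_fisher_frame(frame)["category"].iloc[0] == ""


def _group(tissue="brain", label="MC"):
    return ComparisonGroup(
        label=label, tissue=tissue, sex="M", hybrid_strain="CL",
        parent1_samples=("cg1",), parent2_samples=("wl1",), hybrid_samples=("cl1",),
    )


class TestMergeDivergentWithExpressed:
    def _divergence(self, event_ids, significant):
        return pd.DataFrame(
            {"event_id": event_ids, "tissue": "brain", "significant": significant}
        )

    def _group_psi(self, event_ids, psi):
        return pd.DataFrame(
            {"event_id": event_ids, "strain": "CL", "sex": "M", "tissue": "brain",
             "mean_psi": psi, "n_replicates": 3}
        )

    def test_intersection(self):
        div = self._divergence([f"e{i}" for i in range(10)], [True] * 10)
        psi = self._group_psi([f"e{i}" for i in range(8)], [0.5] * 8)
        assert merge_divergent_with_expressed(div, psi, _group()) == [f"e{i}" for i in range(8)]

    def test_empty_divergent_set(self):
        div = self._divergence(["e1"], [False])
        psi = self._group_psi(["e1"], [0.5])
        assert merge_divergent_with_expressed(div, psi, _group()) == []

    def test_missing_hybrid_psi_excluded(self):
        div = self._divergence(["e1", "e2"], [True, True])
        psi = self._group_psi(["e1", "e2"], [0.5, np.nan])
        assert merge_divergent_with_expressed(div, psi, _group()) == ["e1"]

    def test_tissue_mismatch_rejected(self):
        div = self._divergence(["e1"], [True])
        psi = self._group_psi(["e1"], [0.5])
        with pytest.raises(ValueError, match="tissue"):
            merge_divergent_with_expressed(div, psi, _group(tissue="liver"))

    def test_matches_bruteforce_intersection(self, rng):
        ids = [f"e{i}" for i in range(60)]
        sig = rng.random(60) < 0.5
        expressed = rng.random(60) < 0.7
        div = self._divergence(ids, list(sig))
        psi = self._group_psi(ids, [0.5 if e else np.nan for e in expressed])
        expected = sorted(i for i, s, e in zip(ids, sig, expressed) if s and e)
        assert merge_divergent_with_expressed(div, psi, _group()) == expected


class TestBuildComparisonGroups:
    def test_groups_skip_missing_hybrids(self):
        rows = []
        for strain in ("CG", "WL", "CL", "LC"):
            for sex in ("M", "F"):
                if strain in ("CL", "LC") and sex == "F":
                    continue  # no hybrid females (the liver situation)
                rows.append({"sample_id": f"{strain}{sex}", "strain": strain, "sex": sex,
                             "tissue": "liver", "replicate_index": 1})
        groups = build_comparison_groups(pd.DataFrame(rows), "liver")
        assert sorted(groups) == ["MC", "MR"]
        assert groups["MC"].hybrid_strain == "CL"
        assert groups["MR"].hybrid_strain == "LC"


class TestConsensus:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["event_id", "gene_id", "tissue", "group", "method", "category"]
        )

    def test_mode_supported_by_two_groups(self):
        calls = self._calls(
            [("e1", "g1", "brain", "MC", "threshold", "dominant_cg_up"),
             ("e1", "g1", "brain", "MR", "threshold", "dominant_cg_up"),
             ("e1", "g1", "brain", "FC", "threshold", "additive_cg_high")]
        )
        out = consensus(calls, min_groups=2, key="gene_id")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["category"] == "dominant_cg" and row["n_supporting_groups"] == 2

    def test_single_group_no_consensus(self):
        calls = self._calls([("e1", "g1", "brain", "FC", "threshold", "additive_cg_high")])
        assert consensus(calls, min_groups=2).empty

    def test_tied_modes_emit_no_call(self):
        calls = self._calls(
            [("e1", "g1", "brain", "MC", "threshold", "dominant_cg_up"),
             ("e1", "g1", "brain", "MR", "threshold", "dominant_cg_down"),
             ("e1", "g1", "brain", "FC", "threshold", "over_dominant"),
             ("e1", "g1", "brain", "FR", "threshold", "under_dominant")]
        )
        assert consensus(calls, min_groups=2).empty

    def test_conserved_never_forms_consensus(self):
        calls = self._calls(
            [("e1", "g1", "brain", g, "threshold", "conserved") for g in ("MC", "MR", "FC", "FR")]
        )
        assert consensus(calls, min_groups=2).empty

    def test_matches_bruteforce_tally(self, rng):
        cats = list(CATEGORIES)
        rows = []
        for i in range(500):
            for grp in ("MC", "FC", "MR", "FR"):
                cat = cats[rng.integers(0, len(cats))]
                rows.append((f"e{i}", f"g{i}", "brain", grp, "threshold", cat))
        calls = self._calls(rows)
        out = consensus(calls, min_groups=2, key="event_id")
        got = dict(zip(out["event_id"], out["category"]))

        from collections import Counter
        for i in range(500):
            tally = Counter(
                COLLAPSE[c] for (e, g, t, grp, m, c) in rows if e == f"e{i}" and COLLAPSE[c] != "conserved"
            )
            winners = [m for m, n in tally.items() if n >= 2]
            if len(winners) == 1:
                assert got.get(f"e{i}") == winners[0]
            else:
                assert f"e{i}" not in got
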