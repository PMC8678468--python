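import itertools

import pandas as pd
import pytest
from scipy.stats import kruskal, mannwhitneyu

from asinherit.datasets import REFERENCE_DENOMINATORS, reference_calls, reference_summary_table
from asinherit.inheritance import CATEGORIES
from asinherit.summarize import (
    category_percentages,
    kruskal_wallis_across_tissues,
    mannwhitney_updown,
    round_half_up,
    tabulate,
)
from tests._oracles import mannwhitney_u


class TestTabulate:
    def test_reference_counts_reproduced(self):
        """Expanding the reference table to calls and re-tabulating is the identity."""
        table = tabulate(reference_calls())
        expected = reference_summary_table()
        merged = table.set_index(["tissue", "group"]).sort_index()
        expected = expected.set_index(["tissue", "group"]).sort_index()
        pd.testing.assert_frame_equal(merged, expected, check_dtype=False)
        brain_fc = merged.loc[("brain", "FC")]
        assert brain_fc[list(CATEGORIES)].tolist() == [350, 55, 42, 117, 42, 102, 40, 120, 121]

    def test_empty_calls(self):
        assert tabulate(pd.DataFrame(columns=["tissue", "group", "category"])).empty

    def test_mixed_methods_rejected(self):
        calls = pd.DataFrame(
            {"tissue": "brain", "group": "MC", "method": ["threshold", "fisher"],
             "category": ["conserved", "conserved"]}
        )
        with pytest.raises(ValueError, match="single method"):
            tabulate(calls)

    def test_matches_bruteforce_tally(self, rng):
        cats = list(CATEGORIES)
        rows = [
            {"tissue": ["brain", "liver"][rng.integers(0, 2)],
             "group": ["MC", "FC"][rng.integers(0, 2)],
             "method": "threshold",
             "category": cats[rng.integers(0, 9)]}
            for _ in range(400)
        ]
        table = tabulate(pd.DataFrame(rows)).set_index(["tissue", "group"])
        for (tissue, group), sub in table.iterrows():
            for cat in cats:
                expected = sum(
                    1 for r in rows if r["tissue"] == tissue and r["group"] == group and r["category"] == cat
                )
                assert sub[cat] == expected
        assert (table[list(cats)].sum(axis=1) == table["n_classified"]).all()


class TestCategoryPercentages:
    def test_reference_percentages(self):
        pct = category_percentages(reference_summary_table(), REFERENCE_DENOMINATORS)
        means = pct.drop_duplicates(["tissue", "family"]).set_index(["tissue", "family"])[
            "tissue_mean_pct_rounded"
        ]
        assert means[("brain", "additive")] == 8.7
        assert means[("liver", "additive")] == 8.0
        assert means[("brain", "transgressive")] == 22.7
        assert means[("muscle", "transgressive")] == 11.6
        assert means[("liver", "transgressive")] == 22.5
        assert round_half_up(means[("muscle", "conserved")], 0) == 41.0

    def test_single_group(self):
        table = pd.DataFrame(
            [{"tissue": "brain", "group": "MC", **{c: 0 for c in CATEGORIES},
              "conserved": 50, "n_classified": 50}]
        )
        pct = category_percentages(table, {"brain": 100})
        row = pct[(pct["family"] == "conserved")].iloc[0]
        assert row["pct"] == pytest.approx(50.0)

    def test_missing_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            category_percentages(reference_summary_table(), {"brain": 1030})


class TestKruskalWallis:
    def _pct(self, groups_by_tissue):
        rows = []
        for tissue, values in groups_by_tissue.items():
            for i, v in enumerate(values):
                rows.append({"tissue": tissue, "group": f"G{i}", "family": "conserved",
                             "count": 0, "pct": v})
        return pd.DataFrame(rows)

    def test_identical_proportions_give_null(self):
        pct = self._pct({"brain": [0.3, 0.3], "muscle": [0.3, 0.3], "liver": [0.3, 0.3]})
        h, p = kruskal_wallis_across_tissues(pct, "conserved")
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_h_with_ties(self):
        # {0.1,0.1},{0.5,0.5},{0.9,0.9}: H = 4.571... / tie-correction 0.9143 = 5.0
        pct = self._pct({"brain": [0.1, 0.1], "muscle": [0.5, 0.5], "liver": [0.9, 0.9]})
        h, p = kruskal_wallis_across_tissues(pct, "conserved")
        assert h == pytest.approx(5.0, abs=1e-10)
        # only the 3! pair-preserving partitions of the 90 reach H = 5
        assert p == pytest.approx(6 / 90, abs=1e-12)

    def test_h_matches_scipy_on_tie_free_data(self, rng):
        groups = {t: list(rng.random(4)) for t in ("brain", "muscle", "liver")}
        pct = self._pct(groups)
        h, _ = kruskal_wallis_across_tissues(pct, "conserved")
        h_scipy, _ = kruskal(*groups.values())
        assert h == pytest.approx(h_scipy, abs=1e-10)

    def test_exact_permutation_close_to_chisquare(self, rng):
        groups = {"brain": [0.12, 0.41, 0.77], "muscle": [0.35, 0.52, 0.66],
                  "liver": [0.05, 0.58, 0.93]}
        pct = self._pct(groups)
        h, p_exact = kruskal_wallis_across_tissues(pct, "conserved")  # n = 9 -> exact
        from scipy.stats import chi2
        p_chi = float(chi2.sf(h, df=2))
        assert abs(p_exact - p_chi) < 0.05

    def test_invariant_to_row_order(self, rng):
        groups = {t: list(rng.random(3)) for t in ("brain", "muscle", "liver")}
        pct = self._pct(groups)
        shuffled = pct.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert kruskal_wallis_across_tissues(pct, "conserved") == (
            kruskal_wallis_across_tissues(shuffled, "conserved")
        )


class TestMannWhitney:
    def _table(self, up_cg, down_cg, up_wl, down_wl, over=None, under=None):
        n = len(up_cg)
        rows = []
        for i in range(n):
            row = {"tissue": "brain", "group": f"G{i}", **{c: 0 for c in CATEGORIES}}
            row["dominant_cg_up"] = up_cg[i]
            row["dominant_cg_down"] = down_cg[i]
            row["dominant_wl_up"] = up_wl[i]
            row["dominant_wl_down"] = down_wl[i]
            if over is not None:
                row["over_dominant"] = over[i]
                row["under_dominant"] = under[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def test_identical_sides_give_p_one(self):
        table = self._table([5, 6], [5, 6], [0, 0], [0, 0])
        u, p = mannwhitney_updown(table, "brain", "up_vs_down_dominant")
        assert p == pytest.approx(1.0)

    def test_complete_separation_u(self):
        table = self._table([10, 11, 12, 13], [1, 2, 2, 3], [0, 0, 0, 0], [0, 0, 0, 0])
        u, p = mannwhitney_updown(table, "brain", "up_vs_down_dominant")
        assert u == 16.0  # every up-count beats every down-count

    def test_exact_p_matches_enumeration(self, rng):
        x = list(rng.integers(0, 20, 5))
        y = list(rng.integers(0, 20, 5))
        table = self._table(x, y, [0] * 5, [0] * 5)
        u, p = mannwhitney_updown(table, "brain", "up_vs_down_dominant")
        assert u == mannwhitney_u([float(v) for v in x], [float(v) for v in y])
        # independent enumeration of the permutation distribution of U
        pooled = [float(v) for v in x + y]
        center = len(x) * len(y) / 2
        dev = abs(u - center)
        hits = total = 0
        for chosen in itertools.combinations(range(10), 5):
            xs = [pooled[i] for i in chosen]
            ys = [pooled[i] for i in range(10) if i not in chosen]
            total += 1
            hits += abs(mannwhitney_u(xs, ys) - center) >= dev - 1e-12
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        x, y = [3.0, 9.0, 14.0, 20.0], [1.0, 5.0, 11.0, 13.0]
        table = self._table(x, y, [0] * 4, [0] * 4)
        _, p = mannwhitney_updown(table, "brain", "up_vs_down_dominant")
        p_scipy = mannwhitneyu(x, y, alternative="two-sided", method="exact")[1]
        assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_over_vs_under_contrast(self):
        table = self._table([0] * 2, [0] * 2, [0] * 2, [0] * 2, over=[120, 118], under=[121, 119])
        u, p = mannwhitney_updown(table, "brain", "over_vs_under")
        assert 0 <= p <= 1

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            mannwhitney_updown(self._table([1], [1], [1], [1]), "brain", "sideways")
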