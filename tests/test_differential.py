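"""Bait normalization, differential classes, volcano stats, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxipipe import (
    CategoryAnnotation,
    ScoredInteraction,
    ValidationError,
    classify_pairwise,
    classify_restored,
    compute_log2fc,
    enrichment_test,
    normalize_by_bait,
    volcano_stats,
)

from conftest import make_table


def scored_list(cond, counts):
    return [
        ScoredInteraction(cond, prey, float(avg), [0, 0], prob=1.0, bfdr=0.0)
        for prey, avg in counts.items()
    ]


class TestNormalizeByBait:
    def test_formula(self):
        by_cond = {
            "WT": scored_list("WT", {"A": 10.0}),
            "dF508": scored_list("dF508", {"A": 10.0}),
        }
        norm = normalize_by_bait(by_cond, {"WT": 100.0, "dF508": 50.0}, "WT")
        assert norm.at["A", "WT"] == pytest.approx(10.0)
        assert norm.at["A", "dF508"] == pytest.approx(20.0)

    def test_unit_factor_is_identity(self):
        by_cond = {"WT": scored_list("WT", {"A": 7.0, "B": 3.0})}
        norm = normalize_by_bait(by_cond, {"WT": 42.0}, "WT")
        assert norm.at["A", "WT"] == pytest.approx(7.0)

    def test_zero_self_count_rejected(self):
        by_cond = {"WT": scored_list("WT", {"A": 1.0})}
        with pytest.raises(ValidationError, match="bait not detected"):
            normalize_by_bait(by_cond, {"WT": 0.0}, "WT")

    def test_rank_order_preserved_within_condition(self, rng):
        counts = {f"P{i}": float(c) for i, c in enumerate(rng.uniform(1, 100, 50))}
        by_cond = {"X": scored_list("X", counts), "WT": scored_list("WT", {"P0": 1.0})}
        norm = normalize_by_bait(by_cond, {"WT": 80.0, "X": 13.0}, "WT")
        raw_order = sorted(counts, key=counts.get)
        norm_order = list(norm["X"].loc[raw_order].sort_values().index)
        assert norm_order == raw_order

    def test_scale_invariance(self):
        """Scaling a condition's counts and self-count together is a no-op."""
        c = 3.7
        by_a = {"X": scored_list("X", {"A": 10.0, "B": 4.0})}
        by_b = {"X": scored_list("X", {"A": 10.0 * c, "B": 4.0 * c})}
        n_a = normalize_by_bait({**by_a, "WT": scored_list("WT", {})}, {"WT": 100.0, "X": 50.0}, "WT")
        n_b = normalize_by_bait({**by_b, "WT": scored_list("WT", {})}, {"WT": 100.0, "X": 50.0 * c}, "WT")
        assert np.allclose(n_a["X"].sort_index(), n_b["X"].sort_index())


class TestLog2FC:
    def test_hand_value(self):
        assert compute_log2fc(8.0, 2.0, 0.5) == pytest.approx(math.log2(2.5 / 8.5))

    def test_equal_counts_give_zero(self):
        assert compute_log2fc(5.0, 5.0) == 0.0

    def test_double_zero_gives_zero(self):
        assert compute_log2fc(0.0, 0.0) == 0.0

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            compute_log2fc(8.0, 2.0, 0.0)


def _norm_frame(values):
    return pd.DataFrame(values).T.rename_axis("prey")


class TestClassifyPairwise:
    def test_threshold_rules(self):
        norm = pd.DataFrame(
            {"WT": [4.0, 16.0, 10.0], "dF508": [16.0, 4.0, 11.0]},
            index=["up", "down", "flat"],
        )
        hc = {"up", "down", "flat"}
        calls = classify_pairwise(norm, hc, hc, "WT", "dF508")
        assert calls.label.to_dict() == {
            "up": "gained", "down": "lost", "flat": "unchanged"
        }

    def test_boundary_is_inclusive(self):
        # ref 20.5, alt 10.0 with pseudocount 0.5 -> log2fc exactly -1
        norm = pd.DataFrame({"WT": [20.5], "dF508": [10.0]}, index=["edge"])
        calls = classify_pairwise(norm, {"edge"}, {"edge"}, "WT", "dF508")
        assert calls.at["edge", "log2fc"] == pytest.approx(-1.0)
        assert calls.at["edge", "label"] == "lost"

    def test_prey_confident_nowhere_excluded_with_warning(self):
        norm = pd.DataFrame({"WT": [4.0, 9.0], "dF508": [16.0, 9.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="excluded"):
            calls = classify_pairwise(norm, {"a"}, {"a"}, "WT", "dF508")
        assert list(calls.index) == ["a"]

    def test_antisymmetry_under_condition_swap(self, rng):
        preys = [f"P{i}" for i in range(200)]
        norm = pd.DataFrame(
            {"A": rng.uniform(0, 50, 200), "B": rng.uniform(0, 50, 200)}, index=preys
        )
        hc = set(preys)
        ab = classify_pairwise(norm, hc, hc, "A", "B")
        ba = classify_pairwise(norm, hc, hc, "B", "A")
        assert set(ab.index[ab.label == "gained"]) == set(ba.index[ba.label == "lost"])
        assert set(ab.index[ab.label == "lost"]) == set(ba.index[ba.label == "gained"])


class TestClassifyRestored:
    def _frame(self, wt, mut, drug, prey="p"):
        return pd.DataFrame({"WT": [wt], "mut": [mut], "drug": [drug]}, index=[prey])

    def test_lost_then_regained_is_restored(self):
        norm = self._frame(20.0, 0.0, 18.0)
        hc = {"WT": {"p"}, "mut": set(), "drug": {"p"}}
        calls = classify_restored(norm, hc, "WT", "mut", "drug")
        assert calls.at["p", "label"] == "restored"

    def test_elevated_then_reduced_is_attenuated(self):
        norm = self._frame(5.0, 40.0, 5.0)
        hc = {"WT": {"p"}, "mut": {"p"}, "drug": {"p"}}
        calls = classify_restored(norm, hc, "WT", "mut", "drug")
        assert calls.at["p", "label"] == "attenuated"

    def test_elevated_and_unmoved_is_non_responsive(self):
        norm = self._frame(5.0, 40.0, 38.0)
        hc = {"WT": {"p"}, "mut": {"p"}, "drug": {"p"}}
        calls = classify_restored(norm, hc, "WT", "mut", "drug")
        assert calls.at["p", "label"] == "non_responsive"

    def test_absent_everywhere_excluded(self):
        norm = self._frame(0.0, 0.0, 0.0)
        hc = {"WT": set(), "mut": set(), "drug": set()}
        calls = classify_restored(norm, hc, "WT", "mut", "drug")
        assert calls.empty

    def test_missing_condition_errors(self):
        norm = self._frame(1.0, 1.0, 1.0)
        hc = {"WT": {"p"}, "mut": {"p"}, "drug": {"p"}}
        with pytest.raises(ValidationError):
            classify_restored(norm, hc, "WT", "mut", "absent")

    def test_restored_and_attenuated_disjoint(self, rng):
        preys = [f"P{i}" for i in range(300)]
        norm = pd.DataFrame(
            {c: rng.uniform(0, 40, 300) for c in ("WT", "mut", "drug")}, index=preys
        )
        hc = {c: set(rng.choice(preys, 150, replace=False)) for c in ("WT", "mut", "drug")}
        calls = classify_restored(norm, hc, "WT", "mut", "drug")
        restored = set(calls.index[calls.label == "restored"])
        attenuated = set(calls.index[calls.label == "attenuated"])
        assert not restored & attenuated


class TestVolcano:
    def _table(self, counts_a, counts_b):
        rows = []
        for cond, per_run in (("A", counts_a), ("B", counts_b)):
            for r, counts in enumerate(per_run, start=1):
                for prey, c in counts.items():
                    if c > 0:
                        rows.append((f"{cond}_{r}", "BAIT", cond, r, prey, c))
        return make_table(rows)

    def test_identical_replicates_flat(self):
        table = self._table(
            [{"p": 4}, {"p": 4}], [{"p": 4}, {"p": 4}]
        )
        out = volcano_stats(table, "A", "B")
        assert out.at["p", "log2fc"] == 0.0
        assert out.at["p", "p_value"] == 1.0
        assert out.at["p", "flag"] == "none"

    def test_higher_counts_in_b_flag_green(self):
        table = self._table(
            [{"p": 4}] * 4, [{"p": 16}] * 4
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = volcano_stats(table, "A", "B")
        assert out.at["p", "flag"] == "green"
        assert out.at["p", "p_value"] == np.finfo(float).tiny

    def test_lower_counts_in_b_flag_red(self):
        table = self._table(
            [{"p": 16, "q": 3}, {"p": 15, "q": 4}], [{"p": 4, "q": 3}, {"p": 5, "q": 4}]
        )
        out = volcano_stats(table, "A", "B")
        assert out.at["p", "flag"] == "red"
        assert out.at["q", "flag"] == "none"

    def test_null_pvalues_approximately_uniform(self, rng):
        rows = []
        for cond in ("A", "B"):
            for r in range(1, 5):
                counts = rng.poisson(10, 500)
                for i, c in enumerate(counts):
                    if c > 0:
                        rows.append((f"{cond}_{r}", "BAIT", cond, r, f"P{i:03d}", int(c)))
        out = volcano_stats(make_table(rows), "A", "B")
        ks = stats.kstest(out["p_value"], "uniform").statistic
        assert ks < 0.1


class TestEnrichment:
    def test_extreme_overlap_minimizes_p(self):
        universe = {f"G{i}" for i in range(10)}
        cat = CategoryAnnotation("c1", "cat", frozenset(list(universe)[:5]))
        res = enrichment_test(set(cat.genes), [cat], universe)
        assert res.at["c1", "overlap"] == 5
        # the most extreme draw possible: p = 1 / C(10, 5)
        assert res.at["c1", "p_value"] == pytest.approx(1 / math.comb(10, 5))

    def test_disjoint_selection_p_near_one(self):
        universe = {f"G{i}" for i in range(20)}
        cat = CategoryAnnotation("c1", "cat", frozenset({"G0", "G1"}))
        res = enrichment_test({"G10", "G11", "G12"}, [cat], universe)
        assert res.at["c1", "p_value"] > 0.5

    def test_matches_exact_enumeration(self, rng):
        """Hypergeometric tail equals brute-force enumeration of all draws."""
        universe = [f"G{i}" for i in range(9)]
        category = set(rng.choice(universe, 4, replace=False))
        selected = set(rng.choice(universe, 5, replace=False))
        k_obs = len(category & selected)
        total = hits = 0
        for combo in itertools.combinations(universe, 5):
            total += 1
            hits += len(category & set(combo)) >= k_obs
        cat = CategoryAnnotation("c1", "cat", frozenset(category))
        res = enrichment_test(selected, [cat], set(universe))
        assert res.at["c1", "p_value"] == pytest.approx(hits / total, abs=1e-12)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test({"X"}, [], {"A"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test(set(), [], set())
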