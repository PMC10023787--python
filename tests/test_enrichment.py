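"""Enrichment folds, hit ranking, resynthesis combinations and scatter export."""

import numpy as np
import pytest

from tdel.enrichment import (
    combination_matrix,
    enrichment_fold,
    export_scatter,
    rank_hits,
    read_scatter,
)
from tdel.errors import ConfigError


def spreadsheet_fold(pre, post, alpha):
    """The stated formula evaluated with plain python arithmetic."""
    m = len(set(pre) | set(post))
    t_pre = sum(pre.values())
    t_post = sum(post.values())
    return {
        c: ((post.get(c, 0) + alpha) / (t_post + alpha * m))
        / ((pre.get(c, 0) + alpha) / (t_pre + alpha * m))
        for c in set(pre) | set(post)
    }


class TestEnrichmentFold:
    def test_identical_distributions_give_unit_folds(self):
        counts = {"a": 10, "b": 30, "c": 60}
        for alpha in (0.0, 1.0, 5.0):
            table = enrichment_fold(counts, dict(counts), pseudocount=alpha)
            assert table["fold"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_hand_arithmetic_no_pseudocount(self):
        table = enrichment_fold({"A": 50, "B": 50}, {"A": 90, "B": 10}, pseudocount=0)
        folds = dict(zip(table.code_id, table.fold))
        assert folds["A"] == pytest.approx(1.8)
        assert folds["B"] == pytest.approx(0.2)

    def test_formula_oracle_with_pseudocount(self):
        pre = {"A": 0, "B": 100}
        post = {"A": 10, "B": 90}
        table = enrichment_fold(pre, post, pseudocount=1)
        oracle = spreadsheet_fold(pre, post, 1)
        folds = dict(zip(table.code_id, table.fold))
        for code in oracle:
            assert folds[code] == pytest.approx(oracle[code])

    def test_zero_pre_count_without_pseudocount_is_infinite_flagged(self):
        table = enrichment_fold({"A": 0, "B": 100}, {"A": 10, "B": 90}, pseudocount=0)
        row = table[table.code_id == "A"].iloc[0]
        assert np.isinf(row.fold) and bool(row.infinite)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        pre = {f"c{i}": int(k) for i, k in enumerate(rng.integers(0, 100, 20))}
        post = {f"c{i}": int(k) for i, k in enumerate(rng.integers(0, 100, 20))}
        for alpha in (0.0, 1.0):
            table = enrichment_fold(pre, post, alpha)
            assert table["pre_fraction"].sum() == pytest.approx(1.0)
            assert table["post_fraction"].sum() == pytest.approx(1.0)

    def test_prefraction_weighted_mean_fold_is_one(self):
        # conservation of probability mass at alpha=0
        rng = np.random.default_rng(7)
        pre = {f"c{i}": int(k) + 1 for i, k in enumerate(rng.integers(0, 50, 30))}
        post = {f"c{i}": int(k) for i, k in enumerate(rng.integers(0, 50, 30))}
        table = enrichment_fold(pre, post, pseudocount=0)
        weighted = (table["fold"] * table["pre_fraction"]).sum()
        assert weighted == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ConfigError):
            enrichment_fold({"a": 0}, {"a": 5})


class TestRankHits:
    def _table(self):
        return enrichment_fold(
            {"a": 10, "b": 10, "c": 10, "d": 10},
            {"a": 5, "b": 20, "c": 10, "d": 5},
            pseudocount=1,
        )

    def test_top_k_zero_is_empty(self):
        assert rank_hits(self._table(), top_k=0).empty

    def test_ties_break_by_count_then_id(self):
        table = enrichment_fold(
            {"x": 10, "y": 10, "z": 10}, {"x": 10, "y": 10, "z": 10}, pseudocount=1
        )
        ranked = rank_hits(table)
        assert ranked["code_id"].tolist() == ["x", "y", "z"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(4)
        pre = {f"c{i:02d}": int(k) + 1 for i, k in enumerate(rng.integers(0, 100, 40))}
        post = {f"c{i:02d}": int(k) for i, k in enumerate(rng.integers(0, 100, 40))}
        table = enrichment_fold(pre, post, pseudocount=1)
        ranked = rank_hits(table, top_k=5)
        oracle = sorted(
            table.to_dict("records"),
            key=lambda r: (-r["fold"], -r["post_count"], r["code_id"]),
        )[:5]
        assert ranked["code_id"].tolist() == [r["code_id"] for r in oracle]

    def test_min_post_count_filters(self):
        ranked = rank_hits(self._table(), min_post_count=10)
        assert set(ranked["code_id"]) == {"b", "c"}

    def test_infinite_folds_sort_first(self):
        table = enrichment_fold({"a": 0, "b": 100}, {"a": 10, "b": 90}, pseudocount=0)
        ranked = rank_hits(table)
        assert ranked["code_id"].iloc[0] == "a"


class TestCombinationMatrix:
    def test_resynthesis_45(self):
        m = combination_matrix(["a1", "a2", "a3"],
                               ["b1", "b2", "b3", "b4", "b5"],
                               ["c1", "c2", "c3"])
        assert len(m) == 45

    def test_single_combination(self):
        m = combination_matrix(["a"], ["b"], ["c"])
        assert len(m) == 1
        assert m.iloc[0].tolist() == ["a", "b", "c"]

    def test_matches_nested_loop_oracle(self):
        ids = (["a1", "a2"], ["b1", "b2"], ["c1", "c2"])
        m = combination_matrix(*ids)
        oracle = [(a, b, c) for a in ids[0] for b in ids[1] for c in ids[2]]
        assert list(map(tuple, m.to_numpy())) == oracle

    def test_combined_masses_from_library(self, small_library):
        hits = [[small_library.sub(r).ids[0]] for r in "ABC"]
        m = combination_matrix(*hits, library=small_library, linkage_correction=36.0)
        expected = sum(small_library.sub(r).members[0].mass for r in "ABC") - 36.0
        assert m["combined_mass"].iloc[0] == pytest.approx(expected)

    def test_empty_hit_list_rejected(self):
        with pytest.raises(ConfigError):
            combination_matrix([], ["b"], ["c"])


class TestScatterExport:
    def test_round_trip(self, tmp_path):
        table = enrichment_fold({"a": 10, "b": 20}, {"a": 25, "b": 5}, pseudocount=1)
        path = tmp_path / "scatter.csv"
        export_scatter(table, path)
        back = read_scatter(path)
        assert back["code_id"].tolist() == table["code_id"].tolist()
        assert back["post_count"].tolist() == table["post_count"].tolist()
        assert back["fold"].to_numpy() == pytest.approx(table["fold"].to_numpy())

    def test_row_count_equals_member_count(self):
        table = enrichment_fold({"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1})
        assert len(export_scatter(table)) == 3

    def test_empty_table_gives_header_only_file(self, tmp_path):
        import pandas as pd

        empty = pd.DataFrame(columns=["code_id", "post_count", "fold"])
        path = tmp_path / "empty.csv"
        export_scatter(empty, path)
        assert path.read_text().strip() == "code_id,post_count,fold"
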