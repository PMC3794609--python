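import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueranker import (
    ExpressionCompendium,
    GoldStandard,
    TissueCategoryMap,
    TissueRanking,
    categorize_ranking,
    per_complex_auc,
    per_tissue_auc,
    randomized_null,
    read_gold_standard,
    roc_from_rankings,
    single_protein_ranking,
    topk_overlap,
)
from tissueranker.benchmark import shuffle_within_tissues
from tissueranker.synthetic import planted_complexes


def ranking(entries, cid="cx"):
    return TissueRanking(cid, tuple((t, float(s)) for t, s in entries))


def mann_whitney_auc(pos_scores, neg_scores):
    """Independent pairwise-count oracle: P(pos > neg) + 0.5*P(tie)."""
    wins = ties = 0
    for p, n in itertools.product(pos_scores, neg_scores):
        if p > n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


class TestReadGoldStandard:
    def test_semicolon_rank_order(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("gene\tdisease\ttissue_categories\nLMNA\tcardiomyopathy\tmuscle;heart\n")
        gs = read_gold_standard(p)
        assert len(gs) == 1
        gene, disease, cats = gs.associations[0]
        assert (gene, disease) == ("LMNA", "cardiomyopathy")
        assert cats == ("muscle", "heart")

    def test_duplicate_pair_is_error(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text(
            "gene\tdisease\ttissue_categories\ng\td\ta\ng\td\tb\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_gold_standard(p)

    def test_empty_category_list_is_error(self, tmp_path):
        p = tmp_path / "gs.tsv"
        p.write_text("gene\tdisease\ttissue_categories\ng\td\t;\n")
        with pytest.raises(ValueError, match="empty tissue category"):
            read_gold_standard(p)

    def test_file_order_preserved(self, tmp_path):
        p = tmp_path / "gs.tsv"
        rows = [("g1", "d1", "a"), ("g2", "d1", "b"), ("g1", "d2", "c")]
        p.write_text("gene\tdisease\ttissue_categories\n" +
                     "".join(f"{g}\t{d}\t{c}\n" for g, d, c in rows))
        gs = read_gold_standard(p)
        assert [(g, d) for g, d, _ in gs] == [("g1", "d1"), ("g2", "d1"), ("g1", "d2")]


class TestCategorizeRanking:
    def test_category_takes_best_member_score(self):
        cmap = TissueCategoryMap({"atrial myocardium": "heart", "cardiac ventricle": "heart"})
        r = ranking([("atrial myocardium", 0.7), ("cardiac ventricle", 0.4)])
        out = categorize_ranking(r, cmap)
        assert out.entries == (("heart", 0.7),)

    def test_identity_map_is_noop(self):
        r = ranking([("b", 0.9), ("a", 0.3)])
        out = categorize_ranking(r, TissueCategoryMap.identity(["a", "b"]))
        assert out.entries == r.entries

    def test_matches_group_max_oracle(self):
        cmap = TissueCategoryMap({"t1": "c1", "t2": "c1", "t3": "c2", "t4": "c3", "t5": "c3"})
        scores = {"t1": 0.1, "t2": 0.8, "t3": 0.5, "t4": -0.2, "t5": 0.5}
        r = ranking(sorted(scores.items(), key=lambda kv: -kv[1]))
        out = categorize_ranking(r, cmap)
        expected = {}
        for t, s in scores.items():
            expected[cmap[t]] = max(expected.get(cmap[t], -np.inf), s)
        assert dict(out.entries) == expected
        assert [c for c, _ in out.entries] == sorted(expected, key=lambda c: (-expected[c], c))

    def test_unmapped_tissue_named(self):
        with pytest.raises(KeyError, match="kidney"):
            categorize_ranking(ranking([("kidney", 0.5)]), TissueCategoryMap({"liver": "liver"}))


class TestRocFromRankings:
    def _gs(self, assocs):
        return GoldStandard(tuple(assocs))

    def test_perfect_and_inverted(self):
        cats = ["a", "b", "c", "d", "e"]
        gs = self._gs([("g", "d", ("a",))])
        perfect = {("g", "d"): ranking([(c, 5 - i) for i, c in enumerate(cats)])}
        assert roc_from_rankings(perfect, gs).auc == 1.0
        worst = {("g", "d"): ranking([(c, 5 - i) for i, c in enumerate(reversed(cats))])}
        assert roc_from_rankings(worst, gs).auc == 0.0

    def test_matches_pairwise_oracle_on_mixed_toy(self):
        cats = ["a", "b", "c", "d", "e"]
        orders = {
            ("g1", "d1"): ["b", "a", "c", "d", "e"],
            ("g2", "d1"): ["e", "d", "a", "b", "c"],
            ("g3", "d2"): ["c", "a", "e", "b", "d"],
            ("g4", "d3"): ["a", "b", "d", "c", "e"],
        }
        gs = self._gs([
            ("g1", "d1", ("a", "b")),
            ("g2", "d1", ("e",)),
            ("g3", "d2", ("b", "d")),
            ("g4", "d3", ("c",)),
        ])
        rankings = {
            k: ranking([(c, len(cats) - i) for i, c in enumerate(order)], cid=k[0])
            for k, order in orders.items()
        }
        res = roc_from_rankings(rankings, gs)
        pos, neg = [], []
        for gene, disease, positives in gs:
            order = orders[(gene, disease)]
            for c in cats:
                (pos if c in positives else neg).append(-(order.index(c) + 1))
        assert res.auc == pytest.approx(mann_whitney_auc(pos, neg), rel=1e-9)
        assert res.n_pos == len(pos) and res.n_neg == len(neg)
        # curve endpoints and monotonicity
        assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)
        fprs = [p[0] for p in res.points]
        assert fprs == sorted(fprs)

    def test_degenerate_labels_error(self):
        gs = self._gs([("g", "d", ("a", "b"))])
        rk = {("g", "d"): ranking([("a", 2), ("b", 1)])}
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_from_rankings(rk, gs)

    def test_missing_rankings_skipped(self):
        gs = self._gs([("g", "d", ("a",)), ("missing", "d", ("b",))])
        rk = {("g", "d"): ranking([("a", 2), ("b", 1)])}
        assert roc_from_rankings(rk, gs).auc == 1.0


class TestPerTissueAndPerComplex:
    def test_per_tissue_restriction(self):
        gs = GoldStandard((("g1", "d", ("a",)), ("g2", "d", ("b",))))
        rk = {
            ("g1", "d"): ranking([("a", 2), ("b", 1)], "g1"),
            ("g2", "d"): ranking([("b", 2), ("a", 1)], "g2"),
        }
        res = per_tissue_auc(rk, gs, "a")
        assert res.auc == 1.0  # rank 1 when positive (g1), rank 2 when negative (g2)
        assert res.n_pos == 1 and res.n_neg == 1

    def test_per_tissue_degenerate_category(self):
        gs = GoldStandard((("g1", "d", ("a",)),))
        rk = {("g1", "d"): ranking([("a", 2), ("b", 1)], "g1")}
        with pytest.raises(ValueError, match="'a'"):
            per_tissue_auc(rk, gs, "a")

    def test_per_tissue_matches_oracle(self):
        gs = GoldStandard((("g1", "d", ("a",)), ("g2", "d", ("b",)), ("g3", "d", ("a",))))
        orders = {"g1": ["a", "b", "c"], "g2": ["c", "a", "b"], "g3": ["b", "c", "a"]}
        rk = {
            (g, "d"): ranking([(c, 3 - i) for i, c in enumerate(o)], g)
            for g, o in orders.items()
        }
        res = per_tissue_auc(rk, gs, "a")
        pos = [-(orders[g].index("a") + 1) for g in ("g1", "g3")]
        neg = [-(orders["g2"].index("a") + 1)]
        assert res.auc == pytest.approx(mann_whitney_auc(pos, neg))

    def test_per_complex_extremes_and_oracle(self):
        cats = ["a", "b", "c", "d", "e", "f"]
        r = ranking([(c, 6 - i) for i, c in enumerate(cats)])
        assert per_complex_auc(r, {"a", "b"}) == 1.0
        assert per_complex_auc(r, {"e", "f"}) == 0.0
        positives = {"b", "d", "e"}
        pos = [-(cats.index(c) + 1) for c in positives]
        neg = [-(cats.index(c) + 1) for c in cats if c not in positives]
        assert per_complex_auc(r, positives) == pytest.approx(mann_whitney_auc(pos, neg))
        with pytest.raises(ValueError):
            per_complex_auc(r, set(cats))

    def test_reversal_maps_auc_to_complement(self):
        cats = ["a", "b", "c", "d", "e", "f"]
        r = ranking([(c, 6 - i) for i, c in enumerate(["c", "a", "f", "b", "e", "d"])])
        for positives in ({"a"}, {"c", "f"}, {"b", "d", "e"}):
            a_fwd = per_complex_auc(r, positives)
            a_rev = per_complex_auc(r.reversed(), positives)
            assert a_rev == pytest.approx(1.0 - a_fwd)


class TestTopkOverlap:
    @pytest.mark.parametrize(
        "pred_order, gold, k, expected",
        [
            (["a", "b", "c", "d"], ["a", "b", "c"], 3, 3),
            (["a", "b", "c", "d"], ["d", "e", "f"], 3, 0),
            (["a", "b", "c", "d"], ["c", "e", "f"], 3, 1),
            (["a", "b"], ["a", "b"], 5, 2),
        ],
    )
    def test_examples(self, pred_order, gold, k, expected):
        r = ranking([(c, len(pred_order) - i) for i, c in enumerate(pred_order)])
        assert topk_overlap(r, gold, k) == expected

    def test_self_overlap(self):
        r = ranking([("a", 3), ("b", 2), ("c", 1)])
        for k in (1, 2, 3, 5):
            assert topk_overlap(r, r.tissues, k) == min(k, 3)


class TestSingleProteinRanking:
    def _compendium(self, tissue_values: dict[str, list[float]], gene="g"):
        samples, tissue_of, data = [], {}, []
        for t, vals in tissue_values.items():
            for j, v in enumerate(vals):
                s = f"{t}{j}"
                samples.append(s)
                tissue_of[s] = t
                data.append(v)
        vals = pd.DataFrame([data], index=[gene], columns=samples)
        return ExpressionCompendium(vals, tissue_of)

    def test_shifted_tissue_ranks_first(self):
        rng = np.random.default_rng(0)
        base = {t: rng.normal(0, 1, 6).tolist() for t in ("A", "B", "C")}
        base["B"] = (np.array(base["B"]) + 10).tolist()
        c = self._compendium(base)
        assert single_protein_ranking("g", c).tissues[0] == "B"

    def test_welch_t_matches_formula_oracle(self):
        tissue_values = {
            "A": [1.0, 2.0, 3.0, 4.0],
            "B": [2.0, 2.5, 3.5, 5.0],
            "C": [0.0, 1.0, 0.5, 2.0],
        }
        c = self._compendium(tissue_values)
        r = single_protein_ranking("g", c)
        scores = dict(r.entries)
        for t, vals in tissue_values.items():
            rest = [v for u, vs in tissue_values.items() if u != t for v in vs]
            expected = stats.ttest_ind(vals, rest, equal_var=False).statistic
            assert scores[t] == pytest.approx(expected, rel=1e-9)

    def test_all_constant_ranks_lexicographic(self):
        c = self._compendium({"B": [1.0] * 4, "A": [1.0] * 4, "C": [1.0] * 4})
        r = single_protein_ranking("g", c)
        assert r.tissues == ["A", "B", "C"]
        assert all(math.isnan(s) for _, s in r.entries)

    def test_unknown_gene(self):
        c = self._compendium({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        with pytest.raises(ValueError, match="ghost"):
            single_protein_ranking("ghost", c)


class TestRandomizedNull:
    def test_deterministic_under_seed(self, planted_fixture, default_spec):
        _, comp, gs, cmap = planted_fixture
        cxs = planted_complexes(default_spec)
        a = randomized_null(comp, cxs, gs, cmap, reps=3, seed=7)
        b = randomized_null(comp, cxs, gs, cmap, reps=3, seed=7)
        assert a == b
        assert len(randomized_null(comp, cxs, gs, cmap, reps=1, seed=7)) == 1

    def test_shuffle_preserves_per_tissue_value_multiset(self, planted_fixture):
        _, comp, _, _ = planted_fixture
        rng = np.random.default_rng(0)
        shuffled = shuffle_within_tissues(comp, rng)
        for t in comp.tissues:
            orig = np.sort(comp.tissue_values(t).to_numpy(), axis=0)
            new = np.sort(shuffled.tissue_values(t).to_numpy(), axis=0)
            np.testing.assert_allclose(orig, new)

    def test_null_centers_on_chance(self, planted_fixture, default_spec):
        _, comp, gs, cmap = planted_fixture
        cxs = planted_complexes(default_spec)
        aucs = randomized_null(comp, cxs, gs, cmap, reps=25, seed=11)
        se = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se
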