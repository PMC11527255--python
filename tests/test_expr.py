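"""Expression analysis: normalization, DE, intersection, scoring, ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from rarecell import expr, synth
from rarecell.expr import (
    CountMatrix,
    DEResult,
    GeneSet,
    jasmine_score,
    lfc_concordance,
    ora_enrichment,
    shared_upregulated,
)


def tiny_cm(counts, conditions=None, lines=None, batches=None):
    counts = np.asarray(counts)
    n = counts.shape[1]
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        meta=pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "line": lines or ["L"] * n,
                "condition": conditions or ["x"] * n,
                "batch": batches or ["b0"] * n,
            }
        ),
    )


class TestNormalizeLog:
    def test_proportional_cells_identical(self):
        cm = tiny_cm(np.array([[10, 20], [30, 60], [0, 0]]))
        norm = expr.normalize_log(cm)
        np.testing.assert_allclose(norm[:, 0], norm[:, 1])

    def test_zero_stays_zero(self):
        cm = tiny_cm(np.array([[0, 5], [10, 5]]))
        assert expr.normalize_log(cm)[0, 0] == 0.0

    def test_all_zero_cell_listed_in_error(self):
        cm = tiny_cm(np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="c0"):
            expr.normalize_log(cm)


class TestDifferentialExpression:
    def _de_cm(self, seed=0, sig=None, n_genes=300, cells=30):
        spec = synth.ExprSimSpec(
            n_genes=n_genes,
            lines=("L",),
            conditions=("control", "treated"),
            cells_per_condition=cells,
            survivor_signature=sig or {},
            seed=seed,
        )
        return synth.generate_expression(spec)

    def test_planted_lfc_recovered(self):
        sig = {i: 2.0 for i in range(30)}
        cm = self._de_cm(seed=1, sig=sig, cells=60)
        res = expr.differential_expression(cm, "treated", "control")
        planted = res.table.iloc[:30]
        assert planted["lfc"].median() == pytest.approx(2.0, abs=0.3)
        assert (planted["fdr"] < 0.01).mean() > 0.9

    def test_all_zero_gene_flagged_not_tested(self):
        cm = self._de_cm(seed=2)
        cm.counts[0, :] = 0
        res = expr.differential_expression(cm, "treated", "control")
        row = res.table.iloc[0]
        assert not row["tested"] and np.isnan(row["p_value"])

    def test_too_few_cells_errors(self):
        cm = self._de_cm(seed=3, cells=2)
        with pytest.raises(ValueError, match="cells per side"):
            expr.differential_expression(cm, "treated", "control")

    def test_confounded_batch_errors(self):
        counts = np.random.default_rng(0).poisson(20, (50, 12))
        cm = tiny_cm(
            counts,
            conditions=["a"] * 6 + ["b"] * 6,
            batches=["b0"] * 6 + ["b1"] * 6,
        )
        with pytest.raises(ValueError, match="confounded"):
            expr.differential_expression(cm, "b", "a")

    def test_fdr_rank_consistent_with_pvalues(self):
        cm = self._de_cm(seed=4)
        res = expr.differential_expression(cm, "treated", "control")
        t = res.table[res.table["tested"]].sort_values("p_value")
        # BH adjusted values are monotone in p after the running-min step
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()
        assert t["fdr"].between(0, 1).all()


class TestSharedUpregulated:
    def _result(self, selected, universe):
        rows = []
        for g in universe:
            rows.append(
                {
                    "gene": g,
                    "lfc": 2.0 if g in selected else 0.0,
                    "p_value": 1e-9 if g in selected else 0.9,
                    "fdr": 1e-6 if g in selected else 0.95,
                    "mean_expr": 10.0,
                    "det_rate_case": 0.9,
                    "det_rate_control": 0.9,
                    "tested": True,
                }
            )
        return DEResult(contrast="t", table=pd.DataFrame(rows))

    def test_pairwise_intersection(self):
        uni = list("abcde")
        gs = shared_upregulated([self._result({"a", "b", "c"}, uni), self._result({"b", "c", "d"}, uni)])
        assert set(gs.genes) == {"b", "c"}

    def test_empty_selection_absorbs(self):
        uni = list("abcde")
        gs = shared_upregulated([self._result({"a"}, uni), self._result(set(), uni)])
        assert len(gs) == 0

    def test_order_invariant(self):
        uni = list("abcdef")
        rs = [
            self._result({"a", "b", "c", "d"}, uni),
            self._result({"b", "c", "d", "e"}, uni),
            self._result({"c", "d", "f"}, uni),
        ]
        g1 = shared_upregulated(rs)
        g2 = shared_upregulated(rs[::-1])
        assert set(g1.genes) == set(g2.genes) == {"c", "d"}

    def test_output_subset_of_each_selection(self):
        uni = [f"g{i}" for i in range(20)]
        sels = [set(uni[:12]), set(uni[5:16]), set(uni[8:20])]
        gs = shared_upregulated([self._result(s, uni) for s in sels])
        for s in sels:
            assert set(gs.genes) <= s


class TestLfcConcordance:
    def test_identical_results_r_one(self):
        rng = np.random.default_rng(0)
        uni = [f"g{i}" for i in range(50)]
        t = pd.DataFrame({"gene": uni, "lfc": rng.normal(2, 0.5, 50)})
        r = DEResult("a", t)
        gs = GeneSet("s", tuple(uni))
        assert lfc_concordance(r, r, gs) == pytest.approx(1.0)

    def test_too_few_genes_errors(self):
        t = pd.DataFrame({"gene": ["a", "b"], "lfc": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 genes"):
            lfc_concordance(DEResult("x", t), DEResult("y", t), GeneSet("s", ("a", "b")))


class TestJasmine:
    def test_rank_extremes_scale_to_zero_and_one(self):
        # cell 0: signature genes occupy the top ranks; cell 1: the bottom
        n = 20
        sig = GeneSet("s", tuple(f"g{i}" for i in range(5)))
        mat = np.zeros((n, 2))
        mat[:, 0] = np.concatenate([np.arange(15, 20), np.arange(1, 16)])  # sig highest
        mat[:, 1] = np.concatenate([np.arange(1, 6), np.arange(6, 21)])  # sig lowest
        scores = jasmine_score(mat, [f"g{i}" for i in range(n)], sig)
        assert scores["rank_component"].iloc[0] == 1.0
        assert scores["rank_component"].iloc[1] == 0.0

    def test_identical_cells_degenerate_half(self):
        mat = np.tile(np.arange(1, 11)[:, None], (1, 4)).astype(float)
        sig = GeneSet("s", ("g0", "g1"))
        scores = jasmine_score(mat, [f"g{i}" for i in range(10)], sig)
        assert (scores["score"] == 0.5).all()

    def test_scores_in_unit_interval_and_monotone_invariant(self):
        rng = np.random.default_rng(1)
        mat = rng.lognormal(1, 1, (100, 30)) * (rng.random((100, 30)) > 0.3)
        ids = [f"g{i}" for i in range(100)]
        sig = GeneSet("s", tuple(ids[:15]))
        s1 = jasmine_score(mat, ids, sig)
        assert s1["score"].between(0, 1).all()
        s2 = jasmine_score(np.log1p(mat) ** 1.7, ids, sig)  # monotone transform
        np.testing.assert_allclose(s1["rank_component"], s2["rank_component"])

    def test_survivors_score_above_controls(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            sig_idx = rng.choice(200, 25, replace=False)
            spec = synth.ExprSimSpec(
                n_genes=200,
                lines=("L",),
                conditions=("control", "treated"),
                cells_per_condition=30,
                survivor_signature={int(i): 2.0 for i in sig_idx},
                seed=200 + rep,
            )
            cm = synth.generate_expression(spec)
            norm = expr.normalize_log(cm)
            gs = GeneSet("sig", tuple(f"gene{i}" for i in sig_idx))
            scores = jasmine_score(norm, cm.gene_ids, gs)
            treated = (cm.meta["condition"] == "treated").to_numpy()
            if scores["score"][treated].mean() > scores["score"][~treated].mean():
                wins += 1
        assert wins >= 19  # >= 95% of replicates

    def test_disjoint_gene_set_errors(self):
        with pytest.raises(ValueError, match="intersect"):
            jasmine_score(np.ones((5, 3)), [f"g{i}" for i in range(5)], GeneSet("s", ("x",)))


class TestOra:
    def test_query_equals_collection_analytic_p(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSet("c", tuple(universe[:5]))
        res = ora_enrichment(GeneSet("q", tuple(universe[:5])), [coll], universe)
        expected = 1.0 / comb(20, 5)
        assert res["p_value"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_p_is_one_tail(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSet("c", tuple(universe[20:25]))
        res = ora_enrichment(GeneSet("q", tuple(universe[:5])), [coll], universe)
        assert res["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9) or res["p_value"].iloc[0] <= 1.0
        assert res["overlap"].iloc[0] == 0

    def test_disjoint_collection_skipped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSet("c", ("zzz",))
        with pytest.warns(UserWarning, match="disjoint"):
            res = ora_enrichment(GeneSet("q", tuple(universe[:3])), [coll], universe)
        assert len(res) == 0

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(500)]
        firsts = 0
        for rep in range(20):
            enriched = rng.choice(500, 40, replace=False)
            query_idx = np.concatenate(
                [rng.choice(enriched, 25, replace=False),
                 rng.choice(500, 15, replace=False)]
            )
            colls = [GeneSet("hit", tuple(universe[i] for i in enriched))]
            for j in range(9):
                colls.append(
                    GeneSet(f"bg{j}", tuple(universe[i] for i in rng.choice(500, 40, replace=False)))
                )
            res = ora_enrichment(
                GeneSet("q", tuple(universe[i] for i in query_idx)), colls, universe
            )
            if res["collection"].iloc[0] == "hit":
                firsts += 1
        assert firsts >= 19

    def test_gmt_roundtrip(self, tmp_path):
        sets = [GeneSet("a", ("g1", "g2")), GeneSet("b", ("g3",))]
        p = tmp_path / "x.gmt"
        expr.write_gmt(sets, p)
        back = expr.read_gmt(p)
        assert back == sets
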