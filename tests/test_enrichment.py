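"""Fold computation, target selection, quartiles and set operations."""

import numpy as np
import pandas as pd
import pytest

from riptargetkit.enrichment import (
    CountMatrix,
    CountMatrixError,
    RipEnrichment,
    RipEnrichmentResults,
    assign_quartiles,
    call_targets,
    enrichment_scores,
)
from riptargetkit.simulate import gen_counts, gene_ids, make_truth


def cm_from(rows: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(rows, index=[f"g{i}" for i in range(
        len(next(iter(rows.values()))))]))


class TestCountMatrix:
    def test_rejects_bad_column_names(self):
        with pytest.raises(CountMatrixError, match="role"):
            cm_from({"IP_1": [1], "input_1": [1], "pulldown_1": [1]})

    def test_rejects_missing_role(self):
        with pytest.raises(CountMatrixError, match="IgG"):
            cm_from({"IP_1": [1], "input_1": [1]})

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(CountMatrixError):
            cm_from({"IP_1": [-1], "input_1": [1], "IgG_1": [1]})
        with pytest.raises(CountMatrixError):
            cm_from({"IP_1": [1.5], "input_1": [1], "IgG_1": [1]})

    def test_tsv_roundtrip(self, tmp_path):
        cm = cm_from({"IP_1": [3, 0], "input_1": [5, 1], "IgG_1": [2, 2]})
        p = tmp_path / "c.tsv"
        cm.to_tsv(p)
        assert CountMatrix.from_tsv(p).counts.equals(cm.counts)


class TestEnrichmentScores:
    def unit_sf(self, cm):
        return pd.Series(1.0, index=cm.counts.columns)

    def test_formula_on_hand_values(self):
        cm = cm_from({"IP_1": [40], "input_1": [10], "IgG_1": [10]})
        f = enrichment_scores(cm, pseudocount=1e-9, sf=self.unit_sf(cm))
        assert np.isclose(f.loc["g0", "fold_1"], 4.0)

    def test_ip_equal_igg_gives_unit_fold(self):
        cm = cm_from({"IP_1": [7, 3], "input_1": [9, 1], "IgG_1": [7, 3]})
        f = enrichment_scores(cm, 0.5, sf=self.unit_sf(cm))
        assert np.allclose(f["mean_fold"], 1.0)

    def test_all_zero_gene_pseudocount_symmetry(self):
        cm = cm_from({"IP_1": [0, 5], "input_1": [0, 5], "IgG_1": [0, 5]})
        f = enrichment_scores(cm, 0.5, sf=self.unit_sf(cm))
        assert np.isclose(f.loc["g0", "mean_fold"], 1.0)

    def test_replicate_pairing_required(self):
        cm = cm_from({"IP_1": [1], "IP_2": [1], "input_1": [1], "IgG_1": [1]})
        with pytest.raises(CountMatrixError, match="replicate"):
            enrichment_scores(cm, 0.5, sf=pd.Series(1.0, index=cm.counts.columns))

    def test_consistent_replicate_permutation_invariance(self):
        t = make_truth(50, seed=13)
        c = gen_counts(gene_ids(50), t, n_rep=3).copy()
        cm = CountMatrix(c)
        base = enrichment_scores(cm, 0.5)["mean_fold"]
        # relabel biological replicate units 1->2->3->1 across all roles
        perm = {1: 2, 2: 3, 3: 1}
        renamed = c.rename(
            columns={f"{r}_{i}": f"{r}_{perm[i]}" for r in ("IP", "input", "IgG")
                     for i in (1, 2, 3)}
        )
        permuted = enrichment_scores(CountMatrix(renamed), 0.5)["mean_fold"]
        assert np.allclose(base, permuted)


class TestCallTargets:
    def scores(self, folds):
        return pd.DataFrame(
            {"mean_fold": folds}, index=[f"g{i}" for i in range(len(folds))]
        )

    def test_boundary_values_inclusive(self):
        table = call_targets(self.scores([2.0]), [0.05])
        assert bool(table["selected"].iloc[0])

    def test_high_fold_insignificant_not_selected(self):
        table = call_targets(self.scores([10.0]), [0.2])
        assert not table["selected"].any()

    def test_sorting_and_tiebreaks(self):
        table = call_targets(self.scores([2.0, 5.0, 2.0]), [0.04, 0.01, 0.02])
        assert list(table.index) == ["g1", "g2", "g0"]  # fold desc, then adj_p
        assert list(table["rank"]) == [1, 2, 3]

    def test_selection_monotone_in_cutoffs(self):
        rng = np.random.default_rng(4)
        folds = rng.lognormal(0.5, 1, 100)
        ps = rng.uniform(size=100) ** 2
        base = set(call_targets(self.scores(folds), ps, fold_cutoff=2, alpha=0.05)
                   .query("selected").index)
        stricter_fold = set(call_targets(self.scores(folds), ps, fold_cutoff=3, alpha=0.05)
                            .query("selected").index)
        stricter_alpha = set(call_targets(self.scores(folds), ps, fold_cutoff=2, alpha=0.01)
                             .query("selected").index)
        assert stricter_fold <= base and stricter_alpha <= base


class TestQuartiles:
    def test_eight_genes_top_quartile_of_two(self):
        q = assign_quartiles(pd.Series(range(1, 9)))
        assert list(q) == [4, 4, 3, 3, 2, 2, 1, 1]

    def test_ceiling_convention_for_ten(self):
        q = assign_quartiles(pd.Series(range(1, 11)))
        assert list(q).count(4) == 3  # ceil(10/4)

    def test_tied_folds_resolved_by_gene_id(self):
        table = call_targets(
            pd.DataFrame({"mean_fold": [3.0] * 4}, index=["gd", "gb", "ga", "gc"]),
            [0.01] * 4,
        )
        assert list(table.index) == ["ga", "gb", "gc", "gd"]


def results_from_table(table):
    return RipEnrichmentResults(
        table=table,
        fold_cutoff=2.0,
        alpha=0.05,
        size_factors_=pd.Series(dtype=float),
        mean_normalized_input=pd.Series(1.0, index=table.index),
    )


class TestTargetSets:
    def make_results(self, n):
        folds = np.linspace(10, 2, n)
        table = call_targets(
            pd.DataFrame({"mean_fold": folds}, index=[f"g{i:03d}" for i in range(n)]),
            [0.001] * n,
        )
        return results_from_table(table)

    def test_top_bottom_extremes(self):
        res = self.make_results(100)
        q4 = res.quartile4()
        tb = res.top_bottom(1, subset=q4)
        assert tb["mean_fold"].iloc[0] == q4["mean_fold"].max()
        assert tb["mean_fold"].iloc[-1] == q4["mean_fold"].min()

    def test_top_bottom_k10_of_25(self):
        res = self.make_results(100)
        q4 = res.quartile4()
        assert len(q4) == 25
        assert len(res.top_bottom(10, subset=q4)) == 20

    def test_top_bottom_overflow_errors(self):
        res = self.make_results(12)
        with pytest.raises(ValueError):
            res.top_bottom(10, subset=res.quartile4())

    def test_high_low_disjoint_and_sized(self):
        res = self.make_results(100)
        hl = res.high_low_sets(50, 50)
        assert len(hl) == 100
        assert set(hl[hl["set"] == "high"].index).isdisjoint(hl[hl["set"] == "low"].index)

    def test_high_low_whole_set_and_overflow(self):
        res = self.make_results(30)
        assert len(res.high_low_sets(30, 0)) == 30
        with pytest.raises(ValueError):
            res.high_low_sets(20, 20)


class TestModelFit:
    def test_recovers_planted_targets_and_reports_fraction(self):
        t = make_truth(2000, seed=17, enriched_frac=0.05)
        cm = CountMatrix(gen_counts(gene_ids(2000), t, n_rep=3))
        res = RipEnrichment(cm).fit()
        sel = set(res.selected.index)
        tp = len(sel & t.enriched_genes)
        assert tp / len(t.enriched_genes) >= 0.8
        assert (len(sel) - tp) / max(len(sel), 1) <= 0.1
        frac = res.input_expressed_fraction()
        assert 0.0 < frac < 0.2
        assert "targets" in res.summary()
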