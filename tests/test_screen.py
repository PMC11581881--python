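"""Fold changes, LET correlation screening, cross-omics correlation, hubs."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssnlet.screen import (fold_change, hub_genes, let_screen,
                           methylation_correlation)
from ssnlet.types import FCMatrix, OmicsMatrix


def pearson_oracle(x, y):
    """Textbook formula: r from raw sums, p via t = r sqrt((n-2)/(1-r^2))."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = (((x - x.mean()) * (y - y.mean())).sum()
         / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    t = r * math.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestFoldChange:
    def test_level_ratio(self, small_meta):
        frame = pd.DataFrame([[2, 2, 2, 4, 4, 4, 4, 4, 4]],
                             index=["g1"], columns=small_meta.sample_ids)
        fc = fold_change(OmicsMatrix(frame, "expression"), small_meta, "level")
        assert (fc.frame.loc["g1"] == 2.0).all()

    def test_level_drops_gc_mean_zero_genes(self, small_meta):
        frame = pd.DataFrame([[0, 0, 0, 4, 4, 4, 4, 4, 4],
                              [1, 1, 1, 2, 2, 2, 2, 2, 2]],
                             index=["g0", "g1"], columns=small_meta.sample_ids)
        fc = fold_change(OmicsMatrix(frame, "expression"), small_meta, "level")
        assert fc.gene_ids == ["g1"]

    @pytest.mark.parametrize("d_sf,d_gc,expected", [
        (0, (0, 0, 0), 1.0),   # zero degrees still yield the finite value 1
        (5, (2, 2, 2), 2.0),   # (5+1)/(2+1)
    ])
    def test_degree_plus_one_guard(self, small_meta, d_sf, d_gc, expected):
        frame = pd.DataFrame([list(d_gc) + [d_sf] * 6], index=["g1"],
                             columns=small_meta.sample_ids)
        fc = fold_change(frame, small_meta, "degree")
        assert (fc.frame.loc["g1"] == expected).all()

    def test_degree_fc_is_one_at_gc_mean(self, small_meta, rng):
        """Eq-identity: an SF degree equal to the GC mean gives FC = 1."""
        gc = rng.integers(0, 6, size=3)
        d = gc.mean()
        frame = pd.DataFrame([list(gc) + [d] * 6], index=["g1"],
                             columns=small_meta.sample_ids)
        fc = fold_change(frame, small_meta, "degree")
        assert np.allclose(fc.frame.loc["g1"], 1.0)

    def test_no_gc_samples_is_error(self, small_meta):
        frame = pd.DataFrame([[1] * 6], index=["g1"],
                             columns=small_meta.sf_ids)
        with pytest.raises(ValueError, match="ground-control"):
            fold_change(frame, small_meta, "level")


class TestLetScreen:
    def _fc(self, values, small_meta, mode="level"):
        frame = pd.DataFrame(values, columns=small_meta.sf_ids,
                             index=[f"g{i}" for i in range(len(values))])
        return FCMatrix(frame + 0.0 if mode == "level" else frame,
                        mode=mode, layer="expression")

    def test_perfectly_linear_gene_is_hit_in_both_modes(self, small_meta):
        let = small_meta.let(small_meta.sf_ids)
        fc_vals = [0.01 * let + 1]
        for mode in ("level", "degree"):
            fc = self._fc(fc_vals, small_meta, mode)
            res = let_screen(fc, small_meta, mode=mode)
            assert res.loc["g0", "pcc"] == pytest.approx(1.0)
            assert res.loc["g0", "p_value"] < 1e-8
            assert bool(res.loc["g0", "is_hit"])

    def test_constant_fc_vector_is_not_a_hit(self, small_meta):
        res = let_screen(self._fc([[1.0] * 6], small_meta), small_meta)
        assert not res["is_hit"].any()
        assert math.isnan(res.loc["g0", "pcc"])

    def test_matches_closed_form_oracle(self, rng):
        meta_frame = pd.DataFrame({
            "sample_id": [f"SF{i}" for i in range(22)] + ["GC1"],
            "group": ["SF"] * 22 + ["GC"],
            "let_value": list(rng.uniform(0, 250, 22)) + [np.nan],
            "stage": "heading"})
        from ssnlet.types import SampleMetadata
        meta = SampleMetadata(meta_frame)
        vals = rng.lognormal(0, 0.5, size=(15, 22))
        fc = FCMatrix(pd.DataFrame(vals, columns=meta.sf_ids,
                                   index=[f"g{i}" for i in range(15)]),
                      mode="level", layer="expression")
        res = let_screen(fc, meta)
        let = meta.let(meta.sf_ids)
        for i in range(15):
            r, p = pearson_oracle(vals[i], let)
            assert res["pcc"].iloc[i] == pytest.approx(r, abs=1e-12)
            assert res["p_value"].iloc[i] == pytest.approx(p, abs=1e-12)

    def test_invariant_to_row_and_column_order(self, small_meta, rng):
        vals = rng.lognormal(0, 0.4, size=(6, 6))
        genes = [f"g{i}" for i in range(6)]
        fc = FCMatrix(pd.DataFrame(vals, index=genes,
                                   columns=small_meta.sf_ids),
                      mode="level", layer="expression")
        res = let_screen(fc, small_meta)
        perm_genes = genes[::-1]
        perm_cols = list(reversed(small_meta.sf_ids))
        fc_perm = FCMatrix(fc.frame.loc[perm_genes, perm_cols],
                           mode="level", layer="expression")
        res_perm = let_screen(fc_perm, small_meta)
        for g in genes:
            assert res_perm.loc[g, "pcc"] == pytest.approx(
                res.loc[g, "pcc"], abs=1e-14)

    def test_affine_let_transform_preserves_perfect_linearity(self, small_meta):
        """Guard against accidental rank-correlation: only affine transforms
        of LET keep |PCC| = 1 for a linear gene; a strictly monotone nonlinear
        transform must not."""
        let = small_meta.let(small_meta.sf_ids)
        fc = self._fc([0.01 * let + 1], small_meta)
        affine = let_screen(fc, small_meta)
        assert abs(affine.loc["g0", "pcc"]) == pytest.approx(1.0)
        meta2 = small_meta.frame.copy()
        sf = meta2["group"] == "SF"
        meta2.loc[sf, "let_value"] = np.sqrt(meta2.loc[sf, "let_value"]) ** 3
        from ssnlet.types import SampleMetadata
        nonlinear = let_screen(fc, SampleMetadata(meta2))
        assert abs(nonlinear.loc["g0", "pcc"]) < 1.0 - 1e-6


class TestMethylationCorrelation:
    def test_affine_relation_is_perfect_hit(self, rng):
        samples = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame(rng.normal(size=(3, 6)) + 5,
                            index=["a", "b", "c"], columns=samples)
        meth = expr * -0.05 + 0.6
        res = methylation_correlation(expr, meth.clip(0, 1) * 0 + meth,
                                      ["a", "b"])
        assert np.allclose(np.abs(res["pcc"]), 1.0)
        assert res["is_hit"].all()

    def test_gene_absent_from_methylation_excluded(self, rng):
        samples = [f"s{i}" for i in range(5)]
        expr = pd.DataFrame(rng.normal(size=(2, 5)), index=["a", "b"],
                            columns=samples)
        meth = expr.loc[["a"]] * 0.1 + 0.5
        res = methylation_correlation(expr, meth, ["a", "b"])
        assert res.index.tolist() == ["a"]

    def test_matches_closed_form_oracle_n11(self, rng):
        samples = [f"s{i}" for i in range(11)]
        expr = pd.DataFrame(rng.normal(size=(4, 11)), index=list("abcd"),
                            columns=samples)
        meth = pd.DataFrame(rng.uniform(0, 1, size=(4, 11)),
                            index=list("abcd"), columns=samples)
        res = methylation_correlation(expr, meth, list("abcd"))
        for g in "abcd":
            r, p = pearson_oracle(expr.loc[g], meth.loc[g])
            assert res.loc[g, "pcc"] == pytest.approx(r, abs=1e-12)
            assert res.loc[g, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_too_few_shared_samples_is_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(1, 3)), index=["a"],
                            columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="shared samples"):
            methylation_correlation(expr, expr, ["a"])


class TestHubGenes:
    def test_star_center(self):
        ppi = nx.star_graph(5)
        ppi = nx.relabel_nodes(ppi, {0: "C", **{i: f"L{i}" for i in range(1, 6)}})
        res = hub_genes(list(ppi.nodes), ppi, top_k=1)
        assert res.index.tolist() == ["C"]
        assert res.loc["C", "degree"] == 5

    def test_tie_at_cutoff_included(self):
        # degrees: a=3, b=2, c=2, d=1
        ppi = nx.Graph([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        top3 = hub_genes(list("abcd"), ppi, top_k=3)
        assert len(top3) == 3                      # no tie across rank 3
        top2 = hub_genes(list("abcd"), ppi, top_k=2)
        assert len(top2) == 3                      # b and c tie at rank 2
        assert set(top2.index) == {"a", "b", "c"}

    def test_disjoint_gene_set_gives_empty_result(self):
        ppi = nx.Graph([("a", "b")])
        res = hub_genes(["x", "y"], ppi, top_k=3)
        assert res.empty
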