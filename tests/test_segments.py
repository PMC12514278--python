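"""Segment pipeline: QC, LOQ filter, Q3, clustering, LMM DE, GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import plaquemap as pm

from conftest import simulate_segment_matrix


def make_segments(counts, negprobes=None, meta_overrides=None):
    """SegmentTable from a targets x segments array (+ optional negprobes)."""
    counts = pd.DataFrame(np.asarray(counts, dtype=float))
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"seg{j}" for j in range(counts.shape[1])]
    tclass = pd.Series("endogenous", index=counts.index)
    if negprobes is not None:
        neg = pd.DataFrame(np.asarray(negprobes, dtype=float))
        neg.index = [f"neg{i}" for i in range(neg.shape[0])]
        neg.columns = counts.columns
        counts = pd.concat([counts, neg])
        tclass = pd.concat([tclass,
                            pd.Series("negative_probe", index=neg.index)])
    meta = pd.DataFrame({"slide_id": "s1", "severity": "mild",
                         "location": "adventitia",
                         "marker_segment": "CD45+CD4-",
                         "nuclei_count": 100, "surface_area": 1e4},
                        index=counts.columns)
    if meta_overrides:
        for col, vals in meta_overrides.items():
            meta[col] = vals
    return pm.SegmentTable(counts=counts, meta=meta, target_class=tclass)


class TestSegmentQC:
    def test_boundary_nuclei_failure_named(self):
        seg = make_segments(np.full((5, 2), 500),
                            meta_overrides={"nuclei_count": [19, 20]})
        qc = pm.segment_qc(seg)
        assert not qc["pass"].iloc[0] and qc["reasons"].iloc[0] == "nuclei"
        assert qc["pass"].iloc[1]

    def test_zero_thresholds_pass_everything(self):
        seg = make_segments(np.zeros((5, 3)),
                            meta_overrides={"nuclei_count": [0, 1, 2]})
        qc = pm.segment_qc(seg, pm.SegmentQCParams(
            min_nuclei=0, min_area=0, min_raw_reads=0))
        assert qc["pass"].all()

    def test_planted_failures_flagged_exactly(self):
        seg = make_segments(
            np.column_stack([np.full(5, 300), np.full(5, 300), np.full(5, 10)]),
            meta_overrides={"nuclei_count": [100, 5, 100],
                            "surface_area": [1e4, 1e4, 1e4]})
        qc = pm.segment_qc(seg, pm.SegmentQCParams(min_raw_reads=100))
        assert list(qc["pass"]) == [True, False, False]
        assert qc["reasons"].iloc[1] == "nuclei"
        assert qc["reasons"].iloc[2] == "raw_reads"

    def test_missing_metadata_named(self):
        seg = make_segments(np.ones((5, 2)))
        seg.meta = seg.meta.drop(columns=["nuclei_count"])
        with pytest.raises(pm.ConfigurationError, match="nuclei_count"):
            pm.segment_qc(seg)


class TestLoqFilter:
    def test_loq_formula_constant_probes(self):
        # negprobes {2,2,2} per segment: geoSD 1 -> LOQ = 2
        seg = make_segments(np.full((6, 3), 50), negprobes=np.full((3, 3), 2))
        _, loq = pm.loq_target_filter(seg)
        np.testing.assert_allclose(loq.to_numpy(), 2.0)

    def test_all_zero_target_removed(self):
        counts = np.vstack([np.full((5, 4), 50), np.zeros((1, 4))])
        seg = make_segments(counts, negprobes=np.full((3, 4), 2))
        with pytest.warns(UserWarning, match="removed"):
            filt, _ = pm.loq_target_filter(seg)
        assert "g5" not in filt.targets

    def test_planted_background_targets_exactly_removed(self):
        rng = np.random.default_rng(0)
        signal = rng.integers(20, 200, (20, 6))
        background = rng.integers(0, 2, (5, 6))  # never exceeds LOQ=2
        seg = make_segments(np.vstack([signal, background]),
                            negprobes=np.full((4, 6), 2))
        with pytest.warns(UserWarning):
            filt, _ = pm.loq_target_filter(seg)
        assert set(filt.targets) == {f"g{i}" for i in range(20)}
        assert list(filt.segments) == list(seg.segments)

    def test_background_only_segment_removed(self):
        counts = np.full((20, 4), 100)
        counts[:, 3] = 1  # last segment entirely below its LOQ
        seg = make_segments(counts, negprobes=np.full((3, 4), 2))
        with pytest.warns(UserWarning):
            filt, _ = pm.loq_target_filter(seg)
        assert "seg3" not in filt.segments

    def test_requires_negative_probes(self):
        seg = make_segments(np.ones((5, 3)))
        with pytest.raises(pm.DataError, match="negative-probe"):
            pm.loq_target_filter(seg)


class TestQ3Normalize:
    def test_two_segment_factors(self):
        # Q3s 4 and 16 -> geomean 8 -> factors 0.5 and 2
        seg = make_segments(np.column_stack([[1, 2, 3, 4], [4, 8, 12, 16]]))
        out = pm.q3_normalize(seg)
        np.testing.assert_allclose(out.counts["seg0"], [2, 4, 6, 8])
        np.testing.assert_allclose(out.counts["seg1"], [2, 4, 6, 8])
        assert out.normalized

    def test_single_segment_unchanged(self):
        seg = make_segments(np.array([[1], [5], [9], [13]]))
        out = pm.q3_normalize(seg)
        np.testing.assert_allclose(out.counts.to_numpy(),
                                   seg.counts.to_numpy())

    def test_quartiles_equalized_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            seg = make_segments(rng.integers(1, 500, (40, 7)))
            out = pm.q3_normalize(seg)
            q3 = out.counts.quantile(0.75, axis=0)
            target = np.exp(np.mean(np.log(
                seg.counts.quantile(0.75, axis=0))))
            np.testing.assert_allclose(q3.to_numpy(), target, rtol=1e-12)

    def test_zero_q3_segment_dropped_with_warning(self):
        counts = np.column_stack([[5, 6, 7, 8], [0, 0, 0, 0]])
        seg = make_segments(counts)
        with pytest.warns(UserWarning, match="unnormalizable"):
            out = pm.q3_normalize(seg)
        assert list(out.segments) == ["seg0"]


class TestPearsonHclust:
    def test_duplicate_segments_merge_first_at_zero(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 4))
        X[:, 3] = X[:, 0]  # duplicate
        hc = pm.pearson_hclust(pd.DataFrame(
            X, columns=list("abcd")), "segments")
        assert hc.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(hc.linkage[0, 0]), int(hc.linkage[0, 1])}
        assert merged == {0, 3}

    def test_planted_blocks_contiguous_in_leaf_order(self):
        rng = np.random.default_rng(3)
        block1 = np.tile(rng.random(25), (5, 1)).T + rng.normal(0, .05, (25, 5))
        block2 = np.tile(rng.random(25), (5, 1)).T + rng.normal(0, .05, (25, 5))
        X = np.hstack([block1, block2])
        labels = [f"x{i}" for i in range(5)] + [f"y{i}" for i in range(5)]
        hc = pm.pearson_hclust(pd.DataFrame(X, columns=labels), "segments")
        first5 = {l[0] for l in hc.leaf_order[:5]}
        assert len(first5) == 1  # one block occupies one side

    def test_constant_item_rejected_by_name(self):
        X = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(pm.DataError, match="flat"):
            pm.pearson_hclust(X, "segments")

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((20, 5)), columns=list("abcde"))
        nwk = pm.pearson_hclust(X, "segments").to_newick()
        assert nwk.endswith(";")
        for leaf in "abcde":
            assert leaf in nwk


class TestMixedModelDE:
    def test_forced_zero_variance_equals_ols(self):
        seg = simulate_segment_matrix(30, 8, 3, tau=0.3, sigma=0.5, seed=5)
        de = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                            pseudocount=0.0,
                                            force_var_ratio=0.0)
        y = np.log2(seg.counts.iloc[0].to_numpy())
        g = (seg.meta["group"] == "B").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(g)), g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert de.table["log2fc"].iloc[0] == pytest.approx(beta[1], abs=1e-8)
        assert de.table["se"].iloc[0] == pytest.approx(se, abs=1e-8)

    def test_single_slide_reduces_to_ols(self):
        seg = simulate_segment_matrix(10, 6, 1, tau=0.0, sigma=0.5, seed=6)
        with pytest.warns(UserWarning, match="reduces to OLS"):
            de = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                                pseudocount=0.0)
        assert (de.table["df"] == 2 * 6 - 2).all()

    def test_group_swap_negates_fold_change(self):
        seg = simulate_segment_matrix(20, 6, 3, tau=0.2, sigma=0.5,
                                      lfc=1.0, n_alt=10, seed=7)
        de_ab = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                               pseudocount=0.0)
        de_ba = pm.lmm_differential_expression(seg, "group", ("B", "A"),
                                               pseudocount=0.0)
        np.testing.assert_allclose(de_ab.table["log2fc"],
                                   -de_ba.table["log2fc"], atol=1e-6)
        np.testing.assert_allclose(de_ab.table["p"], de_ba.table["p"],
                                   atol=1e-6)

    def test_matches_reml_mixedlm_reference(self):
        # independent oracle: statsmodels MixedLM (REML) per gene
        import statsmodels.formula.api as smf
        seg = simulate_segment_matrix(5, 8, 4, tau=0.6, sigma=0.4,
                                      lfc=1.0, n_alt=2, seed=8)
        de = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                            pseudocount=0.0)
        for i in range(5):
            df = pd.DataFrame({
                "y": np.log2(seg.counts.iloc[i].to_numpy()),
                "g": (seg.meta["group"] == "B").astype(float).to_numpy(),
                "s": seg.meta["slide_id"].to_numpy()})
            fit = smf.mixedlm("y ~ g", df, groups="s").fit(reml=True)
            assert de.table["log2fc"].iloc[i] == pytest.approx(
                fit.params["g"], abs=2e-3)
            assert de.table["se"].iloc[i] == pytest.approx(
                fit.bse["g"], rel=0.03)

    def test_null_type_one_error_calibrated(self):
        seg = simulate_segment_matrix(2000, 12, 3, tau=0.25, sigma=0.5,
                                      seed=42)
        de = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                            pseudocount=0.0)
        rate = float((de.table["p"] < 0.05).mean())
        half = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) <= half

    def test_power_for_planted_twofold_changes(self):
        seg = simulate_segment_matrix(2000, 12, 3, tau=0.25, sigma=0.5,
                                      lfc=1.0, n_alt=200, seed=9)
        de = pm.lmm_differential_expression(seg, "group", ("A", "B"),
                                            pseudocount=0.0)
        power = float((de.table["fdr"].iloc[:200] < 0.05).mean())
        assert power >= 0.70  # target 80%, +/-10 points


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.2], [0.2]),
    ])
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(pm.bh_adjust(np.array(p)), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(pm.ParameterError):
            pm.bh_adjust(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_matches_step_up_oracle_and_permutation_invariant(self, p):
        p = np.array(p)
        adj = pm.bh_adjust(p)
        # explicit step-up oracle
        m = len(p)
        order = np.argsort(p, kind="stable")
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, oracle, atol=1e-12)
        perm = np.random.default_rng(0).permutation(m)
        np.testing.assert_allclose(pm.bh_adjust(p[perm]), adj[perm],
                                   atol=1e-12)


class TestGsea:
    def _positive_ranking(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.uniform(0.1, 5, n))[::-1]
        return pd.Series(vals, index=[f"g{i}" for i in range(n)])

    def test_planted_top_set_hits_permutation_floor(self):
        ranked = self._positive_ranking()
        params = pm.GseaParams(min_set_size=5, n_perm=1000, seed=1)
        res = pm.preranked_gsea(ranked, {"top": list(ranked.index[:10])},
                                params)
        assert res["ES"].iloc[0] > 0.9
        assert res["p"].iloc[0] == pytest.approx(1.0 / 1001)

    def test_es_bounded_on_random_sets(self):
        rng = np.random.default_rng(2)
        ranked = pd.Series(rng.normal(0, 1, 300),
                           index=[f"g{i}" for i in range(300)])
        sets = {f"S{i}": list(rng.choice(ranked.index, 25, replace=False))
                for i in range(50)}
        res = pm.preranked_gsea(ranked, sets,
                                pm.GseaParams(min_set_size=5, n_perm=200,
                                              seed=3))
        assert (res["ES"].abs() <= 1.0).all()

    def test_coverage_filter_drops_set_with_reason(self):
        ranked = self._positive_ranking()
        sets = {"mostly_missing": ["nope%d" % i for i in range(80)]
                + list(ranked.index[:15])}
        with pytest.warns(UserWarning, match="coverage"):
            res = pm.preranked_gsea(ranked, sets,
                                    pm.GseaParams(min_set_size=5, n_perm=100,
                                                  seed=4))
        assert len(res) == 0

    def test_size_filter_applied_after_intersection(self):
        ranked = self._positive_ranking()
        with pytest.warns(UserWarning, match="size"):
            res = pm.preranked_gsea(
                ranked, {"tiny": list(ranked.index[:4])},
                pm.GseaParams(min_set_size=15, n_perm=100, seed=5))
        assert len(res) == 0

    def test_set_covering_all_genes_rejected(self):
        ranked = self._positive_ranking(n=30)
        with pytest.raises(pm.DataError, match="complement"):
            pm.preranked_gsea(ranked, {"all": list(ranked.index)},
                              pm.GseaParams(min_set_size=5, n_perm=50,
                                            seed=6))

    def test_duplicate_gene_names_rejected(self):
        ranked = pd.Series([1.0, 2.0], index=["g", "g"])
        with pytest.raises(pm.DataError, match="duplicate"):
            pm.preranked_gsea(ranked, {}, pm.GseaParams(n_perm=10))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(800)]
        ranked = pd.Series(rng.normal(0, 1, 800), index=genes)
        sets = {f"S{i}": list(rng.choice(genes, 30, replace=False))
                for i in range(500)}
        res = pm.preranked_gsea(ranked, sets,
                                pm.GseaParams(min_set_size=5, n_perm=1000,
                                              seed=8))
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestPathwayZscore:
    def _de(self, ups, downs, nulls):
        rows = []
        for i in range(ups):
            rows.append(("u%d" % i, 1.0, 0.001))
        for i in range(downs):
            rows.append(("d%d" % i, -1.0, 0.001))
        for i in range(nulls):
            rows.append(("n%d" % i, 0.3, 0.9))
        return pd.DataFrame(rows, columns=["target", "log2fc", "fdr"]
                            ).set_index("target")

    def test_formula_five_up_three_down_of_sixteen(self):
        de = self._de(5, 3, 8)
        z = pm.pathway_zscore(list(de.index), de, alpha=0.05)
        assert z == pytest.approx(0.5)  # (5-3)/sqrt(16)

    def test_all_up_nine(self):
        de = self._de(9, 0, 0)
        assert pm.pathway_zscore(list(de.index), de) == pytest.approx(3.0)

    def test_no_significant_members_zero(self):
        de = self._de(0, 0, 10)
        assert pm.pathway_zscore(list(de.index), de) == 0.0

    def test_empty_intersection_is_missing(self):
        de = self._de(2, 2, 2)
        with pytest.warns(UserWarning, match="no tested members"):
            z = pm.pathway_zscore(["absent1", "absent2"], de)
        assert np.isnan(z)
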