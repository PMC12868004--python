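"""Blocked ANOVA, consensus correlation, BH, fold change and calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from brainprot import (
    AbundanceMatrix,
    AnalysisConfig,
    GeneratorParams,
    Region,
    SampleAnnotation,
    ValidationError,
    benjamini_hochberg,
    blocked_anova_f,
    call_region_specific,
    estimate_consensus_correlation,
    fold_change_vs_rest,
    generate_proteome_dataset,
    lobe_shared_signature,
    region_stats,
    top_k_per_region,
)
from brainprot.evaluate import rho_params
from brainprot.preprocess import normalize
from brainprot.specificity import SpecificityResult


def _log2_matrix(values, samples):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    frame = pd.DataFrame(
        arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=samples
    )
    return AbundanceMatrix(values=frame, stage="log2ppm")


def _two_region_design():
    return [
        SampleAnnotation("a1", "d1", Region.FL),
        SampleAnnotation("a2", "d2", Region.FL),
        SampleAnnotation("b1", "d1", Region.CB),
        SampleAnnotation("b2", "d2", Region.CB),
    ]


class TestRegionStats:
    def test_mean_and_count(self):
        ann = _two_region_design()
        matrix = _log2_matrix([2.0, 4.0, 1.0, np.nan], [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        assert stats.means.loc["p0", "FL"] == 3.0
        assert stats.counts.loc["p0", "FL"] == 2
        assert stats.counts.loc["p0", "CB"] == 1

    def test_fully_missing_region_undefined(self):
        ann = _two_region_design()
        matrix = _log2_matrix([2.0, 4.0, np.nan, np.nan], [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        assert stats.counts.loc["p0", "CB"] == 0
        assert np.isnan(stats.means.loc["p0", "CB"])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        regions = list(Region)[:5]
        ann = [
            SampleAnnotation(f"s{i}", f"d{i % 4}", regions[i % 5]) for i in range(20)
        ]
        arr = rng.normal(size=(50, 20))
        arr[rng.random(arr.shape) < 0.2] = np.nan
        matrix = _log2_matrix(arr, [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        for p in range(50):
            for region in regions:
                cols = [i for i, a in enumerate(ann) if a.region is region]
                vals = arr[p, cols]
                vals = vals[~np.isnan(vals)]
                assert stats.counts.iloc[p][region.value] == len(vals)
                if len(vals):
                    assert stats.means.iloc[p][region.value] == pytest.approx(vals.mean())

    def test_annotation_mismatch_rejected(self):
        ann = _two_region_design()
        matrix = _log2_matrix([1.0, 2.0, 3.0, 4.0], ["a1", "a2", "b1", "zz"])
        with pytest.raises(ValidationError, match="zz"):
            region_stats(matrix, ann)


class TestBlockedAnova:
    def test_worked_two_region_example(self):
        ann = _two_region_design()
        F, df1, df2, p = blocked_anova_f([1.0, 2.0, 3.0, 4.0], ann, rho=0.0)
        assert F == pytest.approx(8.0)
        assert (df1, df2) == (1, 2)
        assert p == pytest.approx(0.10557, abs=1e-4)

    def test_rho_zero_equals_textbook_oneway(self):
        rng = np.random.default_rng(3)
        regions = list(Region)[:4]
        for _ in range(50):
            n_per = rng.integers(2, 5, size=4)
            ann, values, groups = [], [], []
            k = 0
            for r, n in zip(regions, n_per):
                vals = rng.normal(size=n)
                groups.append(vals)
                for v in vals:
                    ann.append(SampleAnnotation(f"s{k}", f"d{k % 3}", r))
                    values.append(v)
                    k += 1
            F, _, _, p = blocked_anova_f(values, ann, rho=0.0)
            ref = sps.f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_equal_values(self):
        ann = _two_region_design()
        F, _, _, p = blocked_anova_f([5.0, 5.0, 5.0, 5.0], ann, rho=0.3)
        assert F == 0.0 and p == 1.0

    def test_affine_invariance_on_complete_blocks(self):
        rng = np.random.default_rng(4)
        regions = list(Region)[:5]
        ann = [
            SampleAnnotation(f"d{d}_{r.value}", f"d{d}", r)
            for d in range(4)
            for r in regions
        ]
        values = rng.normal(size=len(ann))
        F0, _, _, _ = blocked_anova_f(values, ann, rho=0.4)
        F1, _, _, _ = blocked_anova_f(3.0 * values + 11.0, ann, rho=0.4)
        assert F1 == pytest.approx(F0, rel=1e-10)

    def test_invalid_rho_rejected(self):
        ann = _two_region_design()
        with pytest.raises(ValidationError, match="rho"):
            blocked_anova_f([1.0, 2.0, 3.0, 4.0], ann, rho=-1.5)


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force(pvals):
        """Direct step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j."""
        p = np.asarray(pvals, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        best = 1.0
        for i in range(m - 1, -1, -1):
            best = min(best, p[order[i]] * m / (i + 1))
            adj[order[i]] = best
        return adj

    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_missing_preserved_and_m_counts_present_only(self):
        out = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], self.brute_force([0.01, 0.04]))

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(1, 40)
            p = rng.random(n) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(benjamini_hochberg(p), self.brute_force(p))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(
                benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )


class TestConsensusCorrelation:
    @pytest.mark.parametrize("rho_true,band", [(0.0, (-0.05, 0.05)), (0.5, (0.45, 0.55))])
    def test_recovery(self, rho_true, band):
        params = rho_params(seed=21, rho=rho_true, n_proteins=2000)
        matrix, annotations, truth = generate_proteome_dataset(params)
        cc = estimate_consensus_correlation(normalize(matrix), annotations)
        assert truth.rho_true == pytest.approx(rho_true)
        assert band[0] <= cc.rho_consensus <= band[1]
        assert cc.n_used <= 2000

    def test_zero_residual_protein_excluded(self):
        ann = [
            SampleAnnotation(f"d{d}_{r.value}", f"d{d}", r)
            for d in range(3)
            for r in list(Region)[:4]
        ]
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(5, len(ann)))
        arr[0] = 1.0  # all residuals exactly zero
        matrix = _log2_matrix(arr, [a.sample_id for a in ann])
        cc = estimate_consensus_correlation(matrix, ann)
        assert np.isnan(cc.rho_per_protein.iloc[0])
        assert cc.n_used == 4

    def test_single_donor_design_rejected(self):
        ann = [SampleAnnotation(f"s{i}", "d1", r) for i, r in enumerate(list(Region)[:4])]
        matrix = _log2_matrix(np.random.default_rng(8).normal(size=(3, 4)),
                              [a.sample_id for a in ann])
        with pytest.raises(ValidationError, match="oneway"):
            estimate_consensus_correlation(matrix, ann)


class TestFoldChange:
    def test_definition(self):
        ann = _two_region_design()
        matrix = _log2_matrix([4.0, 4.0, 3.0, 3.0], [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        region, tie, fc = fold_change_vs_rest(stats, "p0")
        assert region is Region.FL and not tie
        assert fc == pytest.approx(2.0)

    def test_tie_broken_by_declaration_order(self):
        ann = _two_region_design()
        matrix = _log2_matrix([3.0, 3.0, 3.0, 3.0], [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        region, tie, fc = fold_change_vs_rest(stats, "p0")
        assert region is Region.FL and tie
        assert fc == pytest.approx(1.0)

    def test_single_region_not_computable(self):
        ann = _two_region_design()
        matrix = _log2_matrix([3.0, 4.0, np.nan, np.nan], [a.sample_id for a in ann])
        stats = region_stats(matrix, ann)
        with pytest.raises(ValidationError, match="<2 regions"):
            fold_change_vs_rest(stats, "p0")


def _noise_free_params(**kwargs):
    base = dict(
        n_proteins=120,
        markers_per_region=2,
        log2_effect=2.0,
        donor_sd=0.0,
        resid_sd=0.0,
        depth_spread=0.0,
        mcar_rate=0.0,
        mnar_scale=0.0,
        mnar_mid=-1e9,
        n_absent_cells=0,
        seed=17,
    )
    base.update(kwargs)
    return GeneratorParams(**base)


class TestCalling:
    def test_noise_free_markers_called_exactly(self):
        params = _noise_free_params(resid_sd=1e-6)  # exactly zero residuals are
        # excluded from the correlation pool; keep them infinitesimal instead
        matrix, annotations, truth = generate_proteome_dataset(params)
        result = call_region_specific(normalize(matrix), annotations)
        called = result.table[result.table["call"]]
        expected = truth.marker_region_sets()
        assert set(called["protein_id"]) == set(expected)
        for row in called.itertuples():
            assert str(row.max_region) in expected[row.protein_id]
            # ppm renormalization perturbs the raw 4x slightly because
            # markers shift their regions' total signal
            assert row.fc_vs_rest == pytest.approx(4.0, rel=0.15)

    def test_calls_anti_monotone_in_thresholds(self):
        params = GeneratorParams(n_proteins=400, markers_per_region=5, seed=19)
        matrix, annotations, _ = generate_proteome_dataset(params)
        log2 = normalize(matrix)
        base = set(call_region_specific(log2, annotations).calls["protein_id"])
        for config in (
            AnalysisConfig(fc_threshold=2.5),
            AnalysisConfig(alpha=0.001),
        ):
            stricter = set(call_region_specific(log2, annotations, config).calls["protein_id"])
            assert stricter <= base

    def test_oneway_blocking_skips_consensus(self):
        params = GeneratorParams(n_proteins=100, markers_per_region=2, seed=23)
        matrix, annotations, _ = generate_proteome_dataset(params)
        result = call_region_specific(
            normalize(matrix), annotations, AnalysisConfig(blocking="oneway")
        )
        assert result.consensus is None and result.rho == 0.0

    def test_p_adj_dominates_p(self):
        params = GeneratorParams(n_proteins=300, markers_per_region=0, seed=29)
        matrix, annotations, _ = generate_proteome_dataset(params)
        table = call_region_specific(normalize(matrix), annotations).table
        testable = table[table["testable"]]
        assert (testable["p_adj"] >= testable["p"] - 1e-15).all()
        assert (testable["p_adj"] <= 1.0).all()


class TestTopK:
    def _result_table(self):
        return pd.DataFrame(
            {
                "protein_id": ["a", "b", "c", "d"],
                "max_region": pd.array(["FL", "FL", "FL", "CB"], dtype="string"),
                "fc_vs_rest": [2.0, 3.0, 2.0, 5.0],
                "call": [True, True, True, False],
            }
        )

    def test_truncation_and_tie_order(self):
        top = top_k_per_region(self._result_table(), k=13)
        fl = top[top["region"] == "FL"]
        assert list(fl["protein_id"]) == ["b", "a", "c"]  # fc desc, id asc on ties
        assert len(top[top["region"] == "CB"]) == 0  # not called

    def test_k_truncates(self):
        top = top_k_per_region(self._result_table(), k=2)
        assert list(top[top["region"] == "FL"]["protein_id"]) == ["b", "a"]

    def test_planted_effect_ordering(self):
        """Markers with effects 3 > 2 > 1 appear in that fold-change order."""
        params = _noise_free_params(
            n_proteins=60, markers_per_region=0, resid_sd=1e-6, seed=31
        )
        matrix, annotations, _ = generate_proteome_dataset(params)
        log2 = normalize(matrix)
        values = log2.values.copy()
        fl = [a.sample_id for a in annotations if a.region is Region.FL]
        for pid, effect in zip(["P00001", "P00002", "P00003"], [1.0, 3.0, 2.0]):
            values.loc[pid, fl] += effect
        bumped = AbundanceMatrix(values=values, stage="log2ppm")
        result = call_region_specific(bumped, annotations)
        top = top_k_per_region(result.table, k=13)
        fl_rank = list(top[top["region"] == "FL"]["protein_id"])
        assert fl_rank[:3] == ["P00002", "P00003", "P00001"]


class TestLobeSignature:
    def test_four_lobe_protein_included_three_lobe_excluded(self):
        params = _noise_free_params(n_proteins=80, markers_per_region=0, resid_sd=1e-6)
        matrix, annotations, _ = generate_proteome_dataset(params)
        log2 = normalize(matrix)
        values = log2.values.copy()
        lobes4 = [a.sample_id for a in annotations if a.region.value in
                  {"FL", "TL", "PL", "OL"}]
        lobes3 = [a.sample_id for a in annotations if a.region.value in
                  {"FL", "TL", "PL"}]
        values.loc["P00001", lobes4] += 2.0
        values.loc["P00002", lobes3] += 2.0
        bumped = AbundanceMatrix(values=values, stage="log2ppm")
        sig = lobe_shared_signature(bumped, annotations)
        assert "P00001" in set(sig["protein_id"])
        assert "P00002" not in set(sig["protein_id"])

    def test_recovery_of_planted_four_lobe_proteins(self):
        params = GeneratorParams(
            n_proteins=2000,
            markers_per_region=20,
            log2_effect=2.0,
            resid_sd=0.5,
            donor_sd=0.3,
            mcar_rate=0.10,
            mnar_mid=3.5,
            region_groups=((Region.FL, Region.TL, Region.PL, Region.OL),),
            seed=37,
        )
        matrix, annotations, truth = generate_proteome_dataset(params)
        sig = lobe_shared_signature(normalize(matrix), annotations)
        planted = set(truth.marker_ids)
        found = set(sig["protein_id"])
        assert planted <= found
        assert len(found - planted) <= 1
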