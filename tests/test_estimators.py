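import numpy as np
import pytest

from empoweranc import estimators as est
from empoweranc.nuisance import estimate_nuisances
from empoweranc.pipeline import ANALYSIS_COVARIATES, derive_analysis_table, impute_median_with_indicators

# hand-computed standardized stratum means for the 18-row toy cohort:
# P(W=0) = 1/2; stratum means (low, medium, high) are (1/3, 2/3, 1) at W=0
# and (0, 1/3, 2/3) at W=1
HAND_PSI = {"low": 1 / 6, "medium": 1 / 2, "high": 5 / 6}


@pytest.fixture()
def toy_parts(toy):
    X = toy[["w"]].to_numpy()
    return X, toy["exposure"].to_numpy(), toy["y"].to_numpy().astype(float), toy[
        "village_id"
    ].to_numpy()


class TestTmleOnToyCohort:
    def test_saturated_nuisances_reproduce_hand_standardization(self, toy_parts):
        X, a, y, vil = toy_parts
        nuis = est.saturated_nuisances(X, a, y)
        means = est.tmle_counterfactual_means(a, y, nuis)
        for lvl, psi in HAND_PSI.items():
            assert means.psi[lvl] == pytest.approx(psi, abs=1e-9)

    def test_correct_qbar_means_no_fluctuation(self, toy_parts):
        X, a, y, vil = toy_parts
        nuis = est.saturated_nuisances(X, a, y)
        means = est.tmle_counterfactual_means(a, y, nuis)
        plug_in = {lvl: float(np.mean(nuis.qbar[lvl])) for lvl in HAND_PSI}
        for lvl in HAND_PSI:
            assert abs(means.epsilon[lvl]) < 1e-6
            assert means.psi[lvl] == pytest.approx(plug_in[lvl], abs=1e-9)

    def test_stratum_means_match_hand_table(self):
        # 12-row table, one binary covariate: medians checked by hand
        w = np.repeat([0, 1], 6)
        a = np.tile(np.repeat(["low", "medium", "high"], 2), 2)
        y = np.array([0, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1], dtype=float)
        nuis = est.saturated_nuisances(w.reshape(-1, 1), a, y)
        # W=0: low (0,1)->.5, med (1,1)->1, high (0,0)->0
        # W=1: low (0,0)->0, med (1,0)->.5, high (1,1)->1
        np.testing.assert_allclose(nuis.qbar["low"][:6], 0.5)
        np.testing.assert_allclose(nuis.qbar["medium"][:6], 1 - 1e-12)
        np.testing.assert_allclose(nuis.qbar["high"][6:], 1 - 1e-12)
        np.testing.assert_allclose(nuis.qbar["medium"][6:], 0.5)

    def test_zero_outcome_gives_zero_estimates(self, toy):
        t = toy.copy()
        t["y"] = 0
        X, a, y = t[["w"]].to_numpy(), t["exposure"].to_numpy(), t["y"].to_numpy().astype(float)
        nuis = est.saturated_nuisances(X, a, y)
        ates = est.tmle_pairwise_ates(a, y, nuis, t["village_id"].to_numpy())
        for e in ates.values():
            assert e.psi == 0.0 and e.se == 0.0


class TestTmleOnGeneratedCohort:
    @pytest.fixture(scope="class")
    def analysis(self, cohort2000):
        table = derive_analysis_table(cohort2000.records)
        table, _ = impute_median_with_indicators(table, list(ANALYSIS_COVARIATES))
        spec = est.OUTCOME_SPECS["ge4_vs_1to3"]
        sub = table.loc[spec.subsample_mask(table["anc_visits"].to_numpy())]
        X = sub[list(ANALYSIS_COVARIATES)].to_numpy()
        a = sub["cat_aggregate"].to_numpy()
        y = spec.outcome(sub["anc_visits"].to_numpy())
        nuis = estimate_nuisances(
            X, a, y, outcome_library=("logistic",),
            propensity_library=("logistic",), n_folds=3, seed=0,
        )
        return a, y, nuis, sub["village_id"].to_numpy()

    def test_mean_eic_is_solved_to_numerical_zero(self, analysis):
        a, y, nuis, vil = analysis
        means = est.tmle_counterfactual_means(a, y, nuis)
        for lvl in ("low", "medium", "high"):
            assert abs(np.mean(means.eic[lvl])) < 1e-8

    def test_pairwise_ates_telescope(self, analysis):
        a, y, nuis, vil = analysis
        ates = est.tmle_pairwise_ates(a, y, nuis, vil)
        assert ates[("high", "low")].psi == pytest.approx(
            ates[("high", "medium")].psi + ates[("medium", "low")].psi, abs=1e-12
        )

    def test_estimate_structure(self, analysis):
        a, y, nuis, vil = analysis
        ates = est.tmle_pairwise_ates(a, y, nuis, vil)
        for e in ates.values():
            assert e.ci_lower <= e.psi <= e.ci_upper
            assert e.ci_upper - e.psi == pytest.approx(1.96 * e.se, abs=1e-12)
            assert -1.0 <= e.psi <= 1.0
            assert e.n_used == len(y)
            assert e.n_clusters == len(np.unique(vil))

    def test_count_outcome_backtransform_scales_linearly(self, toy_parts):
        X, a, y, vil = toy_parts
        nuis_bin = est.saturated_nuisances(X, a, y)
        bin_ates = est.tmle_pairwise_ates(a, y, nuis_bin, vil)
        y5 = y * 5.0
        y5_scaled, _ = est.scale_count(y5)
        nuis5 = est.saturated_nuisances(X, a, y5_scaled)
        count_ates = est.tmle_pairwise_ates(a, y5, nuis5, vil, outcome_kind="count")
        for cmp in bin_ates:
            assert count_ates[cmp].psi == pytest.approx(5 * bin_ates[cmp].psi, abs=1e-8)
            assert count_ates[cmp].se == pytest.approx(5 * bin_ates[cmp].se, abs=1e-8)


class TestClusterVariance:
    def test_singleton_clusters_reduce_to_unclustered_se(self):
        rng = np.random.default_rng(8)
        eic = rng.normal(0, 1, 50)
        se_clustered = est.cluster_variance(eic, np.arange(50))
        se_unclustered = np.sqrt(np.sum(eic**2)) / 50
        assert se_clustered == se_unclustered

    def test_three_cluster_hand_computation(self):
        eic = np.array([1.0, 2.0, -1.0, 0.5, -0.5, 3.0])
        clusters = np.array(["a", "a", "b", "b", "c", "c"])
        # cluster sums: 3.0, -0.5, 2.5 -> sqrt(9 + 0.25 + 6.25) / 6
        assert est.cluster_variance(eic, clusters) == pytest.approx(
            np.sqrt(15.5) / 6, abs=1e-15
        )

    def test_duplicating_clusters_scales_as_formula_dictates(self):
        eic = np.array([1.0, 2.0, -1.0, 0.5, -0.5, 3.0])
        clusters = np.array(["a", "a", "b", "b", "c", "c"])
        se1 = est.cluster_variance(eic, clusters)
        eic2 = np.concatenate([eic, eic])
        clusters2 = np.concatenate([clusters, np.char.add(clusters, "2")])
        # doubled n with duplicated cluster sums: sqrt(2 S) / (2n)
        assert est.cluster_variance(eic2, clusters2) == pytest.approx(
            se1 / np.sqrt(2), abs=1e-15
        )

    def test_zero_eic_gives_zero_se(self):
        assert est.cluster_variance(np.zeros(10), np.arange(10) % 3) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            est.cluster_variance(np.ones(5), np.zeros(5))


class TestGcomp:
    def test_saturated_gcomp_matches_hand_standardization(self, toy_parts):
        X, a, y, vil = toy_parts
        for a1, a0 in est.CANONICAL_COMPARISONS:
            gc = est.gcomp_ate(
                X, a, y, (a1, a0), vil, model="saturated", n_boot=50, seed=1
            )
            assert gc.psi == pytest.approx(HAND_PSI[a1] - HAND_PSI[a0], abs=1e-9)

    def test_identical_levels_give_degenerate_zero(self, toy_parts):
        X, a, y, vil = toy_parts
        gc = est.gcomp_ate(X, a, y, ("high", "high"), vil, n_boot=50, seed=1)
        assert gc.psi == 0.0 and gc.ci_lower == 0.0 and gc.ci_upper == 0.0

    def test_main_terms_gcomp_telescopes_exactly(self, toy_parts):
        X, a, y, vil = toy_parts
        psis = {
            cmp: est.gcomp_ate(X, a, y, cmp, vil, n_boot=0, seed=0).psi
            for cmp in est.CANONICAL_COMPARISONS
        }
        assert psis[("high", "low")] == pytest.approx(
            psis[("high", "medium")] + psis[("medium", "low")], abs=1e-12
        )
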