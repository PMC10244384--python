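"""Exposure-gated logistic avidity classifier, feature search, CV, enrichment."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import tcravidity as tv
from tcravidity.classifier import build_feature_matrix, n_residue_subsets
from tcravidity.simulate import generate_feature_coupled_panel
from conftest import random_cdr3

CANON = tv.FeatureDefinition()  # {R,N,D,G,I,L,F}, exposed_presence, >0.30


def profile(tcr_id, fractions):
    return tv.ExposureProfile(tcr_id=tcr_id, exposed_fraction=np.array(fractions))


class TestBuildFeatures:
    def test_exposed_r_sets_only_first_indicator(self):
        seq = "CASSRAQYTEVWF"  # one R, no other canonical letters... except none
        expo = profile("t", [0.1] * len(seq))
        expo.exposed_fraction[4] = 0.5  # the R
        x = tv.build_features(seq, CANON, expo)
        assert x.tolist() == [1, 0, 0, 0, 0, 0, 0]

    def test_buried_r_below_gate_gives_zeros(self):
        seq = "CASSRAQYTEVWF"
        expo = profile("t", [0.1] * len(seq))
        expo.exposed_fraction[4] = 0.2
        assert tv.build_features(seq, CANON, expo).sum() == 0

    def test_gate_is_strict_at_thirty_percent(self):
        seq = "CASSRAQYTEVWF"
        expo = profile("t", [0.0] * len(seq))
        expo.exposed_fraction[4] = 0.30  # exactly at the gate: NOT exposed
        assert tv.build_features(seq, CANON, expo)[0] == 0.0
        expo.exposed_fraction[4] = 0.30 + 1e-9
        assert tv.build_features(seq, CANON, expo)[0] == 1.0

    def test_frequency_of_homopolymer_is_one(self):
        fdef = tv.FeatureDefinition(residues=("N",), encoding="frequency")
        assert tv.build_features("NNNNNNNNNNN", fdef)[0] == pytest.approx(1.0)

    def test_exposed_presence_requires_aligned_profile(self):
        with pytest.raises(ValueError, match="requires an exposure profile"):
            tv.build_features("CASSRAQYTEVWF", CANON, None)
        with pytest.raises(ValueError, match="length"):
            tv.build_features("CASSRAQYTEVWF", CANON, profile("t", [0.5] * 4))

    def test_exposure_gating_only_switches_ones_to_zeros(self, rng):
        presence = tv.FeatureDefinition(residues=CANON.residues, encoding="presence")
        for _ in range(20):
            seq = random_cdr3(rng, int(rng.integers(11, 20)))
            expo = profile("t", rng.random(len(seq)))
            gated = tv.build_features(seq, CANON, expo)
            full = tv.build_features(seq, presence)
            assert np.all(gated <= full)


class TestLogisticFit:
    def test_log_odds_algebra(self, rng):
        X = rng.random((30, 7))
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        res = tv.AvidityLogisticModel(X, y).fit()
        p = res.predict_proba(X)
        linear = res.b0 + X @ res.weights
        assert np.allclose(np.log(p / (1 - p)), linear, atol=1e-10)

    def test_intercept_only_predicts_prevalence(self):
        X = np.zeros((40, 3))
        y = np.array([1] * 10 + [0] * 30)
        res = tv.AvidityLogisticModel(X, y).fit()
        assert np.allclose(res.predict_proba(X), 0.25, atol=1e-6)

    def test_threshold_strictly_greater_than_half(self):
        X = np.zeros((20, 2))
        y = np.array([1, 0] * 10)
        res = tv.AvidityLogisticModel(X, y).fit()
        assert np.allclose(res.predict_proba(X), 0.5, atol=1e-9)
        assert np.all(res.predict_label(X) == 0)  # p == 0.5 is called low

    def test_monotone_in_positively_weighted_feature(self, rng):
        X = rng.random((60, 2))
        y = (X[:, 0] + 0.1 * rng.standard_normal(60) > 0.5).astype(int)
        res = tv.AvidityLogisticModel(X, y).fit()
        assert res.weights[0] > 0
        grid = np.stack([np.linspace(0, 1, 9), np.full(9, 0.5)], axis=1)
        p = res.predict_proba(grid)
        assert np.all(np.diff(p) > 0)

    def test_matches_sklearn_on_nonseparable_data(self, rng):
        X = rng.standard_normal((200, 4))
        logits = 0.5 * X[:, 0] - 0.8 * X[:, 2]
        y = (rng.random(200) < 1 / (1 + np.exp(-logits))).astype(int)
        mine = tv.AvidityLogisticModel(X, y).fit(ridge=1e-6)
        # sklearn minimises sum(loss) + (1/(2C))||w||^2 with unpenalised bias
        skl = LogisticRegression(C=1e6, tol=1e-12, max_iter=10_000).fit(X, y)
        assert np.allclose(mine.weights, skl.coef_[0], atol=1e-5)
        assert mine.b0 == pytest.approx(skl.intercept_[0], abs=1e-5)

    def test_separable_data_finite_and_flagged(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        res = tv.AvidityLogisticModel(X, y).fit()
        assert np.all(np.isfinite(res.params))
        assert res.separable

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both avidity classes"):
            tv.AvidityLogisticModel(np.zeros((5, 2)), np.ones(5))

    def test_planted_weights_recovered_within_three_se(self):
        panel, exps = tv.generate_panel(
            tv.PanelSpec(n_tcrs=2000, seed=7, coupled_exposure=True)
        )
        X = build_feature_matrix([c.cdr3b for c in panel], CANON, exps)
        true = np.array([-1.0, 1.5, -0.8, 0.6, -1.2, 2.0, 0.9, -0.5])
        local = np.random.default_rng(99)
        y = (local.random(2000) < 1 / (1 + np.exp(-(true[0] + X @ true[1:])))).astype(int)
        res = tv.AvidityLogisticModel(X, y, CANON).fit()
        assert np.all(np.abs(res.params - true) <= 3 * res.bse)


class TestEvaluate:
    def test_perfect_separation_all_metrics_one(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        res = tv.AvidityLogisticModel(X, y).fit()
        m = tv.evaluate_classifier(res, X, y)
        assert m["auc"] == 1.0 and m["sensitivity"] == 1.0 and m["specificity"] == 1.0
        assert m["fp"] == 0 and m["fn"] == 0

    def test_auc_equals_concordant_pair_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 51))
            X = rng.random((n, 3))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            res = tv.AvidityLogisticModel(X, y).fit()
            scores = res.predict_proba(X)
            pairs = [
                0.5 if scores[i] == scores[j] else float(scores[i] > scores[j])
                for i in np.where(y == 1)[0]
                for j in np.where(y == 0)[0]
            ]
            oracle = float(np.mean(pairs))
            assert tv.evaluate_classifier(res, X, y)["auc"] == pytest.approx(oracle, abs=1e-12)

    def test_auc_invariant_under_monotone_transform_of_features(self, rng):
        # scaling all weights by a positive constant is a strictly increasing
        # transform of the scores and must leave the AUC unchanged
        X = rng.random((40, 2))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = tv.AvidityLogisticModel(X, y).fit()
        base = tv.evaluate_classifier(res, X, y)["auc"]
        res.params = res.params * 3.0
        assert tv.evaluate_classifier(res, X, y)["auc"] == pytest.approx(base)

    def test_label_independent_scores_give_half_auc(self):
        local = np.random.default_rng(5)
        X = local.random((1000, 3))
        y = local.integers(0, 2, 1000)
        res = tv.AvidityLogisticModel(X, local.integers(0, 2, 1000)).fit()
        auc = tv.evaluate_classifier(res, X, y)["auc"]
        assert 0.45 <= auc <= 0.55

    def test_single_class_auc_reported_as_none(self):
        X = np.array([[0.0], [1.0], [0.5]])
        res = tv.AvidityLogisticModel(
            np.array([[0.0], [1.0]]), np.array([0, 1])
        ).fit()
        m = tv.evaluate_classifier(res, X, np.array([1, 1, 1]))
        assert m["auc"] is None


class TestFeatureSearch:
    def test_subset_enumeration_counts(self):
        assert n_residue_subsets((5,)) == 15_504
        assert n_residue_subsets((5, 6, 7, 8)) == 257_754

    def test_search_is_deterministic(self, rng):
        panel, _ = tv.generate_panel(tv.PanelSpec(n_tcrs=40, seed=2))
        cdr3 = [c.cdr3b for c in panel]
        y = [int(c.is_high_avidity) for c in panel]
        a = tv.exhaustive_feature_search(cdr3, y, sizes=(5,), encodings=("presence",), top_k=3)
        b = tv.exhaustive_feature_search(cdr3, y, sizes=(5,), encodings=("presence",), top_k=3)
        assert a.equals(b)

    def test_reports_total_regression_count(self):
        panel, _ = tv.generate_panel(tv.PanelSpec(n_tcrs=30, seed=4))
        out = tv.exhaustive_feature_search(
            [c.cdr3b for c in panel],
            [int(c.is_high_avidity) for c in panel],
            sizes=(5,),
            encodings=("presence", "frequency"),
            top_k=2,
        )
        assert out["n_regressions"].iloc[0] == 2 * 15_504

    def test_recovers_planted_residue_set(self):
        planted = ("E", "H", "K", "Q", "W")
        fdef = tv.FeatureDefinition(residues=planted, encoding="presence")
        hits = 0
        for seed in range(10):
            panel, _ = tv.generate_panel(
                tv.PanelSpec(n_tcrs=200, seed=seed, enrichment_weight=0.0)
            )
            cdr3 = [c.cdr3b for c in panel]
            Xp = build_feature_matrix(cdr3, fdef)
            local = np.random.default_rng(1000 + seed)
            y = (local.random(200) < 1 / (1 + np.exp(-(-3.0 + Xp @ np.full(5, 3.0))))).astype(int)
            ranked = tv.exhaustive_feature_search(
                cdr3, y, sizes=(5,), encodings=("presence",), top_k=1
            )
            hits += set(ranked.iloc[0]["residues"]) == set(planted)
        assert hits >= 9


class TestCrossValidation:
    def _panel(self, seed=0):
        panel, exps = generate_feature_coupled_panel(tv.PanelSpec(seed=seed))
        X = build_feature_matrix([c.cdr3b for c in panel], CANON, exps)
        y = np.array([int(c.is_high_avidity) for c in panel])
        epitopes = [c.pmhc for c in panel]
        return X, y, epitopes

    def test_folds_partition_the_panel(self):
        X, y, epitopes = self._panel()
        for scheme in ("leave20out_random", "leave20out_stratified"):
            folds = tv.cross_validate(X, y, scheme, n_folds=5, reps=2, seed=1)
            for rep, group in folds.groupby("rep"):
                assert group["n_test"].sum() == len(y)
        loeo = tv.cross_validate(X, y, "leave_one_epitope_out", epitopes=epitopes)
        assert loeo["n_test"].sum() == len(y)
        assert set(loeo["epitope"]) == set(epitopes)

    def test_perfectly_separable_panel_full_success(self):
        local = np.random.default_rng(3)
        X = np.vstack([np.zeros((20, 2)), np.ones((20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        folds = tv.cross_validate(X, y, "leave20out_stratified", n_folds=5, seed=0)
        assert tv.overall_success(folds) == 1.0

    def test_shuffled_labels_center_on_majority_prevalence(self):
        X, y, _ = self._panel()
        local = np.random.default_rng(11)
        successes = []
        for _ in range(20):
            shuffled = local.permutation(y)
            folds = tv.cross_validate(X, shuffled, "leave20out_stratified", seed=5)
            successes.append(tv.overall_success(folds))
        prevalence = max(np.mean(y), 1 - np.mean(y))
        assert abs(np.mean(successes) - prevalence) < 0.12

    def test_single_epitope_rejected(self):
        X, y, _ = self._panel()
        with pytest.raises(ValueError, match="two epitopes"):
            tv.cross_validate(X, y, "leave_one_epitope_out", epitopes=["same"] * len(y))

    def test_unknown_scheme_rejected(self):
        X, y, _ = self._panel()
        with pytest.raises(ValueError, match="scheme"):
            tv.cross_validate(X, y, "bootstrap")


class TestCompositionEnrichment:
    def test_identical_compositions_give_unit_pvalues(self):
        seqs = ["CASSLAPGATNEKLFF", "CASSPDRGHEQYF"]
        table = tv.composition_enrichment(seqs, seqs)
        assert np.all(table["p_value"] == 1.0)
        assert np.allclose(table["difference"], 0.0)

    def test_group_swap_flips_signs_keeps_pvalues(self, rng):
        hi = [random_cdr3(rng, 14) for _ in range(15)]
        lo = [random_cdr3(rng, 14) for _ in range(15)]
        a = tv.composition_enrichment(hi, lo).set_index("residue")
        b = tv.composition_enrichment(lo, hi).set_index("residue")
        assert np.allclose(a["difference"], -b.loc[a.index, "difference"])
        assert np.allclose(a["p_value"], b.loc[a.index, "p_value"])

    def test_planted_enrichment_letters_dominate_significant_set(self):
        panel, _ = tv.generate_panel(tv.PanelSpec(n_tcrs=400, seed=11))
        hi = [c.cdr3b for c in panel if c.is_high_avidity]
        lo = [c.cdr3b for c in panel if not c.is_high_avidity]
        table = tv.composition_enrichment(hi, lo)
        enriched = set(
            table[(table["p_bonferroni"] < 0.01) & (table["difference"] > 0)]["residue"]
        )
        assert enriched, "no significantly enriched letters found"
        assert enriched <= set("NEIKTYV")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            tv.composition_enrichment([], ["CASSLAPGATNEKLFF"])
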