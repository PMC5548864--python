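"""Appearance score, MED ranking, individual effects, censored validation."""

import numpy as np
import pytest

from survsig import (Cohort, Hyperparams, RunEnsemble, SignatureResult,
                     SimulationSpec, appearance_score, censored_validation,
                     individual_effect, med_analysis, oracle_predictions,
                     simulate_cohort)
from survsig.errors import SchemaError

H = Hyperparams(C=32.0, gamma=0.1, nu=0.5)


def _run(features, fitness=0.9):
    return SignatureResult(selected_features=list(features), hyperparams=H,
                           fitness=fitness, mae=5.0, per_r_trace={})


class TestAppearanceScore:
    def test_worked_example(self):
        ens = RunEnsemble([_run(["A", "B"]), _run(["A", "C"]), _run(["A", "B"])])
        chosen, scores = appearance_score(ens)
        np.testing.assert_allclose(scores, [5 / 6, 2 / 3, 5 / 6])
        assert chosen is ens.runs[0]  # tie with run 3 broken by index

    def test_identical_runs_score_one(self):
        ens = RunEnsemble([_run(["X", "Y", "Z"])] * 4)
        _, scores = appearance_score(ens)
        np.testing.assert_allclose(scores, 1.0)

    def test_permutation_invariance_of_score_multiset(self):
        runs = [_run(["A", "B"]), _run(["A", "C"]), _run(["B", "C", "D"])]
        _, s1 = appearance_score(RunEnsemble(runs))
        _, s2 = appearance_score(RunEnsemble(runs[::-1]))
        assert sorted(s1) == pytest.approx(sorted(s2))

    def test_score_grows_with_consensus(self):
        # the {A,B} run scores higher in an ensemble where B reappears
        lonely = RunEnsemble([_run(["A", "B"]), _run(["A", "C"]), _run(["A", "D"])])
        crowded = RunEnsemble([_run(["A", "B"]), _run(["A", "B"]), _run(["A", "D"])])
        _, s_lonely = appearance_score(lonely)
        _, s_crowded = appearance_score(crowded)
        assert s_crowded[0] > s_lonely[0]

    def test_empty_ensemble_rejected(self):
        with pytest.raises(SchemaError):
            appearance_score(RunEnsemble([]))


@pytest.fixture(scope="module")
def med_cohort():
    cohort, planted = simulate_cohort(
        SimulationSpec(M=80, n=16, s=3, beta=(8, 6, 4), noise_sd=2, seed=31))
    return cohort, planted


class TestMedAnalysis:
    def test_planted_features_outrank_decoys(self, med_cohort):
        cohort, planted = med_cohort
        decoys = [f for f in cohort.feature_names if f not in planted][:3]
        sig = _run(list(planted) + decoys)
        table = med_analysis(cohort, sig)
        top3 = set(table.head(3)["feature"])
        assert len(top3 & set(planted)) >= 2

    def test_duplicate_features_get_equal_med(self, med_cohort):
        cohort, planted = med_cohort
        # duplicate the strongest planted column under a new name
        j = cohort.feature_index(planted[0])
        dup = Cohort(cohort.sample_ids, cohort.feature_names + ["dup"],
                     np.column_stack([cohort.X, cohort.X[:, j]]),
                     cohort.y, cohort.censored)
        sig = _run([planted[0], "dup", planted[1], planted[2]])
        table = med_analysis(dup, sig).set_index("feature")
        assert table.loc[planted[0], "med"] == pytest.approx(
            table.loc["dup", "med"], abs=1e-9)

    def test_evaluation_budget_is_one_oa(self, med_cohort, monkeypatch):
        import survsig.analysis as analysis
        calls = []
        original = analysis.cross_validate

        def counting(*args, **kwargs):
            calls.append(1)
            return original(*args, **kwargs)

        monkeypatch.setattr(analysis, "cross_validate", counting)
        cohort, planted = med_cohort
        med_analysis(cohort, _run(list(planted)))  # m=3 -> L4
        assert len(calls) <= 4

    def test_too_small_signature_rejected(self, med_cohort):
        cohort, planted = med_cohort
        with pytest.raises(SchemaError):
            med_analysis(cohort, _run([planted[0]]))


class TestIndividualEffect:
    def test_copy_of_y_is_a_perfect_single_feature(self):
        rng = np.random.default_rng(41)
        y = rng.uniform(10, 90, 60)
        cohort = Cohort([f"s{i}" for i in range(60)], ["copy", "noise"],
                        np.column_stack([y, rng.standard_normal(60)]), y)
        cc, mae = individual_effect(cohort, "copy", gene_values=range(0, 16, 3))
        assert cc >= 0.99
        assert mae < 2.0

    def test_pure_noise_feature_has_low_correlation(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.uniform(10, 90, 150)
            cohort = Cohort([f"s{i}" for i in range(150)], ["noise"],
                            rng.standard_normal((150, 1)), y)
            cc, _ = individual_effect(cohort, "noise", gene_values=range(0, 16, 5))
            if abs(cc) < 0.3:
                hits += 1
        assert hits >= 9

    def test_planted_feature_beats_decoys(self, med_cohort):
        cohort, planted = med_cohort
        grid = range(0, 16, 5)
        strongest, _ = individual_effect(cohort, planted[0], gene_values=grid)
        decoys = [f for f in cohort.feature_names if f not in planted][:3]
        for f in decoys:
            cc, _ = individual_effect(cohort, f, gene_values=grid)
            assert strongest > cc


class _ShiftPredictor:
    features = ["fA"]

    def __init__(self, shift):
        self.shift = shift

    def predict(self, cohort):
        return cohort.y + self.shift


class TestCensoredValidation:
    def _censored_cohort(self, followups):
        n = len(followups)
        return Cohort([f"p{i}" for i in range(n)], ["fA"],
                      np.zeros((n, 1)), np.asarray(followups, dtype=float),
                      np.ones(n, dtype=bool))

    def test_predictor_above_followup_gives_fraction_one(self):
        test = self._censored_cohort([12.0, 30.0, 45.0])
        report = censored_validation(_ShiftPredictor(1.0), test)
        assert report.fraction_predicted_above == 1.0

    def test_two_patient_hand_count(self):
        test = self._censored_cohort([10.0, 20.0])

        class Fixed:
            def predict(self, cohort):
                return np.array([15.0, 15.0])

        report = censored_validation(Fixed(), test)
        assert report.fraction_predicted_above == pytest.approx(0.5)
        assert report.follow_up_mean == pytest.approx(15.0)

    def test_oracle_predictor_on_synthetic_censored_cohort(self):
        spec = SimulationSpec(M=200, n=10, s=3, beta=(6, 5, 4), noise_sd=2,
                              censor_fraction=1.0, seed=51)
        cohort, planted = simulate_cohort(spec)

        class Oracle:
            def predict(self, c):
                return oracle_predictions(c, planted, spec.beta, spec.baseline)

        from survsig import filter_test_cohort
        test = filter_test_cohort(cohort)
        report = censored_validation(Oracle(), test)
        assert report.fraction_predicted_above >= 0.9

    def test_uncensored_cohort_rejected(self):
        cohort = Cohort(["a"], ["fA"], np.zeros((1, 1)), np.array([5.0]),
                        np.array([False]))
        with pytest.raises(SchemaError):
            censored_validation(_ShiftPredictor(1.0), cohort)
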