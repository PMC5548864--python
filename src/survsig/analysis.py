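"""Post-selection analyses: robustness, per-feature contribution, validation.

The GA is stochastic, so one run's signature is not authoritative. Three
procedures turn repeated runs and a chosen signature into interpretable
output:

* **Appearance score** — run the selector R times; score each run's feature
  set by the mean across-run selection frequency of its members and keep the
  highest-scoring (most consensual) run.
* **Main effect difference (MED)** — rank the features *within* a signature
  by how much the CV correlation moves when a feature is included versus
  excluded, estimated from an orthogonal-array design instead of all 2^m
  subsets.
* **Individual effect** — how well each feature predicts survival on its
  own, with its own hyperparameter grid search.
* **Censored validation** — apply the trained model to an all-censored
  cohort; because follow-up lower-bounds true survival, predictions above
  follow-up are consistent with the ground truth, and the fraction of such
  patients summarizes the validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import SchemaError, UndefinedCorrelationError
from .ga import GENE_LEVELS, SignatureResult, decode_hyper
from .oa import build_oa, main_effects
from .regression import Hyperparams, cross_validate, fit_nusvr, kfold_indices


@dataclass
class RunEnsemble:
    """R independent selector runs on one cohort (only the GA seed varies)."""

    runs: list[SignatureResult]

    @property
    def R(self) -> int:
        return len(self.runs)


def appearance_score(ensemble: RunEnsemble) -> tuple[SignatureResult, np.ndarray]:
    """Pick the most consensual run of an ensemble.

    The appearance frequency of feature p is f(p) = (#runs containing p)/R;
    the score of run t with features p_1..p_mt is S_t = mean_i f(p_i).
    Returns the run with the highest score (ties broken toward the earliest
    run) and the full score vector. Scores lie in (0, 1].
    """
    if not ensemble.runs:
        raise SchemaError("empty ensemble")
    R = ensemble.R
    freq: dict[str, int] = {}
    for run in ensemble.runs:
        for p in set(run.selected_features):
            freq[p] = freq.get(p, 0) + 1
    scores = np.array([
        np.mean([freq[p] / R for p in run.selected_features])
        for run in ensemble.runs
    ])
    chosen = ensemble.runs[int(np.argmax(scores))]  # argmax takes the first max
    return chosen, scores


def med_analysis(cohort: Cohort, signature: SignatureResult) -> pd.DataFrame:
    """Main-effect-difference ranking of the features in a signature.

    Builds the smallest OA with m columns; for each OA row, the CV
    correlation is evaluated using only the features at level 1 (level 2 =
    excluded), with the signature's hyperparameters and CV partition. Rows
    whose included set is empty score CC = 0 (no predictor). The MED of a
    feature is the absolute difference between its level means.

    Returns a DataFrame with columns ``feature`` and ``med``, sorted by
    descending MED. Exactly N = 2^ceil(log2(m+1)) CV evaluations are made.
    """
    feats = signature.selected_features
    m = len(feats)
    if m < 2:
        raise SchemaError("MED analysis needs a signature with at least 2 features")
    idx = np.array([cohort.feature_index(f) for f in feats])
    folds = kfold_indices(cohort.M, 10, signature.cv_seed)
    oa = build_oa(m)
    responses = np.empty(oa.N)
    for i, row in enumerate(oa.levels):
        sel = idx[row == 1]
        if len(sel) == 0:
            responses[i] = 0.0
            continue
        try:
            responses[i] = cross_validate(cohort.X[:, sel], cohort.y,
                                          signature.hyperparams, folds=folds).cc
        except UndefinedCorrelationError:
            responses[i] = 0.0
    effects = main_effects(oa, responses)
    table = pd.DataFrame({"feature": feats, "med": effects.med})
    return table.sort_values("med", ascending=False, kind="stable").reset_index(drop=True)


def individual_effect(cohort: Cohort, feature: str, cv_seed: int = 0,
                      gene_values=range(GENE_LEVELS)) -> tuple[float, float]:
    """Best single-feature CV performance of ``feature``.

    Grid-searches the decoded (gamma, C, nu) hyperparameter grid — by
    default all 16^3 gene combinations — for the single-feature nu-SVR
    maximizing CV correlation; returns that CC and its MAE in months.
    ``gene_values`` can be coarsened (e.g. ``range(0, 16, 5)``) when the
    full grid is not needed.
    """
    j = cohort.feature_index(feature)
    col = cohort.X[:, [j]]
    if np.ptp(col) == 0:
        raise UndefinedCorrelationError(f"feature {feature!r} is constant")
    folds = kfold_indices(cohort.M, 10, cv_seed)
    best = (-np.inf, np.inf)
    for genes in itertools.product(gene_values, repeat=3):
        try:
            res = cross_validate(col, cohort.y, decode_hyper(genes), folds=folds)
        except UndefinedCorrelationError:
            continue
        if res.cc > best[0]:
            best = (res.cc, res.mae)
    return best


def effect_table(cohort: Cohort, signature: SignatureResult,
                 gene_values=range(GENE_LEVELS)) -> pd.DataFrame:
    """Combined contribution table: MED rank plus individual CC/MAE per feature."""
    table = med_analysis(cohort, signature)
    singles = [individual_effect(cohort, f, signature.cv_seed, gene_values)
               for f in table["feature"]]
    table["single_cc"] = [s[0] for s in singles]
    table["single_mae"] = [s[1] for s in singles]
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


@dataclass
class TrainedPredictor:
    """Final nu-SVR trained on the full training cohort's selected features."""

    features: list[str]
    hyperparams: Hyperparams
    _model: object

    def predict(self, cohort: Cohort) -> np.ndarray:
        missing = [f for f in self.features if f not in cohort.feature_names]
        if missing:
            raise SchemaError(f"cohort lacks model features: {missing}")
        idx = [cohort.feature_index(f) for f in self.features]
        return np.asarray(self._model.predict(cohort.X[:, idx]))


def fit_final_model(cohort: Cohort, signature: SignatureResult) -> TrainedPredictor:
    """Train the signature's nu-SVR on the full (training) cohort."""
    idx = [cohort.feature_index(f) for f in signature.selected_features]
    model = fit_nusvr(cohort.X[:, idx], cohort.y, signature.hyperparams)
    return TrainedPredictor(features=list(signature.selected_features),
                            hyperparams=signature.hyperparams, _model=model)


@dataclass
class ValidationReport:
    """Censored-cohort validation summary (the per-patient table plus moments)."""

    table: pd.DataFrame  # columns: sample_id, follow_up, predicted
    fraction_predicted_above: float
    follow_up_mean: float
    follow_up_sd: float
    predicted_mean: float
    predicted_sd: float


def censored_validation(model, test: Cohort) -> ValidationReport:
    """Validate a trained predictor on an all-censored cohort.

    Every test patient is alive, so follow-up time is a lower bound on true
    survival: a prediction above follow-up is consistent with the ground
    truth. Reports per-patient (follow-up, prediction), the fraction of
    patients with prediction > follow-up, and mean +/- SD of both quantities
    in months.
    """
    if not np.all(test.censored):
        raise SchemaError("test cohort must be all-censored (alive patients)")
    pred = np.asarray(model.predict(test))
    table = pd.DataFrame({"sample_id": test.sample_ids,
                          "follow_up": test.y, "predicted": pred})
    return ValidationReport(
        table=table,
        fraction_predicted_above=float(np.mean(pred > test.y)),
        follow_up_mean=float(test.y.mean()),
        follow_up_sd=float(test.y.std(ddof=1)) if test.M > 1 else 0.0,
        predicted_mean=float(pred.mean()),
        predicted_sd=float(pred.std(ddof=1)) if test.M > 1 else 0.0,
    )


def run_ensemble(cohort: Cohort, cfg, R: int = 30, seed: int = 0):
    """Run R independent GA selections (GA seed varies, CV partition fixed).

    Returns the :class:`RunEnsemble`. Seeds for the runs are drawn
    deterministically from ``seed``.
    """
    from dataclasses import replace

    from .ga import run_ibcga

    if R < 1:
        raise SchemaError("R must be >= 1")
    seeds = np.random.default_rng(seed).integers(2**31 - 1, size=R)
    runs = [run_ibcga(cohort, replace(cfg, ga_seed=int(s))) for s in seeds]
    return RunEnsemble(runs=runs)
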