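"""Model/Results facade over the selection pipeline.

``SurvivalSignatureModel`` is built from a training cohort; ``fit()`` runs
the GA selector (optionally as a consensus ensemble) and returns a
``SurvivalSignatureResults`` carrying the signature, decoded
hyperparameters, CV performance, per-size trace and (for ensembles) the
appearance scores — with ``summary()``, per-feature contribution tables,
censored-cohort validation and prediction hanging off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (RunEnsemble, ValidationReport, appearance_score,
                       censored_validation, effect_table, fit_final_model,
                       med_analysis, run_ensemble)
from .cohort import Cohort, filter_training_cohort, read_cohort
from .ga import GAConfig, SignatureResult, run_ibcga


class SurvivalSignatureModel:
    """Survival-time regression with GA-driven feature selection.

    Parameters
    ----------
    cohort : Cohort
        Training cohort (uncensored samples; apply
        :func:`survsig.cohort.filter_training_cohort` first if needed —
        ``prefiltered=False`` does it for you).
    """

    def __init__(self, cohort: Cohort, prefiltered: bool = True):
        self.cohort = cohort if prefiltered else filter_training_cohort(cohort)

    @classmethod
    def from_files(cls, expression_path, clinical_path) -> "SurvivalSignatureModel":
        """Read the TSV pair and apply the training filter."""
        return cls(read_cohort(expression_path, clinical_path), prefiltered=False)

    @classmethod
    def from_dataframe(cls, expression: pd.DataFrame, survival_months,
                       censored=None) -> "SurvivalSignatureModel":
        """Build from an (samples x features) expression frame and a survival vector."""
        cohort = Cohort(
            sample_ids=[str(s) for s in expression.index],
            feature_names=[str(c) for c in expression.columns],
            X=expression.to_numpy(dtype=float),
            y=np.asarray(survival_months, dtype=float),
            censored=censored,
        )
        return cls(cohort, prefiltered=False)

    def fit(self, config: GAConfig | None = None, n_runs: int = 1,
            ensemble_seed: int = 0) -> "SurvivalSignatureResults":
        """Run the selector; with ``n_runs > 1``, pick the consensus run.

        ``n_runs`` independent GA runs (sharing the CV partition, differing
        in GA seed) are scored by appearance frequency and the most
        consensual signature is returned.
        """
        cfg = config or GAConfig()
        if n_runs == 1:
            chosen = run_ibcga(self.cohort, cfg)
            ensemble, scores = None, None
        else:
            ensemble = run_ensemble(self.cohort, cfg, R=n_runs, seed=ensemble_seed)
            chosen, scores = appearance_score(ensemble)
        return SurvivalSignatureResults(self, cfg, chosen, ensemble, scores)


class SurvivalSignatureResults:
    """Fitted results: signature, hyperparameters, CV metrics, diagnostics."""

    def __init__(self, model: SurvivalSignatureModel, config: GAConfig,
                 signature: SignatureResult,
                 ensemble: RunEnsemble | None = None,
                 appearance_scores: np.ndarray | None = None):
        self.model = model
        self.config = config
        self.signature = signature
        self.ensemble = ensemble
        self.appearance_scores = appearance_scores
        self._predictor = None

    # -- headline quantities ---------------------------------------------

    @property
    def selected_features(self) -> list[str]:
        return self.signature.selected_features

    @property
    def cc(self) -> float:
        """CV Pearson correlation between real and estimated survival time."""
        return self.signature.fitness

    @property
    def mae_months(self) -> float:
        return self.signature.mae

    @property
    def hyperparams(self):
        return self.signature.hyperparams

    @property
    def top_appearance_score(self) -> float | None:
        if self.appearance_scores is None:
            return None
        return float(np.max(self.appearance_scores))

    # -- diagnostics ------------------------------------------------------

    def med_table(self) -> pd.DataFrame:
        """Main-effect-difference ranking of the signature's features."""
        return med_analysis(self.model.cohort, self.signature)

    def effect_table(self, gene_values=None) -> pd.DataFrame:
        """MED ranking plus best single-feature CC/MAE per signature feature."""
        kwargs = {} if gene_values is None else {"gene_values": gene_values}
        return effect_table(self.model.cohort, self.signature, **kwargs)

    def predictor(self):
        if self._predictor is None:
            self._predictor = fit_final_model(self.model.cohort, self.signature)
        return self._predictor

    def predict(self, cohort: Cohort) -> np.ndarray:
        """Predicted survival time (months) for a cohort carrying the signature features."""
        return self.predictor().predict(cohort)

    def validate(self, test: Cohort) -> ValidationReport:
        """Censored-cohort validation of the final model."""
        return censored_validation(self.predictor(), test)

    def plot_fit(self, ax=None):
        """Scatter of real vs CV-estimated survival time (months)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.signature
        idx = [self.model.cohort.feature_index(f) for f in sig.selected_features]
        from .regression import cross_validate, kfold_indices

        folds = kfold_indices(self.model.cohort.M, self.config.k_folds, sig.cv_seed)
        res = cross_validate(self.model.cohort.X[:, idx], self.model.cohort.y,
                             sig.hyperparams, folds=folds)
        ax.scatter(self.model.cohort.y, res.per_sample_pred, s=12)
        lim = [0, max(self.model.cohort.y.max(), res.per_sample_pred.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("real survival time (months)")
        ax.set_ylabel("estimated survival time (months)")
        ax.set_title(f"CC = {res.cc:.2f}, MAE = {res.mae:.1f} months")
        return ax

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        sig = self.signature
        h = sig.hyperparams
        lines = [
            "Survival signature selection results",
            "=" * 52,
            f"{'Samples':<28}{self.model.cohort.M:>24}",
            f"{'Candidate features':<28}{self.model.cohort.n:>24}",
            f"{'Signature size':<28}{sig.m:>24}",
            f"{'CV Pearson CC':<28}{sig.fitness:>24.4f}",
            f"{'CV MAE (months)':<28}{sig.mae:>24.2f}",
            f"{'CV MAE (years)':<28}{sig.mae / 12:>24.2f}",
            f"{'nu-SVR C':<28}{h.C:>24.4g}",
            f"{'nu-SVR gamma':<28}{h.gamma:>24.4g}",
            f"{'nu-SVR nu':<28}{h.nu:>24.4g}",
        ]
        if self.appearance_scores is not None:
            lines.append(f"{'Ensemble runs':<28}{self.ensemble.R:>24}")
            lines.append(f"{'Top appearance score':<28}{self.top_appearance_score:>24.3f}")
        lines.append("-" * 52)
        lines.append("Selected features (sweep best, ties -> smallest size):")
        for f in sig.selected_features:
            lines.append(f"  {f}")
        return "\n".join(lines)
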