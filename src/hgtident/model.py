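"""Model/Results front end: ``HgtDetector`` and ``HgtResults``.

This is the primary user-facing API.  Build a detector from a labeled
dataset (or directly from a genome bundle / feature table), call
``fit()``, and read the cross-validated Recall and Mean error, per-fold
confusion counts and chosen hyper-parameters off the results object:

    >>> from hgtident import HgtDetector, synthetic
    >>> bundle = synthetic.generate(synthetic.SyntheticSpec(seed=7))
    >>> res = HgtDetector.from_bundle(bundle, seed=7).fit()
    >>> print(res.summary())          # doctest: +SKIP

``fit()`` also trains a final model on the complete dataset at the
hyper-parameters selected on it, for labeling new genes via
``res.predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .classifier import SvmConfig, TrainedModel, apply_scaler, fit_scaler, grid_search, predict
from .dataset import FEATURE_NAMES, N_FEATURES, LabeledDataset
from .features import extract_features
from .ga_select import GaConfig, run_ga
from .imbalance import SmoteConfig, smote
from .metrics import round_half_up
from .pipeline import ExperimentConfig, ExperimentResult, run_experiment
from .seqio import GenomeBundle, read_feature_table


@dataclass
class HgtDetector:
    """A horizontally-transferred-gene detector specification bound to data.

    Parameters
    ----------
    dataset
        Feature matrix + binary labels (1 = HGT).
    feature_mode
        ``"all_features"`` or ``"ga_selected"`` (GA wrapper selection on
        the training folds).
    use_smote
        Oversample the minority class of each training fold to parity.
    n_folds, seed
        Outer CV granularity and the master seed for every stage.
    """

    dataset: LabeledDataset
    feature_mode: str = "all_features"
    use_smote: bool = True
    n_folds: int = 5
    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)
    ga: GaConfig = field(default_factory=GaConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)

    @classmethod
    def from_bundle(cls, bundle: GenomeBundle, **kwargs) -> "HgtDetector":
        return cls(dataset=extract_features(bundle), **kwargs)

    @classmethod
    def from_feature_table(cls, path, **kwargs) -> "HgtDetector":
        return cls(dataset=read_feature_table(path), **kwargs)

    def _config(self) -> ExperimentConfig:
        return ExperimentConfig(
            feature_mode=self.feature_mode,
            use_smote=self.use_smote,
            n_folds=self.n_folds,
            seed=self.seed,
            svm=self.svm,
            ga=self.ga,
            smote=self.smote,
        )

    def fit(self) -> "HgtResults":
        """Cross-validate, then train the final model on the complete dataset."""
        experiment = run_experiment(self.dataset, self._config())
        if experiment.global_mask is not None:
            mask = np.array(experiment.global_mask, dtype=bool)
        elif self.feature_mode == "ga_selected":
            # per-fold GA has no single mask; select one on the full dataset
            # for the final deployable model
            best, _ = run_ga(self.dataset, self.ga, self.svm)
            mask = best.mask
        else:
            mask = np.ones(N_FEATURES, dtype=bool)
        scaler = fit_scaler(self.dataset)
        full = apply_scaler(scaler, self.dataset)
        c, g = grid_search(
            full, self.svm, mask=mask, scaled=True,
            oversample=self.smote if self.use_smote else None,
        )
        if self.use_smote:
            full = smote(full, self.smote)
        svc = SVC(C=c, gamma=g, kernel="rbf")
        svc.fit(full.X[:, mask], full.y)
        final = TrainedModel(scaler=scaler, best_c=c, best_g=g, feature_mask=mask, svc=svc)
        return HgtResults(model=self, experiment=experiment, final_model=final)


@dataclass
class HgtResults:
    """Fit results: cross-validated performance plus the final trained SVM."""

    model: HgtDetector
    experiment: ExperimentResult
    final_model: TrainedModel

    @property
    def recall(self) -> float:
        """Macro-averaged cross-validated Recall, percent."""
        return self.experiment.result.recall_pct

    @property
    def mean_error(self) -> float:
        """Macro-averaged cross-validated Mean error (balanced error rate), percent."""
        return self.experiment.result.mean_error_pct

    @property
    def per_fold(self):
        return self.experiment.result.per_fold

    def predict(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        """Labels (1 = HGT) from the final model trained on the full dataset."""
        return predict(self.final_model, data)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "HGT detection results (RBF-SVM, stratified "
            f"{self.model.n_folds}-fold CV)",
            "=" * 58,
            f"genes: {ds.n_genes}   HGT: {ds.n_positive}   native: {ds.n_negative}",
            f"feature mode: {self.model.feature_mode}   "
            f"SMOTE: {'on' if self.model.use_smote else 'off'}   seed: {self.model.seed}",
            "-" * 58,
            f"Recall     : {round_half_up(self.recall):6.2f} %",
            f"Mean error : {round_half_up(self.mean_error):6.2f} %",
            "-" * 58,
            "fold   tp   fp   tn   fn        c          g",
        ]
        for rec in self.experiment.fold_records:
            c = rec.counts
            lines.append(
                f"{rec.fold:>4} {c.tp:>4} {c.fp:>4} {c.tn:>4} {c.fn:>4} "
                f"{rec.best_c:>9.4g} {rec.best_g:>10.4g}"
            )
        sel = np.flatnonzero(self.final_model.feature_mask)
        lines.append("-" * 58)
        lines.append("final model features: " + ", ".join(FEATURE_NAMES[i] for i in sel))
        lines.append(
            f"final model (c, g): ({self.final_model.best_c:g}, {self.final_model.best_g:g})"
        )
        return "\n".join(lines)
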