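"""RBF-SVM classification: (−1, +1) scaling, (c, g) grid search, train, predict.

Model selection follows the standard libsvm recipe: scale each feature
linearly so the training minimum maps to −1 and the maximum to +1, then
evaluate every (c, g) grid point by stratified inner cross-validation and
keep the point with the best Recall (ties: lower Mean error, then smaller
c, then smaller g — the same objective philosophy as the GA fitness,
which maximizes Recall and records Mean error at that optimum).

The scaler is fitted on the training partition only.  The study this
tool reimplements scaled the complete dataset before cross-validation;
that variant is available via ``scale_full_dataset=True`` in the pipeline but
is off by default because it leaks test information into the scaler.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import N_FEATURES, LabeledDataset
from .metrics import ConfusionCounts, aggregate_folds

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_G_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class ScalerParams:
    """Per-feature linear map fitted on training data: min -> -1, max -> +1.

    Constant features map to 0.  Test values outside the training range
    map outside [-1, 1] (no clipping).
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.maxs - self.mins
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = -1.0 + 2.0 * (X[:, nz] - self.mins[nz]) / span[nz]
        return out


def fit_scaler(train: LabeledDataset | np.ndarray) -> ScalerParams:
    X = train.X if isinstance(train, LabeledDataset) else np.asarray(train, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("scaler needs at least 2 rows")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(params: ScalerParams, data: LabeledDataset | np.ndarray):
    if isinstance(data, LabeledDataset):
        return LabeledDataset(
            ids=list(data.ids),
            X=params.transform(data.X),
            y=data.y.copy(),
            mask=data.mask.copy(),
            synthetic=data.synthetic.copy(),
        )
    return params.transform(data)


@dataclass
class SvmConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    g_grid: tuple[float, ...] = DEFAULT_G_GRID
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.g_grid:
            raise ValueError("parameter grids must be non-empty")
        if min(self.c_grid) <= 0 or min(self.g_grid) <= 0:
            raise ValueError("c and g must be positive")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM with its scaler, parameters and feature mask."""

    scaler: ScalerParams
    best_c: float
    best_g: float
    feature_mask: np.ndarray
    svc: SVC = field(repr=False)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _masked(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("feature mask selects no features")
    return X[:, mask]


def grid_search(
    train: LabeledDataset,
    cfg: SvmConfig,
    mask: np.ndarray | None = None,
    scaled: bool = False,
    oversample: "SmoteConfig | None" = None,
) -> tuple[float, float]:
    """Pick (c, g) maximizing inner-CV Recall on the training data.

    The training matrix is scaled once (unless ``scaled=True``) and split
    by stratified ``inner_cv_folds``-fold CV.  When ``oversample`` is
    given, each inner training partition is SMOTE-oversampled while the
    inner validation partition stays imbalanced — oversampling before
    splitting would place interpolants of validation points in the
    training data and distort the selection.  Ties are broken by lower
    Mean error, then smaller c, then smaller g, so the result does not
    depend on grid ordering.  Deterministic given ``cfg.seed``.
    """
    from .imbalance import smote  # local import to avoid a module cycle

    if mask is None:
        mask = train.mask
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes in the training data")
    X = train.X if scaled else fit_scaler(train).transform(train.X)
    scaled_ds = LabeledDataset(
        ids=list(train.ids), X=X, y=y, mask=train.mask, synthetic=train.synthetic
    )
    skf = StratifiedKFold(n_splits=cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
    inner: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for tr_idx, te_idx in skf.split(X, y):
        sub = scaled_ds.subset_rows(tr_idx)
        if oversample is not None:
            sub = smote(sub, oversample)
        inner.append((_masked(sub.X, mask), sub.y, _masked(X[te_idx], mask), y[te_idx]))
    best: tuple[float, float, float, float] | None = None  # (-recall, err, c, g)
    for c in sorted(cfg.c_grid):
        for g in sorted(cfg.g_grid):
            folds = []
            for X_tr, y_tr, X_te, y_te in inner:
                svc = SVC(C=c, gamma=g, kernel="rbf")
                svc.fit(X_tr, y_tr)
                folds.append(ConfusionCounts.from_labels(y_te, svc.predict(X_te)))
            res = aggregate_folds(folds)
            key = (-res.recall_pct, res.mean_error_pct, c, g)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2], best[3]


def train(
    train_data: LabeledDataset,
    c: float,
    g: float,
    mask: np.ndarray | None = None,
    scaler: ScalerParams | None = None,
) -> TrainedModel:
    """Fit the final RBF-SVM on the complete training dataset at (c, g)."""
    if mask is None:
        mask = train_data.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("feature mask selects no features")
    if mask.shape != (N_FEATURES,):
        raise ValueError(f"mask must have length {N_FEATURES}")
    if scaler is None:
        scaler = fit_scaler(train_data)
    X = _masked(scaler.transform(train_data.X), mask)
    svc = SVC(C=c, gamma=g, kernel="rbf")
    svc.fit(X, train_data.y)
    return TrainedModel(scaler=scaler, best_c=c, best_g=g, feature_mask=mask, svc=svc)


def predict(model: TrainedModel, data: LabeledDataset | np.ndarray) -> np.ndarray:
    """Binary labels (1 = HGT) for every row of ``data``."""
    X = data.X if isinstance(data, LabeledDataset) else np.asarray(data, dtype=float)
    X = _masked(model.scaler.transform(X), model.feature_mask)
    return model.svc.predict(X).astype(int)
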