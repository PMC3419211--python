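"""Core in-memory containers shared across the package.

The canonical feature order is frozen here; every matrix, mask and table
in the package uses it.  ``GC1-GC3`` is a single selectable unit (the mean
absolute positional-GC deviation from the genome background), so the full
vector has 15 entries: 8 named signatures plus the seven k-mer deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical feature names, in the order used by every feature matrix.
FEATURE_NAMES: tuple[str, ...] = (
    "Karlin-DN",
    "Karlin-CB",
    "GC1-GC3",
    "Chi2-DN",
    "Chi2-CB",
    "JS-N",
    "JS-DN",
    "JS-CB",
    "1-mer",
    "2-mer",
    "3-mer",
    "4-mer",
    "5-mer",
    "6-mer",
    "7-mer",
)

N_FEATURES = len(FEATURE_NAMES)

#: Label constants for :class:`~hgtident.seqio.GeneRecord`.
HGT = "HGT"
NATIVE = "NATIVE"
UNKNOWN = "UNKNOWN"


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels and gene identifiers.

    Parameters
    ----------
    ids
        Gene identifiers, one per row.
    X
        Feature matrix of shape ``(n_genes, 15)`` in :data:`FEATURE_NAMES`
        order.
    y
        Integer labels: 1 = HGT (positive), 0 = native (negative).
    mask
        Boolean feature mask of length 15; selected features are ``True``.
    synthetic
        Boolean flags marking rows created by oversampling (SMOTE); real
        genes are ``False``.
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, got shape {self.X.shape}"
            )
        if len(self.ids) != self.X.shape[0] or self.y.shape[0] != self.X.shape[0]:
            raise ValueError("ids, X and y must have matching lengths")
        if self.mask is None:
            self.mask = np.ones(N_FEATURES, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.ids), dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())

    def subset_rows(self, index: np.ndarray) -> "LabeledDataset":
        """Return a row-subset dataset (mask is carried over unchanged)."""
        index = np.asarray(index)
        return LabeledDataset(
            ids=[self.ids[i] for i in np.arange(self.n_genes)[index]]
            if index.dtype == bool
            else [self.ids[i] for i in index],
            X=self.X[index],
            y=self.y[index],
            mask=self.mask.copy(),
            synthetic=self.synthetic[index],
        )
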