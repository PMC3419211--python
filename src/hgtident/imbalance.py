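"""SMOTE: synthetic minority oversampling by neighbor interpolation.

HGT genes are a small minority of any genome, and classifiers trained on
the raw class ratio under-detect them.  SMOTE creates synthetic minority
rows ``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ Uniform[0, 1]`` and
``x_nn`` one of the ``k`` nearest minority neighbors of ``x_i``
(Euclidean distance).  Only the training partition of a CV fold is ever
oversampled; test partitions stay imbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import LabeledDataset


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority after oversampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be positive")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


def smote(dataset: LabeledDataset, cfg: SmoteConfig) -> LabeledDataset:
    """Oversample the minority class up to ``cfg.target_ratio``.

    Original rows pass through bit-identical and first; synthetic rows are
    appended with ids ``smote_<i>`` and ``synthetic=True``.  Deterministic
    given ``cfg.seed``.  Neighbor ties are broken by row index; u = 0 and
    u = 1 are both allowed (endpoints of the parent-neighbor segment).
    """
    y = dataset.y
    n_pos = int(y.sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("SMOTE needs both classes present")
    minority_is_pos = n_pos <= n_neg
    n_min, n_maj = (n_pos, n_neg) if minority_is_pos else (n_neg, n_pos)
    if n_min <= cfg.k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={cfg.k_neighbors}; "
            "use a smaller k"
        )
    n_target = int(np.ceil(cfg.target_ratio * n_maj))
    n_new = max(n_target - n_min, 0)
    if n_new == 0:
        return dataset.subset_rows(np.arange(dataset.n_genes))

    min_label = 1 if minority_is_pos else 0
    min_idx = np.flatnonzero(y == min_label)
    X_min = dataset.X[min_idx]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
    # first neighbor is the point itself; drop it
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(cfg.seed)
    parents = np.concatenate(
        [np.tile(np.arange(n_min), n_new // n_min), rng.permutation(n_min)[: n_new % n_min]]
    )
    chosen = rng.integers(0, cfg.k_neighbors, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    X_parent = X_min[parents]
    X_nn = X_min[neighbor_idx[parents, chosen]]
    X_new = X_parent + u[:, None] * (X_nn - X_parent)

    ids = list(dataset.ids) + [f"smote_{i}" for i in range(n_new)]
    X = np.vstack([dataset.X, X_new])
    y_out = np.concatenate([y, np.full(n_new, min_label, dtype=int)])
    synthetic = np.concatenate([dataset.synthetic, np.ones(n_new, dtype=bool)])
    return LabeledDataset(ids=ids, X=X, y=y_out, mask=dataset.mask.copy(), synthetic=synthetic)
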