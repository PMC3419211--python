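"""Single-feature multiple-threshold baseline.

The comparison arm: one atypicality score, several stringency cutoffs.
Genes whose score exceeds the p-th percentile of the genome-wide score
distribution are called HGT; the sweep reports confusion counts, Recall
and Mean error per cutoff and highlights the best-Recall cutoff with its
Mean error.  This is a deliberately transparent simplification of
multiple-threshold detectors from the literature, not a reimplementation
of any particular published variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FEATURE_NAMES, LabeledDataset
from .metrics import ConfusionCounts, mean_error, recall

DEFAULT_PERCENTILES: tuple[float, ...] = (80.0, 85.0, 90.0, 92.5, 95.0, 97.5, 99.0)


@dataclass
class ThresholdSweep:
    feature_name: str
    percentiles: list[float]
    counts: list[ConfusionCounts]
    recalls: list[float]
    mean_errors: list[float]

    @property
    def best_index(self) -> int:
        """Index of the best-Recall threshold (ties: lower Mean error)."""
        order = sorted(
            range(len(self.percentiles)),
            key=lambda i: (-self.recalls[i], self.mean_errors[i]),
        )
        return order[0]

    @property
    def best_recall(self) -> float:
        return self.recalls[self.best_index]

    @property
    def best_mean_error(self) -> float:
        """Mean error at the best-Recall threshold."""
        return self.mean_errors[self.best_index]


def threshold_sweep(
    dataset: LabeledDataset,
    feature: str,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
) -> ThresholdSweep:
    """Sweep upper-tail percentile cutoffs of one feature's score distribution.

    Cutoffs must be strictly increasing; the flagged gene sets are nested
    (each higher percentile flags a subset of the previous), so Recall is
    non-increasing in the percentile.
    """
    if feature not in FEATURE_NAMES:
        raise ValueError(
            f"unknown feature {feature!r}; valid names: {', '.join(FEATURE_NAMES)}"
        )
    if list(percentiles) != sorted(set(percentiles)):
        raise ValueError("percentiles must be strictly increasing")
    scores = dataset.X[:, FEATURE_NAMES.index(feature)]
    counts: list[ConfusionCounts] = []
    recalls: list[float] = []
    errors: list[float] = []
    for p in percentiles:
        cutoff = np.percentile(scores, p)
        # >= so that percentile 0 flags every gene (degenerate threshold)
        called = (scores >= cutoff).astype(int)
        c = ConfusionCounts.from_labels(dataset.y, called)
        counts.append(c)
        recalls.append(recall(c))
        errors.append(mean_error(c))
    return ThresholdSweep(
        feature_name=feature,
        percentiles=list(percentiles),
        counts=counts,
        recalls=recalls,
        mean_errors=errors,
    )


def sweep_all_features(
    dataset: LabeledDataset, percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
) -> dict[str, ThresholdSweep]:
    """One sweep per feature, in canonical feature order."""
    return {name: threshold_sweep(dataset, name, percentiles) for name in FEATURE_NAMES}
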