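"""Published per-genome evaluation values from the original Hgtident study.

Six bacterial genomes with HGT-DB-annotated transferred genes were
evaluated under 5-fold cross-validation; the printed (Recall, Mean error)
percentages are bundled here as inputs so the study's cross-table
arithmetic — the average improvements between protocol variants — can be
recomputed exactly with :func:`hgtident.metrics.table_deltas`.

The per-genome values themselves are reference data, not something this
package recomputes (that would require the HGT-DB genome downloads).
"""

from __future__ import annotations

from .dataset import FEATURE_NAMES
from .metrics import table_deltas

GENOMES: tuple[str, ...] = (
    "E. coli K12",
    "E. coli O157 Sakai",
    "S. enterica Typhi CT18",
    "S. enterica Paratypi ATCC 9150",
    "C. pneumoniae CWL029",
    "S. agalactiae 2603",
)

# (Recall, Mean error) per genome, all-features SVM vs GA-optimal feature subset
TABLE1_ALL_FEATURES: tuple[tuple[float, float], ...] = (
    (80.62, 18.67),
    (76.83, 17.97),
    (67.32, 27.31),
    (78.34, 20.38),
    (74.52, 19.17),
    (74.73, 20.69),
)
TABLE1_OPTIMAL_SUBSET: tuple[tuple[float, float], ...] = (
    (86.79, 13.50),
    (84.62, 14.31),
    (77.27, 21.92),
    (83.73, 16.05),
    (80.66, 16.10),
    (78.30, 14.27),
)

# (Recall, Mean error) per genome, optimal subset without vs with SMOTE
TABLE3_IMBALANCED: tuple[tuple[float, float], ...] = TABLE1_OPTIMAL_SUBSET
TABLE3_SMOTE: tuple[tuple[float, float], ...] = (
    (92.35, 7.26),
    (89.85, 9.64),
    (86.17, 11.36),
    (91.60, 7.64),
    (83.51, 13.70),
    (87.09, 10.42),
)

# Multiple-threshold single-signature rows A-O of the comparison table:
# one row per signature, (Recall, Mean error) per genome.
TABLE4_METHOD_ORDER: tuple[str, ...] = FEATURE_NAMES
TABLE4_THRESHOLD: dict[str, tuple[tuple[float, float], ...]] = {
    "Karlin-DN": ((81.03, 30.54), (79.05, 22.94), (66.80, 33.99), (89.93, 37.32), (69.27, 37.49), (72.35, 38.57)),
    "Karlin-CB": ((75.56, 28.09), (77.51, 26.19), (71.27, 26.99), (82.80, 22.99), (67.43, 37.33), (76.57, 23.12)),
    "GC1-GC3": ((42.44, 37.98), (47.02, 43.10), (33.96, 47.27), (45.65, 39.51), (40.53, 43.15), (37.19, 46.60)),
    "Chi2-DN": ((64.95, 36.56), (67.29, 29.42), (71.79, 51.44), (78.56, 24.23), (72.60, 44.09), (69.50, 30.51)),
    "Chi2-CB": ((61.09, 38.71), (61.67, 38.72), (61.75, 41.90), (71.13, 24.26), (73.34, 40.56), (80.63, 34.73)),
    "JS-N": ((93.11, 51.24), (86.03, 27.45), (80.22, 25.39), (82.16, 46.98), (68.64, 37.76), (77.50, 29.67)),
    "JS-DN": ((86.50, 30.92), (77.00, 26.20), (78.73, 35.25), (79.41, 24.14), (77.05, 27.10), (67.60, 40.06)),
    "JS-CB": ((90.03, 34.32), (89.12, 33.50), (70.71, 26.89), (90.78, 43.26), (79.71, 28.89), (80.76, 35.67)),
    "1-mer": ((87.13, 36.27), (47.19, 50.51), (34.51, 58.81), (88.93, 46.27), (46.51, 47.38), (37.24, 52.63)),
    "2-mer": ((43.73, 53.22), (49.06, 51.64), (46.27, 58.77), (46.50, 51.87), (47.36, 50.60), (41.15, 52.76)),
    "3-mer": ((43.73, 53.05), (49.06, 50.83), (41.79, 58.49), (51.80, 51.90), (47.36, 50.73), (41.15, 51.32)),
    "4-mer": ((63.73, 44.29), (50.15, 53.19), (35.82, 58.71), (51.80, 52.45), (53.15, 51.19), (35.07, 49.67)),
    "5-mer": ((43.73, 53.34), (52.81, 49.75), (35.82, 58.50), (46.71, 52.00), (48.89, 51.32), (54.13, 49.75)),
    "6-mer": ((51.13, 53.37), (47.53, 51.38), (44.51, 56.80), (46.50, 51.97), (47.36, 50.38), (46.30, 51.69)),
    "7-mer": ((43.73, 54.17), (49.06, 50.92), (44.51, 56.80), (48.83, 52.21), (49.10, 47.41), (49.62, 51.33)),
}
TABLE4_HGTIDENT: tuple[tuple[float, float], ...] = TABLE3_SMOTE


def table4_best_threshold() -> tuple[tuple[float, float], ...]:
    """Per genome, the best-Recall single-signature row and its Mean error
    (the bold-face convention of the comparison table)."""
    out = []
    for gi in range(len(GENOMES)):
        cells = [TABLE4_THRESHOLD[m][gi] for m in TABLE4_METHOD_ORDER]
        out.append(max(cells, key=lambda rc: (rc[0], -rc[1])))
    return tuple(out)


def table1_deltas() -> tuple[float, float]:
    """Mean (Recall gain, Mean-error reduction): optimal subset vs all features."""
    return table_deltas(list(TABLE1_ALL_FEATURES), list(TABLE1_OPTIMAL_SUBSET))


def table3_deltas() -> tuple[float, float]:
    """Mean (Recall gain, Mean-error reduction): SMOTE vs imbalanced training."""
    return table_deltas(list(TABLE3_IMBALANCED), list(TABLE3_SMOTE))


def table4_deltas() -> tuple[float, float]:
    """Mean (Recall gain, Mean-error reduction): combined classifier vs the
    best single-signature threshold row per genome."""
    return table_deltas(list(table4_best_threshold()), list(TABLE4_HGTIDENT))
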