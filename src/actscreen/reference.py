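"""Published reference results of the clinical validation of this protocol.

The screening protocol implemented here was validated on a single-center
clinical cohort (50 participants, 335 ACT samples, participant-level
294/41 train/test split).  These tables carry the figures that validation
reported, so the package's own arithmetic (metric computation, exclusion
accounting, interval estimation) can be exercised against them without
access to the clinical recordings themselves.

Note the published Random Forest row is internally inconsistent: the
before/after accuracies differ by 8.93 points while the printed improvement
is +9.13.  The printed improvement deltas are kept verbatim.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import ConfusionMatrix

__all__ = [
    "PREPROCESSING_COMPARISON",
    "ACQUISITION_COMPARISON",
    "TEST_CONFUSION",
    "INITIAL_SAMPLE_COMPOSITION",
    "mean_preprocessing_improvement",
    "acquisition_improvement",
]

#: Test accuracy (%) of each model before/after preprocessing, with the
#: improvement delta as printed in the clinical validation.
PREPROCESSING_COMPARISON = pd.DataFrame(
    [
        ("random_forest", 75.45, 84.38, 9.13),
        ("gradient_boosting", 72.97, 83.15, 10.18),
        ("svm", 71.18, 79.16, 7.98),
        ("knn", 66.66, 78.94, 12.28),
        ("mlp", 70.00, 71.43, 1.43),
        ("logistic_regression", 68.26, 68.96, 0.70),
        ("naive_bayes", 42.42, 57.77, 15.35),
    ],
    columns=["model", "before_pct", "after_pct", "improvement_pct"],
)

#: Accuracy (%) with 95% CI bounds under single- vs multi-sample acquisition.
ACQUISITION_COMPARISON = pd.DataFrame(
    [
        ("random_forest", 81.21, 69.1, 93.3, 84.38, 73.2, 95.6),
        ("gradient_boosting", 71.47, 57.6, 85.3, 83.15, 71.7, 94.6),
        ("svm", 75.00, 61.7, 88.3, 79.16, 66.7, 91.6),
        ("knn", 71.42, 57.6, 85.2, 78.94, 66.4, 91.5),
        ("mlp", 68.67, 54.5, 82.8, 71.43, 57.6, 85.3),
        ("logistic_regression", 67.20, 52.8, 81.6, 68.96, 54.8, 83.1),
        ("naive_bayes", 51.30, 36.0, 66.6, 57.77, 42.6, 72.9),
    ],
    columns=[
        "model",
        "single_pct", "single_ci_low", "single_ci_high",
        "multi_pct", "multi_ci_low", "multi_ci_high",
    ],
)

#: Random Forest confusion matrix on the 41-sample clinical test set
#: (20 normal, 21 strabismus; one normal misread as strabismus).
TEST_CONFUSION = ConfusionMatrix(tn=19, fp=1, fn=0, tp=21)

#: Initial clinical sample composition by subtype, before the rare-class
#: (hypertropia) exclusion.
INITIAL_SAMPLE_COMPOSITION = {
    "normal": 106,
    "hypertropia": 4,
    "exotropia": 188,
    "esotropia": 41,
}


def mean_preprocessing_improvement() -> float:
    """Arithmetic mean of the printed per-model improvement deltas (%)."""
    return float(np.mean(PREPROCESSING_COMPARISON["improvement_pct"]))


def acquisition_improvement(model: str) -> float:
    """Multi-sample minus single-sample accuracy (%) for one model."""
    row = ACQUISITION_COMPARISON.set_index("model").loc[model]
    return float(row["multi_pct"] - row["single_pct"])
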