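"""Model/Results front end over the screening benchmark.

:class:`ScreeningBenchmark` is constructed from a labeled
:class:`~actscreen.dataset.SampleTable` (or straight from a simulated
cohort); ``fit(seed)`` applies the quality and rare-class filters, draws the
participant-level split, runs the grid-searched model sweep and the
diagnostic evaluation, and returns a :class:`ScreeningResults` carrying the
benchmark table, the fitted classifiers, the diagnostic report and a
``summary()`` rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import classify as _classify
from . import dataset as _dataset
from . import evaluate as _evaluate
from .preprocess import PreprocessConfig
from .simulate import Cohort

__all__ = ["ScreeningBenchmark", "ScreeningResults"]


class ScreeningBenchmark:
    """Benchmark of screening classifiers on a labeled ACT sample table.

    Parameters
    ----------
    table
        Labeled samples with at least the requested feature conditions.
    specs
        Mapping of model name to :class:`~actscreen.classify.ModelSpec`;
        defaults to the full seven-model harness.
    test_fraction, folds, min_confidence, min_class_count
        Split fraction (of samples, assigned at participant level), CV fold
        count, tracking-confidence cutoff and rare-subtype cutoff.
    feature_sets, acquisitions
        The benchmark axes: feature condition ("raw", "preprocessed") and
        acquisition condition ("multi", "single").
    """

    def __init__(
        self,
        table: _dataset.SampleTable,
        specs: dict | None = None,
        test_fraction: float = 0.12,
        folds: int = 5,
        min_confidence: float = 0.25,
        min_class_count: int = 5,
        feature_sets: tuple = ("raw", "preprocessed"),
        acquisitions: tuple = ("multi",),
    ):
        self.table = table
        self.specs = specs if specs is not None else _classify.default_model_specs()
        self.test_fraction = test_fraction
        self.folds = folds
        self.min_confidence = min_confidence
        self.min_class_count = min_class_count
        self.feature_sets = tuple(feature_sets)
        self.acquisitions = tuple(acquisitions)

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        preprocess_config: PreprocessConfig | None = None,
        **kwargs,
    ) -> "ScreeningBenchmark":
        """Extract features from a simulated cohort and build the model."""
        table = _dataset.build_sample_table(cohort, preprocess_config)
        return cls(table, **kwargs)

    def fit(self, seed: int = 0) -> "ScreeningResults":
        """Filter, split, tune/train/test every cell, and evaluate."""
        retained = _dataset.quality_filter(self.table, self.min_confidence)
        retained = _dataset.exclude_rare_classes(retained, self.min_class_count)
        split = _dataset.participant_split(retained, self.test_fraction, seed)
        bench = _classify.run_benchmark(
            retained,
            split,
            specs=self.specs,
            feature_sets=self.feature_sets,
            acquisitions=self.acquisitions,
            folds=self.folds,
            seed=seed,
        )
        rep = _evaluate.report(bench, retained, split)
        return ScreeningResults(
            model=self, table=retained, split=split, benchmark=bench, report=rep
        )


@dataclass(frozen=True)
class ScreeningResults:
    """Fitted benchmark: accuracies, classifiers, diagnostics, summary."""

    model: ScreeningBenchmark = field(repr=False)
    table: _dataset.SampleTable = field(repr=False)
    split: _dataset.Split = field(repr=False)
    benchmark: _classify.Benchmark = field(repr=False)
    report: _evaluate.DiagnosticReport = field(repr=False)

    @property
    def benchmark_table(self) -> pd.DataFrame:
        return self.benchmark.table

    def metrics(
        self,
        model: str = "random_forest",
        features: str = "preprocessed",
        acquisition: str = "multi",
        level: str = "sample",
    ) -> dict:
        """The metric block of one benchmark cell at one aggregation level."""
        section = (
            self.report.sample_level if level == "sample"
            else self.report.patient_level
        )
        return section[f"{model}|{features}|{acquisition}"]

    def preprocessing_improvement(self, acquisition: str = "multi") -> pd.Series:
        """Per-model test-accuracy gain (%): preprocessed minus raw features."""
        t = self.benchmark.table
        t = t[t["acquisition"] == acquisition]
        pre = t[t["features"] == "preprocessed"].set_index("model")["test_accuracy_pct"]
        raw = t[t["features"] == "raw"].set_index("model")["test_accuracy_pct"]
        return (pre - raw).rename("improvement_pct")

    def summary(self) -> str:
        """Human-readable run summary (benchmark table plus headline cell)."""
        lines = ["Strabismus screening benchmark", "=" * 34, ""]
        lines.append(
            f"samples: {len(self.table)}   "
            f"train/test: {len(self.split.train_sample_ids)}/"
            f"{len(self.split.test_sample_ids)}   "
            f"test participants: {len(self.split.test_participants)}"
        )
        lines.append("")
        cols = ["model", "features", "acquisition", "cv_accuracy_pct",
                "test_accuracy_pct", "ci_low_pct", "ci_high_pct"]
        lines.append(
            self.benchmark.table[cols].to_string(
                index=False, float_format=lambda v: f"{v:.2f}"
            )
        )
        key = "random_forest|preprocessed|multi"
        if key in self.report.sample_level:
            m = self.report.sample_level[key]["metrics"]
            p = self.report.patient_level[key]["metrics"]
            lines.append("")
            lines.append("Random forest (preprocessed, multi-sample):")
            lines.append(
                "  sample level : "
                + "  ".join(f"{k}={m[k]:.4f}" for k in m if m[k] is not None)
            )
            lines.append(
                "  patient level: "
                + "  ".join(f"{k}={p[k]:.4f}" for k in p if p[k] is not None)
            )
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Grouped bar chart of test accuracy per model and feature condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.benchmark.table
        t = t[t["acquisition"] == t["acquisition"].iloc[0]]
        pivot = t.pivot(index="model", columns="features",
                        values="test_accuracy_pct")
        pivot.plot.bar(ax=ax, rot=30)
        ax.set_ylabel("test accuracy (%)")
        ax.set_ylim(0, 100)
        ax.figure.tight_layout()
        return ax
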