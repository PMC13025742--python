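"""Diagnostic evaluation: confusion matrices, screening metrics, binomial
confidence intervals and patient-level majority voting.

Strabismus is the positive class throughout.  The five headline metrics are
the standard diagnostic-test proportions — accuracy, sensitivity (recall on
the diseased), specificity, PPV and NPV — each a binomial proportion with a
95% confidence interval.  The Wald (normal-approximation) interval is the
default because it is symmetric about the estimate; the exact
Clopper-Pearson interval is available and preferable near the boundaries,
where Wald collapses to zero width.

Because each participant contributes several ACT samples, a patient-level
verdict is formed by majority voting over their per-sample predictions;
ties break toward strabismus, the screening-safe direction (a false alarm
costs a confirmatory exam, a miss costs a diagnosis).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .exceptions import ConfigError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "DiagnosticReport",
    "confusion",
    "metrics",
    "binomial_ci",
    "majority_vote",
    "report",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")

_CI_METHODS = {"wald": "normal", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with strabismus as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self):
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer")
        if self.total < 1:
            raise ConfigError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def to_dict(self) -> dict:
        return {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp}


def confusion(y_true, y_pred, positive: int = 1) -> ConfusionMatrix:
    """Count a binary confusion matrix; labels must be 0/1 arrays."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ConfigError("y_true and y_pred must be equal-length 1-D, non-empty")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ConfigError(f"{name} must contain only binary labels 0/1")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
        tp=int((pos_t & pos_p).sum()),
    )


def binomial_ci(
    successes: float, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Binomial-proportion confidence interval, clipped to [0, 1].

    ``wald`` is the normal approximation p-hat +/- z*sqrt(p(1-p)/n);
    ``clopper_pearson`` the exact beta interval.  At the boundaries
    (successes 0 or n) the Wald interval has zero width; prefer the exact
    method there.  Fractional success counts are accepted so published
    proportions can be checked at their printed precision.
    """
    if n < 1 or not (0 <= successes <= n):
        raise ConfigError("need 0 <= successes <= n with n >= 1")
    if not (0 < level < 1):
        raise ConfigError("level must be in (0, 1)")
    if method not in _CI_METHODS:
        raise ConfigError(f"unknown CI method {method!r}")
    if method == "wald" and successes in (0, n):
        logger.debug(
            "Wald interval at a boundary proportion has zero width; "
            "the Clopper-Pearson method is preferred there"
        )
    lo, hi = proportion_confint(successes, n, alpha=1 - level,
                                method=_CI_METHODS[method])
    return (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five screening proportions, their denominators and optional CIs.

    Metrics with a zero denominator are NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n: Mapping[str, int] = field(default_factory=dict)
    ci: Mapping[str, tuple] = field(default_factory=dict)
    undefined: frozenset = frozenset()

    def __getitem__(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "metrics": {m: getattr(self, m) for m in METRIC_NAMES},
            "n": dict(self.n),
            "ci": {k: list(v) for k, v in self.ci.items()},
            "undefined": sorted(self.undefined),
        }


def metrics(
    cm: ConfusionMatrix,
    ci: bool = True,
    level: float = 0.95,
    ci_method: str = "wald",
) -> DiagnosticMetrics:
    """Compute accuracy, sensitivity, specificity, PPV and NPV from counts."""
    numer_denom = {
        "accuracy": (cm.tp + cm.tn, cm.total),
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    values, ns, cis, undefined = {}, {}, {}, set()
    for name, (num, den) in numer_denom.items():
        ns[name] = den
        if den == 0:
            values[name] = math.nan
            undefined.add(name)
            continue
        values[name] = num / den
        if ci:
            cis[name] = binomial_ci(num, den, level=level, method=ci_method)
    return DiagnosticMetrics(
        **values, n=ns, ci=cis, undefined=frozenset(undefined)
    )


def majority_vote(participant_ids, y_pred) -> pd.Series:
    """Modal predicted label per participant; ties break toward strabismus (1)."""
    participant_ids = np.asarray(participant_ids)
    y_pred = np.asarray(y_pred, dtype=int)
    if participant_ids.shape != y_pred.shape or len(y_pred) == 0:
        raise ConfigError("participant_ids and y_pred must align and be non-empty")
    df = pd.DataFrame({"pid": participant_ids, "pred": y_pred})
    voted = df.groupby("pid")["pred"].mean() >= 0.5
    return voted.astype(int).rename("prediction")


@dataclass(frozen=True)
class DiagnosticReport:
    """Sample- and patient-level diagnostics for one or more classifiers.

    ``sample_level`` / ``patient_level`` map a cell key
    ``"model|features|acquisition"`` to a dict holding the confusion counts
    and the metric block.
    """

    sample_level: dict = field(repr=False)
    patient_level: dict = field(repr=False)
    n_test_samples: int = 0
    n_test_participants: int = 0

    def to_dict(self) -> dict:
        return {
            "n_test_samples": self.n_test_samples,
            "n_test_participants": self.n_test_participants,
            "sample_level": self.sample_level,
            "patient_level": self.patient_level,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Screening diagnostics", ""]
        for title, section in (
            ("Sample level", self.sample_level),
            ("Patient level (majority vote)", self.patient_level),
        ):
            lines.append(f"## {title}")
            lines.append("")
            lines.append(
                "| cell | accuracy | sensitivity | specificity | PPV | NPV |"
            )
            lines.append("|---|---|---|---|---|---|")
            for key in sorted(section):
                m = section[key]["metrics"]

                def fmt(name):
                    v = m[name]
                    return "n/a" if v is None or (isinstance(v, float) and math.isnan(v)) \
                        else f"{v:.4f}"

                lines.append(
                    f"| {key} | {fmt('accuracy')} | {fmt('sensitivity')} | "
                    f"{fmt('specificity')} | {fmt('ppv')} | {fmt('npv')} |"
                )
            lines.append("")
        return "\n".join(lines)


def _block(y_true, y_pred, ci_method: str) -> dict:
    cm = confusion(y_true, y_pred)
    m = metrics(cm, ci_method=ci_method)
    d = m.to_dict()
    # JSON has no NaN: undefined metrics serialize as null
    d["metrics"] = {
        k: (None if math.isnan(v) else v) for k, v in d["metrics"].items()
    }
    return {"confusion": cm.to_dict(), **d}


def report(
    benchmark,
    sample_table,
    split,
    ci_method: str = "wald",
) -> DiagnosticReport:
    """Build sample- and patient-level diagnostics for every benchmark cell.

    ``benchmark`` is a :class:`actscreen.classify.Benchmark`;
    ``sample_table`` must contain the test samples so true labels and
    participant ids can be aligned with the stored predictions.
    """
    test_tab = sample_table.select_samples(split.test_sample_ids)
    order = {sid: i for i, sid in enumerate(test_tab.sample_ids)}
    if set(benchmark.test_sample_ids) != set(order):
        raise ConfigError("benchmark and split disagree on the test samples")
    idx = np.array([order[sid] for sid in benchmark.test_sample_ids])
    y_true = test_tab.labels[idx]
    pids = test_tab.participant_ids[idx]
    true_by_pid = pd.Series(y_true, index=pids).groupby(level=0).first()

    sample_level, patient_level = {}, {}
    for (name, features, acq), y_pred in benchmark.predictions.items():
        key = f"{name}|{features}|{acq}"
        sample_level[key] = _block(y_true, y_pred, ci_method)
        voted = majority_vote(pids, y_pred)
        voted = voted.reindex(true_by_pid.index)
        patient_level[key] = _block(
            true_by_pid.to_numpy(), voted.to_numpy(), ci_method
        )
    return DiagnosticReport(
        sample_level=sample_level,
        patient_level=patient_level,
        n_test_samples=len(y_true),
        n_test_participants=len(true_by_pid),
    )
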