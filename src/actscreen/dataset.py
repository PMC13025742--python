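"""Assembling the labeled analysis dataset and the leakage-free split.

A *sample* is one complete ACT cycle; a participant contributes several
(typically 3-7).  The table keeps the clinical subtype (normal, exotropia,
esotropia, hypertropia) as metadata and derives the binary screening label
strabismus-vs-normal from it.  The split assigns whole participants to the
train or test side so no individual's samples leak across.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, UnrecoverableSampleError
from .preprocess import PreprocessConfig, raw_features, run_pipeline
from .simulate import Cohort, GazeRecording

__all__ = [
    "NORMAL",
    "STRABISMUS",
    "SampleTable",
    "Split",
    "build_sample_table",
    "quality_filter",
    "exclude_rare_classes",
    "participant_split",
    "write_features",
    "read_features",
]

logger = logging.getLogger(__name__)

NORMAL = 0
STRABISMUS = 1

META_COLUMNS = ("participant_id", "sample_id", "subtype", "label", "quality")


@dataclass(frozen=True)
class SampleTable:
    """Labeled samples: one metadata row plus feature vector(s) per sample.

    ``meta`` columns: participant_id, sample_id, subtype, label (0 = normal,
    1 = strabismus), quality (tracking-confidence score in [0, 1]).
    ``features`` maps a feature-condition name ("raw", "preprocessed") to a
    row-aligned 2-D matrix.
    """

    meta: pd.DataFrame = field(repr=False)
    features: dict = field(repr=False)

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ConfigError(f"meta missing columns: {missing}")
        if self.meta["sample_id"].duplicated().any():
            raise ConfigError("sample_ids must be unique")
        expected = (self.meta["subtype"] != "normal").astype(int)
        if not (self.meta["label"].to_numpy() == expected.to_numpy()).all():
            raise ConfigError("label must be strabismus iff subtype != normal")
        n = len(self.meta)
        for name, X in self.features.items():
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != n:
                raise ConfigError(
                    f"feature matrix {name!r} must be 2-D with one row per sample"
                )
            self.features[name] = X

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=int)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.meta["participant_id"].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def subset(self, keep: np.ndarray) -> "SampleTable":
        """Row-subset by boolean mask or integer positions."""
        keep = np.asarray(keep)
        meta = self.meta.iloc[keep].reset_index(drop=True) if keep.dtype != bool \
            else self.meta.loc[keep].reset_index(drop=True)
        feats = {k: np.asarray(v)[keep] for k, v in self.features.items()}
        return SampleTable(meta, feats)

    def select_samples(self, sample_ids: Iterable[str]) -> "SampleTable":
        wanted = set(sample_ids)
        mask = self.meta["sample_id"].isin(wanted).to_numpy()
        return self.subset(mask)


def build_sample_table(
    source: Cohort | Sequence[GazeRecording],
    config: PreprocessConfig | None = None,
) -> SampleTable:
    """Run feature extraction over recordings and assemble the table.

    Computes both the raw and the preprocessed feature condition for every
    recording; samples that become unrecoverable during preprocessing are
    dropped with a logged count.
    """
    recordings = source.recordings if isinstance(source, Cohort) else tuple(source)
    if not recordings:
        raise ConfigError("no recordings to build a sample table from")
    cfg = config if config is not None else PreprocessConfig()
    rows, raw_rows, pre_rows = [], [], []
    dropped = 0
    for rec in recordings:
        try:
            pre = run_pipeline(rec, cfg)
            raw = raw_features(rec, cfg)
        except UnrecoverableSampleError as exc:
            dropped += 1
            logger.warning("dropping sample %s: %s", rec.sample_id, exc)
            continue
        subtype = rec.condition if rec.condition is not None else "normal"
        rows.append(
            {
                "participant_id": rec.participant_id,
                "sample_id": rec.sample_id,
                "subtype": subtype,
                "label": int(subtype != "normal"),
                "quality": rec.quality,
            }
        )
        raw_rows.append(raw)
        pre_rows.append(pre)
    if dropped:
        logger.info("build_sample_table dropped %d unrecoverable sample(s)", dropped)
    if not rows:
        raise UnrecoverableSampleError("every sample was unrecoverable")
    meta = pd.DataFrame(rows)
    return SampleTable(
        meta, {"raw": np.vstack(raw_rows), "preprocessed": np.vstack(pre_rows)}
    )


def quality_filter(table: SampleTable, min_confidence: float = 0.25) -> SampleTable:
    """Drop samples whose tracking-confidence score is below ``min_confidence``."""
    keep = table.meta["quality"].to_numpy(dtype=float) >= min_confidence
    removed = int((~keep).sum())
    if removed:
        logger.info("quality_filter removed %d of %d samples (< %.2f)",
                    removed, len(table), min_confidence)
    if not keep.any():
        logger.warning("quality_filter removed every sample")
    return table.subset(keep)


def exclude_rare_classes(table: SampleTable, min_count: int = 5) -> SampleTable:
    """Drop every subtype with fewer than ``min_count`` samples entirely.

    Screens out subtypes too rare for reliable model training (e.g. a
    handful of hypertropia samples in an otherwise horizontal-deviation
    cohort).  Idempotent.
    """
    counts = table.meta["subtype"].value_counts()
    rare = set(counts[counts < min_count].index)
    if not rare:
        return table
    keep = ~table.meta["subtype"].isin(rare).to_numpy()
    logger.info("exclude_rare_classes dropped subtype(s) %s (%d samples)",
                sorted(rare), int((~keep).sum()))
    return table.subset(keep)


@dataclass(frozen=True)
class Split:
    """A participant-level train/test partition of sample ids."""

    train_sample_ids: tuple
    test_sample_ids: tuple
    train_participants: tuple
    test_participants: tuple
    seed: int
    test_fraction: float

    def __post_init__(self):
        if set(self.train_sample_ids) & set(self.test_sample_ids):
            raise ConfigError("train and test sample ids overlap")
        if set(self.train_participants) & set(self.test_participants):
            raise ConfigError("participant appears on both sides of the split")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "train_sample_ids": list(self.train_sample_ids),
            "test_sample_ids": list(self.test_sample_ids),
            "train_participants": list(self.train_participants),
            "test_participants": list(self.test_participants),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Split":
        return cls(
            tuple(d["train_sample_ids"]),
            tuple(d["test_sample_ids"]),
            tuple(d["train_participants"]),
            tuple(d["test_participants"]),
            int(d["seed"]),
            float(d["test_fraction"]),
        )


def participant_split(
    table: SampleTable, test_fraction: float = 0.12, seed: int = 0
) -> Split:
    """Assign whole participants to the test side, stratified by binary label.

    Within each class, participants are shuffled (seeded) and added to the
    test side greedily while that brings the class's test sample count
    closer to ``test_fraction`` of its samples; at least one participant per
    class lands on each side.  Deterministic given the seed.
    """
    if not (0 < test_fraction < 1):
        raise ConfigError("test_fraction must be in (0, 1)")
    meta = table.meta
    rng = np.random.default_rng(seed)
    test_participants: list = []
    for label in (NORMAL, STRABISMUS):
        sub = meta[meta["label"] == label]
        pids = sub["participant_id"].unique()
        if len(pids) < 2:
            raise ConfigError(
                f"need at least 2 participants in class {label} to split, "
                f"got {len(pids)}"
            )
        counts = sub.groupby("participant_id")["sample_id"].count()
        order = rng.permutation(pids)
        target = test_fraction * counts.sum()
        current = 0
        chosen = []
        for pid in order:
            c = int(counts[pid])
            if len(chosen) == len(pids) - 1:
                break  # keep at least one participant in training
            if not chosen:
                chosen.append(pid)
                current += c
                continue
            if abs(current + c - target) < abs(current - target):
                chosen.append(pid)
                current += c
            else:
                break
        test_participants.extend(chosen)

    is_test = meta["participant_id"].isin(test_participants).to_numpy()
    split = Split(
        tuple(meta.loc[~is_test, "sample_id"]),
        tuple(meta.loc[is_test, "sample_id"]),
        tuple(sorted(set(meta.loc[~is_test, "participant_id"]))),
        tuple(sorted(set(test_participants))),
        seed,
        test_fraction,
    )
    logger.info(
        "participant_split: %d train / %d test samples (%d / %d participants)",
        len(split.train_sample_ids), len(split.test_sample_ids),
        len(split.train_participants), len(split.test_participants),
    )
    return split


def write_features(table: SampleTable, path, feature_set: str = "preprocessed") -> None:
    """Persist one feature condition as a flat CSV (meta + f00..fNN columns)."""
    X = table.features[feature_set]
    cols = [f"f{i:02d}" for i in range(X.shape[1])]
    df = pd.concat(
        [table.meta.reset_index(drop=True), pd.DataFrame(X, columns=cols)], axis=1
    )
    df.to_csv(path, index=False)


def read_features(path, feature_set: str = "preprocessed") -> SampleTable:
    """Load a features CSV written by :func:`write_features`."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"features file missing columns: {missing}")
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not fcols:
        raise ConfigError("features file contains no feature columns")
    meta = df[list(META_COLUMNS)].copy()
    X = df[sorted(fcols)].to_numpy(dtype=float)
    return SampleTable(meta, {feature_set: X})
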