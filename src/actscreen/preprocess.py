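"""Three-stage preprocessing of ACT gaze recordings.

A raw recording is reduced to the interocular difference signal
RPCX - LPCX (the Y-coordinates are discarded: horizontal deviations dominate
exo-/esotropia), invalid frames are repaired, the baseline interpupillary
separation is removed by median centering, tracking artifacts are deleted
with a 0.025 threshold, the series is compressed 10:1 by window averaging,
and finally resampled to a fixed-length feature vector for the classifiers.

Stages are tagged and order-enforced: raw -> filled -> centered -> filtered
-> compressed.  Applying an operation out of order raises
:class:`StageOrderError`.

On the 0.025 threshold: it is applied here, by default, to frame-to-frame
jumps (a velocity criterion deleting tracking artifacts).  The alternative
reading — deleting points farther than 0.025 from the series average — is
available as ``outlier_mode="deviation_from_mean"``, but taken literally it
would also delete the diagnostic deviation excursions themselves, which for
any useful recording exceed the threshold; the velocity rule preserves them
because physiological drifts build up over several 60 Hz frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, StageOrderError, UnrecoverableSampleError
from .simulate import GazeRecording

__all__ = [
    "STAGES",
    "DeviationSeries",
    "PreprocessConfig",
    "difference_signal",
    "fill_invalid",
    "center_signal",
    "remove_outliers",
    "compress",
    "featurize",
    "run_pipeline",
    "raw_features",
]

logger = logging.getLogger(__name__)

STAGES = ("raw", "filled", "centered", "filtered", "compressed")


@dataclass(frozen=True)
class DeviationSeries:
    """The RPCX - LPCX signal with a validity mask and a pipeline-stage tag."""

    values: np.ndarray
    mask: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        if values.ndim != 1 or mask.shape != values.shape:
            raise ConfigError("values and mask must be 1-D arrays of equal length")
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")
        if mask.any() and not np.isfinite(values[mask]).all():
            raise ConfigError("values must be finite wherever the mask is true")

    def __len__(self) -> int:
        return len(self.values)


def _require_stage(series: DeviationSeries, *stages: str) -> None:
    if series.stage not in stages:
        raise StageOrderError(
            f"expected a series at stage {' or '.join(stages)}, "
            f"got {series.stage!r}: preprocessing stages must run in order "
            f"{' -> '.join(STAGES)}"
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the preprocessing pipeline.

    ``outlier_threshold`` is in normalized screen units (default 0.025);
    ``compression_window`` in frames (default 10, i.e. 60 Hz -> 6 Hz);
    ``feature_length`` is the fixed classifier input dimension (default 60,
    one 10 s recording compressed 10:1).
    """

    outlier_threshold: float = 0.025
    outlier_mode: str = "frame_jump"
    compression_window: int = 10
    feature_length: int = 60
    invalid_policy: str = "interpolate"

    def __post_init__(self):
        if self.outlier_threshold <= 0:
            raise ConfigError("outlier_threshold must be > 0")
        if self.outlier_mode not in ("frame_jump", "deviation_from_mean"):
            raise ConfigError(f"unknown outlier_mode {self.outlier_mode!r}")
        if self.compression_window < 1:
            raise ConfigError("compression_window must be >= 1")
        if self.feature_length < 1:
            raise ConfigError("feature_length must be >= 1")
        if self.invalid_policy not in ("interpolate", "drop"):
            raise ConfigError(f"unknown invalid_policy {self.invalid_policy!r}")


def difference_signal(recording: GazeRecording) -> DeviationSeries:
    """Extract RPCX - LPCX with a per-frame validity mask (stage ``raw``)."""
    if recording.n_frames == 0:
        raise UnrecoverableSampleError("recording has no frames")
    f = recording.frames
    values = f["RPCX"].to_numpy(dtype=float) - f["LPCX"].to_numpy(dtype=float)
    mask = (f["LPV"].to_numpy() == 1) & (f["RPV"].to_numpy() == 1)
    return DeviationSeries(values, mask, stage="raw")


def fill_invalid(series: DeviationSeries, policy: str = "interpolate") -> DeviationSeries:
    """Repair invalid points; the result is fully valid (stage ``filled``).

    ``interpolate`` replaces masked-out points by linear interpolation
    between the nearest valid neighbours (edges take the nearest valid
    value); ``drop`` removes them.
    """
    _require_stage(series, "raw")
    if policy not in ("interpolate", "drop"):
        raise ConfigError(f"unknown invalid policy {policy!r}")
    mask = series.mask
    if not mask.any():
        raise UnrecoverableSampleError("all frames invalid; sample unusable")
    if mask.all():
        return DeviationSeries(series.values.copy(), mask.copy(), stage="filled")
    if policy == "drop":
        vals = series.values[mask]
    else:
        idx = np.arange(len(series))
        vals = np.interp(idx, idx[mask], series.values[mask])
    return DeviationSeries(vals, np.ones(len(vals), dtype=bool), stage="filled")


def center_signal(series: DeviationSeries) -> DeviationSeries:
    """Subtract the series median so the baseline separation maps to ~0."""
    _require_stage(series, "filled")
    if len(series) == 0:
        raise UnrecoverableSampleError("cannot center an empty series")
    vals = series.values - np.median(series.values)
    return DeviationSeries(vals, series.mask.copy(), stage="centered")


def remove_outliers(
    series: DeviationSeries,
    threshold: float = 0.025,
    mode: str = "frame_jump",
) -> DeviationSeries:
    """Delete tracking artifacts exceeding ``threshold`` (stage ``filtered``).

    ``frame_jump`` drops every point whose jump from the *previous original
    point* exceeds the threshold, then closes the gap; ``deviation_from_mean``
    drops points farther than the threshold from the series mean.
    """
    _require_stage(series, "centered")
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    vals = series.values
    if mode == "frame_jump":
        keep = np.ones(len(vals), dtype=bool)
        keep[1:] = np.abs(np.diff(vals)) <= threshold
    elif mode == "deviation_from_mean":
        keep = np.abs(vals - vals.mean()) <= threshold
    else:
        raise ConfigError(f"unknown outlier mode {mode!r}")
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("outlier removal (%s) dropped %d of %d points",
                     mode, dropped, len(vals))
    if not keep.any():
        raise UnrecoverableSampleError("outlier removal dropped every point")
    return DeviationSeries(vals[keep], series.mask[keep], stage="filtered")


def compress(series: DeviationSeries, window: int = 10) -> DeviationSeries:
    """Average non-overlapping windows of ``window`` points into one each.

    A trailing partial window of at least ``window / 2`` points is averaged
    into a final point; shorter tails are discarded.
    """
    _require_stage(series, "filtered")
    if window < 1:
        raise ConfigError("window must be >= 1")
    n = len(series)
    n_full = n // window
    rem = n - n_full * window
    out = []
    if n_full:
        out.append(series.values[: n_full * window].reshape(n_full, window).mean(axis=1))
    if rem >= window / 2:
        out.append([series.values[n_full * window:].mean()])
    if not out or sum(len(o) for o in out) == 0:
        raise UnrecoverableSampleError("series too short to compress")
    vals = np.concatenate([np.asarray(o, dtype=float) for o in out])
    return DeviationSeries(vals, np.ones(len(vals), dtype=bool), stage="compressed")


def featurize(series: DeviationSeries, feature_length: int = 60) -> np.ndarray:
    """Resample a compressed series onto ``feature_length`` equispaced points."""
    _require_stage(series, "compressed")
    if feature_length < 1:
        raise ConfigError("feature_length must be >= 1")
    if len(series) < 2:
        raise UnrecoverableSampleError("need at least 2 points to featurize")
    return _resample(series.values, feature_length)


def _resample(values: np.ndarray, length: int) -> np.ndarray:
    src = np.arange(len(values), dtype=float)
    dst = np.linspace(0.0, len(values) - 1.0, length)
    return np.interp(dst, src, values)


def run_pipeline(
    recording: GazeRecording, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Full pipeline: difference -> fill -> center -> outliers -> compress -> featurize."""
    cfg = config if config is not None else PreprocessConfig()
    series = difference_signal(recording)
    series = fill_invalid(series, cfg.invalid_policy)
    series = center_signal(series)
    series = remove_outliers(series, cfg.outlier_threshold, cfg.outlier_mode)
    series = compress(series, cfg.compression_window)
    return featurize(series, cfg.feature_length)


def raw_features(
    recording: GazeRecording, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Unpreprocessed baseline features for benchmark comparisons.

    The difference signal with invalid frames repaired, linearly resampled to
    the same fixed length as the preprocessed features but with no centering,
    outlier removal or temporal compression — i.e. the signal a classifier
    would see without the preprocessing pipeline.
    """
    cfg = config if config is not None else PreprocessConfig()
    series = fill_invalid(difference_signal(recording), cfg.invalid_policy)
    if len(series) < 2:
        raise UnrecoverableSampleError("need at least 2 valid frames")
    return _resample(series.values, cfg.feature_length)
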