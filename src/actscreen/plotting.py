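"""Quick-look plots of the deviation signal through its preprocessing stages."""

from __future__ import annotations

from .preprocess import (
    PreprocessConfig,
    center_signal,
    compress,
    difference_signal,
    fill_invalid,
    remove_outliers,
)
from .simulate import GazeRecording

__all__ = ["plot_deviation_stages"]


def plot_deviation_stages(recording: GazeRecording,
                          config: PreprocessConfig | None = None, ax=None):
    """Overlay the raw RPCX-LPCX signal, the filtered series and the
    compressed series of one recording, with occlusions shaded."""
    import matplotlib.pyplot as plt

    cfg = config if config is not None else PreprocessConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.5))
    raw = difference_signal(recording)
    filled = fill_invalid(raw, cfg.invalid_policy)
    centered = center_signal(filled)
    filtered = remove_outliers(centered, cfg.outlier_threshold, cfg.outlier_mode)
    compressed = compress(filtered, cfg.compression_window)

    ax.plot(centered.values, lw=0.6, alpha=0.5, label="centered (60 Hz)")
    ax.plot(filtered.values, lw=0.8, alpha=0.8, label="outliers removed")
    n = len(filtered)
    xs = [i * cfg.compression_window + cfg.compression_window / 2
          for i in range(len(compressed))]
    ax.plot([min(x, n - 1) for x in xs], compressed.values, "o-", ms=3,
            label=f"compressed {cfg.compression_window}:1")
    if recording.schedule is not None:
        rate = len(recording.frames) / recording.schedule.duration_s
        for iv in recording.schedule.intervals:
            ax.axvspan(iv.start_s * rate, iv.end_s * rate, alpha=0.06,
                       color="k")
    ax.set_xlabel("frame")
    ax.set_ylabel("RPCX - LPCX (centered)")
    ax.legend(fontsize=8)
    title = recording.condition or "recording"
    ax.set_title(f"{recording.sample_id} ({title})", fontsize=9)
    ax.figure.tight_layout()
    return ax
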