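"""Synthetic alternate cover test (ACT) gaze recordings.

The alternate cover test dissociates the two eyes by occluding them in turn
with an infrared-transparent cover while a remote eye tracker keeps imaging
both pupils at 60 Hz.  In strabismus the covered eye drifts to its anatomical
resting position (outward for exotropia, inward for esotropia, upward for
hypertropia) and re-aligns once fixation is restored, so the interocular
X-coordinate difference RPCX - LPCX carries the diagnostic signal.

The generator models that physiology with two first-order time constants: a
fast, saccade-like drift of the covered eye toward its deviated position
(``deviation_onset_tau_s``) and a slower fusional re-alignment of the freshly
uncovered eye (``deviation_offset_tau_s``).  Because the cover alternates
without a binocular gap, the two envelopes sum to the full deviation amplitude
on the plateaus; the asymmetry of the time constants produces a transient
overshoot of RPCX - LPCX at every occluder swap — the characteristic peaks an
examiner's plots show for strabismic recordings — positive for exotropia and
negative for esotropia.  The eye that is covered at frame zero starts fully
deviated (the occluder is placed before logging begins).

Sensor imperfections are modeled as i.i.d. Gaussian noise on every pupil
coordinate plus sporadic invalid frames (validity flags LPV/RPV drop to 0 and
the logged coordinates hold the last valid value, as trackers do during
blinks or reflections).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ConfigError

__all__ = [
    "LEFT",
    "RIGHT",
    "CONDITIONS",
    "GAZE_COLUMNS",
    "CoverInterval",
    "OcclusionSchedule",
    "SimulationConfig",
    "GazeRecording",
    "Cohort",
    "make_schedule",
    "simulate_recording",
    "simulate_cohort",
]

LEFT = "left"
RIGHT = "right"

#: Recognized clinical conditions.  Hypertropia (vertical deviation) is
#: generated only so the dataset-level rare-class exclusion has work to do.
CONDITIONS = ("normal", "exotropia", "esotropia", "hypertropia")

#: Canonical gaze-log column order (GazePoint-style export).
GAZE_COLUMNS = ("Timestamp", "LPCX", "LPCY", "RPCX", "RPCY", "LPV", "RPV")

_EPS = 1e-9


@dataclass(frozen=True)
class CoverInterval:
    """One monocular occlusion: which eye is covered and for which time span."""

    eye: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.eye not in (LEFT, RIGHT):
            raise ConfigError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if not self.end_s > self.start_s:
            raise ConfigError("cover interval must have positive length")


@dataclass(frozen=True)
class OcclusionSchedule:
    """Ground-truth cover intervals tiling one ACT recording.

    Intervals are ordered, non-overlapping, alternate eyes, and tile
    ``[0, duration_s]`` — the occluder is transferred directly from one eye
    to the other.
    """

    intervals: tuple[CoverInterval, ...]
    duration_s: float

    def __post_init__(self):
        if not self.intervals:
            raise ConfigError("schedule needs at least one interval")
        prev_end = 0.0
        prev_eye = None
        for iv in self.intervals:
            if iv.start_s < -_EPS or iv.end_s > self.duration_s + _EPS:
                raise ConfigError("interval outside [0, duration_s]")
            if abs(iv.start_s - prev_end) > _EPS:
                raise ConfigError("intervals must tile the duration without gaps")
            if iv.eye == prev_eye:
                raise ConfigError("consecutive intervals must alternate eyes")
            prev_end = iv.end_s
            prev_eye = iv.eye

    def eye_masks(self, times_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (left_covered, right_covered) masks at the given times."""
        t = np.asarray(times_s, dtype=float)
        left = np.zeros(t.shape, dtype=bool)
        right = np.zeros(t.shape, dtype=bool)
        for iv in self.intervals:
            m = (t >= iv.start_s - _EPS) & (t < iv.end_s - _EPS)
            if iv.eye == LEFT:
                left |= m
            else:
                right |= m
        return left, right

    def occluded_mask(self, times_s: np.ndarray, eye: str | None = None) -> np.ndarray:
        """Mask of frames during which ``eye`` (or any eye) is covered."""
        left, right = self.eye_masks(times_s)
        if eye == LEFT:
            return left
        if eye == RIGHT:
            return right
        return left | right


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated ACT recording.

    Coordinates are in the tracker's normalized screen units (left pupil
    around 0.62, right around 1.005, cf. a typical GazePoint log), so the
    baseline interpupillary separation RPCX - LPCX sits near 0.385.
    ``deviation_amplitude`` is the total ocular deviation in those units and
    must be 0 exactly for the normal condition and positive otherwise.
    """

    condition: str = "normal"
    deviation_amplitude: float = 0.0
    duration_s: float = 10.0
    sample_rate_hz: float = 60.0
    cover_dwell_range_s: tuple[float, float] = (3.0, 6.0)
    deviation_onset_tau_s: float = 0.08
    deviation_offset_tau_s: float = 0.4
    noise_sd: float = 0.01
    invalid_frame_prob: float = 0.02
    baseline_lpcx: float = 0.62
    baseline_rpcx: float = 1.005
    baseline_y: float = 0.35

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.deviation_amplitude < 0:
            raise ConfigError("deviation_amplitude must be >= 0")
        if (self.deviation_amplitude == 0) != (self.condition == "normal"):
            raise ConfigError(
                "deviation_amplitude must be 0 exactly for 'normal' and "
                "positive for any deviation condition"
            )
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ConfigError("duration_s and sample_rate_hz must be positive")
        lo, hi = self.cover_dwell_range_s
        if not (0 < lo <= hi <= self.duration_s):
            raise ConfigError("cover_dwell_range_s must lie within (0, duration_s]")
        if not (0 <= self.invalid_frame_prob < 1):
            raise ConfigError("invalid_frame_prob must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.deviation_onset_tau_s < 0 or self.deviation_offset_tau_s < 0:
            raise ConfigError("time constants must be >= 0")


@dataclass(frozen=True)
class GazeRecording:
    """One ACT recording: per-frame gaze log plus provenance metadata.

    ``frames`` holds the seven canonical columns of a GazePoint-style log.
    ``condition`` / ``schedule`` / ``deviation_amplitude`` are ground truth
    carried by simulated recordings; recordings ingested from files leave
    them ``None``.
    """

    frames: pd.DataFrame
    participant_id: str = "P000"
    sample_index: int = 0
    condition: str | None = None
    schedule: OcclusionSchedule | None = None
    deviation_amplitude: float | None = None

    def __post_init__(self):
        missing = [c for c in GAZE_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ConfigError(f"frames missing columns: {missing}")
        ts = self.frames["Timestamp"].to_numpy(dtype=float)
        if len(ts) and np.any(np.diff(ts) <= 0):
            raise ConfigError("timestamps must be strictly increasing")
        for col in ("LPV", "RPV"):
            v = self.frames[col].to_numpy()
            if not np.isin(v, (0, 1)).all():
                raise ConfigError(f"{col} flags must be 0 or 1")
        valid = (self.frames["LPV"].to_numpy() == 1) & (
            self.frames["RPV"].to_numpy() == 1
        )
        coords = self.frames[["LPCX", "LPCY", "RPCX", "RPCY"]].to_numpy(dtype=float)
        if valid.any() and not np.isfinite(coords[valid]).all():
            raise ConfigError("coordinates must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def sample_id(self) -> str:
        return f"{self.participant_id}-{self.sample_index:02d}"

    @property
    def quality(self) -> float:
        """Tracking-confidence score: fraction of frames valid in both eyes."""
        if not len(self.frames):
            return 0.0
        both = (self.frames["LPV"].to_numpy() == 1) & (
            self.frames["RPV"].to_numpy() == 1
        )
        return float(both.mean())


def make_schedule(
    duration_s: float,
    cover_dwell_range_s: tuple[float, float] = (3.0, 6.0),
    seed: int | np.random.Generator = 0,
    first_eye: str = LEFT,
) -> OcclusionSchedule:
    """Draw an alternating occlusion schedule tiling ``[0, duration_s]``.

    Dwell lengths are uniform on ``cover_dwell_range_s``; the draw of each
    non-final dwell is capped so the remainder can still be tiled with
    in-range dwells, and the final interval absorbs the exact remainder.
    Deterministic given the seed.
    """
    lo, hi = cover_dwell_range_s
    if not (0 < lo <= hi <= duration_s):
        raise ConfigError("cover_dwell_range_s must lie within (0, duration_s]")
    if duration_s <= lo:
        raise ConfigError("duration_s must exceed the minimum dwell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if first_eye not in (LEFT, RIGHT):
        raise ConfigError("first_eye must be 'left' or 'right'")

    intervals: list[CoverInterval] = []
    t = 0.0
    eye = first_eye
    while duration_s - t > _EPS:
        remaining = duration_s - t
        if remaining <= hi + _EPS:
            dwell = remaining
        else:
            upper = min(hi, remaining - lo)
            # degenerate ranges (hi < 2*lo with awkward durations) fall back
            # to an even split rather than violating the tiling contract
            dwell = remaining / 2.0 if upper < lo else float(rng.uniform(lo, upper))
        intervals.append(CoverInterval(eye, t, t + dwell))
        t += dwell
        eye = RIGHT if eye == LEFT else LEFT
    return OcclusionSchedule(tuple(intervals), duration_s)


def _deviation_envelopes(
    config: SimulationConfig,
    left_covered: np.ndarray,
    right_covered: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-eye deviation magnitude over time (first-order lag dynamics).

    The covered eye relaxes toward the full amplitude with the onset time
    constant; an uncovered eye re-aligns toward 0 with the (slower) offset
    time constant.  The eye covered at frame 0 starts fully deviated.
    """
    n = left_covered.shape[0]
    amp = config.deviation_amplitude
    dt = 1.0 / config.sample_rate_hz

    def factor(tau: float) -> float:
        return 0.0 if tau <= 0 else float(np.exp(-dt / tau))

    f_on = factor(config.deviation_onset_tau_s)
    f_off = factor(config.deviation_offset_tau_s)

    env_l = np.empty(n)
    env_r = np.empty(n)
    el = amp if (n and left_covered[0]) else 0.0
    er = amp if (n and right_covered[0]) else 0.0
    for i in range(n):
        tl = amp if left_covered[i] else 0.0
        tr = amp if right_covered[i] else 0.0
        el = tl + (el - tl) * (f_on if tl > el else f_off)
        er = tr + (er - tr) * (f_on if tr > er else f_off)
        env_l[i] = el
        env_r[i] = er
    return env_l, env_r


def simulate_recording(
    config: SimulationConfig,
    seed: int = 0,
    schedule: OcclusionSchedule | None = None,
    participant_id: str = "P000",
    sample_index: int = 0,
) -> GazeRecording:
    """Simulate one ACT recording under ``config``; deterministic given seed."""
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = make_schedule(config.duration_s, config.cover_dwell_range_s, rng)

    n = int(round(config.duration_s * config.sample_rate_hz))
    t = np.arange(n) / config.sample_rate_hz
    left_cov, right_cov = schedule.eye_masks(t)
    env_l, env_r = _deviation_envelopes(config, left_cov, right_cov)

    lpcx = np.full(n, config.baseline_lpcx)
    rpcx = np.full(n, config.baseline_rpcx)
    lpcy = np.full(n, config.baseline_y)
    rpcy = np.full(n, config.baseline_y)

    if config.condition == "exotropia":
        # outward drift: left eye toward smaller X, right eye toward larger X
        lpcx = lpcx - env_l
        rpcx = rpcx + env_r
    elif config.condition == "esotropia":
        lpcx = lpcx + env_l
        rpcx = rpcx - env_r
    elif config.condition == "hypertropia":
        lpcy = lpcy - env_l
        rpcy = rpcy - env_r

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, 4))
        lpcx = lpcx + noise[:, 0]
        lpcy = lpcy + noise[:, 1]
        rpcx = rpcx + noise[:, 2]
        rpcy = rpcy + noise[:, 3]

    valid = np.ones(n, dtype=bool)
    if config.invalid_frame_prob > 0:
        valid = rng.random(n) >= config.invalid_frame_prob
        coords = np.column_stack([lpcx, lpcy, rpcx, rpcy])
        last = 0
        for i in range(n):
            if valid[i]:
                last = i
            else:
                coords[i] = coords[last]  # tracker holds last valid sample
        lpcx, lpcy, rpcx, rpcy = coords.T

    flags = valid.astype(int)
    frames = pd.DataFrame(
        {
            "Timestamp": t,
            "LPCX": lpcx,
            "LPCY": lpcy,
            "RPCX": rpcx,
            "RPCY": rpcy,
            "LPV": flags,
            "RPV": flags,
        }
    )
    return GazeRecording(
        frames=frames,
        participant_id=participant_id,
        sample_index=sample_index,
        condition=config.condition,
        schedule=schedule,
        deviation_amplitude=config.deviation_amplitude,
    )


@dataclass(frozen=True)
class Cohort:
    """A labeled set of simulated recordings with a per-sample manifest."""

    recordings: tuple[GazeRecording, ...]
    manifest: pd.DataFrame = field(repr=False)

    @property
    def n_participants(self) -> int:
        return self.manifest["participant_id"].nunique()


def _default_amplitude(rng: np.random.Generator) -> float:
    """Per-participant deviation amplitude in normalized units.

    Uniform on [0.05, 0.15]: the clinical deviation range (roughly 10-45
    prism diopters) mapped onto the tracker's coordinate scale, and at least
    3x the default per-coordinate sensor noise.
    """
    return float(rng.uniform(0.05, 0.15))


def simulate_cohort(
    n_normal: int,
    n_exo: int,
    n_eso: int,
    n_hyper: int = 0,
    samples_per_participant_range: tuple[int, int] = (3, 7),
    amplitude_distribution: Callable[[np.random.Generator], float] | None = None,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
) -> Cohort:
    """Simulate a labeled participant cohort; deterministic given seed.

    Each participant receives a condition, a deviation amplitude drawn from
    ``amplitude_distribution`` (deviation conditions only), a jittered
    baseline geometry (interpupillary separation ~ N(0.385, 0.05)), and a
    sample count uniform on ``samples_per_participant_range``.
    """
    counts = {
        "normal": n_normal,
        "exotropia": n_exo,
        "esotropia": n_eso,
        "hypertropia": n_hyper,
    }
    if any(c < 0 for c in counts.values()):
        raise ConfigError("participant counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ConfigError("cohort must contain at least one participant")
    lo, hi = samples_per_participant_range
    if not (1 <= lo <= hi):
        raise ConfigError("samples_per_participant_range must satisfy 1 <= lo <= hi")
    if amplitude_distribution is None:
        amplitude_distribution = _default_amplitude
    template = base_config if base_config is not None else SimulationConfig()

    rng = np.random.default_rng(seed)
    recordings: list[GazeRecording] = []
    rows = []
    pid_no = 0
    for condition in ("normal", "exotropia", "esotropia", "hypertropia"):
        for _ in range(counts[condition]):
            pid_no += 1
            pid = f"P{pid_no:03d}"
            amp = 0.0 if condition == "normal" else amplitude_distribution(rng)
            base_l = 0.62 + rng.normal(0.0, 0.02)
            sep = max(0.2, rng.normal(0.385, 0.05))
            cfg = dataclasses.replace(
                template,
                condition=condition,
                deviation_amplitude=amp,
                baseline_lpcx=base_l,
                baseline_rpcx=base_l + sep,
            )
            n_samples = int(rng.integers(lo, hi + 1))
            for k in range(n_samples):
                rec_seed = int(rng.integers(0, 2**31 - 1))
                rec = simulate_recording(
                    cfg, seed=rec_seed, participant_id=pid, sample_index=k
                )
                recordings.append(rec)
                rows.append(
                    {
                        "participant_id": pid,
                        "sample_id": rec.sample_id,
                        "sample_index": k,
                        "condition": condition,
                        "amplitude": amp,
                        "n_frames": rec.n_frames,
                        "quality": rec.quality,
                    }
                )
    manifest = pd.DataFrame(rows)
    return Cohort(tuple(recordings), manifest)
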