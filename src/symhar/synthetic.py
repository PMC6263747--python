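"""Synthetic triaxial accelerometer streams with the structure of HAR data.

Harmonic-plus-noise model: each activity bout is, per axis, a constant gravity
component plus a sinusoid at the activity's characteristic frequency (with a
random per-bout phase and a small per-bout cadence jitter) plus white Gaussian
noise.  Periodic activities (walking, running) differ in dominant frequency
and amplitude; static postures differ in gravity orientation, and standing
additionally carries a small low-frequency postural sway so that posture pairs
remain distinguishable after window z-normalization removes constant offsets.

Generation is deterministic given the spec seed; every (user, class, bout)
triple draws from its own seeded stream, so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import COLUMNS, ParameterError, SignalFrame

__all__ = ["ActivitySpec", "SyntheticSpec", "default_spec", "generate_synthetic_har", "frame_to_instances"]


@dataclass(frozen=True)
class ActivitySpec:
    """One activity class: per-axis oscillation plus gravity offset and noise."""

    label: str
    freq_hz: tuple[float, float, float]
    amplitude: tuple[float, float, float]
    gravity: tuple[float, float, float]
    noise_sd: float
    freq_jitter: float = 0.05  # fractional per-bout cadence variability


@dataclass(frozen=True)
class SyntheticSpec:
    classes: tuple[ActivitySpec, ...]
    fs: float = 50.0
    seconds_per_bout: float = 5.0
    n_users: int = 10
    bouts_per_user_per_class: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.seconds_per_bout <= 0:
            raise ParameterError("fs and seconds_per_bout must be positive")
        if self.n_users < 1 or self.bouts_per_user_per_class < 1 or not self.classes:
            raise ParameterError("need >= 1 user, bout, and class")
        for cls in self.classes:
            if cls.noise_sd < 0:
                raise ParameterError(f"{cls.label}: noise sd must be >= 0")
            if max(cls.freq_hz) >= self.fs / 2:
                raise ParameterError(f"{cls.label}: frequency above Nyquist")

    @property
    def samples_per_bout(self) -> int:
        return int(round(self.fs * self.seconds_per_bout))


def default_spec(seed: int = 42, distinct_gravity_norms: bool = False) -> SyntheticSpec:
    """The default 4-class desk-scale spec: walk / run / sit / stand.

    Gravity-like offsets are unit-norm by default; ``distinct_gravity_norms``
    shrinks the sitting offset so the two static postures stay separable under
    magnitude fusion, which is blind to orientation.
    """
    sit_gravity = (0.0, -0.6, 0.0) if distinct_gravity_norms else (0.0, -1.0, 0.0)
    classes = (
        ActivitySpec("walk", (2.0, 2.0, 2.0), (0.4, 1.0, 0.4), (0.0, -1.0, 0.0), 0.10),
        ActivitySpec("run", (3.0, 3.0, 3.0), (0.8, 2.0, 0.8), (0.0, -1.0, 0.0), 0.15),
        ActivitySpec("sit", (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), sit_gravity, 0.03),
        ActivitySpec("stand", (0.8, 0.0, 0.8), (0.1, 0.0, 0.3), (0.0, 0.0, 1.0), 0.03),
    )
    return SyntheticSpec(classes=classes, seed=seed)


def _bout_signal(cls: ActivitySpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    jitter = 1.0 + cls.freq_jitter * rng.uniform(-1.0, 1.0)  # shared cadence jitter
    axes = []
    for axis in range(3):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        f = cls.freq_hz[axis] * jitter
        signal = cls.gravity[axis] + cls.amplitude[axis] * np.sin(2.0 * np.pi * f * t + phase)
        axes.append(signal + rng.normal(0.0, cls.noise_sd, size=n) if cls.noise_sd > 0 else signal)
    return np.column_stack(axes)


def generate_synthetic_har(spec: SyntheticSpec) -> SignalFrame:
    """Deterministic labeled multi-user stream laid out bout by bout.

    Sample count is exactly
    ``n_users * len(classes) * bouts_per_user_per_class * round(fs * seconds_per_bout)``.
    """
    n = spec.samples_per_bout
    frames = []
    for user in range(spec.n_users):
        offset = 0.0
        for ci, cls in enumerate(spec.classes):
            for bout in range(spec.bouts_per_user_per_class):
                rng = np.random.default_rng([spec.seed % (2**31), user, ci, bout])
                xyz = _bout_signal(cls, n, spec.fs, rng)
                frames.append(
                    pd.DataFrame(
                        {
                            "user": f"u{user:02d}",
                            "activity": cls.label,
                            "timestamp": offset + np.arange(n) / spec.fs,
                            "x": xyz[:, 0],
                            "y": xyz[:, 1],
                            "z": xyz[:, 2],
                        }
                    )
                )
                offset += n / spec.fs
    data = pd.concat(frames, ignore_index=True)[list(COLUMNS)]
    return SignalFrame(data, fs=spec.fs)


def frame_to_instances(
    frame: SignalFrame, samples_per_instance: int
) -> tuple[list[dict[str, np.ndarray]], list, list]:
    """Chunk contiguous same-label runs into classification instances.

    Returns parallel lists of ``{'x','y','z'}`` instances, labels, and users;
    trailing samples that do not fill an instance are dropped.
    """
    if samples_per_instance < 1:
        raise ParameterError("samples_per_instance must be >= 1")
    instances, labels, users = [], [], []
    df = frame.data
    run_id = (
        (df["activity"] != df["activity"].shift()) | (df["user"] != df["user"].shift())
    ).cumsum()
    for _, run in df.groupby(run_id, sort=False):
        n_full = len(run) // samples_per_instance
        for k in range(n_full):
            chunk = run.iloc[k * samples_per_instance : (k + 1) * samples_per_instance]
            instances.append(
                {
                    "x": chunk["x"].to_numpy(float),
                    "y": chunk["y"].to_numpy(float),
                    "z": chunk["z"].to_numpy(float),
                }
            )
            labels.append(chunk["activity"].iloc[0])
            users.append(chunk["user"].iloc[0])
    return instances, labels, users
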