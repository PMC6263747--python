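"""Sliding-window segmentation with overlap, per-window labeling, z-normalization.

Windows are half-open ``[start, start + w)`` with 0-based starts at multiples
of the stride ``round(w * (1 - overlap))``.  Each window is labeled either by
the most frequent sample label inside it (``majority``, ties broken by the
earliest sample in the window) or discarded when mixed (``strict``).

Normalization subtracts the window mean and divides by the population standard
deviation; windows whose deviation falls below ``sd_floor`` map to the all-zero
vector, so constant windows land in the breakpoint bin containing 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import InsufficientDataError, ParameterError, Segment

__all__ = ["WindowingConfig", "sliding_windows", "znormalize", "znormalize_segment"]

SD_FLOOR = 1e-8


@dataclass(frozen=True)
class WindowingConfig:
    window_samples: int
    overlap_fraction: float = 0.5
    label_policy: str = "majority"

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ParameterError("window_samples must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ParameterError("overlap_fraction must be in [0, 1)")
        if self.label_policy not in ("majority", "strict"):
            raise ParameterError("label_policy must be 'majority' or 'strict'")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")

    @property
    def stride(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))


def _majority_label(window_labels: np.ndarray):
    # most frequent label; ties broken by earliest occurrence in the window
    uniq, first, counts = np.unique(window_labels, return_index=True, return_counts=True)
    best = counts.max()
    candidates = first[counts == best]
    return window_labels[candidates.min()]


def sliding_windows(
    series: np.ndarray,
    cfg: WindowingConfig,
    labels: np.ndarray | None = None,
    axis_tag: str = "x",
) -> list[Segment]:
    """Cut one axis into overlapping fixed-length labeled segments."""
    series = np.asarray(series, dtype=float)
    n, w = len(series), cfg.window_samples
    if n < w:
        raise InsufficientDataError(f"series length {n} < window {w}")
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ParameterError("labels must align with the series")
    segments = []
    for start in range(0, n - w + 1, cfg.stride):
        label = None
        if labels is not None:
            win = labels[start : start + w]
            if cfg.label_policy == "strict":
                if len(np.unique(win)) > 1:
                    continue
                label = win[0]
            else:
                label = _majority_label(win)
        segments.append(
            Segment(series[start : start + w], label=label, axis_tag=axis_tag, start_index=start)
        )
    return segments


def znormalize(values: np.ndarray, sd_floor: float = SD_FLOOR) -> np.ndarray:
    """Center and scale to zero mean / unit population deviation.

    Near-constant input (population sd below ``sd_floor``) returns zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot normalize an empty vector")
    sd = float(values.std())  # population sd
    if sd < sd_floor:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def znormalize_segment(segment: Segment, sd_floor: float = SD_FLOOR) -> Segment:
    return Segment(
        znormalize(segment.values, sd_floor),
        label=segment.label,
        axis_tag=segment.axis_tag,
        start_index=segment.start_index,
    )
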