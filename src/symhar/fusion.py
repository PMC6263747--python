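"""Strategies for feeding triaxial signals to one-dimensional symbolic methods.

* ``stack``     — keep the three axes as synchronized parallel channels; words
  are computed per axis with the same window size and axis-tagged, and the
  instance histogram is the sum of the three per-axis histograms.
* ``magnitude`` — collapse to the Euclidean norm ``sqrt(x^2 + y^2 + z^2)``,
  which is rotation-invariant but blind to gravity orientation.
* ``pca``       — project onto the leading eigenvector of the 3x3 covariance
  of the training samples (fit on training folds only, never on test data).
"""

from __future__ import annotations

import numpy as np

from .data_model import ParameterError

__all__ = [
    "stack_axes",
    "fuse_magnitude",
    "PCAFusion",
    "make_fusion",
    "FUSION_STRATEGIES",
]


def _aligned(x, y, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not len(x) == len(y) == len(z):
        raise ParameterError("axis vectors must have equal length")
    return x, y, z


def stack_axes(x, y, z) -> np.ndarray:
    """Concatenate synchronized equal-length axis segments into one row."""
    return np.concatenate(_aligned(x, y, z))


def fuse_magnitude(x, y, z) -> np.ndarray:
    """Elementwise Euclidean norm of the axis triple."""
    x, y, z = _aligned(x, y, z)
    return np.sqrt(x**2 + y**2 + z**2)


class PCAFusion:
    """Leading-principal-component projection of the (x, y, z) sample cloud.

    Fit on training data only; the sign is fixed by forcing the loading of
    largest magnitude to be nonnegative so the projection is deterministic.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.component_: np.ndarray | None = None
        self.eigenvalues_: np.ndarray | None = None

    def fit(self, instances: list[dict[str, np.ndarray]]) -> "PCAFusion":
        samples = np.concatenate(
            [np.column_stack([inst["x"], inst["y"], inst["z"]]) for inst in instances]
        )
        if len(samples) < 2:
            raise ParameterError("PCA fusion needs >= 2 training samples")
        self.mean_ = samples.mean(axis=0)
        cov = np.cov(samples.T)
        if not np.any(cov > 0):
            raise ParameterError("zero-variance training data")
        eigvals, eigvecs = np.linalg.eigh(cov)
        component = eigvecs[:, -1]
        if component[np.argmax(np.abs(component))] < 0:
            component = -component
        self.component_ = component
        self.eigenvalues_ = eigvals[::-1]
        return self

    def transform(self, instance: dict[str, np.ndarray]) -> np.ndarray:
        if self.component_ is None:
            raise ParameterError("PCAFusion is not fitted")
        samples = np.column_stack([instance["x"], instance["y"], instance["z"]])
        return (samples - self.mean_) @ self.component_


class _StackFusion:
    def fit(self, instances):
        return self

    def transform(self, instance):
        return dict(instance)


class _MagnitudeFusion:
    def fit(self, instances):
        return self

    def transform(self, instance):
        return {"mag": fuse_magnitude(instance["x"], instance["y"], instance["z"])}


class _PCAInstanceFusion:
    def __init__(self) -> None:
        self.pca = PCAFusion()

    def fit(self, instances):
        self.pca.fit(instances)
        return self

    def transform(self, instance):
        return {"pc1": self.pca.transform(instance)}


FUSION_STRATEGIES = ("stack", "magnitude", "pca")


def make_fusion(strategy: str):
    """Uniform fit/transform adapter mapping xyz instances to classifier input."""
    if strategy == "stack":
        return _StackFusion()
    if strategy == "magnitude":
        return _MagnitudeFusion()
    if strategy == "pca":
        return _PCAInstanceFusion()
    raise ParameterError(f"unknown fusion strategy {strategy!r}")
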