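"""Bags of patch features: the basic MIL data unit.

A whole-slide image, after tiling and feature extraction, becomes a *bag*
of instances: an ``n x d1`` matrix of patch embeddings plus the ``n x 2``
pixel coordinates (x, y; 0-based, top-left origin at level 0) of each
patch, and an optional slide-level binary label. Instance-level labels
are never available (weak supervision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["FeatureBag", "DEFAULT_PATCH_SIZE"]

DEFAULT_PATCH_SIZE = 256


@dataclass
class FeatureBag:
    """One slide's instances and metadata.

    Parameters
    ----------
    bag_id:
        Unique slide identifier.
    features:
        ``(n, d1)`` float array of instance embeddings.
    coords:
        ``(n, 2)`` integer array of patch top-left pixel coordinates,
        x before y, unique within the bag.
    label:
        Slide-level binary label (1 = positive) or ``None`` if unknown.
    patch_size:
        Patch edge length in pixels at level 0.
    """

    bag_id: str
    features: np.ndarray
    coords: np.ndarray
    label: int | None = None
    patch_size: int = DEFAULT_PATCH_SIZE
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.validate()

    # properties ---------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def d1(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        """Raise :class:`DataError` naming the offending field."""
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise DataError("features: expected a non-empty 2-D matrix")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataError("coords: expected an (n, 2) integer matrix")
        if self.features.shape[0] != self.coords.shape[0]:
            raise DataError(
                f"coords: row count {self.coords.shape[0]} does not match "
                f"features row count {self.features.shape[0]}"
            )
        if not np.isfinite(self.features).all():
            raise DataError("features: non-finite values present")
        if len(np.unique(self.coords, axis=0)) != self.coords.shape[0]:
            raise DataError("coords: duplicate patch coordinates within the bag")
        if self.label is not None and self.label not in (0, 1):
            raise DataError("label: must be 0, 1 or None")

    def subset(self, indices: np.ndarray, bag_id: str | None = None) -> "FeatureBag":
        """New bag keeping `indices` (features and coords stay aligned)."""
        indices = np.asarray(indices, dtype=np.int64)
        return FeatureBag(
            bag_id=bag_id or self.bag_id,
            features=self.features[indices],
            coords=self.coords[indices],
            label=self.label,
            patch_size=self.patch_size,
        )
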